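"""Synthetic gene-family bundles and PCR matrices with known ground truth.

Families are simulated by evolving a random ancestral protein down a species
tree with i.i.d. per-site amino-acid substitutions, back-translating each
tip with uniform synonymous codon choice, and planting introns at chosen CDS
positions (optionally with per-lineage loss and whole-codon positional
jitter).  Duplications are planted by doubling a subtree's genes.  The
simulations are deliberately indel-free: gap handling is exercised by
hand-built alignments in the test-suite, while these generators provide
seed-deterministic ground truth for intron recovery, duplication calling,
conservation scoring and primer containment.

The module also ships the packaged PCR screening matrix of the reference
intron x genus survey (52 introns, 12 genera) as :func:`table1_fixture`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from epicfinder.model import (
    Alignment,
    ExonStructure,
    GeneFamilyBundle,
    GeneTree,
    SequenceRecord,
    TaxonomyMap,
)
from epicfinder.pcr import CATEGORIES, PcrResultMatrix

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# amino acids with 1- or 2-fold codon degeneracy, used for the conserved
# low-degeneracy exon blocks that flank planted introns (EPIC candidate
# regions are selected precisely for such blocks)
LOW_DEGENERACY_AAS = "CDEFHKMNQWY"

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}

# clade layout of the packaged screening matrix
GENUS_CLADES: Dict[str, str] = {
    "Paracentrotus": "echinoderm", "Amphipholis": "echinoderm",
    "Echinocardium": "echinoderm", "Abatus": "echinoderm",
    "Sterechinus": "echinoderm",
    "Corella": "ascidian", "Perophora": "ascidian", "Styela": "ascidian",
    "Macoma": "bivalve", "Cerastoderma": "bivalve",
    "Corallium": "cnidarian", "Paramuricea": "cnidarian",
}
BILATERIAN_GENERA = [g for g, c in GENUS_CLADES.items() if c != "cnidarian"]


@dataclass
class IntronPlan:
    """One planted intron: CDS position of the last exonic base before it."""

    cds_position: int
    retention: float = 1.0  # per-species probability of keeping the intron
    jitter: int = 0  # max positional shift, nt (applied in whole codons)

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must be in [0,1]")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass
class FamilySimSpec:
    species: List[str]
    clades: Dict[str, str]
    required_clades: List[str] = field(default_factory=list)
    n_codons: int = 120
    substitution_rate: float = 0.05  # per-site P(substitution) per branch
    flank_codons: int = 6  # invariant low-degeneracy codons on each side of an intron
    introns: List[IntronPlan] = field(default_factory=list)
    duplicate_species: List[str] = field(default_factory=list)
    duplicate_root: bool = False
    seed: int = 0


@dataclass
class FamilyGroundTruth:
    intron_columns: List[int]  # consensus (un-jittered) codon-alignment columns
    intron_phases: List[int]
    per_gene_sites: Dict[str, List[Tuple[int, int]]]  # gene -> [(column, phase)]
    duplication_species: List[str]
    codon_alignment: Dict[str, str]


def _evolve_protein(
    ancestor: str, rate: float, frozen: set, rng: np.random.Generator
) -> str:
    out = []
    for i, aa in enumerate(ancestor):
        if i not in frozen and rng.random() < rate:
            out.append(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
        else:
            out.append(aa)
    return "".join(out)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    )


def simulate_family(spec: FamilySimSpec) -> Tuple[GeneFamilyBundle, FamilyGroundTruth]:
    """Simulate one bundle plus its ground-truth record.

    The bundle always passes translation validation; the codon alignment
    recovered by threading equals the generator's stored one; planted intron
    columns/phases (and the jittered per-gene variants) are recorded.
    """
    rng = np.random.default_rng(spec.seed)
    n_nt = 3 * spec.n_codons
    for plan in spec.introns:
        if not 1 <= plan.cds_position < n_nt:
            raise ValueError(
                f"intron CDS position {plan.cds_position} outside 1..{n_nt - 1}"
            )

    ancestor = list(
        AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))] for _ in range(spec.n_codons)
    )
    # EPIC candidates sit in conserved low-degeneracy exon blocks; emulate
    # that by freezing the codons flanking each planted intron and drawing
    # them from 1-/2-fold-degenerate amino acids
    frozen: set = set()
    for plan in spec.introns:
        codon_idx = (plan.cds_position - 1) // 3  # 0-based codon holding the junction
        lo = max(0, codon_idx - spec.flank_codons)
        hi = min(spec.n_codons - 1, codon_idx + 1 + spec.flank_codons)
        for i in range(lo, hi + 1):
            ancestor[i] = LOW_DEGENERACY_AAS[rng.integers(len(LOW_DEGENERACY_AAS))]
            frozen.add(i)
    ancestor = "".join(ancestor)

    genes: List[Tuple[str, str]] = []  # (gene_id, species)
    for sp in spec.species:
        copies = 2 if (spec.duplicate_root or sp in spec.duplicate_species) else 1
        for k in range(1, copies + 1):
            genes.append((f"{sp}_g{k}", sp))

    prot_records, cds_records, structures = [], [], {}
    per_gene_sites: Dict[str, List[Tuple[int, int]]] = {}
    codon_alignment: Dict[str, str] = {}
    for gene_id, sp in genes:
        protein = _evolve_protein(ancestor, spec.substitution_rate, frozen, rng)
        cds = _back_translate(protein, rng)
        prot_records.append(
            SequenceRecord(id=gene_id, species=sp, residues=protein, kind="protein")
        )
        cds_records.append(
            SequenceRecord(id=gene_id, species=sp, residues=cds, kind="nucleotide")
        )
        codon_alignment[gene_id] = cds

        junctions: List[int] = []
        sites: List[Tuple[int, int]] = []
        for plan in spec.introns:
            if rng.random() >= plan.retention:
                continue
            shift_codons = (
                rng.integers(-(plan.jitter // 3), plan.jitter // 3 + 1)
                if plan.jitter >= 3
                else 0
            )
            pos = plan.cds_position + 3 * int(shift_codons)
            pos = max(1, min(n_nt - 1, pos))
            junctions.append(pos)
            sites.append((pos, pos % 3))
        junctions = sorted(set(junctions))
        per_gene_sites[gene_id] = sorted(set(sites))
        bounds = junctions + [n_nt]
        exons, prev = [], 0
        for b in bounds:
            exons.append((prev + 1, b))
            prev = b
        structures[gene_id] = ExonStructure(species=sp, gene_id=gene_id, exons=exons)

    newick = _family_newick(spec, genes)
    tree = GeneTree.from_newick(newick, {g: s for g, s in genes})
    taxonomy = TaxonomyMap(
        species_to_clade=dict(spec.clades),
        required_clades=list(spec.required_clades),
    )
    bundle = GeneFamilyBundle(
        family_id=f"sim{spec.seed}",
        proteins=Alignment(kind="protein", records=prot_records),
        cds={r.id: r for r in cds_records},
        exon_structures=structures,
        tree=tree,
        taxonomy=taxonomy,
    )
    truth = FamilyGroundTruth(
        intron_columns=[p.cds_position for p in spec.introns],
        intron_phases=[p.cds_position % 3 for p in spec.introns],
        per_gene_sites=per_gene_sites,
        duplication_species=(
            list(spec.species) if spec.duplicate_root else list(spec.duplicate_species)
        ),
        codon_alignment=codon_alignment,
    )
    return bundle, truth


def _family_newick(spec: FamilySimSpec, genes: List[Tuple[str, str]]) -> str:
    """Ladder species tree; duplicated species (or a duplicated root) become
    cherries of their two gene copies."""
    by_species: Dict[str, List[str]] = {}
    for gid, sp in genes:
        by_species.setdefault(sp, []).append(gid)

    if spec.duplicate_root:
        def ladder(copy: int) -> str:
            tips = [by_species[sp][copy] for sp in spec.species]
            t = tips[0]
            for tip in tips[1:]:
                t = f"({t},{tip})"
            return t

        return f"({ladder(0)},{ladder(1)});"

    def tip(sp: str) -> str:
        ids = by_species[sp]
        return ids[0] if len(ids) == 1 else "(" + ",".join(ids) + ")"

    t = tip(spec.species[0])
    for sp in spec.species[1:]:
        t = f"({t},{tip(sp)})"
    return t + ";"


def random_gene_tree(
    species: Sequence[str],
    duplicate_species: Sequence[str] = (),
    duplicate_root: bool = False,
    seed: int = 0,
) -> Tuple[GeneTree, List[str]]:
    """Random rooted gene tree with planted duplications; returns the tree
    and the set of species under a duplication (the ground truth)."""
    rng = np.random.default_rng(seed)
    genes = []
    for sp in species:
        n = 2 if (duplicate_root or sp in duplicate_species) else 1
        genes.extend((f"{sp}_g{k}", sp) for k in range(1, n + 1))

    if duplicate_root:
        half1 = [f"{sp}_g1" for sp in species]
        half2 = [f"{sp}_g2" for sp in species]
        newick = f"({_random_subtree(half1, rng)},{_random_subtree(half2, rng)});"
        truth = list(species)
    else:
        tips = []
        for sp in species:
            ids = [g for g, s in genes if s == sp]
            tips.append(ids[0] if len(ids) == 1 else "(" + ",".join(ids) + ")")
        newick = _random_subtree(tips, rng) + ";"
        truth = list(duplicate_species)
    return GeneTree.from_newick(newick, dict(genes)), truth


def _random_subtree(tips: List[str], rng: np.random.Generator) -> str:
    nodes = list(tips)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0]


# ---------------------------------------------------------------------------
# PCR matrices
# ---------------------------------------------------------------------------


def simulate_pcr_matrix(
    n_introns: int,
    genera: Sequence[str],
    category_probs: Optional[Dict[str, float]] = None,
    seed: int = 0,
) -> Tuple[PcrResultMatrix, Dict[str, Dict[str, int]]]:
    """Random category matrix plus the true per-genus counts."""
    import pandas as pd

    probs = category_probs or {"null": 0.45, "A": 0.06, "I": 0.26, "P": 0.23}
    cats = list(CATEGORIES)
    p = np.array([probs.get(c, 0.0) for c in cats], dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("category probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    cells = rng.choice(cats, size=(n_introns, len(genera)), p=p)
    df = pd.DataFrame(
        cells,
        index=[str(i + 1) for i in range(n_introns)],
        columns=list(genera),
    )
    matrix = PcrResultMatrix(data=df)
    truth = {
        g: {c: int((df[g] == c).sum()) for c in cats} for g in genera
    }
    return matrix, truth


def table1_fixture() -> PcrResultMatrix:
    """The packaged intron x genus screening matrix (52 introns, 12 genera).

    Cnidarian loci not surveyed are ``na``; introns 2 and 22 (the same
    intron recovered twice) form the single merge group.
    """
    ref = importlib.resources.files("epicfinder") / "data" / "table1.tsv"
    with importlib.resources.as_file(ref) as path:
        return PcrResultMatrix.from_tsv(path)
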