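"""Core domain types and bundle I/O.

A *gene family bundle* is the unit of work: one orthologous gene family with
its protein multiple alignment, the matching coding sequences, per-gene
exon/intron structures (in CDS coordinates), a rooted gene tree, and a
species-to-clade taxonomy map.  All coordinates are 1-based inclusive; the
only gap symbol accepted is ``'-'``.

On disk a bundle is a directory::

    proteins.fasta   aligned proteins, headers ``>gene_id species=Name``
    cds.fasta        unaligned CDS, same ids
    exons.gff3       one ``exon`` feature per exon, CDS coordinates
    tree.nwk         rooted Newick, leaf labels = gene ids
    taxonomy.tsv     species<TAB>clade, with a ``# required_clades:`` pragma
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

GAP = "-"
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZJUOX*" + GAP)
_NUCLEOTIDE_ALPHABET = set("ACGTN" + GAP)


class BundleError(Exception):
    """Base error for bundle construction and I/O."""


class ConsistencyError(BundleError):
    """Cross-file inconsistency (an id present in one file but not another)."""


class StructuralError(BundleError):
    """A sequence or exon structure violates a structural invariant."""


@dataclass
class SequenceRecord:
    """One (possibly aligned) sequence.

    Parameters
    ----------
    id : str
        Gene identifier, unique within a bundle.
    species : str
        Species the gene belongs to.
    residues : str
        One-letter residues; ``'-'`` is the only gap symbol.
    kind : {"protein", "nucleotide"}
    """

    id: str
    species: str
    residues: str
    kind: str = "protein"

    def __post_init__(self) -> None:
        if not self.residues:
            raise StructuralError(f"record {self.id}: empty residues")
        if "." in self.residues:
            raise StructuralError(
                f"record {self.id}: gap symbol '.' not accepted; use '-'"
            )
        alphabet = (
            _PROTEIN_ALPHABET if self.kind == "protein" else _NUCLEOTIDE_ALPHABET
        )
        bad = set(self.residues.upper()) - alphabet
        if bad:
            raise StructuralError(
                f"record {self.id}: symbols {sorted(bad)} not in {self.kind} alphabet"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class Alignment:
    """A multiple alignment of equal-length :class:`SequenceRecord` rows."""

    kind: str
    records: List[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise StructuralError("alignment needs >=2 records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise StructuralError(f"ragged alignment: lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    def record(self, record_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, in record order."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} outside 1..{self.n_columns}")
        return "".join(r.residues[col - 1] for r in self.records)


@dataclass
class ExonStructure:
    """Exon intervals of one gene, in CDS coordinates (1-based, inclusive).

    Intervals must tile the CDS: ascending, non-overlapping, no gaps, and
    their total length equals the CDS length.
    """

    species: str
    gene_id: str
    exons: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise StructuralError(f"{self.gene_id}: no exons")
        prev_end = 0
        for start, end in self.exons:
            if start != prev_end + 1 or end < start:
                raise StructuralError(
                    f"{self.gene_id}: exons must tile the CDS; "
                    f"got interval ({start},{end}) after end {prev_end}"
                )
            prev_end = end

    @property
    def cds_length(self) -> int:
        return self.exons[-1][1]

    @property
    def junctions(self) -> List[int]:
        """CDS positions of the last exonic base before each intron."""
        return [end for start, end in self.exons[:-1]]


@dataclass
class TaxonomyMap:
    """Species -> clade mapping plus the ordered list of required clades."""

    species_to_clade: Dict[str, str]
    required_clades: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.required_clades)) != len(self.required_clades):
            raise StructuralError("duplicate required clade labels")

    def clade_of(self, species: str) -> str:
        try:
            return self.species_to_clade[species]
        except KeyError:
            raise KeyError(f"species {species!r} missing from taxonomy map")

    def species_in(self, clade: str) -> List[str]:
        return sorted(
            s for s, c in self.species_to_clade.items() if c == clade
        )


@dataclass
class HomologyHit:
    """One homology-search hit (e.g. a tblastn row) against a subject."""

    query_id: str
    subject_id: str
    e_value: float
    similarity: float

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.e_value) or self.e_value < 0:
            raise ValueError(f"e-value must be finite and >=0, got {self.e_value}")
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError(f"similarity must be in [0,1], got {self.similarity}")


class GeneTree:
    """A rooted gene tree whose leaves are genes, each mapped to a species.

    Wraps a :class:`dendropy.Tree`.  Duplication flags are attached to
    internal nodes by :func:`epicfinder.filtering.infer_duplications` and are
    serialised as NHX ``[&&NHX:D=Y]`` comments on write.
    """

    def __init__(self, tree: dendropy.Tree, species: Dict[str, str]):
        self.tree = tree
        self.species = dict(species)
        for leaf in tree.leaf_node_iter():
            gid = leaf.taxon.label
            if gid not in self.species:
                raise ConsistencyError(f"leaf {gid!r} has no species mapping")

    @classmethod
    def from_newick(cls, newick: str, species: Dict[str, str]) -> "GeneTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        tree.is_rooted = True
        return cls(tree, species)

    def leaf_gene_ids(self, node: Optional[dendropy.Node] = None) -> List[str]:
        node = node or self.tree.seed_node
        return [lf.taxon.label for lf in node.leaf_iter()]

    def leaf_species(self, node: Optional[dendropy.Node] = None) -> set:
        return {self.species[g] for g in self.leaf_gene_ids(node)}

    def mrca(self, gene_ids: Sequence[str]) -> dendropy.Node:
        taxa = [
            t for t in self.tree.taxon_namespace if t.label in set(gene_ids)
        ]
        return self.tree.mrca(taxa=taxa)

    def to_newick(self) -> str:
        parts = self._newick_node(self.tree.seed_node)
        return parts + ";"

    def _newick_node(self, node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        inner = ",".join(self._newick_node(c) for c in node.child_nodes())
        dup = getattr(node, "duplication", None)
        nhx = ""
        if dup is not None:
            nhx = "[&&NHX:D={}]".format("Y" if dup.duplicated else "N")
        return f"({inner}){nhx}"


@dataclass
class GeneFamilyBundle:
    """All inputs for one candidate gene family, cross-referenced."""

    family_id: str
    proteins: Alignment
    cds: Dict[str, SequenceRecord]
    exon_structures: Dict[str, ExonStructure]
    tree: GeneTree
    taxonomy: TaxonomyMap
    translation_validated: bool = False

    def __post_init__(self) -> None:
        prot_ids = {r.id for r in self.proteins.records}
        for name, ids in (
            ("CDS", set(self.cds)),
            ("exon structure", set(self.exon_structures)),
        ):
            missing = sorted(prot_ids - ids)
            if missing:
                raise ConsistencyError(
                    f"{name} missing for record(s): {', '.join(missing)}"
                )
        tree_ids = set(self.tree.leaf_gene_ids())
        missing = sorted(prot_ids - tree_ids)
        if missing:
            raise ConsistencyError(
                f"tree leaf missing for record(s): {', '.join(missing)}"
            )
        for r in self.proteins.records:
            self.taxonomy.clade_of(r.species)

    @property
    def gene_ids(self) -> List[str]:
        return [r.id for r in self.proteins.records]

    def species_of(self, gene_id: str) -> str:
        return self.proteins.record(gene_id).species


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_SPECIES_RE = re.compile(r"species=(\S+)")


def read_fasta_records(path: Path, kind: str) -> List[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _SPECIES_RE.search(rec.description)
        species = m.group(1) if m else ""
        records.append(
            SequenceRecord(
                id=rec.id, species=species, residues=str(rec.seq).upper(), kind=kind
            )
        )
    if not records:
        raise BundleError(f"no FASTA records in {path}")
    return records


def write_fasta_records(records: Iterable[SequenceRecord], path: Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=f"species={r.species}")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3 exon structures (CDS-coordinate dialect)
# ---------------------------------------------------------------------------

_GFF_PRAGMA = "##coordinate-system CDS 1-based"


def read_exon_gff3(path: Path) -> Dict[str, ExonStructure]:
    """Read exon features keyed by gene id.

    The dialect is deliberately narrow: ``seqid`` is the gene id, coordinates
    are CDS-based (strand is meaningless and written ``+``), and only ``exon``
    features are considered.
    """
    per_gene: Dict[str, List[Tuple[int, int]]] = {}
    species: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise BundleError(f"{path}: malformed GFF3 line: {line!r}")
            seqid, _, ftype, start, end = cols[0], cols[1], cols[2], cols[3], cols[4]
            if ftype != "exon":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            per_gene.setdefault(seqid, []).append((int(start), int(end)))
            if "species" in attrs:
                species[seqid] = attrs["species"]
    return {
        gid: ExonStructure(
            species=species.get(gid, ""), gene_id=gid, exons=sorted(ivs)
        )
        for gid, ivs in per_gene.items()
    }


def write_exon_gff3(structures: Iterable[ExonStructure], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_GFF_PRAGMA + "\n")
        for st in structures:
            for i, (start, end) in enumerate(st.exons, 1):
                attrs = f"ID=exon:{st.gene_id}.{i};species={st.species}"
                fh.write(
                    "\t".join(
                        [
                            st.gene_id,
                            "epicfinder",
                            "exon",
                            str(start),
                            str(end),
                            ".",
                            "+",
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Taxonomy TSV
# ---------------------------------------------------------------------------


def read_taxonomy(path: Path) -> TaxonomyMap:
    mapping: Dict[str, str] = {}
    required: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# required_clades:"):
                required = [
                    c.strip()
                    for c in line.split(":", 1)[1].split(",")
                    if c.strip()
                ]
                continue
            if not line or line.startswith("#") or line.startswith("species\t"):
                continue
            species, clade = line.split("\t")[:2]
            mapping[species] = clade
    return TaxonomyMap(species_to_clade=mapping, required_clades=required)


def write_taxonomy(taxonomy: TaxonomyMap, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# required_clades: " + ",".join(taxonomy.required_clades) + "\n")
        fh.write("species\tclade\n")
        for species in sorted(taxonomy.species_to_clade):
            fh.write(f"{species}\t{taxonomy.species_to_clade[species]}\n")


# ---------------------------------------------------------------------------
# Homology-hit TSV
# ---------------------------------------------------------------------------


def read_hit_table(path: Path) -> List[HomologyHit]:
    """Read a TSV with columns query_id, subject_id, e_value, similarity."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            HomologyHit(
                query_id=str(row.query_id),
                subject_id=str(row.subject_id),
                e_value=float(row.e_value),
                similarity=float(row.similarity),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_BUNDLE_FILES = {
    "proteins": "proteins.fasta",
    "cds": "cds.fasta",
    "exons": "exons.gff3",
    "tree": "tree.nwk",
    "taxonomy": "taxonomy.tsv",
}


def read_family_bundle(directory: Path, family_id: Optional[str] = None) -> GeneFamilyBundle:
    """Load a bundle directory; raise on missing files or dangling ids."""
    directory = Path(directory)
    paths = {k: directory / v for k, v in _BUNDLE_FILES.items()}
    for key, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"bundle file missing: {p}")
    proteins = Alignment(kind="protein", records=read_fasta_records(paths["proteins"], "protein"))
    cds_records = {
        r.id: r for r in read_fasta_records(paths["cds"], "nucleotide")
    }
    exon_structures = read_exon_gff3(paths["exons"])
    taxonomy = read_taxonomy(paths["taxonomy"])
    species = {r.id: r.species for r in proteins.records}
    tree = GeneTree.from_newick(paths["tree"].read_text(), species)
    return GeneFamilyBundle(
        family_id=family_id or directory.name,
        proteins=proteins,
        cds=cds_records,
        exon_structures=exon_structures,
        tree=tree,
        taxonomy=taxonomy,
    )


def write_family_bundle(bundle: GeneFamilyBundle, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta_records(bundle.proteins.records, directory / "proteins.fasta")
    write_fasta_records(
        [bundle.cds[g] for g in bundle.gene_ids], directory / "cds.fasta"
    )
    write_exon_gff3(
        [bundle.exon_structures[g] for g in bundle.gene_ids],
        directory / "exons.gff3",
    )
    (directory / "tree.nwk").write_text(bundle.tree.to_newick() + "\n")
    write_taxonomy(bundle.taxonomy, directory / "taxonomy.tsv")


# ---------------------------------------------------------------------------
# Translation validation and codon threading
# ---------------------------------------------------------------------------


@dataclass
class TranslationReport:
    """Mismatching amino-acid positions per record (1-based; empty = clean)."""

    mismatches: Dict[str, List[int]]

    @property
    def ok(self) -> bool:
        return not any(self.mismatches.values())


def _translate_cds(cds: str, table_id: int) -> str:
    if len(cds) % 3 != 0:
        raise StructuralError(
            f"CDS length {len(cds)} not divisible by 3"
        )
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in table.stop_codons:
            aas.append("*")
        else:
            aas.append(table.forward_table[codon])
    return "".join(aas)


def validate_translation(bundle: GeneFamilyBundle, table_id: int = 1) -> TranslationReport:
    """Check that each ungapped CDS translates to its ungapped protein.

    ``N``-containing codons translate as ``X`` and match any amino acid; a
    terminal stop codon on the CDS is ignored.  A clean report marks the
    bundle as validated, unlocking :func:`thread_codon_alignment`.
    """
    mismatches: Dict[str, List[int]] = {}
    for rec in bundle.proteins.records:
        prot = rec.ungapped.upper()
        cds = bundle.cds[rec.id].ungapped.upper()
        aa = _translate_cds(cds, table_id)
        if aa.endswith("*") and len(aa) == len(prot) + 1:
            aa = aa[:-1]
        if len(aa) != len(prot):
            mismatches[rec.id] = list(range(1, max(len(aa), len(prot)) + 1))
            continue
        bad = [
            i + 1
            for i, (a, p) in enumerate(zip(aa, prot))
            if a != p and a != "X" and p != "X"
        ]
        mismatches[rec.id] = bad
    report = TranslationReport(mismatches=mismatches)
    if report.ok:
        bundle.translation_validated = True
    return report


def thread_codon_alignment(bundle: GeneFamilyBundle) -> Alignment:
    """Thread each CDS through the protein alignment (PAL2NAL-style).

    Every protein column becomes a codon triplet; a protein gap becomes
    ``---``.  Output length is exactly 3x the protein alignment length, and
    removing gaps from any output row recovers that record's CDS (minus a
    terminal stop, if annotated).
    """
    if not bundle.translation_validated:
        raise StructuralError(
            "bundle not translation-validated; run validate_translation first"
        )
    out = []
    for rec in bundle.proteins.records:
        cds = bundle.cds[rec.id].ungapped.upper()
        n_aa = len(rec.ungapped)
        if len(cds) == 3 * (n_aa + 1):  # trailing stop codon
            cds = cds[: 3 * n_aa]
        row = []
        k = 0
        for ch in rec.residues:
            if ch == GAP:
                row.append("---")
            else:
                row.append(cds[k : k + 3])
                k += 3
        out.append(
            SequenceRecord(
                id=rec.id, species=rec.species, residues="".join(row), kind="nucleotide"
            )
        )
    return Alignment(kind="nucleotide", records=out)
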