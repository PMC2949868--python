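"""Intron position/phase mapping on codon alignments, and positional
conservation across species.

An intron is addressed by the codon-alignment nucleotide column of the last
exonic base 5' of it; its phase is the junction's CDS offset mod 3 (0 =
between codons, 1/2 = inside a codon).  Sites are grouped either strictly
(identical column and phase) or with a small positional tolerance, because
usable EPIC loci may shift by a few nucleotides between phyla.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median_low
from typing import Dict, List, Optional, Sequence, Tuple

from epicfinder.model import Alignment, GeneFamilyBundle, TaxonomyMap

GAP = "-"


@dataclass
class IntronSite:
    """One intron of one gene, located on the codon alignment."""

    gene_id: str
    species: str
    column: int  # nucleotide column immediately 5' of the intron (1-based)
    phase: int  # 0, 1 or 2
    intron_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0/1/2, got {self.phase}")
        if self.intron_length is not None and self.intron_length < 0:
            raise ValueError("intron length must be >=0")


@dataclass
class IntronCluster:
    """A set of sites judged to be the same intron position."""

    cluster_id: str
    sites: List[IntronSite]
    consensus_column: int
    phase: int
    presence: Dict[str, float] = field(default_factory=dict)

    @property
    def span(self) -> int:
        cols = [s.column for s in self.sites]
        return max(cols) - min(cols)

    @property
    def species(self) -> set:
        return {s.species for s in self.sites}


def map_introns(bundle: GeneFamilyBundle, codon_alignment: Alignment) -> List[IntronSite]:
    """Emit one :class:`IntronSite` per inter-exon junction of each gene.

    For a gene with *k* exons this yields *k − 1* sites.  The alignment
    column is found by walking the gene's threaded row and counting non-gap
    bases up to the junction's CDS position; landing on a gap column is
    impossible for correctly threaded input and raises.
    """
    sites: List[IntronSite] = []
    for rec in codon_alignment.records:
        structure = bundle.exon_structures[rec.id]
        junctions = structure.junctions
        if not junctions:
            continue
        wanted = set(junctions)
        col_of: Dict[int, int] = {}
        k = 0
        for col, ch in enumerate(rec.residues, start=1):
            if ch != GAP:
                k += 1
                if k in wanted:
                    col_of[k] = col
        for j in junctions:
            if j not in col_of:
                raise RuntimeError(
                    f"{rec.id}: junction at CDS {j} beyond threaded row "
                    "(corrupt exon structure or threading)"
                )
            sites.append(
                IntronSite(
                    gene_id=rec.id,
                    species=rec.species,
                    column=col_of[j],
                    phase=j % 3,
                )
            )
    return sites


def cluster_introns(
    sites: Sequence[IntronSite],
    mode: str = "strict",
    tolerance: int = 0,
    taxonomy: Optional[TaxonomyMap] = None,
    all_species: Optional[Dict[str, List[str]]] = None,
) -> List[IntronCluster]:
    """Group sites into putative homologous intron positions.

    strict
        sites cluster iff identical column AND phase.
    relaxed
        single-linkage on column distance <= ``tolerance``, within equal
        phase only.

    Consensus column is the member-column median (ties -> smaller).  If
    ``taxonomy`` is given, ``presence[clade]`` is the fraction of that
    clade's species (restricted to ``all_species[clade]`` when provided,
    else all mapped species of the clade) carrying a member site.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")

    groups: List[List[IntronSite]] = []
    if mode == "strict":
        keyed: Dict[Tuple[int, int], List[IntronSite]] = {}
        for s in sites:
            keyed.setdefault((s.column, s.phase), []).append(s)
        groups = [keyed[k] for k in sorted(keyed)]
    else:
        by_phase: Dict[int, List[IntronSite]] = {}
        for s in sites:
            by_phase.setdefault(s.phase, []).append(s)
        for phase in sorted(by_phase):
            chunk = sorted(by_phase[phase], key=lambda s: s.column)
            current = [chunk[0]]
            for s in chunk[1:]:
                # single linkage on a line: chain via the nearest member
                if s.column - current[-1].column <= tolerance:
                    current.append(s)
                else:
                    groups.append(current)
                    current = [s]
            groups.append(current)
        groups.sort(key=lambda g: (g[0].column, g[0].phase))

    clusters = []
    for i, members in enumerate(groups, 1):
        consensus = median_low(sorted(s.column for s in members))
        cl = IntronCluster(
            cluster_id=f"c{i}",
            sites=list(members),
            consensus_column=consensus,
            phase=members[0].phase,
        )
        if taxonomy is not None:
            cl.presence = _presence(cl, taxonomy, all_species)
        clusters.append(cl)
    return clusters


def _presence(
    cluster: IntronCluster,
    taxonomy: TaxonomyMap,
    all_species: Optional[Dict[str, List[str]]],
) -> Dict[str, float]:
    present = cluster.species
    out: Dict[str, float] = {}
    clades = (
        sorted(all_species)
        if all_species is not None
        else sorted(set(taxonomy.species_to_clade.values()))
    )
    for clade in clades:
        universe = (
            all_species[clade]
            if all_species is not None
            else taxonomy.species_in(clade)
        )
        if universe:
            out[clade] = sum(1 for s in universe if s in present) / len(universe)
    return out


def select_candidate_introns(
    clusters: Sequence[IntronCluster],
    min_presence: float = 1.0,
    require_flanking_peaks: bool = False,
    profile=None,
    max_peak_distance: int = 120,
) -> List[Tuple[IntronCluster, float, float]]:
    """Filter and rank clusters as candidate EPIC loci.

    Keeps clusters whose per-clade presence all reach ``min_presence``; when
    ``require_flanking_peaks`` is set, a conservation peak must lie within
    ``max_peak_distance`` columns both 5' and 3' of the consensus column.
    Returns (cluster, min flanking omega, mean presence) sorted descending
    by (min flanking omega, mean presence); without a profile the omega
    component is 0.
    """
    if require_flanking_peaks and profile is None:
        raise ValueError("flanking peaks required but no conservation profile given")

    out = []
    for cl in clusters:
        if cl.presence and min(cl.presence.values()) < min_presence:
            continue
        flank_omega = 0.0
        if profile is not None:
            up = [
                p
                for p in profile.peak_columns
                if cl.consensus_column - max_peak_distance <= p < cl.consensus_column
            ]
            down = [
                p
                for p in profile.peak_columns
                if cl.consensus_column < p <= cl.consensus_column + max_peak_distance
            ]
            if require_flanking_peaks and not (up and down):
                continue
            vals = [profile.omega_at(p) for p in up + down]
            if up and down:
                flank_omega = min(
                    max(profile.omega_at(p) for p in up),
                    max(profile.omega_at(p) for p in down),
                )
            elif vals:
                flank_omega = min(vals)
        mean_presence = (
            sum(cl.presence.values()) / len(cl.presence) if cl.presence else 0.0
        )
        out.append((cl, flank_omega, mean_presence))
    out.sort(key=lambda t: (t[1], t[2]), reverse=True)
    return out
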