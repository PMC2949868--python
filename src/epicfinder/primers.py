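"""Consensus-clamp degenerate primer design (CODEHOP / NucHop).

A CODEHOP-style primer has two parts: a degenerate 3' *core* of at least 11
bases representing every codon combination for the amino acids observed in
the alignment block, and a non-degenerate 5' *clamp* copied literally from a
reference species (sea urchin first, else *Ciona*), which anneals perfectly
to products of earlier PCR cycles.  NucHop primers share the architecture
but derive the core from an observed nucleotide alignment.  Degeneracy (the
number of literal oligos the IUPAC pattern represents) is capped: designs
at or above 32x are rejected unless the 64x escape is allowed, and 8x or
less is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Data import CodonTable

# --- IUPAC arithmetic -------------------------------------------------------

IUPAC_SETS: Dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
SET_TO_IUPAC = {v: k for k, v in IUPAC_SETS.items()}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
IUPAC_COMPLEMENT = {
    sym: SET_TO_IUPAC[frozenset(_COMPLEMENT[b] for b in bases)]
    for sym, bases in IUPAC_SETS.items()
}


class NoPrimerError(Exception):
    """No window satisfied the degeneracy cap; carries the best degeneracy."""

    def __init__(self, message: str, best_degeneracy: Optional[int] = None):
        super().__init__(message)
        self.best_degeneracy = best_degeneracy


def degeneracy(s: str) -> int:
    """Number of literal oligonucleotides an IUPAC string represents."""
    d = 1
    for ch in s.upper():
        try:
            d *= len(IUPAC_SETS[ch])
        except KeyError:
            raise ValueError(f"not an IUPAC nucleotide symbol: {ch!r}")
    return d


def iupac_union(bases) -> str:
    """IUPAC symbol covering a set of (possibly ambiguous) symbols."""
    out = set()
    for b in bases:
        out |= IUPAC_SETS[b.upper()]
    return SET_TO_IUPAC[frozenset(out)]


def reverse_complement(s: str) -> str:
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(s.upper()))


def expand(s: str) -> List[str]:
    """All literal expansions of an IUPAC string (use only on small degeneracy)."""
    out = [""]
    for ch in s.upper():
        out = [p + b for p in out for b in sorted(IUPAC_SETS[ch])]
    return out


def symbols_match(a: str, b: str) -> bool:
    """Set-intersection match of two IUPAC symbols."""
    return bool(IUPAC_SETS[a.upper()] & IUPAC_SETS[b.upper()])


def _codons_for_aa(table_id: int = 1) -> Dict[str, List[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa: Dict[str, List[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    by_aa["*"] = list(table.stop_codons)
    return by_aa


_CODONS_BY_AA = {1: _codons_for_aa(1)}


def degenerate_codon(amino_acids, table_id: int = 1) -> str:
    """Single IUPAC codon covering all codons of the given amino acids.

    Built position-wise, so e.g. Leu's six codons widen to the 8-fold
    pattern YTN rather than an exact 6-codon pool.
    """
    if table_id not in _CODONS_BY_AA:
        _CODONS_BY_AA[table_id] = _codons_for_aa(table_id)
    codons = []
    for aa in amino_acids:
        aa = aa.upper()
        if aa == "X":
            codons.append("NNN")
            continue
        codons.extend(_CODONS_BY_AA[table_id][aa])
    return "".join(
        iupac_union(c[i] for c in codons) for i in range(3)
    )


# --- primer containers ------------------------------------------------------


@dataclass
class PrimerParams:
    clamp_length: int = 12
    core_codons: int = 4  # 12 nt; >= the 11-base minimum
    core_length: int = 12  # NucHop core, nt
    cap: int = 32  # reject designs with degeneracy >= cap
    allow_64: bool = False  # permit a single 64x design (cap becomes <=64)
    preferred_cap: int = 8
    max_shift_codons: int = 6
    max_placement_mismatches: int = 2
    codon_table: int = 1

    @property
    def effective_cap(self) -> int:
        # "less than 32x" normally; the escape admits exactly up to 64x
        return 65 if self.allow_64 else self.cap


@dataclass
class PrimerCandidate:
    """One designed primer; ``sequence`` is clamp + core (+ intron extension)."""

    orientation: str  # "forward" | "reverse"
    method: str  # "CH" | "NH" | "D"
    clamp: str
    core: str
    reference_species: str = ""
    extension: str = ""  # 2-nt intron-limit suffix, if any
    footprint_columns: Tuple[int, int] = (0, 0)  # forward-strand cols, 1-based
    abuts_intron: bool = False
    mismatch_range: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if degeneracy(self.clamp) != 1:
            raise ValueError("clamp must be non-degenerate")
        if len(self.core) < 11:
            raise ValueError(f"core must be >=11 nt, got {len(self.core)}")

    @property
    def sequence(self) -> str:
        return self.clamp + self.core + self.extension

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.core)  # clamp and extension are literal

    @property
    def descriptor(self) -> str:
        code = f"{self.method}{len(self.clamp)}+{len(self.core)}-{self.degeneracy}"
        if self.extension:
            code += f"+2{self.extension}"
        if self.mismatch_range and self.mismatch_range != (0, 0):
            code += f"-m{self.mismatch_range[0]}-{self.mismatch_range[1]}"
        return code


@dataclass
class PrimerPair:
    label: str  # a / b / c / d
    forward: PrimerCandidate
    reverse: PrimerCandidate
    amplicon_sizes: Dict[str, Optional[int]] = field(default_factory=dict)


# --- CODEHOP design ---------------------------------------------------------


def _codon_start(column: int) -> int:
    """Start column of the codon block containing ``column`` (codon grid is
    global on a threaded alignment: blocks [1-3], [4-6], ...)."""
    return column - (column - 1) % 3


def _observed_aas(protein_alignment, prot_col: int) -> List[str]:
    col = protein_alignment.column(prot_col)
    aas = sorted({c for c in col.upper() if c not in "-*"})
    return aas


def _reference_row(
    codon_alignment,
    ref_priority: Sequence[str],
    aux_sequences: Optional[Dict[str, str]],
) -> Tuple[str, str]:
    """(species, aligned nucleotide row) for the first available reference."""
    for species in ref_priority:
        if aux_sequences and species in aux_sequences:
            return species, aux_sequences[species].upper()
        for rec in codon_alignment.records:
            if rec.species == species:
                return species, rec.residues.upper()
    raise NoPrimerError(
        f"no reference sequence available among priority species {list(ref_priority)}"
    )


def design_codehop(
    protein_alignment,
    codon_alignment,
    intron_cluster,
    side: str = "5'",
    ref_priority: Sequence[str] = ("Strongylocentrotus", "Ciona"),
    params: Optional[PrimerParams] = None,
) -> PrimerCandidate:
    """Design a CODEHOP primer in the exon flanking an intron cluster.

    ``side="5'"`` gives a forward primer whose 3' end sits at the last full
    codon before the intron; ``side="3'"`` gives a reverse primer (designed
    on the reverse complement) starting at the first full codon after it.
    If the codon-expansion core at the boundary exceeds the degeneracy cap,
    the window slides away from the intron up to ``max_shift_codons`` before
    giving up with :class:`NoPrimerError`.
    """
    params = params or PrimerParams()
    boundary = intron_cluster.consensus_column
    length = codon_alignment.n_columns
    ref_species, ref_row = _reference_row(codon_alignment, ref_priority, None)

    forward = side == "5'"
    best_deg: Optional[int] = None
    for shift in range(params.max_shift_codons + 1):
        if forward:
            end = (
                boundary if boundary % 3 == 0 else _codon_start(boundary) - 1
            ) - 3 * shift
            start = end - 3 * params.core_codons + 1
            clamp_cols = (start - params.clamp_length, start - 1)
        else:
            start = (
                boundary + 1 if boundary % 3 == 0 else _codon_start(boundary) + 3
            ) + 3 * shift
            end = start + 3 * params.core_codons - 1
            clamp_cols = (end + 1, end + params.clamp_length)
        if start < 1 or end > length or clamp_cols[0] < 1 or clamp_cols[1] > length:
            continue

        core_fwd = ""
        ok = True
        for col in range(start, end + 1, 3):
            prot_col = (col - 1) // 3 + 1
            aas = _observed_aas(protein_alignment, prot_col)
            if not aas:
                ok = False  # gap-only column: no codon information
                break
            core_fwd += degenerate_codon(aas, params.codon_table)
        if not ok:
            continue
        deg = degeneracy(core_fwd)
        if best_deg is None or deg < best_deg:
            best_deg = deg
        if deg >= params.effective_cap:
            continue

        clamp_fwd = ref_row[clamp_cols[0] - 1 : clamp_cols[1]]
        if "-" in clamp_fwd or len(clamp_fwd) < params.clamp_length:
            continue  # reference gapped under the clamp; slide on
        if forward:
            clamp, core = clamp_fwd, core_fwd
            footprint = (clamp_cols[0], end)
            abuts = shift == 0 and boundary % 3 == 0
        else:
            clamp = reverse_complement(clamp_fwd)
            core = reverse_complement(core_fwd)
            footprint = (start, clamp_cols[1])
            abuts = shift == 0 and boundary % 3 == 0
        return PrimerCandidate(
            orientation="forward" if forward else "reverse",
            method="CH",
            clamp=clamp,
            core=core,
            reference_species=ref_species,
            footprint_columns=footprint,
            abuts_intron=abuts,
        )
    raise NoPrimerError(
        f"no {side} codehop window under cap {params.effective_cap} "
        f"(best degeneracy {best_deg})",
        best_degeneracy=best_deg,
    )


def design_nuchop(
    block: Sequence[str],
    orientation: str = "forward",
    reference: Optional[str] = None,
    params: Optional[PrimerParams] = None,
) -> PrimerCandidate:
    """Design a NucHop primer from a gap-free aligned nucleotide block.

    The 3'-terminal ``core_length`` columns become the column-wise IUPAC
    union of observed bases; the preceding ``clamp_length`` columns become a
    majority consensus (ties resolved by the reference sequence when given,
    else alphabetically).  For a reverse primer pass the reverse complement
    of the block sequences.
    """
    params = params or PrimerParams()
    block = [s.upper() for s in block]
    if any("-" in s for s in block):
        raise ValueError("NucHop block must be gap-free")
    need = params.clamp_length + params.core_length
    if min(len(s) for s in block) < need:
        raise ValueError(f"block shorter than clamp+core = {need} nt")
    width = min(len(s) for s in block)
    core_cols = range(width - params.core_length, width)
    clamp_cols = range(width - need, width - params.core_length)

    core = "".join(iupac_union(s[i] for s in block) for i in core_cols)
    deg = degeneracy(core)
    if deg >= params.effective_cap:
        raise NoPrimerError(
            f"NucHop core degeneracy {deg} exceeds cap {params.effective_cap}",
            best_degeneracy=deg,
        )
    clamp = ""
    ref = reference.upper() if reference else None
    for i in clamp_cols:
        counts: Dict[str, int] = {}
        for s in block:
            counts[s[i]] = counts.get(s[i], 0) + 1
        top = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == top)
        if len(winners) > 1 and ref is not None and ref[i] in winners:
            clamp += ref[i]
        else:
            clamp += winners[0]
    return PrimerCandidate(
        orientation=orientation,
        method="NH",
        clamp=clamp,
        core=core,
    )


def extend_into_intron(candidate: PrimerCandidate, intron_cluster=None, bases: int = 2) -> PrimerCandidate:
    """Append the canonical splice bases at the intron limit.

    A forward primer ending at the exon/intron boundary gains the donor
    ``GT``; a reverse primer gains ``CT`` (the reverse complement of the
    acceptor ``AG`` read on its strand).
    """
    if not candidate.abuts_intron:
        raise ValueError("primer 3' end does not abut the intron boundary")
    if bases != 2:
        raise ValueError("intron-limit extension is defined for 2 bases")
    suffix = "GT" if candidate.orientation == "forward" else "CT"
    return replace(candidate, extension=suffix)


def count_mismatches(
    candidate: PrimerCandidate, sequences: Dict[str, str]
) -> Tuple[int, int]:
    """(min, max) per-species mismatches of the primer against footprint
    sequences, under IUPAC set-intersection matching.  The intron-limit
    extension is not compared (footprints are exonic)."""
    probe = candidate.clamp + candidate.core
    counts = []
    for species, seq in sequences.items():
        seq = seq.upper()
        if len(seq) < len(probe):
            raise ValueError(f"{species}: footprint shorter than primer")
        n = sum(
            1 for p, s in zip(probe, seq) if not symbols_match(p, s)
        )
        counts.append(n)
    if not counts:
        raise ValueError("no sequences supplied")
    return min(counts), max(counts)


def enumerate_pairs(
    F: Optional[PrimerCandidate] = None,
    R: Optional[PrimerCandidate] = None,
    F2: Optional[PrimerCandidate] = None,
    R2: Optional[PrimerCandidate] = None,
) -> List[PrimerPair]:
    """Pairs labelled a=(F,R), b=(F2,R), c=(F,R2), d=(F2,R2); only pairs
    whose two members exist are emitted."""
    if F is None or R is None:
        raise ValueError("at least F and R are required")
    combos = [("a", F, R), ("b", F2, R), ("c", F, R2), ("d", F2, R2)]
    return [
        PrimerPair(label=lab, forward=f, reverse=r)
        for lab, f, r in combos
        if f is not None and r is not None
    ]


def _best_placement(pattern: str, cds: str, max_mismatches: int) -> Optional[int]:
    """0-based offset of the best (fewest mismatches, then 5'-most) placement
    of an IUPAC pattern on a literal CDS; None if over the mismatch budget."""
    best = None
    best_mm = max_mismatches + 1
    for off in range(len(cds) - len(pattern) + 1):
        mm = 0
        for p, s in zip(pattern, cds[off : off + len(pattern)]):
            if not symbols_match(p, s):
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_mm, best = mm, off
    return best


def predict_exon_amplicon(
    pair: PrimerPair,
    cds: str,
    params: Optional[PrimerParams] = None,
) -> Optional[int]:
    """Expected amplicon length on the intron-less CDS, 5' end of the forward
    primer to 5' end of the reverse primer inclusive; None if either primer
    cannot be placed.  Intron-limit extensions are excluded (they are not in
    the CDS)."""
    params = params or PrimerParams()
    cds = cds.upper()
    fwd_probe = pair.forward.clamp + pair.forward.core
    rev_probe = reverse_complement(pair.reverse.clamp + pair.reverse.core)
    f_off = _best_placement(fwd_probe, cds, params.max_placement_mismatches)
    r_off = _best_placement(rev_probe, cds, params.max_placement_mismatches)
    if f_off is None or r_off is None:
        return None
    fwd_5p = f_off + 1  # 1-based
    rev_5p = r_off + len(rev_probe)  # reverse primer's 5' base, forward coords
    if rev_5p < fwd_5p:
        return None
    return rev_5p - fwd_5p + 1
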