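"""IUPAC degeneracy arithmetic and consensus-clamp primer design."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epicfinder import model
from epicfinder.introns import cluster_introns, map_introns
from epicfinder.primers import (
    NoPrimerError,
    PrimerCandidate,
    PrimerParams,
    count_mismatches,
    degenerate_codon,
    degeneracy,
    design_codehop,
    design_nuchop,
    enumerate_pairs,
    expand,
    extend_into_intron,
    iupac_union,
    predict_exon_amplicon,
    reverse_complement,
    symbols_match,
)
from epicfinder.synthetic import FamilySimSpec, IntronPlan, simulate_family

IUPAC = "ACGTRYSWKMBDHVN"


@pytest.mark.parametrize("s,d", [("ACGT", 1), ("RYN", 16), ("N", 4), ("BDHV", 81)])
def test_degeneracy_examples(s, d):
    assert degeneracy(s) == d


def test_degeneracy_rejects_non_iupac():
    with pytest.raises(ValueError):
        degeneracy("ACGU")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet=IUPAC, min_size=1, max_size=8))
def test_degeneracy_equals_explicit_expansion_count(s):
    if degeneracy(s) <= 1024:
        exp = expand(s)
        assert len(exp) == degeneracy(s)
        assert len(set(exp)) == len(exp)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.text(alphabet=IUPAC, min_size=1, max_size=5),
    st.text(alphabet=IUPAC, min_size=1, max_size=5),
)
def test_degeneracy_is_multiplicative_under_concatenation(x, y):
    assert degeneracy(x + y) == degeneracy(x) * degeneracy(y)


def test_reverse_complement_involution_and_degeneracy_preservation():
    rnd = random.Random(1)
    for _ in range(50):
        s = "".join(rnd.choice(IUPAC) for _ in range(rnd.randint(1, 15)))
        assert reverse_complement(reverse_complement(s)) == s
        assert degeneracy(reverse_complement(s)) == degeneracy(s)


@pytest.mark.parametrize(
    "aas,expected",
    [
        (["M"], "ATG"),
        (["W"], "TGG"),
        (["D", "E"], "GAN"),  # GAY u GAR widens to GAN position-wise
        (["L"], "YTN"),  # six Leu codons widen to the 8-fold pattern
        (["E"], "GAR"),
    ],
)
def test_degenerate_codon_against_genetic_code(aas, expected):
    assert degenerate_codon(aas) == expected


def test_degenerate_codon_covers_every_source_codon():
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1].forward_table
    rnd = random.Random(6)
    aas = sorted(set(table.values()))
    for _ in range(40):
        chosen = rnd.sample(aas, rnd.randint(1, 4))
        pattern = degenerate_codon(chosen)
        for codon, aa in table.items():
            if aa in chosen:
                assert all(symbols_match(p, c) for p, c in zip(pattern, codon))


# --- design on simulated families ------------------------------------------

SPECIES = ["Homo", "Danio", "Ciona", "Strongylocentrotus"]
CLADES = {s: s for s in SPECIES}


def _design(seed, side="5'", cds_position=180):
    spec = FamilySimSpec(
        species=SPECIES,
        clades=CLADES,
        introns=[IntronPlan(cds_position=cds_position)],
        seed=seed,
    )
    bundle, _ = simulate_family(spec)
    model.validate_translation(bundle)
    codon = model.thread_codon_alignment(bundle)
    (cluster,) = cluster_introns(map_introns(bundle, codon), "strict")
    primer = design_codehop(
        bundle.proteins, codon, cluster, side, ["Strongylocentrotus", "Ciona"]
    )
    return bundle, codon, cluster, primer


def test_codehop_clamp_is_reference_literal_and_core_contains_sources():
    for seed in range(8):
        bundle, codon, cluster, primer = _design(seed)
        assert degeneracy(primer.clamp) == 1
        assert len(primer.core) >= 11
        s, e = primer.footprint_columns
        ref = codon.record(
            next(g for g in bundle.gene_ids if bundle.species_of(g) == primer.reference_species)
        )
        clamp_region = ref.residues[s - 1 : s - 1 + len(primer.clamp)]
        assert primer.clamp == clamp_region
        core_start = s + len(primer.clamp)
        for rec in codon.records:
            frag = rec.residues[core_start - 1 : e]
            if "-" in frag:
                continue
            assert all(
                symbols_match(p, c) for p, c in zip(primer.core, frag)
            ), f"core not a superset of {rec.id} (seed {seed})"


def test_reverse_codehop_core_is_reverse_complement_of_downstream_block():
    bundle, codon, cluster, primer = _design(3, side="3'")
    assert primer.orientation == "reverse"
    s, e = primer.footprint_columns
    core_fwd = reverse_complement(primer.core)
    for rec in codon.records:
        frag = rec.residues[s - 1 : s - 1 + len(core_fwd)]
        if "-" in frag:
            continue
        assert all(symbols_match(p, c) for p, c in zip(core_fwd, frag))


def test_codehop_cap_rejection_reports_best_degeneracy():
    bundle, codon, cluster, _ = _design(0)
    tight = PrimerParams(cap=2, max_shift_codons=2)
    with pytest.raises(NoPrimerError) as err:
        design_codehop(
            bundle.proteins, codon, cluster, "5'",
            ["Strongylocentrotus", "Ciona"], tight,
        )
    assert err.value.best_degeneracy is not None
    assert err.value.best_degeneracy >= 2


def test_nuchop_identical_block_is_literal():
    block = ["ACGTACGTACGTACGTACGTACGT"] * 4
    p = design_nuchop(block)
    assert p.degeneracy == 1
    assert p.sequence == block[0]


def test_nuchop_union_column_and_containment():
    base = "ACGTACGTACGTACGTACGTACGT"
    variant = base[:23] + "G"  # last column {T,G} -> K
    p = design_nuchop([base, variant])
    assert p.core[-1] == "K"
    assert p.degeneracy == 2
    for s in (base, variant):
        assert all(symbols_match(a, b) for a, b in zip(p.sequence, s))


def test_nuchop_rejects_gaps_and_short_blocks():
    with pytest.raises(ValueError, match="gap"):
        design_nuchop(["ACGT-CGTACGTACGTACGTACGT"] * 2)
    with pytest.raises(ValueError, match="shorter"):
        design_nuchop(["ACGTACGT"] * 2)


def test_nuchop_clamp_majority_with_reference_tiebreak():
    s1 = "A" + "C" * 23
    s2 = "G" + "C" * 23
    p_ref = design_nuchop([s1, s2], reference=s2)
    assert p_ref.clamp[0] == "G"
    p_lex = design_nuchop([s1, s2])
    assert p_lex.clamp[0] == "A"


def test_intron_limit_extension_forward_gt_reverse_ct():
    _, _, _, fwd = _design(2, side="5'")
    assert fwd.abuts_intron  # planted at a codon boundary
    ext = extend_into_intron(fwd)
    assert ext.extension == "GT"
    assert ext.sequence.endswith("GT")
    assert "+2GT" in ext.descriptor

    _, _, _, rev = _design(2, side="3'")
    ext_r = extend_into_intron(rev)
    assert ext_r.extension == "CT"


def test_extension_requires_adjacency():
    primer = PrimerCandidate(
        orientation="forward", method="CH", clamp="ACGTACGTACGT",
        core="ATGATGATGATG", abuts_intron=False,
    )
    with pytest.raises(ValueError, match="abut"):
        extend_into_intron(primer)


def test_descriptor_grammar():
    primer = PrimerCandidate(
        orientation="forward", method="CH", clamp="ACGTACGTACGT",
        core="ATGGARTAYTGY",
    )
    assert primer.descriptor == "CH12+12-8"
    primer.mismatch_range = (0, 2)
    assert primer.descriptor == "CH12+12-8-m0-2"


def test_clamp_must_be_non_degenerate_and_core_at_least_11():
    with pytest.raises(ValueError, match="clamp"):
        PrimerCandidate("forward", "CH", clamp="ACGR", core="A" * 12)
    with pytest.raises(ValueError, match="11"):
        PrimerCandidate("forward", "CH", clamp="ACGT", core="A" * 10)


def test_count_mismatches_min_max():
    primer = PrimerCandidate(
        orientation="forward", method="D", clamp="ACGTACGTACGT",
        core="ATGATGATGAT",
    )
    exact = primer.clamp + primer.core
    two_off = "TT" + exact[2:]
    assert count_mismatches(primer, {"a": exact, "b": two_off}) == (0, 2)


def test_count_mismatches_uses_set_intersection():
    primer = PrimerCandidate(
        orientation="forward", method="D", clamp="ACGT" * 3, core="R" + "A" * 10,
    )
    seq = primer.clamp + "G" + "A" * 10  # R matches G
    assert count_mismatches(primer, {"a": seq}) == (0, 0)


def _dummy(orientation="forward"):
    return PrimerCandidate(
        orientation=orientation, method="CH", clamp="ACGTACGTACGT", core="A" * 12
    )


def test_pair_enumeration_labels():
    F, R, F2, R2 = _dummy(), _dummy("reverse"), _dummy(), _dummy("reverse")
    assert [p.label for p in enumerate_pairs(F=F, R=R)] == ["a"]
    assert [p.label for p in enumerate_pairs(F=F, R=R, F2=F2, R2=R2)] == list("abcd")
    assert [p.label for p in enumerate_pairs(F=F, R=R, R2=R2)] == ["a", "c"]
    with pytest.raises(ValueError):
        enumerate_pairs(F=F)


def test_amplicon_size_is_five_prime_to_five_prime():
    rnd = random.Random(12)
    filler = "".join(rnd.choice("ACGT") for _ in range(100))
    fwd_seq = "ATGGCTAAGGATTGCCACAA"  # 20 nt
    rev_site = "CCGGTTAACCGGTTAACCTT"  # forward-strand site, 20 nt
    cds = fwd_seq + filler[:40] + rev_site + filler[40:60]
    # primers whose probes are exactly the planted sites
    fwd = PrimerCandidate("forward", "D", clamp=fwd_seq[:9], core=fwd_seq[9:])
    rev = PrimerCandidate(
        "reverse", "D",
        clamp=reverse_complement(rev_site)[:9],
        core=reverse_complement(rev_site)[9:],
    )
    (pair,) = enumerate_pairs(F=fwd, R=rev)
    # 5' of forward at 1; 5' of reverse at 20+40+20 = 80 -> amplicon 80
    assert predict_exon_amplicon(pair, cds) == 80


def test_unplaceable_primer_reports_none():
    fwd = _dummy()
    rev = _dummy("reverse")
    (pair,) = enumerate_pairs(F=fwd, R=rev)
    assert predict_exon_amplicon(pair, "GGCC" * 30) is None


def test_extension_excluded_from_amplicon_placement():
    bundle, codon, cluster, fwd = _design(4, side="5'")
    rev = design_codehop(
        bundle.proteins, codon, cluster, "3'", ["Strongylocentrotus", "Ciona"]
    )
    (plain,) = enumerate_pairs(F=fwd, R=rev)
    (extended,) = enumerate_pairs(F=extend_into_intron(fwd), R=rev)
    for gid in bundle.gene_ids:
        cds = bundle.cds[gid].ungapped
        assert predict_exon_amplicon(plain, cds) == predict_exon_amplicon(extended, cds)
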