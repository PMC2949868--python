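"""Shared builders for hand-sized bundles used across the suite."""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import pytest

from epicfinder.model import (
    Alignment,
    ExonStructure,
    GeneFamilyBundle,
    GeneTree,
    SequenceRecord,
    TaxonomyMap,
)


def make_bundle(
    proteins: List[Tuple[str, str, str]],
    cds: Dict[str, str],
    exons: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    newick: Optional[str] = None,
    clades: Optional[Dict[str, str]] = None,
    required: Optional[List[str]] = None,
) -> GeneFamilyBundle:
    """Build a bundle from (id, species, aligned protein) triples and CDS.

    Exon structures default to a single exon tiling each CDS; the tree
    defaults to a ladder over the gene ids; every species defaults to its
    own clade.
    """
    prot_records = [
        SequenceRecord(id=g, species=sp, residues=seq, kind="protein")
        for g, sp, seq in proteins
    ]
    cds_records = {
        g: SequenceRecord(id=g, species=sp, residues=cds[g], kind="nucleotide")
        for g, sp, _ in proteins
    }
    structures = {}
    for g, sp, _ in proteins:
        ivs = (exons or {}).get(g) or [(1, len(cds[g].replace("-", "")))]
        structures[g] = ExonStructure(species=sp, gene_id=g, exons=ivs)
    if newick is None:
        tip = proteins[0][0]
        for g, _, _ in proteins[1:]:
            tip = f"({tip},{g})"
        newick = tip + ";"
    species_map = {g: sp for g, sp, _ in proteins}
    if clades is None:
        clades = {sp: sp for _, sp, _ in proteins}
    taxonomy = TaxonomyMap(species_to_clade=clades, required_clades=required or [])
    return GeneFamilyBundle(
        family_id="toy",
        proteins=Alignment(kind="protein", records=prot_records),
        cds=cds_records,
        exon_structures=structures,
        tree=GeneTree.from_newick(newick, species_map),
        taxonomy=taxonomy,
    )


@pytest.fixture
def toy_bundle() -> GeneFamilyBundle:
    """Four species, two required clades, gap in one protein row."""
    return make_bundle(
        proteins=[
            ("h1", "Homo", "MAWK"),
            ("d1", "Danio", "MAWK"),
            ("c1", "Ciona", "M-WK"),
            ("s1", "Strongylocentrotus", "MAWK"),
        ],
        cds={
            "h1": "ATGGCTTGGAAA",
            "d1": "ATGGCATGGAAG",
            "c1": "ATGTGGAAA",
            "s1": "ATGGCCTGGAAA",
        },
        exons={
            "h1": [(1, 6), (7, 12)],
            "d1": [(1, 6), (7, 12)],
            "c1": [(1, 3), (4, 9)],
            "s1": [(1, 6), (7, 12)],
        },
        newick="((h1,d1),(c1,s1));",
        clades={
            "Homo": "vertebrate",
            "Danio": "vertebrate",
            "Ciona": "urochordate",
            "Strongylocentrotus": "echinoderm",
        },
        required=["vertebrate", "urochordate"],
    )
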