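# epicfinder

Tools for discovering **potentially universal EPIC loci** — Exon-Primed
Intron-Crossing PCR markers whose primers sit in conserved exons on either
side of a variable intron.  Such loci give molecular ecologists codominant,
sequence-interpretable nuclear markers that work across phyla, but finding
them requires avoiding multigene families (paralogy breaks codominant
genotyping) and locating intron positions that are conserved from
vertebrates to cnidarians.

The package implements the full desk pipeline:

1. **Family filtering** — gene families are kept only when every required
   clade is represented in the gene tree and no duplication node sits at the
   root (MRCA) of a required clade.  Duplication nodes are called by the
   species-overlap rule: an internal node is a duplication iff at least two
   of its child subtrees share a species.  A duplication confined to a
   single species within a clade is exempted.  Homology hits from
   unannotated genomes are filtered at e-value < 10⁻⁵ and protein
   similarity > 0.5 (strict inequalities).
2. **Intron mapping** — exon/intron structures in CDS coordinates are
   projected onto the codon alignment (threaded PAL2NAL-style from the
   protein alignment).  An intron is addressed by the alignment column of
   the last exonic base 5′ of it, with phase = (CDS offset mod 3).  Sites
   cluster either strictly (identical column and phase) or with a small
   tolerance (default 6 nt, single linkage within equal phase), since good
   EPIC positions may shift by a few nucleotides between phyla.
3. **Conservation scoring** — a sliding 20-nt window over the codon
   alignment scores ω = geometric mean of up to four components: ω₀, the
   mean pairwise identity among the core (database) sequences, and ω₁…ω₃,
   the best identity between any core sequence and each auxiliary-genome
   sequence.  Local peaks of ω are called in 51-column windows and used to
   demand conserved blocks on both sides of a candidate intron.
4. **Primer design** — CODEHOP-style consensus-clamp degenerate primers: a
   degenerate 3′ core (≥ 11 nt) built by codon expansion of the amino acids
   observed in each aligned column, and a literal 5′ clamp copied from a
   reference species (sea urchin first, else *Ciona*).  NucHop primers use
   the same architecture with a nucleotide-union core.  Designs with
   degeneracy ≥ 32× are rejected (a 64× escape hatch exists; ≤ 8× is
   preferred).  Pair labels a/b/c/d enumerate (F,R), (F2,R), (F,R2),
   (F2,R2); expected exon-only amplicon sizes are predicted per species.
5. **PCR scoring** — gel outcomes are graded P (promising) / I (intron-size
   amplicon with defects) / A (amplification too short to hold an intron) /
   null, pooled to the best category across protocols, individuals and
   congeneric species, and summarised: per-genus counts, per-clade means of
   amplifying (P+I) loci, "universal" introns (P or I in every genus
   tested), correspondence-analysis ordination of genera, and a
   Fisher–Freeman–Halton exact test relating primer degeneracy to outcome.

A seed-deterministic synthetic-data module generates family bundles with
planted introns, duplications and conserved primer-friendly flanks, so every
stage is testable without any database access.  The published 52-intron ×
12-genus screening matrix ships as a packaged fixture
(`epicfinder.synthetic.table1_fixture`).

## Worked example

```python
from epicfinder.synthetic import table1_fixture, GENUS_CLADES, BILATERIAN_GENERA
from epicfinder.pcr import summarize_by_genus, find_universal_introns, clade_mean_amplifying

m = table1_fixture()
print(summarize_by_genus(m).loc[["Paracentrotus", "Corallium"]])
#                 P   I  A  null  total  na
# genus
# Paracentrotus  15   9  3    25     52   0
# Corallium       6  12  5     6     29  23

print(find_universal_introns(m))
# ['5', '21', '25', '50', '2+22']

print(clade_mean_amplifying(m, {g: "bilaterian" for g in BILATERIAN_GENERA}))
# {'bilaterian': 24.0}
```

Paracentrotus shows 15 promising and 9 intron-sized loci of 52 screened; the
cnidarian *Corallium* amplifies 18 (P+I) of its 29 surveyed loci.  Five
introns (5, 21, 25, 50, and the merged 2/22 pair) amplify intron-sized
products in *every* genus where they were tested — including cnidarians —
and a bilaterian genus amplifies 24 introns on average.

The same steps are available from a shell:

```bash
epicfinder simulate family --seed 5 --out bundle/
epicfinder map-introns --bundle bundle/ --mode relaxed --tolerance 6 --out introns.tsv
epicfinder score-pcr --matrix src/epicfinder/data/table1.tsv --out summary/
```

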