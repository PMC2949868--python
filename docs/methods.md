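# Methods

## Scope and data model

The unit of work is a *gene family bundle*: one orthologous family with an
aligned protein set, the matching coding sequences, per-gene exon/intron
structures, a rooted gene tree, and a species→clade taxonomy.  All
coordinates are 1-based inclusive.  Exon structures are expressed in CDS
coordinates, not genomic ones, so strand never enters the picture; this
matches a workflow that starts from annotated CDS and intron positions
rather than raw genomes.  The only accepted gap symbol is `-` (`.` is
rejected outright — determinism over dialect guessing).  Bundles are stored
as plain text (FASTA, a narrow CDS-coordinate GFF3 dialect with a header
pragma, Newick, TSV); the GFF3 dialect is read and written by a small
dedicated parser because generic GFF machinery assumes genomic conventions
this format deliberately avoids.

Translation uses the standard genetic code by default (the surveyed taxa are
standard-code metazoans); the table id is configurable.  `N`-containing
codons translate as `X` and match any amino acid during validation; a
terminal stop is ignored.  Codon threading is only available on a
translation-validated bundle, which guarantees the mapping from protein
columns to codon triplets is exact.

## Family filtering

Duplication nodes are called by species overlap: an internal node is a
duplication iff ≥ 2 of its child subtrees share at least one species.  No
species-tree reconciliation is attempted — the overlap rule is the
tree-intrinsic operational definition of "the same clusters of taxa appear
several times", and it needs no species tree.  A family is retained iff
every required clade has at least one leaf and the MRCA of each required
clade's leaves is not a duplication node whose offending species include
more than one species of that clade.  A duplication touching exactly one
species of a clade (anywhere inside it) is logged as an exemption, not
fatal: a single duplicated species says nothing about paralogy across the
clade.  The "root of a taxon" is interpreted as the MRCA of that clade's
leaves in the gene tree — the only reading available without a species
tree.  Hit-table thresholds are strict (`<` 10⁻⁵ e-value, `>` 0.5
similarity) and configurable.

## Intron mapping and clustering

An intron is addressed by the codon-alignment column of the last exonic
base 5′ of it; the phase is the junction's CDS offset mod 3.  Addressing by
the 5′ column in the *ungapped* CDS frame makes the location stable under
alignment gap columns.

Clustering of sites across species is either strict (identical column and
phase) or relaxed: single-linkage over column distance ≤ tolerance, within
equal phase only.  The tolerance defaults to 6 nt (two codons); the notion
of "slight" positional variation has no canonical value, so the knob is
exposed and logged rather than hard-coded.  Single linkage can chain
members further than the tolerance apart (the span is reported, never
clamped); with well-separated intron positions — the regime the tool
targets — chaining is harmless, and the strict mode is always available as
a refinement.  The consensus column is the member median with ties broken
to the smaller column.

Candidate selection keeps clusters meeting a per-clade presence threshold
and, optionally, demands a conservation peak within a configurable distance
(default 120 columns) on both sides of the consensus column; candidates are
ranked by (min flanking ω, mean presence), descending, where the flanking ω
is the smaller of the best 5′ and best 3′ peak values.

## Conservation score ω

For a window the score is the geometric mean of 1–4 components: ω₀ is the
mean identity over **all unordered pairs** of core sequences (the wording
"pairs of sequences" admits subsets; all pairs is the deterministic,
symmetric choice and is documented as such), and ωᵢ (i = 1..3) is the best
identity between any core sequence and auxiliary species i, emitted only
when that species has a sequence.  Windows are 20 nt wide, slide by one
column, and the value is assigned to the window's **centre** column
(`start + (w−1)//2`) so peak coordinates compare directly to intron
columns.  Positions with a gap in either sequence are excluded from the
identity denominator (a gap is missing data, not a mismatch); a window with
no comparable positions scores 0.  Any zero component forces ω = 0.

Peaks are strict maxima over a centred 51-column window, with truncated
windows at the track ends; on ties the leftmost position of a tied run is
the peak and the rest are suppressed (so a constant track has exactly one
peak).  The peak window must be odd.  In plot exports the auxiliary
components are halved for readability — presentation only; analysis values
are never scaled.

## Primer design

CODEHOP cores are built by per-position IUPAC union of all codons of the
amino acids observed in each aligned column.  This single-pattern
representation can exceed the exact codon-set cardinality (Leu's six codons
widen to the 8-fold `YTN`); exact multi-pattern pools are out of scope.
The default core is 4 codons (12 nt, above the 11-base minimum) and the
clamp 12 literal nt from the first available reference species
(*Strongylocentrotus*, else *Ciona*).  The forward core ends at the last
full codon before the intron; the reverse design operates on the reverse
complement of the first full codons after it.  If the boundary window
exceeds the cap the window slides away from the intron up to 6 codons
before reporting failure with the best degeneracy found.  Caps: reject at
≥ 32× by default, an escape permits up to 64×, and ≤ 8× is the preferred
band used for ranking.  No melting-temperature or secondary-structure
screening is attempted.

A primer whose 3′ end abuts the intron boundary can be extended by the
canonical splice donor `GT` (forward) or, for a reverse primer at the
acceptor, `CT` (the reverse complement of `AG` read on the primer strand).

Mismatch auditing and amplicon placement use IUPAC set-intersection
matching.  Placement on a CDS allows ≤ 2 mismatches by default, with ties
resolved to the 5′-most position; amplicon size is measured 5′ end of the
forward primer to 5′ end of the reverse primer, inclusive, on the
intron-less CDS, and intron-limit extensions are excluded (they are not
exonic).  Pair labels: a = (F,R), b = (F2,R), c = (F,R2), d = (F2,R2).

## PCR scoring

"Intron-sized" is operationalised as fragment size ≥ expected exon-only
size + 70 bp; 70 is the permissive end of the "about 70–100 bp" working
definition of a useful intron and is configurable.  When the expected size
is unknown, every fragment is treated as potentially intron-sized (short
products can then never demote a result to A).  Faintness, band counts and
constant-band flags come from explicit annotations in the input — gel
densitometry is out of scope.  P requires every individual to show a clean,
non-faint, intron-sized product with at most three fragments (three only
with a constant band); I marks intron-sized products with any defect
(faint, multi-banded, or a failing individual); A marks products all too
short; null, no product anywhere.  Pooling is the join (maximum) under
null < A < I < P, so it is associative, commutative and idempotent; `na`
cells (not tested) are ignored and pool to `na` only when nothing was
tested.

In the packaged screening matrix, `na` distinguishes untested cnidarian
loci from true nulls (blank cells); the merge group {2, 22} — one intron
recovered independently twice — is pooled per genus by best category before
universality is assessed.  An intron is "universal" when it is P or I in
every genus where it was tested.

Correspondence analysis scores cells null/A/I/P as 0/1/2/3, drops zero-sum
rows and columns with a warning, and computes column (genus) principal
coordinates from the SVD of the standardised residual matrix.  Signs are
fixed by a column-order-independent convention (largest-magnitude
coordinate positive per dimension).  Full-rank coordinates reproduce the
chi-square distances between genus profiles, which the tests verify.

The degeneracy/outcome analysis builds a 4 × 3 table of outcome category ×
number of primers in the pair with more than 6-fold degeneracy (0/1/2) and
runs a Fisher–Freeman–Halton exact test under the probability-ordering
criterion: p is the total null (multivariate hypergeometric) probability of
margin-fixed tables no more probable than the observed one.  Enumeration is
exact up to a configurable table budget; beyond it a seeded Monte Carlo
estimate is used (tables sampled by shuffling column labels against row
labels) and the standard error is reported.  No installed library offers
the r × c exact test, so the enumerator is implemented here and checked
against an independent brute-force enumerator and, on 2 × 2 subcases,
against the closed-form hypergeometric value.

## Synthetic data

The generator evolves a random ancestral protein down a ladder species tree
with i.i.d. per-site amino-acid substitutions (default rate 0.05 per
branch), back-translates each tip with uniform synonymous codon choice, and
plants introns at chosen CDS positions with per-lineage retention
probability and positional jitter.  Jitter is applied in whole-codon steps
so jittered copies keep the planted phase, which is what same-intron
positional wobble looks like in frame-preserving evolution.  The codons
flanking each planted intron (default 6 per side) are invariant and drawn
from 1-/2-fold-degenerate amino acids: candidate EPIC regions are *selected*
for conserved, low-degeneracy blocks, and the generator encodes that study
condition; with fully random columns CODEHOP cores routinely and correctly
exceed the 32× cap.  Duplications are planted by doubling a subtree's gene
copies.  Everything is seed-deterministic (same seed ⇒ byte-identical
bundle files).

What the simulations deliberately omit: indels (alignments are gap-free;
gap handling is exercised by hand-built alignments in the tests), codon
models and rate heterogeneity, realistic branch lengths, and any gel-level
noise.  Passing recovery and containment tests therefore demonstrate the
pipeline's correctness on clean, known-truth input — not robustness to
alignment error in real data.

## Problem sizes

The test-suite and the acceptance script use deliberately small
simulations: families of 4 species × 60–120 codons, 100–500 replicates for
recovery rates, 100 families for primer containment, 200 random trees for
duplication calling, and exact-test enumeration on tables with n ≤ 40.
These sizes give stable rates while keeping each suite a matter of seconds.

## Known limitations

* Single-pattern IUPAC cores overstate degeneracy for 6-codon amino acids.
* The relaxed-cluster span can exceed the tolerance through single-linkage
  chaining when intron positions are dense.
* Amplicon prediction places primers on the CDS only; genomic off-target
  placements are not modelled.
* The published per-genus summary for *Corella* is internally inconsistent
  with the published per-locus matrix (A = 3/null = 27 versus A = 4/null =
  26 computed from the matrix, whose per-intron count rows confirm all four
  A cells); the package reports what the matrix yields and the test-suite
  surfaces the discrepancy rather than patching either table.
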