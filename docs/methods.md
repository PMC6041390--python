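# Methods

## Scope and data model

`ighclone` analyses rearranged immunoglobulin heavy-chain (IGH) sequences
at desk scale: tens of sequences per animal, as produced by hybridoma
panels. The in-memory model is deliberately small: a `GermlineDB` of V and
J segments with CDR3 anchor coordinates, per-sequence `Annotation` objects
(gene calls, CDR3 in both delineations, mutation list), `Clone` partitions,
per-clone `LineageReport`s, and serology containers (`DilutionSeries`,
`StandardCurve`, `CtTable`). Tabular interchange uses an AIRR-style
rearrangement TSV written with pandas. All internal coordinates are
0-based half-open; positions in reports follow the 1-based community
convention.

## Germline reference

The packaged reference is synthetic and representative, not a curated
allele database: 10 V segments of 98 codons (random stop-free ORFs ending
in the conserved Cys104 codon) carrying the V-gene labels that appear in
the packaged hybridoma panel, and 4 J segments reverse-translated from
murine-JH-like amino-acid sequences containing the W(F)GxG motif. Random
V sequences are pairwise ~75% divergent, far beyond any realistic
assignment ambiguity, which is what the assignment tests require. The
reference is regenerated bit-identically by `scripts/make_germline.py`
(fixed seed) and round-trips byte-identically through the 60-column FASTA
writer. Anchors travel in a separate TSV (`id`, `segment`,
`anchor_codon_index`); loading validates that every V anchor translates to
C and every J anchor to W or F.

## V/J assignment and CDR3 delineation

Assignment aligns the query against every germline of one segment class
with a free-end-gap global (overlap) alignment: match +1, mismatch −1,
gap open −5, gap extend −1 (Biopython `PairwiseAligner`). The best score
wins; ties break by higher identity over aligned non-gap columns, then by
gene name, making the result deterministic. Identity excludes N columns
from the denominator. A query whose best identity falls below 50% is an
*unassignable* outcome, not an exception.

The CDR3 spans the codons strictly after Cys104 up to and excluding
Trp118, located by mapping the anchor codon coordinates through the V and
J alignments. A frame break or unmappable anchor flags the record
`junction_unresolved`; an internal stop flags it `nonproductive`. The
Kabat CDR-H3 is the IMGT CDR3 with its first two residues removed. This
rule is an inference from the packaged panel: the printed per-row
Kabat-convention arginine counts equal the arginines outside the first
two IMGT positions in all 31 rows, and the unit tests pin all 31.

One open bookkeeping question is the panel's published residue
denominator of 289 CDR3 amino acids. The printed IMGT CDR3 lengths sum to
371; removing two residues per row (the Kabat rule that reproduces every
printed arginine count) gives 309; removing three gives 278. No uniform
convention we tested reproduces 289, so the published denominator is
carried as a fixture annotation and used for the published-table
chi-square, while the recomputed-from-sequence denominator (309 under
Kabat) is reported alongside. The arginine total of 47 is reproduced
exactly either way, and significance against the background is far below
p = 0.001 under both denominators.

## Mutation enumeration

Mutations are called per mismatched aligned column over germline-covered
positions of V and J; untemplated junction columns have no germline and
are never counted. A codon with several substitutions is classified by
its joint translation, and all base changes in that codon share the
effect (so total counts bases, non-silent counts bases in codons whose
joint translation changed — matching a total/non-silent bookkeeping in
which `non-silent ≤ total`). N bases neither produce calls nor enter
identity denominators. Mutations are keyed by (region, position,
observed base), so independent changes to different bases at one site
count separately — a conservative choice for homoplasy handling.

## Clonal grouping

Two records from the same mouse link iff identical V call, identical J
call, identical D call *when both records carry one* (no D reference is
packaged, and D assignment on short junctions is unreliable; absent D
calls never block linkage), equal CDR3 nucleotide length, and CDR3
identity strictly greater than the threshold (default 0.95). Identity is
1 − Hamming/length on the equal-length CDR3s; the length condition makes
gapped alignment unnecessary. Clones are connected components (single
linkage), ids are deterministic (per mouse, numbered by smallest member
id). The threshold and the strict inequality are configurable. For the
amino-acid-only packaged panel the criterion cannot be re-derived
(nucleotides were not published); the printed clone labels are used as
the ground-truth partition.

## Lineage topology

For a clone, let U be the distinct mutations across members, S those in
≥ 2 members and P = U − S the private ones. The star index P/U is 1 for a
pure star (each member mutating independently from the founder) and 1/k
in the limit of a perfect k-member ladder (each member inheriting its
predecessor's mutations plus one step of new ones). Calls: *bush* above
0.7, *stepwise* below 0.4, otherwise *indeterminate*; clones with fewer
than 3 members or no mutations are always indeterminate. Both cuts are
artifact-defined parameters — no formula exists for the qualitative
"bush-like vs stepwise" distinction — and were calibrated on the packaged
simulator: the stepwise cut must sit above 1/3, the floor of the smallest
informative ladder (k = 3); with 0.4/0.7 the simulator's star and ladder
clones (sizes 3–6, rate 0.01/site) are each called 100% correctly among
non-indeterminate cases.

Genealogies are built by greedy perfect phylogeny on the member×mutation
matrix: mutations sharing a carrier set define candidate clades, accepted
in decreasing size when nested with or disjoint from all accepted clades.
Four-gamete violations are reported as homoplasies and placed on every
carrier's terminal edge rather than dropped, so the tree explains every
mutation at least once (exactly once for compatible matrices, which is
verified by an exhaustive path-union check in the tests). Trees export as
Newick with branch lengths equal to edge mutation counts.

## Composition statistics

Arginine counting operates on the IMGT string or its Kabat view. The
enrichment test builds the 2×2 table [[R_obs, nonR_obs], [R_bg, nonR_bg]]
and applies Pearson's chi-square without continuity correction (the
correction is a flag); if any expected cell falls below 1 it switches to
Fisher's exact test with a logged notice. The background defaults to the
abYsis mouse CDR3 counts (6,203/166,000) and is overridable. Recurrent V
usage counts, per V gene, the mice in which at least two sequences carry
that gene (clone sizes summed per mouse and V): this covers both a single
expanded clone and repeated independent use, which is how recurrence
presents in the packaged panel (in one mouse the recurrent V gene appears
in two singleton clones of different CDR3 length).

## Serology

ELISA curves are interpolated piecewise-linearly in (log reciprocal
dilution, OD) after an isotonic (non-increasing) projection that absorbs
minor non-monotonicity; no 4-parameter logistic fit is attempted at desk
scale. The reference OD is the midpoint of the standard's dynamic range —
a documented choice, as no interpolation OD is prescribed by the assay
description. A sample's relative units are
`RU = 100 × titer(sample)/titer(standard)` where titer is the reciprocal
dilution at which the curve crosses the reference OD; the standard
evaluated against itself therefore scores exactly its anchor value
(100 RU at the 1/200 anchor), and a parallel curve shifted by titer
factor f scores 100 f. Samples never reaching the reference OD are
reported below quantification with their bounding dilution. With 2-fold
dilution spacing, piecewise-linear interpolation of a sigmoid carries
≲ 1% curvature error depending on where the crossing lands between
points; the noise-free self-consistency checks are exact to 0.1%.

The positivity cutoff is mean + 3 sample SD of a control panel (≥ 5
sera) — an artifact-defined rule, flagged as such, since the source assay
shows its cutoff only graphically. Note that for skewed (lognormal)
control distributions the exceedance of this rule is ~1%, well above the
0.13% normal-theory value; the Monte-Carlo test asserts the honest rate.

Relative expression follows the ΔCt method:
`fold = 2^−(ΔCt_sample − ΔCt_calibrator)` with ΔCt = Ct_target − Ct_ref.
The −/+/++/+++ bins (< 0.01, < 0.1, < 0.5, ≥ 0.5 of the calibrator) are
artifact-defined and configurable; the published categories carry no
numeric bounds.

The Mann–Whitney U test enumerates the exact null over all C(n, n_a)
splits of the pooled midranks for combined n ≤ 12 (ties handled by
midranks; two-sided p = 2·min(tail masses), capped at 1), and uses the
normal approximation with tie correction above that. scipy's exact
implementation serves as an independent cross-check in the tests, never
as the small-sample implementation.

## Simulator

`simulate_repertoire` emulates the statistical structure of a clonally
expanded hybridoma panel. Defaults are the study conditions of the
packaged panel: 3 mice; clone sizes 1–6 with mass (0.50, 0.14, 0.22,
0.04, 0.04, 0.06) mirroring the panel's size spectrum (nine singletons
up to one six-member clone); isotypes drawn (IgG2c, IgG2b, IgG3) =
(25, 5, 1)/31; junction (CDR3) lengths 27–42 nt matching the printed
9–14 aa range; substitution rate 0.005/site per lineage step, which
yields the panel's "moderate" per-sequence mutation counts (~1–2 per
step over ~330 templated sites). Each clone draws a V and J gene, an
in-frame untemplated insert (sense codons only, so stop-free by
construction; codon draws reweighted toward the six arginine codons by
`arg_selection_weight`), an isotype and a size. *Star* mode mutates each
member independently from the founder; *ladder* mode mutates sequentially
with inheritance, never revisiting an inherited site, so member sets are
strictly nested.

Substitutions target the V/J-templated framework only: the junction
region between the anchors is held fixed within a clone by default. This
makes the planted CDR3 exactly recoverable, clone membership unambiguous
(grouping recovers the planted partition with ARI 1.0 for any seed), and
the planted mutation lists exactly equal to what annotation should call.
`mutate_junction=True` lifts this for realism studies at the cost of those
exact-recovery guarantees. Real SHM differs in known ways the generator
does not model: hot-spot (WRC/GYW) targeting, indels, class-switch
mechanics and selection-driven replacement biases. Passing tests
therefore demonstrate correctness of the bookkeeping and inference
machinery under clean point-substitution diversification, not robustness
to every biological artefact of real repertoires.

`simulate_elisa` produces parallel log-logistic OD curves (OD between
0.05 and 2.5, EC50 at reciprocal dilution 1600, Hill 1.5), the standard
in 1/2 serial dilutions from 1/200 (8 points) and samples from 1/100
(10 points, so titer factors up to ~10 stay quantifiable), with Gaussian
OD noise (default SD 0.02). A factor-f sample is the standard shifted by
log f in log-dilution, so recovered RU/100 estimates f directly.
`simulate_ct` plants known fold changes into Ct tables. One seeded
generator drives each dataset; identical seeds give byte-identical
FASTA/TSV output.

## Problem sizes and determinism

The validation suite runs at desk scale, chosen to exercise every code
path while staying quick: ~200 annotated records for truth-recovery and
grouping checks, 200 simulated clones (100 star + 100 ladder, sizes 3–6)
for topology calibration, 1,000 Monte-Carlo replicates for the cutoff
test. Every stochastic test fixes its seed; hypothesis-based property
tests run derandomized. The full suite completes in well under a minute.

## Known limitations

* No D-segment reference or D calls; the clonal criterion's D clause
  activates only when calls are supplied externally.
* No allele-level germline resolution, indel SHM, or light chains.
* The Kabat view is a panel-validated inference (strip two residues), not
  a full Kabat numbering engine.
* Chi-square p-values are asymptotic; for totals ≤ 40 they agree with an
  exact enumeration only to ~10% relative at moderate proportions, and
  the Fisher fallback covers degenerate tables.
* ELISA quantification assumes parallel sample/standard curves; strongly
  non-parallel samples violate the single-titer-shift model and are not
  flagged beyond the below-quantification rule.
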