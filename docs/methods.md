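# Methods

This note documents the models and procedures implemented in `barcodeaudit`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic data generator does and does not
emulate.

## The audit problem

A DNA-barcode reference library pairs aligned mitochondrial COI sequences
(~658 bp) with expert morphospecies identifications. Before such a library
can back DNA-based identification, it has to be audited: do conspecific
sequences cluster tightly, are species separated by a "barcode gap", which
species share barcodes with others, and which fall apart into several
molecular clusters (MOTUs — molecular operational taxonomic units)?
`barcodeaudit` implements that audit end to end on any aligned library, and
ships a calibrated simulator so every stage can be exercised without
external data.

## Distances

Pairwise distances use the Kimura two-parameter model,

d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

with P and Q the transition and transversion proportions among *comparable*
sites: positions where both sequences carry an unambiguous A/C/G/T
(pairwise deletion). Ambiguity codes and alignment gaps are treated alike —
deleted, never fractionally matched. When 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 the
correction is undefined and the pair is flagged SATURATED; a pair with no
comparable site is UNDEFINED. Both are excluded from every aggregate (with a
per-species exclusion count), never clamped: clamping would invent data.
Distances are proportions internally; percent appears only in report output,
rounded to two decimals.

The all-pairs matrix is computed from one-hot base indicators with BLAS
matrix products (7 Gram-type products per matrix), so libraries of a few
thousand sequences take seconds on one core.

Per species the audit reports the mean and maximum intraspecific distance
(species with ≥ 2 specimens), and min.NN: the smallest distance from any of
its sequences to the most similar sequence of any other species
(specimen-level, not centroid-level). A species "has a barcode gap" when
min.NN strictly exceeds its maximum intraspecific distance. Nearest-neighbour
ties are broken by lexicographic species name, with all tied species
reported.

## MOTU delimitation

`threshold_cluster` is single-linkage clustering: two specimens share a MOTU
iff a chain of pairs each within the threshold connects them. Single linkage
was chosen over complete/average linkage because the major barcode
delimitation families (BIN/ABGD-like) are connectivity based, and because it
makes the refinement property exact: the partition at a smaller threshold
provably refines the partition at a larger one. Labels are `M1, M2, …` in
first-appearance order so outputs diff cleanly. Saturated pairs act as
infinite distances.

`scan_thresholds` chooses the threshold automatically by maximising a
barcode-gap score over a candidate grid (default: 0 plus the midpoints
between consecutive distinct pairwise distances). The score of a candidate's
partition is

score(t) = (min between-MOTU distance) − (max within-MOTU chain distance),

where the within term is the largest single-linkage merge height used inside
any MOTU. Measuring cohesion by chain rather than cluster diameter is a
deliberate choice: when two species share identical haplotypes, any
connectivity-based partition must put them in one MOTU whose *diameter*
spans interspecific divergence, and a diameter-based score then turns
negative at every biologically sensible threshold, collapsing the scan to
near-haplotype thresholds. The chain measure is the single-linkage-native
notion of cohesion and keeps one sharing pair from erasing the gap signal of
the whole library. Under single linkage the partition, and hence the score,
changes only at merge heights, so the scan evaluates each distinct partition
once regardless of grid density; the between term equals the next merge
height. Ties are broken by larger threshold, then fewer MOTUs; partitions
with one MOTU or only singletons are excluded unless nothing else exists, in
which case the single-MOTU partition is returned with a degeneracy flag.

The scan is a transparent stand-in for published distance-based
delimitation services (ASAP and relatives) whose internal scoring is not
reproduced here; partitions produced by such services (or BOLD BINs, or
tree-based bPTP) are consumed as first-class imported partitions via extra
metadata columns and audited identically.

`per_group_scan` repeats the scan independently within a metadata group
(typically subfamily), mirroring the practice of delimiting clades
separately — different clades genuinely settle on different thresholds.
Groups with fewer than two specimens are skipped with a warning.

## Congruence

For each species under each partition: `n_motus` is the number of distinct
labels among its specimens, `shares` is true when any of those MOTUs also
holds another species, and the category follows the 0/1/k convention
(0 sharing, 1 congruent/unique, k ≥ 2 split into k). Sharing and splitting
are orthogonal, so category counts may sum to more than the species count;
`n_both` makes the overlap explicit and the split-arity breakdown is
reported separately because "number of split species" and "split into how
many" answer different questions.

Two methods *agree* on a species iff (a) they induce the same set partition
of its specimens and (b) the same multiset of heterospecific specimens
(keyed by species) co-occurs with it across its MOTUs. The literature never
defines "identical MOTU assignment" operationally; this is the weakest
definition computable from partitions alone that still notices a method
quietly merging a focal species with a different partner. Agreement is
computed on the intersection of the partitions' specimen domains (imported
partitions may not label every specimen), and Venn-style pattern counts sum
to the number of species in that common domain.

Case tables mirror the audit surfaces taxonomists actually read: MOTUs
containing several species with per-pair minimum distances and an
identical-haplotype flag, and species split over multiple MOTUs whose
maximum intraspecific distance exceeds a threshold (default 3%, the
conventional deep-split bar). `motus_per_species_by_subset` counts distinct
MOTUs per species in two specimen subsets (e.g. regional vs continental
sampling).

## Neighbor-Joining trees

Classical NJ on the Q criterion with deterministic lowest-index tie-breaks.
Negative estimated branch lengths — routine with noisy distances — are
clamped to zero with the deficit moved to the sister edge, preserving the
path length between the joined pair. On additive matrices the method is
exact (verified against brute-force topology enumeration in the tests). No
bootstrap support is computed. Trees are unrooted; rooting is left to the
consumer. `collapse_by` condenses monophyletic species or MOTU leaf sets to
single `label (n=k)` leaves and flags non-monophyletic groups instead of
collapsing them.

## MOTU counts vs sampling effort

Tree-based delimitation tends to oversplit well-sampled species, so MOTUs
per species grows with specimens per species. The model is an NB2 negative
binomial GLM with log link: mean μ = exp(β0 + β1·x), variance μ + μ²/θ.
NB2 was chosen (and named explicitly) because "negative binomial" alone is
ambiguous; it is the default of the common mixed-model count packages.
Fitting alternates Fisher-scoring IRLS for β — with step halving, so the
log-likelihood trace is non-decreasing by construction — and bounded
golden-section maximisation of the profile likelihood over log θ in
[10⁻³, 10⁸]. When the profile is flat towards large θ (equi- or
under-dispersed data) θ pins at the upper bound, the Poisson limit, rather
than jittering on the plateau. Convergence: relative log-likelihood change
< 10⁻⁸, at most 100 outer iterations (non-convergence is flagged on the
fit, not raised). Standard errors come from the inverse observed information
X′ diag(θμ(θ+y)/(θ+μ)²) X; the slope is tested with a Wald z. Species with
a single specimen are excluded by the caller: a one-specimen species cannot
reveal splitting.

## Synthetic libraries

`simulate_library` emulates the statistical shape of a national-scale
barcode library:

* **Species tree.** A star: each species' ancestor evolves from a common
  random root along a stem of (target_inter − target_intra)/2 expected
  substitutions per site; specimens radiate from the ancestor with stems of
  target_intra/2. Expected conspecific distance ≈ target_intra (default
  0.4%), expected heterospecific distance ≈ target_inter (default 6.5%). A
  star rather than a birth–death tree because every downstream analysis uses
  only distance structure, and the star keeps the interspecific expectation
  exact. Consequence worth knowing: *nearest-neighbour* distances are the
  minimum over many approximately equal species pairs, so their mean
  (~4.3% at 476 species) sits below the pairwise mean by an extreme-value
  effect — real libraries, with genuinely close sister pairs, share this
  property for different reasons.
* **Substitution process.** Per-site event simulation under the K2P model:
  a substitution is a transition with probability κ/(κ+2) (κ default 2),
  otherwise one of the two transversions; branch length is expected
  substitutions per site. The K2P distance estimator is therefore
  asymptotically unbiased on the output, which the calibration tests
  exploit.
* **Sampling effort.** Specimens per species follow a fixed distribution on
  1–24 with explicit singleton (14%) and doubleton (9%) masses and geometric
  decay beyond, giving median 5 — the shape of uneven real-world sampling.
* **Pathologies.** `SHARE_PAIR`: the recipient species is a recently
  diverged sister of the donor (ancestors one intraspecific unit apart) and
  additionally carries one verbatim copy of a donor haplotype, so min.NN is
  exactly 0 and the two barcode clouds genuinely overlap — the way barcode
  sharing arises in young or hybridizing species pairs. `DEEP_SPLIT`: one
  sub-clade of the species sits on an extra branch of
  deep_split_factor × target_intra (default 10×, i.e. 4% — comfortably
  above the 3% deep-split convention). The default is set by distance
  arithmetic: the factor must keep the *smallest* realized split (one
  Poisson-distributed branch over 658 sites, minimum over dozens of
  injections) above the within-species merge-height range, and 8× leaves no
  margin at this sequence length. `SINGLETON` forces n = 1. Scenario
  species are disjoint; infeasible allocations fail before generation.
* **Truth.** Alongside the morphospecies partition, the generator emits the
  expected barcode-level partition (share pairs merged, deep splits split) —
  the best any distance-based method could do — plus per-scenario
  annotations and substitution-event counts.

Everything is deterministic given the seed; fixture seeds are published in
the fixture manifests.

What the generator does **not** emulate: coalescent genealogies and shared
ancestral polymorphism, recombination, codon structure and selection,
sequencing error, missing data beyond an optional uniform ambiguity rate,
and geographically structured variation. Passing tests on synthetic data
therefore show that the *pipeline machinery* is correct and calibrated, not
that any particular real fauna has these properties.

## Problem sizes and defaults

The standard test and reproduction scale is 476 species in five subfamilies
(13/3/146/248/66 species), ~2 500–3 100 specimens at 658 aligned sites —
the scale of a complete national family-level library; the full audit at
that scale runs in well under a minute on one core. Key defaults: quality
filter ≥ 500 unambiguous sites and ≤ 2% ambiguity; deep-split report bar 3%
maximum intraspecific distance; nearest-neighbour alert threshold 2%; NB2
reference parameters (β0 = 0.2335, β1 = 0.0790, θ = 5) for calibration
studies of the count model.

## Known limitations

* The threshold scan is a transparent reconstruction of distance-based
  delimitation, not a reimplementation of any published service's scoring;
  imported partitions are the right tool when fidelity to a specific method
  matters.
* Single linkage chains: one misidentified or chimeric sequence can bridge
  two species at low thresholds. The congruence tables make such cases
  visible but the clustering itself will not resist them.
* K2P saturation handling excludes pairs rather than substituting a
  distance; on deeply divergent inputs (not the intended use) many pairs
  may vanish from the aggregates.
* The NB2 fit assumes independent species; phylogenetic autocorrelation of
  splitting propensity is not modelled.
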