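# Methods

This note documents the statistical and numerical choices behind
`barcodegap`: what each stage computes, the conventions that make results
bit-reproducible, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Distance model

Distances are Kimura 2-parameter (K2P):
`d = -½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)` with `P` the transition and `Q` the
transversion proportion. K2P assumes equal base frequencies and a single
transition/transversion rate ratio; neither holds exactly for AT-rich
mitochondrial data, but K2P remains the de-facto standard in barcoding, and
using it keeps results comparable across studies. No other substitution
model is offered by design.

Conventions:

* **Pairwise deletion.** For each pair, only columns where both sequences
  carry an unambiguous A/C/G/T are compared. IUPAC ambiguity codes and N
  are treated as missing, never fractionally matched, so transition and
  transversion counts stay integral. Complete deletion (dropping a column
  for all pairs if any sequence is ambiguous there) would discard data for
  no benefit at barcode-scale alignments.
* **Saturation.** When `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` the correction is
  undefined. Default policy: raise, naming the pair — saturated barcode
  pairs almost always indicate a contaminant or misalignment, and silence
  would hide that. Opt-in policy (`on_saturation="missing"`, used by the
  pipeline): record the pair as NaN with a logged warning and exclude it
  from all downstream pooling.
* Distances are kept at full double precision internally; only rendered
  reports round (3 decimals by default).

The matrix computation is cross-checked in the test suite against an
independent per-pair counting oracle and against `ape::dist.dna(model =
"K80", pairwise.deletion = TRUE)` in R, agreeing to ~1e-16.

## Barcode-gap statistics

Pairwise distances are partitioned by shared vs differing species label.
Two gap criteria are reported: the distribution-level comparison
(medians/ranges plus a Wilcoxon rank-sum test) and the strict
`min(inter) > max(intra)` extremes criterion, also evaluated per specimen
(furthest conspecific vs nearest non-conspecific).

Wilcoxon test: exact null distribution when both samples have ≤ 25 values
and the pooled sample is tie-free; otherwise the normal approximation with
tie and continuity correction (both via `scipy.stats.mannwhitneyu`). Both
the two-sided and the one-sided (inter stochastically greater) p-values
are reported, since the convention varies between studies. **Caveat,
attached to every report:** the `n(n−1)/2` pairwise distances are not
independent observations, so the p-value describes the observed separation
rather than supporting a calibrated inference. Medians use the
midpoint-of-central-values convention for even counts. Boxplot data follow
Tukey's rule (whiskers to the most extreme point within 1.5 IQR).

## Threshold optimisation

The pooled pairwise distances are smoothed with a Gaussian kernel using
the rule-of-thumb bandwidth `0.9 · min(sd, IQR/1.34) · n^(−1/5)` (sample
sd, `ddof=1`; if IQR = 0 the sd alone; if the values are constant the
input is degenerate and an error is raised), evaluated on 512 equally
spaced points spanning the data range extended by 3 bandwidths on each
side. These specific constants are fixed — not tunable — because the
threshold is only reproducible if the density estimate is.

Local minima are grid points strictly lower than both neighbours; plateaus
are not minima (an optional plateau-tolerant mode accepts the leftmost
point of a flat valley). The *selected* threshold is the first (smallest)
minimum — the dip between the conspecific mode near zero and the
heterospecific mode — but all minima are reported so a user can override
the choice. When no interior minimum exists (unimodal distances: a single
species, or no gap) the pipeline falls back to the fixed 1% threshold with
a prominent warning rather than aborting.

The bandwidth rule is scale-equivariant, so multiplying all distances by a
constant multiplies every reported minimum by the same constant; this is
property-tested.

## Identification criteria

All three criteria are leave-one-out: the query is removed from the
database before matching.

* **Best close match** — nearest candidate(s) within a threshold
  (default: the optimised density-dip value, logged with the output):
  nothing within the threshold → `no_id`; tied-nearest all conspecific →
  `correct`; none conspecific → `incorrect`; mixed → `ambiguous`.
* **Near neighbour** — no threshold; `true` iff any tied-nearest candidate
  is conspecific.
* **Threshold identification** — every candidate within a fixed 1%
  distance (the BOLD service rule, emulated locally): empty → `no_id`,
  all conspecific → `correct`, mixed → `ambiguous`, none → `incorrect`.

Tie-breaking and boundaries are fixed conventions: candidates within a
relative 1e-12 of the minimum distance count as tied (exact float equality
is too brittle for recomputed matrices); threshold comparisons are
inclusive (`d ≤ t`, reading "within the threshold" inclusively); summary
percentages are rounded half-up to two decimals, so e.g. 3/56 → 5.36 and
27/56 → 48.21.

## MOTU delimitation and congruence

MOTUs are connected components of the graph with an edge wherever
`d ≤ t` — single-linkage chaining, so two specimens further apart than the
threshold share a MOTU whenever a chain of intermediates links them. The
edge rule is inclusive for the same reproducibility reason as above. MOTU
labels are content-derived (size-descending, then lexicographically
smallest member), so partitions and labels are invariant under input
order; this is property-tested, as is equivalence with a brute-force
transitive-closure oracle.

The congruence report gives each MOTU's species composition, each species'
MOTU spread, and the mismatch list: specimens whose label differs from
their MOTU's majority species (majority ties broken lexicographically and
flagged). The report presents raw composition only; deciding which
mismatches are misidentifications and which are real lineage sharing is
the user's taxonomic judgement, not the package's.

A single-linkage dendrogram is exportable as an ultrametric newick string
(node height = half the merge distance, so cophenetic distance equals the
single-linkage merge distance); cutting it at a distance threshold
reproduces `delimit_motus` exactly, which the tests verify via an
independent newick-parsing cut.

## Synthetic-data generator

The generator emulates the distance structure the analyses consume, not
sequence evolution in full:

* **Topology.** A star within and between species: root → species
  ancestors (branch `inter_depth`, default 0.075 substitutions/site) →
  individuals (branch `intra_depth`, default 0.002). No coalescent, so
  expected pairwise divergences are exact path lengths: `2·intra_depth`
  within species and `2·(inter_depth + intra_depth)` between
  (`expected_k2p`), i.e. ~0.004 and ~0.15–0.154 at the defaults — the
  intra/inter medians typical of a congeneric COI study.
* **Substitution process.** The two-parameter process (transition rate
  κ = 2 relative to each transversion type), applied per site via its
  exact finite-time transition probabilities, so branch lengths are exact
  expected substitution counts rather than Poisson approximations, and
  K2P applied to the simulated data is estimating its own generating
  parameter.
* **Composition.** The root sequence is drawn from the configured base
  frequencies (default A 0.242 / C 0.211 / G 0.183 / T 0.364, 654 sites).
  The two-parameter process is stationary on the *uniform* composition, so
  tip composition drifts slightly toward 0.25 (about −0.011 on T at the
  default depths) — deliberately mirroring the standard mismatch of
  running K2P on compositionally skewed data. Note also that all rows
  descend from one root draw, so per-dataset composition has a sampling sd
  of ~0.017 per base; composition checks in the tests therefore compare
  seed-averaged composition against the closed-form tip expectation.
* **Label errors.** `inject_mislabels` reassigns n specimens' observed
  labels to a uniformly random *different* species, recording exactly
  which, to emulate morphological misidentification with known truth.
* **Determinism.** One `numpy` generator seeded from the config; identical
  config + seed gives byte-identical FASTA. Seeds are mandatory in the
  CLI; there is no wall-clock seeding.

What passing tests on this generator do **not** show about real data:
there is no rate variation among sites or lineages, no indels, no
coalescent polymorphism (so no para/polyphyly at the sequence level), no
geographic structure, and label errors are independent of phenotype,
whereas real misidentifications are correlated with morphological
similarity. The generator validates the *machinery* — that the pipeline
recovers a known structure exactly — not the biological difficulty of any
particular group.

## Problem sizes and runtime

The packaged tests and the acceptance script run the full pipeline at the
study scale the package targets (56 specimens × 654 sites, 1 540 pairwise
distances), plus oracle comparisons on many small random instances
(8-specimen matrices, ≤ 10-value rank-sum enumerations, 50-seed mixture
sweeps); the whole suite completes in a few seconds on one CPU.

## Known limitations

* Only K2P; groups where model choice matters need external distances
  (the square-TSV reader accepts externally computed matrices).
* The rank-sum p-value's non-independence caveat above.
* First-local-minimum threshold selection can pick a spurious shallow dip
  if the intraspecific mode is ragged; all minima are reported for manual
  override.
* Single-linkage chaining can fuse species connected by intermediate
  haplotypes; that is the intended semantics of the delimitation rule, not
  a defect, but users should inspect the MOTU-count-vs-threshold curve
  (`motu_count_curve`) near the chosen threshold.
* Leave-one-out scoring against *observed* labels penalises more than the
  mislabelled specimens themselves: a mislabelled specimen also sits in
  the nearest-neighbour sets of its true conspecifics, so label errors
  have a multiplier effect on "incorrect"/"ambiguous" rates. The
  congruence report, not the identification table, is the right tool for
  locating the mislabelled specimens.
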