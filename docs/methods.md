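# Methods

## The consensus model

A called variant is identified by the tuple (chromosome, 1-based
position, reference allele, alternate allele).  Matching is exact on all
four fields after normalization (uppercase alleles, optional chr-prefix
harmonization at read time); no indel left-alignment is performed, and
analyses are restricted to SNVs (`select_snvs`) inside evaluable regions
(`restrict`, BED half-open convention, membership tested at pos−1).
Note that although VCF records carry an ID column, it is almost always
"." in somatic call sets, so the alternate allele is the discriminating
fourth field.

For *n* replicate call sets of one mapper × caller pipeline, the
detection count of a key is the number of call sets containing it, and
the consensus set at threshold *m* is every key with count ≥ m
(inclusive).  Consequences used as test invariants: consensus(·, 1) is
the union, consensus(·, n) the intersection; the sets are anti-monotone
in m, so TP is non-increasing and FN non-decreasing down a sweep table;
for n = 3 the union of the three pairwise intersections equals the m≥2
set and their common intersection the m≥3 set; all results are invariant
under permutation of the call-set list.  Votes are never pooled across
different pipelines (an explicit `allow_mixed` override exists for
exploration).

Three grouping schemes turn a replicate manifest into voting groups:
**within_center** (one group per center × pipeline over that center's
replicates; centers with a single replicate are excluded with a logged
notice), **cross_center** (one group per replicate number × pipeline
spanning centers), and **all_centers** (one group per pipeline over
every center × replicate; with three triple-replicate centers that is
nine voters per pipeline).

## Evaluation

Scoring a call set against a truth set (both already region-restricted
and SNV-selected) gives TP = |calls ∩ truth|, FP = |calls \ truth|,
FN = |truth \ calls|; precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R) = 2TP/(2TP+FP+FN).  Truth mass is conserved: TP+FN equals
the restricted truth size for every call set scored against it.
Degenerate 0/0 ratios are reported as 0.0 with an explicit
`*_defined = False` flag rather than NaN.  Reports round to 3 decimals
with round-half-even (`decimal`-based, not float `round`); internal math
is unrounded.  The golden check for these formulas is the published
within-center benchmark table for the FD-center replicates
(`replicall.reference`): 18 rows of (TP, FP, FN, precision, recall, F1)
at truth size 1,159, all reproduced at printed precision.

## The synthetic study generator

The generator emulates a multi-center tumor/normal exome replicate study
at desk scale.  Defaults (all overridable via `StudyConfig`):

* **Truth set** — 1,159 unique SNVs (the benchmark truth size) placed
  uniformly in exome-like targets: 10 chromosomes × 120 targets of
  1,000 bp spaced every 8,000 bp (1.2 Mb covered).  VAFs are drawn from
  a mixture of clonal Gaussian peaks at 0.50 (weight 0.45, sd 0.05) and
  0.25 (weight 0.25, sd 0.04) plus a subclonal Beta(2, 8) tail
  (weight 0.30), clipped to [0.02, 0.98].
* **Centers** — three triple-replicate centers with mean coverages
  (55, 60, 65)×, (95, 240, 110)× and (100, 105, 95)×: one
  low-coverage center, one with an outlier deep replicate, one moderate
  and even, so coverage-driven performance differences are visible.
* **Sensitivity** — a truth variant is detected independently per call
  set with probability sigmoid(slope · VAF · depth + intercept), with
  per-site depth ~ Poisson(mean coverage × mapper efficiency; bwa 1.0,
  bowtie 0.92).  Caller defaults (slope, intercept): mutect
  (0.18, −0.3), strelka (0.15, −0.4), ss (0.12, −0.5) — ordered the way
  the three callers rank in practice.  `CallerModel.constant(s)` gives
  coverage-independent sensitivity (slope 0) for calibration runs, and
  `CallerModel.perfect()` the noiseless limit.
* **False positives, three pools** — (i) center-shared artifact sites
  (80 per center), recurring across that center's replicates and
  pipelines; (ii) caller-shared systematic sites (mutect 25, strelka 60,
  ss 140), recurring wherever that caller runs; (iii) private
  Poisson-count sites unique to a call set (rates 150/250/450).  Each
  shared-pool site enters a call set with inclusion probability 0.7.
  Pool and truth positions are drawn without collision; private sites
  are rejected against truth and pools.
* **Attributes** — observed VAF = Binomial(depth, VAF)/depth for true
  calls and Beta(1.5, 12) for artifacts; QUAL Gaussian around a
  caller-level mean (higher for true calls, overlapping distributions);
  tumor/normal depths Poisson.  These feed the classifier as features.

Randomness: one `numpy` SeedSequence stream per (center, replicate,
pipeline) plus separate streams for truth and pools, all keyed on the
master seed — so adding a pipeline or replicate never perturbs existing
call sets, and materialization is byte-identical across runs.

Under these defaults the within-center m-sweep peaks at m=2 in mean F1
(union ≈ 0.71, majority ≈ 0.93, intersection ≈ 0.87 averaged over
groups and seeds): majority voting removes nearly all private noise
while the strict intersection pays too much recall.  This is the
qualitative behavior of real replicate benchmarks and is asserted, seed-
averaged, in the acceptance tests.

**What the generator does not emulate.**  Detection events are
independent across replicates given the VAF; there is no read-level
error model, no center-level correlated dropout (shared capture kits or
library preparation failing the same sites in all of a center's
replicates), no indels, and no tumor-purity model beyond the VAF
mixture.  One observable consequence: with the three-pool mechanism,
center-shared artifacts survive within-center voting but are split
across cross-center groups, so under the default pools cross-center
m≥2 consensus has the precision edge and the within-center scheme does
not dominate it.  In real multi-center data the within-center approach
can win through center-correlated coverage effects on recall — a
mechanism outside this generator's scope.  The generator's test suite
asserts only what the mechanism implies: with pools zeroed the two
schemes are statistically indistinguishable, and with center pools on
the direction is determined by the pool configuration.  Passing tests
therefore demonstrate the algebra, calibration and orderings above, not
agreement with any particular real study's absolute numbers.

`estimate_profile` inverts the generator: per-call-set sensitivity is
the detected fraction of truth and the FP count is |calls \ truth|.
With constant sensitivity 0.8 and private rate 100 (pools off) the
averages over 30–100 simulated studies recover the configured values
within ±0.03 and 3 standard errors respectively.

## Label-transfer experiment

Candidates are the union of one replicate's per-caller call sets plus an
equal number of sampled in-region negative positions (simulation mode
only; negatives carry zeroed caller features).  Features per candidate:
per-caller membership flag, per-caller QUAL with a paired missingness
flag, shared VAF/tumor-depth/normal-depth (first caller carrying the key
wins, missing imputed to 0 with flags), and the cross-caller detection
count.  Labels come either from the truth set ("gt") or from the
within-center consensus of one pipeline at threshold m.  The split is a
chromosome holdout — train on the first five chromosomes, test on the
rest — because replicates of a single tumor would otherwise leak
positions between train and test.

The classifier is a seeded `HistGradientBoostingClassifier`
(scikit-learn, 200 iterations by default, decision threshold 0.5, never
tuned on test data).  A gradient-boosted tabular model was chosen over
any specific deep architecture because the question under study — how
much performance is lost when consensus sets replace validated truth as
training labels — is architecture-agnostic and must run in seconds.
Evaluation is always against truth membership of the test candidates,
never against the training labels; truth variants called by no caller
are not candidates and hence invisible to every model equally.  On the
default study the m≥2-labeled model tests within ~0.02 F1 of the
truth-labeled model (asserted ≤ 0.05 seed-averaged), while m=1 labels
(union: noisy positives) and m=3 labels (intersection: missing
positives) cost more — the label-precision/recall trade moves opposite
to the raw consensus direction, which is surfaced in the experiment
table but deliberately not asserted as an invariant.

## Numerical and design conventions

* FILTER "." counts as passing (unfiltered caller output carries no PASS).
* Multi-allelic records split into one key per alternate allele;
  duplicate keys keep the first record's attributes (and, in consensus
  merges, the first contributing call set in list order wins).
* VCF output is sorted karyotype-aware (chr2 before chr10), then by
  position, ref, alt; round-trips exactly through the reader.
* Overlapping *and* adjacent BED intervals merge on construction.
* Inclusive thresholds everywhere (≥ m).
* Reported metrics: 3 decimals, round-half-even; the printed benchmark
  cells are consistent with this choice.
* Problem sizes in the shipped checks — 30–100 simulated studies for
  seed-averaged claims, 300–1,000 random triples for brute-force
  agreement, 3–5 studies for classifier comparisons — are the package's
  default verification scale; all are single-CPU and complete in
  seconds to a few minutes.

## Known limitations

Exact-key matching cannot credit equivalent representations of the same
indel (out of scope: SNVs only); votes are unweighted (no quality-aware
voting); the simulator's independence assumptions above; and the
classifier experiment measures label quality relative to the bundled
generator, not any specific production feature extractor.
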