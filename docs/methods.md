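# Methods

This note records the statistical conventions, modelling choices and known
limitations behind `listcensus`, at the level of detail a user would need to
trust or challenge its outputs.

## Data model

Both survey methods consume the same atom: a *detection event* — one
timestamped sighting of one species with a count of individuals in view.
Continuous footage is thus represented as discrete snapshots; this is the
minimal structure from which both MaxN (a max over snapshot counts) and the
MLT master list (a chronology of qualifying records) are computable. Species
codes are opaque exact-match strings (no taxonomy resolution), and times are
seconds from video start, because the re-detection rule is relative, not
wall-clock.

## MLT sampling rules

- **Master list.** A species' first detection is always recorded. A later
  detection is recorded iff strictly more than `gap_s` seconds (default 180,
  "more than three minutes") have passed since that species' previous
  detection, recorded or not: detections approximate presence in the field
  of view, so the clock restarts at every sighting. At `gap_s = 0` every
  detection qualifies; with `gap_s` beyond the video duration each species
  appears at most once.
- **Segmentation.** Records are walked in order; a record joins the open
  list iff its species is not already in it; at k species (default 5) the
  list closes. Every master-list record is either placed or skipped as a
  within-open-list duplicate, never both. Simultaneous detections keep input
  row order (stable sorts throughout), making the partition deterministic.
- **Pooling.** Within one habitat (status × depth), the end-of-video partial
  lists are concatenated — ascending `video_id`, then original order; the
  ordering is a config policy because any choice is defensible — and
  re-segmented. A final leftover shorter than k is kept as one last
  (incomplete) pooled list so that no master-list information is discarded
  for richness estimation. Pooled lists are flagged: they enter richness
  matrices but are excluded from the multivariate analysis, where video is a
  random factor and pooled lists belong to no video.

## Richness estimators

The classic formula dialect is used, with every formula in one function:

- Chao2 uses the small-sample factor A = (m−1)/m and the bias-corrected
  branch Sobs + A·Q1(Q1−1)/2 when Q2 = 0; Chao1 analogously on F1/F2.
  Confidence intervals use the log-normal method on T = value − Sobs with
  the published Chao variance formulas; at T = 0 the interval collapses to
  [Sobs, Sobs].
- ACE/ICE use a rare/infrequent threshold of 10 and floor the squared
  coefficient of variation at zero; a zero coverage estimate (all rare
  individuals singletons) falls back to the corresponding Chao estimator,
  with a warning attached to the result.
- The accumulation curve randomises *sample order* (uniform permutations
  without replacement, 50 runs by default), which is what "removing sample
  order effects" requires; it is not a with-replacement bootstrap.
- Michaelis–Menten asymptotes are least-squares fits of S(t) = Smax·t/(B+t),
  initialised from the exact two-point solution through the first and last
  curve points (and solved algebraically when only two points exist).
  `runs` fits each randomised run and averages Smax; `means` fits the mean
  curve once. Both modes are provided because published tables are often
  ambiguous about which was used.
- Estimate trajectories recompute an estimator on the first t samples under
  a fixed order (input order by default; any explicit order or run-averaging
  can be supplied); the stability diagnostic is |value(m) − value(m−1)|.
- For MaxN-side abundance-based estimators (Chao1, ACE), species abundance
  is the summed MaxN across a habitat's videos, rounded to integers — the
  only integer-valued aggregate the data model offers. Incidence-based
  estimators binarise the video × species matrix.

Verification: all six closed-form estimators are checked in the test suite
against an independently transcribed, loop-based version of the published
formulas on random matrices (tolerance 1e-9), and against the `vegan` R
package (`specpool`, `estimateR`) on shared cases. The only deliberate
difference from `vegan` is Chao1, where `vegan` reports the bias-corrected
variant while this package uses the classic form with a bias-corrected
branch only when F2 = 0.

## Diversity indices

Fisher's alpha is the bracketed Brent root of S = α·ln(1 + N/α) (tolerance
1e-9; requires S ≥ 2 and N > S, otherwise no finite root exists). Brillouin
diversity uses log-gamma; its evenness divides by the Brillouin value of the
maximally even partition of N into S parts. Pielou's J is H′/ln S. Natural
logs throughout. Jackknife standard errors are first-order
leave-one-sample-out on the pooled counts: SE² = ((m−1)/m)·Σ(θ₍ᵢ₎ − θ̄)².
Input counts are integer by construction — list counts on the MLT side,
summed MaxN on the MaxN side — because Brillouin's factorials demand it.

## Multivariate analysis

- **Distance.** Square-root transform, then a dummy species with constant
  value 1 appended to every sample (√1 = 1, so transform order is
  immaterial), then Bray–Curtis. The dummy bounds distances between
  depauperate samples and makes two empty samples identical (distance 0)
  rather than undefined.
- **Partitioning.** Sums of squares come from the Gower-centred matrix
  G = −½·J·D²·J; for any grouping, tr(H·G) with H the block-averaging
  projection is the among-group SS, and each model term's SS subtracts the
  SS of all strictly marginal terms (those whose factor closure is a strict
  subset). Degrees of freedom follow the same subtraction on cell counts.
  This is the classical balanced decomposition; it tolerates mild imbalance,
  and terms whose df fall to zero or below under a reduced design are
  dropped (coarsest first) with a warning, their variation flowing to the
  finer terms and residual.
- **Denominators.** Pseudo-F for a term uses, per expected-mean-squares
  rules for mixed models, the mean square of the lowest-order *random* term
  whose closure strictly contains the term's (Status over Site(Status);
  Depth and Status × Depth over Depth × Site(Status); Depth × Site(Status)
  over Video(Site × Depth) when videos carry list replicates); otherwise the
  residual. Exact equivalence with any particular commercial package's
  internal choices is not claimed.
- **Permutations.** p = (b+1)/(n_perm+1). The exchangeable units for a term
  are the cells of its denominator term: whole units are permuted within
  strata given by the denominator's factors that are neither in the tested
  term nor nested under it (sites exchange across status levels; a site's
  depth cells exchange within the site). With a residual denominator,
  samples permute within the term's nesting parents. Unequal unit sizes fall
  back to within-strata sample permutation — an approximation accepted for
  mildly unbalanced reduced designs.
- **Monte-Carlo p.** The asymptotic permutation distribution is sampled by
  treating numerator and denominator sums of squares as mixtures of
  independent chi-squares weighted by the eigenvalues of G (negative
  eigenvalues of the non-Euclidean Bray–Curtis embedding are kept). With a
  single eigenvalue — univariate Euclidean data — the simulated ratio is
  exactly F-distributed, which the tests exploit as an oracle.

Calibration: the suite verifies that one-way univariate pseudo-F equals the
classical ANOVA F to 1e-9, that SS_total = (1/n)·Σ d²ᵢⱼ, and that the
empirical type-I error over 1000 null simulations at 999 permutations lies
in [0.03, 0.07].

## Simulator

The generator emulates a factorial BRUV survey: status (fished/ROA) × depth
(deep/shallow) × sites (nested in status, with lognormal per-site,
per-species effects, σ = 0.2) × one-hour deployments.

- Species abundances are lognormal(0, 1.2) over 90 species by default
  (log-series available); habitat effects multiply abundance per status and
  depth level, scalar or per-species (per-species contrasts produce
  compositional turnover, the interesting case for PERMANOVA power).
- Abundance counts *individuals*. Individuals travel in groups — size 1 for
  solitary species, zero-truncated negative binomial (mean 5, dispersion
  0.7) for the schooling 20% — so group arrivals are Poisson with rate
  abundance × `arrival_rate_scale` / mean group size per hour. A detection's
  count in view adds a Poisson number of co-present groups over a 60 s dwell
  window. This makes the in-view count grow with true density (without
  which MaxN would carry no abundance signal for solitary species once
  detection saturates) and reproduces the known method contrast: schooling
  concentrates individuals into fewer arrivals, depressing list-presence
  indices and inflating per-sighting counts.
- The default `arrival_rate_scale` of 0.2 yields ~4–6 list samples per
  video and per-habitat Sobs around 60–70% of the pool — the sampling
  intensity regime of real reef surveys. The rank-recovery experiments
  instead use scale 2.0 with 12 videos per habitat: the smallest round
  values at which every species is expected at least once per habitat,
  while staying below the saturation regime in which the re-detection gap
  censors common species (a real phenomenon of the 3-minute rule, visible
  in the simulator at high rates).
- Deliberate simplifications: arrival processes are independent across
  species (no attraction/repulsion around bait), group sizes are i.i.d.
  across a species' detections, and detection probability does not vary
  with distance, light or habitat structure. Passing tests therefore show
  that the *methods* behave as claimed under a faithful sampling process,
  not that any particular field system meets these assumptions.

## Problem sizes in tests and the acceptance script

The estimator-equivalence checks use 100 random matrices of up to 10 × 20;
type-I calibration uses 1000 null datasets of n = 12 at 999 permutations;
rank recovery uses 60–100 seeded surveys at the scale-2.0 conditions; the
power experiment uses 30 surveys with a two-fold compositional status
contrast, efforts of 5/3/2 videos per habitat, and Monte-Carlo p-values
(500 draws) — the same p-value type a field analysis would use for designs
this small. These sizes were chosen so each experiment's Monte-Carlo error
is comfortably below the margins being asserted.

## Known limitations

- The SS decomposition is exact for balanced designs only; severely
  unbalanced surveys should be interpreted with care (dropped-term warnings
  are the signal to look for).
- The restricted-permutation scheme is an approximation for interaction
  terms and for unbalanced units (falls back to within-strata sample
  permutation rather than residual rotation).
- Published top-ten tables sometimes rank on unrounded index values; when
  only rounded counts are available, tie handling can differ from the
  original ranking (the package's tie policy — descending value, then
  species name — is deterministic, and printed rank columns can be used
  directly where exact reproduction of a published ranking matters).
- No coverage-based rarefaction/extrapolation (Hill numbers); only the
  eight estimators above.
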