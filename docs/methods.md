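# Methods

## The model of an identity signal

A call is an 11-vector: 10 peak-frequency-contour (PFC) values sampled
evenly in time across the call, plus duration.  Identity signalling is a
variance phenomenon: a feature informs about identity to the extent that
individuals differ in it (between-individual variance σ²_B) more than each
individual varies from call to call (within-individual variance σ²_W).
Every metric in the package is a different summary of that ratio.

Contours of different lengths are reduced to 10 samples by linear
interpolation at evenly spaced time points, endpoints included (sample i at
fraction i/9 of the call).  This is time-normalised resampling, not
pairwise alignment: each call's features depend on that call alone, which
keeps downstream statistics well defined.  Interpolation cannot overshoot
the traced contour and preserves monotone segments; resampling an already
10-point uniform contour is the identity.

## Score space

Features are z-scored (mean 0, SD 1, denominator n−1) and rotated onto the
principal components of the standardized data.  All components are kept
and the scores are deliberately *not* rescaled: the per-component variance
ratios are exactly what HS consumes.  Eigenvector signs are fixed by
making the largest-magnitude loading of each component positive, so score
files are reproducible across platforms.  Because the rotation is
orthogonal, Euclidean quantities (WID, BID) are identical in feature and
score space — a property the tests assert to 1e−8.

## HS, signature capacity, DS, IVS

Per component, a one-way fixed-effects decomposition by individual gives
SS_total and SS_within; `HS_c = ½ log₂(SS_total/SS_within)` and HS is the
sum over components.  Two choices are configurable because the field's
conventions vary and neither can be called canonical:

- `hs_variant`: sum over all components, or only those with a significant
  individual effect (ANOVA p < 0.05, the default headline value; both are
  always reported).
- `hs_estimator`: the plain sums-of-squares ratio (default) or the
  df-corrected mean-squares ratio.

Signature capacity is `⌊2^HS⌋` — the floor, not rounding, consistently
with reading 2^HS as "how many individuals the signal can keep apart"
(3.98 bits support 15 full signatures, not 16).

DS is leave-one-out classification accuracy of an LDA with shared pooled
within-class covariance; priors default to class call-proportions of the
full sample (uniform priors available).  A singular pooled covariance
raises an error advising score truncation (`ds_components`) rather than
silently regularising.  IVS = DS/(100/n) = DS·n/100, reported to two
decimals, makes discrimination comparable across samples with different
numbers of individuals.

## WID, BID

WID_i is the mean Euclidean distance of individual i's calls to its own
centroid; BID_i the distance from the population centroid to i's centroid.
The population centroid is the mean over *all calls*, so individuals with
more calls pull it harder; this matches the definition of the statistic as
an analogue of the between-group component of an F-test, and is asserted
by a dedicated test (unequal call counts shift the centroid).  Individuals
with a single call have undefined WID and are skipped with a warning.

## Acoustic niche overlap

Individual i's calls are modelled as N(μ_i, Σ_i) in the leading PC
dimensions.  Parameters get the noninformative conjugate posterior:
Σ ~ Inverse-Wishart(n−1, S) with S the sample sum-of-squares matrix, and
μ | Σ ~ N(x̄, Σ/n).  The α-level niche region of a parameter draw is its
Mahalanobis ellipsoid at the χ²_d(α) quantile.  The directional overlap
i→j is the posterior-averaged probability that a call simulated from i's
distribution lies in j's region; each Monte-Carlo draw pairs one posterior
draw of i (generating the call) with one of j (defining the region).
Defaults: α = 0.99 and 10,000 Monte-Carlo draws.  The aggregate ANO of a
focal individual is the *sum* (not mean) of its row of the overlap matrix,
so it ranges 0..n−1 and its scale grows with group size — comparisons
between groups of different sizes carry that scale difference, which the
worked example in the README shows explicitly.

Numerical choices: niche dimensionality defaults to the leading components
with explained variance > 1e−8, capped at (smallest call count − 1), the
propriety limit of the inverse-Wishart; the applied cap is logged, and
fits with fewer than d+2 calls are flagged as barely proper.  Each ordered
pair's RNG stream derives from (seed, CRC32(focal id), CRC32(other id)),
so a fixed seed gives bit-identical matrices and permuting the individual
order merely permutes rows and columns.

## Group comparisons

Per-individual WID, BID and aggregate ANO are compared between two
conditions with the Wilcoxon rank-sum test: W is the rank sum of the first
sample minus n₁(n₁+1)/2; the exact two-sided p (twice the smaller tail,
clipped at 1) is used when both n < 50 and there are no ties, otherwise
the tie-corrected normal approximation with continuity correction.
Quartiles interpolate order statistics at h = (n−1)p + 1.  One test per
metric at α = 0.05, no multiplicity adjustment — three raw p-values per
two-condition comparison.

## The synthetic generator

`simulate_population` draws individual mean vectors m_i = base + b_i and
calls x_ij = m_i + e_ij, with b and e Gaussian and independent across the
11 features.  It emulates the hierarchical structure the analysis assumes
— nothing more: no call-order autocorrelation, no response-to-playback
effects, no frequency drift within a night, no non-Gaussian tails.
Passing tests on this generator therefore validate the *statistics*, not
the field-recording conditions.

Defaults, chosen once as realistic for the study system: 22 individuals ×
25 calls; base contour a rise–fall shape 630 → 1000 → 700 Hz (inside the
species' 500–2000 Hz fundamental band) with base duration 0.35 s;
σ_B = σ_W = 60 Hz per PFC feature (total call-to-call SD ≈ 85 Hz,
consistent with the observed spread of contour extremes in this species)
and 0.05 s / 0.04 s for duration.  At ratio σ²_B/σ²_W = 1 the implied
identity information is 11 × ½ log₂ 2 = 5.5 bits, inside the 4–6.4-bit
band reported for this call type.  Durations are floored at 0.05 s.
`contour_smoothness = k` shapes individual PFC offsets with k cosine basis
functions (rescaled to keep the per-feature SD at σ_B) for smoother,
more contour-like signatures; 0 (default) gives independent offsets.

Under independent features the large-sample identity information has the
closed form `expected_hs = Σ ½ log₂(1 + σ²_B/σ²_W)`.  Empirical HS carries
two finite-sample effects: an upward inflation of order 1/calls and a
downward concave-log deficit of order 1/individuals (amplified when HS is
computed after a sample-PCA rotation, which spreads the per-component
variance ratios).  The recovery tests assert both directions: bias
decreases monotonically in calls-per-individual, and its magnitude
shrinks as individuals grow.

## Problem sizes used in the test-suite

Property checks run at deliberately modest sizes chosen to make their
Monte-Carlo tolerances honest: the chance-level DS check at 10 individuals
× 25 calls averaged over 5 seeds (tolerance ±3 percentage points); the
coincident-niche limit at 800 calls, 3,000 posterior draws and 30,000
Monte-Carlo points (tolerance ±0.02 around α); the plug-in overlap against
a polar-quadrature oracle at 200,000 points (±0.01); exact Wilcoxon
p-values against full enumeration for all sample sizes up to 6; and the
two-condition directional study (14 vs 10 individuals, dense condition
given 3× the between-individual SD) over 50 replicates at 400 posterior
draws and 400 Monte-Carlo points per pair, requiring the expected
direction (higher HS, lower median aggregate ANO in the dense condition)
in at least 90% of replicates.  The full end-to-end CLI run uses the
22 vs 22 design at 1,000 draws.

## Known limitations

- ANO's aggregate scale depends on group size; only compare it across
  groups with the design in mind.
- The niche model is Gaussian; multimodal repertoires (several call
  variants per male) would violate it.
- Manual screening of badly traced contours is out of scope; validation
  is purely numerical (finite, positive, in-band frequencies).
- HS variants differ by fractions of a bit at realistic sample sizes; the
  package reports both rather than declaring one correct.
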