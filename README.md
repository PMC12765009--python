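# hootid

Vocal-individuality analysis of territorial calls, built around the male
little owl's (*Athene noctua*) "hoook" call: from per-call feature tables
(10 peak-frequency-contour samples + duration) to the standard metrics of
individual identity signalling, with a synthetic call-population generator
standing in for field recordings.

## Who this is for

Bioacousticians and behavioural ecologists asking "how individually
distinctive are these calls, and does distinctiveness differ between
groups?" — e.g. between a high-density and a low-density population, or
between males with and without calling neighbours.

## What it computes

Given calls scored on 11 features (10 evenly time-spaced peak-frequency
values f₁..f₁₀ in Hz plus duration in s), z-scored and rotated onto
principal components:

- **HS (Beecher's information statistic)** — per component
  `HS_c = ½ log₂(SS_total / SS_within)` from a one-way decomposition by
  individual, summed over components (by default over components whose
  individual effect is significant at p < 0.05; the all-components sum and
  a mean-squares estimator are also reported).  `⌊2^HS⌋` is the implied
  number of distinguishable signatures.
- **DS (discrimination score)** — % of calls assigned to the correct
  individual by linear discriminant analysis under leave-one-out
  cross-validation; **IVS** = DS / (100/n) corrects DS by the chance rate.
- **WID / BID** — per-individual mean distance of calls to the
  individual's centroid, and distance of that centroid from the
  population centroid (mean over all calls), in score space.
- **ANO (acoustic niche overlap)** — each individual's calls are modelled
  as a multivariate normal with a noninformative conjugate
  (inverse-Wishart / normal) posterior; the directional overlap is the
  Monte-Carlo probability that a call of the focal individual falls inside
  another individual's α-level niche ellipsoid (α = 0.99, 10,000 draws),
  and the aggregate ANO sums this over all other individuals.
- **Group comparisons** — Wilcoxon rank-sum tests (exact for small
  tie-free samples) with median/IQR summaries of per-individual WID, BID
  and ANO, at α = 0.05.

Input is either the package's flat CSV dialect
(`individual_id, group_label, call_id, duration_s, pfc_01..pfc_10`) or a
Raven-style tab-delimited selection table whose variable-length contours
are resampled to 10 evenly spaced values by linear interpolation.

## Worked example

```sh
hootid simulate --seed 7 --design local --out-dir run
hootid report  --seed 7 --design local --out-dir run
```

prints (synthetic data: 14 CLUMPED vs 10 ISOLATED males, 25 calls each,
equal generator settings):

```
CLUMPED: HS = 4.31 (19 unique signatures); DS = 80.6%, 14 individuals; IVS = 11.28
ISOLATED: HS = 4.49 (22 unique signatures); DS = 88.8%, 10 individuals; IVS = 8.88
WID: W = 85, p = 0.403
BID: W = 64, p = 0.752
ANO: W = 125, p = 0.00067 *
```

Reading: each group's calls carry ~4.3–4.5 bits of identity information
(enough for ~19–22 distinct signatures); leave-one-out discrimination is
far above chance (chance is 7.1% and 10%, hence IVS ≫ 1).  WID and BID do
not differ between the conditions — as expected, the generator treated
them identically — while the aggregate ANO differs strongly because ANO
sums over group-mates and the groups have different sizes (13 vs 9
"others"), a scale effect to keep in mind whenever group sizes differ.
All outputs land in `run/` (tables, overlap matrices, JSON report), each
carrying the resolved configuration and seed in its header.

The same pipeline is available as library functions
(`hootid.simulate_population`, `hootid.calc_hs`, `hootid.calc_ds`,
`hootid.individual_variation`, `hootid.overlap_matrix`, ...); see
`docs/methods.md` for the statistical details and design choices.

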