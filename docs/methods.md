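# Methods

## Scoring model

Each (compound, organ) observation consists of three mean pixel
intensities on the 8-bit [0, 255] scale, extracted upstream from a
biodistribution image: organ ORGᵢ, muscle MUᵢ, system background BG. The
exposure adjustment function (EAF)

    c(x) = clamp(127.5/(127.5 − BG) · (x − 127.5) + 127.5, 0, 255)

is the unique linear contrast remap through (BG, 0) and (127.5, 127.5): it
standardizes every image to background 0 while fixing the mid-intensity.
The distribution score is Scoreᵢ = c(ORGᵢ) − c(MUᵢ) ∈ [−255, 255]. Key
properties (all tested): c(BG) = 0, c(127.5) = 127.5, c(·, BG=0) is the
identity, c is non-decreasing in x, and the score is antisymmetric under
swapping organ and muscle.

**Assumptions.** One background per image applies to both organ and muscle;
BG < 127.5 — at or above the midpoint the slope is undefined or negative
and the row is rejected as a degenerate image rather than clamped (such
rows are collected in the validation report; the run continues without
them). Scores stay real-valued until report time.

**Quantiles.** Per organ, over the whole library: label −1 iff score < 0
(score 0 counts as non-negative); the n non-negative scores are labeled
0–3 by rank, with quartile edges at ranks ⌈k·n/4⌉ and ties sharing the
label of their lowest rank. Rank-based labeling avoids any interpolation
convention and makes labels invariant under strictly increasing transforms
of the scores. "High-scoring" means label ≥ 2. Whether quartiles should be
pooled across organs instead is not determinable from the source analysis;
per-organ is implemented because the score distributions are reported per
organ.

## Segmentation

Liver scheme: logD bands (−∞, −1), [−1, 2.3], (2.3, ∞) × TPSA bands
[90, ∞) (top row: I, II, III by increasing logD) and [0, 90) (bottom row:
IV, V, VI). Kidney scheme: logD bands at −5, 0, 5.5 giving I–IV,
lower-closed. The middle liver band is closed on both logD ends so that
the two named uptake regions are strict inequalities ("logD < −1 or
> 2.3, TPSA < 90"). The numbering is the unique one consistent with the
published labels for regions IV and VI and with ICG (logD 4.91, TPSA
120.65 Å²) sitting in region III of both schemes. Thresholds are
configurable (`RegionScheme`); defaults reproduce the published lines.
These thresholds were chosen by eye in the original analysis; this module
reproduces them and deliberately does not re-derive them from data.

## Enrichment statistics

For stratum counts (x, y, m, n) the point probability is the
hypergeometric pmf and the enrichment p-value is the upper tail P(X ≥ m).
The published table's "p" column is the point mass, so both are always
reported side by side. Counting semantics: a stratum's charge filter
restricts the region membership counts (n, m) only; the type totals (y, x)
always cover every compound of the type. This is the only reading that
reproduces the published counts (e.g. n = 44 positively charged
pentamethines in liver region IV against y = 250 pentamethines total).

Probabilities are computed from log-gamma binomial coefficients with
log-sum-exp for the tail; over the full feasible range y ≤ 300 the pmf
sums to 1 within 10⁻¹², and for y ≤ 12 pmf and tail match exhaustive
subset enumeration to 10⁻¹³ (both asserted in the suite, with
`scipy.stats.hypergeom` as a second, independent cross-check). Empty
strata (n = 0) get p = 1 by the empty-draw convention. No
multiple-testing correction is applied, matching the source analysis; the
report records the number of strata tested. Percentages are rounded
half-away-from-zero to integers, and only at presentation time.

## Synthetic library generator

The generator provides ground-truthed inputs with the published library's
composition and descriptor marginals. Defaults (all configurable through
`SyntheticConfig`):

| parameter | default | rationale |
|---|---|---|
| n_total | 764 | published library size |
| skeleton mix | 250/764 pentamethine, 264/764 heptamethine, rest phenoxazine/squaraine/trimethine (110/70/70) | published counts; the split of the 250 "others" is not published and is a generator convention |
| MW | truncated N(600, 100²) Da on [250, 1200]; +100 Da heptamethine, −50 Da pentamethine offsets | mean ≈ 600 Da, most mass in 400–800; heavier 7-carbon bridge |
| logD (pH 7.4) | 0.85·N(3, 2²) + 0.15·N(−3, 3²), truncated to [−15, 12] | stated range and mean > 2; the hydrophilic component gives the sulfonated tail. Weights chosen so the truncated-mixture mean is ≈ 2.1 |
| TPSA | Gamma(shape 0.7, mean 50 Å²) | right-skewed, mean ≈ 50, mode at 0 (≈ 40% of compounds below 20 Å²) |
| net charge | {−2…+3} with probs 0.03/0.07/0.17/0.40/0.22/0.11 | mode +1, mean ≈ +1.04 ("very close to 1") |
| rotatable bonds / HBD / HBA | Poisson(8) / Poisson(1) / Poisson(5) | typical for alkyl-substituted cyanines |
| uptake_high / uptake_base | 0.85 / 0.40 | planted-effect recovery study condition |
| effect size | Gamma(shape 1.5, mean 120) intensity units | variable uptake strength; reproduces the right-skewed score histogram (median < mean among non-negative scores) that a constant effect cannot |
| noise SD | 6 intensity units | ~5% of the effect mean |
| BG range | U(5, 40); muscle base U(20, 60) | dark-box backgrounds well below the 127.5 validity limit |

Intensities: organ = clamp(BG + base + effect·U + noise), muscle =
clamp(BG + base + noise), where U ~ Bernoulli(propensity) and the
propensity is `uptake_high` for positively charged compounds in liver
regions IV/VI or kidney regions II/III ("enriched strata") and
`uptake_base` otherwise. The additive construction guarantees
non-uptaking compounds score ≈ 0 after exposure adjustment, whatever
their background. `PlantedTruth` records the propensity, the enriched
flag and the realized Bernoulli draw per (compound, organ).

Randomness: one root `SeedSequence`; descriptor and intensity generation
use separate spawned child streams, so identical configs reproduce
byte-identical CSV output.

**What the generator does not emulate:** correlations between descriptors
beyond the per-skeleton MW offsets (real libraries couple charge, TPSA and
logD through shared substituents); pharmacokinetic time courses (a single
fixed post-injection time point is assumed); compound-specific transporter
or protein-binding effects; chemically valid structures (SMILES fields are
optional templates). Passing tests on synthetic data therefore validate
the pipeline's statistical machinery and power, not any claim about real
fluorophore chemistry.

## Pipeline power and calibration

With n = 500 compounds, uptake 0.85 vs 0.40, the pooled positively charged
liver-region-VI stratum yields an upper-tail probability < 10⁻³ in 98 of
100 seeded replicates (asserted ≥ 95); with equal propensities the tail
probabilities over 200 replicates are compatible with uniform
(Kolmogorov–Smirnov p > 0.01). The replicate counts keep the whole check
under ~20 s; the statistic is the same single-stratum tail the pipeline
reports. The pooled (both-cyanine) stratum is used because it carries the
full planted signal; per-type strata are exercised by the default
four-stratum analysis.

## Numerical and degenerate-input choices

* BG ≥ 127.5, out-of-range intensities, orphan intensity ids: the first
  two are per-row validation failures that exclude the row and are
  reported; orphan ids (intensities with no descriptor row) abort the run
  with the offending ids listed, since they indicate mismatched tables.
* Invalid descriptor rows (negative MW, non-integer charge, unknown
  skeleton, unparseable numerics) are collected in a validation report,
  never silently dropped.
* logD is never computed from structure. Descriptor computation from
  SMILES (RDKit) fills MW, TPSA, formal charge, rotatable bonds and
  HBD/HBA, and marks logD "supplied-externally": mixing logD predictors
  across a library would shift region assignments invisibly.
* Hydrogen-bond counts are exposed as donors and acceptors separately plus
  their sum, since "hydrogen bonds" alone is ambiguous.
* Net charge is the formal charge sum — the only reproducible reading of
  "total charge"; "positively charged" means net charge > 0, as opposed to
  zwitterions at net 0.

## Known limitations

* The published full-database headline rates (e.g. 61% of cyanines
  high-scoring for liver) cannot be recomputed because the database is not
  deposited; the suite checks instead that the printed counts are
  arithmetically self-consistent and validates the pipeline on synthetic
  ground truth.
* The published narrative for one kidney stratum gives a high-scoring
  heptamethine count (151) that disagrees with the table's x = 154; the
  table is treated as authoritative.
* Quantile labels depend on library composition: adding compounds changes
  other compounds' labels. This is inherent to the rank-based definition.
* The exact test treats compounds as exchangeable draws; structural
  correlation within skeleton families makes the p-values optimistic for
  real libraries.
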