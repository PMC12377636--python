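# fluorodist

Biodistribution scoring and chemical-space enrichment analysis for
near-infrared (NIR) fluorescent contrast-agent libraries.

## The problem

Intravenously injected contrast agents are eliminated mainly through two
routes — hepatobiliary (liver → bile → intestine) or renal (kidney →
urine) — and which route a fluorophore takes is strongly shaped by its
physicochemical profile: molecular weight, hydrophobicity (logD at pH 7.4),
topological polar surface area (TPSA), and net charge. For a chemist
triaging hundreds of candidate cyanine dyes, knowing which corner of
(logD, TPSA) space a design lives in is an early, cheap predictor of where
it will end up in vivo.

`fluorodist` implements the complete analysis pipeline for this kind of
organ-uptake screen:

1. **Exposure-adjusted distribution scores.** Each compound–organ image
   yields mean 8-bit intensities for the organ (ORGᵢ), a muscle reference
   (MUᵢ) and the system background (BG). Because images differ in exposure,
   raw intensities are remapped by the linear contrast adjustment through
   (BG, 0) and the fixed midpoint (127.5, 127.5),

   c(x) = clamp( 127.5/(127.5 − BG) · (x − 127.5) + 127.5, 0, 255 ),

   and the **distribution score** is Scoreᵢ = c(ORGᵢ) − c(MUᵢ). A compound
   no brighter in the organ than in muscle scores ≈ 0 on any imaging system.
2. **Quantile labels.** Per organ, negative scores get label −1; the
   non-negative scores are split into ascending empirical quartiles 0–3.
   Labels ≥ 2 are "high-scoring" (≈ the upper half of organ uptake).
3. **Chemical-space segmentation.** Liver scheme: six regions from logD
   bands at −1 and 2.3 crossed with a TPSA band at 90 Å²; kidney scheme:
   four regions from logD bands at −5, 0 and 5.5.
4. **Hypergeometric enrichment.** For a stratum with y compounds of a type,
   x of them high-scoring, n of the type in a region (optionally restricted
   to a charge class) and m of those high-scoring, the probability that a
   random draw does as well is

   P(X = m) = C(x, m) · C(y−x, n−m) / C(y, n),

   computed in log space, reported together with the upper tail P(X ≥ m).

Because the original 764-compound database is not deposited in a
machine-readable form, the package ships a **seeded synthetic-library
generator** that emulates its composition (250 pentamethines, 264
heptamethines, 250 others) and descriptor distributions, and plants a
configurable region-dependent uptake effect so the whole pipeline can be
validated against a known ground truth.

## Worked example

```python
from fluorodist import BiodistributionModel, SyntheticConfig, generate_library

records, truth = generate_library(SyntheticConfig(seed=1))
results = BiodistributionModel.from_records(records).fit()
print(results.summary())
```

```
Biodistribution enrichment analysis
============================================================
Library: n=764  mean MW=612.7 Da  mean logD=2.05  mean TPSA=51.8 A^2  mean charge=+1.00
kidney: 318/764 high-scoring (42%)
liver: 298/764 high-scoring (39%)
------------------------------------------------------------
stratum                                         x    y    m    n  %high      p_pmf     p_tail
liver, pentamethine, region IV, positive       93  250    9   16    56%     0.0575     0.0883
liver, heptamethine, region VI, positive      111  264   52   76    68%   2.86e-08   3.59e-08
kidney, pentamethine, region III, positive    100  250   61  119    51%   0.000257   0.000413
kidney, heptamethine, region III, positive    108  264   70  134    52%   7.09e-05    0.00011
strata tested: 4 (no multiplicity correction)
```

Reading the table: of the 264 synthetic heptamethines (y), 111 are
high-scoring for the liver (x); 76 positively charged heptamethines sit in
liver region VI (n) and 52 of those are high-scoring (m) — 68% versus the
42% type-wide rate, with a point probability of 2.9 × 10⁻⁸ under random
placement. The planted effect (uptake probability 0.85 in positively
charged compounds in liver regions IV/VI and kidney regions II/III, 0.40
elsewhere) is recovered in the large strata; the small liver-pentamethine
stratum (n = 16) illustrates the power limit of an exact count-based test.

The same pipeline runs from the shell:

```bash
fluorodist simulate --n 764 --seed 1 --out lib/
fluorodist run --descriptors lib/descriptors.csv --intensities lib/intensities.csv --out out/
fluorodist report --results out/
```

`run` accepts any descriptor + intensity CSV pair with the same columns, so
a real screening table can replace the synthetic one unchanged.

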