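# testecho

Quantitative ultrasound staging of canine testicular maturation: grayscale
echotexture analysis, colour-Doppler vascularity scoring, morphometric and
semen arithmetic, and the rank-based statistics needed to track puberty in
a longitudinal cohort — together with a seeded synthetic-data generator
that emulates a biweekly Beagle follow-up (8 dogs × 2 testes, weeks 4–40)
so the whole pipeline is testable without clinical data.

It is aimed at veterinary andrology / theriogenology groups who quantify
B-mode testicular images with ImageJ-style ROI statistics and want those
measurements, and the downstream staging analysis, reproducible in code.

## What it computes

**Echotexture.** Each 8-bit B-mode frame carries binary masks for the
parenchyma, mediastinum testis, and capsule (tunica albuginea). Two ROI
conventions are implemented:

- *spot-meter*: nine square 2 mm² spots placed on a deterministic 3×3 grid
  inside the parenchyma (never touching the mediastinum); echogenicity is
  the mean of the nine spot means, heterogeneity the SD of those means;
- *region-area*: per-pixel mean and SD over the whole outlined parenchyma
  with the mediastinum excluded — the headline heterogeneity metric.

Mean grayscale intensity (GI, 0–255) is categorised as low (0–85),
moderate (86–170) or high (171–255) echogenicity, and standardized as
percent echogenicity = reference GI / parenchymal GI × 100, with the
capsule (or, in the modified variant, the mediastinum) as reference.

**Doppler.** Colour-flow overlays are scored 0–4 (modified Gumbsch scale)
from 8-connected components: 0 no flow, 1 small signals, 2 up to three
distinct vessels, 3 more than three, 4 a visible vessel course
(operationalised as component elongation ≥ 4 or skeleton length ≥ 30 px).

**Morphometry and semen.** Ellipsoid volumes V = 0.5236·l·w·h from
callipers, ultrasonographic volume V = 0.71·l·w·h, haemocytometer
concentration (mean chamber count × 10⁶ /mL), total sperm =
concentration × ejaculate volume, viability from eosin-nigrosin counts,
and the strict fertility threshold total sperm > 200 × 10⁶.

**Staging and statistics.** Exams are staged pre-pubertal / pubertal /
post-pubertal around the first-ejaculate, first-spermatozoa and fertile
milestones (default weeks 28/30/36). The battery runs Spearman rank
correlations between all parameters, Kruskal–Wallis tests across
structures and periods, Wilcoxon signed-rank left–right comparisons,
lagged GI-vs-total-sperm correlations (lags 0/+2/+4 weeks), OLS slope fits
over the rising GI phase, plateau detection on weekly medians, and a
six-indicator maturity panel (heterogeneity > 19, capsule ratio < 200,
mediastinum GI > 190, capsule GI in its 210–220 plateau, > 80 % of testes
scored 4, volume plateaued).

## Worked example

```python
from testecho import (CohortConfig, measure_cohort, analyze_cohort,
                      maturity_panel, first_fertile_week, detect_plateau)

cfg = CohortConfig(n_dogs=8, master_seed=1)
df = measure_cohort(cfg)          # simulate, render, measure every exam

report = analyze_cohort(df)
slope, se = report.slopes["parenchyma"]
print(f"parenchymal GI slope: {slope:.3f} +/- {se:.3f} units/week")
rho0, p0 = report.lagged[0]
print(f"GI vs same-day total sperm: rho = {rho0:.3f} (p = {p0:.2g})")
med = df.groupby("week").gi_region.median()
print(f"GI plateau from week {detect_plateau(med.to_dict())}")
print(f"first fertile week: {first_fertile_week(df)}")
panel = maturity_panel(df, 36, doppler_col="doppler_score_measured")
print(f"week-36 verdict: {panel.verdict} ({sum(panel.indicators())}/6 indicators)")
```

prints

```
parenchymal GI slope: 2.513 +/- 0.021 units/week
GI vs same-day total sperm: rho = 0.740 (p = 1.1e-20)
GI plateau from week 30
first fertile week: 36
week-36 verdict: mature (6/6 indicators)
```

The slope estimate recovers the generator's programmed rising-phase rate
(2.525 GI units/week) within its standard error; parenchymal echogenicity
plateaus at week 30 while total sperm keeps rising, and the cohort median
total sperm first exceeds 200 million spermatozoa at week 36, at which
point all six maturity indicators agree.

The same pipeline is available from the shell:

```bash
testecho simulate --dogs 8 --seed 1 --out run/
testecho measure --cohort run/cohort.csv --frames run/frames --out run/measured.csv
testecho measure-morpho --in run/measured.csv --out run/measured.csv
testecho analyze --in run/measured.csv --out run/analysis/
testecho report --in run/measured.csv
```

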