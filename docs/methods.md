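# Methods

## Scope and model

`testecho` implements the quantitative core of a longitudinal
ultrasonographic study of testicular maturation in the dog: echotexture
measured as 8-bit grayscale statistics over anatomical region masks,
colour-Doppler vascularity graded 0–4, morphometric/semen arithmetic, and
rank-based staging statistics. Clinical image segmentation is out of
scope: region masks are inputs (drawn by an operator or produced by the
synthetic renderer). All inference is rank-based (Spearman,
Kruskal–Wallis, Wilcoxon) because the design is small-n (8 dogs), heavily
tied, and far from Gaussian; no mixed-effects longitudinal modelling is
attempted.

## Synthetic cohort: what it emulates

The generator reproduces the *statistical structure* the analysis assumes,
for a biweekly follow-up of 8 Beagle dogs (2 testes each) from week 4 to
week 40 of age:

- **Parenchymal grayscale intensity (GI)**: 58 at week 4, a programmed
  3-unit dip to 55 at week 6 (a known early-infancy echogenicity dip),
  then a linear rise of 2.525 GI units/week to a plateau at week 30
  (≈115.6, i.e. "moderate" echogenicity), with a small residual drift of
  0.4 units/week afterwards. The drift is deliberate: mature testes are
  not literally constant, and a perfectly flat plateau with iid noise
  cannot carry the same-day GI–sperm rank correlation the analysis is
  designed to detect. It stays well inside the 2-unit plateau-detection
  tolerance, so the plateau is still dated to week 30.
- **Heterogeneity** (region-area pixel SD): linear from 8 (week 4) to 22
  (week 36), flat after — crossing the maturity threshold of 19 before
  the fertile milestone.
- **Mediastinum testis**: first imaged at week 8 by default; in the
  canonical 8-dog cohort onset weeks follow the observed pattern (one dog
  at week 4, six by week 6, all by week 8). Its GI is anchored globally:
  80 + 4.251·(week − 8), clamped to [55, 199], so it exceeds 190 at the
  fertile week.
- **Capsule (tunica albuginea)**: linear from 150 (week 4) to a 215
  plateau at week 32. The high starting value is a deliberate design
  choice: the capsule is hyperechoic from birth and matures earlier than
  the parenchyma, so the capsule/parenchyma percent echogenicity *falls*
  with age (≈260 → ≈181), dropping below 200 at maturity and correlating
  negatively with every growth and semen parameter. A low capsule start
  would invert that sign structure.
- **Growth** (weight, height, scrotal/testis/US volumes): logistic curves
  whose midpoints and scales are solved from percent-of-maturity anchors
  (height ≈95 % of adult at week 30 and 99 % at 36; weight 86 %/95 %;
  testis volume lagging both), with adult values of 12 kg, 38 cm, and
  8.5 cm³ US testis volume (clinical calliper volume 1.55× larger, scrotal
  sac 2.4×). Adult anchors are Beagle-plausible defaults, not fitted to a
  published table (the study's appendix medians are not available); they
  are the least-anchored parameters in the generator.
- **Semen**: missing before the first-ejaculate milestone (week 28); at
  week 28 volume only (two dogs show a few spermatozoa); at week 30 very
  low counts with zero motility; medians then {32: 4×10⁷, 34: 1.2×10⁸,
  36: 3×10⁸, 38: 3.4×10⁸, 40: 3.63×10⁸} spermatozoa — the week-40 value
  matching the adult Beagle mean — so the cohort median first exceeds the
  2×10⁸ fertility threshold at week 36. Total sperm = concentration ×
  volume holds exactly by construction.
- **Doppler**: each testis is assigned a score class per week by
  *stratified* largest-remainder allocation to the study's printed
  per-week score proportions (at n = 16 testes the integer counts are
  exact), then an overlay is rendered class-conditionally. This makes
  classifier round-trip tests meaningful and the week-36 top-score
  percentage (13/16 = 81.25 %) deterministic.

**Coupling.** A dog-week latent maturation state z follows a stationary
AR(1) across exams (per-step autocorrelation 0.6). Testis-level GI
deviations are noise_sd·(0.9 z + 0.436 e) (unit variance, default
noise_sd 1.5 GI units) and log total sperm adds 0.33 z + 0.1 e. A dog
examined "ahead" of the cohort is ahead in both echotexture and sperm
output and stays so for a few weeks, which yields the designed property
that the GI–sperm rank correlation is strongest same-day and decays at
+2/+4-week lags. The weights were set once from that target correlation
structure and are part of the generator's definition.

**Speckle.** Parenchymal texture is gamma-distributed multiplicative
speckle: shape k = (μ/σ)² and scale μ/k reproduce the target mean and SD
exactly before quantization. At the default operating points (μ 55–120,
σ 8–22) the [0, 255] clip is inactive (the mean is > 6σ from both edges)
and 8-bit rounding adds variance 1/12, so no moment correction is needed;
region means recover trajectories to within sampling error (SE ≈ σ/√N ≈
0.16 GI at N ≈ 20 000 parenchymal pixels). Mediastinum and capsule pixels
are Gaussian (SD 6) around their trajectory values. Frame geometry is a
prolate ellipse (l = 1.5·w) sized from the US volume curve at
0.15 mm/pixel in a 256² image; the capsule is the outer 3-pixel rim, the
mediastinum a central horizontal band ~0.7 mm thick.

**What the generator does not emulate**: acoustic physics (no RF,
beamforming, attenuation, shadowing or focal-zone effects), scanner
post-processing, operator-dependent plane selection, focal lesions, or
segmentation error — masks are exact. Passing tests therefore demonstrate
that the measurement and staging pipeline is correct and self-consistent
under the assumed data-generating process, not that it is robust to
real-scanner artefacts.

## Measurement conventions

- **Spot-meter**: spot side = round(√(2 mm²)/mm_per_pixel) pixels (14 px
  at 0.1 mm/px). Placement is deterministic, not operator-interactive: the
  bounding box of usable parenchyma (parenchyma ∖ mediastinum) is divided
  into a 3×3 grid of cells and each spot snaps to the fully-valid position
  nearest its cell centre (ties broken row-major); a shrink search handles
  convex boundaries. If any cell admits no valid square the frame is
  "spot-meter infeasible" — which genuinely happens for young testes,
  where fixed-area spots do not fit; such frames are flagged and excluded
  from technique-agreement analyses.
- **Heterogeneity differs by technique**: SD of the nine spot means
  (spot-meter convention) versus SD of all mask pixels (region-area).
  They estimate different things (between-ROI variation vs total texture
  variance) and are both reported; region-area is the headline metric and
  the one thresholded at 19.
- All SDs use the n−1 denominator. Ratios are reference/parenchyma × 100.
  Echogenicity categories round half-up before classification, making 85
  the largest "low" value. A pre-onset mediastinum yields a distinguished
  "not imaged" result (None/NaN), never zero.
- **Doppler**: components are 8-connected (thin angled vessels stay
  connected); noise filter at 4 px; "distinct" means ≥ 10 px; "course
  visible" means best-fit-ellipse elongation ≥ 4 or skeleton ≥ 30 px, and
  dominates the count-based grades. Week-level proportions round half-up
  to integers.

## Statistical conventions

- Spearman p-values use the t-approximation; constant vectors are flagged
  (NaN + warning) rather than silently zeroed. Kruskal–Wallis applies tie
  correction; an all-identical pooled sample returns H = 0, p = 1.
- Left–right comparison: Wilcoxon signed-rank on (dog, week)-matched
  pairs, pooled per parameter; all-zero differences give p = 1. No
  multiple-testing correction is applied by default (raw p-values are
  reported, as is conventional in this literature); tests of the
  exchangeability invariant use a Bonferroni-style bound instead.
- Lagged correlations pool dogs and testes, and the GI side is restricted
  to exams with a same-day ejaculate, so every lag correlates the same GI
  exam set against later sperm counts. Without that restriction the
  lagged sets would include steep pre-pubertal GI weeks and the lag
  ordering would invert.
- Slope fits are OLS on all testis-level points (weekly-median fitting is
  available via a flag) over the default rising windows: weeks 6–30 for
  parenchyma, 8–36 for mediastinum.
- Plateau detection: earliest week after which every successive change of
  the weekly median is ≤ tolerance (2 GI units; 5 % for volumes). This is
  a simple, documented criterion standing in for by-eye plateau calls.
- Maturity panel: six booleans on cohort medians at the queried week;
  verdict "mature" at ≥ 4 true (configurable), "immature" at ≤ 1.

## Problem sizes and determinism

The canonical cohort is 8 dogs × 2 testes × 19 biweekly exams = 304
frames at 256×256 pixels; a full simulate–render–measure–analyze pass
takes a few seconds on one CPU, and the test suite and acceptance script
use that size directly. All randomness flows from one master seed through
fixed per-dog/per-week/per-frame seed sequences, so tables, frames and
downstream reports are bit-reproducible, and extending the week grid
never perturbs earlier records.

## Known limitations

- Adult somatometric anchors and semen medians are plausible defaults,
  not fitted to published per-week tables; absolute levels of those
  curves (not their milestone structure) should not be over-interpreted.
- The spot-placement grid is one reasonable formalisation of a procedure
  that is operator-chosen in practice.
- The Doppler size/elongation thresholds operationalise a visual scale;
  on real overlays they would need calibration to the scanner's colour
  map and spatial resolution.
- Percent-of-maturity figures require an adult reference value; the
  package computes them only when such a reference is supplied.
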