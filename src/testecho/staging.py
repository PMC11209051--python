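"""Age-period staging and the rank-based statistical battery.

The longitudinal window is partitioned into pre-pubertal (up to and
including the first-ejaculate week), pubertal, and post-pubertal (from the
first fertile ejaculate) periods.  Inference is deliberately rank-based,
matching the non-Gaussian, small-n longitudinal design: Spearman
correlations between all measured parameters, Kruskal-Wallis tests across
anatomical structures and across periods, Wilcoxon signed-rank left-right
comparisons, lagged grayscale-vs-sperm correlations, OLS slope fits over
the rising phase, plateau detection on weekly medians, and a configurable
maturity-indicator panel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import is_fertile

PERIODS = ("pre-pubertal", "pubertal", "post-pubertal")
DEFAULT_MILESTONES = (28, 30, 36)

#: cohort-table parameters entering the correlation matrix, in report order
CORRELATION_PARAMS = [
    "weight", "height", "total_sperm", "motility",
    "scrotum_volume", "testis_volume", "us_volume",
    "gi_region", "het_region", "gi_mt", "gi_capsule",
    "ratio_mt", "ratio_cap",
]

STRUCTURE_COLUMNS = {"parenchyma": "gi_region", "mediastinum": "gi_mt",
                     "capsule": "gi_capsule"}

#: default rising-phase windows for slope fits (weeks, inclusive)
SLOPE_WINDOWS = {"parenchyma": (6, 30), "mediastinum": (8, 36)}


@dataclass
class MaturityPanel:
    """Six maturity indicators evaluated on cohort medians at one week."""

    het_gt_19: bool
    ratio_lt_200: bool
    mt_gt_190: bool
    capsule_in_plateau: bool
    doppler4_gt_80pct: bool
    volume_plateaued: bool
    verdict: str = ""

    def indicators(self) -> Tuple[bool, ...]:
        return (self.het_gt_19, self.ratio_lt_200, self.mt_gt_190,
                self.capsule_in_plateau, self.doppler4_gt_80pct,
                self.volume_plateaued)


@dataclass
class CorrelationReport:
    matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    lagged: Dict[int, Tuple[float, float]]
    kw_structures: Tuple[float, float]
    kw_periods: Dict[str, Tuple[float, float]]
    lr_compare: pd.Series
    slopes: Dict[str, Tuple[float, float]]


# ---------------------------------------------------------------------------
# staging

def period_of_week(week: float, milestones: Sequence[int] = DEFAULT_MILESTONES) -> str:
    fe, _fs, ft = milestones
    if week <= fe:
        return "pre-pubertal"
    if week < ft:
        return "pubertal"
    return "post-pubertal"


def assign_periods(df: pd.DataFrame, milestones="cohort-default",
                   per_dog: Optional[Mapping[str, Sequence[int]]] = None
                   ) -> pd.DataFrame:
    """Label every exam record with its maturation period.

    With the default cohort-level milestones (28/30/36) the periods are
    weeks 4-28, 30-34 and 36-40.  In per-dog mode each dog's own milestone
    triple is used; missing dogs raise a KeyError.
    """
    out = df.copy()
    if per_dog is not None:
        missing = set(out["dog_id"]) - set(per_dog)
        if missing:
            raise KeyError(f"missing milestones for dogs: {sorted(missing)}")
        out["period"] = [
            period_of_week(w, per_dog[d])
            for d, w in zip(out["dog_id"], out["week"])]
        return out
    ms = DEFAULT_MILESTONES if milestones == "cohort-default" else tuple(milestones)
    out["period"] = out["week"].map(lambda w: period_of_week(w, ms))
    return out


# ---------------------------------------------------------------------------
# rank statistics

def spearman(x: Iterable[float], y: Iterable[float]) -> Tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the t-approximation.  Constant input is flagged with a
    warning and yields (nan, nan).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined",
                      RuntimeWarning, stacklevel=2)
        return math.nan, math.nan
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups: Iterable[float]) -> Tuple[float, float]:
    """Kruskal-Wallis H with tie correction; chi-square p-value.

    Degenerate input with all values identical returns H = 0, p = 1.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def _wilcoxon_p(diffs: np.ndarray) -> float:
    diffs = diffs[~np.isnan(diffs)]
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 1.0
    return float(stats.wilcoxon(nz).pvalue)


def left_right_compare(df: pd.DataFrame,
                       parameters: Optional[Sequence[str]] = None) -> pd.Series:
    """Paired Wilcoxon signed-rank left-vs-right p-value per parameter.

    Pairs are matched on (dog, week); the pooled per-parameter p summarises
    all exams.  Identical sides give p = 1.
    """
    if parameters is None:
        parameters = [c for c in CORRELATION_PARAMS if c in df.columns]
        parameters += [c for c in ("testis_l", "testis_w", "testis_h")
                       if c in df.columns]
        parameters = [p for p in parameters
                      if p not in ("weight", "height")]  # dog-level, not paired
    wide = df.pivot_table(index=["dog_id", "week"], columns="testis_side",
                          values=list(parameters), aggfunc="first")
    out = {}
    for p in parameters:
        try:
            left, right = wide[(p, "left")], wide[(p, "right")]
        except KeyError as exc:
            raise ValueError(f"unpaired records for parameter {p!r}") from exc
        out[p] = _wilcoxon_p((left - right).to_numpy(dtype=float))
    return pd.Series(out, name="p_left_right")


def lagged_correlation(df: pd.DataFrame, lags: Sequence[int] = (0, 2, 4),
                       gi_col: str = "gi_region",
                       sperm_col: str = "total_sperm"
                       ) -> Dict[int, Tuple[float, float]]:
    """Spearman rho between parenchymal GI at week w and total sperm at w+lag.

    Pools all dogs/testes.  Grayscale values enter only from exams at which
    an ejaculate was collected the same day (the semen-bearing weeks), so
    every lag correlates the same GI exam set against later sperm counts.
    A lag with no overlapping exams raises a ValueError.
    """
    sperm = df[["dog_id", "testis_side", "week", sperm_col]].dropna()
    gi = df[["dog_id", "testis_side", "week", gi_col]].dropna().merge(
        sperm[["dog_id", "testis_side", "week"]],
        on=["dog_id", "testis_side", "week"])
    out = {}
    for lag in lags:
        shifted = sperm.copy()
        shifted["week"] = shifted["week"] - lag
        merged = gi.merge(shifted, on=["dog_id", "testis_side", "week"])
        if len(merged) < 3:
            raise ValueError(f"no overlapping exams at lag {lag:+d} weeks")
        out[lag] = spearman(merged[gi_col], merged[sperm_col])
    return out


def fit_gi_slope(df: pd.DataFrame, structure: str = "parenchyma",
                 week_range: Optional[Tuple[float, float]] = None,
                 on_medians: bool = False) -> Tuple[float, float]:
    """OLS slope (grayscale units/week) of a structure's GI over its rising phase.

    Fits all testis-level points by default; ``on_medians`` fits the weekly
    medians instead.  Returns ``(slope, standard error)``.
    """
    col = STRUCTURE_COLUMNS.get(structure, structure)
    lo, hi = week_range if week_range is not None else SLOPE_WINDOWS[structure]
    sub = df[(df["week"] >= lo) & (df["week"] <= hi)][["week", col]].dropna()
    if on_medians:
        sub = sub.groupby("week", as_index=False).median()
    if sub["week"].nunique() < 3:
        raise ValueError("need at least three distinct weeks for a slope fit")
    res = stats.linregress(sub["week"], sub[col])
    return float(res.slope), float(res.stderr)


def detect_plateau(series_by_week: Mapping[float, float],
                   tolerance: float = 2.0) -> Optional[float]:
    """Earliest week after which every successive change is within tolerance.

    ``series_by_week`` maps week -> (median) value.  Returns None when the
    series never settles; a constant series plateaus at its first week.
    """
    weeks = sorted(series_by_week)
    if len(weeks) < 4:
        raise ValueError("need at least four points to detect a plateau")
    vals = np.array([series_by_week[w] for w in weeks], dtype=float)
    changes = np.abs(np.diff(vals))
    for i in range(len(weeks) - 1):
        if np.all(changes[i:] <= tolerance):
            return weeks[i]
    return None


# ---------------------------------------------------------------------------
# maturity panel

def maturity_panel(df: pd.DataFrame, week: float,
                   doppler_col: str = "doppler_score",
                   volume_col: str = "us_volume",
                   mature_if: int = 4) -> MaturityPanel:
    """Evaluate the six maturity indicators on cohort medians at one week.

    Thresholds: region heterogeneity > 19, capsule/parenchyma percent
    echogenicity < 200, mediastinum GI > 190, capsule GI >= 210 (the lower
    edge of its 210-220 plateau), > 80 % of testes scored 4, and testicular
    volume plateaued (successive weekly median changes <= 5 %).  Verdict is
    ``mature`` when at least ``mature_if`` indicators hold, ``immature``
    when at most one does, else ``peripubertal``.
    """
    here = df[df["week"] == week]
    if here.empty:
        raise ValueError(f"no exam records at week {week}")
    for col in ("het_region", "ratio_cap", "gi_mt", "gi_capsule",
                doppler_col, volume_col):
        if col not in df.columns:
            raise KeyError(f"missing required column {col!r}")

    med = here.median(numeric_only=True)
    doppler = here[doppler_col].dropna()
    pct4 = (doppler == 4).mean() * 100 if len(doppler) else 0.0

    vol_med = (df[df["week"] <= week].groupby("week")[volume_col]
               .median().dropna())
    plateaued = False
    if len(vol_med) >= 3:
        rel = np.abs(np.diff(vol_med.to_numpy())) / vol_med.to_numpy()[:-1]
        plateaued = bool(np.all(rel[-2:] <= 0.05))

    panel = MaturityPanel(
        het_gt_19=bool(med.get("het_region", math.nan) > 19),
        ratio_lt_200=bool(med.get("ratio_cap", math.nan) < 200),
        mt_gt_190=bool(med.get("gi_mt", math.nan) > 190),
        capsule_in_plateau=bool(med.get("gi_capsule", math.nan) >= 210),
        doppler4_gt_80pct=bool(pct4 > 80),
        volume_plateaued=plateaued,
    )
    n_true = sum(panel.indicators())
    panel.verdict = ("mature" if n_true >= mature_if
                     else "immature" if n_true <= 1 else "peripubertal")
    return panel


# ---------------------------------------------------------------------------
# full battery

def correlation_matrix(df: pd.DataFrame,
                       params: Optional[Sequence[str]] = None
                       ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman matrix and p-values over the requested parameters."""
    params = [p for p in (params or CORRELATION_PARAMS) if p in df.columns]
    rho = pd.DataFrame(np.eye(len(params)), index=params, columns=params)
    pm = pd.DataFrame(np.zeros((len(params), len(params))),
                      index=params, columns=params)
    for i, a in enumerate(params):
        for b in params[i + 1:]:
            pair = df[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                r = p = math.nan
            else:
                r, p = spearman(pair[a], pair[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pm.loc[a, b] = pm.loc[b, a] = p
    return rho, pm


def first_fertile_week(df: pd.DataFrame,
                       sperm_col: str = "total_sperm") -> Optional[int]:
    """Earliest week whose cohort-median total sperm is a fertile count."""
    med = df.groupby("week")[sperm_col].median()
    for week, m in med.items():
        if not math.isnan(m) and is_fertile(m):
            return int(week)
    return None


def analyze_cohort(df: pd.DataFrame,
                   lags: Sequence[int] = (0, 2, 4)) -> CorrelationReport:
    """Run the full statistical battery on a measured cohort table."""
    staged = assign_periods(df)
    rho, pm = correlation_matrix(df)

    kw_structures = kruskal_wallis(*(
        staged[c].dropna() for c in STRUCTURE_COLUMNS.values()))
    kw_periods = {}
    for name, col in STRUCTURE_COLUMNS.items():
        groups = [staged.loc[staged["period"] == per, col].dropna()
                  for per in PERIODS]
        kw_periods[name] = kruskal_wallis(*[g for g in groups if len(g)])

    slopes = {s: fit_gi_slope(df, s) for s in SLOPE_WINDOWS
              if STRUCTURE_COLUMNS[s] in df.columns}
    return CorrelationReport(
        matrix=rho, p_matrix=pm,
        lagged=lagged_correlation(df, lags=lags),
        kw_structures=kw_structures,
        kw_periods=kw_periods,
        lr_compare=left_right_compare(df),
        slopes=slopes,
    )
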