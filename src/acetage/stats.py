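"""Inaccuracy metrics, rank tests, agreement, and stage-timing summaries.

Bias is the mean signed difference (estimated − chronological age); a
positive value means overestimation.  Absolute error is the mean unsigned
difference, so ``|bias| <= absolute_error`` always.  Comparisons between
reference choices use the Wilcoxon signed-rank test on the same test
individuals; stage-attainment timing between populations uses Mann-Whitney
U on the per-stage age samples.  All tests are two-sided with the 0.05
significance threshold; no multiple-testing correction is applied across
the many per-stage tests (documented, deliberate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import SkeletalRecord

SIGNIFICANCE_LEVEL = 0.05

#: Wide age bands used for per-band inaccuracy reports: [15, 40), [40, 65),
#: [65, inf).  Age 65 belongs to the oldest band so the partition is total.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (15.0, 40.0),
    (40.0, 65.0),
    (65.0, float("inf")),
)


def band_label(lo: float, hi: float) -> str:
    return f">={lo:.0f}" if np.isinf(hi) else f"{lo:.0f}-{hi - 1:.0f}"


@dataclass
class EstimatePair:
    """Estimated vs chronological age for one estimated individual."""

    individual_id: str
    chronological_age: float
    estimated_age: float


@dataclass
class InaccuracyReport:
    """Bias / absolute error over one scope (global or an age band)."""

    scope: str
    n: int
    bias: float
    absolute_error: float
    no_estimation_count: int = 0


@dataclass
class RankTestResult:
    """Statistic, two-sided p, sample sizes, and which method produced p."""

    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    degenerate: bool = False


def _signed_errors(pairs: Sequence[EstimatePair]) -> np.ndarray:
    if len(pairs) == 0:
        raise ValueError("no estimate pairs")
    return np.array([p.estimated_age - p.chronological_age for p in pairs])


def bias(pairs: Sequence[EstimatePair]) -> float:
    """Mean signed error in years; positive = overestimation."""
    return float(_signed_errors(pairs).mean())


def absolute_error(pairs: Sequence[EstimatePair]) -> float:
    """Mean unsigned error in years."""
    return float(np.abs(_signed_errors(pairs)).mean())


def band_report(
    pairs: Sequence[EstimatePair],
    no_estimation_counts: dict[str, int] | None = None,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
) -> list[InaccuracyReport]:
    """Per-band reports (banded by chronological age) plus a global report.

    ``no_estimation_counts`` maps scope labels (band labels or "global")
    to counts of individuals the estimator declined; they are excluded
    from the means and reported separately.
    """
    no_est = no_estimation_counts or {}
    reports: list[InaccuracyReport] = []
    for lo, hi in bands:
        label = band_label(lo, hi)
        sub = [p for p in pairs if lo <= p.chronological_age < hi]
        if sub:
            reports.append(InaccuracyReport(label, len(sub), bias(sub),
                                            absolute_error(sub),
                                            no_est.get(label, 0)))
        else:
            reports.append(InaccuracyReport(label, 0, float("nan"),
                                            float("nan"), no_est.get(label, 0)))
    if pairs:
        reports.append(InaccuracyReport("global", len(pairs), bias(pairs),
                                        absolute_error(pairs),
                                        no_est.get("global", 0)))
    else:
        reports.append(InaccuracyReport("global", 0, float("nan"), float("nan"),
                                        no_est.get("global", 0)))
    return reports


def reports_to_frame(reports: Iterable[InaccuracyReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"scope": r.scope, "n": r.n, "bias": r.bias,
          "absolute_error": r.absolute_error,
          "no_estimation_count": r.no_estimation_count} for r in reports]
    )


# ---------------------------------------------------------------------------
# Rank tests.  scipy supplies the distributions; the exact-vs-approximate
# switch is fixed here so the method used is always reported.

WILCOXON_EXACT_MAX_PAIRS = 25
MANNWHITNEY_EXACT_MAX_PRODUCT = 400


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking (classic Wilcoxon).  The
    exact null distribution is used for <= 25 remaining pairs with untied
    absolute differences; otherwise the normal approximation with tie
    correction.  All-zero differences give the degenerate p = 1 result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("paired samples must be equal-length 1-d and non-empty")
    d = x - y
    d = d[d != 0.0]
    if len(d) == 0:
        return RankTestResult(0.0, 1.0, (0,), "degenerate (all zero differences)",
                              degenerate=True)
    untied = len(np.unique(np.abs(d))) == len(d)
    if len(d) <= WILCOXON_EXACT_MAX_PAIRS and untied:
        res = sps.wilcoxon(d, alternative="two-sided", method="exact")
        return RankTestResult(float(res.statistic), float(res.pvalue),
                              (len(d),), "exact")
    res = sps.wilcoxon(d, alternative="two-sided", method="approx",
                       correction=False)
    stat = float(res.zstatistic) if hasattr(res, "zstatistic") else float(res.statistic)
    return RankTestResult(stat, float(res.pvalue), (len(d),),
                          "normal approximation, tie-corrected")


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U test on two independent age samples.

    Exact when ``len(a) * len(b) <= 400`` and the pooled sample is
    tie-free; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if len(a) * len(b) <= MANNWHITNEY_EXACT_MAX_PRODUCT and tie_free:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        method = "normal approximation, tie-corrected"
    return RankTestResult(float(res.statistic), float(res.pvalue),
                          (len(a), len(b)), method)


# ---------------------------------------------------------------------------
# Observer agreement

#: Verbal agreement bands for kappa (0.61-0.79 substantial, 0.80-1.00
#: almost perfect; lower bands per the same convention).
LANDIS_KOCH_BANDS = (
    (0.00, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def landis_koch_label(kappa: float) -> str:
    if np.isnan(kappa):
        return "undefined"
    if kappa < 0:
        return "poor"
    for upper, label in LANDIS_KOCH_BANDS:
        if kappa < upper:
            return label
    return "almost perfect"


@dataclass
class KappaResult:
    kappa: float
    weighting: str
    label: str
    n: int
    undefined: bool = False


def weighted_kappa(
    ratings1: Sequence[int],
    ratings2: Sequence[int],
    n_categories: int | None = None,
    weighting: str = "linear",
) -> KappaResult:
    """Weighted kappa for two ordinal rating vectors.

    kappa = 1 − (Σ w_ij O_ij) / (Σ w_ij E_ij) with disagreement weights
    w_ij = |i−j| (linear) or (i−j)² (quadratic), O the observed and E the
    chance-expected (marginal-product) proportion tables.  When chance
    disagreement is zero (e.g. a rater uses one constant category equal to
    the other rater's) kappa is undefined and flagged.
    """
    r1 = np.asarray(ratings1, dtype=int)
    r2 = np.asarray(ratings2, dtype=int)
    if r1.shape != r2.shape or r1.ndim != 1 or len(r1) < 2:
        raise ValueError("ratings must be equal-length 1-d with >= 2 items")
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise ValueError("ratings must be non-negative category indices")
    k = n_categories or int(max(r1.max(), r2.max())) + 1
    if weighting not in ("linear", "quadratic"):
        raise ValueError("weighting must be 'linear' or 'quadratic'")
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = np.abs(i - j) if weighting == "linear" else (i - j) ** 2
    observed = np.zeros((k, k))
    np.add.at(observed, (r1, r2), 1.0)
    observed /= len(r1)
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    denom = float((w * expected).sum())
    if denom == 0.0:
        return KappaResult(float("nan"), weighting, "undefined", len(r1),
                           undefined=True)
    kappa = 1.0 - float((w * observed).sum()) / denom
    return KappaResult(kappa, weighting, landis_koch_label(kappa), len(r1))


# ---------------------------------------------------------------------------
# Stage timing

@dataclass
class StageTimingRow:
    """Chronological-age summary of one (variable, stage) cell."""

    variable: str
    stage: int
    n: int
    mean_age: float
    sd: float  # NaN when n == 1


def stage_timing_summary(records: Sequence[SkeletalRecord]) -> list[StageTimingRow]:
    """Mean chronological age (and SD) of individuals at each stage."""
    cells: dict[tuple[str, int], list[float]] = {}
    for rec in records:
        for var, stage in rec.profile.items():
            if stage is not None:
                cells.setdefault((var, int(stage)), []).append(float(rec.age))
    rows = []
    for (var, stage) in sorted(cells):
        ages = np.array(cells[(var, stage)])
        sd = float(ages.std(ddof=1)) if len(ages) > 1 else float("nan")
        rows.append(StageTimingRow(var, stage, len(ages), float(ages.mean()), sd))
    return rows


def timing_to_frame(rows: Iterable[StageTimingRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"variable": r.variable, "stage": r.stage, "n": r.n,
          "mean_age": r.mean_age, "sd": r.sd} for r in rows]
    )


def compare_stage_timing(
    pop_a: Sequence[SkeletalRecord],
    pop_b: Sequence[SkeletalRecord],
    significance_level: float = SIGNIFICANCE_LEVEL,
) -> pd.DataFrame:
    """Per-(variable, stage) timing comparison between two populations.

    Emits both summaries and a Mann-Whitney U test on the two per-stage age
    samples, with a significance flag at the 0.05 threshold.  A stage seen
    in only one population yields a row with the test marked not applicable.
    """
    if len(pop_a) == 0 or len(pop_b) == 0:
        raise ValueError("both populations must be non-empty")

    def cell_ages(records):
        cells: dict[tuple[str, int], list[float]] = {}
        for rec in records:
            for var, stage in rec.profile.items():
                if stage is not None:
                    cells.setdefault((var, int(stage)), []).append(float(rec.age))
        return cells

    cells_a = cell_ages(pop_a)
    cells_b = cell_ages(pop_b)
    rows = []
    for key in sorted(set(cells_a) | set(cells_b)):
        var, stage = key
        ages_a = np.array(cells_a.get(key, []))
        ages_b = np.array(cells_b.get(key, []))
        row = {
            "variable": var, "stage": stage,
            "n_a": len(ages_a),
            "mean_a": float(ages_a.mean()) if len(ages_a) else np.nan,
            "sd_a": float(ages_a.std(ddof=1)) if len(ages_a) > 1 else np.nan,
            "n_b": len(ages_b),
            "mean_b": float(ages_b.mean()) if len(ages_b) else np.nan,
            "sd_b": float(ages_b.std(ddof=1)) if len(ages_b) > 1 else np.nan,
        }
        if len(ages_a) and len(ages_b):
            res = mann_whitney_u(ages_a, ages_b)
            row.update(U=res.statistic, p=res.p_value,
                       significant=bool(res.p_value < significance_level),
                       test="applicable")
        else:
            row.update(U=np.nan, p=np.nan, significant=False,
                       test="not applicable (stage absent in one population)")
        rows.append(row)
    return pd.DataFrame(rows)


def boxplot_summary(records: Sequence[SkeletalRecord]) -> pd.DataFrame:
    """Five-number age summary per (variable, stage).

    Quartiles use linear interpolation between order statistics (the
    numpy default, "type 7"), fixed so summaries are reproducible.
    """
    rows = []
    cells: dict[tuple[str, int], list[float]] = {}
    for rec in records:
        for var, stage in rec.profile.items():
            if stage is not None:
                cells.setdefault((var, int(stage)), []).append(float(rec.age))
    for (var, stage) in sorted(cells):
        ages = np.array(cells[(var, stage)])
        q1, med, q3 = np.percentile(ages, [25, 50, 75])
        rows.append({"variable": var, "stage": stage, "n": len(ages),
                     "min": float(ages.min()), "q1": float(q1),
                     "median": float(med), "q3": float(q3),
                     "max": float(ages.max())})
    return pd.DataFrame(rows)
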