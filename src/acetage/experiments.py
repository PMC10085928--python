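"""Crossed reference/test experiment design and its summary tables.

The evaluation protocol estimates each population's test sample twice:
once with its own (population-matched) reference sample and once with the
other population's (crossed) reference, sex-stratified end-to-end.  The
four experiments are

    1  matched:  population A test on population A reference
    2  matched:  population B test on population B reference
    3  crossed:  population A test on population B reference
    4  crossed:  population B test on population A reference

Because the same test individuals are estimated in both arms, matched and
crossed accuracies are compared with the Wilcoxon signed-rank test on the
per-individual signed and absolute errors, globally and per age band.
Individuals the estimator declines (no estimation) in either arm are
excluded from that paired comparison and accounted separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import AgeClassGrid, VariableCatalog
from .estimator import (
    AgeEstimate,
    build_reference_table,
    estimate_batch,
)
from .records import SkeletalRecord
from .stats import (
    DEFAULT_BANDS,
    EstimatePair,
    InaccuracyReport,
    RankTestResult,
    band_label,
    band_report,
    reports_to_frame,
    wilcoxon_signed_rank,
)


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment: which reference estimates which test sample."""

    experiment_id: int
    reference_population: str
    test_population: str
    sex: str
    alpha: float = 0.0

    @property
    def matched(self) -> bool:
        return self.reference_population == self.test_population


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    reports: list[InaccuracyReport]
    pairs: list[EstimatePair]
    estimates: list[AgeEstimate]
    no_estimation_ids: list[str]

    @property
    def global_report(self) -> InaccuracyReport:
        return next(r for r in self.reports if r.scope == "global")

    def report_for(self, scope: str) -> InaccuracyReport:
        return next(r for r in self.reports if r.scope == scope)


def run_experiment(
    spec: ExperimentSpec,
    reference: Sequence[SkeletalRecord],
    test: Sequence[SkeletalRecord],
    grid: AgeClassGrid | None = None,
    catalog: VariableCatalog | None = None,
) -> ExperimentResult:
    """Estimate a test sample against a reference sample and report."""
    if len(reference) == 0 or len(test) == 0:
        raise ValueError("reference and test collections must be non-empty")
    ref_sexes = {r.sex for r in reference}
    test_sexes = {r.sex for r in test}
    if ref_sexes != {spec.sex} or test_sexes != {spec.sex}:
        raise ValueError(
            f"experiment {spec.experiment_id}: sex-specific design requires all "
            f"records of sex {spec.sex!r} (reference {ref_sexes}, test {test_sexes})"
        )
    table = build_reference_table(reference, grid=grid, catalog=catalog,
                                  population=spec.reference_population,
                                  sex=spec.sex)
    if np.count_nonzero(table.class_count) == 0:
        raise ValueError("reference too sparse: no populated age class")
    estimates = estimate_batch(test, table, alpha=spec.alpha)
    pairs, no_est_ids = [], []
    no_est_per_scope: dict[str, int] = {}
    for rec, est in zip(test, estimates):
        if est.estimated:
            pairs.append(EstimatePair(rec.individual_id, float(rec.age),
                                      float(est.point_estimate)))
        else:
            no_est_ids.append(rec.individual_id)
            for lo, hi in DEFAULT_BANDS:
                if lo <= rec.age < hi:
                    label = band_label(lo, hi)
                    no_est_per_scope[label] = no_est_per_scope.get(label, 0) + 1
            no_est_per_scope["global"] = no_est_per_scope.get("global", 0) + 1
    reports = band_report(pairs, no_estimation_counts=no_est_per_scope)
    return ExperimentResult(spec, reports, pairs, estimates, no_est_ids)


@dataclass
class PairedComparison:
    """Matched vs crossed arm on identical test individuals, one scope."""

    test_population: str
    sex: str
    scope: str
    metric: str  # "bias" (signed errors) or "absolute_error"
    n: int
    matched_mean: float
    crossed_mean: float
    test: RankTestResult


@dataclass
class CrossedDesignResult:
    experiments: dict[tuple[int, str], ExperimentResult]  # (experiment_id, sex)
    comparisons: list[PairedComparison]
    no_estimation_counts: dict[tuple[str, str, str], int]  # (test pop, sex, ref pop)

    def matched_no_estimation_mean(self) -> float:
        vals = [c for (tp, _s, rp), c in self.no_estimation_counts.items() if tp == rp]
        return float(np.mean(vals))

    def crossed_no_estimation_mean(self) -> float:
        vals = [c for (tp, _s, rp), c in self.no_estimation_counts.items() if tp != rp]
        return float(np.mean(vals))

    def inaccuracy_table(self) -> pd.DataFrame:
        """Long-form per-experiment per-scope bias/error table."""
        rows = []
        for (exp_id, sex), result in sorted(self.experiments.items()):
            frame = reports_to_frame(result.reports)
            frame.insert(0, "experiment", exp_id)
            frame.insert(1, "sex", sex)
            frame.insert(2, "reference_population", result.spec.reference_population)
            frame.insert(3, "test_population", result.spec.test_population)
            rows.append(frame)
        return pd.concat(rows, ignore_index=True)

    def comparison_table(self) -> pd.DataFrame:
        """Matched-vs-crossed paired Wilcoxon results per scope and metric."""
        return pd.DataFrame(
            [{"test_population": c.test_population, "sex": c.sex,
              "scope": c.scope, "metric": c.metric, "n": c.n,
              "matched_mean": c.matched_mean, "crossed_mean": c.crossed_mean,
              "statistic": c.test.statistic, "p": c.test.p_value,
              "method": c.test.method} for c in self.comparisons]
        )

    def no_estimation_table(self) -> pd.DataFrame:
        """Per-pairing no-estimation counts with matched/crossed means."""
        rows = [
            {"test_population": tp, "sex": s, "reference_population": rp,
             "pairing": "matched" if tp == rp else "crossed", "count": c}
            for (tp, s, rp), c in sorted(self.no_estimation_counts.items())
        ]
        frame = pd.DataFrame(rows)
        frame["pairing_mean"] = np.where(
            frame["pairing"] == "matched",
            self.matched_no_estimation_mean(),
            self.crossed_no_estimation_mean(),
        )
        return frame


def _paired_comparisons(
    test_records: Sequence[SkeletalRecord],
    matched: ExperimentResult,
    crossed: ExperimentResult,
    sex: str,
) -> list[PairedComparison]:
    ages = {r.individual_id: float(r.age) for r in test_records}
    matched_est = {p.individual_id: p.estimated_age for p in matched.pairs}
    crossed_est = {p.individual_id: p.estimated_age for p in crossed.pairs}
    shared = [i for i in matched_est if i in crossed_est]  # both arms estimated
    comparisons: list[PairedComparison] = []
    scopes = [(band_label(lo, hi), lo, hi) for lo, hi in DEFAULT_BANDS]
    scopes.append(("global", -np.inf, np.inf))
    for scope, lo, hi in scopes:
        ids = [i for i in shared if lo <= ages[i] < hi]
        if not ids:
            continue
        m_err = np.array([matched_est[i] - ages[i] for i in ids])
        c_err = np.array([crossed_est[i] - ages[i] for i in ids])
        for metric, m_vals, c_vals in (
            ("bias", m_err, c_err),
            ("absolute_error", np.abs(m_err), np.abs(c_err)),
        ):
            comparisons.append(
                PairedComparison(
                    test_population=matched.spec.test_population,
                    sex=sex,
                    scope=scope,
                    metric=metric,
                    n=len(ids),
                    matched_mean=float(m_vals.mean()),
                    crossed_mean=float(c_vals.mean()),
                    test=wilcoxon_signed_rank(m_vals, c_vals),
                )
            )
    return comparisons


def run_crossed_design(
    references: Mapping[tuple[str, str], Sequence[SkeletalRecord]],
    tests: Mapping[tuple[str, str], Sequence[SkeletalRecord]],
    alpha: float = 0.0,
    grid: AgeClassGrid | None = None,
    catalog: VariableCatalog | None = None,
) -> CrossedDesignResult:
    """Run the four-experiment crossed design per sex.

    ``references`` and ``tests`` map ``(population, sex)`` to record
    lists; exactly two populations and the sexes present in both maps are
    crossed.  Matched experiments get ids 1 and 2 (in population sort
    order), crossed experiments ids 3 and 4 (test population A on
    reference B, then test B on reference A).
    """
    pops = sorted({p for (p, _s) in references})
    if len(pops) != 2 or sorted({p for (p, _s) in tests}) != pops:
        raise ValueError("crossed design needs exactly two populations "
                         "present in both references and tests")
    pop_a, pop_b = pops
    sexes = sorted({s for (_p, s) in tests})
    experiments: dict[tuple[int, str], ExperimentResult] = {}
    comparisons: list[PairedComparison] = []
    no_est: dict[tuple[str, str, str], int] = {}
    design = [
        (1, pop_a, pop_a), (2, pop_b, pop_b),
        (3, pop_b, pop_a), (4, pop_a, pop_b),
    ]  # (experiment id, reference population, test population)
    for sex in sexes:
        for exp_id, ref_pop, test_pop in design:
            spec = ExperimentSpec(exp_id, ref_pop, test_pop, sex, alpha=alpha)
            result = run_experiment(spec, references[(ref_pop, sex)],
                                    tests[(test_pop, sex)], grid=grid,
                                    catalog=catalog)
            experiments[(exp_id, sex)] = result
            no_est[(test_pop, sex, ref_pop)] = len(result.no_estimation_ids)
        for test_pop, matched_id, crossed_id in (
            (pop_a, 1, 3), (pop_b, 2, 4),
        ):
            comparisons.extend(
                _paired_comparisons(
                    tests[(test_pop, sex)],
                    experiments[(matched_id, sex)],
                    experiments[(crossed_id, sex)],
                    sex,
                )
            )
    return CrossedDesignResult(experiments, comparisons, no_est)


def summarize_no_estimates(
    counts: Mapping[tuple[str, str, str], int]
) -> pd.DataFrame:
    """Per-pairing no-estimation counts plus matched and crossed means.

    ``counts`` maps (test population, sex, reference population) to the
    number of individuals the estimator declined in that pairing.
    """
    rows = [
        {"test_population": tp, "sex": s, "reference_population": rp,
         "pairing": "matched" if tp == rp else "crossed", "count": int(c)}
        for (tp, s, rp), c in counts.items()
    ]
    frame = pd.DataFrame(rows)
    means = frame.groupby("pairing")["count"].mean()
    frame["pairing_mean"] = frame["pairing"].map(means)
    return frame
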