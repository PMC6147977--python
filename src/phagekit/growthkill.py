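"""Suppression metrics and synergy tests for OD590 kill curves.

Two summary metrics per replicate trajectory — the OD at the end of the
assay (end-OD) and the trapezoid area under the curve (AUC, OD*h) — are
compared between a phage+antibiotic combination arm and its baseline arm
(phage alone at the same MOI, or the best-acting single agent at the same
dosage) with a one-tailed Welch t-test. Significance stars follow the usual
convention: *** p < 0.001, ** p < 0.01, * p < 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from phagekit.datatypes import ODTimeSeries, Treatment

__all__ = [
    "SynergyTestResult",
    "auc_trapezoid",
    "end_od",
    "one_tailed_ttest",
    "evaluate_combinations",
    "stars_for_p",
]

logger = logging.getLogger(__name__)

_GRID_TOL = 1e-9


def auc_trapezoid(series: ODTimeSeries) -> float:
    """Area under the OD curve by the trapezoid rule (OD*h).

    Sums (f(t_i) + f(t_{i+1}))/2 * dt over the n-1 observed intervals. For
    the standard assay (49 points, 20-min spacing) dt is the exact rational
    1/3 h, not its printed rounding.
    """
    if len(series) < 2:
        raise ValueError("need >= 2 points for AUC")
    steps = np.diff(series.times)
    if np.max(np.abs(steps - steps[0])) > _GRID_TOL:
        raise ValueError("AUC requires a uniform time grid")
    return float(np.trapezoid(series.od, dx=series.dt))


def end_od(series: ODTimeSeries) -> float:
    """OD reading at the final grid point (t = 16 h in the standard assay)."""
    if len(series) == 0:
        raise ValueError("empty series")
    return float(series.od[-1])


def stars_for_p(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class SynergyTestResult:
    """Outcome of one combination-vs-baseline comparison on one metric."""

    combination: Treatment
    baseline: Treatment
    metric: str                 # "endOD" | "AUC"
    t_stat: float
    p_one_sided: float
    stars: str
    enhanced: bool              # suppression significantly stronger at alpha
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.p_one_sided <= 1:
            raise ValueError("p must lie in [0, 1]")


def one_tailed_ttest(
    treated: np.ndarray,
    baseline: np.ndarray,
    combination: Treatment | None = None,
    baseline_treatment: Treatment | None = None,
    metric: str = "endOD",
    alpha: float = 0.05,
    equal_var: bool = False,
) -> SynergyTestResult:
    """One-tailed two-sample t-test for enhanced suppression.

    Alternative hypothesis: the treated (combination) arm's mean metric is
    *below* the baseline arm's (stronger suppression). Welch's
    unequal-variance statistic by default; ``equal_var=True`` selects the
    Student variant. Both arms having zero variance and equal means is a
    degenerate case reported as t = 0, p = 0.5.
    """
    treated = np.asarray(treated, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if len(treated) < 2 or len(baseline) < 2:
        raise ValueError("need >= 2 replicates per arm")
    degenerate = False
    if np.var(treated) == 0 and np.var(baseline) == 0:
        if treated.mean() == baseline.mean():
            t_stat, p = 0.0, 0.5
            degenerate = True
        else:
            # perfectly separated constant arms
            t_stat = -np.inf if treated.mean() < baseline.mean() else np.inf
            p = 0.0 if treated.mean() < baseline.mean() else 1.0
            degenerate = True
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.ttest_ind(
                treated, baseline, equal_var=equal_var, alternative="less"
            )
        t_stat, p = float(res.statistic), float(res.pvalue)
    return SynergyTestResult(
        combination=combination
        or Treatment(strain_id="treated"),
        baseline=baseline_treatment or Treatment(strain_id="baseline"),
        metric=metric,
        t_stat=t_stat,
        p_one_sided=p,
        stars=stars_for_p(p),
        enhanced=p < alpha,
        degenerate=degenerate,
    )


_METRIC_FN = {"endOD": end_od, "AUC": auc_trapezoid}


def _arm_metrics(
    experiment: list[ODTimeSeries],
) -> dict[Treatment, dict[str, list[float]]]:
    arms: dict[Treatment, dict[str, list[float]]] = {}
    for s in experiment:
        rec = arms.setdefault(s.treatment, {m: [] for m in _METRIC_FN})
        for m, fn in _METRIC_FN.items():
            rec[m].append(fn(s))
    return arms


def evaluate_combinations(
    experiment: list[ODTimeSeries],
    baseline_rule: str = "phage_alone",
    alpha: float = 0.05,
    equal_var: bool = False,
    metrics: tuple[str, ...] = ("endOD", "AUC"),
) -> list[SynergyTestResult]:
    """Test every phage+antibiotic combination arm against its baseline.

    ``baseline_rule="phage_alone"`` compares against the phage-alone arm at
    the same MOI; ``"best_single"`` against whichever single-agent arm
    (phage at the same MOI, or antibiotic at the same dosage) has the lower
    mean of the metric under test. Combinations missing their baseline arm
    are skipped with a logged warning. Both metrics are evaluated per
    combination; the result order follows the input order of combinations.
    """
    if baseline_rule not in ("phage_alone", "best_single"):
        raise ValueError(f"unknown baseline_rule {baseline_rule!r}")
    bad = [m for m in metrics if m not in _METRIC_FN]
    if bad:
        raise ValueError(f"unknown metrics {bad}")
    arms = _arm_metrics(experiment)
    combos = [
        t for t in arms
        if t.moi > 0 and t.antibiotic is not None
    ]
    results: list[SynergyTestResult] = []
    for combo in combos:
        phage_arm = Treatment(strain_id=combo.strain_id, moi=combo.moi)
        ab_arm = Treatment(
            strain_id=combo.strain_id, moi=0.0,
            antibiotic=combo.antibiotic, concentration=combo.concentration,
        )
        for metric in metrics:
            candidates: list[Treatment] = []
            if baseline_rule == "phage_alone":
                candidates = [phage_arm]
            else:
                candidates = [t for t in (phage_arm, ab_arm) if t in arms]
            candidates = [t for t in candidates if t in arms]
            if not candidates:
                logger.warning(
                    "skipping combination %s (%s): baseline arm missing",
                    combo.label, metric,
                )
                continue
            baseline = min(
                candidates, key=lambda t: float(np.mean(arms[t][metric]))
            )
            results.append(
                one_tailed_ttest(
                    np.array(arms[combo][metric]),
                    np.array(arms[baseline][metric]),
                    combination=combo,
                    baseline_treatment=baseline,
                    metric=metric,
                    alpha=alpha,
                    equal_var=equal_var,
                )
            )
    return results
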