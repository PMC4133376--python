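"""Decoder scoring and the repeated-retraining reliability assessment.

Accuracy is the fraction of assigned rivalry time points whose decoded
stimulus matches the behavioral report, tested against chance with an
exact one-sided binomial tail at p=1/2.  Because network training is
stochastic, the whole train+classify procedure is repeated many times
(1000 in the original protocol) on the task signal, and again on the
rest-block control signal; the per-repetition house percentages form two
distributions whose moments, kurtosis and normality separate a subject who
experienced rivalry (balanced, leptokurtic-or-normal task distribution,
tighter than the control) from one who did not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats as sps

from .decoder import ConvergenceError

__all__ = [
    "SuccessReport",
    "ReliabilityReport",
    "success_rate",
    "binomial_pvalue",
    "distribution_stats",
    "reliability_run",
    "reliability_verdict",
]


@dataclass
class SuccessReport:
    n_task: int
    n_assigned: int
    n_success: int
    discarded_pct: float
    success_pct: float
    p_value: float | None = None

    def to_dict(self):
        return {
            "n_task": self.n_task,
            "n_assigned": self.n_assigned,
            "n_success": self.n_success,
            "success_pct": self.success_pct,
            "discarded_pct": self.discarded_pct,
            "p_value": self.p_value,
        }


@dataclass
class ReliabilityReport:
    task_fractions: np.ndarray   # per-repetition house % of assigned points
    rest_fractions: np.ndarray
    task_stats: dict
    rest_stats: dict
    n_requested: int
    task_failures: int = 0
    rest_failures: int = 0
    verdict: dict | None = None


def success_rate(assignments: np.ndarray, percept_labels: np.ndarray) -> SuccessReport:
    """Score assignments against the behavioral percept vector.

    A success is an assigned time point whose label matches the report.
    Time points with unknown behavioral label (before the first button
    press) are excluded from both the success numerator and denominator;
    the discarded percentage counts unassigned points over all task points.
    """
    a = np.asarray(assignments, dtype=object)
    b = np.asarray(percept_labels, dtype=object)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} assignments vs {len(b)} labels")
    n_task = len(a)
    known = b != "unknown"
    assigned = (a != "unassigned") & known
    n_assigned = int(assigned.sum())
    n_success = int(np.sum(a[assigned] == b[assigned]))
    discarded_pct = 100.0 * float(np.mean(a == "unassigned")) if n_task else 0.0
    success_pct = 100.0 * n_success / n_assigned if n_assigned else float("nan")
    return SuccessReport(
        n_task=n_task,
        n_assigned=n_assigned,
        n_success=n_success,
        discarded_pct=discarded_pct,
        success_pct=success_pct,
    )


def binomial_pvalue(k_success: int, n_assigned: int) -> float:
    """Exact one-sided binomial tail P(X >= k | n, 1/2).

    Computed with exact integer arithmetic (sum of binomial coefficients
    over 2^n), so it is correct to full float precision for any practical n.
    """
    k, n = int(k_success), int(n_assigned)
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n and n >= 1")
    tail = sum(comb(n, i) for i in range(k, n + 1))
    return float(tail / (1 << n))


def distribution_stats(values) -> dict:
    """Sample moments and normality diagnostics of a repetition distribution.

    Returns mean, variance (n-1), skewness, Fisher excess kurtosis (normal
    => 0, leptokurtic > 0, platykurtic < 0) and the Shapiro-Wilk p-value.
    A constant sample gets ``degenerate=True`` with NaN shape statistics.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    out = {"n": len(x), "mean": float(x.mean()), "variance": float(x.var(ddof=1))}
    if np.ptp(x) == 0:
        out.update(skewness=float("nan"), excess_kurtosis=float("nan"),
                   shapiro_p=float("nan"), degenerate=True)
        return out
    out["skewness"] = float(sps.skew(x, bias=True))
    out["excess_kurtosis"] = float(sps.kurtosis(x, fisher=True, bias=True))
    out["shapiro_p"] = float(sps.shapiro(x).pvalue)
    out["degenerate"] = False
    return out


def _house_pct(output) -> float:
    a = output.assignments
    n_house = int(np.sum(a == "house"))
    n_face = int(np.sum(a == "face"))
    if n_house + n_face == 0:
        raise ConvergenceError("no assigned time points in repetition")
    return 100.0 * n_house / (n_house + n_face)


def reliability_run(pipeline_fn, task_inputs, rest_inputs, n_rep: int = 1000,
                    seed: int = 0, max_failure_fraction: float = 0.10) -> ReliabilityReport:
    """Repeat the train+classify procedure ``n_rep`` times on the task signal
    and, independently, on the rest-block control signal.

    ``pipeline_fn(inputs, seed) -> ClassificationOutput`` must encapsulate
    training (with restarts) and classification.  Each repetition records
    the house percentage of assigned points.  Repetitions that fail to
    converge are counted and excluded; more than ``max_failure_fraction``
    failures on either arm aborts the run.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(n_rep, 2))
    task_fracs, rest_fracs = [], []
    task_failures = rest_failures = 0
    for r in range(n_rep):
        try:
            task_fracs.append(_house_pct(pipeline_fn(task_inputs, int(rep_seeds[r, 0]))))
        except ConvergenceError:
            task_failures += 1
        try:
            rest_fracs.append(_house_pct(pipeline_fn(rest_inputs, int(rep_seeds[r, 1]))))
        except ConvergenceError:
            rest_failures += 1
    if max(task_failures, rest_failures) > max_failure_fraction * n_rep:
        raise ConvergenceError(
            f"too many failed repetitions (task {task_failures}, rest {rest_failures} of {n_rep})"
        )
    return ReliabilityReport(
        task_fractions=np.asarray(task_fracs),
        rest_fractions=np.asarray(rest_fracs),
        task_stats=distribution_stats(task_fracs),
        rest_stats=distribution_stats(rest_fracs),
        n_requested=n_rep,
        task_failures=task_failures,
        rest_failures=rest_failures,
    )


def reliability_verdict(report: ReliabilityReport, n_rois: int, model_val_mse: float) -> dict:
    """The four-condition checklist deciding whether the decoder output can
    be trusted to reflect experienced rivalry:

    1. the localizer yielded at least 3 ROIs;
    2. the accepted network trained to validation MSE < 0.02;
    3. the task-arm distribution is balanced (mean house % in [25, 75]) and
       leptokurtic or at most normal (excess kurtosis > 0 or Shapiro p > .05);
    4. the task arm is tighter and more symmetric than the rest control
       (smaller variance and smaller |skewness|).
    """
    ts, rs = report.task_stats, report.rest_stats
    if ts.get("degenerate") or rs.get("degenerate"):
        raise ValueError("degenerate repetition distribution; verdict undefined")
    cond1 = n_rois >= 3
    cond2 = model_val_mse < 0.02
    balanced = 25.0 <= ts["mean"] <= 75.0
    lepto_or_normal = ts["excess_kurtosis"] > 0 or ts["shapiro_p"] > 0.05
    cond3 = balanced and lepto_or_normal
    cond4 = ts["variance"] < rs["variance"] and abs(ts["skewness"]) < abs(rs["skewness"])
    verdict = {
        "rois_present": bool(cond1),
        "training_mse_ok": bool(cond2),
        "balanced_leptokurtic_task": bool(cond3),
        "task_tighter_than_rest": bool(cond4),
        "overall": bool(cond1 and cond2 and cond3 and cond4),
    }
    report.verdict = verdict
    return verdict
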