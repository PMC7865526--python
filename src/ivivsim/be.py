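"""Non-compartmental metrics and average-bioequivalence assessment.

NCA reduces each sampled profile to AUC(0-tlast) (linear trapezoid), Cmax
and Tmax.  Bioequivalence for a 2x2 crossover uses the classical
fixed-effects analysis on the log scale (sequence, subject within sequence,
period, treatment): the treatment effect estimate is

    delta = (mean of within-subject log T-R differences in sequence TR
             + mean in sequence RT) / 2

with ``Var(delta) = MSE * (1/n1 + 1/n2) / 2`` where MSE is the ANOVA
residual mean square (half the pooled variance of the within-subject
differences) and ``df = n1 + n2 - 2``.  This closed form is algebraically
identical to the OLS fit of the full fixed-effects model.  The 90% CI
``exp(delta -/+ t(0.05, df) * SE)`` must lie within 0.80-1.25 (inclusive)
for each metric, and overall bioequivalence requires every metric to pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NCAResult",
    "SubjectOutcome",
    "CrossoverDataset",
    "MetricResult",
    "BEResult",
    "nca",
    "be_2x2",
    "decide_overall",
    "assess_be",
    "DEFAULT_LIMITS",
]

DEFAULT_LIMITS = (0.80, 1.25)


@dataclass(frozen=True)
class NCAResult:
    """AUC to the last sample, maximum concentration and its (first) time."""

    auc_last: float
    cmax: float
    tmax: float


@dataclass(frozen=True)
class SubjectOutcome:
    """One subject's sequence and per-period NCA results (period order 1, 2)."""

    subject_id: int
    sequence: str
    period_nca: tuple[NCAResult, NCAResult]

    def by_product(self, metric: str) -> dict[str, float]:
        """Metric value per product for this subject."""
        out = {}
        for period, res in zip((1, 2), self.period_nca):
            out[self.sequence[period - 1]] = getattr(res, metric)
        return out


@dataclass(frozen=True)
class CrossoverDataset:
    """All subjects of one simulated 2x2 crossover study."""

    subjects: tuple[SubjectOutcome, ...]

    def __post_init__(self) -> None:
        for s in self.subjects:
            if s.sequence not in ("TR", "RT"):
                raise ValueError(f"bad sequence {s.sequence!r}")

    def split_sequences(self) -> tuple[list[SubjectOutcome], list[SubjectOutcome]]:
        tr = [s for s in self.subjects if s.sequence == "TR"]
        rt = [s for s in self.subjects if s.sequence == "RT"]
        return tr, rt


@dataclass(frozen=True)
class MetricResult:
    """BE decision components for one metric (AUC or Cmax)."""

    metric: str
    gmr: float
    ci90: tuple[float, float]
    passed: bool
    mse: float
    df: int


@dataclass(frozen=True)
class BEResult:
    """Per-metric results and the overall accept/reject decision."""

    metrics: dict[str, MetricResult]
    overall_pass: bool


def nca(times: np.ndarray, concentrations: np.ndarray) -> NCAResult:
    """Non-compartmental AUC(0-tlast), Cmax, Tmax from sampled data.

    AUC by linear trapezoid over all samples; Tmax is the earliest time at
    which the maximum is attained.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 samples for NCA")
    if t.size != c.size or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing and match concentrations")
    auc = float(np.trapezoid(c, t))
    imax = int(np.argmax(c))
    return NCAResult(auc_last=auc, cmax=float(c[imax]), tmax=float(t[imax]))


def be_2x2(
    dataset: CrossoverDataset,
    metric: str = "auc_last",
    limits: tuple[float, float] = DEFAULT_LIMITS,
    alpha: float = 0.05,
) -> MetricResult:
    """Average-bioequivalence test of one metric in a 2x2 crossover.

    90% CI (for the default ``alpha=0.05``) of the T/R geometric mean ratio
    from the log-scale crossover ANOVA; pass iff the CI lies inside
    ``limits`` inclusive.  With degenerate (zero) residual variance the CI
    collapses to the GMR point estimate.
    """
    tr, rt = dataset.split_sequences()
    n1, n2 = len(tr), len(rt)
    if n1 < 3 or n2 < 3:
        raise ValueError(f"need >= 3 subjects per sequence, got TR={n1}, RT={n2}")

    def logdiffs(group: list[SubjectOutcome]) -> np.ndarray:
        vals = []
        for s in group:
            per_product = s.by_product(metric)
            if per_product["T"] <= 0 or per_product["R"] <= 0:
                raise ValueError(
                    f"non-positive {metric} for subject {s.subject_id}: log scale undefined"
                )
            vals.append(math.log(per_product["T"]) - math.log(per_product["R"]))
        return np.array(vals)

    d1, d2 = logdiffs(tr), logdiffs(rt)
    delta = 0.5 * (d1.mean() + d2.mean())
    # Var(d_i) = 2 * sigma_w^2, and MSE estimates sigma_w^2
    pooled = ((d1 - d1.mean()) @ (d1 - d1.mean()) + (d2 - d2.mean()) @ (d2 - d2.mean()))
    df = n1 + n2 - 2
    mse = pooled / (2.0 * df)
    se = math.sqrt(mse * (1.0 / n1 + 1.0 / n2) / 2.0)
    gmr = math.exp(delta)
    if se <= 1e-12:  # degenerate (numerically zero) residual variance
        lo = hi = gmr
    else:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        lo, hi = math.exp(delta - tcrit * se), math.exp(delta + tcrit * se)
    passed = limits[0] <= lo and hi <= limits[1]
    return MetricResult(metric=metric, gmr=gmr, ci90=(lo, hi), passed=passed,
                        mse=float(mse), df=df)


def decide_overall(metric_results: dict[str, MetricResult]) -> bool:
    """Overall bioequivalence: every assessed metric must pass."""
    if not metric_results:
        raise ValueError("no metric results supplied")
    return all(r.passed for r in metric_results.values())


def assess_be(
    dataset: CrossoverDataset,
    metrics: tuple[str, ...] = ("auc_last", "cmax"),
    limits: tuple[float, float] = DEFAULT_LIMITS,
) -> BEResult:
    """Run the 2x2 analysis for each metric and combine into one decision."""
    results = {m: be_2x2(dataset, m, limits) for m in metrics}
    return BEResult(metrics=results, overall_pass=decide_overall(results))
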