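"""Monte Carlo estimation of the probability of bioequivalence acceptance.

One virtual study = draw a population, simulate both crossover periods per
subject through the dissolution-transit-absorption-disposition model, sample
each profile per the scheme with proportional residual error, compute NCA
metrics, and run the 2x2 average-bioequivalence analysis on AUC and Cmax.
Repeating the study under independent sub-seeds and recording the pass/fail
outcomes yields the percent probability of acceptance for a scenario; grids
of scenarios (sample size x sampling scheme x transit x variability levels)
map the robustness of that probability, and batches are ranked by a
conservative joint statistic (the mean over scenarios of the minimum
acceptance across the drugs of a combination product).

All randomness descends from one master seed through ``SeedSequence`` spawns,
so every replicate is reproducible in isolation and results do not depend on
execution order.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .be import BEResult, CrossoverDataset, SubjectOutcome, assess_be, nca
from .transit import TransitScenario, get_transit_scenario
from .trial import (
    SAMPLING_SCHEMES,
    DrugModelSpec,
    VariabilitySpec,
    draw_population,
    observe,
    simulate_profile,
)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "TABLE_FACTORS",
    "REDUCED_FACTORS",
    "run_virtual_study",
    "estimate_probability",
    "build_scenario_grid",
    "summarize_grid",
    "compare_batches",
]

#: Full factor domains of the scenario grid.
TABLE_FACTORS = {
    "sample_size": (12, 18, 24, 30, 36),
    "scheme": ("typical", "sparse", "dense"),
    "transit_id": (1, 2, 3, 4, 5),
    "bsv_cv": (5.0, 10.0, 20.0),
    "wsv_cv": (5.0, 10.0, 20.0),
}

#: Reduced factorial: the most probable levels of each factor.
REDUCED_FACTORS = {
    "sample_size": (12, 18, 24),
    "scheme": ("typical", "sparse", "dense"),
    "transit_id": (1, 2),
    "bsv_cv": (5.0, 10.0),
    "wsv_cv": (10.0, 20.0),
}


@dataclass(frozen=True)
class Scenario:
    """One Monte Carlo condition of the virtual-study grid."""

    sample_size: int
    scheme: str
    transit_id: int
    bsv_cv: float
    wsv_cv: float
    gastric_state: str = "fasted"
    residual_cv: float = 5.0

    def __post_init__(self) -> None:
        if self.sample_size < 6 or self.sample_size % 2:
            raise ValueError("sample_size must be even and >= 6")
        if self.scheme not in SAMPLING_SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.gastric_state not in ("fasted", "fed"):
            raise ValueError("gastric_state must be 'fasted' or 'fed'")

    @property
    def variability(self) -> VariabilitySpec:
        return VariabilitySpec(self.bsv_cv, self.wsv_cv, self.residual_cv)


@dataclass(frozen=True)
class ScenarioResult:
    """Acceptance tally of one scenario's Monte Carlo run."""

    scenario: Scenario
    n_reps: int
    n_success: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_success <= self.n_reps:
            raise ValueError("n_success must be within [0, n_reps]")

    @property
    def acceptance_pct(self) -> float:
        return 100.0 * self.n_success / self.n_reps

    @property
    def binomial_se_pct(self) -> float:
        p = self.n_success / self.n_reps
        return 100.0 * math.sqrt(p * (1.0 - p) / self.n_reps)


def run_virtual_study(
    scenario: Scenario,
    spec: DrugModelSpec,
    seed: int | np.random.SeedSequence | None = None,
    transit: TransitScenario | None = None,
) -> BEResult:
    """Simulate one complete virtual 2x2 crossover BE study.

    Fully reproducible per seed: population draw and every observation draw
    descend from independent ``SeedSequence`` spawns of the master seed.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pop_ss, obs_ss = ss.spawn(2)
    if transit is None:
        transit = get_transit_scenario(scenario.transit_id)

    subjects = draw_population(
        scenario.sample_size, spec, scenario.variability,
        seed=np.random.default_rng(pop_ss),
    )
    scheme_times = np.array(SAMPLING_SCHEMES[scenario.scheme], dtype=float)
    obs_rng = np.random.default_rng(obs_ss)

    outcomes = []
    for subj in subjects:
        period_nca = []
        for period in (1, 2):
            product = subj.product_in_period(period)
            profile = simulate_profile(
                subj.period_params[period - 1], product, spec, transit,
                gastric_state=scenario.gastric_state, t_grid=scheme_times,
            )
            t, c = observe(profile, scheme_times, scenario.residual_cv, seed=obs_rng)
            period_nca.append(nca(t, c))
        outcomes.append(
            SubjectOutcome(subj.subject_id, subj.sequence, tuple(period_nca))
        )
    return assess_be(CrossoverDataset(tuple(outcomes)))


def estimate_probability(
    scenario: Scenario,
    spec: DrugModelSpec,
    n_reps: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
) -> ScenarioResult:
    """Percent probability of BE acceptance over ``n_reps`` virtual studies."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    transit = get_transit_scenario(scenario.transit_id)
    n_success = 0
    for rep_ss in ss.spawn(n_reps):
        result = run_virtual_study(scenario, spec, seed=rep_ss, transit=transit)
        n_success += int(result.overall_pass)
    return ScenarioResult(scenario=scenario, n_reps=n_reps, n_success=n_success)


def build_scenario_grid(
    factors: dict | None = None,
    mode: str = "full",
    extra_scenarios: list[Scenario] | None = None,
) -> list[Scenario]:
    """Enumerate the scenario grid.

    ``mode="full"`` takes the Cartesian product of the full factor domains
    (675 scenarios), ``"reduced"`` the reduced factorial (72), and
    ``"custom"`` requires explicit ``factors``.  ``extra_scenarios`` are
    appended (the hand-picked single-condition additions of a study plan);
    duplicates are dropped with a warning.
    """
    if mode == "full":
        base = dict(TABLE_FACTORS)
    elif mode == "reduced":
        base = dict(REDUCED_FACTORS)
    elif mode == "custom":
        if not factors:
            raise ValueError("custom mode requires a factors mapping")
        base = {}
    else:
        raise ValueError(f"mode must be full|reduced|custom, got {mode!r}")
    if factors:
        base.update(factors)
    for name, levels in base.items():
        if not levels:
            raise ValueError(f"factor {name!r} has no levels")

    names = list(base)
    grid = [
        Scenario(**dict(zip(names, combo)))
        for combo in itertools.product(*(base[n] for n in names))
    ]
    for sc in extra_scenarios or []:
        grid.append(sc)
    seen: set[Scenario] = set()
    unique: list[Scenario] = []
    for sc in grid:
        if sc in seen:
            warnings.warn(f"duplicate scenario dropped: {sc}", stacklevel=2)
            continue
        seen.add(sc)
        unique.append(sc)
    return unique


def summarize_grid(
    results: list[ScenarioResult], bin_width: float = 5.0
) -> dict:
    """Histogram and aggregates of acceptance percentages across scenarios."""
    if not results:
        raise ValueError("no results to summarize")
    pct = np.array([r.acceptance_pct for r in results])
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    edges[-1] = 100.0 + 1e-9  # include 100% in the top bin
    counts, _ = np.histogram(pct, bins=edges)
    return {
        "n_scenarios": len(results),
        "bin_edges": [float(e) for e in np.arange(0.0, 100.0 + bin_width, bin_width)],
        "bin_counts": [int(c) for c in counts],
        "mean_acceptance_pct": float(pct.mean()),
        "median_acceptance_pct": float(np.median(pct)),
        "min_acceptance_pct": float(pct.min()),
        "max_acceptance_pct": float(pct.max()),
    }


def compare_batches(
    batch_results: dict[str, dict[str, list[ScenarioResult]]],
) -> list[tuple[str, float]]:
    """Rank formulation batches by a conservative joint acceptance score.

    ``batch_results[batch][drug]`` holds one ScenarioResult list per drug,
    over an identical scenario set for every batch and drug.  The score is
    the mean over scenarios of the minimum acceptance across drugs (a
    combination product passes only if every compound does); ranking is
    descending with stable tie-break by batch label.
    """
    if not batch_results:
        raise ValueError("no batches supplied")

    def scenario_key(res: list[ScenarioResult]) -> tuple:
        return tuple(r.scenario for r in res)

    reference: tuple | None = None
    scores: dict[str, float] = {}
    for batch, per_drug in sorted(batch_results.items()):
        if not per_drug:
            raise ValueError(f"batch {batch!r} has no drug results")
        keys = {scenario_key(res) for res in per_drug.values()}
        if len(keys) != 1:
            raise ValueError(f"batch {batch!r}: scenario sets differ across drugs")
        (key,) = keys
        if reference is None:
            reference = key
        elif key != reference:
            raise ValueError(f"batch {batch!r}: scenario set differs from other batches")
        mat = np.array([[r.acceptance_pct for r in res] for res in per_drug.values()])
        scores[batch] = float(mat.min(axis=0).mean())
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
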