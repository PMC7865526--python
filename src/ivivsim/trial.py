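"""Virtual-subject generation and concentration-time profile simulation.

A virtual bioequivalence study couples three layers per subject and period:

1. first-order dissolution toward the pH-specific plateau of the GI segment
   currently occupied (``dD_cum/dt = Kd_seg * max(m0_seg*Dose - D_cum, 0)``),
2. first-order "true" absorption of dissolved drug from the lumen, gated by
   the absorption lag time and the segment's absorption availability, and
3. linear one- or two-compartment disposition.

Between event times (segment boundaries, the absorption lag, the end of
total transit) the full system is linear and time-invariant, so the default
backend propagates it exactly by eigendecomposition of the augmented system
matrix; an adaptive Runge-Kutta backend (``method="rk45"``) with restarts at
every event time is available and serves as a fallback for ill-conditioned
eigensystems.

Population variability is lognormal on all PK parameters: between-subject
(one draw per subject) and within-subject (one draw per period), with CVs
converted via ``sigma = sqrt(ln(1 + (cv/100)**2))``.  Residual proportional
error applies at observation time only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .dissolution import FirstOrderParams
from .pk import OneCompartmentParams, TwoCompartmentParams
from .transit import TransitScenario, conditions_for, segment_at

__all__ = [
    "SAMPLING_SCHEMES",
    "DrugModelSpec",
    "VariabilitySpec",
    "VirtualSubject",
    "SimulatedProfile",
    "draw_population",
    "simulate_profile",
    "observe",
]

#: Named sampling schemes (minutes after dosing).
SAMPLING_SCHEMES: dict[str, tuple[float, ...]] = {
    "sparse": (0, 10, 40, 60, 90, 160, 240, 480, 720, 1440),
    "typical": (0, 10, 20, 40, 60, 90, 120, 180, 240, 360, 480, 720, 960, 1440),
    "dense": (0, 10, 20, 40, 60, 80, 100, 120, 150, 180, 240, 360, 480, 600,
              720, 960, 1440),
}

_PERTURBED = ("cl_f", "v1_f", "q_f", "v2_f", "kat", "tlag")


def cv_to_sigma(cv_percent: float) -> float:
    """Lognormal sigma reproducing a coefficient of variation in percent."""
    if cv_percent < 0:
        raise ValueError("cv must be >= 0")
    return math.sqrt(math.log(1.0 + (cv_percent / 100.0) ** 2))


@dataclass(frozen=True)
class VariabilitySpec:
    """Between-subject, within-subject and residual variability (CV%)."""

    bsv_cv: float = 0.0
    wsv_cv: float = 0.0
    residual_cv: float = 5.0

    def __post_init__(self) -> None:
        for name in ("bsv_cv", "wsv_cv", "residual_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DrugModelSpec:
    """Full in vitro + in vivo parameterization of one compound.

    ``dissolution`` maps product ("T" or "R") to a dict of buffer pH ->
    :class:`~ivivsim.dissolution.FirstOrderParams`.  ``kat`` is the averaged
    "true" absorption rate constant used for both products; what separates
    Test from Reference in simulation is the dissolution parameter set only.
    """

    name: str
    dose_mg: float
    disposition: OneCompartmentParams | TwoCompartmentParams
    kat: float
    dissolution: dict[str, dict[float, FirstOrderParams]]

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose_mg must be non-negative")
        if self.kat <= 0:
            raise ValueError("kat must be positive")
        for product in ("T", "R"):
            if product not in self.dissolution:
                raise ValueError(f"dissolution parameters for product {product!r} missing")

    @property
    def model(self) -> str:
        if isinstance(self.disposition, TwoCompartmentParams):
            return "two_compartment_lag"
        return "one_compartment"

    def typical_params(self) -> dict[str, float]:
        """Typical subject-period parameter vector (disposition + kat)."""
        d = self.disposition
        params = {"cl_f": d.cl_f, "v1_f": d.v1_f, "kat": self.kat, "tlag": d.tlag}
        if isinstance(d, TwoCompartmentParams):
            params["q_f"] = d.q_f
            params["v2_f"] = d.v2_f
        return params


@dataclass(frozen=True)
class VirtualSubject:
    """One subject of a 2x2 crossover: sequence and per-period PK parameters."""

    subject_id: int
    sequence: str  # "TR" or "RT"
    period_params: tuple[dict[str, float], dict[str, float]]

    def __post_init__(self) -> None:
        if self.sequence not in ("TR", "RT"):
            raise ValueError("sequence must be 'TR' or 'RT'")
        if len(self.period_params) != 2:
            raise ValueError("exactly two periods required")

    def product_in_period(self, period: int) -> str:
        """Product ('T'/'R') administered in period 1 or 2."""
        if period not in (1, 2):
            raise ValueError("period must be 1 or 2")
        return self.sequence[period - 1]


@dataclass(frozen=True)
class SimulatedProfile:
    """Dense model concentrations plus the state trajectories behind them."""

    times: np.ndarray
    concentrations: np.ndarray
    dissolved_cum: np.ndarray
    lumen: np.ndarray
    central: np.ndarray
    peripheral: np.ndarray | None = None


def draw_population(
    n: int,
    spec: DrugModelSpec,
    variability: VariabilitySpec,
    seed: int | np.random.Generator | None = None,
) -> list[VirtualSubject]:
    """Draw ``n`` virtual subjects with lognormal parameter variability.

    Each PK parameter gets an independent between-subject factor
    ``exp(eta)``, ``eta ~ N(0, sigma_bsv^2)``, shared by both periods, and an
    independent within-subject factor per period.  Sequences are balanced:
    a random permutation assigns half the subjects to TR and half to RT.
    """
    if n < 2 or n % 2:
        raise ValueError(f"n must be even and >= 2 for a balanced 2x2 design, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s_bsv = cv_to_sigma(variability.bsv_cv)
    s_wsv = cv_to_sigma(variability.wsv_cv)
    typical = spec.typical_params()
    names = [k for k in _PERTURBED if k in typical]

    perm = rng.permutation(n)
    sequences = np.empty(n, dtype=object)
    sequences[perm[: n // 2]] = "TR"
    sequences[perm[n // 2:]] = "RT"

    subjects = []
    for i in range(n):
        bsv = {k: math.exp(rng.normal(0.0, s_bsv)) if s_bsv else 1.0 for k in names}
        periods = []
        for _ in range(2):
            wsv = {k: math.exp(rng.normal(0.0, s_wsv)) if s_wsv else 1.0 for k in names}
            periods.append({k: typical[k] * bsv[k] * wsv[k] for k in names})
        subjects.append(VirtualSubject(i + 1, str(sequences[i]), (periods[0], periods[1])))
    return subjects


# --- piecewise-linear propagation -------------------------------------------


def _event_times(
    scenario: TransitScenario, tlag: float, t_end: float
) -> list[float]:
    events = {0.0, t_end}
    for e in (scenario.stomach_min, scenario.small_intestine_end,
              scenario.total_min, tlag):
        if 0.0 < e < t_end:
            events.add(float(e))
    return sorted(events)


def _interval_constants(
    t0: float,
    dcum0: float,
    params: dict[str, float],
    product_diss: dict[float, FirstOrderParams],
    spec: DrugModelSpec,
    scenario: TransitScenario,
    gastric_state: str,
    stomach_absorption_scale: float,
    colon_absorption_scale: float,
) -> tuple[float, float, float]:
    """(Kd_eff, plateau_amount, absorption_rate) in force just after ``t0``."""
    segment = segment_at(t0, scenario)
    cond = conditions_for(
        segment, gastric_state, product_diss,
        stomach_absorption_scale=stomach_absorption_scale,
        colon_absorption_scale=colon_absorption_scale,
    )
    m_plateau = cond.dissolution_params.m0 * spec.dose_mg
    kd = cond.dissolution_params.kd
    # no re-precipitation: clamp dissolution off if already past this
    # segment's plateau; halt dissolution beyond total transit time
    if dcum0 >= m_plateau - 1e-12 or t0 >= scenario.total_min:
        kd, m_plateau = 0.0, dcum0
    r = cond.absorption_scale * params["kat"] if t0 >= params.get("tlag", 0.0) else 0.0
    return kd, m_plateau, r


def _system_matrix(
    kd: float, r: float, params: dict[str, float], two_cpt: bool
) -> np.ndarray:
    """Homogeneous system matrix for one constant-coefficient interval.

    The dissolution state is expressed as ``u = D_cum - plateau`` so the
    constant release input disappears and the system is strictly linear:
    ``du/dt = -kd*u``, ``dL/dt = -kd*u - r*L``, plus disposition.
    """
    kel = params["cl_f"] / params["v1_f"]
    if two_cpt:
        k12 = params["q_f"] / params["v1_f"]
        k21 = params["q_f"] / params["v2_f"]
        a = np.zeros((4, 4))
        a[0, 0] = -kd
        a[1, 0] = -kd
        a[1, 1] = -r
        a[2, 1] = r
        a[2, 2] = -(kel + k12)
        a[2, 3] = k21
        a[3, 2] = k12
        a[3, 3] = -k21
    else:
        a = np.zeros((3, 3))
        a[0, 0] = -kd
        a[1, 0] = -kd
        a[1, 1] = -r
        a[2, 1] = r
        a[2, 2] = -kel
    return a


def _propagate_eig(
    a: np.ndarray, z0: np.ndarray, dts: np.ndarray
) -> np.ndarray | None:
    """States at offsets ``dts`` via eigendecomposition; None if ill-conditioned."""
    w, v = np.linalg.eig(a)
    try:
        c = np.linalg.solve(v, z0)
    except np.linalg.LinAlgError:
        return None
    if np.linalg.cond(v) > 1e10:
        return None
    out = (v @ (c[:, None] * np.exp(np.outer(w, dts)))).real
    return out


def _rhs_factory(kd, m_plateau, r, params, two_cpt):
    kel = params["cl_f"] / params["v1_f"]
    if two_cpt:
        k12 = params["q_f"] / params["v1_f"]
        k21 = params["q_f"] / params["v2_f"]

        def rhs(t, x):
            release = kd * max(m_plateau - x[0], 0.0)
            return [
                release,
                release - r * x[1],
                r * x[1] - (kel + k12) * x[2] + k21 * x[3],
                k12 * x[2] - k21 * x[3],
            ]
    else:

        def rhs(t, x):
            release = kd * max(m_plateau - x[0], 0.0)
            return [release, release - r * x[1], r * x[1] - kel * x[2]]

    return rhs


def simulate_profile(
    params: dict[str, float],
    product: str,
    spec: DrugModelSpec,
    scenario: TransitScenario,
    gastric_state: str = "fasted",
    t_grid: np.ndarray | None = None,
    method: str = "analytic",
    stomach_absorption_scale: float = 0.0,
    colon_absorption_scale: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulatedProfile:
    """Simulate one subject-period concentration-time profile.

    ``params`` is a subject-period parameter vector (``cl_f``, ``v1_f``,
    ``kat``, ``tlag`` and, for two-compartment drugs, ``q_f``, ``v2_f``);
    ``product`` selects which formulation's dissolution parameters drive
    release.  ``method`` is ``"analytic"`` (exact piecewise matrix
    exponential, the default) or ``"rk45"`` (adaptive Runge-Kutta with
    restarts at every event time).  Concentration is central amount divided
    by ``v1_f`` (mg/mL when dose is mg and volume mL).
    """
    if product not in spec.dissolution:
        raise KeyError(f"unknown product {product!r}")
    if method not in ("analytic", "rk45"):
        raise ValueError("method must be 'analytic' or 'rk45'")
    if t_grid is None:
        t_grid = np.arange(0.0, 1441.0, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and increase strictly")

    two_cpt = spec.model == "two_compartment_lag"
    nstates = 4 if two_cpt else 3
    product_diss = spec.dissolution[product]
    t_end = float(t_grid[-1])
    events = _event_times(scenario, params.get("tlag", 0.0), t_end)

    if spec.dose_mg == 0:
        zeros = np.zeros_like(t_grid)
        return SimulatedProfile(t_grid, zeros, zeros, zeros, zeros,
                                zeros if two_cpt else None)

    states = np.zeros((nstates, t_grid.size))
    x = np.zeros(nstates)
    for a_t, b_t in zip(events[:-1], events[1:]):
        kd, m_plateau, r = _interval_constants(
            a_t, x[0], params, product_diss, spec, scenario, gastric_state,
            stomach_absorption_scale, colon_absorption_scale,
        )
        mask = (t_grid >= a_t) & (t_grid < b_t) if b_t < t_end else (
            (t_grid >= a_t) & (t_grid <= b_t))
        eval_t = t_grid[mask]
        # endpoint state is needed to seed the next interval; avoid
        # duplicating it when the grid already ends the interval
        if eval_t.size and eval_t[-1] == b_t:
            dts = eval_t - a_t
        else:
            dts = np.append(eval_t - a_t, b_t - a_t)

        got = None
        if method == "analytic":
            amat = _system_matrix(kd, r, params, two_cpt)
            z0 = x.copy()
            z0[0] -= m_plateau  # u = D_cum - plateau (homogeneous form)
            out = _propagate_eig(amat, z0, dts)
            if out is not None:
                got = out
                got[0] += m_plateau
        if got is None:  # rk45 requested, or eigensystem fallback
            rhs = _rhs_factory(kd, m_plateau, r, params, two_cpt)
            sol = solve_ivp(
                rhs, (a_t, b_t), x, method="RK45", t_eval=a_t + dts,
                rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise RuntimeError(
                    f"ODE solver failed on [{a_t}, {b_t}]: {sol.message}"
                )
            got = sol.y
        if eval_t.size:
            states[:, mask] = got[:, : eval_t.size]
        x = got[:, -1]

    states = np.clip(states, 0.0, None)  # wash tiny negative round-off
    conc = states[2] / params["v1_f"]
    return SimulatedProfile(
        times=t_grid,
        concentrations=conc,
        dissolved_cum=states[0],
        lumen=states[1],
        central=states[2],
        peripheral=states[3] if two_cpt else None,
    )


def observe(
    profile: SimulatedProfile,
    scheme: str | np.ndarray,
    residual_cv: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a profile at a scheme's times with proportional residual error.

    ``C_obs = C * exp(eps)``, ``eps ~ N(0, sigma^2)`` with sigma from
    ``residual_cv`` -- multiplicative, so observations stay positive and the
    error is proportional to first order.  Returns ``(times, concentrations)``.
    """
    if isinstance(scheme, str):
        if scheme not in SAMPLING_SCHEMES:
            raise KeyError(f"unknown scheme {scheme!r}; choose from {sorted(SAMPLING_SCHEMES)}")
        times = np.array(SAMPLING_SCHEMES[scheme], dtype=float)
    else:
        times = np.asarray(scheme, dtype=float)
    if times.min() < profile.times[0] or times.max() > profile.times[-1]:
        raise ValueError("sampling times fall outside the simulated grid")
    conc = np.interp(times, profile.times, profile.concentrations)
    if residual_cv:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        conc = conc * np.exp(rng.normal(0.0, cv_to_sigma(residual_cv), size=conc.size))
    return times, conc
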