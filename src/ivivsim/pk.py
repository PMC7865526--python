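"""Compartmental PK parameterizations and absorption-rate calculations.

Two drug-specific calculations live here beside the parameter containers:

* numerical inversion of the one-compartment Tmax equation
  ``Tmax = ln(Ka/Kel) / (Ka - Kel)`` for the absorption rate constant Ka,
  exploiting that Tmax is strictly decreasing in Ka; and
* the mean-time decomposition of the composite (literature) absorption rate
  constant into dissolution and "true" absorption (permeation) components.
  Release and permeation are consecutive first-order steps, so their mean
  times add: ``1/Ka = 1/Kd + 1/Kat``, giving ``Kat = 1/(1/Ka - 1/Kd)``.

The literature parameter sets for the amlodipine / irbesartan /
hydrochlorothiazide triple combination (10/300/12.5 mg) ship as a built-in
registry, with the composite Ka decomposed per product (Test and Reference
use their own pH 6.8 dissolution rate constants) and averaged, since
permeation is a property of the active substance, not the formulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from scipy.optimize import brentq

import math

__all__ = [
    "OneCompartmentParams",
    "TwoCompartmentParams",
    "TrueAbsorption",
    "kel_from_clearance",
    "tmax_one_compartment",
    "ka_from_tmax",
    "kat_from_ka_kd",
    "average_true_ka",
    "decompose_true_absorption",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class OneCompartmentParams:
    """One-compartment disposition with first-order absorption.

    ``cl_f`` apparent clearance (mL/min), ``v1_f`` apparent central volume
    (mL), ``ka`` literature composite absorption rate constant (1/min).  The
    elimination rate constant ``kel = cl_f / v1_f`` is derived.
    """

    cl_f: float
    v1_f: float
    ka: float

    def __post_init__(self) -> None:
        _require_positive(cl_f=self.cl_f, v1_f=self.v1_f, ka=self.ka)

    @property
    def kel(self) -> float:
        return self.cl_f / self.v1_f

    @property
    def tlag(self) -> float:
        return 0.0


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Two-compartment disposition with absorption lag time.

    ``q_f`` is the apparent inter-compartmental clearance (mL/min), ``v2_f``
    the apparent peripheral volume (mL), ``tlag`` the absorption lag (min).
    """

    cl_f: float
    q_f: float
    v1_f: float
    v2_f: float
    ka: float
    tlag: float = 0.0

    def __post_init__(self) -> None:
        _require_positive(cl_f=self.cl_f, q_f=self.q_f, v1_f=self.v1_f,
                          v2_f=self.v2_f, ka=self.ka)
        if self.tlag < 0:
            raise ValueError(f"tlag must be >= 0, got {self.tlag}")

    @property
    def kel(self) -> float:
        return self.cl_f / self.v1_f


@dataclass(frozen=True)
class TrueAbsorption:
    """Mean-time bookkeeping of the Ka -> (Kd, Kat) decomposition.

    ``mt_total = 1/Ka`` is the mean time of the whole absorption process,
    the sum of the mean dissolution time ``mt_dissolution = 1/Kd`` and the
    mean "true" absorption time ``mt_absorption = 1/Kat``.  ``kat`` is the
    arithmetic mean of the Test and Reference values and is what the
    simulations use.
    """

    kat_t: float
    kat_r: float
    kat: float
    mt_total_t: float = math.nan
    mt_total_r: float = math.nan
    mt_dissolution_t: float = math.nan
    mt_dissolution_r: float = math.nan
    mt_absorption_t: float = math.nan
    mt_absorption_r: float = math.nan


def kel_from_clearance(cl_f: float, v1_f: float) -> float:
    """Elimination rate constant (1/min) from apparent clearance and volume."""
    _require_positive(cl_f=cl_f, v1_f=v1_f)
    return cl_f / v1_f


def tmax_one_compartment(ka: float, kel: float) -> float:
    """Time of peak concentration for first-order absorption and elimination.

    ``ln(ka/kel)/(ka - kel)`` for distinct rates, with the analytic limit
    ``1/kel`` at ``ka == kel``; symmetric in its two arguments.
    """
    _require_positive(ka=ka, kel=kel)
    if ka == kel:
        return 1.0 / kel
    return math.log(ka / kel) / (ka - kel)


def ka_from_tmax(tmax: float, kel: float, tol: float = 1e-10) -> float:
    """Solve ``tmax_one_compartment(ka, kel) == tmax`` for ``ka > 0``.

    The Tmax map is strictly decreasing in Ka, so the root is unique;
    bracketed root finding with automatic bracket expansion is used.  When
    ``tmax > 1/kel`` the solution lies on the flip-flop branch (Ka < Kel),
    which is returned rather than rejected.  ``tol`` bounds the Tmax
    residual of the returned root.
    """
    _require_positive(tmax=tmax, kel=kel)
    if math.isclose(tmax, 1.0 / kel, rel_tol=1e-14):
        return kel

    def resid(ka: float) -> float:
        return tmax_one_compartment(ka, kel) - tmax

    lo, hi = kel * 0.5, kel * 2.0
    for _ in range(200):
        if resid(lo) > 0 >= resid(hi) or resid(lo) >= 0 > resid(hi):
            break
        # resid is decreasing in ka: widen toward the sign change
        if resid(hi) > 0:
            hi *= 2.0
        if resid(lo) < 0:
            lo *= 0.5
    else:
        raise RuntimeError(f"bracket expansion failed for tmax={tmax}, kel={kel}")
    ka = brentq(resid, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    # tol is applied to the Tmax residual, relative for large Tmax so the
    # check is attainable at double precision across the whole rate range
    if abs(resid(ka)) > tol * max(1.0, tmax):
        raise RuntimeError(
            f"ka_from_tmax did not meet tolerance: residual {resid(ka):.3e}"
        )
    return float(ka)


def kat_from_ka_kd(ka: float, kd: float) -> float:
    """"True" (permeation-only) absorption rate constant by mean-time subtraction.

    ``Kat = 1/(1/Ka - 1/Kd)``; requires ``kd > ka`` (the mean dissolution time
    ``1/Kd`` must be shorter than the total mean absorption time ``1/Ka``).
    Always exceeds ``ka``: removing the dissolution component shortens the
    mean time.
    """
    _require_positive(ka=ka, kd=kd)
    if kd <= ka:
        raise ValueError(
            f"kd ({kd}) must exceed ka ({ka}): the mean dissolution time 1/Kd "
            "cannot be >= the total mean absorption time 1/Ka"
        )
    return 1.0 / (1.0 / ka - 1.0 / kd)


def average_true_ka(kat_t: float, kat_r: float) -> TrueAbsorption:
    """Average the Test and Reference "true" absorption rate constants.

    Permeation is a property of the active substance, not the formulation,
    so ``kat = (Kat_T + Kat_R) / 2`` serves both products in simulation.
    """
    _require_positive(kat_t=kat_t, kat_r=kat_r)
    return TrueAbsorption(
        kat_t=kat_t,
        kat_r=kat_r,
        kat=0.5 * (kat_t + kat_r),
        mt_absorption_t=1.0 / kat_t,
        mt_absorption_r=1.0 / kat_r,
    )


def decompose_true_absorption(ka: float, kd_t: float, kd_r: float) -> TrueAbsorption:
    """Decompose the composite Ka per product and average the results.

    ``Kat_T`` uses the Test pH 6.8 dissolution rate constant, ``Kat_R`` the
    Reference one; the mean-time bookkeeping fields are fully populated so
    that ``mt_total = mt_dissolution + mt_absorption`` holds per product by
    construction.
    """
    kat_t = kat_from_ka_kd(ka, kd_t)
    kat_r = kat_from_ka_kd(ka, kd_r)
    base = average_true_ka(kat_t, kat_r)
    return TrueAbsorption(
        kat_t=base.kat_t,
        kat_r=base.kat_r,
        kat=base.kat,
        mt_total_t=1.0 / ka,
        mt_total_r=1.0 / ka,
        mt_dissolution_t=1.0 / kd_t,
        mt_dissolution_r=1.0 / kd_r,
        mt_absorption_t=base.mt_absorption_t,
        mt_absorption_r=base.mt_absorption_r,
    )
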