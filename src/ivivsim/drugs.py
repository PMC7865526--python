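"""Built-in literature parameterizations for the worked triple combination.

The amlodipine / irbesartan / hydrochlorothiazide (10/300/12.5 mg) immediate
release combination ships as a ready-made registry: disposition parameters
and composite absorption rate constants from published population PK work,
and first-order dissolution parameters (m0, Kd) fitted per buffer pH for the
Test product, with the Reference product's pH 6.8 dissolution rate constant
given separately.  Where the Reference product's remaining dissolution
parameters were not published, the Test values are reused (documented in the
methods note).

Units are kept exactly as published: clearances in mL/min, volumes in mL,
rate constants in 1/min, lag times in minutes.  Note the amlodipine V1/F of
1300 mL together with Cl/F = 370 mL/min implies an implausibly short
elimination half-life (~2.4 min); the values are carried as published and
flagged here rather than corrected.

The "true" absorption rate constant Kat is not stored: it is recomputed at
import-free call time from Ka and the two pH 6.8 Kd values via the mean-time
decomposition in :mod:`ivivsim.pk`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dissolution import FirstOrderParams
from .pk import (
    OneCompartmentParams,
    TrueAbsorption,
    TwoCompartmentParams,
    decompose_true_absorption,
)
from .trial import DrugModelSpec

__all__ = ["DRUGS", "DrugRecord", "builtin_drug_spec", "true_absorption_for"]


@dataclass(frozen=True)
class DrugRecord:
    """Raw literature inputs for one compound (before Kat decomposition)."""

    name: str
    dose_mg: float
    model: str  # "one_compartment" | "two_compartment_lag"
    cl_f: float
    v1_f: float
    ka: float
    q_f: float | None = None
    v2_f: float | None = None
    tlag: float = 0.0
    # per-pH (m0, kd) for the Test product
    test_dissolution: dict[float, tuple[float, float]] | None = None
    kd_r_ph68: float = 0.0  # Reference product dissolution rate at pH 6.8


DRUGS: dict[str, DrugRecord] = {
    "amlodipine": DrugRecord(
        name="amlodipine",
        dose_mg=10.0,
        model="one_compartment",
        cl_f=370.0,
        v1_f=1300.0,
        ka=0.01417,
        test_dissolution={
            1.2: (0.9087, 1.4954),
            4.5: (0.856, 0.5734),
            6.8: (0.898, 0.2886),
        },
        kd_r_ph68=0.2679,
    ),
    "irbesartan": DrugRecord(
        name="irbesartan",
        dose_mg=300.0,
        model="two_compartment_lag",
        cl_f=225.0,
        q_f=295.0,
        v1_f=13800.0,
        v2_f=85800.0,
        tlag=100.8,
        ka=0.00507,
        test_dissolution={
            1.2: (0.899, 0.1726),
            4.5: (0.0234, 0.1295),
            6.8: (0.7076, 0.0811),
        },
        kd_r_ph68=0.0767,
    ),
    "hydrochlorothiazide": DrugRecord(
        name="hydrochlorothiazide",
        dose_mg=12.5,
        model="two_compartment_lag",
        cl_f=575.0,
        q_f=423.33,
        v1_f=137000.0,
        v2_f=146000.0,
        tlag=24.24,
        ka=0.01288,
        test_dissolution={
            1.2: (0.9655, 0.4534),
            4.5: (0.9476, 0.2358),
            6.8: (0.8874, 0.2934),
        },
        kd_r_ph68=0.2776,
    ),
}


def true_absorption_for(name: str) -> TrueAbsorption:
    """Kat decomposition for a built-in drug, recomputed from Ka and Kd."""
    rec = _record(name)
    kd_t = rec.test_dissolution[6.8][1]
    return decompose_true_absorption(rec.ka, kd_t, rec.kd_r_ph68)


def _record(name: str) -> DrugRecord:
    key = name.lower()
    if key not in DRUGS:
        raise KeyError(f"unknown drug {name!r}; built-ins: {sorted(DRUGS)}")
    return DRUGS[key]


def builtin_drug_spec(name: str) -> DrugModelSpec:
    """Assemble the full simulation spec for a built-in drug.

    The Reference product reuses the Test m0 at every pH and the Test Kd at
    pH 1.2 and 4.5; only its pH 6.8 dissolution rate constant was published
    separately.
    """
    rec = _record(name)
    if rec.model == "one_compartment":
        disposition: OneCompartmentParams | TwoCompartmentParams = OneCompartmentParams(
            cl_f=rec.cl_f, v1_f=rec.v1_f, ka=rec.ka
        )
    else:
        disposition = TwoCompartmentParams(
            cl_f=rec.cl_f, q_f=rec.q_f, v1_f=rec.v1_f, v2_f=rec.v2_f,
            ka=rec.ka, tlag=rec.tlag,
        )
    test = {ph: FirstOrderParams(m0, kd) for ph, (m0, kd) in rec.test_dissolution.items()}
    ref = dict(test)
    ref[6.8] = FirstOrderParams(rec.test_dissolution[6.8][0], rec.kd_r_ph68)
    return DrugModelSpec(
        name=rec.name,
        dose_mg=rec.dose_mg,
        disposition=disposition,
        kat=true_absorption_for(rec.name).kat,
        dissolution={"T": test, "R": ref},
    )
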