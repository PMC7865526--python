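"""File formats, run configuration, and the synthetic dissolution generator.

Dissolution CSV schema (UTF-8, comma-separated, header mandatory)::

    product,ph,vessel,time_min,pct_dissolved
    T,6.8,1,0,0.0
    T,6.8,1,5,63.1
    ...

``product`` is T or R, ``ph`` one of 1.2/4.5/6.8, ``vessel`` an integer
(conventionally 1-12).  Twelve vessels per product/pH group are expected;
other counts load with a warning.

Run configuration schema (YAML or JSON)::

    drug: amlodipine            # built-in name, or a full inline drug block
    mode: reduced               # full | reduced | custom
    n_reps: 10000
    seed: 12345
    residual_cv: 5.0
    gastric_state: fasted
    stomach_absorption_scale: 0.0
    colon_absorption_scale: 1.0
    factors:                    # optional overrides of the factor domains
      sample_size: [12, 24]
    extra_scenarios:            # optional appended single scenarios
      - {sample_size: 24, scheme: typical, transit_id: 1, bsv_cv: 20, wsv_cv: 10}

All outputs are plain text: CSV tables and pretty-printed, key-sorted JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dissolution import DissolutionCurve, DissolutionSummary, ModelFit
from .montecarlo import Scenario, ScenarioResult
from .trial import cv_to_sigma

__all__ = [
    "read_dissolution_csv",
    "write_dissolution_csv",
    "generate_synthetic_dissolution",
    "write_fit_report",
    "RunConfig",
    "load_config",
    "provenance_block",
    "write_json",
]

_CSV_COLUMNS = ["product", "ph", "vessel", "time_min", "pct_dissolved"]


def read_dissolution_csv(path: str | Path) -> dict[tuple[str, float], list[DissolutionCurve]]:
    """Load dissolution curves grouped by (product, pH).

    Validates the header, per-vessel time monotonicity and non-negative
    responses; malformed rows raise with the offending vessel named.  Groups
    without 12 vessels load with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_product = set(df["product"].unique()) - {"T", "R"}
    if bad_product:
        raise ValueError(f"{path}: product must be T or R, found {sorted(bad_product)}")

    groups: dict[tuple[str, float], list[DissolutionCurve]] = {}
    for (product, ph, vessel), sub in df.groupby(["product", "ph", "vessel"], sort=True):
        sub = sub.sort_index()
        curve = DissolutionCurve(
            vessel_id=f"{product}-pH{ph}-v{vessel}",
            ph_condition=float(ph),
            times=sub["time_min"].to_numpy(dtype=float),
            percent_dissolved=sub["pct_dissolved"].to_numpy(dtype=float),
        )
        groups.setdefault((str(product), float(ph)), []).append(curve)
    for key, curves in groups.items():
        if len(curves) != 12:
            warnings.warn(
                f"{path}: expected 12 vessels for {key}, found {len(curves)}",
                stacklevel=2,
            )
    return groups


def write_dissolution_csv(
    path: str | Path, groups: dict[tuple[str, float], list[DissolutionCurve]]
) -> None:
    """Inverse of :func:`read_dissolution_csv` (round-trips exactly)."""
    rows = []
    for (product, ph), curves in sorted(groups.items()):
        for curve in curves:
            vessel = curve.vessel_id.rsplit("v", 1)[-1]
            for t, y in zip(curve.times, curve.percent_dissolved):
                rows.append((product, ph, vessel, t, y))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def generate_synthetic_dissolution(
    m0: float,
    kd: float,
    times: Iterable[float] = (0, 5, 10, 15, 20, 30, 45, 60, 90, 120, 180, 240),
    n_vessels: int = 12,
    noise_cv: float = 3.0,
    seed: int | np.random.Generator | None = None,
    product: str = "T",
    ph: float = 6.8,
) -> list[DissolutionCurve]:
    """Synthetic per-vessel profiles from a first-order release model.

    Percent dissolved is ``100*m0*(1 - exp(-kd*t)) * exp(eps)`` with
    multiplicative lognormal noise of the given CV (the t=0 point stays 0).
    Emulates a 12-vessel dissolution run; seed-reproducible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(list(times), dtype=float)
    clean = 100.0 * m0 * (1.0 - np.exp(-kd * t))
    sigma = cv_to_sigma(noise_cv)
    curves = []
    for v in range(1, n_vessels + 1):
        noisy = clean * (np.exp(rng.normal(0.0, sigma, size=t.size)) if sigma else 1.0)
        curves.append(
            DissolutionCurve(
                vessel_id=f"{product}-pH{ph}-v{v}",
                ph_condition=ph,
                times=t,
                percent_dissolved=noisy,
            )
        )
    return curves


def write_fit_report(
    path: str | Path,
    fits: dict[tuple[str, float], list[ModelFit]],
    summaries: dict[tuple[str, float], DissolutionSummary],
) -> None:
    """Per-vessel fits and per-pH summaries as one JSON report."""
    report: dict[str, Any] = {"provenance": provenance_block(), "groups": {}}
    for key in sorted(fits):
        product, ph = key
        group_fits = fits[key]
        summary = summaries[key]
        report["groups"][f"{product}@pH{ph}"] = {
            "model_id": summary.model_id,
            "mean_params": summary.mean_params,
            "rse_percent": summary.rse_percent,
            "n_vessels": summary.n_vessels,
            "vessels": [
                {
                    "vessel_id": f.vessel_id,
                    "params": f.params,
                    "param_se": f.param_se,
                    "ssr": f.ssr,
                    "aic": f.aic,
                    "bic": f.bic,
                }
                for f in group_fits
            ],
        }
    write_json(path, report)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one grid run (schema in module docstring)."""

    drug: str
    mode: str = "reduced"
    n_reps: int = 10_000
    seed: int = 0
    residual_cv: float = 5.0
    gastric_state: str = "fasted"
    stomach_absorption_scale: float = 0.0
    colon_absorption_scale: float = 1.0
    factors: dict[str, tuple] | None = None
    extra_scenarios: tuple[Scenario, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("full", "reduced", "custom"):
            raise ValueError(f"mode must be full|reduced|custom, got {self.mode!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.gastric_state not in ("fasted", "fed"):
            raise ValueError("gastric_state must be fasted|fed")
        for name in ("residual_cv", "stomach_absorption_scale", "colon_absorption_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML/JSON run configuration."""
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "factors" in raw and raw["factors"] is not None:
        raw["factors"] = {k: tuple(v) for k, v in raw["factors"].items()}
    if "extra_scenarios" in raw:
        raw["extra_scenarios"] = tuple(
            Scenario(**sc) for sc in raw["extra_scenarios"] or []
        )
    return RunConfig(**raw)


def provenance_block(config: RunConfig | None = None, seed: int | None = None) -> dict:
    """Reproducibility stamp written into every output file."""
    block: dict[str, Any] = {"package": "ivivsim", "version": __version__}
    if config is not None:
        payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
        block["config_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
        block["seed"] = config.seed
    if seed is not None:
        block["seed"] = seed
    return block


def write_json(path: str | Path, payload: dict) -> None:
    """Pretty-printed, key-sorted JSON for diff-stable outputs."""
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n",
        encoding="utf-8",
    )


def scenario_results_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Tidy per-scenario table of a grid run."""
    rows = []
    for r in results:
        sc = dataclasses.asdict(r.scenario)
        sc.update(
            n_reps=r.n_reps,
            n_success=r.n_success,
            acceptance_pct=r.acceptance_pct,
            binomial_se_pct=r.binomial_se_pct,
        )
        rows.append(sc)
    return pd.DataFrame(rows)
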