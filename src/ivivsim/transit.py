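"""Gastrointestinal transit scenarios and segment-condition mapping.

Transit through the gut is modelled deterministically: the dose sits in the
stomach, then the small intestine, then the large intestine for the
scenario's mean residence times, and the dissolution parameters in force
switch with the segment.  Fasted stomach conditions correspond to the pH 1.2
dissolution medium, fed stomach to pH 4.5, and the small intestine to pH
6.8; the large intestine reuses the pH 6.8 parameters (the nearest
physiological medium among the three tested).  Absorption is off in the
stomach by default and on downstream.

Five built-in scenarios span fast to slow gastric emptying, each summing to
a total transit time of 2160 min (36 h).
"""

from __future__ import annotations

from dataclasses import dataclass

from .dissolution import FirstOrderParams

__all__ = [
    "TransitScenario",
    "SegmentConditions",
    "builtin_transit_scenarios",
    "get_transit_scenario",
    "segment_at",
    "conditions_for",
    "STOMACH",
    "SMALL_INTESTINE",
    "LARGE_INTESTINE",
    "TOTAL_TRANSIT_MIN",
]

STOMACH = "stomach"
SMALL_INTESTINE = "small_intestine"
LARGE_INTESTINE = "large_intestine"

TOTAL_TRANSIT_MIN = 2160.0

#: (stomach, small intestine, large intestine) mean residence times, minutes.
_BUILTIN = {
    1: (10.0, 180.0, 1970.0),
    2: (20.0, 200.0, 1940.0),
    3: (30.0, 215.0, 1915.0),
    4: (45.0, 240.0, 1875.0),
    5: (60.0, 265.0, 1835.0),
}


@dataclass(frozen=True)
class TransitScenario:
    """Mean residence times (min) per GI segment; must sum to ``total_min``."""

    scenario_id: int | str
    stomach_min: float
    small_intestine_min: float
    large_intestine_min: float
    total_min: float = TOTAL_TRANSIT_MIN

    def __post_init__(self) -> None:
        for name in ("stomach_min", "small_intestine_min", "large_intestine_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        total = self.stomach_min + self.small_intestine_min + self.large_intestine_min
        if abs(total - self.total_min) > 1e-9:
            raise ValueError(
                f"residence times sum to {total}, expected total_min={self.total_min}"
            )

    @property
    def small_intestine_end(self) -> float:
        return self.stomach_min + self.small_intestine_min


@dataclass(frozen=True)
class SegmentConditions:
    """Dissolution parameters and absorption availability in one GI segment."""

    segment: str
    gastric_state: str
    dissolution_params: FirstOrderParams
    absorption_allowed: bool
    absorption_scale: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.absorption_scale <= 1.0:
            raise ValueError("absorption_scale must be in [0, 1]")


def builtin_transit_scenarios() -> list[TransitScenario]:
    """The five built-in transit scenarios, fast to slow gastric emptying."""
    return [get_transit_scenario(i) for i in sorted(_BUILTIN)]


def get_transit_scenario(scenario_id: int) -> TransitScenario:
    if scenario_id not in _BUILTIN:
        raise KeyError(f"no built-in transit scenario {scenario_id!r}; use 1-5")
    st, si, li = _BUILTIN[scenario_id]
    return TransitScenario(scenario_id, st, si, li)


def segment_at(t: float, scenario: TransitScenario) -> str:
    """GI segment occupied at time ``t`` (min) after ingestion.

    Boundaries are half-open: stomach on ``[0, stomach_min)``, small
    intestine on ``[stomach_min, stomach_min + small_intestine_min)``, large
    intestine thereafter.  Beyond ``total_min`` the label stays
    ``large_intestine`` (dissolution is halted there by the simulation layer).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if t < scenario.stomach_min:
        return STOMACH
    if t < scenario.small_intestine_end:
        return SMALL_INTESTINE
    return LARGE_INTESTINE


# segment + gastric state -> dissolution buffer pH
_PH_MAP = {
    (STOMACH, "fasted"): 1.2,
    (STOMACH, "fed"): 4.5,
    (SMALL_INTESTINE, "fasted"): 6.8,
    (SMALL_INTESTINE, "fed"): 6.8,
    (LARGE_INTESTINE, "fasted"): 6.8,
    (LARGE_INTESTINE, "fed"): 6.8,
}


def conditions_for(
    segment: str,
    gastric_state: str,
    dissolution_by_ph: dict[float, FirstOrderParams],
    stomach_absorption_scale: float = 0.0,
    colon_absorption_scale: float = 1.0,
) -> SegmentConditions:
    """Dissolution parameters and absorption scale for one segment.

    ``dissolution_by_ph`` maps buffer pH (1.2/4.5/6.8) to that product's
    first-order parameters.  Stomach absorption defaults to none (gastric
    absorption is negligible for most drugs); colonic absorption defaults to
    fully available but is configurable.
    """
    if gastric_state not in ("fasted", "fed"):
        raise ValueError(f"gastric_state must be 'fasted' or 'fed', got {gastric_state!r}")
    key = (segment, gastric_state)
    if key not in _PH_MAP:
        raise ValueError(f"unknown segment {segment!r}")
    ph = _PH_MAP[key]
    if ph not in dissolution_by_ph:
        raise KeyError(
            f"no dissolution parameters for pH {ph} (needed for {segment}, {gastric_state})"
        )
    scale = {
        STOMACH: stomach_absorption_scale,
        SMALL_INTESTINE: 1.0,
        LARGE_INTESTINE: colon_absorption_scale,
    }[segment]
    return SegmentConditions(
        segment=segment,
        gastric_state=gastric_state,
        dissolution_params=dissolution_by_ph[ph],
        absorption_allowed=scale > 0.0,
        absorption_scale=scale,
    )
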