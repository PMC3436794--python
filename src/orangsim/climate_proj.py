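"""Climate-anomaly projection.

Scenario climate is expressed as anomaly ("delta") rasters at a few epochs
relative to a baseline climatology: additive degC for temperature and
multiplicative per cent for seasonal precipitation. Between epochs the
deltas are interpolated linearly in time; beyond the last epoch there is no
extrapolation. A novelty mask flags cells pushed outside the observed
climate range, where a fitted distribution model is extrapolating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ClimateStack:
    """Aligned climate layers for one point in time."""

    temperature: np.ndarray      # mean annual temperature, degC
    wet_precip: np.ndarray       # wet-season (Oct-Mar) precipitation, mm/month
    dry_precip: np.ndarray       # dry-season (Apr-Sep) precipitation, mm/month
    year: float

    def validate(self) -> None:
        if self.temperature.shape != self.wet_precip.shape or \
           self.temperature.shape != self.dry_precip.shape:
            raise ValueError("climate layers are not aligned")
        if np.any(self.wet_precip < 0) or np.any(self.dry_precip < 0):
            raise ValueError("precipitation must be non-negative")


@dataclass
class AnomalySchedule:
    """Per-epoch anomaly rasters for one emissions scenario.

    ``temp_delta`` is additive degC; ``wet_delta``/``dry_delta`` are
    multiplicative per cent (100 = unchanged). The first epoch is the
    baseline year and must carry no change.
    """

    scenario: str
    epochs: list[int]
    temp_delta: dict[int, np.ndarray]
    wet_delta: dict[int, np.ndarray]
    dry_delta: dict[int, np.ndarray]

    def validate(self) -> None:
        if list(self.epochs) != sorted(set(self.epochs)):
            raise ValueError("epochs must be strictly increasing")
        e0 = self.epochs[0]
        if np.any(self.temp_delta[e0] != 0.0):
            raise ValueError("first-epoch temperature delta must be zero")
        if np.any(self.wet_delta[e0] != 100.0) or np.any(self.dry_delta[e0] != 100.0):
            raise ValueError("first-epoch precipitation delta must be 100%")
        for d in (self.temp_delta, self.wet_delta, self.dry_delta):
            missing = [e for e in self.epochs if e not in d]
            if missing:
                raise ValueError(f"missing delta rasters for epochs {missing}")


def _interp_delta(deltas: dict[int, np.ndarray], epochs: list[int],
                  year: float) -> np.ndarray:
    """Piecewise-linear interpolation of delta rasters in time."""
    if year <= epochs[0]:
        return deltas[epochs[0]]
    for lo, hi in zip(epochs[:-1], epochs[1:]):
        if lo <= year <= hi:
            w = (year - lo) / (hi - lo)
            return (1.0 - w) * deltas[lo] + w * deltas[hi]
    raise AssertionError("unreachable")  # range-checked by caller


def climate_at(baseline: ClimateStack, schedule: AnomalySchedule,
               year: float) -> ClimateStack:
    """Project baseline climate to ``year`` under the anomaly schedule.

    Temperature deltas add; precipitation deltas scale (per cent / 100).
    Exact at epoch years; linear in between. Years outside
    [baseline year, last epoch] raise rather than extrapolate.
    """
    schedule.validate()
    last = schedule.epochs[-1]
    if year < baseline.year or year > last:
        raise ValueError(
            f"year {year} outside projectable range [{baseline.year}, {last}]")
    dt = _interp_delta(schedule.temp_delta, schedule.epochs, year)
    dw = _interp_delta(schedule.wet_delta, schedule.epochs, year)
    dd = _interp_delta(schedule.dry_delta, schedule.epochs, year)
    out = ClimateStack(
        temperature=baseline.temperature + dt,
        wet_precip=np.clip(baseline.wet_precip * dw / 100.0, 0.0, None),
        dry_precip=np.clip(baseline.dry_precip * dd / 100.0, 0.0, None),
        year=year,
    )
    out.validate()
    return out


def observed_climate_range(baseline: ClimateStack) -> dict[str, tuple[float, float]]:
    """Per-variable [min, max] over the baseline climatology grid."""
    return {
        "temperature": (float(baseline.temperature.min()),
                        float(baseline.temperature.max())),
        "wet_precip": (float(baseline.wet_precip.min()),
                       float(baseline.wet_precip.max())),
        "dry_precip": (float(baseline.dry_precip.min()),
                       float(baseline.dry_precip.max())),
    }


def flag_novel_climate(projected: ClimateStack,
                       observed_range: dict[str, tuple[float, float]],
                       ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Flag cells whose projected climate leaves the observed range.

    Returns ``(mask, exceedance)``: mask is true where any variable is
    outside its observed [min, max]; exceedance maps each variable to a
    signed per-cell magnitude (positive above the maximum, negative below
    the minimum, zero inside the range).
    """
    layers = {"temperature": projected.temperature,
              "wet_precip": projected.wet_precip,
              "dry_precip": projected.dry_precip}
    mask = np.zeros(projected.temperature.shape, dtype=bool)
    exceedance: dict[str, np.ndarray] = {}
    for name, arr in layers.items():
        lo, hi = observed_range[name]
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError(f"observed range for {name!r} must be finite")
        exc = np.where(arr > hi, arr - hi, np.where(arr < lo, arr - lo, 0.0))
        exceedance[name] = exc
        mask |= exc != 0.0
    return mask, exceedance
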