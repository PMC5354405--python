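"""CEM43 thermal dose accumulation and lethal-dose-area metrics.

Thermal damage is summarized as cumulative equivalent minutes at 43 degC:
each sampling interval of length dt minutes at temperature T contributes
``dt * R**(43 - T)``, with R = 0.5 at or above the 43 degC breakpoint and
R = 0.25 below it (the standard isoeffect-rate values). A dose above
240 CEM43 is taken as lethal to tissue; the area of the map strictly above
that threshold, in mm^2, is the confinement metric compared against the
sonication layer's target area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .thermometry import ThermometrySeries

__all__ = ["DoseModel", "DoseMap", "cem43", "accumulate_cem43", "lethal_area"]


@dataclass(frozen=True)
class DoseModel:
    """CEM43 model constants (Sapareto-Dewey isoeffect rates)."""

    reference_temp: float = 43.0
    r_below: float = 0.25
    r_at_or_above: float = 0.5
    lethal_threshold_min: float = 240.0

    def __post_init__(self) -> None:
        if not (0 < self.r_below < 1 and 0 < self.r_at_or_above < 1):
            raise InvalidInputError("R values must lie in (0, 1)")


@dataclass
class DoseMap:
    """Per-pixel CEM43 (minutes) with pixel-area metadata."""

    cem43_min: np.ndarray
    pixel_area_mm2: float

    def __add__(self, other: "DoseMap") -> "DoseMap":
        if self.cem43_min.shape != other.cem43_min.shape:
            raise InvalidInputError("dose maps have mismatched shapes")
        return DoseMap(self.cem43_min + other.cem43_min, self.pixel_area_mm2)


def cem43(
    temps: np.ndarray, dt_minutes: float, model: DoseModel = DoseModel()
) -> np.ndarray:
    """Accumulate CEM43 over the leading (time) axis of ``temps``.

    Temperature is treated as piecewise constant over each ``dt_minutes``
    sampling interval, matching discrete MR thermometry sampling.
    """
    if dt_minutes <= 0:
        raise InvalidInputError("dt_minutes must be > 0")
    t = np.asarray(temps, dtype=float)
    r = np.where(t >= model.reference_temp, model.r_at_or_above, model.r_below)
    return (dt_minutes * r ** (model.reference_temp - t)).sum(axis=0)


def accumulate_cem43(
    series: ThermometrySeries,
    model: DoseModel = DoseModel(),
    slice_name: str = "coronal_+0mm",
) -> DoseMap:
    """CEM43 dose map for one thermometry slice.

    Requires uniformly spaced dynamics (enforced by the series container);
    the dose is additive over concatenated series.
    """
    if slice_name not in series.slices:
        raise InvalidInputError(
            f"unknown slice {slice_name!r}; have {sorted(series.slices)}"
        )
    dt = np.diff(series.times)
    if len(dt) == 0:
        raise InvalidInputError("need >= 2 dynamics to accumulate dose")
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise InvalidInputError("dynamics are not uniformly spaced")
    dt_min = float(dt[0]) / 60.0
    return DoseMap(
        cem43_min=cem43(series.slices[slice_name], dt_min, model),
        pixel_area_mm2=series.geometry.pixel_area_mm2,
    )


def lethal_area(dose: DoseMap, threshold_min: float = 240.0) -> float:
    """Area (mm^2) of pixels with dose strictly above ``threshold_min``."""
    if threshold_min <= 0:
        raise InvalidInputError("threshold must be > 0")
    return float((dose.cem43_min > threshold_min).sum()) * dose.pixel_area_mm2
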