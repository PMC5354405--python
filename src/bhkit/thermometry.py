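"""PRFS temperature reconstruction and temperature metrics.

The water proton resonance frequency falls by about 0.01 ppm per degC, so at
echo time TE a temperature rise dT shifts the image phase by
``2 pi gamma B0 alpha dT TE`` (alpha negative). Inverting this on the phase
difference against a pre-heating reference dynamic yields per-pixel
temperature maps. Phase is unwrapped temporally (dynamic-to-dynamic), which is
sufficient for compact focal heating where each 1.8 s step changes the phase
by well under pi; no spatial unwrapping is attempted.

Metrics mirror a standard MR-HIFU monitoring workflow: the maximum
temperature inside a rectangular ROI over time, and the spatial full width at
half maximum (FWHM) of the final temperature-elevation map, reported as the
equivalent-circle diameter of the super-half-maximum region.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, UndefinedFWHMError
from .synthetic import ComplexDynamics, ThermometryGeometry

__all__ = [
    "ThermometrySeries",
    "RoiSpec",
    "phase_to_temperature",
    "roi_max_series",
    "temperature_fwhm",
]


@dataclass
class ThermometrySeries:
    """Per-slice temperature maps over MR dynamics.

    ``slices`` maps slice name -> (nt, n_row, n_col) degC; ``coords`` the
    in-plane pixel-center coordinates (row_mm, col_mm) per slice.
    """

    slices: dict[str, np.ndarray]
    coords: dict[str, tuple[np.ndarray, np.ndarray]]
    geometry: ThermometryGeometry
    times: np.ndarray
    baseline_temp: float

    def __post_init__(self) -> None:
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
            raise InvalidInputError("dynamic times must be uniformly spaced")


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular in-plane region of interest, default 40 x 30 mm.

    ``extent_mm`` is (row, col) full extent; ``center_mm`` its center in the
    slice's in-plane coordinates (the targeted region sits at the origin).
    """

    extent_mm: tuple[float, float] = (30.0, 40.0)
    center_mm: tuple[float, float] = (0.0, 0.0)

    def mask(self, row_mm: np.ndarray, col_mm: np.ndarray) -> np.ndarray:
        er, ec = self.extent_mm
        cr, cc = self.center_mm
        rows = np.abs(row_mm - cr) <= er / 2.0
        cols = np.abs(col_mm - cc) <= ec / 2.0
        return rows[:, None] & cols[None, :]


def phase_to_temperature(
    dynamics: ComplexDynamics, baseline_temp: float | None = None
) -> ThermometrySeries:
    """Reconstruct temperature maps from complex PRFS dynamics.

    The first dynamic is the reference; per-pixel phase differences are
    unwrapped along time and divided by the PRFS phase-per-degC factor.
    Requires at least two dynamics. A warning is issued if any
    dynamic-to-dynamic phase step approaches pi (ambiguous unwrapping).
    """
    geom = dynamics.geometry
    if baseline_temp is None:
        baseline_temp = dynamics.baseline_temp
    out = {}
    for name, img in dynamics.slices.items():
        if img.shape[0] < 2:
            raise InvalidInputError("need >= 2 dynamics (first is the reference)")
        dphi = np.angle(img * np.conj(img[0]))
        steps = np.diff(dphi, axis=0)
        if np.abs(steps).max(initial=0.0) > 0.9 * math.pi:
            warnings.warn(
                f"phase step near pi in slice {name}: temporal unwrapping "
                "may be ambiguous",
                stacklevel=2,
            )
        dphi = np.unwrap(dphi, axis=0)
        out[name] = baseline_temp + dphi / geom.phase_per_degc
    return ThermometrySeries(
        slices=out,
        coords={k: (r.copy(), c.copy()) for k, (r, c) in dynamics.coords.items()},
        geometry=geom,
        times=dynamics.times.copy(),
        baseline_temp=baseline_temp,
    )


def roi_max_series(
    series: ThermometrySeries, roi: RoiSpec, slice_name: str = "coronal_+0mm"
) -> np.ndarray:
    """Maximum temperature inside the ROI at each dynamic (degC)."""
    if slice_name not in series.slices:
        raise InvalidInputError(
            f"unknown slice {slice_name!r}; have {sorted(series.slices)}"
        )
    row, col = series.coords[slice_name]
    mask = roi.mask(row, col)
    if not mask.any():
        raise InvalidInputError("ROI contains no pixels on this slice")
    temps = series.slices[slice_name]
    return temps[:, mask].max(axis=1)


def temperature_fwhm(
    temp_map: np.ndarray,
    baseline: float,
    pixel_mm: float | tuple[float, float],
    method: str = "area",
) -> float:
    """Spatial FWHM (mm) of the temperature elevation in a 2D map.

    ``area`` (default): the set of pixels whose elevation above ``baseline``
    is at least half the peak elevation is measured, and the diameter of the
    circle with that area, 2 sqrt(A / pi), is returned. Disjoint hot spots
    pool their area. Rotation-invariant, and equal to the 1D profile FWHM for
    an isotropic peak.

    ``profile``: FWHM of the 1D profiles through the hottest pixel along rows
    and columns, linearly interpolated at the half-maximum crossing, averaged
    over the two axes.
    """
    elev = np.asarray(temp_map, dtype=float) - baseline
    peak = elev.max()
    if peak <= 0:
        raise UndefinedFWHMError("no temperature elevation above baseline")
    if np.isscalar(pixel_mm):
        pr = pc = float(pixel_mm)
    else:
        pr, pc = pixel_mm
    if method == "area":
        area = float((elev >= peak / 2.0).sum()) * pr * pc
        return 2.0 * math.sqrt(area / math.pi)
    if method == "profile":
        ir, ic = np.unravel_index(np.argmax(elev), elev.shape)
        return 0.5 * (
            _profile_fwhm(elev[ir, :], pc) + _profile_fwhm(elev[:, ic], pr)
        )
    raise InvalidInputError(f"unknown FWHM method {method!r}")


def _profile_fwhm(profile: np.ndarray, pixel: float) -> float:
    """Interpolated width of a 1D profile at half its maximum."""
    half = profile.max() / 2.0
    above = np.where(profile >= half)[0]
    lo, hi = above[0], above[-1]
    left = float(lo)
    if lo > 0:
        left = lo - (profile[lo] - half) / (profile[lo] - profile[lo - 1])
    right = float(hi)
    if hi < len(profile) - 1:
        right = hi + (profile[hi] - half) / (profile[hi] - profile[hi + 1])
    return (right - left) * pixel
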