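"""Closed-form boiling-histotripsy physics.

Weak-shock theory predicts that once a millisecond HIFU pulse develops a shock
front of amplitude :math:`A_s` at the focus, absorption at the shock heats the
medium at a rate

.. math:: H = \\frac{\\beta f_0 A_s^3}{6 \\rho_0^2 c_0^4}

(W/m^3), where :math:`\\beta` is the acoustic nonlinearity coefficient,
:math:`f_0` the driving frequency, :math:`\\rho_0` the density and :math:`c_0`
the sound speed. Neglecting conduction over the few milliseconds involved, the
focal volume reaches 100 °C after

.. math:: t_b = \\frac{\\Delta T\\, c_v}{H}

seconds, with :math:`\\Delta T` the gap between boiling and local temperature
and :math:`c_v` the volumetric heat capacity. Boiling within a single pulse is
the defining event of boiling histotripsy: the vapor cavity, not thermal
necrosis, does the mechanical work.

This module also carries the pulse-timing arithmetic (pulse length, duty
cycle), attenuation derating, the 3x3x3 sonication-pattern geometry, and the
per-layer target-area quantity used to judge thermal-dose confinement.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, NoBoilError
from .units import MPA_TO_PA, db_to_amplitude_ratio

__all__ = [
    "AcousticPulse",
    "Medium",
    "PressureMeasurement",
    "SonicationPattern",
    "heating_rate",
    "time_to_boil",
    "derate_pressure",
    "pulse_timing",
    "layer_target_area",
    "schedule",
    "load_pressure_table",
    "pressure_measurements",
    "PHANTOM_MEDIUM",
]


@dataclass(frozen=True)
class AcousticPulse:
    """One sonication's electrical/acoustic settings.

    Parameters
    ----------
    acoustic_power : float
        Transducer acoustic output power in watts.
    frequency : float
        Driving frequency f0 in Hz.
    cycles_per_pulse : float
        Number of acoustic cycles per pulse.
    prf : float
        Pulse repetition frequency in Hz.
    """

    acoustic_power: float
    frequency: float
    cycles_per_pulse: float
    prf: float

    def __post_init__(self) -> None:
        for name in ("acoustic_power", "frequency", "cycles_per_pulse", "prf"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.duty_cycle >= 1.0:
            raise InvalidInputError(
                f"duty cycle {self.duty_cycle:.3f} >= 1: pulses overlap"
            )

    @property
    def pulse_length(self) -> float:
        """Pulse length in seconds (= cycles / f0)."""
        return self.cycles_per_pulse / self.frequency

    @property
    def duty_cycle(self) -> float:
        """On-fraction of the pulsing scheme (= pulse length x PRF)."""
        return self.pulse_length * self.prf


@dataclass(frozen=True)
class Medium:
    """Acoustic and thermal constants of the sonicated medium.

    Defaults are not provided deliberately; see ``PHANTOM_MEDIUM`` for the
    polyacrylamide tissue-mimicking-phantom values.
    """

    beta: float  # acoustic nonlinearity coefficient (dimensionless)
    rho0: float  # density, kg/m^3
    c0: float  # sound speed, m/s
    cv: float  # volumetric heat capacity, J/(m^3 degC)
    attenuation: float = 0.0  # dB/(cm MHz)
    thermal_diffusivity: float = 1.35e-7  # m^2/s, water-like
    boiling_temp: float = 100.0  # degC
    baseline_temp: float = 37.5  # degC

    def __post_init__(self) -> None:
        for name in ("beta", "rho0", "c0", "cv"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.attenuation < 0 or self.thermal_diffusivity < 0:
            raise InvalidInputError("attenuation and diffusivity must be >= 0")
        if self.boiling_temp <= self.baseline_temp:
            raise InvalidInputError("boiling_temp must exceed baseline_temp")

    @property
    def delta_t_boil(self) -> float:
        """Temperature rise needed to boil from baseline, degC."""
        return self.boiling_temp - self.baseline_temp


#: Polyacrylamide tissue-mimicking phantom at a 37.5 degC thermometry baseline.
PHANTOM_MEDIUM = Medium(beta=4.0, rho0=1020.0, c0=1544.0, cv=5.3e6, attenuation=0.676)


@dataclass(frozen=True)
class PressureMeasurement:
    """Hydrophone focal-pressure measurement at one acoustic power.

    ``shock_amplitude`` follows the peak-to-peak convention: the pressure jump
    across a fully developed shock front spans from the rarefaction trough to
    the compression peak, so A_s = p+ + |p-| (free-field, Pa).
    """

    acoustic_power: float
    peak_positive: float  # MPa, mean
    peak_negative_magnitude: float  # MPa, mean |p-|
    peak_positive_sd: float = 0.0
    peak_negative_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.peak_positive > self.peak_negative_magnitude > 0:
            raise InvalidInputError(
                "expected peak_positive > peak_negative_magnitude > 0, got "
                f"{self.peak_positive} / {self.peak_negative_magnitude} MPa"
            )

    @property
    def shock_amplitude(self) -> float:
        """Peak-to-peak shock amplitude A_s in Pa."""
        return (self.peak_positive + self.peak_negative_magnitude) * MPA_TO_PA


@dataclass(frozen=True)
class SonicationPattern:
    """Regular grid of focal locations, beam axis along z.

    The characterization experiments use a 3x3x3 cube with 1 mm spacing;
    traversal is layer-by-layer starting at the transducer-proximal layer
    (lowest z), row-major within each layer.
    """

    grid_shape: tuple[int, int, int] = (3, 3, 3)
    spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.grid_shape):
            raise InvalidInputError("grid_shape entries must be >= 1")
        if self.spacing_mm <= 0:
            raise InvalidInputError("spacing must be > 0")

    @property
    def n_foci(self) -> int:
        nx, ny, nz = self.grid_shape
        return nx * ny * nz

    def focus_coordinates(self) -> np.ndarray:
        """Ordered (n, 3) array of focus coordinates in mm, centered on 0.

        Ordering: z (beam axis) slowest from most negative (proximal) to most
        positive, then y, then x — i.e. proximal layer first, row-major.
        """
        nx, ny, nz = self.grid_shape
        ax = [(np.arange(n) - (n - 1) / 2) * self.spacing_mm for n in (nx, ny, nz)]
        zz, yy, xx = np.meshgrid(ax[2], ax[1], ax[0], indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def layer_extent_mm(self) -> tuple[float, float]:
        """In-plane (x, y) extent of one layer: (n-1) x spacing per axis."""
        nx, ny, _ = self.grid_shape
        return ((nx - 1) * self.spacing_mm, (ny - 1) * self.spacing_mm)


def heating_rate(shock_amplitude: float, medium: Medium, frequency: float) -> float:
    """Weak-shock heating rate H in W/m^3.

    H = beta * f0 * A_s^3 / (6 * rho0^2 * c0^4); zero amplitude yields zero.
    """
    if shock_amplitude < 0:
        raise InvalidInputError("shock amplitude must be >= 0")
    if frequency <= 0:
        raise InvalidInputError("frequency must be > 0")
    a = np.asarray(shock_amplitude, dtype=float)
    h = medium.beta * frequency * a**3 / (6.0 * medium.rho0**2 * medium.c0**4)
    return float(h) if np.isscalar(shock_amplitude) or a.ndim == 0 else h


def heating_rate_field(shock_amplitude: np.ndarray, medium: Medium, frequency: float) -> np.ndarray:
    """Vectorized weak-shock heating rate for an amplitude field (Pa)."""
    a = np.asarray(shock_amplitude, dtype=float)
    if (a < 0).any():
        raise InvalidInputError("shock amplitude must be >= 0")
    return medium.beta * frequency * a**3 / (6.0 * medium.rho0**2 * medium.c0**4)


def time_to_boil(heating_rate_w_m3: float, medium: Medium) -> float:
    """Time in seconds for the focus to reach boiling under constant heating.

    t_b = (boiling - baseline) * cv / H. Conduction is neglected, valid when
    t_b is on the millisecond scale. Raises :class:`NoBoilError` for H <= 0.
    """
    if heating_rate_w_m3 <= 0:
        raise NoBoilError("heating rate <= 0: the focus never boils")
    return medium.delta_t_boil * medium.cv / heating_rate_w_m3


def derate_pressure(
    free_field: float, attenuation: float, frequency: float, depth_cm: float
) -> float:
    """Scale a free-field pressure to in-situ using linear-in-f attenuation.

    p_insitu = p * 10^(-attenuation[dB/cm/MHz] * f[MHz] * depth[cm] / 20).
    """
    if attenuation < 0 or frequency < 0 or depth_cm < 0 or free_field < 0:
        raise InvalidInputError("derate_pressure arguments must be >= 0")
    return free_field * db_to_amplitude_ratio(attenuation * frequency * 1e-6 * depth_cm)


def pulse_timing(pulse: AcousticPulse) -> tuple[float, float]:
    """Return (pulse length in ms, duty cycle in percent)."""
    return pulse.pulse_length * 1e3, pulse.duty_cycle * 100.0


def layer_target_area(pattern: SonicationPattern, focal_width_mm: float) -> float:
    """Target area (mm^2) of one in-plane sonication layer.

    The grid footprint of a layer, dilated by the -6 dB focal half-width on
    each side: (extent_x + w)(extent_y + w). For the 3x3 layer at 1 mm spacing
    with a 1.6 mm focal width this is (2 + 1.6)^2 ~= 13 mm^2, the confinement
    target against which the lethal thermal-dose area is judged.
    """
    if focal_width_mm <= 0:
        raise InvalidInputError("focal width must be > 0")
    ex, ey = pattern.layer_extent_mm()
    return (ex + focal_width_mm) * (ey + focal_width_mm)


def schedule(
    pattern: SonicationPattern,
    pulse: AcousticPulse,
    repeats: int,
    pulses_per_location: int = 1,
    overhead_per_location_s: float = 0.0,
) -> pd.DataFrame:
    """Pulse-by-pulse sonication schedule.

    One row per pulse with columns ``time_s`` and ``focus_index``. The pattern
    is traversed in :meth:`SonicationPattern.focus_coordinates` order, firing
    ``pulses_per_location`` pulses at 1/PRF spacing before advancing, and the
    whole cube is repeated ``repeats`` times. ``overhead_per_location_s``
    models per-location system overhead (printed total times slightly exceed
    the nominal n_foci * repeats / PRF).
    """
    if repeats < 1:
        raise InvalidInputError("repeats must be >= 1")
    if pulses_per_location < 1:
        raise InvalidInputError("pulses_per_location must be >= 1")
    if pattern.n_foci == 0:
        raise InvalidInputError("empty sonication pattern")
    period = 1.0 / pulse.prf
    rows = []
    t = 0.0
    for _ in range(repeats):
        for idx in range(pattern.n_foci):
            for _ in range(pulses_per_location):
                rows.append((t, idx))
                t += period
            t += overhead_per_location_s
    return pd.DataFrame(rows, columns=["time_s", "focus_index"])


def load_pressure_table(path=None) -> pd.DataFrame:
    """Load a hydrophone pressure table (columns power_W, p_pos_MPa, p_pos_sd,
    p_neg_MPa, p_neg_sd). Without ``path``, the packaged characterization
    table covering 500-650 W is returned."""
    if path is None:
        ref = importlib.resources.files("bhkit.data") / "pressure_table.csv"
        with importlib.resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def pressure_measurements(table: pd.DataFrame | None = None) -> list[PressureMeasurement]:
    """Convert a pressure table into :class:`PressureMeasurement` objects."""
    if table is None:
        table = load_pressure_table()
    return [
        PressureMeasurement(
            acoustic_power=row.power_W,
            peak_positive=row.p_pos_MPa,
            peak_negative_magnitude=row.p_neg_MPa,
            peak_positive_sd=row.p_pos_sd,
            peak_negative_sd=row.p_neg_sd,
        )
        for row in table.itertuples()
    ]
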