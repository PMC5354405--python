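"""Synthetic data generation: pulsed-BH heating fields, PRFS-encoded MR
dynamics, and speckled tadpole lesion phantoms.

The heating simulator is a deliberately simple two-timescale model. Within a
millisecond pulse, conduction is negligible and each voxel's temperature jumps
by H(A_s(r)) * tau / c_v, where the shock amplitude A_s(r) follows a Gaussian
ellipsoid around the active focus; voxels whose local time-to-boil is shorter
than the pulse are flagged as fractionated and the temperature is clamped at
the boiling point (vapor formation absorbs the excess — bubble dynamics are
not modelled). Between pulses, heat spreads by explicit finite-difference
diffusion with no perfusion, appropriate for gel phantoms and ex vivo tissue.

The thermometry renderer voxel-averages the fine temperature field into the
scanner's slice geometry and encodes it in the phase of a complex image via
the proton-resonance-frequency-shift (PRFS) relation, with complex Gaussian
noise — the forward model whose inverse lives in :mod:`bhkit.thermometry`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError
from .physics import AcousticPulse, Medium, SonicationPattern, heating_rate_field, schedule

__all__ = [
    "FocalField",
    "GridSpec",
    "SimGrid",
    "ThermometryGeometry",
    "ComplexDynamics",
    "LesionPhantomSpec",
    "LesionPhantom",
    "simulate_sonication",
    "render_thermometry",
    "voxel_average_temperature",
    "make_lesion_volume",
]

#: sigma of a Gaussian whose value falls to 1/2 at distance h is h / sqrt(2 ln 2)
_HALF_TO_SIGMA = 1.0 / math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class FocalField:
    """Gaussian-ellipsoid focal shock-amplitude field.

    ``a_s0`` is the on-axis shock amplitude (Pa); ``sigma_r_mm`` and
    ``sigma_z_mm`` parametrize the lateral and axial fall-off. Use
    :meth:`from_minus6db_widths` to construct from the -6 dB focal dimensions
    (1.6 x 1.6 x 10 mm for the transducer modelled here).
    """

    a_s0: float
    sigma_r_mm: float
    sigma_z_mm: float

    def __post_init__(self) -> None:
        if self.a_s0 < 0 or self.sigma_r_mm <= 0 or self.sigma_z_mm <= 0:
            raise InvalidInputError("FocalField requires a_s0 >= 0 and sigmas > 0")

    @classmethod
    def from_minus6db_widths(
        cls, a_s0: float, width_r_mm: float = 1.6, width_z_mm: float = 10.0
    ) -> "FocalField":
        """Build from full -6 dB widths: amplitude halves at width/2 off-axis."""
        return cls(
            a_s0=a_s0,
            sigma_r_mm=0.5 * width_r_mm * _HALF_TO_SIGMA,
            sigma_z_mm=0.5 * width_z_mm * _HALF_TO_SIGMA,
        )

    def amplitude(self, x_mm, y_mm, z_mm, center_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
        cx, cy, cz = center_mm
        r2 = ((np.asarray(x_mm) - cx) ** 2 + (np.asarray(y_mm) - cy) ** 2) / (
            2.0 * self.sigma_r_mm**2
        )
        z2 = (np.asarray(z_mm) - cz) ** 2 / (2.0 * self.sigma_z_mm**2)
        return self.a_s0 * np.exp(-(r2 + z2))


@dataclass(frozen=True)
class GridSpec:
    """Uniform cubic-voxel simulation grid, centered on the pattern center.

    ``shape`` is (nx, ny, nz) with z the beam axis; ``voxel_mm`` the isotropic
    voxel edge.
    """

    shape: tuple[int, int, int]
    voxel_mm: float

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0 or any(n < 2 for n in self.shape):
            raise InvalidInputError("grid needs voxel_mm > 0 and >= 2 voxels per axis")

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * self.voxel_mm for n in self.shape
        )

    def meshgrid_mm(self):
        ax, ay, az = self.axes_mm()
        return np.meshgrid(ax, ay, az, indexing="ij")


@dataclass
class SimGrid:
    """Simulated temperature time series on a :class:`GridSpec`.

    ``temperature`` has shape (nt, nx, ny, nz) in degC; ``fractionated`` is a
    boolean mask of the same shape, monotone nondecreasing in time.
    """

    grid: GridSpec
    times: np.ndarray
    temperature: np.ndarray
    fractionated: np.ndarray
    baseline_temp: float

    @property
    def voxel_volume_mm3(self) -> float:
        return self.grid.voxel_mm**3

    def fractionated_volume_mm3(self) -> float:
        return float(self.fractionated[-1].sum()) * self.voxel_volume_mm3


def max_stable_step(grid: GridSpec, diffusivity_m2_s: float) -> float:
    """Largest stable explicit-Euler step for 3D diffusion: dx^2 / (6 D)."""
    if diffusivity_m2_s == 0:
        return math.inf
    dx_m = grid.voxel_mm * 1e-3
    return dx_m**2 / (6.0 * diffusivity_m2_s)


def simulate_sonication(
    pattern: SonicationPattern,
    pulse: AcousticPulse,
    medium: Medium,
    focal_field: FocalField,
    grid: GridSpec,
    repeats: int,
    pulses_per_location: int = 1,
    record_dt_s: float = 1.8,
    cooldown_s: float = 0.0,
    dt_substep_s: float | None = None,
    clamp_boiling: bool = True,
    boundary: str = "fixed",
) -> SimGrid:
    """Run the two-timescale pulsed-heating model.

    Pulses are fired per :func:`bhkit.physics.schedule`; each deposits an
    instantaneous temperature jump H(A_s(r)) * tau / c_v (clamped at the
    boiling point unless ``clamp_boiling`` is False), and the field diffuses
    between pulses. Snapshots are recorded every ``record_dt_s`` (the MR
    dynamic scan time) starting at t=0 (the pre-sonication baseline) and
    continuing ``cooldown_s`` past the last pulse.

    ``boundary`` selects the diffusion boundary condition: ``"fixed"``
    (default) holds the box edge at the baseline temperature, emulating the
    large surrounding phantom acting as a heat sink; ``"insulating"`` uses
    zero-flux edges (useful for energy-conservation checks).

    Raises :class:`InvalidInputError` if ``dt_substep_s`` exceeds the maximum
    stable explicit diffusion step (named in the message), or if the grid is
    too coarse to resolve the lateral focal width.
    """
    if boundary not in ("fixed", "insulating"):
        raise InvalidInputError(f"unknown boundary condition {boundary!r}")
    if grid.voxel_mm > focal_field.sigma_r_mm:
        raise InvalidInputError(
            f"voxel {grid.voxel_mm} mm too coarse: must be <= lateral sigma "
            f"{focal_field.sigma_r_mm:.3f} mm to resolve the focus"
        )
    dt_max = max_stable_step(grid, medium.thermal_diffusivity)
    if dt_substep_s is None:
        dt_sub = 0.5 * dt_max
    elif dt_substep_s > dt_max:
        raise InvalidInputError(
            f"diffusion step {dt_substep_s} s unstable; maximum stable step is "
            f"{dt_max:.4g} s for this grid and diffusivity"
        )
    else:
        dt_sub = dt_substep_s

    sched = schedule(pattern, pulse, repeats, pulses_per_location)
    end_time = float(sched.time_s.iloc[-1]) + 1.0 / pulse.prf + cooldown_s
    record_times = np.arange(0.0, end_time + 0.5 * record_dt_s, record_dt_s)

    foci = pattern.focus_coordinates()
    x, y, z = grid.meshgrid_mm()
    tau = pulse.pulse_length
    dx_m = grid.voxel_mm * 1e-3
    diff_coef = medium.thermal_diffusivity / dx_m**2  # 1/s per Laplacian unit

    # event queue: records (priority 0, so t=0 snapshot precedes the t=0 pulse)
    events = sorted(
        [(t, 0, -1) for t in record_times]
        + [(t, 1, int(i)) for t, i in zip(sched.time_s, sched.focus_index)]
    )

    temp = np.full(grid.shape, medium.baseline_temp, dtype=np.float64)
    frac = np.zeros(grid.shape, dtype=bool)
    snapshots, frac_snaps = [], []

    def diffuse(duration: float) -> None:
        if duration <= 0 or medium.thermal_diffusivity == 0:
            return
        n = max(1, math.ceil(duration / dt_sub))
        dt = duration / n
        nonlocal temp
        if boundary == "fixed":
            for _ in range(n):
                temp += diff_coef * dt * ndimage.laplace(
                    temp, mode="constant", cval=medium.baseline_temp
                )
        else:
            for _ in range(n):
                temp += diff_coef * dt * ndimage.laplace(temp, mode="nearest")

    t_now = 0.0
    for t_ev, kind, idx in events:
        diffuse(t_ev - t_now)
        t_now = t_ev
        if kind == 0:
            snapshots.append(temp.astype(np.float32))
            frac_snaps.append(frac.copy())
        else:
            amp = focal_field.amplitude(x, y, z, center_mm=foci[idx])
            jump = heating_rate_field(amp, medium, pulse.frequency) * tau / medium.cv
            temp = temp + jump
            boiled = temp >= medium.boiling_temp
            frac |= boiled
            if clamp_boiling:
                np.minimum(temp, medium.boiling_temp, out=temp)

    return SimGrid(
        grid=grid,
        times=record_times,
        temperature=np.stack(snapshots),
        fractionated=np.stack(frac_snaps),
        baseline_temp=medium.baseline_temp,
    )


GAMMA_MHZ_PER_T = 42.58  # proton gyromagnetic ratio / 2pi


@dataclass(frozen=True)
class ThermometryGeometry:
    """MR thermometry slice geometry and PRFS encoding constants.

    Defaults follow a clinical 1.5 T MR-HIFU protocol: 3 coronal slices
    perpendicular to the beam axis (at the focus and +/-7 mm from it) plus a
    sagittal slice containing the beam axis; 2.5 x 2.5 mm in-plane voxels,
    7 mm slice thickness, 1.8 s dynamic scan time, TE 19 ms. The PRFS
    coefficient alpha = -0.01 ppm/degC converts a temperature rise into a
    phase change phi = -2 pi gamma B0 |alpha| dT TE at echo time TE.
    """

    coronal_offsets_mm: tuple[float, ...] = (0.0, 7.0, -7.0)
    inplane_voxel_mm: float = 2.5
    slice_thickness_mm: float = 7.0
    dynamic_time_s: float = 1.8
    te_s: float = 0.019
    b0_t: float = 1.5
    alpha_ppm_per_c: float = -0.01
    gamma_mhz_per_t: float = GAMMA_MHZ_PER_T

    def __post_init__(self) -> None:
        if self.inplane_voxel_mm <= 0 or self.slice_thickness_mm <= 0:
            raise InvalidInputError("voxel sizes must be > 0")
        if not 0 < self.te_s < self.dynamic_time_s:
            raise InvalidInputError("need 0 < TE < dynamic time")

    @property
    def phase_per_degc(self) -> float:
        """Phase change (rad) per degC of temperature rise; negative."""
        return (
            2.0
            * math.pi
            * self.gamma_mhz_per_t
            * 1e6
            * self.b0_t
            * self.alpha_ppm_per_c
            * 1e-6
            * self.te_s
        )

    def slice_names(self) -> list[str]:
        return [f"coronal_{off:+g}mm" for off in self.coronal_offsets_mm] + ["sagittal"]

    @property
    def pixel_area_mm2(self) -> float:
        return self.inplane_voxel_mm**2


@dataclass
class ComplexDynamics:
    """Complex MR image dynamics per thermometry slice.

    ``slices`` maps slice name -> complex array (nt, n_row, n_col). For
    coronal slices rows are y and columns x; for the sagittal slice rows are
    z and columns x. ``coords`` maps slice name -> (row_mm, col_mm) center
    coordinates of the thermometry pixels.
    """

    slices: dict[str, np.ndarray]
    coords: dict[str, tuple[np.ndarray, np.ndarray]]
    geometry: ThermometryGeometry
    times: np.ndarray
    baseline_temp: float


def _bin_axis(coords_mm: np.ndarray, out_voxel_mm: float):
    """Assign fine-grid coordinates to output pixels centered on 0."""
    n_out = max(1, int(np.floor((coords_mm[-1] - coords_mm[0]) / out_voxel_mm)) + 1)
    centers = (np.arange(n_out) - (n_out - 1) / 2.0) * out_voxel_mm
    idx = np.clip(
        np.round((coords_mm - centers[0]) / out_voxel_mm).astype(int), 0, n_out - 1
    )
    return idx, centers


def _slab_mean(temps: np.ndarray, axis_coords: np.ndarray, axis: int, center: float, thickness: float):
    sel = np.abs(axis_coords - center) <= thickness / 2.0
    if not sel.any():
        raise InvalidInputError(
            f"slice at {center} mm lies outside the simulated grid"
        )
    return temps.take(np.where(sel)[0], axis=axis).mean(axis=axis)


def _inplane_average(plane: np.ndarray, row_coords, col_coords, out_voxel):
    """plane is (nt, nrow_fine, ncol_fine) -> (nt, nrow_out, ncol_out) means."""
    ridx, rcent = _bin_axis(row_coords, out_voxel)
    cidx, ccent = _bin_axis(col_coords, out_voxel)
    nt = plane.shape[0]
    out = np.zeros((nt, rcent.size, ccent.size))
    cnt = np.zeros((rcent.size, ccent.size))
    np.add.at(cnt, (ridx[:, None], cidx[None, :]), 1.0)
    for t in range(nt):
        acc = np.zeros_like(cnt)
        np.add.at(acc, (ridx[:, None], cidx[None, :]), plane[t])
        out[t] = acc / np.maximum(cnt, 1)
    return out, (rcent, ccent)


def voxel_average_temperature(sim: SimGrid, geom: ThermometryGeometry):
    """Average the fine simulation field into thermometry pixels.

    Returns (slices, coords): slice name -> temperature (nt, n_row, n_col)
    and the in-plane pixel-center coordinates. This is the noiseless ground
    truth that PRFS reconstruction should recover exactly.
    """
    ax, ay, az = sim.grid.axes_mm()
    temps = sim.temperature.astype(np.float64)  # (nt, nx, ny, nz)
    slices, coords = {}, {}
    for off in geom.coronal_offsets_mm:
        slab = _slab_mean(temps, az, axis=3, center=off, thickness=geom.slice_thickness_mm)
        # slab is (nt, nx, ny): rows = y, cols = x
        binned, (r, c) = _inplane_average(
            np.swapaxes(slab, 1, 2), ay, ax, geom.inplane_voxel_mm
        )
        name = f"coronal_{off:+g}mm"
        slices[name], coords[name] = binned, (r, c)
    # sagittal: plane containing beam axis, normal = y; rows = z, cols = x
    slab = _slab_mean(temps, ay, axis=2, center=0.0, thickness=geom.slice_thickness_mm)
    binned, (r, c) = _inplane_average(
        np.swapaxes(slab, 1, 2), az, ax, geom.inplane_voxel_mm
    )
    slices["sagittal"], coords["sagittal"] = binned, (r, c)
    return slices, coords


def render_thermometry(
    sim: SimGrid,
    geom: ThermometryGeometry,
    noise_sd_celsius: float = 0.0,
    seed: int | np.random.Generator | None = None,
    baseline_phase: float = 0.3,
) -> ComplexDynamics:
    """Encode a simulated temperature series as complex PRFS dynamics.

    The fine field is voxel-averaged into the slice geometry, then each pixel
    becomes ``exp(i (phi0 + phase_per_degc * dT))`` with unit magnitude.
    ``noise_sd_celsius`` sets the additive complex Gaussian noise so that the
    *reconstructed* temperature difference (which subtracts an equally noisy
    reference dynamic) has approximately that standard deviation; each image's
    per-component phase noise is therefore ``|phase_per_degc| * sd / sqrt(2)``.
    """
    slices, coords = voxel_average_temperature(sim, geom)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phase_sd = abs(geom.phase_per_degc) * noise_sd_celsius / math.sqrt(2.0)
    out = {}
    for name, temp in slices.items():
        phase = baseline_phase + geom.phase_per_degc * (temp - sim.baseline_temp)
        img = np.exp(1j * phase)
        if noise_sd_celsius > 0:
            noise = rng.normal(0.0, phase_sd, img.shape) + 1j * rng.normal(
                0.0, phase_sd, img.shape
            )
            img = img + noise
        out[name] = img
    return ComplexDynamics(
        slices=out,
        coords=coords,
        geometry=geom,
        times=sim.times.copy(),
        baseline_temp=sim.baseline_temp,
    )


@dataclass(frozen=True)
class LesionPhantomSpec:
    """Tadpole-shaped lesion phantom: ellipsoid head plus cone tail.

    The head has semi-axes ``head_semiaxes_mm`` (x, y, z with z the beam
    axis); the tail is a cone of base radius ``tail_radius_mm`` and length
    ``tail_length_mm`` pointing toward the transducer (negative z), its base
    on the head surface. ``contrast`` is the lesion/background mean-intensity
    difference on a unit background of ``background_intensity``. Speckle is
    multiplicative gamma noise with ``speckle_looks`` looks, blurred by a
    small Gaussian point-spread function to emulate an ultrasound B-mode-like
    texture.
    """

    head_semiaxes_mm: tuple[float, float, float] = (5.0, 5.0, 10.0)
    tail_radius_mm: float = 1.5
    tail_length_mm: float = 10.0
    background_intensity: float = 0.25
    contrast: float = 0.75
    speckle_looks: float = 4.0
    psf_sigma_mm: float = 0.4

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.head_semiaxes_mm):
            raise InvalidInputError("head semi-axes must be > 0")
        if self.tail_radius_mm < 0 or self.tail_length_mm < 0:
            raise InvalidInputError("tail dimensions must be >= 0")

    @property
    def lesion_intensity(self) -> float:
        return self.background_intensity + self.contrast

    @property
    def analytic_volume_mm3(self) -> float:
        """Exact head + tail volume: 4/3 pi abc + pi r^2 L / 3."""
        a, b, c = self.head_semiaxes_mm
        head = 4.0 / 3.0 * math.pi * a * b * c
        tail = math.pi * self.tail_radius_mm**2 * self.tail_length_mm / 3.0
        return head + tail


@dataclass
class LesionPhantom:
    """Speckled intensity volume with its exact ground-truth mask."""

    image: np.ndarray
    mask: np.ndarray
    voxel_mm: float
    spec: LesionPhantomSpec
    degenerate_tail: bool = False

    @property
    def mask_volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_mm**3


def make_lesion_volume(
    spec: LesionPhantomSpec,
    voxel_mm: float = 0.5,
    seed: int | np.random.Generator | None = None,
    margin_mm: float = 4.0,
) -> LesionPhantom:
    """Render a tadpole lesion phantom at isotropic ``voxel_mm`` resolution."""
    if voxel_mm <= 0:
        raise InvalidInputError("voxel_mm must be > 0")
    degenerate = False
    if 0 < spec.tail_radius_mm < voxel_mm:
        warnings.warn(
            f"tail radius {spec.tail_radius_mm} mm is below the voxel size "
            f"{voxel_mm} mm; the tail is unresolved",
            stacklevel=2,
        )
        degenerate = True

    a, b, c = spec.head_semiaxes_mm
    lim_x = a + margin_mm
    lim_y = b + margin_mm
    z_lo = -(c + spec.tail_length_mm + margin_mm)
    z_hi = c + margin_mm
    nx = int(round(2 * lim_x / voxel_mm)) + 1
    ny = int(round(2 * lim_y / voxel_mm)) + 1
    nz = int(round((z_hi - z_lo) / voxel_mm)) + 1
    x = (np.arange(nx) - (nx - 1) / 2.0) * voxel_mm
    y = (np.arange(ny) - (ny - 1) / 2.0) * voxel_mm
    z = z_lo + np.arange(nz) * voxel_mm
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    head = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    mask = head
    if spec.tail_radius_mm > 0 and spec.tail_length_mm > 0:
        # cone: apex at z = -(c+L), base radius r at z = -c
        frac = (Z + c + spec.tail_length_mm) / spec.tail_length_mm
        in_z = (frac >= 0.0) & (frac <= 1.0) & (Z <= -c)
        tail = in_z & (
            X**2 + Y**2 <= (spec.tail_radius_mm * np.clip(frac, 0, 1)) ** 2
        )
        mask = head | tail

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.where(mask, spec.lesion_intensity, spec.background_intensity)
    looks = spec.speckle_looks
    speckle = rng.gamma(shape=looks, scale=1.0 / looks, size=mask.shape)
    image = means * speckle
    if spec.psf_sigma_mm > 0:
        image = ndimage.gaussian_filter(image, sigma=spec.psf_sigma_mm / voxel_mm)
    return LesionPhantom(
        image=image.astype(np.float32),
        mask=mask,
        voxel_mm=voxel_mm,
        spec=spec,
        degenerate_tail=degenerate,
    )
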