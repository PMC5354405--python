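"""End-to-end experiment orchestration on synthetic data.

`run_characterization` reproduces the study workflow for each configured
sonication parameter set: simulate pulsed heating on the focal grid, render
and reconstruct PRFS thermometry, extract the ROI maximum-temperature series
and final FWHM, accumulate CEM43 dose and its lethal area, generate and
segment a matching lesion phantom, and finally compare outcomes across
parameter levels. Every run is fully determined by the config plus a seed,
and the config (with its hash) is serialized next to the outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .dose import DoseModel, accumulate_cem43, lethal_area
from .errors import InvalidInputError
from .lesion import segment_lesion
from .physics import (
    AcousticPulse,
    Medium,
    PHANTOM_MEDIUM,
    SonicationPattern,
    derate_pressure,
    heating_rate,
    load_pressure_table,
    time_to_boil,
)
from .synthetic import (
    FocalField,
    GridSpec,
    LesionPhantomSpec,
    ThermometryGeometry,
    make_lesion_volume,
    render_thermometry,
    simulate_sonication,
)
from .thermometry import RoiSpec, phase_to_temperature, roi_max_series, temperature_fwhm

logger = logging.getLogger("bhkit")

FOCAL_SLICE = "coronal_+0mm"


@dataclass(frozen=True)
class RunSpec:
    """One sonication parameter set."""

    name: str
    power_w: float
    cycles_per_pulse: float
    prf_hz: float
    repeats: int = 2
    pulses_per_location: int = 1


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a characterization run.

    The simulation grid defaults are reduced relative to the physical
    experiment (a ~25 mm cube around the focal pattern at 0.6 mm voxels and
    a handful of cube repeats) so that a full sweep runs on a laptop; the
    physics and analysis path are identical at larger sizes.
    """

    runs: list[RunSpec]
    frequency_hz: float = 1.2e6
    medium: Medium = field(default_factory=lambda: PHANTOM_MEDIUM)
    grid_shape: tuple[int, int, int] = (41, 41, 41)
    voxel_mm: float = 0.6
    geometry: ThermometryGeometry = field(default_factory=ThermometryGeometry)
    noise_sd_celsius: float = 0.5
    cooldown_s: float = 10.0
    derate_depth_cm: float = 3.0  # sonication depth; in-situ amplitude for the sim
    lesion_replicates: int = 3
    lesion_growth_margin_mm: float = 3.5
    lesion_voxel_mm: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        runs = [RunSpec(**r) for r in raw.pop("runs")]
        medium = Medium(**raw.pop("medium")) if "medium" in raw else PHANTOM_MEDIUM
        geometry = (
            ThermometryGeometry(**raw.pop("geometry")) if "geometry" in raw else ThermometryGeometry()
        )
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(runs=runs, medium=medium, geometry=geometry, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def shock_amplitude_for_power(power_w: float, table: pd.DataFrame | None = None) -> float:
    """Peak-to-peak free-field shock amplitude (Pa) at a given power.

    Linearly interpolated within the hydrophone table's power range.
    """
    if table is None:
        table = load_pressure_table()
    powers = table.power_W.to_numpy(dtype=float)
    ptp = (table.p_pos_MPa + table.p_neg_MPa).to_numpy(dtype=float) * 1e6
    if not powers.min() <= power_w <= powers.max():
        raise InvalidInputError(
            f"power {power_w} W outside measured range {powers.min()}-{powers.max()} W"
        )
    return float(np.interp(power_w, powers, ptp))


@dataclass
class RunResult:
    spec: RunSpec
    time_to_boil_ms: float
    tmax_series: np.ndarray
    times: np.ndarray
    peak_temp_c: float
    fwhm_mm: dict[str, float]
    lethal_area_mm2: float
    lesion_volumes_mm3: list[float]
    fractionated_volume_mm3: float


def _run_one(config: ExperimentConfig, spec: RunSpec, rng: np.random.Generator) -> RunResult:
    medium = config.medium
    a_s = shock_amplitude_for_power(spec.power_w)
    h = heating_rate(a_s, medium, config.frequency_hz)
    t_b_ms = time_to_boil(h, medium) * 1e3

    pulse = AcousticPulse(
        acoustic_power=spec.power_w,
        frequency=config.frequency_hz,
        cycles_per_pulse=spec.cycles_per_pulse,
        prf=spec.prf_hz,
    )
    pattern = SonicationPattern()
    a_s_insitu = derate_pressure(
        a_s, medium.attenuation, config.frequency_hz, config.derate_depth_cm
    )
    focal = FocalField.from_minus6db_widths(a_s_insitu)
    grid = GridSpec(shape=config.grid_shape, voxel_mm=config.voxel_mm)
    sim = simulate_sonication(
        pattern,
        pulse,
        medium,
        focal,
        grid,
        repeats=spec.repeats,
        pulses_per_location=spec.pulses_per_location,
        record_dt_s=config.geometry.dynamic_time_s,
        cooldown_s=config.cooldown_s,
    )
    dyn = render_thermometry(sim, config.geometry, config.noise_sd_celsius, seed=rng)
    series = phase_to_temperature(dyn)
    tmax = roi_max_series(series, RoiSpec(), FOCAL_SLICE)
    fwhm = {}
    end_idx = int(np.searchsorted(series.times, sim.times.max() - config.cooldown_s))
    end_idx = min(max(end_idx, 1), len(series.times) - 1)
    for name, maps in series.slices.items():
        try:
            fwhm[name] = temperature_fwhm(
                maps[end_idx], series.baseline_temp, config.geometry.inplane_voxel_mm
            )
        except Exception:
            fwhm[name] = float("nan")
    dose_map = accumulate_cem43(series, DoseModel(), FOCAL_SLICE)
    area = lethal_area(dose_map)

    # Lesion phantom sized from the fractionated region: the mechanical lesion
    # envelops the boiled core, so the head semi-axes are the fractionated
    # half-extents plus a growth margin.
    frac = sim.fractionated[-1]
    volumes = []
    if frac.any():
        half_ext = []
        for axis in range(3):
            idx = np.where(frac.any(axis=tuple(i for i in range(3) if i != axis)))[0]
            half_ext.append((idx[-1] - idx[0] + 1) * grid.voxel_mm / 2.0)
        m = config.lesion_growth_margin_mm
        lesion_spec = LesionPhantomSpec(
            head_semiaxes_mm=(half_ext[0] + m, half_ext[1] + m, half_ext[2] + m / 2),
        )
        for _ in range(config.lesion_replicates):
            phantom = make_lesion_volume(lesion_spec, config.lesion_voxel_mm, seed=rng)
            res = segment_lesion(phantom.image, (0.0, 0.0, 0.0), phantom.voxel_mm)
            volumes.append(res.volume_mm3)

    return RunResult(
        spec=spec,
        time_to_boil_ms=t_b_ms,
        tmax_series=tmax,
        times=series.times,
        peak_temp_c=float(tmax.max()),
        fwhm_mm=fwhm,
        lethal_area_mm2=area,
        lesion_volumes_mm3=volumes,
        fractionated_volume_mm3=sim.fractionated_volume_mm3(),
    )


def run_characterization(config: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Execute every configured run; returns (and optionally writes) a summary.

    Failures are isolated per run (logged with traceback); if any run failed,
    a RuntimeError naming them is raised after the loop so that partial
    results are still written.
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg = config.to_dict()
        cfg["config_hash"] = io.config_hash(config.to_dict())
        io.write_json(cfg, out / "config.json")

    rows, failed = [], []
    for spec in config.runs:
        try:
            res = _run_one(config, spec, rng)
        except Exception:
            logger.error("run %s failed:\n%s", spec.name, traceback.format_exc())
            failed.append(spec.name)
            continue
        row = {
            "run": spec.name,
            "power_w": spec.power_w,
            "cycles_per_pulse": spec.cycles_per_pulse,
            "prf_hz": spec.prf_hz,
            "repeats": spec.repeats,
            "time_to_boil_ms": res.time_to_boil_ms,
            "peak_temp_c": res.peak_temp_c,
            "fwhm_mm": res.fwhm_mm.get(FOCAL_SLICE, float("nan")),
            "lethal_area_mm2": res.lethal_area_mm2,
            "fractionated_volume_mm3": res.fractionated_volume_mm3,
            "lesion_volume_mm3_mean": float(np.mean(res.lesion_volumes_mm3))
            if res.lesion_volumes_mm3
            else float("nan"),
            "lesion_volume_mm3_sd": float(np.std(res.lesion_volumes_mm3, ddof=1))
            if len(res.lesion_volumes_mm3) > 1
            else float("nan"),
        }
        rows.append(row)
        if out is not None:
            pd.DataFrame(
                {"time_s": res.times, "t_max_C": res.tmax_series}
            ).to_csv(out / f"{spec.name}_tmax.csv", index=False)
            io.write_json(
                {
                    "fwhm_mm": res.fwhm_mm,
                    "lethal_area_mm2": res.lethal_area_mm2,
                    "time_to_boil_ms": res.time_to_boil_ms,
                    "lesion_volumes_mm3": res.lesion_volumes_mm3,
                },
                out / f"{spec.name}_metrics.json",
            )
    summary = pd.DataFrame(rows)
    if not summary.empty:
        # monotone-trend flag over the sweep, e.g. FWHM rising with PRF
        summary = summary.sort_values("prf_hz").reset_index(drop=True)
        summary["fwhm_monotone_in_prf"] = bool(
            len(summary) > 1 and summary.fwhm_mm.is_monotonic_increasing
        )
    if out is not None:
        summary.to_csv(out / "summary.csv", index=False)
    if failed:
        raise RuntimeError(f"runs failed: {failed}")
    return summary
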