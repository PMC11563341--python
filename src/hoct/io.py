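"""HDF5 container, CSV, and TIFF input/output.

One HDF5 container per run, with groups ``/sweep`` (profile as JSON attrs),
``/acquisition``, ``/modulation`` (per-column schedule), ``/interferograms``
(2-D sample x A-scan, time- and/or k-domain), ``/phantom`` (reflector table),
and optionally ``/phase`` and ``/compensated`` once dispersion compensation
has run.  Root attributes carry the package version, the seed, and the config
hash.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError
from .reconstruct import BScan, ModulationSchedule
from .simulate import AcquisitionSpec, ReflectorPhantom
from .sweep import SweepProfile
from .wigner import PhaseError, PWVDMap

__all__ = [
    "RunData",
    "sweep_profile_to_json",
    "sweep_profile_from_json",
    "save_container",
    "load_container",
    "save_phase_csv",
    "load_phase_csv",
    "save_schedule_csv",
    "load_schedule_csv",
    "export_bscan_tiff",
    "export_pwvd_tiff",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def sweep_profile_to_json(profile: SweepProfile) -> str:
    from scipy.constants import c as C_LIGHT
    delta_lambda = profile.bandwidth_ang * profile.lambda0**2 / (2 * np.pi * C_LIGHT)
    return json.dumps({
        "lambda0_m": profile.lambda0,
        "delta_lambda_m": delta_lambda,
        "rep_rate_hz": profile.rep_rate,
        "duty": profile.duty,
        "omega_poly_coeffs": list(profile.omega_poly),
    })


def sweep_profile_from_json(text: str) -> SweepProfile:
    from scipy.constants import c as C_LIGHT
    d = json.loads(text)
    bandwidth_ang = 2 * np.pi * C_LIGHT * d["delta_lambda_m"] / d["lambda0_m"]**2
    return SweepProfile(tuple(d["omega_poly_coeffs"]), d["lambda0_m"],
                        bandwidth_ang, d["rep_rate_hz"], d["duty"])


@dataclass
class RunData:
    """In-memory image of a run container."""

    profile: SweepProfile
    acquisition: AcquisitionSpec
    schedule: ModulationSchedule
    mode: str
    phantoms: list
    lateral_positions: np.ndarray
    interferograms: np.ndarray  # (n_samples, n_ascans), time domain
    time_grid: np.ndarray
    k_values: np.ndarray | None = None  # (n_samples, n_ascans), k domain
    k_grid: np.ndarray | None = None
    compensated: np.ndarray | None = None  # complex corrected spectra
    phase: PhaseError | None = None
    attrs: dict = field(default_factory=dict)


def _write_ds(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


def save_container(path, data: RunData) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        for key, val in data.attrs.items():
            f.attrs[key] = val
        g = f.create_group("sweep")
        g.attrs["profile_json"] = sweep_profile_to_json(data.profile)
        g = f.create_group("acquisition")
        acq = data.acquisition
        g.attrs.update({
            "n_samples": acq.n_samples, "sample_rate_hz": acq.sample_rate,
            "antialias_cutoff_hz": acq.antialias_cutoff or 0.0,
            "reference_amplitude": acq.reference_amplitude,
            "noise_sigma": acq.noise_sigma, "seed": acq.seed,
        })
        g = f.create_group("modulation")
        g.attrs["mode"] = data.mode
        _write_ds(g, "f_m_hz", data.schedule.f_m)
        _write_ds(g, "A_m_rad", data.schedule.A_m)
        _write_ds(g, "p", data.schedule.p)
        _write_ds(g, "clipped", data.schedule.clipped.astype(np.uint8))
        g.attrs["vco_range_hz"] = list(data.schedule.vco_range)
        g = f.create_group("phantom")
        rows = []
        for i, ph in enumerate(data.phantoms):
            for z, a in ph.reflectors:
                rows.append((i, z, a, ph.n))
        rows = np.array(rows, dtype=float) if rows else np.zeros((0, 4))
        _write_ds(g, "reflectors", rows)
        g.attrs["columns"] = "ascan_index,z_m,amplitude,n"
        _write_ds(g, "lateral_positions_m", data.lateral_positions)
        g = f.create_group("interferograms")
        _write_ds(g, "values", data.interferograms)
        _write_ds(g, "time_grid_s", data.time_grid)
        g.attrs["domain"] = "time"
        if data.k_values is not None:
            _write_ds(g, "k_values", data.k_values)
            _write_ds(g, "k_grid_rad_per_m", data.k_grid)
        if data.compensated is not None:
            g = f.create_group("compensated")
            _write_ds(g, "values", data.compensated)
        if data.phase is not None:
            g = f.create_group("phase")
            pe = data.phase
            _write_ds(g, "phi_rad", pe.phi)
            _write_ds(g, "delta_z_m", pe.displacement)
            _write_ds(g, "valid", pe.valid_mask.astype(np.uint8))
            _write_ds(g, "k_rad_per_m", pe.k_axis)
            g.attrs["policy"] = pe.integration_constant_policy


def load_container(path) -> RunData:
    with h5py.File(path, "r") as f:
        profile = sweep_profile_from_json(f["sweep"].attrs["profile_json"])
        ga = f["acquisition"].attrs
        cutoff = float(ga["antialias_cutoff_hz"]) or None
        acq = AcquisitionSpec(
            n_samples=int(ga["n_samples"]), sample_rate=float(ga["sample_rate_hz"]),
            antialias_cutoff=cutoff,
            reference_amplitude=float(ga["reference_amplitude"]),
            noise_sigma=float(ga["noise_sigma"]), seed=int(ga["seed"]))
        gm = f["modulation"]
        schedule = ModulationSchedule(
            f_m=gm["f_m_hz"][:], A_m=gm["A_m_rad"][:], p=gm["p"][:],
            vco_range=tuple(gm.attrs["vco_range_hz"]),
            clipped=gm["clipped"][:].astype(bool))
        mode = gm.attrs["mode"]
        rows = f["phantom"]["reflectors"][:]
        phantoms = []
        n_ascans = f["interferograms"]["values"].shape[1]
        for i in range(n_ascans):
            sel = rows[rows[:, 0] == i]
            if sel.size:
                phantoms.append(ReflectorPhantom(
                    tuple((r[1], r[2]) for r in sel), n=float(sel[0, 3])))
            else:
                phantoms.append(ReflectorPhantom(((0.0, 0.0),)))
        data = RunData(
            profile=profile, acquisition=acq, schedule=schedule, mode=mode,
            phantoms=phantoms,
            lateral_positions=f["phantom"]["lateral_positions_m"][:],
            interferograms=f["interferograms"]["values"][:],
            time_grid=f["interferograms"]["time_grid_s"][:],
            attrs=dict(f.attrs))
        if "k_values" in f["interferograms"]:
            data.k_values = f["interferograms"]["k_values"][:]
            data.k_grid = f["interferograms"]["k_grid_rad_per_m"][:]
        if "compensated" in f:
            data.compensated = f["compensated"]["values"][:]
        if "phase" in f:
            g = f["phase"]
            data.phase = PhaseError(
                phi=g["phi_rad"][:], displacement=g["delta_z_m"][:],
                valid_mask=g["valid"][:].astype(bool),
                k_axis=g["k_rad_per_m"][:],
                integration_constant_policy=g.attrs["policy"])
    return data


def save_phase_csv(pe: PhaseError, path) -> None:
    df = pd.DataFrame({
        "k_rad_per_m": pe.k_axis, "delta_z_m": pe.displacement,
        "phi_rad": pe.phi, "valid": pe.valid_mask.astype(int),
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_phase_csv(path) -> PhaseError:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"k_rad_per_m", "delta_z_m", "phi_rad", "valid"}
    if not required.issubset(df.columns):
        raise ConfigError(f"phase CSV missing columns {required - set(df.columns)}")
    return PhaseError(phi=df["phi_rad"].to_numpy(),
                      displacement=df["delta_z_m"].to_numpy(),
                      valid_mask=df["valid"].to_numpy().astype(bool),
                      k_axis=df["k_rad_per_m"].to_numpy())


def save_phantom_csv(phantoms, path) -> None:
    """Reflector table: one row per reflector, keyed by A-scan index."""
    rows = [(i, z, a, ph.n)
            for i, ph in enumerate(phantoms) for z, a in ph.reflectors]
    df = pd.DataFrame(rows, columns=["ascan_index", "z_m", "amplitude", "n"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_phantom_csv(path):
    df = pd.read_csv(path, float_precision="round_trip")
    phantoms = []
    for i in sorted(df["ascan_index"].unique()):
        sel = df[df["ascan_index"] == i]
        phantoms.append(ReflectorPhantom(
            tuple(zip(sel["z_m"], sel["amplitude"])), n=float(sel["n"].iloc[0])))
    return phantoms


def save_kclock(path, kclock) -> None:
    """Store a k-clock series as an HDF5 dataset with its sample rate."""
    with h5py.File(path, "a") as f:
        if "kclock" in f:
            del f["kclock"]
        ds = f.create_dataset("kclock", data=kclock.values, track_times=False)
        ds.attrs["sample_rate_hz"] = kclock.sample_rate
        ds.attrs["mzi_delay_s"] = kclock.mzi_delay
        f.create_dataset("kclock_valid", data=kclock.valid.astype(np.uint8),
                         track_times=False)


def load_kclock(path):
    from .sweep import KClock
    with h5py.File(path, "r") as f:
        ds = f["kclock"]
        return KClock(values=ds[:], sample_rate=float(ds.attrs["sample_rate_hz"]),
                      mzi_delay=float(ds.attrs["mzi_delay_s"]),
                      valid=f["kclock_valid"][:].astype(bool))


def save_schedule_csv(schedule: ModulationSchedule, path) -> None:
    df = pd.DataFrame({
        "ascan_index": np.arange(len(schedule)), "f_m_hz": schedule.f_m,
        "A_m_rad": schedule.A_m, "p": schedule.p,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_schedule_csv(path, vco_range=(1e9, 2e9)) -> ModulationSchedule:
    df = pd.read_csv(path, float_precision="round_trip")
    return ModulationSchedule(f_m=df["f_m_hz"].to_numpy(),
                              A_m=df["A_m_rad"].to_numpy(),
                              p=df["p"].to_numpy(), vco_range=vco_range)


def export_bscan_tiff(b: BScan, path, floor_db: float = -60.0,
                      ceil_db: float = 0.0, extra_metadata: dict | None = None):
    """16-bit log-magnitude TIFF with the dB floor/ceiling in the metadata."""
    mag = b.magnitude()
    peak = mag.max() or 1.0
    db = 20.0 * np.log10(np.maximum(mag / peak, 1e-12))
    scaled = np.clip((db - floor_db) / (ceil_db - floor_db), 0.0, 1.0)
    img = (scaled * np.iinfo(np.uint16).max).astype(np.uint16)
    meta = {"floor_db": floor_db, "ceil_db": ceil_db,
            "dz_pixel_m": b.dz_pixel, "lateral_pitch_m": b.lateral_pitch,
            "flattened": bool(b.flattened)}
    meta.update(extra_metadata or {})
    tifffile.imwrite(path, img, description=json.dumps(meta))


def export_pwvd_tiff(m: PWVDMap, path):
    """32-bit float TIFF of the distribution for inspection."""
    meta = {"dk_rad_per_m": m.dk, "dz_m": m.dz,
            "kernel_widths": list(m.kernel_widths)}
    tifffile.imwrite(path, m.values.astype(np.float32),
                     description=json.dumps(meta))
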