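"""End-to-end processing stages shared by the library API and the CLI."""

from __future__ import annotations

import logging
import time

import numpy as np

from . import __version__
from .config import RunConfig
from .io import RunData
from .reconstruct import ascan, assemble_bscan, predicted_shift, \
    reconstruct_curvature
from .simulate import Interferogram, ModulationSpec, resample_linear_in_k, \
    simulate_interferogram
from .wigner import PhaseError, compensate, estimate_phase_error

log = logging.getLogger("hoct")

__all__ = ["simulate_run", "compensate_run", "reconstruct_run"]


def _timed(stage):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("%s finished in %.2f s", stage, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_timed("simulate")
def simulate_run(cfg: RunConfig) -> RunData:
    """Simulate all A-scans of a run; deterministic given the config seed."""
    igs = []
    t_grid = None
    for i, phantom in enumerate(cfg.phantoms):
        mod = ModulationSpec(f_m=float(cfg.schedule.f_m[i]),
                             A_m=float(cfg.schedule.A_m[i]),
                             p_select=int(cfg.schedule.p[i]), mode=cfg.mode)
        acq = cfg.acquisition
        if acq.noise_sigma > 0:
            # one master seed, decorrelated per column
            acq = type(acq)(n_samples=acq.n_samples, sample_rate=acq.sample_rate,
                            antialias_cutoff=acq.antialias_cutoff,
                            reference_amplitude=acq.reference_amplitude,
                            noise_sigma=acq.noise_sigma,
                            seed=(cfg.seed * 100003 + i) % (2**31 - 1))
        ig = simulate_interferogram(cfg.profile, phantom, mod, acq)
        igs.append(ig.values)
        t_grid = ig.grid
    values = np.stack(igs, axis=1)
    return RunData(
        profile=cfg.profile, acquisition=cfg.acquisition,
        schedule=cfg.schedule, mode=cfg.mode, phantoms=list(cfg.phantoms),
        lateral_positions=np.asarray(cfg.lateral_positions),
        interferograms=values, time_grid=t_grid,
        attrs={"package_version": __version__, "config_hash": cfg.hash,
               "seed": cfg.seed})


@_timed("compensate")
def compensate_run(data: RunData, reuse_phase: PhaseError | None = None,
                   detrend: bool = True, n_index: float | None = None) -> RunData:
    """Resample linear-in-k, estimate (or reuse) phi(k), correct every column.

    The phase is estimated once, from the column of maximum fringe energy,
    and re-applied to every column of the frame (coarse-grained reuse, as for
    live correction); compensating twice with the same phase is guarded
    against via a container flag.
    """
    if data.attrs.get("compensated_flag"):
        log.info("container already compensated; skipping re-application")
        return data
    n_idx = n_index if n_index is not None else data.phantoms[0].n
    n_cols = data.interferograms.shape[1]
    k_cols = []
    k_grid = None
    for i in range(n_cols):
        ig = Interferogram(values=data.interferograms[:, i], domain="time",
                           grid=data.time_grid)
        ig_k = resample_linear_in_k(ig, data.profile)
        k_cols.append(ig_k.values)
        k_grid = ig_k.grid
    k_values = np.stack(k_cols, axis=1)
    if reuse_phase is not None:
        pe = reuse_phase
    else:
        energies = np.sum(k_values**2, axis=0)
        ref_col = int(np.argmax(energies))
        pe = estimate_phase_error(
            Interferogram(values=k_values[:, ref_col], domain="wavenumber",
                          grid=k_grid), n=n_idx, detrend=detrend)
    comp = np.stack([
        compensate(Interferogram(values=k_values[:, i], domain="wavenumber",
                                 grid=k_grid), pe)
        for i in range(n_cols)], axis=1)
    data.k_values = k_values
    data.k_grid = k_grid
    data.compensated = comp
    data.phase = pe
    data.attrs["compensated_flag"] = 1
    return data


@_timed("reconstruct")
def reconstruct_run(data: RunData, physical_frame: bool = False,
                    window: str = "hann", use_compensated: bool | None = None):
    """Form the B-scan; optionally restore the physical (curved) frame.

    Uses the compensated complex spectra when present (unless overridden);
    otherwise the raw k-domain (or freshly resampled) real spectra, which keep
    the conjugate image.
    """
    n_idx = data.phantoms[0].n
    if data.k_values is None:
        k_cols, k_grid = [], None
        for i in range(data.interferograms.shape[1]):
            ig = Interferogram(values=data.interferograms[:, i], domain="time",
                               grid=data.time_grid)
            ig_k = resample_linear_in_k(ig, data.profile)
            k_cols.append(ig_k.values)
            k_grid = ig_k.grid
        data.k_values = np.stack(k_cols, axis=1)
        data.k_grid = k_grid
    if use_compensated is None:
        use_compensated = data.compensated is not None
    spectra = data.compensated if use_compensated else data.k_values
    columns = []
    for i in range(spectra.shape[1]):
        off = predicted_shift(float(data.schedule.f_m[i]),
                              int(data.schedule.p[i]), data.profile, n_idx)
        columns.append(ascan(spectra[:, i], data.k_grid, window=window,
                             n_index=n_idx, depth_offset=off,
                             p=int(data.schedule.p[i])))
    pitch = 0.0
    if data.lateral_positions.size > 1:
        pitch = float(np.diff(data.lateral_positions).mean())
    b = assemble_bscan(columns, schedule=data.schedule, lateral_pitch=pitch)
    if physical_frame:
        b = reconstruct_curvature(b)
    return b
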