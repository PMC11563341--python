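"""Run configuration: a single JSON document, schema-validated, SI units.

All physical keys carry explicit unit suffixes (``_m``, ``_hz``, ``_rad``).
A configuration names the sweep, the acquisition, the modulation (a constant
setting or a parabolic flattening schedule), the phantom (discrete reflectors
or a curved layered surface), pipeline flags, and the master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .reconstruct import ModulationSchedule, parabolic_schedule, predicted_shift
from .simulate import AcquisitionSpec, make_curved_phantom, ReflectorPhantom
from .sweep import SweepProfile, default_perturbation, make_nominal_sweep, \
    make_perturbed_sweep

__all__ = ["RunConfig", "config_hash"]


def _get(d: dict, path: str, default=...):
    cur = d
    for part in path.split("."):
        if not isinstance(cur, dict) or part not in cur:
            if default is ...:
                raise ConfigError(f"missing config key {path!r}")
            return default
        cur = cur[part]
    return cur


def config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunConfig:
    profile: SweepProfile
    acquisition: AcquisitionSpec
    schedule: ModulationSchedule
    mode: str
    phantoms: list
    lateral_positions: np.ndarray
    seed: int
    compensation: str = "estimate"  # estimate | reuse | none
    detrend: bool = True
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def hash(self) -> str:
        return config_hash(self.raw)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        seed = int(_get(cfg, "seed", 0))
        base = make_nominal_sweep(
            _get(cfg, "sweep.lambda0_m"), _get(cfg, "sweep.delta_lambda_m"),
            _get(cfg, "sweep.rep_rate_hz"), _get(cfg, "sweep.duty"))
        perturb = _get(cfg, "sweep.perturb_poly_coeffs", None)
        rel = _get(cfg, "sweep.perturb_rel_alpha", 0.0)
        if perturb is not None:
            profile = make_perturbed_sweep(base, perturb)
        elif rel > 0:
            profile = make_perturbed_sweep(base, default_perturbation(base, rel))
        else:
            profile = base
        cutoff = _get(cfg, "acquisition.antialias_cutoff_hz", None)
        acq = AcquisitionSpec(
            n_samples=int(_get(cfg, "acquisition.n_samples", 640)),
            sample_rate=_get(cfg, "acquisition.sample_rate_hz", 550e6),
            antialias_cutoff=cutoff,
            reference_amplitude=_get(cfg, "acquisition.reference_amplitude", 1.0),
            noise_sigma=_get(cfg, "acquisition.noise_sigma", 0.0),
            seed=seed)
        mode = _get(cfg, "modulation.mode", "linear-term")
        p = int(_get(cfg, "modulation.p", 1))
        a_m = _get(cfg, "modulation.A_m_rad", 1.841)
        phantom_cfg = _get(cfg, "phantom")
        ptype = _get(phantom_cfg, "type")
        sched_cfg = _get(cfg, "modulation.schedule", None)
        if ptype == "reflectors":
            refl = _get(phantom_cfg, "reflectors_m")
            n_idx = _get(phantom_cfg, "n", 1.0)
            n_ascans = int(_get(cfg, "bscan.n_ascans", 1))
            phantom = ReflectorPhantom(tuple((z, a) for z, a in refl), n=n_idx)
            phantoms = [phantom] * n_ascans
            lateral = np.arange(n_ascans) * _get(cfg, "bscan.lateral_pitch_m", 0.0)
        elif ptype == "surface":
            sag = _get(phantom_cfg, "sag_m")
            width = _get(phantom_cfg, "width_m", 12.5e-3)
            apex = _get(phantom_cfg, "apex_depth_m")
            layers = _get(phantom_cfg, "layers_m", [[0.0, 1.0]])
            n_idx = _get(phantom_cfg, "n", 1.0)
            n_ascans = int(_get(cfg, "bscan.n_ascans", 256))
            jitter = _get(phantom_cfg, "amplitude_jitter", 0.0)

            def surface(x, *, _sag=sag, _w=width, _apex=apex):
                return _apex + _sag * (2.0 * x / _w) ** 2

            lateral, phantoms = make_curved_phantom(
                surface, n_ascans, layers=[tuple(l) for l in layers], n=n_idx,
                seed=seed, width=width, amplitude_jitter=jitter)
        else:
            raise ConfigError(f"unknown phantom type {ptype!r}")
        if sched_cfg is not None:
            if _get(sched_cfg, "type") != "parabolic":
                raise ConfigError("only parabolic schedules are supported")
            n_idx = _get(phantom_cfg, "n", 1.0)
            schedule = parabolic_schedule(
                len(phantoms), _get(sched_cfg, "sag_m"),
                _get(sched_cfg, "f_center_hz"), profile, n=n_idx,
                vco_range=tuple(_get(sched_cfg, "vco_range_hz", [1e9, 2e9])),
                p=p, A_m=a_m)
        else:
            f_m = _get(cfg, "modulation.f_m_hz")
            schedule = ModulationSchedule(
                f_m=np.full(len(phantoms), float(f_m)), A_m=a_m, p=p,
                vco_range=tuple(_get(cfg, "modulation.vco_range_hz",
                                     [0.0, np.inf])))
        comp = _get(cfg, "pipeline.compensation", "estimate")
        if comp not in ("estimate", "reuse", "none"):
            raise ConfigError(f"unknown compensation mode {comp!r}")
        return cls(profile=profile, acquisition=acq, schedule=schedule,
                   mode=mode, phantoms=phantoms, lateral_positions=lateral,
                   seed=seed, compensation=comp,
                   detrend=bool(_get(cfg, "pipeline.detrend", True)), raw=cfg)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            try:
                cfg = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ConfigError(f"config is not valid JSON: {exc}") from exc
        return cls.from_dict(cfg)
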