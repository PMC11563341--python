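"""Packaged demonstration configurations.

Three desk-scale scenarios: a three-reflector phantom under a perturbed sweep
(dispersion genesis and cure), a convex fruit-like surface, and a concave
retina-like surface spanning 12.5 mm x 4 mm that is flattened during
acquisition and digitally re-curved afterwards.
"""

from __future__ import annotations

import copy

from scipy.constants import c as C_LIGHT
import numpy as np

from .errors import ConfigError

__all__ = ["demo_config", "DEMO_NAMES"]

# nominal source: 1060 nm centre, 95 nm span, 400 kHz, 50 % duty
_SWEEP = {"lambda0_m": 1060e-9, "delta_lambda_m": 95e-9,
          "rep_rate_hz": 400e3, "duty": 0.5}
_ACQ = {"n_samples": 640, "sample_rate_hz": 550e6}

# shift coefficient of the nominal source, m per Hz of modulation
_B = 2 * np.pi * C_LIGHT * _SWEEP["delta_lambda_m"] / _SWEEP["lambda0_m"]**2
_ALPHA0 = _B * _SWEEP["rep_rate_hz"] / _SWEEP["duty"]
_SHIFT_PER_HZ = 2 * np.pi * C_LIGHT / (2 * _ALPHA0)

_F_CENTER = 1.2e9
_ZC = _SHIFT_PER_HZ * _F_CENTER  # depth imaged at the centre frequency

_CONFIGS = {
    "three-reflector": {
        "seed": 0,
        "sweep": {**_SWEEP, "perturb_rel_alpha": 0.05},
        "acquisition": _ACQ,
        "modulation": {"mode": "linear-term", "p": 1, "A_m_rad": 1.841,
                       "f_m_hz": _F_CENTER},
        "phantom": {"type": "reflectors", "n": 1.0,
                    "reflectors_m": [[_ZC + 0.4e-3, 1.0],
                                     [_ZC + 0.8e-3, 0.8],
                                     [_ZC + 1.2e-3, 0.6]]},
        "bscan": {"n_ascans": 16},
        "pipeline": {"compensation": "estimate"},
    },
    "grape": {
        "seed": 0,
        "sweep": dict(_SWEEP),
        "acquisition": _ACQ,
        "modulation": {"mode": "linear-term", "p": 1, "A_m_rad": 1.841,
                       "schedule": {"type": "parabolic", "sag_m": 1.5e-3,
                                    "f_center_hz": _F_CENTER,
                                    "vco_range_hz": [1e9, 2e9]}},
        "phantom": {"type": "surface", "sag_m": 1.5e-3, "width_m": 12e-3,
                    "apex_depth_m": _ZC + 0.5e-3,
                    "layers_m": [[0.0, 1.0], [0.15e-3, 0.5]], "n": 1.0},
        "bscan": {"n_ascans": 64},
        "pipeline": {"compensation": "none"},
    },
    "retina": {
        "seed": 0,
        "sweep": dict(_SWEEP),
        "acquisition": _ACQ,
        "modulation": {"mode": "linear-term", "p": 1, "A_m_rad": 1.841,
                       "schedule": {"type": "parabolic", "sag_m": 4e-3,
                                    "f_center_hz": _F_CENTER,
                                    "vco_range_hz": [1e9, 2e9]}},
        "phantom": {"type": "surface", "sag_m": 4e-3, "width_m": 12.5e-3,
                    "apex_depth_m": _ZC + 0.5e-3,
                    "layers_m": [[0.0, 1.0], [0.2e-3, 0.5]], "n": 1.0},
        "bscan": {"n_ascans": 64},
        "pipeline": {"compensation": "none"},
    },
}

DEMO_NAMES = tuple(_CONFIGS)


def demo_config(name: str) -> dict:
    """Return a copy of a packaged demo configuration dict."""
    if name not in _CONFIGS:
        raise ConfigError(f"unknown demo {name!r}; choose from {DEMO_NAMES}")
    return copy.deepcopy(_CONFIGS[name])
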