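"""Forward simulation of balanced-detector interferograms.

A discrete reflector at depth ``z_s`` (background index ``n``) delays the
sample field by ``tau_s = 2 n z_s / c``; the balanced detector keeps only the
interference term, so each reflector contributes

    A_r A_s cos( phi(t - tau_s) - phi(t) + m(t) )

where ``phi`` is the sweep phase and ``m(t)`` the electro-optic reference-arm
modulation.  Sinusoidal modulation ``m(t) = A_m sin(2 pi f_m t)`` splits the
fringe into harmonics with Jacobi-Anger amplitudes ``J_p(A_m)``; the selected
sideband convention is the one that *reduces* the apparent fringe frequency,
so harmonic ``p`` images at the apparent depth ``z_s - p omega_m c / (2 n
alpha)``.  For pipeline studies the frequency shift may instead be applied as
a pure linear phase term ``m(t) = p * 2 pi f_m t`` (``linear-term`` mode),
which isolates the selected harmonic exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import special
from scipy.constants import c as C_LIGHT
from scipy.optimize import minimize_scalar

from .errors import AliasingError, InvalidParameterError
from .sweep import SweepProfile

__all__ = [
    "ReflectorPhantom",
    "ModulationSpec",
    "AcquisitionSpec",
    "Interferogram",
    "harmonic_amplitude",
    "optimal_modulation_amplitude",
    "simulate_interferogram",
    "resample_linear_in_k",
    "make_curved_phantom",
]


@dataclass(frozen=True)
class ReflectorPhantom:
    """Discrete reflectors: list of ``(depth_m, amplitude)`` in a medium of index n."""

    reflectors: tuple
    n: float = 1.0

    def __post_init__(self):
        refl = tuple((float(z), float(a)) for z, a in self.reflectors)
        if any(a < 0 for _, a in refl):
            raise InvalidParameterError("reflector amplitudes must be non-negative")
        if any(not np.isfinite(z) for z, _ in refl):
            raise InvalidParameterError("reflector depths must be finite")
        if self.n < 1:
            raise InvalidParameterError("refractive index must be >= 1")
        object.__setattr__(self, "reflectors", refl)


@dataclass(frozen=True)
class ModulationSpec:
    """Electro-optic phase modulation of the reference arm.

    ``mode`` is ``"exact-sine"`` (physical sinusoidal drive, all harmonics)
    or ``"linear-term"`` (only the selected harmonic ``p_select``, as a pure
    linear phase).
    """

    f_m: float = 0.0
    A_m: float = 0.0
    p_select: int = 1
    mode: str = "linear-term"

    def __post_init__(self):
        if self.f_m < 0 or self.A_m < 0:
            raise InvalidParameterError("f_m and A_m must be non-negative")
        if self.mode not in ("exact-sine", "linear-term"):
            raise InvalidParameterError(f"unknown modulation mode {self.mode!r}")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Digitiser settings for one A-scan."""

    n_samples: int = 640
    sample_rate: float = 550e6
    antialias_cutoff: float | None = None
    reference_amplitude: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 16:
            raise InvalidParameterError("n_samples must be at least 16")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")


@dataclass
class Interferogram:
    """A sampled fringe signal in the time or wavenumber domain."""

    values: np.ndarray
    domain: str  # "time" | "wavenumber"
    grid: np.ndarray  # seconds, or rad/m
    provenance: dict = field(default_factory=dict)

    @property
    def grid_step(self) -> float:
        return float(self.grid[1] - self.grid[0])


def harmonic_amplitude(A_m: float, p: int) -> float:
    """Amplitude of the p-th modulation harmonic, ``J_p(A_m)`` (Jacobi-Anger)."""
    return float(special.jv(p, A_m))


def optimal_modulation_amplitude():
    """Modulation amplitude maximizing the first harmonic.

    Returns ``(A_m, amplitude, intensity_penalty_dB)`` where ``A_m`` is the
    argmax of ``J_1`` (~1.841 rad), ``amplitude`` its maximum (~0.582), and the
    penalty ``20 log10(amplitude)`` (~-4.7 dB) the unavoidable cost of sine
    modulation relative to the fundamental.
    """
    res = minimize_scalar(lambda a: -special.j1(a), bounds=(0.5, 3.5),
                          method="bounded", options={"xatol": 1e-12})
    a_opt = float(res.x)
    amp = float(special.j1(a_opt))
    return a_opt, amp, 20.0 * np.log10(amp)


def _significant_harmonics(A_m: float, tol: float = 1e-4):
    p = 0
    orders = []
    while True:
        if abs(special.jv(p, A_m)) > tol:
            orders.extend([p, -p] if p else [0])
        elif p > A_m + 4:
            break
        p += 1
    return sorted(set(orders))


def _max_component_freq(profile: SweepProfile, phantom: ReflectorPhantom,
                        mod: ModulationSpec, t_lo: float, t_hi: float):
    """Largest instantaneous fringe frequency over reflectors and harmonics."""
    t = np.linspace(max(t_lo, 0.0), t_hi, 2049)
    if mod.mode == "linear-term":
        orders = [mod.p_select]
    else:
        orders = _significant_harmonics(mod.A_m) if mod.f_m > 0 else [0]
    f_max = 0.0
    for z_s, _ in phantom.reflectors:
        tau_s = 2.0 * phantom.n * z_s / C_LIGHT
        f_r = (profile.omega(t) - profile.omega(t - tau_s)) / (2 * np.pi)
        for p in orders:
            f_max = max(f_max, float(np.max(np.abs(f_r - p * mod.f_m))))
    return f_max


def _brickwall_lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    spec[freqs > cutoff] = 0.0
    return np.fft.irfft(spec, n=x.size)


def simulate_interferogram(profile: SweepProfile, phantom: ReflectorPhantom,
                           mod: ModulationSpec,
                           acq: AcquisitionSpec) -> Interferogram:
    """Synthesize one time-domain balanced-detector interferogram.

    The fringe is the cosine of the difference between the (delayed) sample
    phase and the modulated reference phase, summed over reflectors; the
    background term is rejected (perfect balanced detection), so the output is
    mean-zero.  Components above the Nyquist rate raise
    :class:`AliasingError` unless ``acq.antialias_cutoff`` is set, in which
    case the signal is generated at an internally oversampled rate, brick-wall
    low-pass filtered (the hardware anti-alias filter), and decimated onto the
    requested grid.
    """
    if not phantom.reflectors:
        raise InvalidParameterError("phantom holds no reflectors")
    fs = acq.sample_rate
    n = acq.n_samples
    t_end = (n - 1) / fs
    if t_end > profile.t_sweep * (1 + 1e-12):
        raise InvalidParameterError(
            "acquisition window exceeds the sweep duration")
    f_max = _max_component_freq(profile, phantom, mod, 0.0, t_end)
    oversample = 1
    if f_max >= fs / 2:
        if acq.antialias_cutoff is None:
            raise AliasingError(
                f"fringe component at {f_max:.3g} Hz exceeds Nyquist "
                f"{fs / 2:.3g} Hz and no anti-alias filter is enabled")
        if acq.antialias_cutoff > fs / 2:
            raise AliasingError(
                "antialias_cutoff must not exceed the acquisition Nyquist rate")
        while f_max >= oversample * fs / 2:
            oversample *= 2
    t = np.arange(n * oversample) / (fs * oversample)
    if mod.f_m > 0 and mod.A_m == 0 and mod.mode == "exact-sine":
        m_t = np.zeros_like(t)
    elif mod.mode == "exact-sine":
        m_t = mod.A_m * np.sin(2 * np.pi * mod.f_m * t)
    else:  # linear-term: isolate the selected harmonic as a pure phase ramp
        m_t = mod.p_select * 2 * np.pi * mod.f_m * t
    values = np.zeros_like(t)
    phi_t = profile.phase(t)
    for z_s, a_s in phantom.reflectors:
        tau_s = 2.0 * phantom.n * z_s / C_LIGHT
        values += acq.reference_amplitude * a_s * np.cos(
            profile.phase(t - tau_s) - phi_t + m_t)
    if oversample > 1:
        values = _brickwall_lowpass(values, fs * oversample,
                                    acq.antialias_cutoff)
        values = values[::oversample]
        t = t[::oversample]
    elif acq.antialias_cutoff is not None:
        values = _brickwall_lowpass(values, fs, acq.antialias_cutoff)
    if acq.noise_sigma > 0:
        rng = np.random.default_rng(acq.seed)
        values = values + rng.normal(0.0, acq.noise_sigma, size=values.size)
    values = values - values.mean()  # balanced detection removes the background
    prov = {"sweep": profile, "modulation": mod, "acquisition": acq,
            "phantom": phantom}
    return Interferogram(values=values, domain="time", grid=t, provenance=prov)


def resample_linear_in_k(ig: Interferogram,
                         profile: SweepProfile) -> Interferogram:
    """Model the hardware k-clock: linear interpolation onto a uniform k grid.

    The grid spans the k extremes of the sampled window with the same sample
    count; requires a strictly monotone omega(t).
    """
    if ig.domain != "time":
        raise InvalidParameterError("input interferogram must be time-domain")
    k_t = profile.omega(ig.grid) / C_LIGHT
    if not np.all(np.diff(k_t) > 0):
        raise InvalidParameterError("omega(t) is not monotone over the sweep")
    k_uniform = np.linspace(k_t[0], k_t[-1], ig.values.size)
    values = np.interp(k_uniform, k_t, ig.values)
    values = values - values.mean()
    return Interferogram(values=values, domain="wavenumber", grid=k_uniform,
                         provenance=dict(ig.provenance))


def make_curved_phantom(surface: Callable[[float], float], n_ascans: int,
                        layers: Sequence = ((0.0, 1.0),), n: float = 1.0,
                        seed: int | None = None, *, width: float = 12.5e-3,
                        amplitude_jitter: float = 0.0):
    """Per-A-scan reflector phantoms tracing a curved layered surface.

    ``surface`` maps lateral position (m, centred on 0 over ``width``) to
    surface depth (m); each lateral position receives reflectors at the
    surface depth plus each layer offset.  ``seed`` drives optional
    multiplicative amplitude jitter; identical seeds give identical phantoms.
    Returns ``(lateral_positions, [ReflectorPhantom, ...])``.
    """
    if n_ascans < 1:
        raise InvalidParameterError("n_ascans must be at least 1")
    x = np.linspace(-width / 2.0, width / 2.0, n_ascans) if n_ascans > 1 \
        else np.array([0.0])
    rng = np.random.default_rng(seed)
    phantoms = []
    for xi in x:
        z0 = float(surface(xi))
        refl = []
        for off, amp in layers:
            a = float(amp)
            if amplitude_jitter > 0:
                a *= float(np.clip(1.0 + amplitude_jitter * rng.standard_normal(),
                                   0.0, None))
            refl.append((z0 + float(off), a))
        phantoms.append(ReflectorPhantom(tuple(refl), n=n))
    return x, phantoms
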