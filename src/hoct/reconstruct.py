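"""A-/B-scan formation, electronic depth shifting, flattening, curvature recovery.

The harmonic of order ``p`` images at an apparent depth offset by
``delta_z_m = p omega_m c / (2 n alpha0)`` from the true reflector depth
(subtracted, in this package's sideband convention).  Driving the modulation
frequency per A-scan lets the programmed shift cancel a curved surface so the
flattened image fits the limited axial range; the curvature is restored
post-acquisition by translating each column back by its programmed shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import c as C_LIGHT
from scipy.signal import get_window

from .errors import InvalidParameterError, ScheduleError
from .sweep import SweepProfile

__all__ = [
    "AScan",
    "ModulationSchedule",
    "BScan",
    "ascan",
    "predicted_shift",
    "parabolic_schedule",
    "assemble_bscan",
    "reconstruct_curvature",
    "peak_snr",
    "incoherent_average",
]


@dataclass
class AScan:
    """One complex depth profile.

    ``z_axis`` is signed depth with 0 at zero path difference; the conjugate
    band is the negative half.  ``depth_offset`` records the programmed
    electronic shift ``delta_z_m`` of this column.
    """

    profile: np.ndarray
    dz_pixel: float
    z_axis: np.ndarray = field(repr=False, default=None)
    depth_offset: float = 0.0
    p: int = 0
    subpixel_remainder: float = 0.0

    def magnitude(self) -> np.ndarray:
        return np.abs(self.profile)


@dataclass
class ModulationSchedule:
    """Per-A-scan modulation settings with VCO-range bookkeeping."""

    f_m: np.ndarray
    A_m: np.ndarray
    p: np.ndarray
    vco_range: tuple = (1e9, 2e9)
    clipped: np.ndarray = None

    def __post_init__(self):
        self.f_m = np.atleast_1d(np.asarray(self.f_m, dtype=float))
        self.A_m = np.broadcast_to(np.asarray(self.A_m, dtype=float),
                                   self.f_m.shape).copy()
        self.p = np.broadcast_to(np.asarray(self.p, dtype=int),
                                 self.f_m.shape).copy()
        if self.clipped is None:
            lo, hi = self.vco_range
            self.clipped = (self.f_m < lo) | (self.f_m > hi)

    def __len__(self):
        return self.f_m.size

    @property
    def constant(self) -> bool:
        return bool(np.all(self.f_m == self.f_m[0]) and np.all(self.p == self.p[0]))


@dataclass
class BScan:
    """Lateral stack of complex A-scans plus its flattening schedule."""

    columns: list
    lateral_pitch: float
    schedule: ModulationSchedule | None = None
    flattened: bool = False

    def magnitude(self) -> np.ndarray:
        """(depth, lateral) magnitude image."""
        return np.stack([c.magnitude() for c in self.columns], axis=1)

    @property
    def dz_pixel(self) -> float:
        return self.columns[0].dz_pixel

    @property
    def z_axis(self) -> np.ndarray:
        return self.columns[0].z_axis


def ascan(spectrum: np.ndarray, k_axis: np.ndarray, window: str = "hann",
          n_index: float = 1.0, depth_offset: float = 0.0, p: int = 0,
          oversample: int = 1) -> AScan:
    """Fourier-transform a k-domain spectrum to a depth profile.

    The named window (default Hann; ``"boxcar"`` for none) tapers the spectral
    edges before the transform.  The full FFT is kept, fftshifted to a signed
    depth axis: a real spectrum yields the symmetric conjugate pair, a complex
    (analytic, compensated) spectrum only the true image.  The depth pixel is
    ``2 pi / (2 n k_span)``.
    """
    spectrum = np.asarray(spectrum)
    k_axis = np.asarray(k_axis, dtype=float)
    n = spectrum.size
    dk = k_axis[1] - k_axis[0]
    win = get_window(window, n) if window not in (None, "none") else np.ones(n)
    if oversample < 1:
        raise InvalidParameterError("oversample must be a positive integer")
    n_fft = n * int(oversample)  # zero-padding: sub-bin peak metrology
    prof = np.fft.fftshift(np.fft.fft(spectrum * win, n_fft))
    z_axis = np.fft.fftshift(np.fft.fftfreq(n_fft, d=dk)) * 2 * np.pi / (2 * n_index)
    dz = float(z_axis[1] - z_axis[0])
    return AScan(profile=prof, dz_pixel=dz, z_axis=z_axis,
                 depth_offset=depth_offset, p=p)


def predicted_shift(f_m: float, p: int, profile: SweepProfile,
                    n: float = 1.0) -> float:
    """Programmed axial shift ``delta_z_m = p (2 pi f_m) c / (2 n alpha0)`` in metres.

    ``alpha0 = B R / D`` from the profile's nominal parameters; at the nominal
    1060 nm / 95 nm / 400 kHz / 50 % source this is 7.4 mm per GHz of
    modulation frequency.
    """
    if f_m < 0:
        raise InvalidParameterError("f_m must be non-negative")
    return p * (2 * np.pi * f_m) * C_LIGHT / (2.0 * n * profile.alpha0)


def parabolic_schedule(n_ascans: int, sag: float, f_center: float,
                       profile: SweepProfile, n: float = 1.0,
                       vco_range: tuple = (1e9, 2e9), p: int = 1,
                       A_m: float = 1.841) -> ModulationSchedule:
    """Per-column modulation frequencies cancelling a parabolic surface.

    The apex (scan centre) maps to ``f_center``; a column a normalized lateral
    distance ``u`` from the apex is ``sag * u**2`` deeper and receives the
    extra modulation frequency that shifts it back level.  Columns outside the
    VCO range are clipped to it and flagged.
    """
    if sag < 0:
        raise InvalidParameterError("sag must be non-negative")
    if n_ascans < 1:
        raise InvalidParameterError("n_ascans must be at least 1")
    u = np.linspace(-1.0, 1.0, n_ascans) if n_ascans > 1 else np.zeros(1)
    shift_per_hz = predicted_shift(1.0, p, profile, n)
    f_m = f_center + sag * u**2 / shift_per_hz
    lo, hi = vco_range
    clipped = (f_m < lo) | (f_m > hi)
    if np.all(clipped):
        raise ScheduleError("entire schedule falls outside the VCO range")
    f_m = np.clip(f_m, lo, hi)
    return ModulationSchedule(f_m=f_m, A_m=A_m, p=p, vco_range=vco_range,
                              clipped=clipped)


def assemble_bscan(columns, schedule: ModulationSchedule | None = None,
                   lateral_pitch: float = 0.0) -> BScan:
    """Stack A-scan columns into a B-scan (flattened frame when the schedule varies)."""
    if not columns:
        raise InvalidParameterError("no columns to assemble")
    n0, dz0 = columns[0].profile.size, columns[0].dz_pixel
    for col in columns:
        if col.profile.size != n0 or not np.isclose(col.dz_pixel, dz0):
            raise InvalidParameterError("columns disagree in geometry")
    flattened = schedule is not None and not schedule.constant
    return BScan(columns=list(columns), lateral_pitch=lateral_pitch,
                 schedule=schedule, flattened=flattened)


def reconstruct_curvature(b: BScan) -> BScan:
    """Undo the flattening: translate each column by its programmed shift.

    Columns are moved in depth by integer pixels (the sub-pixel remainder is
    recorded on each column, not interpolated away) onto a common canvas of
    height ``n_samples + max programmed shift``; the result is in the physical
    frame (``flattened = False``).
    """
    if b.schedule is None:
        raise InvalidParameterError(
            "curvature reconstruction requires a recorded schedule")
    dz = b.dz_pixel
    offsets = np.array([col.depth_offset for col in b.columns])
    shifts_px = np.round(offsets / dz).astype(int)
    if np.any(shifts_px < 0):
        raise InvalidParameterError("negative programmed shifts are not supported")
    max_shift = int(shifts_px.max())
    n_z = b.columns[0].profile.size
    z0 = b.columns[0].z_axis[0]
    z_axis = z0 + dz * np.arange(n_z + max_shift)
    new_cols = []
    for col, s_px, off in zip(b.columns, shifts_px, offsets):
        canvas = np.zeros(n_z + max_shift, dtype=complex)
        if s_px + n_z > canvas.size:
            raise InvalidParameterError("column shifted outside the canvas")
        canvas[s_px:s_px + n_z] = col.profile
        new_cols.append(AScan(profile=canvas, dz_pixel=dz, z_axis=z_axis,
                              depth_offset=0.0, p=col.p,
                              subpixel_remainder=float(off - s_px * dz)))
    return BScan(columns=new_cols, lateral_pitch=b.lateral_pitch,
                 schedule=b.schedule, flattened=False)


def peak_snr(a: AScan, signal_window: tuple, noise_window: tuple) -> float:
    """Peak-signal to RMS-noise ratio, in dB, between disjoint depth windows."""
    s_lo, s_hi = signal_window
    n_lo, n_hi = noise_window
    if max(s_lo, n_lo) < min(s_hi, n_hi):
        raise InvalidParameterError("signal and noise windows overlap")
    z = a.z_axis
    sig_mask = (z >= s_lo) & (z < s_hi)
    noi_mask = (z >= n_lo) & (z < n_hi)
    if not sig_mask.any() or not noi_mask.any():
        raise InvalidParameterError("a window contains no depth pixels")
    mag = a.magnitude()
    peak = float(mag[sig_mask].max())
    noise = float(np.sqrt(np.mean(mag[noi_mask] ** 2)))
    return 20.0 * np.log10(peak / noise)


def incoherent_average(bscans) -> np.ndarray:
    """Magnitude average of repeated frames (display-style incoherent averaging)."""
    mags = [b.magnitude() for b in bscans]
    return np.mean(mags, axis=0)
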