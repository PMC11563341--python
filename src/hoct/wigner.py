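"""Pseudo Wigner-Ville time-frequency analysis and numerical dispersion compensation.

Sweep-rate variability ``alpha(t) = alpha0 + delta_alpha(t)`` leaves a
residual spectral phase error ``phi(k)`` in frequency-shifted (harmonic)
interferograms even after linear-in-k resampling, blurring the A-scan like
material dispersion.  The Wigner-Ville distribution (WVD) of the k-domain
fringe,

    S_W(k, z) = integral over kappa of  f(k + kappa/2) conj(f(k - kappa/2))
                e^{-i z kappa} d kappa,

resolves the apparent reflector depth as a function of wavenumber.  Smoothing
with separable Gaussian kernels in k and z (the *pseudo* WVD) suppresses the
quadratic cross terms.  Tracking the depth displacement ``delta_z(k)`` of the
distribution relative to a reference wavenumber by cross-correlation, and
integrating it,

    phi(k) = integral of 2 n delta_z(k) dk   (up to constant + linear terms),

recovers the phase error directly from image data; multiplying the analytic
signal by ``exp(-i phi(k))`` compensates it.  The constant/linear gauge terms
(an overall phase and a rigid image shift) are removed by detrending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as _signal
from scipy.constants import c as C_LIGHT
from scipy.integrate import cumulative_trapezoid

from .errors import (
    GridMismatchError,
    InvalidParameterError,
    NoSignalError,
)
from .simulate import Interferogram
from .sweep import SweepProfile

__all__ = [
    "PWVDMap",
    "PhaseError",
    "analytic_signal",
    "wvd",
    "pwvd",
    "extract_displacement",
    "phase_error_from_displacement",
    "compensate",
    "theoretical_ridge",
    "estimate_phase_error",
]


@dataclass
class PWVDMap:
    """(Pseudo) Wigner-Ville distribution over (wavenumber, depth).

    ``values[i_z, i_k]`` is real; each column (fixed k) reads as an A-scan
    built from spectral content near that wavenumber.
    """

    values: np.ndarray
    k_axis: np.ndarray
    z_axis: np.ndarray
    kernel_widths: tuple = (0.0, 0.0)  # (sigma_k rad/m, sigma_z m)

    @property
    def dz(self) -> float:
        return float(self.z_axis[1] - self.z_axis[0])

    @property
    def dk(self) -> float:
        return float(self.k_axis[1] - self.k_axis[0])


@dataclass
class PhaseError:
    """Spectral phase correction ``phi(k)`` with its provenance displacement."""

    phi: np.ndarray
    displacement: np.ndarray
    valid_mask: np.ndarray
    k_axis: np.ndarray
    integration_constant_policy: str = "mean-and-linear-removed"


def analytic_signal(ig: Interferogram) -> np.ndarray:
    """One-sided-spectrum complex signal of a mean-zero k-domain fringe.

    The real part equals the input; the imaginary part is its Hilbert
    transform, suppressing negative-frequency (conjugate) content ahead of the
    quadratic WVD.
    """
    if ig.domain != "wavenumber":
        raise InvalidParameterError("analytic_signal requires a k-domain interferogram")
    x = np.asarray(ig.values, dtype=float)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0 and abs(x.mean()) > 1e-6 * rms:
        raise InvalidParameterError("interferogram must be mean-zero")
    return _signal.hilbert(x)


def wvd(sig: np.ndarray, dk: float, k_axis: np.ndarray | None = None,
        n_index: float = 1.0) -> PWVDMap:
    """Discrete Wigner-Ville distribution of a complex k-domain signal.

    Half-integer lags are handled by 2x band-limited interpolation of the
    signal before forming the instantaneous autocorrelation
    ``f(k + kappa/2) conj(f(k - kappa/2))``; the lag FFT is then taken per
    column.  The depth axis is scaled for double-pass fringes
    ``exp(i 2 n k z)``, so a pure tone at depth ``z_s`` concentrates on the
    constant line ``z = z_s``.
    """
    sig = np.asarray(sig)
    n = sig.size
    f2 = _signal.resample(sig, 2 * n)  # band-limited 2x interpolation
    centers = 2 * np.arange(n)  # sample m of f2 sits at k_0 + m*dk/2
    lags = np.fft.fftfreq(n, d=1.0 / n).astype(int)  # 0..n/2-1, -n/2..-1
    idx_plus = centers[None, :] + lags[:, None]
    idx_minus = centers[None, :] - lags[:, None]
    valid = (idx_plus >= 0) & (idx_plus < 2 * n) & \
            (idx_minus >= 0) & (idx_minus < 2 * n)
    acf = np.zeros((n, n), dtype=complex)
    acf[valid] = f2[idx_plus[valid]] * np.conj(f2[idx_minus[valid]])
    values = np.fft.fft(acf, axis=0).real
    values = np.fft.fftshift(values, axes=0)
    z_axis = np.fft.fftshift(np.fft.fftfreq(n, d=dk)) * 2 * np.pi / (2 * n_index)
    if k_axis is None:
        k_axis = np.arange(n) * dk
    return PWVDMap(values=values, k_axis=np.asarray(k_axis), z_axis=z_axis)


def default_kernel_widths(k_axis: np.ndarray, z_axis: np.ndarray):
    """Package defaults: sigma_k = (k span)/48, sigma_z = 0.5 depth pixel.

    Wide enough in k to average out cross terms (which oscillate rapidly along
    k for components separated in depth) and to regularise the extracted ridge
    while keeping the bias on curved ridges within two depth pixels; minimal
    in z so auto-term peaks survive.
    """
    sigma_k = (k_axis[-1] - k_axis[0]) / 48.0
    sigma_z = 0.5 * float(z_axis[1] - z_axis[0])
    return sigma_k, sigma_z


def pwvd(sig: np.ndarray, dk: float, k_axis: np.ndarray | None = None,
         n_index: float = 1.0, sigma_k: float | None = None,
         sigma_z: float | None = None) -> PWVDMap:
    """Pseudo WVD: separable Gaussian smoothing of the WVD along k and z."""
    m = wvd(sig, dk, k_axis=k_axis, n_index=n_index)
    if sigma_k is None or sigma_z is None:
        d_k, d_z = default_kernel_widths(m.k_axis, m.z_axis)
        sigma_k = d_k if sigma_k is None else sigma_k
        sigma_z = d_z if sigma_z is None else sigma_z
    if sigma_k < 0 or sigma_z < 0:
        raise InvalidParameterError("kernel widths must be non-negative")
    sig_px = (sigma_z / m.dz, sigma_k / m.dk)
    values = ndimage.gaussian_filter(m.values, sigma=sig_px, mode="nearest")
    return PWVDMap(values=values, k_axis=m.k_axis, z_axis=m.z_axis,
                   kernel_widths=(sigma_k, sigma_z))


def _ridge_dp(corr: np.ndarray, penalty: float, max_step: int):
    """Dynamic-programming ridge through a (n_shift, n_k) score matrix.

    Maximizes the summed score minus ``penalty * step**2`` per column-to-column
    depth jump; forward pass plus backward traceback.
    """
    n_s, n_k = corr.shape
    steps = np.arange(-max_step, max_step + 1)
    cost = penalty * steps.astype(float) ** 2
    score = corr[:, 0].copy()
    back = np.zeros((n_s, n_k), dtype=np.int32)
    pad = np.full(max_step, -np.inf)
    for j in range(1, n_k):
        padded = np.concatenate([pad, score, pad])
        # candidate[i, s] = score[i + steps[s]] - cost[s]
        cand = np.lib.stride_tricks.sliding_window_view(padded, 2 * max_step + 1)
        cand = cand - cost[::-1]
        best = np.argmax(cand, axis=1)
        score = cand[np.arange(n_s), best] + corr[:, j]
        back[:, j] = best - max_step  # step taken *backwards* (i_prev = i + step)
    path = np.empty(n_k, dtype=np.int32)
    path[-1] = int(np.argmax(score))
    for j in range(n_k - 1, 0, -1):
        path[j - 1] = path[j] + back[path[j], j]
    return path


def extract_displacement(m: PWVDMap, reference_policy: str = "max-power",
                         penalty: float = 0.1, *, max_step: int = 32,
                         power_threshold: float = 0.1,
                         band_halfwidth: int = 10):
    """Track the depth displacement ``delta_z(k)`` of the distribution.

    The reference column is the wavenumber of maximum total envelope power
    (ties break toward lower k), band-pass filtered to its dominant depth band
    (+- ``band_halfwidth`` pixels).  It is cross-correlated against every
    column; the correlation ridge is traced with a quadratic jump penalty and
    refined to sub-pixel precision by 3-point parabolic interpolation.
    Columns whose envelope power falls below ``power_threshold`` of the
    maximum are masked invalid.  ``delta_z`` is reported relative to the
    reference column.
    """
    if reference_policy != "max-power":
        raise InvalidParameterError(f"unknown reference policy {reference_policy!r}")
    v = m.values
    n_z, n_k = v.shape
    # column envelope power: the peak of the column's depth envelope.  Falls
    # off both under laser spectral roll-off and at the grid edges, where the
    # discrete WVD loses lag support and can no longer localise depth.
    power = v.max(axis=0)
    p_max = float(power.max())
    if p_max <= 0:
        raise NoSignalError("distribution carries no envelope power")
    valid = power >= power_threshold * p_max
    if not np.any(valid):
        raise NoSignalError("all columns below the envelope-power threshold")
    ref_idx = int(np.argmax(power))
    ref = v[:, ref_idx].copy()
    peak = int(np.argmax(ref))
    band = np.zeros(n_z, dtype=bool)
    band[max(0, peak - band_halfwidth):peak + band_halfwidth + 1] = True
    ref[~band] = 0.0
    # full cross-correlation via zero-padded FFT, shifts -n_z/2 .. n_z/2-1
    nfft = 2 * n_z
    ref_f = np.fft.rfft(ref, nfft)
    col_f = np.fft.rfft(v, nfft, axis=0)
    corr = np.fft.irfft(col_f * np.conj(ref_f)[:, None], nfft, axis=0)
    shifts = np.arange(-n_z // 2, n_z // 2)
    corr = corr[shifts % nfft, :]
    norms = np.sqrt(np.sum(v**2, axis=0)) * np.sqrt(np.sum(ref**2))
    corr = corr / np.where(norms > 0, norms, 1.0)
    path = _ridge_dp(corr, penalty, max_step)
    # 3-point parabolic sub-pixel refinement
    delta = np.zeros(n_k)
    for j in range(n_k):
        i = path[j]
        if 0 < i < corr.shape[0] - 1:
            ym, y0, yp = corr[i - 1, j], corr[i, j], corr[i + 1, j]
            denom = ym - 2 * y0 + yp
            if denom != 0:
                delta[j] = float(np.clip(0.5 * (ym - yp) / denom, -0.5, 0.5))
    pos = shifts[path] + delta
    delta_z = (pos - pos[ref_idx]) * m.dz
    return delta_z, valid


def phase_error_from_displacement(delta_z: np.ndarray, valid_mask: np.ndarray,
                                  n: float, k_axis: np.ndarray,
                                  detrend: bool = True) -> PhaseError:
    """Integrate the displacement into the spectral phase error.

    ``phi(k)`` is the cumulative trapezoidal integral of ``2 n delta_z(k)``
    over the longest contiguous valid region (which must span at least 25 % of
    the grid), extended as constant beyond it, then mean- and best-fit-line-
    removed so the gauge constant and any rigid image shift are absorbed.
    """
    delta_z = np.asarray(delta_z, dtype=float)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    n_k = delta_z.size
    # longest contiguous run of valid columns
    best_lo = best_hi = -1
    lo = None
    for i, ok in enumerate(np.concatenate([valid_mask, [False]])):
        if ok and lo is None:
            lo = i
        elif not ok and lo is not None:
            if i - lo > best_hi - best_lo:
                best_lo, best_hi = lo, i
            lo = None
    if best_hi - best_lo < 0.25 * n_k:
        raise NoSignalError(
            "fewer than 25% of columns form a contiguous valid region")
    region = slice(best_lo, best_hi)
    k = np.asarray(k_axis, dtype=float)
    phi = np.empty(n_k)
    phi_region = cumulative_trapezoid(2.0 * n * delta_z[region], k[region],
                                      initial=0.0)
    phi[region] = phi_region
    phi[:best_lo] = phi_region[0]
    phi[best_hi:] = phi_region[-1]
    mask = np.zeros(n_k, dtype=bool)
    mask[region] = True
    policy = "none"
    if detrend:
        coef = np.polynomial.polynomial.polyfit(k[mask], phi[mask], 1)
        phi = phi - np.polynomial.polynomial.polyval(k, coef)
        phi = phi - phi[mask].mean()
        policy = "mean-and-linear-removed"
    return PhaseError(phi=phi, displacement=delta_z, valid_mask=mask,
                      k_axis=k, integration_constant_policy=policy)


def compensate(ig, pe: PhaseError) -> np.ndarray:
    """Apply the phase correction: analytic signal times ``exp(-i phi(k))``.

    Accepts a k-domain :class:`Interferogram` (converted to its analytic
    signal) or an already-complex spectrum on the same grid.
    """
    if isinstance(ig, Interferogram):
        if ig.domain != "wavenumber":
            raise InvalidParameterError("compensate requires a k-domain interferogram")
        if ig.values.size != pe.k_axis.size or not np.allclose(
                ig.grid, pe.k_axis, rtol=0, atol=1e-9 * abs(pe.k_axis[-1])):
            raise GridMismatchError("interferogram grid does not match phase grid")
        sig = analytic_signal(ig)
    else:
        sig = np.asarray(ig)
        if sig.size != pe.k_axis.size:
            raise GridMismatchError("signal length does not match phase grid")
    return sig * np.exp(-1j * pe.phi)


def theoretical_ridge(profile: SweepProfile, f_m: float, p: int,
                      n: float, k_axis: np.ndarray) -> np.ndarray:
    """Predicted displacement of the p-th harmonic from the sweep-rate error.

    The virtual reference delay varies with the angular-acceleration error as
    ``delta_z(k) = p omega_m c / (2 n alpha0^2) * delta_alpha(t(k))`` in this
    package's sideband sign convention (the selected harmonic lowers the
    apparent fringe frequency).  ``t(k)`` inverts the sweep ``omega(t) = c k``.
    """
    t_dense = np.linspace(0.0, profile.t_sweep, 8193)
    omega_dense = profile.omega(t_dense)
    t_of_k = np.interp(np.asarray(k_axis) * C_LIGHT, omega_dense, t_dense)
    alpha = profile.alpha(t_of_k)
    delta_alpha = alpha - profile.alpha0
    omega_m = 2 * np.pi * f_m
    return p * omega_m * C_LIGHT / (2.0 * n * profile.alpha0**2) * delta_alpha


def estimate_phase_error(ig: Interferogram, n: float = 1.0, *,
                         sigma_k: float | None = None,
                         sigma_z: float | None = None,
                         penalty: float = 0.1,
                         detrend: bool = True) -> PhaseError:
    """Full pipeline: analytic signal -> PWVD -> ridge -> integrated phi(k)."""
    sig = analytic_signal(ig)
    m = pwvd(sig, ig.grid_step, k_axis=ig.grid, n_index=n,
             sigma_k=sigma_k, sigma_z=sigma_z)
    delta_z, valid = extract_displacement(m, penalty=penalty)
    return phase_error_from_displacement(delta_z, valid, n, ig.grid,
                                         detrend=detrend)
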