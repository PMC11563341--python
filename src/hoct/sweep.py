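"""Swept-source laser model.

A swept source is described by the instantaneous angular frequency of its
output, ``omega(t)``, over one active sweep window ``[0, t_sweep]`` with
``t_sweep = duty / rep_rate``.  ``omega(t)`` is a polynomial of degree at most
five; the optical phase ``phi(t)`` is its exact integral and the angular
acceleration ``alpha(t) = d omega / dt`` its exact derivative.  The nominal
(linear-sweep) acceleration is ``alpha0 = B * R / D`` where ``B`` is the swept
angular bandwidth, ``R`` the sweep repetition rate and ``D`` the duty cycle.

The auxiliary Mach-Zehnder interferometer ("k-clock") produces the fringe
``cos(phi(t) - phi(t - tau))`` whose instantaneous frequency tracks
``alpha(t) * tau / (2 pi)``; recovering a fifth-order polynomial sweep model
from its spectrogram is how a real source's non-linearity is characterised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial
from scipy import signal as _signal
from scipy.constants import c as C_LIGHT

from .errors import (
    AliasingError,
    DomainError,
    FitFailureError,
    InvalidParameterError,
    InvalidSweepError,
)

__all__ = [
    "SweepProfile",
    "KClock",
    "make_nominal_sweep",
    "make_perturbed_sweep",
    "default_perturbation",
    "evaluate_sweep",
    "synthesize_kclock",
    "fit_sweep_from_kclock",
]

_MONOTONE_GRID = 4097  # dense grid used for monotonicity / extrema checks


@dataclass(frozen=True)
class SweepProfile:
    """Laser frequency trajectory over one sweep.

    Parameters
    ----------
    omega_poly : tuple of float
        Ascending polynomial coefficients of the instantaneous angular
        frequency ``omega(t)`` in rad/s, with ``t`` in seconds from the sweep
        start.  Degree at most five.
    lambda0 : float
        Central wavelength in metres.
    bandwidth_ang : float
        Swept angular-frequency span ``B = omega(t_sweep) - omega(0)`` in
        rad/s.
    rep_rate : float
        Sweep repetition rate ``R`` in Hz.
    duty : float
        Duty cycle ``D`` in (0, 1]; only the active window is modeled.
    """

    omega_poly: tuple
    lambda0: float
    bandwidth_ang: float
    rep_rate: float
    duty: float

    @property
    def t_sweep(self) -> float:
        """Active sweep duration ``D / R`` in seconds."""
        return self.duty / self.rep_rate

    @property
    def alpha0(self) -> float:
        """Nominal angular acceleration ``B R / D`` in rad/s^2."""
        return self.bandwidth_ang * self.rep_rate / self.duty

    # -- polynomial views ---------------------------------------------------
    def _omega(self) -> Polynomial:
        return Polynomial(self.omega_poly)

    def omega(self, t):
        """Instantaneous angular frequency [rad/s]."""
        return self._omega()(np.asarray(t, dtype=float))

    def alpha(self, t):
        """Angular acceleration d(omega)/dt [rad/s^2]."""
        return self._omega().deriv()(np.asarray(t, dtype=float))

    def phase(self, t):
        """Optical phase, the running integral of omega with phase(0) = 0 [rad]."""
        return self._omega().integ(lbnd=0.0)(np.asarray(t, dtype=float))

    def wavenumber(self, t):
        """k(t) = omega(t) / c in rad/m."""
        return self.omega(t) / C_LIGHT


@dataclass(frozen=True)
class KClock:
    """Sampled Mach-Zehnder k-clock fringe."""

    values: np.ndarray
    sample_rate: float
    mzi_delay: float
    valid: np.ndarray = field(repr=False, default=None)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate


def _check_monotone(poly: Polynomial, t_sweep: float) -> None:
    t = np.linspace(0.0, t_sweep, _MONOTONE_GRID)
    d = poly.deriv()(t)
    if not np.all(d > 0):
        raise InvalidSweepError(
            "omega(t) must be strictly increasing over the sweep window"
        )


def make_nominal_sweep(lambda0: float, delta_lambda: float, rep_rate: float,
                       duty: float) -> SweepProfile:
    """Build the ideal linear sweep for a source of given optical parameters.

    The angular bandwidth follows from the wavelength span as
    ``B = 2 pi c delta_lambda / lambda0**2``; the sweep runs linearly from
    ``omega_c - B/2`` to ``omega_c + B/2`` over ``t_sweep = duty / rep_rate``.
    """
    if lambda0 <= 0 or delta_lambda <= 0 or rep_rate <= 0:
        raise InvalidParameterError("lambda0, delta_lambda, rep_rate must be positive")
    if not 0 < duty <= 1:
        raise InvalidParameterError("duty cycle must lie in (0, 1]")
    bandwidth_ang = 2 * np.pi * C_LIGHT * delta_lambda / lambda0**2
    t_sweep = duty / rep_rate
    omega_c = 2 * np.pi * C_LIGHT / lambda0
    alpha0 = bandwidth_ang / t_sweep
    omega_poly = (omega_c - bandwidth_ang / 2.0, alpha0)
    return SweepProfile(omega_poly, lambda0, bandwidth_ang, rep_rate, duty)


def make_perturbed_sweep(base: SweepProfile, perturb_poly) -> SweepProfile:
    """Add a frequency perturbation ``delta_omega(t)`` to a sweep.

    ``perturb_poly`` holds ascending coefficients of ``delta_omega(t)`` in
    rad/s.  The total polynomial degree must stay at or below five and the
    perturbed ``omega(t)`` strictly monotone.  The swept span is re-reported
    from the endpoint frequencies.
    """
    perturb = Polynomial(np.atleast_1d(np.asarray(perturb_poly, dtype=float)))
    total = base._omega() + perturb
    coeffs = np.trim_zeros(total.coef, trim="b")
    if coeffs.size == 0:
        coeffs = np.zeros(1)
    if coeffs.size - 1 > 5:
        raise InvalidSweepError("total omega(t) degree must be at most five")
    total = Polynomial(coeffs)
    _check_monotone(total, base.t_sweep)
    bandwidth_ang = float(total(base.t_sweep) - total(0.0))
    return SweepProfile(tuple(total.coef), base.lambda0, bandwidth_ang,
                        base.rep_rate, base.duty)


def default_perturbation(base: SweepProfile, rel_alpha_peak: float = 0.05):
    """Packaged fifth-order perturbation with a set peak |delta_alpha| / alpha0.

    The shape is a degree-five polynomial in ``u = t / t_sweep`` that vanishes
    at both sweep endpoints (so the swept span and hence the k grid are
    unchanged) and whose derivative peaks at ``rel_alpha_peak * alpha0``.  At
    the default 5 % level it visibly broadens first-harmonic images while
    keeping omega(t) monotone.
    """
    if rel_alpha_peak < 0:
        raise InvalidParameterError("rel_alpha_peak must be non-negative")
    T = base.t_sweep
    q = Polynomial.fromroots([0.0, 1.0, 0.3, 0.7, 0.5])
    u = np.linspace(0.0, 1.0, _MONOTONE_GRID)
    peak_dq = np.max(np.abs(q.deriv()(u)))
    scale = rel_alpha_peak * base.alpha0 * T / peak_dq
    # compose q(t / T) and rescale: coefficient j picks up T**-j
    coeffs = scale * q.coef / T ** np.arange(q.coef.size)
    return coeffs


def evaluate_sweep(profile: SweepProfile, t):
    """Return ``(omega, alpha, phase)`` of the sweep at times ``t``.

    ``phase`` is the exact polynomial integral of ``omega`` from 0;
    ``alpha`` the exact derivative.  Times outside ``[0, t_sweep]`` raise
    :class:`DomainError`.
    """
    t = np.asarray(t, dtype=float)
    tol = 1e-12 * profile.t_sweep
    if np.any(t < -tol) or np.any(t > profile.t_sweep + tol):
        raise DomainError("t outside the sweep window [0, t_sweep]")
    return profile.omega(t), profile.alpha(t), profile.phase(t)


def _peak_fringe_freq(profile: SweepProfile, mzi_delay: float) -> float:
    t = np.linspace(mzi_delay, profile.t_sweep, _MONOTONE_GRID)
    f = (profile.omega(t) - profile.omega(t - mzi_delay)) / (2 * np.pi)
    return float(np.max(np.abs(f)))


def synthesize_kclock(profile: SweepProfile, mzi_delay: float,
                      sample_rate: float) -> KClock:
    """Simulate the auxiliary-interferometer fringe ``cos(phi(t) - phi(t - tau))``.

    Sampled uniformly in time over one sweep; the first ``mzi_delay`` worth of
    samples (where the delayed arm predates the sweep) are flagged invalid.
    """
    if mzi_delay < 0:
        raise InvalidParameterError("mzi_delay must be non-negative")
    if sample_rate <= 0:
        raise InvalidParameterError("sample_rate must be positive")
    if mzi_delay > 0:
        f_peak = _peak_fringe_freq(profile, mzi_delay)
        if sample_rate < 2.0 * f_peak:
            raise AliasingError(
                f"sample rate {sample_rate:.3g} Hz under-samples the k-clock "
                f"fringe (peak {f_peak:.3g} Hz)"
            )
    n = int(np.floor(profile.t_sweep * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    values = np.cos(profile.phase(t) - profile.phase(t - mzi_delay))
    valid = t >= mzi_delay
    return KClock(values=values, sample_rate=sample_rate, mzi_delay=mzi_delay,
                  valid=valid)


def _spectrogram_ridge(x, fs, nperseg, noverlap):
    """STFT peak frequency per segment with parabolic sub-bin refinement.

    A Gaussian analysis window is used because the log-magnitude of a
    Gaussian-windowed tone is exactly parabolic, making the 3-point sub-bin
    interpolation unbiased.
    """
    freqs, times, sxx = _signal.spectrogram(
        x, fs=fs, window=("gaussian", nperseg / 6.0), nperseg=nperseg,
        noverlap=noverlap, detrend=False, mode="magnitude",
    )
    df = freqs[1] - freqs[0]
    f_est = np.empty(times.size)
    for i in range(times.size):
        col = sxx[:, i]
        p = int(np.argmax(col))
        if 0 < p < col.size - 1 and col[p] > 0:
            lm, l0, lp = np.log(col[p - 1] + 1e-300), np.log(col[p] + 1e-300), \
                np.log(col[p + 1] + 1e-300)
            denom = lm - 2 * l0 + lp
            delta = 0.5 * (lm - lp) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        f_est[i] = (p + delta) * df
    return times, f_est


def fit_sweep_from_kclock(kclock: KClock, sample_rate: float | None = None,
                          mzi_delay: float | None = None, *,
                          lambda0: float = 1060e-9, duty: float = 0.5,
                          degree: int = 5,
                          max_residual: float = 0.05) -> SweepProfile:
    """Recover a fifth-order sweep model from a recorded k-clock fringe.

    The spectrogram of the fringe (Gaussian window, 1/64 of the sweep samples,
    75 % overlap, parabolic sub-bin peak interpolation) yields the
    instantaneous fringe frequency ``f(t) = [omega(t) - omega(t - tau)] /
    (2 pi)``, which is linear in the polynomial coefficients of ``omega``
    and solved by least squares.  The fringe carries no information about
    the absolute optical frequency, so the constant coefficient is anchored
    to the centre wavelength ``lambda0``.

    Raises :class:`FitFailureError` (with diagnostics) when the relative
    spectrogram residual exceeds ``max_residual``.
    """
    fs = sample_rate if sample_rate is not None else kclock.sample_rate
    tau = mzi_delay if mzi_delay is not None else kclock.mzi_delay
    if tau <= 0:
        raise InvalidParameterError("mzi_delay must be positive for fitting")
    x = np.asarray(kclock.values, dtype=float)
    n = x.size
    T = (n - 1) / fs
    nperseg = max(16, n // 64)
    noverlap = (3 * nperseg) // 4
    times, f_meas = _spectrogram_ridge(x, fs, nperseg, noverlap)
    # drop segments overlapping the invalid start-of-sweep region
    keep = times - 0.5 * nperseg / fs >= tau
    times, f_meas = times[keep], f_meas[keep]
    if times.size < degree + 2:
        raise FitFailureError("too few spectrogram segments for the fit",
                              {"n_segments": int(times.size)})
    u = times / T
    tau_u = tau / T
    powers = np.arange(1, degree + 1)
    design = (u[:, None] ** powers - (u[:, None] - tau_u) ** powers) / (2 * np.pi)
    b, *_ = np.linalg.lstsq(design, f_meas, rcond=None)
    resid = f_meas - design @ b
    rel_resid = float(np.sqrt(np.mean(resid**2)) / np.mean(np.abs(f_meas)))
    if rel_resid > max_residual:
        raise FitFailureError(
            f"spectrogram fit residual {rel_resid:.3g} exceeds {max_residual:.3g}",
            {"rel_residual": rel_resid, "n_segments": int(times.size)},
        )
    omega_c = 2 * np.pi * C_LIGHT / lambda0
    b0 = omega_c - float(np.sum(b / (powers + 1)))
    coeffs_u = np.concatenate([[b0], b])
    coeffs_t = coeffs_u / T ** np.arange(coeffs_u.size)
    poly = Polynomial(coeffs_t)
    _check_monotone(poly, T)
    bandwidth_ang = float(poly(T) - poly(0.0))
    rep_rate = duty / T
    return SweepProfile(tuple(poly.coef), lambda0, bandwidth_ang, rep_rate, duty)
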