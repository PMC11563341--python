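# Methods

## Physical model

### Sweep

A sweep is the instantaneous angular frequency `omega(t)` of the laser over
one active window `[0, t_sweep]`, `t_sweep = D / R` (duty cycle over
repetition rate). `omega(t)` is a polynomial of degree ≤ 5; the optical phase
`phi(t)` is its exact integral and the angular acceleration
`alpha(t) = d omega/dt` its exact derivative, so the three views are always
mutually consistent to machine precision. Only the active window is modeled;
flyback is ignored. The nominal acceleration is `alpha0 = B R / D` with the
angular bandwidth `B = 2 pi c * delta_lambda / lambda0^2`; because the
bandwidth of a perturbed profile is re-reported from its endpoint
frequencies, `alpha0` always equals the sweep-mean acceleration.

Wavenumber convention: `k = omega / c` in rad/m; all fringe phases are
double-pass, `2 n k z`.

The packaged non-linearity is a degree-5 polynomial in `u = t / t_sweep`
that vanishes at both endpoints (the swept span, and hence the k grid, is
unchanged) scaled so that the peak `|delta_alpha| / alpha0` equals a
requested level, 5 % by default — enough to visibly blur first-harmonic
images while keeping the sweep monotone.

### Interferogram

A reflector at depth `z_s` in a medium of index `n` delays the sample field
by `tau_s = 2 n z_s / c`. With perfect balanced detection only the
interference term survives:

    I(t) = sum_s  A_r A_s cos( phi(t - tau_s) - phi(t) + m(t) ) ,

`m(t)` the electro-optic reference-arm modulation. Sine modulation
`m(t) = A_m sin(omega_m t)` splits the fringe into harmonics with
Jacobi-Anger amplitudes `J_p(A_m)`; `J_1` peaks at `A_m ≈ 1.841 rad` with
value 0.582 (−4.7 dB in intensity), the built-in optimum. The *selected*
sideband is the one that lowers the apparent fringe frequency, so harmonic
`p` images at apparent depth `z_s - delta_z` with
`delta_z = p omega_m c / (2 n alpha0)`; reconstruction adds `delta_z` back.
In `linear-term` mode the selected harmonic is isolated exactly by the pure
phase ramp `m(t) = p omega_m t`, which is how the dispersion studies are
run; `exact-sine` mode produces all harmonics and is used for sideband and
SNR metrology.

Aliasing is checked against the instantaneous frequency of every significant
component. Since GHz-band sine modulation creates harmonics far beyond the
digitiser Nyquist rate, and a digital filter applied after sampling cannot
undo aliasing, enabling the anti-alias filter makes the simulator generate
the signal at an internally oversampled rate, apply an ideal brick-wall
low-pass (the hardware filter before the ADC), and decimate onto the
requested grid. Without the filter, out-of-band components raise an error.

The hardware k-clock is modeled as linear interpolation of the time-sampled
fringe onto a uniform grid of `k(t) = omega(t)/c`, spanning the k extremes of
the sampled window. Note a real consequence kept deliberately: linear
interpolation attenuates fringes that approach the Nyquist rate, so deep
reflectors lose amplitude in a way no phase correction can restore. The
defaults (640 samples at 550 MHz over the 1.25 µs sweep) cover 93 % of the
sweep — the stated 550 MHz is a peak k-clock rate, so a uniform-in-time grid
at that rate cannot span the whole sweep.

### Sweep recovery from the k-clock

The auxiliary Mach-Zehnder fringe `cos(phi(t) - phi(t - tau))` has
instantaneous frequency `[omega(t) - omega(t - tau)] / 2 pi ≈ alpha(t) tau /
2 pi`. Its spectrogram (Gaussian window of 1/64 of the sweep samples, 75 %
overlap) is reduced to a frequency track by 3-point parabolic interpolation
of the log magnitude — with a Gaussian window that interpolation is exactly
unbiased for a tone, which is why Gaussian is preferred over Hann here: the
Hann bias was large enough to break the round-trip contraction property.
The finite difference `omega(t) - omega(t - tau)` is linear in the
polynomial coefficients, so a degree-5 model is recovered by linear least
squares; the fringe carries no information about the absolute optical
frequency, so the constant term is anchored to a supplied centre wavelength
(default 1060 nm). Relative residuals above 5 % raise a fit failure with
diagnostics.

## Dispersion estimation and compensation

Sweep-rate variability leaves the harmonic fringe, resampled in k, with a
residual spectral phase `phi_err(k)`; its derivative displaces the apparent
depth by `delta_z(k) = phi_err'(k) / 2n`. The estimator:

1. **Analytic signal** (Hilbert transform) of the mean-zero k-domain fringe.
   This suppresses the negative-frequency half and with it the worst
   quadratic cross terms before any Wigner-Ville processing.
2. **Discrete WVD** `S(k, z) = FFT_kappa[ f(k + kappa/2) conj(f(k - kappa/2)) ]`.
   Half-integer lags are realised by 2× band-limited interpolation of the
   signal, avoiding the even/odd-lag ambiguity of the discrete WVD. Summing a
   column over depth recovers `|f(k)|^2` exactly (the lag-0 term), which the
   tests use as a marginal invariant.
3. **Pseudo-WVD**: separable Gaussian smoothing. Defaults
   `sigma_k = (k span)/48`, `sigma_z = 0.5` depth pixel. Rationale: cross
   terms between components separated in depth oscillate rapidly *along k*,
   so the k kernel kills them (measured ≥ 100× on a two-tone fixture) while
   a curved ridge is biased by only ~(sigma_k^2/2) z''(k), under two depth
   pixels for the packaged 5 % perturbation; the z kernel is kept minimal so
   tone auto-terms lose less than 2× peak. A wider k kernel also regularises
   the extracted ridge — the width is a bias/variance compromise, and
   span/48 balances ridge fidelity against the phase-noise floor of the
   integrated correction.
4. **Ridge extraction**: the reference column (maximum envelope power, ties
   to lower k) is band-pass filtered to its dominant depth band (±10 pixels)
   and cross-correlated against every column (zero-padded FFT correlation,
   per-column normalised). The correlation ridge is traced by dynamic
   programming maximising correlation minus `0.1 × (step in pixels)^2`,
   forward pass plus backward traceback, then refined by 3-point parabolic
   interpolation. Columns whose envelope *peak* falls below 10 % of the
   maximum are masked invalid — the peak (not the marginal) is used because
   it also drops where the discrete WVD loses lag support at the grid edges,
   which is exactly where the ridge stops being trustworthy even for a flat
   laser spectrum.
5. **Integration**: `phi(k) = int 2 n delta_z(k) dk` by cumulative
   trapezoid over the longest contiguous valid run (must cover ≥ 25 % of the
   grid), constant-extended beyond it. The `2n` factor follows from the
   double-pass fringe phase `2 n k z`, which dimensional analysis requires
   even though the displacement-integral relation is often quoted without
   it. The mean and the best-fit line are then removed: the integration
   constant and any rigid image shift are gauge freedoms, and the policy is
   recorded on the result.
6. **Compensation** multiplies the analytic signal by `exp(-i phi(k))`.
   Applying the same factor to the *real* spectrum instead sharpens the true
   image while doubling the phase error of its conjugate — useful when the
   conjugate is deliberately kept in frame, and covered by a test.

A phase estimated from one column (or one B-scan) can be re-applied to the
rest of the frame — the pipeline estimates once, from the column of maximum
fringe energy, and reuses it; a container flag guards against double
application.

## Flattening and curvature reconstruction

`parabolic_schedule` inverts the shift law per column: a column a normalised
lateral distance `u` from the apex of a surface with sag `s` receives
`f_m(u) = f_center + s u^2 / (shift per Hz)`, clipped to the VCO range with
per-column flags (entirely out-of-range schedules are an error). A-scans are
formed by windowed FFT (default Hann) on a signed depth axis, zero at zero
path difference; an `oversample` factor zero-pads the transform for
scallop-free peak metrology. Curvature reconstruction translates each column
by its programmed shift in integer pixels onto a canvas of height
`n_samples + max shift`, recording the sub-pixel remainder on the column
instead of interpolating (magnitude images stay crisp; geometry is preserved
in metadata). Flatten → reconstruct is the identity on surface geometry to
within one depth pixel, verified on a 12.5 mm × 4 mm concave surface of 256
columns, where the flattened frame holds the true and conjugate images in
disjoint depth bands.

## What the synthetic world does and does not contain

The simulator carries: polynomial sweep non-linearity, the full modulation
physics (all sine harmonics, Bessel weights), balanced detection, linear-in-k
resampling with its interpolation droop, optional white Gaussian detector
noise (seeded; off by default, since no specific noise model is claimed),
and curved layered phantoms. It does **not** carry: laser intensity
envelope/roll-off (the source is treated as perfectly coherent), speckle,
multiple scattering, material dispersion, polarisation, detector saturation,
or k-clock jitter beyond the sweep polynomial. A green suite therefore
establishes the signal-processing chain — harmonic formation, shift law,
dispersion genesis and cure, flattening geometry — not radiometric
performance; measured SNR roll-off of a physical instrument is out of reach
of this model.

Scene defaults used in the end-to-end checks: first harmonic, `f_m` in the
1–2 GHz VCO band (centre 1.2 GHz), target apparent depth 0.5 mm — the upper
part of the 1.9 mm window, as curved-sample imaging uses in practice. The
amplitude-recovery check is sensitive to this choice for a physical reason:
deeper apparent depths push the fringe toward Nyquist where the k-clock
*interpolation* (not dispersion) eats amplitude.

## Numerical choices and edge cases

- Monotonicity of `omega(t)` is enforced on a dense grid at construction;
  violations raise immediately rather than corrupting the k grid.
- Sub-pixel peaks everywhere use 3-point parabolic interpolation, clipped to
  ±0.5 pixel; ties in the reference-column choice break toward lower k.
- The balanced-detection invariant (mean-zero fringe) is enforced by
  subtracting the sample mean; a zero-depth reflector therefore vanishes.
- CSV round trips are bit-exact (`%.17g` out, `float_precision="round_trip"`
  in); HDF5 datasets are written with `track_times=False` so identical runs
  produce identical containers.
- All randomness (detector noise, phantom amplitude jitter) flows from a
  single integer seed recorded in the container provenance.

## Known limitations

- The ridge tracker assumes one dominant displacement ridge; heavily
  multi-band samples with *different* per-band phase errors (depth-dependent
  dispersion, i.e. time-domain sampling) are diagnosed but not corrected.
- A phase estimated at one modulation frequency is reused unscaled across a
  schedule; for sweep-induced errors the true `phi` scales with `omega_m`,
  so strongly varying schedules receive a first-order correction only.
- The k-clock fit anchors the absolute frequency to a stated centre
  wavelength; an error there shifts `omega(t)` rigidly (harmless to fringe
  formation, which depends on frequency differences).
- Depth shifts are non-negative in curvature reconstruction (`p ≥ 1`
  schedules); negative-order sidebands would need a sign-extended canvas.
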