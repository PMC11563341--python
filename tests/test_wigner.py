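"""Wigner-Ville analysis, ridge extraction, phase integration, compensation."""

import numpy as np
import pytest

import hoct
from hoct.errors import GridMismatchError, InvalidParameterError, NoSignalError
from hoct.simulate import Interferogram

N = 256
DK = 830.0
K = np.arange(N) * DK + 5.2e5


def tone(z):
    return np.exp(1j * 2 * z * (K - K[0]))


def as_interferogram(values):
    return Interferogram(values=values, domain="wavenumber", grid=K)


class TestAnalyticSignal:
    def test_tone_has_flat_envelope(self):
        x = np.cos(2 * 0.6e-3 * (K - K[0]))
        sig = hoct.analytic_signal(as_interferogram(x - x.mean()))
        env = np.abs(sig[48:-48])
        assert np.all(np.abs(env - 1.0) < 0.01)

    def test_real_part_round_trip(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(N)
        x -= x.mean()
        sig = hoct.analytic_signal(as_interferogram(x))
        assert np.allclose(sig.real, x, atol=1e-9 * np.std(x))

    def test_chirp_instantaneous_frequency(self):
        rate = 2 * 0.4e-3 / (K[-1] - K[0])
        phase = 2 * 0.3e-3 * (K - K[0]) + 0.5 * rate * (K - K[0]) ** 2
        x = np.cos(phase)
        sig = hoct.analytic_signal(as_interferogram(x - x.mean()))
        inst = np.gradient(np.unwrap(np.angle(sig)), K)
        expected = 2 * 0.3e-3 + rate * (K - K[0])
        interior = slice(32, -32)
        assert np.allclose(inst[interior], expected[interior], rtol=0.01)

    def test_rejects_time_domain(self):
        ig = Interferogram(values=np.zeros(N), domain="time", grid=K)
        with pytest.raises(InvalidParameterError):
            hoct.analytic_signal(ig)


class TestWVD:
    def test_tone_ridge_constant(self):
        z0 = 0.5e-3
        m = hoct.wvd(tone(z0), DK, k_axis=K)
        ridge = m.z_axis[np.argmax(m.values, axis=0)]
        interior = slice(16, -16)
        assert np.all(np.abs(ridge[interior] - z0) <= m.dz)

    def test_linear_chirp_lies_on_line(self):
        z_lo, z_hi = 0.25e-3, 0.55e-3
        rate = 2 * (z_hi - z_lo) / (K[-1] - K[0])
        phase = 2 * z_lo * (K - K[0]) + 0.5 * rate * (K - K[0]) ** 2
        m = hoct.wvd(np.exp(1j * phase), DK, k_axis=K)
        ridge = m.z_axis[np.argmax(m.values, axis=0)]
        theory = z_lo + (z_hi - z_lo) * (K - K[0]) / (K[-1] - K[0])
        interior = slice(16, -16)
        rms = np.sqrt(np.mean((ridge - theory)[interior] ** 2)) / m.dz
        assert rms <= 1.0

    def test_two_tone_cross_term_at_midpoint(self):
        z1, z2 = 0.3e-3, 0.8e-3
        m = hoct.wvd(tone(z1) + tone(z2), DK, k_axis=K)

        def band_peak(z0):
            i = np.argmin(np.abs(m.z_axis - z0))
            return np.abs(m.values[i - 3:i + 4, :]).max()

        # the oscillatory cross term is comparable to the auto terms
        assert band_peak((z1 + z2) / 2) > 0.5 * band_peak(z1)

    def test_marginal_recovers_spectrum(self):
        sig = tone(0.3e-3) + 0.5 * tone(0.8e-3)
        m = hoct.wvd(sig, DK, k_axis=K)
        marginal = m.values.sum(axis=0)
        expected = N * np.abs(sig) ** 2
        interior = slice(32, -32)
        assert np.allclose(marginal[interior], expected[interior], rtol=0.01)


class TestPWVD:
    def test_cross_term_suppression(self):
        z1, z2 = 0.3e-3, 0.8e-3
        sig = tone(z1) + tone(z2)
        m0 = hoct.wvd(sig, DK, k_axis=K)
        mp = hoct.pwvd(sig, DK, k_axis=K)

        def band_peak(m, z0):
            i = np.argmin(np.abs(m.z_axis - z0))
            return np.abs(m.values[i - 3:i + 4, :]).max()

        mid = (z1 + z2) / 2
        assert band_peak(m0, mid) / band_peak(mp, mid) >= 10.0
        assert band_peak(m0, z1) / band_peak(mp, z1) <= 2.0

    def test_delta_kernel_limit(self):
        sig = tone(0.3e-3) + tone(0.8e-3)
        m0 = hoct.wvd(sig, DK, k_axis=K)
        ms = hoct.pwvd(sig, DK, k_axis=K, sigma_k=0.0, sigma_z=0.0)
        scale = np.sqrt(np.mean(m0.values**2))
        assert np.sqrt(np.mean((ms.values - m0.values) ** 2)) < 1e-6 * scale

    def test_dispersion_free_invariance(self):
        m = hoct.pwvd(tone(0.6e-3), DK, k_axis=K)
        delta_z, valid = hoct.extract_displacement(m)
        assert np.all(np.abs(delta_z[valid]) < 0.2 * m.dz)


class TestExtractDisplacement:
    def test_rigid_shift_recovered(self):
        m = hoct.pwvd(tone(0.6e-3), DK, k_axis=K)
        shift_px = 7
        rolled = hoct.PWVDMap(values=np.roll(m.values, shift_px, axis=0),
                              k_axis=m.k_axis, z_axis=m.z_axis,
                              kernel_widths=m.kernel_widths)
        # reference column still peaks at the rolled position, so delta_z
        # relative to the reference must be zero everywhere
        delta_z, valid = hoct.extract_displacement(rolled)
        assert np.all(np.abs(delta_z[valid]) < 0.5 * m.dz)

    def test_no_signal_error(self):
        m = hoct.PWVDMap(values=np.zeros((N, N)), k_axis=K,
                         z_axis=np.arange(N) * 1e-6)
        with pytest.raises(NoSignalError):
            hoct.extract_displacement(m)


class TestPhaseErrorFromDisplacement:
    def test_zero_displacement(self):
        pe = hoct.phase_error_from_displacement(
            np.zeros(N), np.ones(N, bool), 1.0, K)
        assert np.allclose(pe.phi, 0.0, atol=1e-12)

    def test_constant_displacement_detrends_to_zero(self):
        """A rigid shift is a pure linear phase: no blur once detrended."""
        pe = hoct.phase_error_from_displacement(
            np.full(N, 3e-6), np.ones(N, bool), 1.0, K)
        assert np.allclose(pe.phi, 0.0, atol=1e-9)

    def test_linear_displacement_gives_quadratic_phase(self):
        n_idx = 1.4
        a = 5e-9 / DK
        kc = K.mean()
        delta_z = a * (K - kc)
        pe = hoct.phase_error_from_displacement(
            delta_z, np.ones(N, bool), n_idx, K)
        expected = n_idx * a * (K - kc) ** 2
        expected -= np.polynomial.polynomial.polyval(
            K, np.polynomial.polynomial.polyfit(K, expected, 1))
        expected -= expected.mean()
        scale = np.max(np.abs(expected))
        assert np.allclose(pe.phi, expected, atol=1e-6 * scale)

    def test_insufficient_valid_region(self):
        valid = np.zeros(N, bool)
        valid[:N // 8] = True
        with pytest.raises(NoSignalError):
            hoct.phase_error_from_displacement(np.zeros(N), valid, 1.0, K)


class TestCompensate:
    def test_zero_phase_is_identity(self):
        x = np.cos(2 * 0.6e-3 * (K - K[0]))
        x -= x.mean()
        ig = as_interferogram(x)
        pe = hoct.PhaseError(phi=np.zeros(N), displacement=np.zeros(N),
                             valid_mask=np.ones(N, bool), k_axis=K)
        out = hoct.compensate(ig, pe)
        assert np.allclose(out, hoct.analytic_signal(ig))

    def test_known_quadratic_inverse(self):
        """Injecting exp(i phi) then compensating with phi is exact."""
        phi = 8.0 * ((K - K.mean()) / (K[-1] - K[0])) ** 2
        clean = tone(0.6e-3)
        dispersed = clean * np.exp(1j * phi)
        pe = hoct.PhaseError(phi=phi, displacement=np.zeros(N),
                             valid_mask=np.ones(N, bool), k_axis=K)
        out = hoct.compensate(dispersed, pe)
        a0 = hoct.ascan(clean, K)
        a1 = hoct.ascan(out, K)
        rms = np.sqrt(np.mean(np.abs(a1.profile - a0.profile) ** 2))
        assert rms < 1e-6 * np.max(np.abs(a0.profile))

    def test_grid_mismatch(self):
        pe = hoct.PhaseError(phi=np.zeros(N // 2),
                             displacement=np.zeros(N // 2),
                             valid_mask=np.ones(N // 2, bool),
                             k_axis=K[:N // 2])
        with pytest.raises(GridMismatchError):
            hoct.compensate(tone(0.5e-3), pe)

    def test_conjugate_blur_doubles(self, nominal, perturbed, acq, peak_tools):
        """Applying exp(-i phi) to the real spectrum sharpens the true image
        and doubles the phase error of its conjugate."""
        _, fwhm_bins = peak_tools
        f_m = 1.2e9
        z_s = hoct.predicted_shift(f_m, 1, nominal) + 0.5e-3
        phant = hoct.ReflectorPhantom(((z_s, 1.0),))
        mod = hoct.ModulationSpec(f_m=f_m, A_m=1.841, p_select=1,
                                  mode="linear-term")
        ig = hoct.simulate_interferogram(perturbed, phant, mod, acq)
        igk = hoct.resample_linear_in_k(ig, perturbed)
        pe = hoct.estimate_phase_error(igk, n=1.0)
        corrected_real = igk.values * np.exp(-1j * pe.phi)
        a = hoct.ascan(corrected_real, igk.grid, oversample=4)
        mag, z = np.abs(a.profile), a.z_axis
        pos = mag.copy()
        pos[z <= 0] = 0
        neg = mag.copy()
        neg[z >= 0] = 0
        a_raw = hoct.ascan(igk.values, igk.grid, oversample=4)
        raw = np.abs(a_raw.profile)
        raw_pos = raw.copy()
        raw_pos[z <= 0] = 0
        assert fwhm_bins(pos) < 0.6 * fwhm_bins(raw_pos)  # true image sharpens
        # conjugate is blurrier than the uncorrected image
        assert neg.max() < 0.8 * pos.max()


class TestEstimatorConsistency:
    def test_phase_matches_ground_truth(self, nominal, perturbed, acq):
        """PWVD-estimated phi(k) agrees with the simulation ground truth up to
        constant + linear terms within 0.5 rad RMS on the valid region."""
        f_m = 1.2e9
        z_s = hoct.predicted_shift(f_m, 1, nominal) + 0.5e-3
        phant = hoct.ReflectorPhantom(((z_s, 1.0),))
        mod = hoct.ModulationSpec(f_m=f_m, A_m=1.841, p_select=1,
                                  mode="linear-term")
        igk = hoct.resample_linear_in_k(
            hoct.simulate_interferogram(perturbed, phant, mod, acq), perturbed)
        igk0 = hoct.resample_linear_in_k(
            hoct.simulate_interferogram(nominal, phant, mod, acq), nominal)
        gt = np.unwrap(np.angle(hoct.analytic_signal(igk))) \
            - np.unwrap(np.angle(hoct.analytic_signal(igk0)))
        pe = hoct.estimate_phase_error(igk, n=1.0)
        resid = pe.phi - gt
        k, v = igk.grid, pe.valid_mask
        coef = np.polynomial.polynomial.polyfit(k[v], resid[v], 1)
        resid = resid - np.polynomial.polynomial.polyval(k, coef)
        assert np.sqrt(np.mean(resid[v] ** 2)) <= 0.5

    def test_ground_truth_and_estimate_agree_on_position(
            self, nominal, perturbed, acq, peak_tools):
        subpixel_peak, _ = peak_tools
        f_m = 1.2e9
        z_s = hoct.predicted_shift(f_m, 1, nominal) + 0.5e-3
        phant = hoct.ReflectorPhantom(((z_s, 1.0),))
        mod = hoct.ModulationSpec(f_m=f_m, A_m=1.841, p_select=1,
                                  mode="linear-term")
        igk = hoct.resample_linear_in_k(
            hoct.simulate_interferogram(perturbed, phant, mod, acq), perturbed)
        igk0 = hoct.resample_linear_in_k(
            hoct.simulate_interferogram(nominal, phant, mod, acq), nominal)
        gt_phi = np.unwrap(np.angle(hoct.analytic_signal(igk))) \
            - np.unwrap(np.angle(hoct.analytic_signal(igk0)))
        k = igk.grid
        coef = np.polynomial.polynomial.polyfit(k, gt_phi, 1)
        gt_phi = gt_phi - np.polynomial.polynomial.polyval(k, coef)
        gt_pe = hoct.PhaseError(phi=gt_phi, displacement=np.zeros(k.size),
                                valid_mask=np.ones(k.size, bool), k_axis=k)
        est_pe = hoct.estimate_phase_error(igk, n=1.0)
        pk_gt = subpixel_peak(np.abs(hoct.ascan(
            hoct.compensate(igk, gt_pe), k).profile))
        pk_est = subpixel_peak(np.abs(hoct.ascan(
            hoct.compensate(igk, est_pe), k).profile))
        assert abs(pk_gt - pk_est) <= 1.0
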