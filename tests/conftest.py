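import numpy as np
import pytest

import hoct

# nominal source: 1060 nm centre, 95 nm span, 400 kHz, 50 % duty
NOMINAL = dict(lambda0=1060e-9, delta_lambda=95e-9, rep_rate=400e3, duty=0.5)


@pytest.fixture(scope="session")
def nominal():
    return hoct.make_nominal_sweep(**NOMINAL)


@pytest.fixture(scope="session")
def perturbed(nominal):
    """Fifth-order sweep with peak |delta_alpha|/alpha0 = 5 %."""
    return hoct.make_perturbed_sweep(
        nominal, hoct.default_perturbation(nominal, 0.05))


@pytest.fixture(scope="session")
def acq():
    return hoct.AcquisitionSpec()


def subpixel_peak(mag):
    """Index of the magnitude peak with 3-point parabolic refinement."""
    mag = np.asarray(mag)
    j = int(np.argmax(mag))
    if 0 < j < mag.size - 1:
        denom = mag[j - 1] - 2 * mag[j] + mag[j + 1]
        if denom != 0:
            return j + 0.5 * (mag[j - 1] - mag[j + 1]) / denom
    return float(j)


def fwhm_bins(mag):
    """Full width at half maximum of the dominant peak, in (possibly
    oversampled) bins, by linear interpolation of the half crossings."""
    mag = np.asarray(mag)
    i = int(np.argmax(mag))
    half = mag[i] / 2.0
    lo = i
    while mag[lo] > half:
        lo -= 1
    hi = i
    while mag[hi] > half:
        hi += 1
    left = lo + (half - mag[lo]) / (mag[lo + 1] - mag[lo])
    right = hi - 1 + (mag[hi - 1] - half) / (mag[hi - 1] - mag[hi])
    return right - left


@pytest.fixture(scope="session")
def peak_tools():
    return subpixel_peak, fwhm_bins
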