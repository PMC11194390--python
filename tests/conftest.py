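import numpy as np
import pytest

from pulsekfd.preprocess import admissible_theta, synth_gaussian_beat
from pulsekfd.synthetic_cohort import CohortSpec, build_cohort
from pulsekfd.wk4_simulator import HemodynamicProfile, make_inflow


@pytest.fixture(scope="session")
def reference_profile():
    """Cohort-mean WK4 subject (SV 61.7 mL, AC 1.03 mL/mmHg, R 0.78)."""
    return HemodynamicProfile(
        C1_baseline=1.03,
        C2=0.08 * 1.03,
        R=0.78,
        SV=61.7,
        HR=1.0 / 0.82,
        C1_modulation=0.3,
    )


@pytest.fixture(scope="session")
def reference_inflow(reference_profile):
    p = reference_profile
    return make_inflow(p.SV, p.HR, p.T_systole_fraction, 500.0)


@pytest.fixture(scope="session")
def cohort_varying():
    """200-subject time-varying-C1 cohort with morphology features."""
    return build_cohort(CohortSpec(n_subjects=200, seed=1, model="varying"))


@pytest.fixture(scope="session")
def cohort_fixed():
    return build_cohort(CohortSpec(n_subjects=200, seed=1, model="fixed"))


def make_admissible_beat(params, n=410, fs=500.0, hr=1.22):
    """Synthesize an admissible 5-Gaussian beat rescaled to unit maximum.

    Amplitudes enter the model linearly, so dividing the two free amplitude
    parameters by the waveform maximum rescales the whole beat to max 1
    while keeping the parameter vector admissible.
    """
    theta = admissible_theta(*params)
    beat = synth_gaussian_beat(theta, n, fs, hr)
    g = float(beat.samples.max())
    theta[0] /= g
    theta[3] /= g
    return theta, synth_gaussian_beat(theta, n, fs, hr)


ADMISSIBLE_BEAT_PARAMS = [
    # a1, c1, w1, a2, d2, w2, u1, v1, wr1, u2, v2, wr2, u3, v3, wr3
    [1.0, 0.18, 0.07, 0.45, 0.10, 0.09, 0.55, 0.30, 0.09, 0.7, 0.35, 0.11, 0.6, 0.4, 0.13],
    [0.9, 0.15, 0.05, 0.50, 0.12, 0.08, 0.60, 0.25, 0.08, 0.6, 0.40, 0.10, 0.5, 0.5, 0.12],
    [1.1, 0.22, 0.06, 0.35, 0.08, 0.10, 0.50, 0.35, 0.10, 0.8, 0.30, 0.12, 0.7, 0.35, 0.14],
]
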