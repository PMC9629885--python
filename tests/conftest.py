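import numpy as np
import pytest

import ada_affinity as aa
from ada_affinity.pipeline import analyze_study


@pytest.fixture(scope="session")
def dose_series():
    """The assay's 8-point, 5-fold series from 1000 ng/mL (molar doses)."""
    return aa.make_dose_series()


@pytest.fixture(scope="session")
def mono_truth():
    return aa.BindingParamsMono(ab=1000.0, kd=2e-12)


@pytest.fixture(scope="session")
def bi_truth():
    return aa.BindingParamsBi(ab1=500.0, kd1=1e-12, ab2=500.0, kd2=1e-9)


@pytest.fixture(scope="session")
def noiseless_mono_curve(dose_series, mono_truth):
    signals = aa.response_mono(dose_series.doses_molar, mono_truth)
    return aa.AffinityCurve("mono0", dose_series.doses_molar, signals)


@pytest.fixture(scope="session")
def noiseless_bi_curve(dose_series, bi_truth):
    signals = aa.response_bi(dose_series.doses_molar, bi_truth)
    return aa.AffinityCurve("bi0", dose_series.doses_molar, signals)


def lognormal_noise(signals: np.ndarray, cv: float, rng) -> np.ndarray:
    """Mean-preserving multiplicative log-normal noise at the given CV."""
    sigma = np.sqrt(np.log1p(cv**2))
    return signals * rng.lognormal(-0.5 * sigma**2, sigma, signals.size)


@pytest.fixture(scope="session")
def default_study():
    """One simulated default scenario (seed 1) analysed end to end; shared
    across tests because the 27 curve fits dominate suite runtime."""
    scenario = aa.default_scenario(seed=1)
    curves, truth = aa.simulate_study(scenario)
    results, trajectories = analyze_study(curves)
    return {
        "scenario": scenario,
        "curves": curves,
        "truth": truth,
        "results": results,
        "trajectories": trajectories,
    }
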