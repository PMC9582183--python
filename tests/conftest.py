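import numpy as np
import pytest

from metaif import (
    ConcentrationCurve,
    ParametricFamily,
    PKParameters,
    TimeGrid,
    simulate_tissue_curve,
)

STUDY_N_FRAMES = 46
STUDY_DT = 11.9


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def study_grid():
    """The study's acquisition grid: 46 frames every 11.9 s."""
    return TimeGrid(np.arange(STUDY_N_FRAMES) * STUDY_DT)


@pytest.fixture
def gamma_aif(study_grid):
    """Gamma-variate AIF on the study grid, peak 5 mmol/L, 4 baseline frames."""
    t = study_grid.times
    tau = np.maximum(t - t[4], 0.0) / 60.0  # minutes post bolus
    shape = np.where(tau > 0, tau ** 1.719 * np.exp(-tau / 0.237), 0.0)
    values = 5.0 * shape / shape.max()
    return ConcentrationCurve(study_grid, values)


@pytest.fixture
def tissue_curve(gamma_aif):
    return simulate_tissue_curve(gamma_aif, PKParameters(0.6, 1.2))


@pytest.fixture
def gamma_family():
    return ParametricFamily("gamma", 2.0, 0.5)
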