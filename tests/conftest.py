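import numpy as np
import pandas as pd
import pytest

from focmts import simulate, fda, density
from focmts.preprocessing import MEASURES, zscore_apply, zscore_fit


@pytest.fixture(scope="session")
def case_control():
    """Default synthetic case-control cohort (92 ASD / 82 TD), one seed."""
    return simulate.generate_case_control(simulate.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def fitted_model(case_control):
    """FDA model on a fixed redox-heavy subset of the synthetic cohort."""
    subset = ["methionine", "cysteine", "Cys-Gly", "GSSG", "percent_oxidized"]
    norm = zscore_fit(case_control, list(MEASURES))
    ztab = zscore_apply(case_control, norm)
    return fda.fit_fda(ztab, subset, norm)


@pytest.fixture(scope="session")
def thresholded(fitted_model):
    return density.estimate_thresholded(fitted_model.t_td, fitted_model.t_asd)


@pytest.fixture()
def raw_panel():
    """One complete raw panel with easily checked ratios."""
    return {
        "methionine": 25.0, "SAM": 100.0, "SAH": 20.0, "homocysteine": 6.0,
        "adenosine": 0.25, "cysteine": 210.0, "Glu-Cys": 2.2, "Cys-Gly": 40.0,
        "tGSH": 4.0, "fGSH": 1.8, "GSSG": 0.15,
    }
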