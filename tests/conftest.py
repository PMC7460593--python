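import numpy as np
import pytest
from hypothesis import settings

from protonrbe import ExperimentDesign, Mode, TrueLQ
from protonrbe.reference import REFERENCE_LQ

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def small_design() -> ExperimentDesign:
    """Study-sized design for one mode/position: 2 runs x 6 wells, 0/1/3/5 Gy."""
    return ExperimentDesign(
        modes=(Mode.PBS,),
        positions=(1,),
        doses=(1.0, 3.0, 5.0),
        runs=2,
        wells_per_condition=6,
        plating_efficiency=0.30,
        seed=13,
    )


@pytest.fixture
def full_design() -> ExperimentDesign:
    """Both modes and both positions with the study defaults."""
    return ExperimentDesign(seed=13)


@pytest.fixture
def truth_all() -> dict[str, TrueLQ]:
    """Generative LQ truths at the published per-condition fit values."""
    return {k: TrueLQ(v.alpha, v.beta) for k, v in REFERENCE_LQ.items()}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
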