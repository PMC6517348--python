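import numpy as np
import pytest

from fmrecall import ABCConfig, ModelParams, preset_experiment
from fmrecall.designs import ConditionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exp1():
    return preset_experiment("exp1_brooks")


@pytest.fixture
def gt2():
    return preset_experiment("gt_exp2")


@pytest.fixture
def paper_params():
    """Parameter point in the region of the auditory dual-task fits."""
    return ModelParams(
        a_spatial=30.62,
        a_verbal=25.51,
        F_tapping=9.14,
        F_suppression=10.59,
        F_dissociation=10.90,
    )


@pytest.fixture
def cond7():
    """A 7-item single-task condition with the standard auditory coding."""
    return ConditionSpec(
        id="single7",
        task_domain="verbal",
        dual_task="none",
        list_length=7,
        n_md=20,
        n_mi=20,
    )


@pytest.fixture
def tiny_abc():
    """Smallest ABC settings that still exercise every code path."""
    return ABCConfig(
        n_particles=40,
        n_generations=2,
        n_sim_trials=80,
        pilot_samples=40,
        kernel_factor=1.0,
    )
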