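import dataclasses

import numpy as np
import pytest

from ncelab.synth import ParamDistributions, SynthConfig, generate_session


def null_rate_params() -> ParamDistributions:
    """Across-unit distributions with every congruency/selection effect off."""
    return ParamDistributions(
        cue_transient_gain=(1.0, 0.0, 1.0, 2.0),
        distractor_suppression=(0.0, 0.0, 0.0, 0.9),
        distractor_enhancement=(0.0, 0.0, 0.0, 0.9),
        u_early=(0.0, 0.0, 0.0, np.inf),
        u_mid=(0.0, 0.0, -np.inf, 0.0),
        u_late=(0.0, 0.0, 0.0, np.inf),
        selection_amplitude=(0.0, 0.0, 0.0, np.inf),
    )


@pytest.fixture(scope="session")
def small_session():
    """A small effect-bearing session shared by read-only tests."""
    cfg = SynthConfig(session_id="fix-small", n_units=12,
                      trials_per_condition=10, fixation_break_prob=0.0)
    return generate_session(cfg, seed=7)


@pytest.fixture(scope="session")
def null_session():
    """A congruency-null session (no effects beyond the visual response)."""
    cfg = SynthConfig(session_id="fix-null", n_units=12,
                      trials_per_condition=10, fixation_break_prob=0.0,
                      rate_params=null_rate_params())
    return generate_session(cfg, seed=11)


@pytest.fixture()
def tiny_config():
    """A fast pipeline configuration for orchestration tests."""
    return {
        "seed": 5,
        "synth": {"subjects": {"S": 2}, "n_units": 10,
                  "trials_per_condition": 8},
        "analysis": {"n_boot": 25, "regression_n_boot": 50,
                     "rules": ["spatial"]},
    }
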