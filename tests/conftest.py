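import numpy as np
import pytest

from motiondcm import reference
from motiondcm.design import build_inputs
from motiondcm.forward import noise_sd_for_snr, simulate_bold
from motiondcm.stimuli import FrameGeometry, ScheduleConfig, build_session


@pytest.fixture(scope="session")
def geometry():
    return FrameGeometry()


@pytest.fixture(scope="session")
def session_design():
    return build_session(ScheduleConfig(), np.random.default_rng(11))


@pytest.fixture(scope="session")
def inputs(session_design):
    with pytest.warns(UserWarning):
        return build_inputs(session_design)


@pytest.fixture(scope="session")
def winner_spec():
    return reference.active_winner_spec()


@pytest.fixture(scope="session")
def winner_params():
    return reference.active_winner_params()


@pytest.fixture(scope="session")
def noisy_bold(winner_params, inputs):
    """One subject's synthetic session at SNR 3 (seeded)."""
    params = reference.active_winner_params()
    params.noise_sd = noise_sd_for_snr(params, inputs, 3.0)
    return simulate_bold(params, inputs, seed=5)


@pytest.fixture(scope="session")
def cohort():
    """Ten synthetic subjects at SNR 3, one session each (seeds 1-10):
    session design, nested inputs and BOLD simulated from the reference
    active-run winning-model parameters."""
    import warnings

    out = []
    for s in range(1, 11):
        rng = np.random.default_rng(s)
        design = build_session(ScheduleConfig(), rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inp = build_inputs(design)
        params = reference.active_winner_params()
        params.noise_sd = noise_sd_for_snr(params, inp, 3.0)
        out.append(
            {
                "bold": simulate_bold(params, inp, seed=rng),
                "inputs": inp,
                "noise_sd": params.noise_sd,
            }
        )
    return out


@pytest.fixture(scope="session")
def winner_recovery(cohort, winner_spec):
    """Invert the winning model on every cohort subject and pool by BPA."""
    from motiondcm.bms import bayesian_parameter_average
    from motiondcm.invert import default_priors, invert

    priors = default_priors(winner_spec)
    posts = [
        invert(winner_spec, priors, subj["bold"], subj["inputs"]) for subj in cohort
    ]
    return {
        "posts": posts,
        "bpa": bayesian_parameter_average(posts),
        "noise_sd": [subj["noise_sd"] for subj in cohort],
    }
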