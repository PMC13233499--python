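import numpy as np
import pytest

from asme.decision import StoppingRule, run_protocol
from asme.harness import ExperimentConfig, online_trial_scores, simulate_session, train_pipeline


@pytest.fixture(scope="session")
def highsnr():
    """One full-scale synthetic participant at default SNR, decoded with the
    online LDA pipeline: session, fitted pipeline, per-trial score streams and
    full-length decisions.  Shared across tests because it is the expensive
    end-to-end computation."""
    cfg = ExperimentConfig(seed=11)
    session = simulate_session(cfg)
    pipe = train_pipeline(session, cfg)
    trials = online_trial_scores(pipe, session, cfg)
    decisions = [run_protocol(t, StoppingRule("full")) for t in trials]
    return {"config": cfg, "session": session, "pipeline": pipe, "trials": trials,
            "decisions": decisions}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
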