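import numpy as np
import pytest

from revdyn import rnn, synth, task


@pytest.fixture(scope="session")
def small_synth_session():
    """Desk-scale synthetic cortical session shared across analysis tests."""
    cfg = synth.SynthConfig(
        n_neurons=120, n_blocks=14, trials_per_block=48, reversal_halfwidth=8,
        t_start=-900.0, t_end=1000.0, seed=7,
    )
    return synth.generate_session(cfg)


@pytest.fixture(scope="session")
def tiny_rnn():
    """Small untrained network + stimuli for dynamics tests."""
    rng = np.random.default_rng(11)
    bundle = rnn.init_bundle(40, rng, g=2.0, act_a=4.0)
    stimuli = rnn.make_stimuli(40, rng, base=1.0)
    return bundle, stimuli


@pytest.fixture(scope="session")
def timing():
    return rnn.TrialTiming()
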