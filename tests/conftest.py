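import numpy as np
import pytest

import odorcode as oc

# Fixed cohort seed for fixtures shared across the suite.
COHORT_SEED = 9001


@pytest.fixture(scope="session")
def cohort4():
    """Four default-config synthetic sessions with ground truth."""
    return oc.generate_cohort(4, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def session1(cohort4):
    sessions, truths = cohort4
    return sessions[0], truths[0]


def make_toy_session():
    """Tiny handcrafted session with deterministic spikes for exact checks.

    Three odour trials of one stimulus at onsets 100, 200, 300 s.  Neuron
    ``a`` has baseline-window [-5, 0) counts 5, 10, 0 (rates 1, 2, 0 Hz)
    and response-window [0, 2) counts 4, 2, 0 (rates 2, 1, 0 Hz); neuron
    ``b`` has identical baseline counts on every trial (zero variance).
    """
    onsets = [100.0, 200.0, 300.0]
    spikes_a = []
    for onset, (n_base, n_resp) in zip(onsets, [(5, 4), (10, 2), (0, 0)]):
        spikes_a.extend(onset - 5.0 + 0.25 * np.arange(n_base))
        spikes_a.extend(onset + 0.1 + 0.25 * np.arange(n_resp))
    spikes_b = []
    for onset in onsets:
        spikes_b.extend(onset - 5.0 + np.array([0.5, 1.5, 2.5]))
        spikes_b.append(onset + 0.5)
    trials = [
        oc.TrialRecord(
            trial_idx=i,
            modality="odour",
            stimulus_id=1,
            onset_s=onset,
            presentation_cycle=i + 1,
            phase="rating",
            rating="liked",
        )
        for i, onset in enumerate(onsets)
    ]
    neurons = [
        oc.NeuronRecord("a", "PC", np.sort(spikes_a)),
        oc.NeuronRecord("b", "AMY", np.sort(spikes_b)),
    ]
    return oc.SessionData("toy", "p-toy", neurons, trials)


@pytest.fixture()
def toy_session():
    return make_toy_session()
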