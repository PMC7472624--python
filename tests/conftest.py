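import numpy as np
import pytest

from eegspeech import preprocess as pp
from eegspeech import synthetic as syn


@pytest.fixture(scope="session")
def small_words_dataset():
    """Two subjects, 6 words, 8 trials/class, with class signal and blinks."""
    prot = syn.words_protocol(n_subjects=2, trials_per_class=8)
    model = syn.SignalModelSpec(seed=42, snr=1.0)
    return prot, model, syn.generate_dataset(prot, model)


@pytest.fixture(scope="session")
def null_trialset():
    """One subject, 6 words, 20 trials/class, no class signal, no blinks."""
    prot = syn.words_protocol(n_subjects=1, trials_per_class=20)
    model = syn.SignalModelSpec(seed=7, snr=0.0, blink_rate=0.0)
    return syn.generate_dataset(prot, model)[0]


@pytest.fixture(scope="session")
def signal_trialset_128():
    """One subject at 128 Hz with strong class-dependent band power."""
    prot = syn.words_protocol(n_subjects=1, trials_per_class=12)
    model = syn.SignalModelSpec(seed=5, snr=2.0, blink_rate=0.0)
    trials = syn.generate_dataset(prot, model)[0]
    return pp.downsample(trials, 128.0)


@pytest.fixture(scope="session")
def twoclass_128():
    """Two-class, 100 trials/class, 128 Hz, very separable (CNN tests)."""
    prot = syn.words_protocol(
        n_subjects=1, trials_per_class=100, classes=("cls_a", "cls_b")
    )
    model = syn.SignalModelSpec(seed=7, snr=2.0, blink_rate=0.0)
    trials = syn.generate_dataset(prot, model)[0]
    trials = pp.downsample(pp.bandpass_fir(trials, 2.0, 40.0), 128.0)
    y = trials.encoded_labels()
    rng = np.random.default_rng(0)
    idx = rng.permutation(trials.n_trials)
    return trials, y, idx[:150], idx[150:]
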