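import numpy as np
import pytest

import chestmotion as cm


def make_tone_features(n_per_class: int, seed: int, noise: float = 0.05):
    """Perfectly separable spectral features: each class is a pure tone in a
    distinct (bin, axis) slot plus a little noise.  Returns (features, labels)."""
    rng = np.random.default_rng(seed)
    slots = [(2, 0), (4, 1), (6, 2), (8, 0), (3, 1), (9, 2)]
    feats, labels = [], []
    for cls, (b, a) in zip(cm.ACTIVITY_LABELS, slots):
        for _ in range(n_per_class):
            spec = np.abs(rng.normal(0.0, noise, size=(11, 3)))
            spec[b, a] += 5.0
            feats.append(cm.FeatureSequence(spectra=spec, bin_hz=0.5, label=cls))
            labels.append(cls)
    return feats, labels


@pytest.fixture(scope="session")
def small_subject_data():
    """Five synthetic subjects, 10 s per activity: 59 windows each."""
    out = {}
    for sid in "ABCDE":
        ls = cm.simulate_training_session(sid, seed=42)
        feats = cm.stream_to_features(ls.stream, labels=ls.labels, subject_id=sid)
        out[sid] = (feats, [f.label for f in feats])
    return out


@pytest.fixture(scope="session")
def quick_model(small_subject_data):
    """A model trained briefly on the five small subjects (shared by tests
    that need any working classifier, not a converged one)."""
    feats, labels = [], []
    for f, l in small_subject_data.values():
        feats.extend(f)
        labels.extend(l)
    cfg = cm.LstmConfig(seed=11, max_epochs=300)
    return cm.train(feats, labels, cfg)
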