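import numpy as np
import pytest

from speechscreen.audio_io import AudioSignal


@pytest.fixture
def sine_signal() -> AudioSignal:
    """1 s, 440 Hz sine at 16 kHz, amplitude 0.5."""
    t = np.arange(16000) / 16000.0
    return AudioSignal(samples=0.5 * np.sin(2 * np.pi * 440 * t), sample_rate=16000)


@pytest.fixture
def noise_signal() -> AudioSignal:
    """1 s of seeded white noise at 16 kHz."""
    rng = np.random.default_rng(123)
    return AudioSignal(samples=0.3 * rng.standard_normal(16000), sample_rate=16000)


def holdout_accuracy(config, train_frac: float = 0.7, seed: int | None = None) -> float:
    """Generate a cohort, featurize, train on a split, return held-out accuracy."""
    from speechscreen.classifier import train
    from speechscreen.synthetic import featurize_cohort, generate_cohort

    seed = config.seed if seed is None else seed
    records = generate_cohort(config)
    X, y = featurize_cohort(records, config)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    n_train = int(train_frac * len(y))
    model = train(X[idx[:n_train]], y[idx[:n_train]], seed=seed)
    test = idx[n_train:]
    return float((model.predict_labels(X[test]) == y[test]).mean())
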