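import numpy as np
import pytest

from spherodict import EmbeddingModel, default_config, generate_corpus

SQ2 = 1 / np.sqrt(2)


@pytest.fixture(scope="session")
def toy_model():
    """Hand-set 2-D geometry: x, y orthogonal; w between them; v opposite x."""
    return EmbeddingModel.from_vectors(
        {
            "x": (1.0, 0.0),
            "y": (0.0, 1.0),
            "w": (SQ2, SQ2),
            "v": (-1.0, 0.0),
            "rare": (0.6, 0.8),
        },
        freqs={"x": 50, "y": 40, "w": 30, "v": 20, "rare": 2},
    )


def random_model(n_words: int, dim: int, seed: int, min_freq: int = 10) -> EmbeddingModel:
    """Random unit-ish vectors with random frequencies, for oracle sweeps."""
    rng = np.random.default_rng(seed)
    words = [f"w{i:03d}" for i in range(n_words)]
    mat = rng.normal(size=(n_words, dim))
    freqs = {w: int(f) for w, f in zip(words, rng.integers(1, 200, size=n_words))}
    return EmbeddingModel(words, mat, freqs)


@pytest.fixture(scope="session")
def small_corpus():
    """500 synthetic visits + ground truth under the default conditions."""
    cfg = default_config(n_visits=500, seed=7)
    visits, truth = generate_corpus(cfg)
    return cfg, visits, truth
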