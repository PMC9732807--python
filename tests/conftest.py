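import numpy as np
import pytest

from snirfkit import (GenSpec, default_corpus_spec, generate,
                      make_fig2_example, make_minimal_example, write_snirf)


@pytest.fixture
def minimal_model():
    return make_minimal_example()


@pytest.fixture
def fig2_model():
    return make_fig2_example()


@pytest.fixture
def corpus_model():
    return generate(default_corpus_spec(seed=0))


@pytest.fixture
def corpus_path(tmp_path, corpus_model):
    path = str(tmp_path / "full.snirf")
    write_snirf(corpus_model, path)
    return path


def random_genspec(rng: np.random.Generator, seed: int) -> GenSpec:
    """Small randomized recording shapes for round-trip sweeps."""
    n_blocks = int(rng.integers(1, 3))
    return GenSpec(
        n_sources=int(rng.integers(1, 4)),
        n_detectors=int(rng.integers(1, 4)),
        wavelengths=tuple(float(w) for w in
                          rng.choice([690.0, 760.0, 808.0, 830.0, 850.0],
                                     size=int(rng.integers(1, 3)),
                                     replace=False)),
        n_blocks=n_blocks,
        duration_s=float(rng.uniform(0.5, 1.5)),
        sampling_rate_hz=tuple(float(r) for r in
                               rng.uniform(5.0, 30.0, size=n_blocks)),
        n_stim=int(rng.integers(0, 3)),
        n_aux=int(rng.integers(0, 3)),
        seed=seed,
    )
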