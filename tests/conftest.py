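import numpy as np
import pytest

import combind as cb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


@pytest.fixture
def small_spec():
    """Planted-dimer spec with two informative 8-nt motifs, fixed gap 3."""
    return cb.DimerSpec(
        pwm_tf1=cb.consensus_pwm("ACGGAAGT", 0.9, name="tf1"),
        pwm_tf2=cb.consensus_pwm("TGACTCAT", 0.9, name="tf2"),
        spacing_distribution={3: 1.0},
    )


@pytest.fixture(scope="session")
def trained_small_model():
    """A small trained ComBind model + benchmark shared across tests."""
    spec = cb.DimerSpec(
        pwm_tf1=cb.consensus_pwm("ACGGAAGT", 0.9, name="tf1"),
        pwm_tf2=cb.consensus_pwm("TGACTCAT", 0.9, name="tf2"),
        spacing_distribution={g: 1.0 for g in range(4)},
    )
    rng = np.random.default_rng(99)
    bench = cb.make_benchmark(spec, 400, rng)
    split = cb.split_dataset(bench.labels, cb.SplitSpec(seed=99))
    train = [bench.reads[i] for i in split.train_idx]
    train_y = bench.labels[split.train_idx]
    test = [bench.reads[i] for i in split.test_idx]
    test_y = bench.labels[split.test_idx]
    model = cb.train_combind(train, train_y, spec.pwm_tf1, spec.pwm_tf2,
                             cb.ForestConfig(n_trees=60, seed=99))
    return {
        "spec": spec, "bench": bench, "model": model,
        "train": train, "train_y": train_y, "test": test, "test_y": test_y,
    }
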