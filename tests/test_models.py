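"""Window selection, forest training, and model scoring."""

import numpy as np
import pytest

import combind as cb
from combind.models import _forest_max_proba

from conftest import random_seq


class ConstantForest:
    """Stub satisfying the scoring interface with a fixed probability."""

    def __init__(self, value, window_length):
        self.value = value
        self.window_length = window_length

    def predict_proba1(self, windows):
        n = windows.shape[0] if isinstance(windows, np.ndarray) else len(windows)
        return np.full(n, self.value)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "fraction,expected",
    [(0.10, 2), (0.20, 5), (0.30, 8), (0.40, 10), (0.50, 12)],
)
def test_mtry_round_half_even_at_window_25(fraction, expected):
    cfg = cb.ForestConfig(mtry_fraction=fraction)
    assert cfg.mtry(25) == expected


def test_mtry_floor_of_one():
    assert cb.ForestConfig(mtry_fraction=0.1).mtry(3) == 1


def test_config_validation():
    with pytest.raises(ValueError):
        cb.ForestConfig(n_trees=0)
    with pytest.raises(ValueError):
        cb.ForestConfig(mtry_fraction=0.0)
    assert cb.ForestConfig().n_trees == 200


def test_default_grid_is_4x5():
    grid = cb.default_grid()
    assert len(grid) == 20
    assert {c.min_node_size for c in grid} == {1, 5, 10, 15}
    assert {c.mtry_fraction for c in grid} == {0.1, 0.2, 0.3, 0.4, 0.5}


# ---------------------------------------------------------------------------
# forest training
# ---------------------------------------------------------------------------

def test_train_forest_separable_and_deterministic():
    wins = ["AAAAAA"] * 20 + ["TTTTTT"] * 20
    y = [1] * 20 + [0] * 20
    cfg = cb.ForestConfig(n_trees=50, seed=3)
    f = cb.train_forest(wins, y, cfg)
    proba = f.predict_proba1(wins)
    assert np.all(proba[:20] > 0.9) and np.all(proba[20:] < 0.1)
    f2 = cb.train_forest(wins, y, cfg)
    assert np.array_equal(proba, f2.predict_proba1(wins))


def test_train_forest_errors():
    with pytest.raises(ValueError, match="both classes"):
        cb.train_forest(["ACGT", "ACGT"], [1, 1], cb.ForestConfig(n_trees=5))
    with pytest.raises(ValueError, match="mixed lengths"):
        cb.train_forest(["ACGT", "ACG"], [1, 0], cb.ForestConfig(n_trees=5))
    with pytest.raises(ValueError, match="N"):
        cb.train_forest(["ACGN", "ACGT"], [1, 0], cb.ForestConfig(n_trees=5))


def test_forest_oob_probabilities_available(rng):
    wins = [random_seq(rng, 8) for _ in range(60)]
    y = rng.integers(0, 2, 60)
    y[:3] = 1
    y[3:6] = 0
    f = cb.train_forest(wins, y, cb.ForestConfig(n_trees=100, seed=0))
    oob = f.oob_proba1
    assert oob.shape == (60,)
    assert np.all((oob >= 0) & (oob <= 1))


# ---------------------------------------------------------------------------
# window selection
# ---------------------------------------------------------------------------

def test_select_windows_jointrf_finds_planted_site(rng):
    pwm = cb.consensus_pwm("ACGGAAGTGA", 0.97, name="joint")
    reads, labels = [], []
    starts = []
    for i in range(10):
        start = int(rng.integers(0, 30))
        read = random_seq(rng, start) + "ACGGAAGTGA" + random_seq(rng, 30 - start)
        reads.append(cb.double_strand(cb.DnaSequence(read, id=f"r{i}")))
        labels.append(1)
        starts.append(start)
    reads.append(cb.double_strand(random_seq(rng, 40)))
    labels.append(0)
    wins, y = cb.select_windows_jointrf(pwm, reads, labels)
    assert len(wins) == len(reads) and list(y) == labels
    for w, start in zip(wins[:10], starts):
        assert w.bases == "ACGGAAGTGA"
        assert w.origin[1] == start and w.origin[2] == "+"


def test_select_windows_uniform_pwm_tiebreak(rng):
    uniform = cb.Pwm(np.full((4, 6), 0.25))
    reads = [cb.double_strand(random_seq(rng, 20)) for _ in range(5)]
    wins, _ = cb.select_windows_jointrf(uniform, reads, [1] * 5)
    for w, r in zip(wins, reads):
        assert w.origin[1] == 0 and w.origin[2] == "+"
        assert w.bases == r.forward.bases[:6]


def test_select_windows_combind_orientation_sides(rng):
    """A TF1 consensus at the left read edge wins via the right-extended
    TF1 matrix in the TF1-TF2 orientation."""
    pwm1 = cb.consensus_pwm("ACGGAAGT", 0.97, name="tf1")
    pwm2 = cb.consensus_pwm("TGACTCAT", 0.97, name="tf2")
    read = "ACGGAAGT" + random_seq(rng, 32)
    ds = cb.double_strand(read)
    wins, _ = cb.select_windows_combind(pwm1, pwm2, "tf1-tf2", [ds], [1])
    assert len(wins[0].bases) == 25
    assert wins[0].origin[1] == 0 and wins[0].origin[2] == "+"
    assert wins[0].bases.startswith("ACGGAAGT")


def test_select_windows_combind_window_length_and_errors(rng):
    pwm1 = cb.consensus_pwm("ACGGAAGT", 0.9)
    pwm2 = cb.consensus_pwm("TGACTCAT", 0.9)
    reads = [cb.double_strand(random_seq(rng, 40)) for _ in range(8)]
    for orientation in ("tf1-tf2", "tf2-tf1"):
        wins, _ = cb.select_windows_combind(pwm1, pwm2, orientation, reads,
                                            [1] * 8)
        assert all(len(w.bases) == 25 for w in wins)
    with pytest.raises(ValueError, match="orientation"):
        cb.select_windows_combind(pwm1, pwm2, "sideways", reads, [1] * 8)
    long = cb.consensus_pwm("A" * 26, 0.9)
    with pytest.raises(ValueError, match="longer"):
        cb.select_windows_combind(long, pwm2, "tf1-tf2", reads, [1] * 8)


def test_select_windows_best_score_matches_scan_max(rng):
    """Batch selection agrees with the single-read scanner."""
    pwm1 = cb.consensus_pwm("ACGGAAGT", 0.9, name="tf1")
    pwm2 = cb.consensus_pwm("TGACTCAT", 0.9, name="tf2")
    mats = [cb.extend_pwm(pwm1, "right", 25), cb.extend_pwm(pwm2, "left", 25)]
    reads = [cb.double_strand(random_seq(rng, 40)) for _ in range(20)]
    wins, _ = cb.select_windows_combind(pwm1, pwm2, "tf1-tf2", reads, [1] * 20)
    for ds, w in zip(reads, wins):
        best = max(cb.scan_max(m, ds).score for m in mats)
        chosen = max(
            np.prod([m.probs["ACGT".index(c), j]
                     for j, c in enumerate(w.bases)])
            for m in mats
        )
        assert np.isclose(chosen, best)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def test_score_constant_forest(rng):
    ds = cb.double_strand(random_seq(rng, 40))
    jm = cb.JointRFModel(ConstantForest(0.5, 10), None)
    assert cb.score_jointrf(jm, ds) == 0.5

    cm = cb.ComBindModel(ConstantForest(1.0, 25), ConstantForest(0.0, 25),
                         None, None)
    assert cb.score_combind(cm, ds) == 0.5  # (1.0 + 0.0) / 2
    cm2 = cb.ComBindModel(ConstantForest(0.3, 25), ConstantForest(0.3, 25),
                          None, None)
    assert np.isclose(cb.score_combind(cm2, ds), 0.3)


def test_forest_max_proba_matches_bruteforce(trained_small_model, rng):
    model = trained_small_model["model"]
    reads = trained_small_model["test"][:15]
    got = _forest_max_proba(model.rf1, reads)
    for ds, g in zip(reads, got):
        windows = []
        for strand in "+-":
            for start in range(len(ds) - 25 + 1):
                windows.append(str(cb.window(ds, start, 25, strand)))
        expected = model.rf1.predict_proba1(windows).max()
        assert np.isclose(g, expected)


def test_combind_score_is_mean_of_orientations(trained_small_model):
    model = trained_small_model["model"]
    reads = trained_small_model["test"][:30]
    s, s1, s2 = cb.score_combind_batch(model, reads)
    assert np.allclose(s, (s1 + s2) / 2)
    assert np.all((s >= 0) & (s <= 1))


def test_scores_invariant_under_reverse_complement(trained_small_model):
    model = trained_small_model["model"]
    reads = trained_small_model["test"][:20]
    rc = [cb.double_strand(str(r.reverse)) for r in reads]
    s, _, _ = cb.score_combind_batch(model, reads)
    s_rc, _, _ = cb.score_combind_batch(model, rc)
    assert np.allclose(s, s_rc)


def test_score_read_too_short(trained_small_model):
    model = trained_small_model["model"]
    with pytest.raises(ValueError, match="shorter"):
        cb.score_combind(model, cb.double_strand("ACGTACGT"))


# ---------------------------------------------------------------------------
# training drivers
# ---------------------------------------------------------------------------

def test_train_combind_reproducible(small_spec, rng):
    bench = cb.make_benchmark(small_spec, 120, rng)
    cfg = cb.ForestConfig(n_trees=30, seed=5)
    m1 = cb.train_combind(bench.reads, bench.labels, small_spec.pwm_tf1,
                          small_spec.pwm_tf2, cfg)
    m2 = cb.train_combind(bench.reads, bench.labels, small_spec.pwm_tf1,
                          small_spec.pwm_tf2, cfg)
    s1, _, _ = cb.score_combind_batch(m1, bench.reads[:20])
    s2, _, _ = cb.score_combind_batch(m2, bench.reads[:20])
    assert np.array_equal(s1, s2)
    assert m1.rf1.window_length == 25 and m1.rf2.window_length == 25
    # the two orientation forests use distinct derived seeds
    assert m1.rf1.config.seed != m1.rf2.config.seed


def test_train_jointrf_selects_matching_pwm(small_spec):
    """Given the true composite motif and a decoy, held-out AUROC selects
    the true one."""
    rng = np.random.default_rng(21)
    bench = cb.make_benchmark(small_spec, 300, rng)
    split = cb.split_dataset(bench.labels, cb.SplitSpec(seed=21))
    train = [bench.reads[i] for i in split.train_idx]
    train_y = bench.labels[split.train_idx]
    test = [bench.reads[i] for i in split.test_idx]
    test_y = bench.labels[split.test_idx]
    true_pwm = small_spec.composite_pwm(3)
    decoy = cb.consensus_pwm("GCGCGCGCGCGCGCGCGCG", 0.9, name="decoy")
    cfg = cb.ForestConfig(n_trees=40, seed=2)
    model, report = cb.train_jointrf(train, train_y, [true_pwm, decoy], cfg,
                                     test, test_y)
    assert model.pairwise_pwm.name == true_pwm.name
    assert set(report) == {true_pwm.name, "decoy"}
    assert report[true_pwm.name] > report["decoy"]


def test_train_jointrf_single_pwm_shortcut(small_spec, rng):
    bench = cb.make_benchmark(small_spec, 80, rng)
    pwm = small_spec.composite_pwm(3)
    model, report = cb.train_jointrf(bench.reads, bench.labels, [pwm],
                                     cb.ForestConfig(n_trees=20, seed=1),
                                     [], [])
    assert model.window_length == pwm.length
    assert len(report) == 1
    with pytest.raises(ValueError, match="at least one"):
        cb.train_jointrf(bench.reads, bench.labels, [],
                         cb.ForestConfig(n_trees=20), [], [])


def test_model_serialization_roundtrip(trained_small_model, tmp_path):
    model = trained_small_model["model"]
    reads = trained_small_model["test"][:10]
    path = tmp_path / "model.joblib"
    cb.save_model(model, path)
    loaded = cb.load_model(path)
    s1, _, _ = cb.score_combind_batch(model, reads)
    s2, _, _ = cb.score_combind_batch(loaded, reads)
    assert np.array_equal(s1, s2)
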