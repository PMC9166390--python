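"""JointRF and ComBind: random-forest models of TF-pair binding sites.

The exact position of a binding site within an enriched read is unknown, so
both models first pick, for every read, the most likely binding window with
PWMs used as position *probability* matrices, then train a random forest on
the window's nucleotides as positional categorical features.

* **JointRF** selects windows with a single composite (pairwise) PWM that
  already fixes the pair's orientation and spacing; its forest window
  length equals the composite motif length.
* **ComBind** needs no composite motif.  For each of the two strand-order
  orientations (TF1-TF2 and TF2-TF1) it extends the two individual-TF PWMs
  with uniform columns to 25 positions — TF1 right / TF2 left for TF1-TF2,
  mirrored for TF2-TF1 — picks each read's best 25-nt window over both
  extended matrices and both strands, and trains one forest per
  orientation.  The remaining two of the four physical orientations are
  reflections onto the opposite strand and are covered because every scan
  considers both strands.

Scoring an unseen double strand takes the forest's class-1 probability over
every window of both strands and keeps the maximum ("max-per-position"
score); ComBind returns the average of its two orientation scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .pwm import LogOddsMatrix, Pwm, extend_pwm
from .seqio import DnaDoubleStrand, encode

__all__ = [
    "ForestConfig",
    "Forest",
    "FeatureWindow",
    "JointRFModel",
    "ComBindModel",
    "default_grid",
    "select_windows_jointrf",
    "select_windows_combind",
    "train_forest",
    "score_jointrf",
    "score_jointrf_batch",
    "score_combind",
    "score_combind_batch",
    "train_jointrf",
    "train_combind",
    "combind_grid_trainer",
    "jointrf_grid_trainer",
    "save_model",
    "load_model",
]

#: hyperparameter grid searched in pre-training
NODE_SIZE_GRID = (1, 5, 10, 15)
MTRY_FRACTION_GRID = (0.10, 0.20, 0.30, 0.40, 0.50)

#: window length used by ComBind: long enough for two adjacent motifs plus
#: spacing, short enough that a site in the middle of a 40-nt read fits
COMBIND_WINDOW = 25


def _round_half_even(x: Decimal) -> int:
    return int(x.quantize(Decimal(1), rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    ``mtry_fraction`` is the number of variables tried at each tree node
    expressed as a fraction of the *window length* (the per-position
    variable count, not the expanded indicator count), rounded half to
    even.  200 trees is the default ensemble size; per-tree bootstraps
    leave about one third of the rows out-of-bag.
    """

    n_trees: int = 200
    min_node_size: int = 1
    mtry_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if not 0 < self.mtry_fraction <= 1:
            raise ValueError("mtry_fraction must be in (0, 1]")

    def mtry(self, window_length: int) -> int:
        """Variables tried per split: round(frac x length), at least 1.

        Rounding is half-to-even on the exact decimal product, so e.g.
        0.30 x 25 = 7.5 -> 8 and 0.10 x 25 = 2.5 -> 2.
        """
        exact = Decimal(str(self.mtry_fraction)) * Decimal(window_length)
        return max(1, _round_half_even(exact))


def default_grid(seed: int = 0) -> List[ForestConfig]:
    """The default 4 x 5 pre-training grid (node size x mtry fraction)."""
    return [
        ForestConfig(min_node_size=ns, mtry_fraction=mf, seed=seed)
        for ns in NODE_SIZE_GRID
        for mf in MTRY_FRACTION_GRID
    ]


@dataclass(frozen=True)
class FeatureWindow:
    """A training window: ordered nucleotides plus provenance."""

    bases: str
    origin: Tuple[str, int, str] = ("", 0, "+")  # (read id, start, strand)

    def __len__(self) -> int:
        return len(self.bases)


def _one_hot(codes: np.ndarray) -> np.ndarray:
    """(n, L) base codes -> (n, 4L) indicator block matrix."""
    if codes.ndim != 2:
        raise ValueError("expected a 2-D code matrix")
    if np.any(codes > 3):
        raise ValueError("windows containing N must never reach a forest")
    n, L = codes.shape
    out = np.zeros((n, 4 * L), dtype=np.uint8)
    rows = np.repeat(np.arange(n), L)
    cols = np.arange(L)[None, :].repeat(n, axis=0).ravel() * 4 + codes.ravel()
    out[rows, cols] = 1
    return out


def _encode_windows(windows: Sequence[Union[FeatureWindow, str]]) -> np.ndarray:
    return np.vstack([encode(w.bases if isinstance(w, FeatureWindow) else w)
                      for w in windows])


class Forest:
    """A bagged ensemble of Gini-split classification trees.

    Thin wrapper around :class:`sklearn.ensemble.RandomForestClassifier`
    holding the window length and exposing class-1 probabilities plus
    out-of-bag probabilities for the training rows.  ``min_node_size``
    is enforced as "nodes with fewer instances are not split"; mtry is
    computed from the window length so the one-hot expansion does not
    change the fraction-of-variables semantics.
    """

    def __init__(self, clf: RandomForestClassifier, window_length: int,
                 config: ForestConfig):
        self.clf = clf
        self.window_length = window_length
        self.config = config
        self._pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])

    def predict_proba1(self, windows) -> np.ndarray:
        """Class-1 probability for windows (strings, FeatureWindows, or an
        (n, L) integer code matrix)."""
        codes = windows if isinstance(windows, np.ndarray) else _encode_windows(windows)
        if codes.shape[1] != self.window_length:
            raise ValueError(
                f"window length {codes.shape[1]} != trained length "
                f"{self.window_length}"
            )
        return self.clf.predict_proba(_one_hot(codes))[:, self._pos_col]

    @property
    def oob_proba1(self) -> np.ndarray:
        """Out-of-bag class-1 probability for each training row."""
        return self.clf.oob_decision_function_[:, self._pos_col]


def train_forest(
    windows: Sequence[Union[FeatureWindow, str]],
    labels: Sequence[int],
    config: ForestConfig,
) -> Forest:
    """Train a forest on equal-length pure-ACGT windows with 0/1 labels."""
    labels = np.asarray(labels, dtype=int)
    if len(windows) != len(labels):
        raise ValueError("windows and labels differ in length")
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("training requires both classes (labels 0 and 1)")
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"windows have mixed lengths {sorted(lengths)}")
    (L,) = lengths
    codes = _encode_windows(windows)
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        min_samples_split=max(2, config.min_node_size),
        max_features=config.mtry(L),
        bootstrap=True,
        oob_score=True,
        random_state=config.seed % (2**31),
        n_jobs=1,
    )
    clf.fit(_one_hot(codes), labels)
    return Forest(clf, L, config)


# ---------------------------------------------------------------------------
# window selection
# ---------------------------------------------------------------------------

def _stack_codes(reads: Sequence[DnaDoubleStrand], reverse: bool) -> np.ndarray:
    return np.vstack([encode(r.reverse if reverse else r.forward) for r in reads])


def _prob_table(pwm: Pwm) -> np.ndarray:
    return np.vstack([pwm.probs, np.full((1, pwm.length), 0.25)])


def _batch_best(
    matrices: Sequence[Pwm], reads: Sequence[DnaDoubleStrand]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-read best probability-product window over matrices and strands.

    Returns (scores, starts, strand_is_minus, matrix_index).  Ties break to
    the + strand, then the smallest start, then the earlier matrix.  Starts
    for '-' windows are on the forward axis (the window is the reverse
    complement of the forward slice at that start).  Requires equal-length
    reads >= matrix length; reads must be N-free (N would score 0.25 but
    selected windows feed forests, which reject N).
    """
    n = len(reads)
    if n == 0:
        return (np.empty(0), np.empty(0, int), np.empty(0, bool), np.empty(0, int))
    lengths = {len(r) for r in reads}
    if len(lengths) != 1:
        raise ValueError("batch selection requires equal-length reads")
    (R,) = lengths
    codes_f = _stack_codes(reads, reverse=False)
    codes_r = _stack_codes(reads, reverse=True)
    best_score = np.full(n, -np.inf)
    best_start = np.zeros(n, dtype=int)
    best_minus = np.zeros(n, dtype=bool)
    best_mat = np.zeros(n, dtype=int)
    for mi, pwm in enumerate(matrices):
        w = pwm.length
        if w > R:
            raise ValueError(f"motif {pwm.name!r} ({w}) longer than reads ({R})")
        table = _prob_table(pwm)
        pos = np.arange(w)
        wins_f = np.lib.stride_tricks.sliding_window_view(codes_f, w, axis=1)
        wins_r = np.lib.stride_tricks.sliding_window_view(codes_r, w, axis=1)
        plus = table[wins_f, pos].prod(axis=2)          # (n, R-w+1)
        # windows of the reverse strand at reverse-axis start j cover
        # forward-axis start R-w-j; scan the reverse sequence and map back
        minus_rev_axis = table[wins_r, pos].prod(axis=2)
        minus = minus_rev_axis[:, ::-1]                 # now indexed by fwd start
        i_plus = plus.argmax(axis=1)
        i_minus = minus.argmax(axis=1)
        s_plus = plus[np.arange(n), i_plus]
        s_minus = minus[np.arange(n), i_minus]
        use_minus = s_minus > s_plus
        score = np.where(use_minus, s_minus, s_plus)
        start = np.where(use_minus, i_minus, i_plus)
        better = score > best_score
        best_score[better] = score[better]
        best_start[better] = start[better]
        best_minus[better] = use_minus[better]
        best_mat[better] = mi
    return best_score, best_start, best_minus, best_mat


def _windows_from_hits(
    reads: Sequence[DnaDoubleStrand],
    starts: np.ndarray,
    minus: np.ndarray,
    length: int,
) -> List[FeatureWindow]:
    from .seqio import window as _window

    out = []
    for r, s, m in zip(reads, starts, minus):
        strand = "-" if m else "+"
        out.append(FeatureWindow(str(_window(r, int(s), length, strand)),
                                 origin=(r.id, int(s), strand)))
    return out


def select_windows_jointrf(
    pwm: Pwm,
    reads: Sequence[DnaDoubleStrand],
    labels: Sequence[int],
) -> Tuple[List[FeatureWindow], np.ndarray]:
    """Best composite-PWM window of every read (positives and negatives).

    Probability-product scoring, no N-padding: training reads are pure
    ACGT and the window must stay inside the read.
    """
    labels = np.asarray(labels, dtype=int)
    if len(reads) != len(labels):
        raise ValueError("reads and labels differ in length")
    _, starts, minus, _ = _batch_best([pwm], reads)
    return _windows_from_hits(reads, starts, minus, pwm.length), labels


def select_windows_combind(
    pwm_tf1: Pwm,
    pwm_tf2: Pwm,
    orientation: str,
    reads: Sequence[DnaDoubleStrand],
    labels: Sequence[int],
    window_length: int = COMBIND_WINDOW,
) -> Tuple[List[FeatureWindow], np.ndarray]:
    """Best uniform-extended-PWM window of every read for one orientation.

    For orientation ``'tf1-tf2'`` the candidate matrices are TF1 extended
    right and TF2 extended left (both to ``window_length`` columns); for
    ``'tf2-tf1'`` the sides swap.  Each read contributes the single window
    maximizing the probability score over both matrices and both strands.
    """
    if orientation not in ("tf1-tf2", "tf2-tf1"):
        raise ValueError(f"orientation must be 'tf1-tf2' or 'tf2-tf1', got "
                         f"{orientation!r}")
    labels = np.asarray(labels, dtype=int)
    if len(reads) != len(labels):
        raise ValueError("reads and labels differ in length")
    if orientation == "tf1-tf2":
        mats = [extend_pwm(pwm_tf1, "right", window_length),
                extend_pwm(pwm_tf2, "left", window_length)]
    else:
        mats = [extend_pwm(pwm_tf2, "right", window_length),
                extend_pwm(pwm_tf1, "left", window_length)]
    _, starts, minus, _ = _batch_best(mats, reads)
    return _windows_from_hits(reads, starts, minus, window_length), labels


# ---------------------------------------------------------------------------
# trained models and scoring
# ---------------------------------------------------------------------------

@dataclass
class JointRFModel:
    forest: Forest
    pairwise_pwm: Pwm

    @property
    def window_length(self) -> int:
        return self.forest.window_length


@dataclass
class ComBindModel:
    rf1: Forest  # orientation TF1-TF2
    rf2: Forest  # orientation TF2-TF1
    pwm_tf1: Pwm
    pwm_tf2: Pwm
    window_length: int = COMBIND_WINDOW


def _forest_max_proba(
    forest: Forest, reads: Sequence[DnaDoubleStrand]
) -> np.ndarray:
    """Max class-1 probability over all windows of both strands, per read.

    All windows of all reads are scored in one forest call; '-'-strand
    windows are exactly the sliding windows of the reverse-complement
    sequence.
    """
    w = forest.window_length
    n = len(reads)
    if n == 0:
        return np.empty(0)
    for r in reads:
        if len(r) < w:
            raise ValueError(f"read {r.id!r} shorter than window length {w}")
    lengths = {len(r) for r in reads}
    blocks = []
    counts = []
    for L in sorted(lengths):
        idx = [i for i, r in enumerate(reads) if len(r) == L]
        codes_f = np.vstack([encode(reads[i].forward) for i in idx])
        codes_r = np.vstack([encode(reads[i].reverse) for i in idx])
        wins_f = np.lib.stride_tricks.sliding_window_view(codes_f, w, axis=1)
        wins_r = np.lib.stride_tricks.sliding_window_view(codes_r, w, axis=1)
        m = wins_f.shape[1]
        flat = np.concatenate(
            [wins_f.reshape(-1, w), wins_r.reshape(-1, w)], axis=0
        )
        blocks.append((idx, m, flat))
    out = np.empty(n)
    for idx, m, flat in blocks:
        proba = forest.predict_proba1(np.ascontiguousarray(flat))
        k = len(idx)
        both = np.concatenate(
            [proba[: k * m].reshape(k, m), proba[k * m :].reshape(k, m)], axis=1
        )
        out[idx] = both.max(axis=1)
    return out


def score_jointrf_batch(model: JointRFModel,
                        reads: Sequence[DnaDoubleStrand]) -> np.ndarray:
    """JointRF scores for a batch of reads (max-per-position forest probability)."""
    return _forest_max_proba(model.forest, reads)


def score_jointrf(model: JointRFModel, ds: DnaDoubleStrand) -> float:
    return float(score_jointrf_batch(model, [ds])[0])


def score_combind_batch(
    model: ComBindModel, reads: Sequence[DnaDoubleStrand]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ComBind scores for a batch of reads.

    Returns ``(score, s1, s2)`` where ``s1``/``s2`` are the per-orientation
    max-per-position probabilities and ``score = (s1 + s2) / 2``.
    """
    s1 = _forest_max_proba(model.rf1, reads)
    s2 = _forest_max_proba(model.rf2, reads)
    return (s1 + s2) / 2.0, s1, s2


def score_combind(model: ComBindModel, ds: DnaDoubleStrand) -> float:
    return float(score_combind_batch(model, [ds])[0][0])


# ---------------------------------------------------------------------------
# training drivers
# ---------------------------------------------------------------------------

def _spawn_seeds(seed: int, n: int) -> List[int]:
    """Derive n child seeds deterministically from a master seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def train_combind(
    reads: Sequence[DnaDoubleStrand],
    labels: Sequence[int],
    pwm_tf1: Pwm,
    pwm_tf2: Pwm,
    config: ForestConfig,
    window_length: int = COMBIND_WINDOW,
) -> ComBindModel:
    """Train the two orientation forests of ComBind on the full training set."""
    seeds = _spawn_seeds(config.seed, 2)
    forests = []
    for orientation, s in zip(("tf1-tf2", "tf2-tf1"), seeds):
        wins, y = select_windows_combind(
            pwm_tf1, pwm_tf2, orientation, reads, labels, window_length
        )
        cfg = ForestConfig(config.n_trees, config.min_node_size,
                           config.mtry_fraction, seed=s)
        forests.append(train_forest(wins, y, cfg))
    return ComBindModel(forests[0], forests[1], pwm_tf1, pwm_tf2, window_length)


def train_jointrf(
    reads: Sequence[DnaDoubleStrand],
    labels: Sequence[int],
    pairwise_pwms: Sequence[Pwm],
    config: ForestConfig,
    eval_reads: Sequence[DnaDoubleStrand],
    eval_labels: Sequence[int],
) -> Tuple[JointRFModel, Dict[str, float]]:
    """Train one JointRF per composite PWM; return the best by held-out AUROC.

    Model selection uses the supplied held-out split (never the final test
    set) to avoid leaking test information into the choice of motif.  The
    report maps each motif name to its held-out AUROC.
    """
    from .evaluation import auroc

    pairwise_pwms = list(pairwise_pwms)
    if not pairwise_pwms:
        raise ValueError("at least one pairwise PWM is required")
    seeds = _spawn_seeds(config.seed, len(pairwise_pwms))
    report: Dict[str, float] = {}
    best: Optional[Tuple[float, int, JointRFModel]] = None
    for i, (pwm, s) in enumerate(zip(pairwise_pwms, seeds)):
        wins, y = select_windows_jointrf(pwm, reads, labels)
        cfg = ForestConfig(config.n_trees, config.min_node_size,
                           config.mtry_fraction, seed=s)
        model = JointRFModel(train_forest(wins, y, cfg), pwm)
        if len(pairwise_pwms) == 1:
            score = float("nan")
            if len(eval_reads):
                score = auroc(score_jointrf_batch(model, eval_reads),
                              np.asarray(eval_labels))
            report[pwm.name or f"pwm{i}"] = score
            return model, report
        score = auroc(score_jointrf_batch(model, eval_reads),
                      np.asarray(eval_labels))
        report[pwm.name or f"pwm{i}"] = score
        if best is None or score > best[0]:
            best = (score, i, model)
    assert best is not None
    return best[2], report


def combind_grid_trainer(pwm_tf1: Pwm, pwm_tf2: Pwm,
                         window_length: int = COMBIND_WINDOW):
    """Trainer closure for hyperparameter grid search.

    One grid cell trains a single-orientation (TF1-TF2) forest and scores
    the hold-out reads by max-per-position probability: a proxy for the
    full two-forest model at half the cost, since both orientation forests
    share hyperparameters.
    """

    def trainer(fit_reads, fit_labels, eval_reads, eval_labels, config):
        wins, y = select_windows_combind(
            pwm_tf1, pwm_tf2, "tf1-tf2", fit_reads, fit_labels, window_length
        )
        forest = train_forest(wins, y, config)
        return _forest_max_proba(forest, eval_reads)

    return trainer


def jointrf_grid_trainer(pairwise_pwm: Pwm):
    """Trainer closure for JointRF hyperparameter grid search."""

    def trainer(fit_reads, fit_labels, eval_reads, eval_labels, config):
        wins, y = select_windows_jointrf(pairwise_pwm, fit_reads, fit_labels)
        forest = train_forest(wins, y, config)
        return _forest_max_proba(forest, eval_reads)

    return trainer


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: Union[JointRFModel, ComBindModel],
               path: Union[str, Path]) -> None:
    """Serialize a trained model to a single joblib archive with a manifest."""
    if isinstance(model, ComBindModel):
        payload = {
            "manifest": {
                "format_version": _FORMAT_VERSION,
                "kind": "combind",
                "window_length": model.window_length,
                "pwm_tf1": model.pwm_tf1.name,
                "pwm_tf2": model.pwm_tf2.name,
            },
            "model": model,
        }
    elif isinstance(model, JointRFModel):
        payload = {
            "manifest": {
                "format_version": _FORMAT_VERSION,
                "kind": "jointrf",
                "window_length": model.window_length,
                "pairwise_pwm": model.pairwise_pwm.name,
            },
            "model": model,
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    joblib.dump(payload, path)


def load_model(path: Union[str, Path]):
    payload = joblib.load(path)
    version = payload.get("manifest", {}).get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    return payload["model"]
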