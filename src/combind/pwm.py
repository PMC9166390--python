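"""Position weight matrices: parsing, log-odds, extension, and scanning.

A PWM here is a column-stochastic 4xL probability matrix (rows A,C,G,T).
Two scoring conventions coexist deliberately:

* **probability-product** scores (PWM used as a position *probability*
  matrix) drive training-window selection inside the forest models;
* **log-odds sum** scores against a background distribution drive the
  stand-alone PWM scoring baseline.

Both scan every window of both strands of a double-strand read and keep the
maximum ("max-per-position" scoring).  For the baseline, reads are padded
with N characters, which score probability 0.25 — exactly zero log-odds
under the uniform background — so a motif may overhang the read ends.
Zero-probability matrix cells with no pseudocount yield -inf log-odds;
dataset-level -inf scores are later replaced by the finite dataset minimum
(:func:`replace_neg_inf`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np

from .seqio import BASE_ORDER, DnaDoubleStrand, DnaSequence, encode

__all__ = [
    "Pwm",
    "LogOddsMatrix",
    "ScanHit",
    "parse_pwm",
    "to_log_odds",
    "extend_pwm",
    "pad_with_N",
    "scan_max",
    "score_with_pwm_set",
    "replace_neg_inf",
    "UNIFORM_BACKGROUND",
]

UNIFORM_BACKGROUND = np.full(4, 0.25)

_COL_TOL = 1e-9
# complement permutation of the A,C,G,T row order
_COMP_ROWS = np.array([3, 2, 1, 0])


@dataclass(frozen=True)
class Pwm:
    """Column-stochastic 4xL base-probability matrix with a motif name."""

    probs: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError(f"PWM must be 4xL, got shape {probs.shape}")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("PWM entries must lie in [0, 1]")
        colsums = probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ValueError("PWM columns must each sum to 1")
        # snap tiny float error so the strict invariant holds downstream
        probs = probs / colsums
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)
        assert np.all(np.abs(probs.sum(axis=0) - 1.0) <= _COL_TOL)

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def __len__(self) -> int:
        return self.length

    def consensus(self) -> str:
        return "".join(BASE_ORDER[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.probs[_COMP_ROWS, ::-1], name=self.name)

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (uniform background)."""
        p = np.clip(self.probs, 1e-12, 1.0)
        return 2.0 + (self.probs * np.log2(p)).sum(axis=0)


@dataclass(frozen=True)
class LogOddsMatrix:
    """4xL log-odds score matrix against a background base distribution."""

    scores: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    name: str = ""

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[0] != 4:
            raise ValueError(f"log-odds matrix must be 4xL, got {scores.shape}")
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return self.scores.shape[1]

    def __len__(self) -> int:
        return self.length

    def reverse_complement(self) -> "LogOddsMatrix":
        return LogOddsMatrix(
            self.scores[_COMP_ROWS, ::-1], background=self.background, name=self.name
        )


@dataclass(frozen=True)
class ScanHit:
    """Best-scoring window of a matrix over a double strand.

    ``start`` is a 0-based offset on the forward strand's axis of the
    scanned sequence (the padded axis when scanning padded reads);
    ``strand='-'`` means the window is read from the reverse-complement
    strand over the same physical positions.
    """

    score: float
    start: int
    strand: str
    matrix_name: str = ""


def parse_pwm(path: Union[str, Path], dialect: Optional[str] = None) -> Pwm:
    """Parse a PWM file; counts are column-normalised to probabilities.

    Dialects:

    ``matrix4rows``
        four whitespace-separated rows in A,C,G,T order, optional ``>name``
        header line;
    ``jaspar``
        ``>identifier`` header then rows like ``A [ 1 2 3 ]``;
    ``meme``
        MEME minimal motif format (letter-probability matrix is L rows of
        4 columns).

    With ``dialect=None`` the dialect is sniffed from the content.
    """
    path = Path(path)
    text = path.read_text()
    if dialect is None:
        if "letter-probability matrix" in text:
            dialect = "meme"
        elif re.search(r"^[ACGT]\s*\[", text, flags=re.M):
            dialect = "jaspar"
        else:
            dialect = "matrix4rows"
    if dialect == "matrix4rows":
        return _parse_matrix4rows(text, path.stem)
    if dialect == "jaspar":
        return _parse_jaspar(text, path.stem)
    if dialect == "meme":
        return _parse_meme(text, path.stem)
    raise ValueError(f"unknown PWM dialect {dialect!r}")


def _normalise(rows: List[List[float]], name: str) -> Pwm:
    if len(rows) != 4:
        raise ValueError(f"PWM must have 4 rows (A,C,G,T), got {len(rows)}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged PWM rows, lengths {sorted(lengths)}")
    mat = np.array(rows, dtype=float)
    if np.any(mat < 0):
        raise ValueError("negative PWM entries")
    colsums = mat.sum(axis=0)
    if np.any(colsums <= 0):
        raise ValueError("all-zero PWM column")
    return Pwm(mat / colsums, name=name)


def _parse_matrix4rows(text: str, default_name: str) -> Pwm:
    name = default_name
    rows: List[List[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].strip() or name
            continue
        rows.append([float(x) for x in line.split()])
    return _normalise(rows, name)


def _parse_jaspar(text: str, default_name: str) -> Pwm:
    name = default_name
    rows = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0] if line[1:].strip() else name
            continue
        m = re.match(r"^([ACGT])\s*\[?\s*([^\]]*)\]?\s*$", line)
        if not m:
            raise ValueError(f"unparseable JASPAR row: {line!r}")
        rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    if set(rows) != set("ACGT"):
        raise ValueError(f"JASPAR record must have A,C,G,T rows, got {sorted(rows)}")
    return _normalise([rows[b] for b in BASE_ORDER], name)


def _parse_meme(text: str, default_name: str) -> Pwm:
    name = default_name
    lines = text.splitlines()
    rows: List[List[float]] = []
    in_matrix = False
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("MOTIF"):
            parts = stripped.split()
            if len(parts) > 1:
                name = parts[1]
        if stripped.startswith("letter-probability matrix"):
            in_matrix = True
            continue
        if in_matrix:
            if not stripped:
                break
            vals = stripped.split()
            if len(vals) != 4:
                break
            rows.append([float(v) for v in vals])
    if not rows:
        raise ValueError("no letter-probability matrix found in MEME input")
    return _normalise(list(map(list, zip(*rows))), name)


def to_log_odds(
    pwm: Pwm,
    background: Optional[np.ndarray] = None,
    pseudocount: float = 0.0,
) -> LogOddsMatrix:
    """Convert probabilities to log-odds against a background.

    With ``pseudocount`` c > 0 each probability p becomes
    ``(p + c*b) / (1 + c)`` before dividing by the background b, so uniform
    columns still map to exactly zero under the uniform background.  With
    c = 0 zero probabilities yield -inf, which is permitted: the baseline
    scoring pipeline replaces surviving -inf dataset scores afterwards.
    Natural log by default; AUROC evaluation is rank-based so the base
    cannot affect model comparison.
    """
    if background is None:
        background = UNIFORM_BACKGROUND
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or np.any(background <= 0):
        raise ValueError("background must be 4 strictly positive probabilities")
    if abs(background.sum() - 1.0) > 1e-6:
        raise ValueError("background must sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    b = background[:, None]
    p = (pwm.probs + pseudocount * b) / (1.0 + pseudocount)
    with np.errstate(divide="ignore"):
        scores = np.log(p / b)
    return LogOddsMatrix(scores, background=background, name=pwm.name)


def extend_pwm(pwm: Pwm, side: str, target_len: int = 25) -> Pwm:
    """Extend a motif with uniform (0.25, 0.25, 0.25, 0.25) columns.

    The uniform columns reserve scanning space for the partner motif of a
    pair without constraining its sequence; under a uniform background they
    contribute zero to every log-odds window score.  Motifs longer than
    ``target_len`` are an error — truncation would silently drop motif
    information.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if pwm.length > target_len:
        raise ValueError(
            f"motif {pwm.name!r} has {pwm.length} columns, longer than "
            f"target length {target_len}"
        )
    if pwm.length == target_len:
        return pwm
    pad = np.full((4, target_len - pwm.length), 0.25)
    blocks = (pwm.probs, pad) if side == "right" else (pad, pwm.probs)
    return Pwm(np.hstack(blocks), name=pwm.name)


def pad_with_N(seq: DnaSequence, k: int = 5) -> DnaSequence:
    """Pad both ends with ``k`` N characters (N scores 0.25 / zero log-odds)."""
    if k < 0:
        raise ValueError("pad length must be >= 0")
    if k == 0:
        return seq
    return DnaSequence("N" * k + seq.bases + "N" * k, id=seq.id)


def _matrix_rows(matrix: Union[Pwm, LogOddsMatrix]) -> np.ndarray:
    """5xL score table for integer-encoded bases, N row included."""
    if isinstance(matrix, Pwm):
        n_row = np.full((1, matrix.length), 0.25)
        return np.vstack([matrix.probs, n_row])
    n_row = np.zeros((1, matrix.length))
    return np.vstack([matrix.scores, n_row])


def _window_scores(table: np.ndarray, codes: np.ndarray, product: bool) -> np.ndarray:
    """Score every window of one strand; table is 5xW, codes 1-D uint8."""
    w = table.shape[1]
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.empty(0)
    wins = np.lib.stride_tricks.sliding_window_view(codes, w)
    per_pos = table[wins, np.arange(w)]
    return per_pos.prod(axis=1) if product else per_pos.sum(axis=1)


def scan_max(
    matrix: Union[Pwm, LogOddsMatrix],
    ds: DnaDoubleStrand,
    pad: bool = False,
) -> ScanHit:
    """Best window of a matrix over both strands of a double strand.

    Probability matrices score windows as products of per-position
    probabilities (N contributes 0.25); log-odds matrices as sums
    (N contributes 0).  Ties break to the + strand, then the smallest
    start.  With ``pad=True`` the read is first N-padded with 5 characters
    per end and hit coordinates refer to the padded axis.
    """
    fwd = pad_with_N(ds.forward, 5) if pad else ds.forward
    if matrix.length > len(fwd):
        raise ValueError(
            f"matrix of length {matrix.length} longer than "
            f"{'padded ' if pad else ''}read of length {len(fwd)}"
        )
    product = isinstance(matrix, Pwm)
    codes = encode(fwd)
    codes_rc = encode(fwd.reverse_complement())
    table = _matrix_rows(matrix)
    # a '-'-strand window at forward start s is the reverse-complement
    # strand read left-to-right, i.e. window R-w-s of the revcomp sequence;
    # scanning that sequence directly keeps factor order (and hence float
    # rounding) identical on both strands, so exact ties break cleanly
    plus = _window_scores(table, codes, product)
    minus = _window_scores(table, codes_rc, product)[::-1]
    i_plus = int(np.argmax(plus))
    i_minus = int(np.argmax(minus))
    if plus[i_plus] >= minus[i_minus]:
        return ScanHit(float(plus[i_plus]), i_plus, "+", matrix.name)
    return ScanHit(float(minus[i_minus]), i_minus, "-", matrix.name)


def score_with_pwm_set(
    matrices: Sequence[LogOddsMatrix], ds: DnaDoubleStrand
) -> float:
    """Baseline PWM score: max over matrices of padded max-per-position scores.

    Reads are N-padded (5 per end) before scanning.  A -inf result (every
    window of every matrix hits a zero-probability base) is returned as is
    and replaced at dataset level by :func:`replace_neg_inf`.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("empty PWM set")
    return max(scan_max(m, ds, pad=True).score for m in matrices)


def replace_neg_inf(scores: Iterable[float]) -> np.ndarray:
    """Replace -inf scores with the dataset minimum finite score."""
    arr = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores,
                     dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("no finite score in vector; cannot replace -inf")
    out = arr.copy()
    out[np.isneginf(out)] = finite.min()
    return out
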