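"""Synthetic dimer-motif read sets emulating a pairwise-selection library.

Positives are fixed-length reads of first-order Markov background carrying
(with probability ``planted_fraction``, default 1: a selection library is
enriched so every read entails a site) one composite two-motif site:
letters drawn per column from the two TF PWMs, an inter-motif gap of
background letters (negative gap = motif overlap, realized by averaging the
overlapped columns), one of four orientations (TF1->TF2 or TF2->TF1, each
on either strand), planted uniformly among feasible positions.  Negatives
are dinucleotide-preserving shuffles of the positives, so the two classes
differ only in motif content — the discrimination the models target.
Ground truth (position, gap, orientation, strand) is recorded per read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .pwm import Pwm
from .seqio import BASE_ORDER, DnaDoubleStrand, DnaSequence, double_strand
from .shuffle import build_negative_set

__all__ = [
    "DimerSpec",
    "PlantedSite",
    "Benchmark",
    "consensus_pwm",
    "default_dimer_spec",
    "generate_reads",
    "make_benchmark",
]

#: orientation labels: motif order along the chosen strand, then strand
ORIENTATIONS = ("tf1-tf2:+", "tf2-tf1:+", "tf1-tf2:-", "tf2-tf1:-")


def consensus_pwm(consensus: str, p_consensus: float = 0.85,
                  name: str = "") -> Pwm:
    """Build an informative PWM concentrated on a consensus sequence.

    Each column puts ``p_consensus`` on the consensus base and splits the
    remainder evenly; ``p_consensus`` = 0.85 gives about 1.15 bits per
    column, comfortably information-rich for an 8-12 nt TF motif.
    """
    if not 0.25 < p_consensus <= 1.0:
        raise ValueError("p_consensus must be in (0.25, 1]")
    probs = np.full((4, len(consensus)), (1.0 - p_consensus) / 3.0)
    for j, c in enumerate(consensus.upper()):
        probs[BASE_ORDER.index(c), j] = p_consensus
    return Pwm(probs, name=name or f"consensus_{consensus}")


@dataclass(frozen=True)
class DimerSpec:
    """Generator parameters for a planted two-motif (dimer) read set.

    Defaults model the study conditions: 40-nt reads, a site in every
    positive read, gap uniform on 0..10 nt, all four orientations equally
    likely, uniform dinucleotide background.
    """

    pwm_tf1: Pwm
    pwm_tf2: Pwm
    read_length: int = 40
    spacing_distribution: Dict[int, float] = field(
        default_factory=lambda: {g: 1 / 11 for g in range(11)}
    )
    orientation_probs: Tuple[float, float, float, float] = (0.25,) * 4
    background_dinucleotide_probs: np.ndarray = field(
        default_factory=lambda: np.full(16, 1 / 16)
    )
    planted_fraction: float = 1.0

    def __post_init__(self) -> None:
        dinuc = np.asarray(self.background_dinucleotide_probs, dtype=float)
        if dinuc.shape != (16,) or np.any(dinuc < 0):
            raise ValueError("background dinucleotide probs must be 16 "
                             "non-negative values")
        object.__setattr__(
            self, "background_dinucleotide_probs", dinuc / dinuc.sum()
        )
        gaps = dict(self.spacing_distribution)
        total = sum(gaps.values())
        if not gaps or total <= 0 or any(p < 0 for p in gaps.values()):
            raise ValueError("spacing distribution must be a non-empty "
                             "non-negative probability map")
        object.__setattr__(
            self, "spacing_distribution",
            {g: p / total for g, p in gaps.items()},
        )
        ori = np.asarray(self.orientation_probs, dtype=float)
        if ori.shape != (4,) or np.any(ori < 0) or ori.sum() <= 0:
            raise ValueError("orientation probs must be 4 non-negative values")
        object.__setattr__(self, "orientation_probs", tuple(ori / ori.sum()))
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must lie in [0, 1]")
        min_overlap = min(self.spacing_distribution)
        if min_overlap < -min(self.pwm_tf1.length, self.pwm_tf2.length):
            raise ValueError("overlap exceeds the shorter motif length")
        if self.max_site_length() > self.read_length:
            raise ValueError(
                f"site of up to {self.max_site_length()} nt cannot fit a "
                f"{self.read_length}-nt read"
            )

    def max_site_length(self) -> int:
        return (self.pwm_tf1.length + self.pwm_tf2.length
                + max(self.spacing_distribution))

    def composite_pwm(self, gap: int, order: str = "tf1-tf2") -> Pwm:
        """Fixed-gap composite PWM (first motif, gap, second motif).

        Gap columns are the background mononucleotide marginal; overlapped
        columns (negative gap) are the average of the two motifs' columns,
        which keeps columns stochastic.  This is also the fixed-spacing
        pairwise-PWM baseline for a given gap.
        """
        m1, m2 = (self.pwm_tf1, self.pwm_tf2)
        if order == "tf2-tf1":
            m1, m2 = m2, m1
        elif order != "tf1-tf2":
            raise ValueError(f"unknown order {order!r}")
        mono = self.background_mono()[:, None]
        if gap >= 0:
            cols = np.hstack([m1.probs, np.repeat(mono, gap, axis=1), m2.probs])
        else:
            k = -gap
            if k > min(m1.length, m2.length):
                raise ValueError("overlap exceeds the shorter motif")
            left = m1.probs[:, : m1.length - k]
            mid = (m1.probs[:, m1.length - k :] + m2.probs[:, :k]) / 2.0
            cols = np.hstack([left, mid, m2.probs[:, k:]])
        return Pwm(cols, name=f"{m1.name}_{gap:+d}_{m2.name}")

    def background_mono(self) -> np.ndarray:
        """Mononucleotide marginal of the dinucleotide distribution."""
        return self.background_dinucleotide_probs.reshape(4, 4).sum(axis=1)


def default_dimer_spec(**overrides) -> DimerSpec:
    """A ready-made spec with two informative 10-nt motifs."""
    defaults = dict(
        pwm_tf1=consensus_pwm("ACGGAAGTGA", name="tf1"),
        pwm_tf2=consensus_pwm("TGACTCATTC", name="tf2"),
    )
    defaults.update(overrides)
    return DimerSpec(**defaults)


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one positive read; ``start`` is None when no site
    was planted (possible only with planted_fraction < 1)."""

    read_id: str
    start: Optional[int]
    gap: Optional[int]
    orientation: Optional[str]
    strand: Optional[str]


@dataclass(frozen=True)
class Benchmark:
    reads: List[DnaDoubleStrand]
    labels: np.ndarray
    truth: List[PlantedSite]


def _markov_background_batch(spec: DimerSpec, n: int, length: int,
                             rng: np.random.Generator) -> np.ndarray:
    """First-order Markov background as an (n, length) base-code matrix."""
    dinuc = spec.background_dinucleotide_probs.reshape(4, 4)
    mono = dinuc.sum(axis=1)
    trans = np.where(mono[:, None] > 0,
                     dinuc / np.maximum(mono[:, None], 1e-300), 0.25)
    cum_mono = mono.cumsum()
    cum_trans = trans.cumsum(axis=1)
    u = rng.random((n, length))
    out = np.empty((n, length), dtype=np.int64)
    out[:, 0] = np.searchsorted(cum_mono, u[:, 0], side="right").clip(0, 3)
    for i in range(1, length):
        out[:, i] = (u[:, i : i + 1] > cum_trans[out[:, i - 1]]).sum(axis=1)
    return out


def _markov_background(spec: DimerSpec, length: int,
                       rng: np.random.Generator) -> str:
    codes = _markov_background_batch(spec, 1, length, rng)[0]
    return "".join(BASE_ORDER[b] for b in codes)


def _sample_from_pwm(probs: np.ndarray, rng: np.random.Generator) -> str:
    cum = probs.cumsum(axis=0)
    u = rng.random(probs.shape[1])
    cols = (u[None, :] > cum).sum(axis=0).clip(0, 3)
    return "".join(BASE_ORDER[b] for b in cols)


def generate_reads(
    spec: DimerSpec, n: int, rng: np.random.Generator
) -> Tuple[List[DnaSequence], List[PlantedSite]]:
    """Generate ``n`` positive reads with recorded planted-site truth."""
    if n < 1:
        raise ValueError("n must be >= 1")
    gaps = sorted(spec.spacing_distribution)
    gap_p = np.array([spec.spacing_distribution[g] for g in gaps])
    bg_codes = _markov_background_batch(spec, n, spec.read_length, rng)
    reads: List[DnaSequence] = []
    truth: List[PlantedSite] = []
    for i in range(n):
        rid = f"pos{i}"
        bg = "".join(BASE_ORDER[b] for b in bg_codes[i])
        if rng.random() >= spec.planted_fraction:
            reads.append(DnaSequence(bg, id=rid))
            truth.append(PlantedSite(rid, None, None, None, None))
            continue
        ori = int(rng.choice(4, p=np.asarray(spec.orientation_probs)))
        order, strand = ORIENTATIONS[ori].split(":")
        gap = int(gaps[rng.choice(len(gaps), p=gap_p)])
        site_pwm = spec.composite_pwm(gap, order)
        site = _sample_from_pwm(site_pwm.probs, rng)
        if strand == "-":
            site = str(DnaSequence(site).reverse_complement())
        start = int(rng.integers(0, spec.read_length - len(site) + 1))
        seq = bg[:start] + site + bg[start + len(site):]
        reads.append(DnaSequence(seq, id=rid))
        truth.append(PlantedSite(rid, start, gap, order, strand))
    return reads, truth


def make_benchmark(
    spec: DimerSpec, n: int, rng: np.random.Generator
) -> Benchmark:
    """Balanced labeled benchmark: ``n`` positives plus their shuffles.

    Negatives are one dinucleotide-preserving shuffle per positive, so the
    classes share per-read dinucleotide composition exactly.  The combined
    set is randomly ordered; everything is reproducible from ``rng``.
    """
    positives, truth = generate_reads(spec, n, rng)
    negatives = build_negative_set(positives, rng)
    reads = [double_strand(s) for s in positives] + [
        double_strand(DnaSequence(str(s), id=f"neg{i}"))
        for i, s in enumerate(negatives)
    ]
    labels = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])
    order = rng.permutation(2 * n)
    reads = [reads[i] for i in order]
    labels = labels[order]
    return Benchmark(reads, labels, truth)
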