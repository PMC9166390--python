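"""Motif construction from forest out-of-bag behaviour, and motif export.

A trained forest cannot be read off like a PWM, but its out-of-bag (OOB)
predictions on the training windows can be summarized as one: counting
base frequencies over the positive-labeled windows whose OOB class-1
probability clears a threshold yields a position frequency matrix of what
the forest recognizes as a binding site.  This is informative for
fixed-configuration (JointRF-style) forests; ComBind forests mix
orientations and spacings in one window set, so their exported motifs blur
across configurations and should be read with that caveat.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .models import FeatureWindow, Forest
from .pwm import Pwm
from .seqio import BASE_ORDER

__all__ = ["oob_positive_pfm", "write_motif", "plot_motif"]


def oob_positive_pfm(
    forest: Forest,
    windows: Sequence[FeatureWindow],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> Pwm:
    """Column-normalized base frequencies of OOB-positive training windows.

    Qualifying windows are the positive-labeled training rows whose
    out-of-bag class-1 probability exceeds ``threshold`` (default 0.5, i.e.
    the forest's OOB majority vote calls them positive).
    """
    labels = np.asarray(labels, dtype=int)
    if len(windows) != len(labels):
        raise ValueError("windows and labels differ in length")
    oob = forest.oob_proba1
    if len(oob) != len(windows):
        raise ValueError("forest was not trained on these windows "
                         "(OOB row count mismatch)")
    keep = (labels == 1) & (oob > threshold)
    if not keep.any():
        raise ValueError("no positive window exceeds the OOB threshold")
    counts = np.zeros((4, forest.window_length))
    for i in np.flatnonzero(keep):
        for j, c in enumerate(windows[i].bases):
            counts[BASE_ORDER.index(c), j] += 1
    return Pwm(counts / counts.sum(axis=0), name="oob_positive")


def write_motif(pwm: Pwm, path: Union[str, Path], format: str = "jaspar") -> None:
    """Write a motif as JASPAR, MEME minimal, or a plain 4-row matrix.

    Probabilities are written with 6 decimals and round-trip through
    ``parse_pwm`` to that precision.
    """
    path = Path(path)
    if format == "jaspar":
        lines = [f">{pwm.name}"]
        for bi, b in enumerate(BASE_ORDER):
            vals = " ".join(f"{v:.6f}" for v in pwm.probs[bi])
            lines.append(f"{b} [ {vals} ]")
    elif format == "matrix4rows":
        lines = [f">{pwm.name}"]
        for bi in range(4):
            lines.append(" ".join(f"{v:.6f}" for v in pwm.probs[bi]))
    elif format == "meme":
        lines = [
            "MEME version 4", "",
            "ALPHABET= ACGT", "",
            "strands: + -", "",
            "Background letter frequencies",
            "A 0.25 C 0.25 G 0.25 T 0.25", "",
            f"MOTIF {pwm.name or 'motif'}",
            f"letter-probability matrix: alength= 4 w= {pwm.length}",
        ]
        for j in range(pwm.length):
            lines.append(" ".join(f"{pwm.probs[bi, j]:.6f}" for bi in range(4)))
    else:
        raise ValueError(f"unknown motif format {format!r}")
    path.write_text("\n".join(lines) + "\n")


def plot_motif(pwm: Pwm, path: Union[str, Path]) -> None:
    """Render a simple information-content letter chart (cosmetic).

    Per-column stacked bars, letter heights proportional to base
    probability times column information content in bits.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ic = pwm.information_content()
    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * pwm.length), 2.4))
    for j in range(pwm.length):
        order = np.argsort(pwm.probs[:, j])
        bottom = 0.0
        for bi in order:
            h = pwm.probs[bi, j] * ic[j]
            if h <= 0:
                continue
            b = BASE_ORDER[bi]
            ax.bar(j, h, bottom=bottom, width=0.9, color=colors[b])
            if h > 0.15:
                ax.text(j, bottom + h / 2, b, ha="center", va="center",
                        fontsize=8, color="white", fontweight="bold")
            bottom += h
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    ax.set_title(pwm.name)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
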