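"""Dinucleotide-count-preserving sequence shuffling.

Negative (background) reads are built by shuffling each enriched read once
while conserving its exact multiset of overlapping dinucleotides.  Because
dinucleotide frequencies vary systematically across genomic DNA, a plain
mononucleotide shuffle would let a classifier separate the classes on
composition alone; conserving 2-mers forces the models to learn motif
content instead.

The shuffle is the random-Euler-path construction of Altschul & Erickson:
the sequence is viewed as a walk on the 4-vertex base graph whose edges are
its dinucleotides; a uniformly random last-edge tree directed toward the
terminal vertex is drawn, remaining out-edges are permuted, and the Euler
path is read off.  The output has the same length, the same first and last
base, and bit-identical dinucleotide counts.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .seqio import DnaSequence

__all__ = ["dinucleotide_shuffle", "build_negative_set", "dinucleotide_counts"]


def dinucleotide_counts(seq) -> np.ndarray:
    """16-bin count vector of overlapping dinucleotides (AA, AC, ..., TT)."""
    s = str(seq)
    counts = np.zeros(16, dtype=np.int64)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for a, b in zip(s, s[1:]):
        counts[idx[a] * 4 + idx[b]] += 1
    return counts


def _last_edge_tree(adj: dict, last: str, rng: np.random.Generator) -> dict:
    """Draw random last edges forming a tree toward ``last``; retry until valid.

    For each non-terminal vertex one of its out-edges is picked uniformly at
    random as the edge the Euler path will leave it by last; the draw is
    accepted when following last edges from every vertex reaches ``last``
    (the Altschul–Erickson validity condition).  Acceptance probability is
    bounded well away from zero on a 4-vertex graph, so the rejection loop
    terminates quickly.
    """
    vertices = [v for v in adj if v != last and adj[v]]
    while True:
        pick = {v: adj[v][rng.integers(len(adj[v]))] for v in vertices}
        ok = True
        for v in vertices:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in pick:
                    ok = False
                    break
                seen.add(cur)
                cur = pick[cur]
            if not ok:
                break
        if ok:
            return pick


def dinucleotide_shuffle(seq, rng: np.random.Generator) -> DnaSequence:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Deterministic given ``rng`` state.  Requires length >= 2 and a pure
    A/C/G/T alphabet (reads containing N are excluded upstream).
    """
    s = str(seq)
    if len(s) < 2:
        raise ValueError("dinucleotide shuffle requires length >= 2")
    if set(s) - set("ACGT"):
        bad = next(c for c in s if c not in "ACGT")
        raise ValueError(f"dinucleotide shuffle requires A/C/G/T only, got {bad!r}")

    first, last = s[0], s[-1]
    adj: dict = {}
    for a, b in zip(s, s[1:]):
        adj.setdefault(a, []).append(b)
    adj.setdefault(last, [])

    pick = _last_edge_tree(adj, last, rng)

    # permute the remaining out-edges of every vertex; append the chosen
    # last edge so the walk leaves each vertex by it last
    ordered: dict = {}
    for v, targets in adj.items():
        rest = list(targets)
        if v in pick:
            rest.remove(pick[v])
        rest = [rest[i] for i in rng.permutation(len(rest))]
        if v in pick:
            rest.append(pick[v])
        ordered[v] = rest

    # walk the Euler path
    out = [first]
    ptr = {v: 0 for v in ordered}
    cur = first
    for _ in range(len(s) - 1):
        nxt = ordered[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    shuffled = "".join(out)
    name = getattr(seq, "id", "")
    return DnaSequence(shuffled, id=f"{name}_shuf" if name else "shuf")


def build_negative_set(
    reads: Sequence, rng: np.random.Generator
) -> List[DnaSequence]:
    """One dinucleotide-preserving shuffle per read, in corresponding order.

    Produces an equally sized negative set: ``len(output) == len(reads)``.
    Errors from individual shuffles are re-raised with the read index.
    """
    negatives: List[DnaSequence] = []
    for i, read in enumerate(reads):
        try:
            negatives.append(dinucleotide_shuffle(read, rng))
        except ValueError as exc:
            raise ValueError(f"read {i} ({getattr(read, 'id', '')!r}): {exc}") from exc
    return negatives
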