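"""DNA sequence types and read I/O.

The unit of analysis throughout the package is a short fixed-length read
considered together with its reverse complement (a *double strand*): a
selection experiment enriches physical DNA molecules, so a binding site may
lie on either strand of a sequenced fragment.  Coordinates are 0-based and
half-open everywhere in the library; writers that report positions to files
document their own (1-based inclusive) convention.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Sequence, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "DnaSequence",
    "DnaDoubleStrand",
    "reverse_complement",
    "read_reads",
    "write_fasta",
    "window",
    "encode",
    "BASE_ORDER",
]

#: Row order used for every matrix in the package.
BASE_ORDER = "ACGT"

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class InvalidBaseError(ValueError):
    """A character outside {A,C,G,T,N} was found in a sequence."""


@dataclass(frozen=True)
class DnaSequence:
    """An immutable DNA string over {A,C,G,T,N}, upper-cased on construction.

    Parameters
    ----------
    bases:
        The sequence text.  Lowercase letters are accepted and normalised;
        anything outside ``ACGTNacgtn`` raises :class:`InvalidBaseError`
        naming the offending position, so corrupt input surfaces early.
    id:
        Optional record identifier carried through from the source file.
    """

    bases: str
    id: str = ""

    def __post_init__(self) -> None:
        up = self.bases.upper()
        for i, c in enumerate(up):
            if c not in _VALID:
                raise InvalidBaseError(
                    f"invalid base {c!r} at position {i} in sequence {self.id!r}"
                )
        object.__setattr__(self, "bases", up)

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def __getitem__(self, item) -> str:
        return self.bases[item]

    def __iter__(self) -> Iterator[str]:
        return iter(self.bases)

    def reverse_complement(self) -> "DnaSequence":
        return DnaSequence(self.bases.translate(_COMPLEMENT)[::-1], id=self.id)


def reverse_complement(seq: Union[DnaSequence, str]) -> DnaSequence:
    """Reverse complement; ``N`` maps to ``N``.  An involution."""
    if not isinstance(seq, DnaSequence):
        seq = DnaSequence(seq)
    return seq.reverse_complement()


# byte-level lookup table: ASCII code -> base index (A=0,C=1,G=2,T=3,N=4)
_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _i in _ENCODE.items():
    _LUT[ord(_c)] = _i


def encode(seq: Union[DnaSequence, str]) -> np.ndarray:
    """Integer-encode a sequence (A=0, C=1, G=2, T=3, N=4) as uint8."""
    return _LUT[np.frombuffer(str(seq).encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class DnaDoubleStrand:
    """A read paired with its reverse complement; the unit of scoring.

    ``reverse`` is derived from ``forward`` at construction and the pairing
    invariant therefore holds by construction.
    """

    forward: DnaSequence
    id: str = ""
    reverse: DnaSequence = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "reverse", self.forward.reverse_complement())
        if not self.id:
            object.__setattr__(self, "id", self.forward.id)

    def __len__(self) -> int:
        return len(self.forward)


def double_strand(seq: Union[DnaSequence, str], id: str = "") -> DnaDoubleStrand:
    """Convenience constructor for a :class:`DnaDoubleStrand`."""
    if not isinstance(seq, DnaSequence):
        seq = DnaSequence(seq, id=id)
    return DnaDoubleStrand(seq, id=id or seq.id)


def window(ds: DnaDoubleStrand, start: int, length: int, strand: str) -> DnaSequence:
    """Extract a sub-sequence of a double strand.

    Coordinates are 0-based half-open on the *forward* strand's axis; with
    ``strand='-'`` the window covers the same physical positions but is read
    from the reverse-complement strand (i.e. the reverse complement of the
    forward-strand slice).
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if start < 0 or length <= 0 or start + length > len(ds):
        raise IndexError(
            f"window [{start},{start + length}) out of range for read of "
            f"length {len(ds)}"
        )
    sub = DnaSequence(ds.forward.bases[start : start + length], id=ds.id)
    return sub if strand == "+" else sub.reverse_complement()


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_reads(path: Union[str, Path], format: str = "fasta") -> List[DnaSequence]:
    """Read DNA sequences from FASTA, FASTQ, or a plain one-per-line dump.

    Gzip-transparent (by ``.gz`` suffix).  FASTQ qualities are discarded:
    the models use sequence content only.  An empty file yields an empty
    list.  Malformed records raise ``ValueError`` with the record index.
    """
    fmt = format.lower().replace("-", "").replace("_", "")
    reads: List[DnaSequence] = []
    with _open_text(path) as fh:
        if fmt in ("fasta", "fastq"):
            for i, rec in enumerate(SeqIO.parse(fh, fmt)):
                try:
                    reads.append(DnaSequence(str(rec.seq), id=rec.id))
                except InvalidBaseError as exc:
                    raise ValueError(f"record {i} ({rec.id}): {exc}") from exc
        elif fmt == "plainlines":
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                try:
                    reads.append(DnaSequence(line, id=f"read{i}"))
                except InvalidBaseError as exc:
                    raise ValueError(f"line {i}: {exc}") from exc
        else:
            raise ValueError(f"unknown read format {format!r}")
    return reads


def write_fasta(reads: Sequence[DnaSequence], path: Union[str, Path]) -> None:
    """Write sequences as FASTA, one record per read."""
    with open(path, "wt") as fh:
        for i, s in enumerate(reads):
            fh.write(f">{s.id or f'read{i}'}\n{s.bases}\n")
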