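"""Genome and enhancer I/O: BED ingestion, fixed-length normalization, one-hot encoding.

Enhancers are modelled as fixed-length genomic intervals (default 2 kb), obtained by
re-centering each annotated interval on its midpoint. Sequences are encoded as L x 4
binary matrices with channel order A, C, G, T; ambiguous bases (N) become all-zero
rows so that downstream convolutions contribute nothing at those positions.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

#: Fixed enhancer length in bp after normalization.
DEFAULT_ENHANCER_LENGTH = 2000

#: Fixed channel order of the one-hot encoding.
ALPHABET = "ACGT"

_CHANNEL_INDEX = {base: i for i, base in enumerate(ALPHABET)}


class BedParseError(ValueError):
    """A BED record could not be parsed; the message names the offending line."""


class SequenceLookupError(KeyError):
    """A chromosome was not found in the genome."""


class EncodingError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


@dataclass(frozen=True)
class Enhancer:
    """A genomic interval carrying an identifier and, once fetched, its sequence."""

    id: str
    chrom: str
    start: int
    end: int
    sequence: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"enhancer {self.id}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"enhancer {self.id}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def load_enhancers(path: str | os.PathLike) -> list[Enhancer]:
    """Read enhancers from a BED file (>=3 tab-separated columns).

    Records keep file order. When the name column is absent the id is
    ``"{chrom}:{start}-{end}"``. Malformed lines raise :class:`BedParseError`
    naming the 1-based line number.
    """
    enhancers: list[Enhancer] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}, line {lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}, line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else (
                f"{chrom}:{start}-{end}"
            )
            try:
                enhancers.append(Enhancer(id=name, chrom=chrom, start=start, end=end))
            except ValueError as exc:
                raise BedParseError(f"{path}, line {lineno}: {exc}") from exc
    return enhancers


def normalize_length(e: Enhancer, L: int = DEFAULT_ENHANCER_LENGTH) -> Enhancer:
    """Re-center ``e`` on its midpoint and extend to exactly ``L`` bp.

    The midpoint of odd-length intervals is ``floor((start+end)/2)``. When the
    symmetric window would cross position 0 it is shifted right so the output
    keeps length ``L`` (sequence fetch later pads with N past the chromosome end).
    """
    if L % 2 != 0:
        raise ValueError(f"L must be even, got {L}")
    mid = e.midpoint
    start = mid - L // 2
    end = mid + L // 2
    if start < 0:
        start, end = 0, L
    return replace(e, start=start, end=end, sequence=None)


def fetch_sequence(genome, e: Enhancer) -> str:
    """Fetch the uppercase sequence of ``e`` from an indexed genome.

    ``genome`` is any mapping of chromosome name to string-convertible sequence
    (a :class:`pyfaidx.Fasta`, or a plain dict for tests). Positions outside the
    chromosome return 'N', so the result always has length ``end - start``.
    """
    try:
        record = genome[e.chrom]
    except KeyError as exc:
        raise SequenceLookupError(f"chromosome {e.chrom!r} not in genome") from exc
    chrom_seq = str(record[:]) if hasattr(record, "__getitem__") else str(record)
    chrom_len = len(chrom_seq)
    lo = min(max(e.start, 0), chrom_len)
    hi = min(max(e.end, 0), chrom_len)
    core = chrom_seq[lo:hi].upper()
    left_pad = "N" * (lo - e.start)
    right_pad = "N" * (e.end - e.start - len(core) - len(left_pad))
    return left_pad + core + right_pad


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a sequence as an ``len(seq) x 4`` binary matrix (channels A,C,G,T).

    N encodes as an all-zero row. Any other character raises
    :class:`EncodingError` naming the first offending position.
    """
    seq = seq.upper()
    mat = np.zeros((len(seq), 4), dtype=np.float64)
    for i, base in enumerate(seq):
        if base == "N":
            continue
        try:
            mat[i, _CHANNEL_INDEX[base]] = 1.0
        except KeyError:
            raise EncodingError(f"invalid base {base!r} at position {i}") from None
    return mat


def one_hot_decode(mat: np.ndarray) -> str:
    """Invert :func:`one_hot_encode`; all-zero rows decode to 'N'."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError(f"expected an Lx4 matrix, got shape {mat.shape}")
    out = []
    for row in mat:
        if not row.any():
            out.append("N")
        else:
            out.append(ALPHABET[int(np.argmax(row))])
    return "".join(out)


def encode_enhancers(
    enhancers: Iterable[Enhancer], genome: Mapping | None = None
) -> dict[str, np.ndarray]:
    """One-hot encode a collection of enhancers, fetching sequences when needed."""
    encoded: dict[str, np.ndarray] = {}
    for e in enhancers:
        seq = e.sequence
        if seq is None:
            if genome is None:
                raise ValueError(f"enhancer {e.id} has no sequence and no genome given")
            seq = fetch_sequence(genome, e)
        encoded[e.id] = one_hot_encode(seq)
    return encoded
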