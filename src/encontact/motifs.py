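"""Convert trained convolution kernels into probabilistic PWMs.

Each kernel is a pattern recognizer: scanning it (without rectification) over a
one-hot sequence gives a per-position activation score, and positions scoring
strictly above half the sequence maximum are "activated". The length-M
subsequences aligned at activated positions are stacked, their per-column
nucleotide counts (plus a pseudocount) normalized into a position weight
matrix, and the PWMs exported in MEME minimal motif format for downstream
matching with TOMTOM against JASPAR, e.g.::

    tomtom -thresh 0.1 -eval kernels.meme JASPAR2018_CORE_vertebrates.meme

(TOMTOM itself is not wrapped here.)
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .nn import cross_correlate
from .sequence_io import ALPHABET

DEFAULT_MIN_SITES = 10
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class KernelPWM:
    """A kernel's motif: per-column probabilities plus the activated-site support."""

    kernel_id: int
    matrix: np.ndarray  # (M, 4), rows sum to 1
    n_sites: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM must be Mx4, got {self.matrix.shape}")
        if np.any(self.matrix < 0):
            raise ValueError("PWM entries must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


def activation_scores(kernel: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Raw (un-rectified) per-position kernel scores over a one-hot matrix.

    ``S[i] = sum_{m,n} w[m,n] * X[i+m, n]``; unlike the network's forward pass
    there is no ReLU, so scores may be negative.
    """
    return cross_correlate(X, kernel)


def activated_positions(S: np.ndarray) -> list[int]:
    """Positions scoring strictly above half the maximum score of the sequence.

    When the maximum is not positive no position is considered activated (the
    relative threshold is only meaningful for positive maxima).
    """
    S = np.asarray(S, dtype=np.float64)
    if S.size == 0:
        raise ValueError("empty score vector")
    maxs = S.max()
    if maxs <= 0:
        return []
    return np.flatnonzero(S > 0.5 * maxs).tolist()


def build_pwm(
    kernel: np.ndarray,
    sequences: Iterable[np.ndarray],
    kernel_id: int = 0,
    min_sites: int = DEFAULT_MIN_SITES,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> KernelPWM | None:
    """Aggregate activated subsequences across a scan corpus into a PWM.

    For every sequence, each activated start position contributes its aligned
    length-M one-hot block to the per-column nucleotide counts. Counts get a
    per-nucleotide pseudocount before normalization. Returns ``None`` when
    fewer than ``min_sites`` sites are collected.
    """
    kernel = np.asarray(kernel, dtype=np.float64)
    M = kernel.shape[0]
    counts = np.zeros((M, 4), dtype=np.float64)
    n_sites = 0
    for X in sequences:
        X = np.asarray(X, dtype=np.float64)
        S = cross_correlate(X, kernel)
        for i in activated_positions(S):
            counts += X[i : i + M]
            n_sites += 1
    if n_sites < min_sites:
        return None
    counts += pseudocount
    matrix = counts / counts.sum(axis=1, keepdims=True)
    return KernelPWM(kernel_id=kernel_id, matrix=matrix, n_sites=n_sites)


def extract_model_pwms(
    model,
    sequences: Iterable[np.ndarray],
    min_sites: int = DEFAULT_MIN_SITES,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[KernelPWM]:
    """PWMs for every convolution kernel of both towers of a trained model."""
    sequences = list(sequences)
    pwms = []
    for kid, kernel in enumerate(model.kernels):
        pwm = build_pwm(kernel, sequences, kernel_id=kid,
                        min_sites=min_sites, pseudocount=pseudocount)
        if pwm is not None:
            pwms.append(pwm)
    return pwms


def pwm_column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-column Pearson correlation between two equal-width PWMs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    cors = []
    for col_a, col_b in zip(a, b):
        sa, sb = col_a.std(), col_b.std()
        if sa == 0 or sb == 0:
            cors.append(0.0)
        else:
            cors.append(float(np.corrcoef(col_a, col_b)[0, 1]))
    return float(np.mean(cors))


def best_match_correlation(pwms: Sequence[KernelPWM], target: np.ndarray) -> float:
    """Best mean per-column correlation of any PWM with a target motif.

    All alignment offsets of the shorter matrix within the longer are tried;
    the maximum over kernels and offsets is returned.
    """
    target = np.asarray(target, dtype=float)
    best = -1.0
    for pwm in pwms:
        a, b = pwm.matrix, target
        if a.shape[0] < b.shape[0]:
            a, b = b, a
        w = b.shape[0]
        for off in range(a.shape[0] - w + 1):
            best = max(best, pwm_column_correlation(a[off : off + w], b))
    return best


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------


def export_meme(pwms: Sequence[KernelPWM], path: str | os.PathLike,
                background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> None:
    """Write PWMs as a MEME minimal motif file (TOMTOM-compatible)."""
    if not pwms:
        raise ValueError("no PWMs to export")
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {ALPHABET}\n\n")
        fh.write("strands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, background)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF kernel_{pwm.kernel_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= {pwm.n_sites} E= 0\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path: str | os.PathLike) -> list[KernelPWM]:
    """Parse a MEME minimal motif file written by :func:`export_meme`."""
    pwms: list[KernelPWM] = []
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        if not line.startswith("MOTIF"):
            continue
        name = line.split()[1]
        header = next(lines)
        tokens = header.replace("=", " = ").split()
        width = int(tokens[tokens.index("w") + 2])
        n_sites = int(tokens[tokens.index("nsites") + 2])
        rows = [[float(x) for x in next(lines).split()] for _ in range(width)]
        kernel_id = int(name.rsplit("_", 1)[1]) if "_" in name else len(pwms)
        matrix = np.asarray(rows)
        matrix = matrix / matrix.sum(axis=1, keepdims=True)
        pwms.append(KernelPWM(kernel_id=kernel_id, matrix=matrix, n_sites=n_sites))
    return pwms


def write_site_counts(pwms: Sequence[KernelPWM], path: str | os.PathLike) -> None:
    """Per-kernel activated-site counts as TSV."""
    with open(path, "w") as fh:
        fh.write("kernel_id\tn_sites\twidth\n")
        for pwm in pwms:
            fh.write(f"{pwm.kernel_id}\t{pwm.n_sites}\t{pwm.width}\n")
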