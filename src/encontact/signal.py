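"""Accessibility and activity statistics for predicted enhancer interactions.

Three families of measures:

* **Openness** — per-site chromatin accessibility as a fold change,
  ``O = N / (M / W)``: the read count at a site over the mean per-site read
  density of a length-W background window (1 Mb by default) centered on it.
  The fold change cancels sequencing depth. The *co-opening degree* of an
  enhancer pair is the absolute Pearson correlation of their replicate-averaged
  openness vectors; a pair is called co-opening when the correlation test gives
  p < 0.05.

* **Activity** — a peak's activity score ``PAS = (N/P) / (M/W)`` compares its
  in-peak read density against the background window density; an enhancer's
  activity score (EAS) is the maximum PAS over overlapping peaks and the
  enhancer is *active* when EAS is strictly greater than 1. Counting the
  experiments in which an enhancer is active measures activity across cell
  lines.

* **Network** — predicted positive pairs form an undirected simple graph whose
  top-decile-degree nodes are the hub enhancers.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .sequence_io import Enhancer

DEFAULT_BACKGROUND_WINDOW = 1_000_000
COOPEN_ALPHA = 0.05
HUB_TOP_FRACTION = 0.10
ACTIVE_EAS_THRESHOLD = 1.0


@dataclass
class SignalTrack:
    """Per-site read counts for one replicate, keyed by chromosome."""

    replicate_id: str
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.counts.items():
            arr = np.asarray(arr, dtype=np.float64)
            if np.any(arr < 0):
                raise ValueError(f"{self.replicate_id}/{chrom}: negative counts")
            self.counts[chrom] = arr


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"invalid peak [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# bedGraph / BED I/O
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | os.PathLike,
                  chrom_lengths: Mapping[str, int],
                  replicate_id: str | None = None) -> SignalTrack:
    """Load a bedGraph (chrom, start, end, count) into dense per-site arrays."""
    counts = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split()[:4]
            if chrom in counts:
                counts[chrom][int(start):int(end)] += float(value)
    return SignalTrack(replicate_id=replicate_id or os.path.basename(str(path)),
                       counts=counts)


def write_bedgraph(track: SignalTrack, path: str | os.PathLike) -> None:
    """Write a dense track as run-length-compressed bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.counts):
            arr = track.counts[chrom]
            if arr.size == 0:
                continue
            changes = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], changes])
            ends = np.concatenate([changes, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_peaks(path: str | os.PathLike, experiment_id: str = "") -> list[Peak]:
    """Read peaks from BED/narrowPeak (extra columns ignored)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            peaks.append(Peak(fields[0], int(fields[1]), int(fields[2]),
                              experiment_id=experiment_id))
    return peaks


# ---------------------------------------------------------------------------
# Openness (accessibility)
# ---------------------------------------------------------------------------


def _window_sum(arr: np.ndarray, lo: int, hi: int) -> float:
    return float(arr[max(lo, 0):min(hi, arr.size)].sum())


def openness_score(track: SignalTrack, chrom: str, site: int,
                   W: int = DEFAULT_BACKGROUND_WINDOW) -> float:
    """Depth-normalized accessibility at one site: N over windowed density M/W.

    The background window is centered on the site and clipped at chromosome
    ends, but W in the denominator stays nominal. Zero background gives 0.
    """
    arr = track.counts[chrom]
    if not 0 <= site < arr.size:
        raise IndexError(f"site {site} outside {chrom} (length {arr.size})")
    if W <= 0:
        raise ValueError("background window must be positive")
    N = float(arr[site])
    M = _window_sum(arr, site - W // 2, site - W // 2 + W)
    return 0.0 if M == 0 else N / (M / W)


def openness_vector(track: SignalTrack, chrom: str, start: int, end: int,
                    W: int = DEFAULT_BACKGROUND_WINDOW) -> np.ndarray:
    """Vectorized per-site openness over an interval (N-padded out of range)."""
    arr = track.counts[chrom]
    L = end - start
    out = np.zeros(L, dtype=np.float64)
    cum = np.concatenate([[0.0], np.cumsum(arr)])
    for i in range(L):
        site = start + i
        if not 0 <= site < arr.size:
            continue
        lo = max(site - W // 2, 0)
        hi = min(site - W // 2 + W, arr.size)
        M = cum[hi] - cum[lo]
        out[i] = 0.0 if M == 0 else arr[site] / (M / W)
    return out


def enhancer_openness_vector(e: Enhancer, tracks: Sequence[SignalTrack],
                             W: int = DEFAULT_BACKGROUND_WINDOW) -> np.ndarray:
    """Replicate-averaged per-site openness across the enhancer interval."""
    if not tracks:
        raise ValueError("need at least one replicate track")
    vectors = [openness_vector(t, e.chrom, e.start, e.end, W) for t in tracks]
    return np.mean(vectors, axis=0)


@dataclass(frozen=True)
class CoopeningResult:
    degree: float | None  # |Pearson r|, None when undefined (constant vector)
    p_value: float | None
    co_opening: bool


def coopening_degree(v1: np.ndarray, v2: np.ndarray,
                     alpha: float = COOPEN_ALPHA) -> CoopeningResult:
    """Absolute Pearson correlation of two openness vectors, with its test.

    A pair is flagged co-opening when the correlation is significant at
    ``alpha``. Constant vectors leave the correlation undefined and the flag
    false.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("openness vectors must be 1-D and of equal length")
    if v1.size < 3:
        raise ValueError("need at least 3 sites")
    if v1.std() == 0 or v2.std() == 0:
        return CoopeningResult(degree=None, p_value=None, co_opening=False)
    r, p = stats.pearsonr(v1, v2)
    return CoopeningResult(degree=float(abs(r)), p_value=float(p),
                           co_opening=bool(p < alpha))


# ---------------------------------------------------------------------------
# Activity (peaks)
# ---------------------------------------------------------------------------


def peak_activity_score(peak: Peak, track: SignalTrack,
                        W: int = DEFAULT_BACKGROUND_WINDOW,
                        include_peak_in_background: bool = True) -> float:
    """Fold change of in-peak read density over the background window density.

    The window is centered on the peak midpoint; W stays nominal when clipped.
    """
    arr = track.counts[peak.chrom]
    N = _window_sum(arr, peak.start, peak.end)
    mid = (peak.start + peak.end) // 2
    lo, hi = mid - W // 2, mid - W // 2 + W
    M = _window_sum(arr, lo, hi)
    if not include_peak_in_background:
        M -= N
    if M <= 0:
        return 0.0
    return (N / peak.length) / (M / W)


def enhancer_activity_score(
    e: Enhancer, peaks_with_pas: Iterable[tuple[Peak, float]]
) -> tuple[float, bool]:
    """Maximum PAS over peaks overlapping the enhancer; active iff EAS > 1 (strict).

    With no overlapping peak the score is 0 and the enhancer inactive.
    """
    eas = 0.0
    found = False
    for peak, pas in peaks_with_pas:
        if peak.chrom == e.chrom and peak.start < e.end and e.start < peak.end:
            found = True
            eas = max(eas, pas)
    if not found:
        return 0.0, False
    return eas, eas > ACTIVE_EAS_THRESHOLD


def activity_across_experiments(
    e: Enhancer,
    experiments: Sequence[tuple[Sequence[Peak], SignalTrack]],
    W: int = DEFAULT_BACKGROUND_WINDOW,
) -> int:
    """Number of experiments (peak set + track) in which the enhancer is active."""
    count = 0
    for peaks, track in experiments:
        scored = [(p, peak_activity_score(p, track, W)) for p in peaks
                  if p.chrom == e.chrom]
        _, active = enhancer_activity_score(e, scored)
        count += int(active)
    return count


# ---------------------------------------------------------------------------
# Enhancer network and hubs
# ---------------------------------------------------------------------------


def build_network(positive_records: Iterable) -> nx.Graph:
    """Undirected simple graph over predicted positive pairs.

    Accepts prediction records (``e1``/``e2`` attributes) or plain id pairs.
    Duplicate pairs collapse to a single edge; self-pairs are rejected with a
    warning.
    """
    import warnings

    g = nx.Graph()
    for rec in positive_records:
        e1 = rec.e1 if hasattr(rec, "e1") else rec[0]
        e2 = rec.e2 if hasattr(rec, "e2") else rec[1]
        if e1 == e2:
            warnings.warn(f"self-pair {e1!r} ignored", stacklevel=2)
            continue
        g.add_edge(e1, e2)
    return g


def call_hub_enhancers(net: nx.Graph,
                       top_fraction: float = HUB_TOP_FRACTION,
                       include_ties: bool = False) -> set[str]:
    """The ceil(top_fraction * n) highest-degree enhancers.

    Ties at the cutoff break deterministically by enhancer id; with
    ``include_ties`` every node tied with the cutoff degree is kept instead.
    """
    n = net.number_of_nodes()
    if n < 10:
        raise ValueError(f"need >= 10 nodes to call hubs, got {n}")
    k = math.ceil(top_fraction * n)
    ranked = sorted(net.degree, key=lambda item: (-item[1], item[0]))
    if include_ties:
        cutoff = ranked[k - 1][1]
        return {node for node, deg in ranked if deg >= cutoff}
    return {node for node, _ in ranked[:k]}


def compare_groups(counts_a: Sequence[float], counts_b: Sequence[float]) -> float:
    """One-sided Wilcoxon rank-sum p-value for "a stochastically greater than b".

    Normal approximation with tie correction.
    """
    if len(counts_a) == 0 or len(counts_b) == 0:
        raise ValueError("both samples must be non-empty")
    result = stats.mannwhitneyu(counts_a, counts_b, alternative="greater",
                                method="asymptotic")
    return float(result.pvalue)


def write_network(net: nx.Graph, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("e1\te2\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def write_hub_report(net: nx.Graph, hubs: set[str],
                     activity_counts: Mapping[str, int] | None,
                     path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("id\tdegree\tis_hub\tactivity_count\n")
        for node in sorted(net.nodes):
            act = "" if activity_counts is None else activity_counts.get(node, 0)
            fh.write(f"{node}\t{net.degree[node]}\t{int(node in hubs)}\t{act}\n")
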