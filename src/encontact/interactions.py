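"""Labeled enhancer-pair construction from region-level chromatin interactions.

Region-level loops (e.g., HiChIP anchor pairs) are annotated with enhancers and
partitioned into the unambiguous "1v1" set (exactly one enhancer per anchor —
labeled positives for training) and the ambiguous "mvm" set (several enhancers
in at least one anchor — candidate sets to fine-map). Negatives come from three
backgrounds of increasing difficulty: random pairs, random enhancers (one end of
a positive kept fixed), and distance-matched "random contacts" drawn to mirror
the positive distance distribution across five quantile bins.

Distances are midpoint-to-midpoint in bp; all pairs are intra-chromosomal, since
distance is undefined across chromosomes.
"""

from __future__ import annotations

import itertools
import os
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .sequence_io import Enhancer

DEFAULT_TRAIN_CHROMS = frozenset(f"chr{i}" for i in range(1, 19))

#: Retry budget multiplier for rejection sampling of negatives.
RETRY_FACTOR = 100


class SamplingError(RuntimeError):
    """Negative sampling exhausted its retry budget."""


class DistanceError(ValueError):
    """Distance requested between enhancers on different chromosomes."""


@dataclass(frozen=True)
class RegionInteraction:
    """One region-level contact: two anchors plus a source identifier."""

    anchor1: tuple[str, int, int]
    anchor2: tuple[str, int, int]
    source_id: str

    def __post_init__(self) -> None:
        for chrom, start, end in (self.anchor1, self.anchor2):
            if end <= start:
                raise ValueError(
                    f"interaction {self.source_id}: invalid anchor [{start}, {end})")


@dataclass(frozen=True)
class EEPair:
    """An enhancer pair with a contact label; identity is unordered."""

    e1: str
    e2: str
    label: int | None = None  # 1 positive, 0 negative, None unknown
    distance: int | None = None

    def __post_init__(self) -> None:
        if self.e1 == self.e2:
            raise ValueError(f"self-pair {self.e1!r}")

    @property
    def key(self) -> tuple[str, str]:
        """Order-free identity used for deduplication and exclusion."""
        return (self.e1, self.e2) if self.e1 <= self.e2 else (self.e2, self.e1)


@dataclass
class CandidateSet:
    """All candidate pairs enumerated from one ambiguous region interaction."""

    source: str
    candidates: list[EEPair] = field(default_factory=list)


@dataclass
class DatasetSplit:
    train: list[EEPair]
    test: list[EEPair]
    scheme: str
    seed: int | None = None


# ---------------------------------------------------------------------------
# BEDPE I/O
# ---------------------------------------------------------------------------


def load_interactions(path: str | os.PathLike) -> list[RegionInteraction]:
    """Read region interactions from a BEDPE file (first 6 columns + optional name)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    interactions = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = str(row[6]) if len(row) > 6 else f"interaction_{i}"
        interactions.append(RegionInteraction(
            anchor1=(str(row[0]), int(row[1]), int(row[2])),
            anchor2=(str(row[3]), int(row[4]), int(row[5])),
            source_id=name))
    return interactions


def write_pairs(pairs: Iterable[EEPair], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [(p.e1, p.e2, p.label, p.distance) for p in pairs],
        columns=["e1_id", "e2_id", "label", "distance"],
    ).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | os.PathLike) -> list[EEPair]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        label = None if pd.isna(row.label) else int(row.label)
        dist = None if pd.isna(row.distance) else int(row.distance)
        out.append(EEPair(str(row.e1_id), str(row.e2_id), label, dist))
    return out


# ---------------------------------------------------------------------------
# Annotation and partition
# ---------------------------------------------------------------------------


def annotate_interactions(
    interactions: Sequence[RegionInteraction], enhancers: Sequence[Enhancer]
) -> dict[str, tuple[list[Enhancer], list[Enhancer]]]:
    """Map each interaction to the enhancers overlapping its two anchors.

    Overlap means >= 1 bp intersection (half-open intervals). Interactions with
    no enhancer on either anchor are dropped.
    """
    trees: dict[str, IntervalTree] = {}
    for e in enhancers:
        trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, e)

    def hits(anchor: tuple[str, int, int]) -> list[Enhancer]:
        chrom, start, end = anchor
        tree = trees.get(chrom)
        if tree is None:
            return []
        found = sorted(tree.overlap(start, end), key=lambda iv: (iv.begin, iv.end))
        return [iv.data for iv in found]

    annotated = {}
    for inter in interactions:
        a1, a2 = hits(inter.anchor1), hits(inter.anchor2)
        if a1 and a2:
            annotated[inter.source_id] = (a1, a2)
    return annotated


def partition_1v1_mvm(
    annotated: Mapping[str, tuple[list[Enhancer], list[Enhancer]]],
) -> tuple[list[EEPair], list[CandidateSet]]:
    """Split annotated interactions into labeled 1v1 positives and mvm candidate sets.

    Interactions with exactly one enhancer per anchor yield a positive pair
    (deduplicated across interactions, unordered); all others enumerate the
    inter-anchor cross product as unlabeled candidates. Pairing two enhancers
    of the same anchor, and pairing an enhancer with itself (the same enhancer
    overlapping both anchors), are never emitted.
    """
    def dist(a: Enhancer, b: Enhancer) -> int | None:
        if a.chrom != b.chrom:
            return None
        return abs(a.midpoint - b.midpoint)

    positives: list[EEPair] = []
    seen: set[tuple[str, str]] = set()
    mvm: list[CandidateSet] = []
    for source, (a1, a2) in annotated.items():
        if len(a1) == 1 and len(a2) == 1:
            e1, e2 = a1[0], a2[0]
            if e1.id == e2.id:
                continue
            pair = EEPair(e1.id, e2.id, label=1, distance=dist(e1, e2))
            if pair.key not in seen:
                seen.add(pair.key)
                positives.append(pair)
        else:
            cands = [EEPair(x.id, y.id, label=None, distance=dist(x, y))
                     for x, y in itertools.product(a1, a2) if x.id != y.id]
            if cands:
                mvm.append(CandidateSet(source=source, candidates=cands))
    return positives, mvm


def pair_distance(p: EEPair, enhancers: Mapping[str, Enhancer]) -> int:
    """Midpoint-to-midpoint distance in bp; undefined across chromosomes."""
    a, b = enhancers[p.e1], enhancers[p.e2]
    if a.chrom != b.chrom:
        raise DistanceError(f"{p.e1} on {a.chrom} vs {p.e2} on {b.chrom}")
    return abs(a.midpoint - b.midpoint)


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------


def _positive_keys(positives: Iterable[EEPair]) -> set[tuple[str, str]]:
    return {p.key for p in positives}


def _by_chrom(pool: Sequence[Enhancer]) -> dict[str, list[Enhancer]]:
    out: dict[str, list[Enhancer]] = {}
    for e in pool:
        out.setdefault(e.chrom, []).append(e)
    for chrom in out:
        out[chrom].sort(key=lambda e: e.midpoint)
    return out


def distance_bins(distances: Sequence[int], n_bins: int = 5) -> np.ndarray:
    """Empirical-quantile bin edges splitting positives into equal-count bins."""
    qs = np.linspace(0, 1, n_bins + 1)
    return np.quantile(np.asarray(distances, dtype=float), qs)


def sample_negatives_distance_matched(
    positives: Sequence[EEPair],
    pool: Sequence[Enhancer],
    n_bins: int = 5,
    seed: int | np.random.Generator = 0,
) -> list[EEPair]:
    """Negatives mirroring the positive distance distribution ("random contacts").

    Positive distances are split into ``n_bins`` equal-count quantile bins; each
    bin then receives exactly as many sampled negatives (same-chromosome pool
    pairs whose distance falls inside the bin, excluding positives) as it holds
    positives.
    """
    if len(positives) < n_bins:
        raise ValueError(f"need >= {n_bins} positives, got {len(positives)}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lookup = {e.id: e for e in pool}
    dists = np.array([
        p.distance if p.distance is not None else pair_distance(p, lookup)
        for p in positives
    ], dtype=float)
    edges = distance_bins(dists, n_bins)
    # ties at edges go to the lower bin
    bin_of = np.clip(np.searchsorted(edges, dists, side="left") - 1, 0, n_bins - 1)
    per_bin = np.bincount(bin_of, minlength=n_bins)

    chroms = _by_chrom(pool)
    chrom_names = [c for c in chroms if len(chroms[c]) >= 2]
    if not chrom_names:
        raise SamplingError("pool has no chromosome with >= 2 enhancers")
    weights = np.array([len(chroms[c]) for c in chrom_names], dtype=float)
    weights /= weights.sum()
    mids = {c: [e.midpoint for e in chroms[c]] for c in chrom_names}

    exclude = _positive_keys(positives)
    negatives: list[EEPair] = []
    taken: set[tuple[str, str]] = set()
    for b in range(n_bins):
        lo = edges[b]
        hi = edges[b + 1]
        needed = int(per_bin[b])
        attempts = 0
        budget = max(1, needed) * RETRY_FACTOR
        got = 0
        while got < needed:
            if attempts >= budget:
                raise SamplingError(
                    f"bin {b} [{lo:.0f}, {hi:.0f}]: found {got}/{needed} negatives "
                    f"within the retry budget")
            attempts += 1
            chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
            es = chroms[chrom]
            a = es[rng.integers(len(es))]
            # candidates whose midpoint distance from a lies in (lo, hi]
            m = mids[chrom]
            cand_idx = []
            for sign in (-1, 1):
                lo_pos = a.midpoint + sign * hi if sign < 0 else a.midpoint + lo
                hi_pos = a.midpoint - lo if sign < 0 else a.midpoint + hi
                i0, i1 = bisect_left(m, lo_pos), bisect_right(m, hi_pos)
                cand_idx.extend(range(i0, i1))
            cand_idx = [i for i in cand_idx
                        if lo <= abs(m[i] - a.midpoint) <= hi and es[i].id != a.id]
            if not cand_idx:
                continue
            bpartner = es[cand_idx[rng.integers(len(cand_idx))]]
            pair = EEPair(a.id, bpartner.id, label=0,
                          distance=abs(a.midpoint - bpartner.midpoint))
            if pair.key in exclude or pair.key in taken:
                continue
            taken.add(pair.key)
            negatives.append(pair)
            got += 1
    return negatives


def sample_negatives_fixed_anchor(
    positives: Sequence[EEPair],
    pool: Sequence[Enhancer],
    seed: int | np.random.Generator = 0,
) -> list[EEPair]:
    """"Random enhancers" background: keep one end of each positive, redraw the other."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lookup = {e.id: e for e in pool}
    chroms = _by_chrom(pool)
    exclude = _positive_keys(positives)
    taken: set[tuple[str, str]] = set()
    negatives = []
    for p in positives:
        kept_id = p.e1 if rng.random() < 0.5 else p.e2
        kept = lookup[kept_id]
        candidates = chroms.get(kept.chrom, [])
        attempts = 0
        budget = RETRY_FACTOR
        while True:
            if attempts >= budget or len(candidates) < 2:
                raise SamplingError(
                    f"could not rewire positive ({p.e1}, {p.e2}) on {kept.chrom}")
            attempts += 1
            other = candidates[rng.integers(len(candidates))]
            if other.id == kept.id:
                continue
            neg = EEPair(kept.id, other.id, label=0,
                         distance=abs(kept.midpoint - other.midpoint))
            if neg.key in exclude or neg.key in taken:
                continue
            taken.add(neg.key)
            negatives.append(neg)
            break
    return negatives


def sample_negatives_random_pairs(
    pool: Sequence[Enhancer],
    n: int,
    positives: Sequence[EEPair] = (),
    seed: int | np.random.Generator = 0,
) -> list[EEPair]:
    """"Random pairs" background: uniform distinct same-chromosome pairs, no positives."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chroms = _by_chrom(pool)
    chrom_names = [c for c in chroms if len(chroms[c]) >= 2]
    n_pairs_per_chrom = {c: len(chroms[c]) * (len(chroms[c]) - 1) // 2
                         for c in chrom_names}
    exclude = _positive_keys(positives)
    capacity = sum(n_pairs_per_chrom.values()) - len(exclude)
    if n > capacity:
        raise SamplingError(f"requested {n} negatives but only {capacity} distinct "
                            "same-chromosome non-positive pairs exist")
    weights = np.array([n_pairs_per_chrom[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    taken: set[tuple[str, str]] = set()
    negatives: list[EEPair] = []
    attempts = 0
    budget = max(1, n) * RETRY_FACTOR
    while len(negatives) < n:
        if attempts >= budget:
            raise SamplingError(f"found {len(negatives)}/{n} random pairs within budget")
        attempts += 1
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        es = chroms[chrom]
        i, j = rng.choice(len(es), size=2, replace=False)
        pair = EEPair(es[i].id, es[j].id, label=0,
                      distance=abs(es[i].midpoint - es[j].midpoint))
        if pair.key in exclude or pair.key in taken:
            continue
        taken.add(pair.key)
        negatives.append(pair)
    return negatives


# ---------------------------------------------------------------------------
# Train/test splits
# ---------------------------------------------------------------------------


def split_folds(pairs: Sequence[EEPair], k: int = 10,
                seed: int = 0, stratified: bool = True) -> DatasetSplit:
    """Random k-group split (group 0 = test, rest = train), stratified by label."""
    if len(pairs) < k:
        raise ValueError(f"need >= {k} pairs, got {len(pairs)}")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(pairs))
    fold = np.empty(len(pairs), dtype=int)
    if stratified:
        labels = np.array([p.label if p.label is not None else -1 for p in pairs])
        for lab in np.unique(labels):
            members = idx[labels == lab]
            rng.shuffle(members)
            fold[members] = np.arange(members.size) % k
    else:
        perm = rng.permutation(idx)
        fold[perm] = np.arange(len(pairs)) % k
    test = [pairs[i] for i in idx[fold == 0]]
    train = [pairs[i] for i in idx[fold != 0]]
    return DatasetSplit(train=train, test=test, scheme="folds", seed=seed)


def split_by_chromosome(
    pairs: Sequence[EEPair],
    enhancers: Mapping[str, Enhancer],
    train_chroms: frozenset[str] | set[str] = DEFAULT_TRAIN_CHROMS,
) -> DatasetSplit:
    """Assign pairs to train/test by chromosome, so no enhancer is shared."""
    train, test = [], []
    for p in pairs:
        chrom = enhancers[p.e1].chrom
        (train if chrom in train_chroms else test).append(p)
    if not test:
        warnings.warn("chromosome split produced an empty test set", stacklevel=2)
    return DatasetSplit(train=train, test=test, scheme="chromosome")


# ---------------------------------------------------------------------------
# k-mer featurization (baseline input)
# ---------------------------------------------------------------------------


def kmer_featurize(seq: str, k: int = 6) -> np.ndarray:
    """Count all 4^k k-mers over the sequence (lexicographic order in A,C,G,T).

    Windows containing N (or any non-ACGT character) contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros(4**k, dtype=np.float64)
    seq = seq.upper()
    code = 0
    valid = 0  # number of consecutive valid bases ending here
    mask = 4 ** (k - 1)
    for ch in seq:
        b = index.get(ch)
        if b is None:
            code, valid = 0, 0
            continue
        code = (code % mask) * 4 + b
        valid = min(valid + 1, k)
        if valid == k:
            counts[code] += 1
    return counts
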