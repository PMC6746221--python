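"""Self-contained synthetic fixtures for the whole pipeline.

The generator emulates the post-loop-calling representation of a HiChIP-style
experiment: a random genome, fixed-length enhancers, contact pairs whose truth
is carried by a planted pair of sequence motifs, ambiguous region-level
interactions around true pairs, accessibility read tracks with controllable
co-opening correlation, and peak/track pairs with a planted active enhancer
set. Every generator is a pure function of (config, seed): outputs are
byte-identical across runs.

Positive pairs carry an instance of motif A in the first enhancer and motif B
in the second; negative pairs never contain both motifs and reuse the positive
distance distribution, so genomic distance carries no label information and
sequence is the only informative signal.
"""

from __future__ import annotations

import json
import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .interactions import EEPair, RegionInteraction
from .sequence_io import ALPHABET, Enhancer

# rng substream tags, one per generator
_TAG_GENOME, _TAG_PAIRS, _TAG_MVM, _TAG_TRACKS, _TAG_PEAKS = range(5)


def _consensus_pwm(consensus: str, major: float = 0.94) -> np.ndarray:
    """Sharp PWM around a consensus string (information content ~1.6 bits/column)."""
    minor = (1.0 - major) / 3.0
    pwm = np.full((len(consensus), 4), minor)
    for i, base in enumerate(consensus):
        pwm[i, ALPHABET.index(base)] = major
    return pwm


#: Default planted motifs: two dissimilar AP-1-like / E-box-like consensus patterns.
DEFAULT_MOTIF_A = _consensus_pwm("TGACTCATTG")
DEFAULT_MOTIF_B = _consensus_pwm("CCACGTGACC")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark."""

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 1_000_000
    n_enhancers: int = 400
    L: int = 2000
    motif_a: np.ndarray = field(default_factory=lambda: DEFAULT_MOTIF_A.copy())
    motif_b: np.ndarray = field(default_factory=lambda: DEFAULT_MOTIF_B.copy())
    n_pos: int = 1000
    n_neg: int = 1000
    insertion_temperature: float = 0.5  # 1 = sample from the PWM as-is; <1 sharpens
    coopening_rho: float = 0.9
    read_depth: float = 1.0
    n_replicates: int = 2

    def __post_init__(self) -> None:
        for m in (self.motif_a, self.motif_b):
            m = np.asarray(m)
            if m.ndim != 2 or m.shape[1] != 4 or np.any(m < 0):
                raise ValueError("motifs must be non-negative width x 4 matrices")
            if not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError("motif rows must sum to 1")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("pair counts must be non-negative")
        if not 0.0 <= self.coopening_rho <= 1.0:
            raise ValueError("coopening_rho must be in [0, 1]")
        if self.insertion_temperature <= 0:
            raise ValueError("insertion_temperature must be positive")

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def generate_genome(cfg: SyntheticConfig) -> dict[str, str]:
    """I.i.d. uniform-composition chromosomes, reproducible per seed."""
    rng = cfg.rng(_TAG_GENOME)
    bases = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    genome = {}
    for c in range(cfg.n_chroms):
        draw = rng.integers(0, 4, size=cfg.chrom_len)
        genome[f"chr{c + 1}"] = bases[draw].tobytes().decode()
    return genome


def write_fasta(genome: dict[str, str], path: str | os.PathLike,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Planted pair dataset
# ---------------------------------------------------------------------------


@dataclass
class PlantedDataset:
    """Genome + enhancers + labeled pairs with full ground truth."""

    genome: dict[str, str]
    enhancers: list[Enhancer]
    pairs: list[EEPair]
    status: dict[str, str]  # enhancer id -> "A" | "B" | "none"
    planted_at: dict[str, int]  # enhancer id -> motif offset within the enhancer
    motif_a: np.ndarray
    motif_b: np.ndarray

    @property
    def sequences(self) -> dict[str, str]:
        return {e.id: e.sequence for e in self.enhancers}

    def truth_sidecar(self) -> dict:
        return {
            "status": self.status,
            "planted_at": self.planted_at,
            "motif_a": self.motif_a.tolist(),
            "motif_b": self.motif_b.tolist(),
        }


def _sample_motif_instance(pwm: np.ndarray, rng: np.random.Generator,
                           temperature: float) -> str:
    p = pwm ** (1.0 / temperature)
    p = p / p.sum(axis=1, keepdims=True)
    return "".join(ALPHABET[rng.choice(4, p=row)] for row in p)


def contains_motif(seq: str, pwm: np.ndarray, frac: float = 0.55) -> bool:
    """Log-odds detector: does any window score above ``frac`` of the consensus?

    Used to validate planted instances and to bound chance occurrences; the
    threshold is a fraction of the best achievable log-odds score (uniform
    background), high enough that random sequence rarely passes.
    """
    from .sequence_io import one_hot_encode

    pwm = np.asarray(pwm, dtype=float)
    lods = np.log(pwm / 0.25)
    best = float(lods.max(axis=1).sum())
    X = one_hot_encode(seq)
    w = pwm.shape[0]
    if X.shape[0] < w:
        return False
    windows = np.lib.stride_tricks.sliding_window_view(X, w, axis=0)
    scores = np.einsum("icm,mc->i", windows, lods)
    return bool(scores.max() > frac * best)


def plant_pair_dataset(cfg: SyntheticConfig) -> PlantedDataset:
    """Generate enhancers and labeled contact pairs with planted motif structure.

    Enhancers are laid out on a non-overlapping grid with jitter; 40% carry an
    instance of motif A, 40% motif B, 20% neither, written into the genome
    within the central 80% of the enhancer (clear of pooling edges). Positives
    pair an A-carrier (first end) with a same-chromosome B-carrier (second
    end); negatives are drawn to mirror the positive distance distribution
    across five quantile bins and never contain both motifs.
    """
    rng = cfg.rng(_TAG_PAIRS)
    genome_arrays = {c: bytearray(s.encode()) for c, s in generate_genome(cfg).items()}
    chrom_names = sorted(genome_arrays)

    per_chrom = cfg.n_enhancers // cfg.n_chroms
    slot = cfg.chrom_len // per_chrom
    if slot < cfg.L:
        raise GenerationError(
            f"cannot place {per_chrom} non-overlapping enhancers of {cfg.L} bp "
            f"on a {cfg.chrom_len} bp chromosome")

    enhancers: list[Enhancer] = []
    for chrom in chrom_names:
        for i in range(per_chrom):
            start = slot * i + int(rng.integers(0, slot - cfg.L + 1))
            eid = f"{chrom}_e{i:04d}"
            enhancers.append(Enhancer(id=eid, chrom=chrom, start=start,
                                      end=start + cfg.L))

    # motif assignment: 40% A, 40% B, 20% none
    order = rng.permutation(len(enhancers))
    n_a = int(0.4 * len(enhancers))
    n_b = int(0.4 * len(enhancers))
    status = {}
    for rank, idx in enumerate(order):
        e = enhancers[idx]
        status[e.id] = "A" if rank < n_a else ("B" if rank < n_a + n_b else "none")

    planted_at: dict[str, int] = {}
    for e in enhancers:
        s = status[e.id]
        if s == "none":
            continue
        pwm = cfg.motif_a if s == "A" else cfg.motif_b
        width = pwm.shape[0]
        lo = int(0.1 * cfg.L)
        hi = int(0.9 * cfg.L) - width
        offset = int(rng.integers(lo, hi + 1))
        instance = _sample_motif_instance(pwm, rng, cfg.insertion_temperature)
        genome_arrays[e.chrom][e.start + offset : e.start + offset + width] = (
            instance.encode())
        planted_at[e.id] = offset

    genome = {c: bytes(a).decode() for c, a in genome_arrays.items()}
    enhancers = [
        Enhancer(id=e.id, chrom=e.chrom, start=e.start, end=e.end,
                 sequence=genome[e.chrom][e.start : e.end])
        for e in enhancers
    ]
    by_status_chrom: dict[tuple[str, str], list[Enhancer]] = {}
    for e in enhancers:
        by_status_chrom.setdefault((status[e.id], e.chrom), []).append(e)

    # positives: A-carrier x B-carrier, same chromosome, unique unordered pairs
    pairs: list[EEPair] = []
    used: set[tuple[str, str]] = set()
    budget = cfg.n_pos * 200
    attempts = 0
    while len(pairs) < cfg.n_pos:
        if attempts >= budget:
            raise GenerationError("could not draw enough distinct positive pairs")
        attempts += 1
        chrom = chrom_names[int(rng.integers(cfg.n_chroms))]
        a_pool = by_status_chrom.get(("A", chrom), [])
        b_pool = by_status_chrom.get(("B", chrom), [])
        if not a_pool or not b_pool:
            continue
        a = a_pool[int(rng.integers(len(a_pool)))]
        b = b_pool[int(rng.integers(len(b_pool)))]
        pair = EEPair(a.id, b.id, label=1, distance=abs(a.midpoint - b.midpoint))
        if pair.key in used:
            continue
        used.add(pair.key)
        pairs.append(pair)

    # negatives: distance-matched across five quantile bins, never both motifs
    pos_dists = np.array([p.distance for p in pairs], dtype=float)
    edges = np.quantile(pos_dists, np.linspace(0, 1, 6))
    mids = {}
    for key, pool in by_status_chrom.items():
        pool.sort(key=lambda e: e.midpoint)
        mids[key] = [e.midpoint for e in pool]

    def negative_end_statuses() -> tuple[str, str]:
        t = int(rng.integers(3))
        if t == 0:
            return "none", "none"
        motif = "A" if t == 1 else "B"
        variant = int(rng.integers(3))
        if variant == 0:
            return motif, "none"
        if variant == 1:
            return "none", motif
        return motif, motif

    negatives: list[EEPair] = []
    attempts = 0
    budget = max(1, cfg.n_neg) * 500
    while len(negatives) < cfg.n_neg:
        if attempts >= budget:
            raise GenerationError("could not draw enough distance-matched negatives")
        attempts += 1
        b_idx = int(rng.integers(5))
        lo, hi = edges[b_idx], edges[b_idx + 1]
        chrom = chrom_names[int(rng.integers(cfg.n_chroms))]
        s1, s2 = negative_end_statuses()
        pool1 = by_status_chrom.get((s1, chrom), [])
        pool2 = by_status_chrom.get((s2, chrom), [])
        if not pool1 or not pool2:
            continue
        x = pool1[int(rng.integers(len(pool1)))]
        m = mids[(s2, chrom)]
        cand = []
        for a_lo, a_hi in ((x.midpoint - hi, x.midpoint - lo),
                           (x.midpoint + lo, x.midpoint + hi)):
            i0, i1 = bisect_left(m, a_lo), bisect_right(m, a_hi)
            cand.extend(range(i0, i1))
        cand = [i for i in cand if pool2[i].id != x.id]
        if not cand:
            continue
        y = pool2[cand[int(rng.integers(len(cand)))]]
        pair = EEPair(x.id, y.id, label=0, distance=abs(x.midpoint - y.midpoint))
        if pair.key in used:
            continue
        used.add(pair.key)
        negatives.append(pair)

    return PlantedDataset(genome=genome, enhancers=enhancers,
                          pairs=pairs + negatives, status=status,
                          planted_at=planted_at, motif_a=np.asarray(cfg.motif_a),
                          motif_b=np.asarray(cfg.motif_b))


# ---------------------------------------------------------------------------
# Ambiguous (mvm) regions
# ---------------------------------------------------------------------------


@dataclass
class MvmTruth:
    regions: list[RegionInteraction]
    true_pairs: dict[str, tuple[str, str]]  # source id -> (e1, e2)


def generate_mvm_regions(cfg: SyntheticConfig, dataset: PlantedDataset,
                         n_regions: int = 200) -> MvmTruth:
    """Region-level interactions with several candidate enhancers per anchor.

    Each region wraps one planted-true pair: the first anchor covers the
    A-carrier plus 1-3 contiguous neighbors that are not A-carriers, the
    second the B-carrier plus 1-3 neighbors that are not B-carriers, so the
    enumerated cross product contains exactly one true pair.
    """
    rng = cfg.rng(_TAG_MVM)
    positives = [p for p in dataset.pairs if p.label == 1]
    by_chrom: dict[str, list[Enhancer]] = {}
    for e in dataset.enhancers:
        by_chrom.setdefault(e.chrom, []).append(e)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda e: e.start)
    index_of = {e.id: i for chrom in by_chrom for i, e in enumerate(by_chrom[chrom])}
    lookup = {e.id: e for e in dataset.enhancers}

    def expand(center_id: str, forbidden_status: str,
               n_extra: int) -> list[Enhancer] | None:
        e = lookup[center_id]
        row = by_chrom[e.chrom]
        i = index_of[center_id]
        chosen = [i]
        left, right = i - 1, i + 1
        while len(chosen) < n_extra + 1:
            options = []
            if left >= 0 and dataset.status[row[left].id] != forbidden_status:
                options.append("L")
            if right < len(row) and dataset.status[row[right].id] != forbidden_status:
                options.append("R")
            if not options:
                return None
            side = options[int(rng.integers(len(options)))]
            if side == "L":
                chosen.append(left)
                left -= 1
            else:
                chosen.append(right)
                right += 1
        return [row[j] for j in sorted(chosen)]

    regions: list[RegionInteraction] = []
    true_pairs: dict[str, tuple[str, str]] = {}
    attempts = 0
    budget = n_regions * 100
    while len(regions) < n_regions:
        if attempts >= budget:
            raise GenerationError(
                f"placed only {len(regions)}/{n_regions} ambiguous regions")
        attempts += 1
        p = positives[int(rng.integers(len(positives)))]
        n1 = int(rng.integers(1, 4))
        n2 = int(rng.integers(1, 4))
        members1 = expand(p.e1, "A", n1)
        members2 = expand(p.e2, "B", n2)
        if members1 is None or members2 is None:
            continue
        ids1 = {e.id for e in members1}
        ids2 = {e.id for e in members2}
        if ids1 & ids2:
            continue
        a1 = (members1[0].chrom, members1[0].start, members1[-1].end)
        a2 = (members2[0].chrom, members2[0].start, members2[-1].end)
        if a1[0] == a2[0] and a1[1] < a2[2] and a2[1] < a1[2]:
            continue  # anchors overlap; the candidate set would be ill-defined
        source = f"region_{len(regions):04d}"
        regions.append(RegionInteraction(anchor1=a1, anchor2=a2, source_id=source))
        true_pairs[source] = (p.e1, p.e2)
    return MvmTruth(regions=regions, true_pairs=true_pairs)


def write_bedpe(regions: Sequence[RegionInteraction], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            c1, s1, e1 = r.anchor1
            c2, s2, e2 = r.anchor2
            fh.write(f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\t{r.source_id}\t.\n")


# ---------------------------------------------------------------------------
# Accessibility tracks
# ---------------------------------------------------------------------------


def _smooth_field(rng: np.random.Generator, L: int, sigma: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian field (correlation length ~ sigma bp)."""
    from scipy.ndimage import gaussian_filter1d

    field = gaussian_filter1d(rng.standard_normal(L), sigma, mode="wrap")
    return field / field.std()


def generate_tracks(cfg: SyntheticConfig, enhancers: Sequence[Enhancer],
                    coopening_pairs: Sequence[tuple[str, str]] = ()):
    """Per-replicate Poisson read tracks with controllable co-opening.

    Each enhancer's read rate is background plus a rectified smoothed Gaussian
    field (a rough, peaky accessibility profile). Both members of a designated
    co-opening pair mix in a shared latent field with weight ``coopening_rho``
    (the correlation of the underlying Gaussian fields is exactly rho);
    replicates are conditionally independent draws from the same rates.
    """
    from .signal import SignalTrack

    rng = cfg.rng(_TAG_TRACKS)
    L = cfg.L
    sigma = max(3.0, L / 150)  # short correlation length keeps null |r| small
    height = 10.0 * cfg.read_depth
    bg = 0.02 * cfg.read_depth
    rho = cfg.coopening_rho

    shared_of: dict[str, int] = {}
    shared_fields: list[np.ndarray] = []
    for i, (a, b) in enumerate(coopening_pairs):
        shared_fields.append(_smooth_field(rng, L, sigma))
        shared_of[a] = i
        shared_of[b] = i

    rates: dict[str, np.ndarray] = {}
    for e in enhancers:
        own = _smooth_field(rng, L, sigma)
        if e.id in shared_of:
            field = rho * shared_fields[shared_of[e.id]] + np.sqrt(1 - rho**2) * own
        else:
            field = own
        rates[e.id] = bg + height * np.maximum(field, 0.0)

    chrom_lens = {}
    for e in enhancers:
        chrom_lens[e.chrom] = max(chrom_lens.get(e.chrom, 0), e.end, cfg.chrom_len)

    tracks = []
    for r in range(cfg.n_replicates):
        counts = {c: rng.poisson(bg, size=n).astype(np.float64)
                  for c, n in chrom_lens.items()}
        for e in enhancers:
            counts[e.chrom][e.start : e.end] = rng.poisson(rates[e.id])
        tracks.append(SignalTrack(replicate_id=f"rep{r + 1}", counts=counts))
    return tracks


# ---------------------------------------------------------------------------
# Peaks and activity
# ---------------------------------------------------------------------------


def generate_peaks(cfg: SyntheticConfig, enhancers: Sequence[Enhancer],
                   active_subset: set[str], experiment_id: str = "exp1",
                   peak_halfwidth: int = 250, enrichment: float = 5.0,
                   decoy_factor: float = 0.7, seed_offset: int = 0):
    """A peak set plus matching track with a planted active-enhancer subset.

    Peaks over active enhancers get read density ``enrichment`` times the
    background (activity score well above 1); every inactive enhancer gets a
    decoy peak at ``decoy_factor`` times background (activity score below 1),
    so the planted active set is recoverable from the scores alone.
    """
    from .signal import Peak, SignalTrack

    rng = cfg.rng(_TAG_PEAKS + 100 * (seed_offset + 1))
    bg = 0.1 * cfg.read_depth
    chrom_lens = {}
    for e in enhancers:
        chrom_lens[e.chrom] = max(chrom_lens.get(e.chrom, 0), e.end, cfg.chrom_len)
    counts = {c: rng.poisson(bg, size=n).astype(np.float64)
              for c, n in chrom_lens.items()}
    peaks = []
    active_flags = {}
    for e in enhancers:
        mid = e.midpoint
        start = max(mid - peak_halfwidth, 0)
        end = min(mid + peak_halfwidth, chrom_lens[e.chrom])
        is_active = e.id in active_subset
        rate = bg * (enrichment if is_active else decoy_factor)
        counts[e.chrom][start:end] = rng.poisson(rate, size=end - start)
        peaks.append(Peak(e.chrom, start, end, experiment_id=experiment_id))
        active_flags[e.id] = is_active
    track = SignalTrack(replicate_id=experiment_id, counts=counts)
    return peaks, track, active_flags


# ---------------------------------------------------------------------------
# Full fixture emission
# ---------------------------------------------------------------------------


def generate_all(cfg: SyntheticConfig, outdir: str | os.PathLike,
                 n_mvm_regions: int = 200) -> dict[str, str]:
    """Emit the complete fixture suite (FASTA, BED, TSV, BEDPE, bedGraph, JSON)."""
    from .interactions import write_pairs
    from .signal import write_bedgraph

    os.makedirs(outdir, exist_ok=True)
    out = lambda name: os.path.join(str(outdir), name)

    dataset = plant_pair_dataset(cfg)
    write_fasta(dataset.genome, out("genome.fa"))
    with open(out("enhancers.bed"), "w") as fh:
        for e in dataset.enhancers:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.id}\n")
    write_pairs(dataset.pairs, out("pairs.tsv"))

    mvm = generate_mvm_regions(cfg, dataset, n_regions=n_mvm_regions)
    write_bedpe(mvm.regions, out("mvm.bedpe"))

    positives = [p for p in dataset.pairs if p.label == 1]
    coopen = [(p.e1, p.e2) for p in positives[: max(1, len(positives) // 10)]]
    tracks = generate_tracks(cfg, dataset.enhancers, coopen)
    paths = {"genome": out("genome.fa"), "enhancers": out("enhancers.bed"),
             "pairs": out("pairs.tsv"), "mvm": out("mvm.bedpe")}
    for t in tracks:
        p = out(f"dnase_{t.replicate_id}.bedgraph")
        write_bedgraph(t, p)
        paths[f"track_{t.replicate_id}"] = p

    active = {e.id for e in dataset.enhancers[: len(dataset.enhancers) // 4]}
    peaks, track, flags = generate_peaks(cfg, dataset.enhancers, active)
    with open(out("peaks.bed"), "w") as fh:
        for pk in peaks:
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\n")
    write_bedgraph(track, out("chip_exp1.bedgraph"))
    paths.update(peaks=out("peaks.bed"), chip=out("chip_exp1.bedgraph"))

    truth = dataset.truth_sidecar()
    truth["mvm_true_pairs"] = {k: list(v) for k, v in mvm.true_pairs.items()}
    truth["coopening_pairs"] = [list(x) for x in coopen]
    truth["active_enhancers"] = sorted(active)
    with open(out("truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    paths["truth"] = out("truth.json")
    return paths
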