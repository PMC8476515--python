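"""Seeded simulator of a full deletion-scanning selection experiment.

The simulator emulates the experimental chain end to end: a variant pool
drawn uniformly over junction pairs (which induces the triangular
deletion-length marginal of a real ligation library), gel size selection,
fitness-weighted resampling of the sorted pool, and error-bearing 100-nt
single-end reads spanning scar junctions.  Every draw flows from one
``numpy`` Generator, so a (seed, config) pair reproduces the experiment
bit for bit.

What it deliberately does not model: PCR bias, jackpot clones, cloning
bottlenecks, indel sequencing errors, or quality-score structure.  The
fitness model is a step landscape (tolerated windows over a low baseline);
real deletion landscapes have richer sub-domain structure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import stats

from .caller import CallerConfig, PoolCounts, count_variants
from .constructs import build_variant_sequence, deletion_count
from .core import (
    BSAI_SITE,
    BSMBI_SITE,
    DeletionVariant,
    MiserError,
    NHEI_SITE,
    OrfRecord,
    SCAR_AS,
    SCAR_TS,
    SPEI_SITE,
    SizeWindow,
    revcomp,
)
from .landscape import (
    CombinedScores,
    ToleratedRegion,
    call_tolerated_regions,
    enrichment_scores,
    interval_jaccard,
    normalize_and_combine,
)

__all__ = [
    "FitnessWindow",
    "FitnessLandscape",
    "SimConfig",
    "EmptyLibraryError",
    "random_orf",
    "dcas9_domain_windows",
    "default_simulation",
    "sample_library",
    "pool_counts",
    "sort_pool",
    "emit_reads",
    "run_end_to_end",
    "EndToEndResult",
]

#: Motifs excluded from synthetic reference ORFs so that the chemistry and
#: the caller see a clean target (the scar set is closed under reverse
#: complement; BsaI/BsmbI are checked on both strands).
DEFAULT_FORBIDDEN = (
    NHEI_SITE,
    SPEI_SITE,
    SCAR_AS,
    SCAR_TS,
    BSAI_SITE,
    revcomp(BSAI_SITE),
    BSMBI_SITE,
    revcomp(BSMBI_SITE),
)

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
)


class EmptyLibraryError(MiserError):
    """The size window excludes every possible variant."""


def random_orf(
    n_codons: int,
    rng: np.random.Generator,
    id: str = "synthetic_orf",
    forbidden: tuple[str, ...] = DEFAULT_FORBIDDEN,
) -> OrfRecord:
    """A random stop-free ORF containing none of the forbidden motifs.

    Codons are drawn uniformly from the 61 sense codons; whenever appending
    a codon creates a forbidden motif near the junction, that codon is
    rejection-resampled.
    """
    if n_codons < 2:
        raise MiserError("n_codons must be >= 2")
    guard = max((len(m) for m in forbidden), default=0)
    codons: list[str] = []
    seq = ""
    while len(codons) < n_codons:
        codon = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
        tail = seq[-(guard + 2) :] + codon
        if any(m in tail for m in forbidden):
            continue
        codons.append(codon)
        seq += codon
    return OrfRecord(id=id, nt_seq=seq)


@dataclass(frozen=True)
class FitnessWindow:
    """A residue interval whose fully-contained deletions retain function."""

    start: int
    end: int
    height: float = 1.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise MiserError(f"window start {self.start} > end {self.end}")
        if not 0 < self.height <= 1:
            raise MiserError(f"height {self.height} outside (0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class FitnessLandscape:
    """Step-function fitness: windows of tolerance over a low baseline.

    A deletion's fitness is the height of the smallest window fully
    containing its deleted span (nested windows model sub-domain structure),
    the baseline if no window contains it, and 1.0 for zero-length
    scar-only insertions.
    """

    windows: tuple[FitnessWindow, ...] = ()
    baseline: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.baseline <= 1:
            raise MiserError(f"baseline {self.baseline} outside (0, 1]")

    def fitness(self, a: int, b: int) -> float:
        if b == a:
            return 1.0
        start, end = a + 1, b
        best: FitnessWindow | None = None
        for w in self.windows:
            if w.start <= start and end <= w.end:
                if best is None or w.length < best.length:
                    best = w
        return best.height if best is not None else self.baseline


def dcas9_domain_windows(height: float = 1.0) -> tuple[FitnessWindow, ...]:
    """The four large tolerated regions of dCas9 (REC2, REC3, HNH, RuvC-III)."""
    return (
        FitnessWindow(180, 297, height),
        FitnessWindow(503, 708, height),
        FitnessWindow(792, 897, height),
        FitnessWindow(1010, 1081, height),
    )


@dataclass(frozen=True)
class SimConfig:
    """Experiment-scale knobs for one simulated selection.

    Defaults mirror the screen the simulator emulates: 100-nt single-end
    reads, a read pool dominated (50%) by full-length reads that never cross
    a scar, and a low substitution error rate typical of short-read data.
    """

    orf: OrfRecord
    n_library_variants: int = 1500
    size_window: SizeWindow | None = None
    n_reads_naive: int = 200_000
    n_reads_sorted: int = 200_000
    read_len: int = 100
    substitution_error_rate: float = 0.001
    wt_read_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_library_variants, self.n_reads_naive, self.n_reads_sorted) < 0:
            raise MiserError("counts must be >= 0")
        for rate in (self.substitution_error_rate, self.wt_read_fraction):
            if not 0 <= rate <= 1:
                raise MiserError(f"rate {rate} outside [0, 1]")


def default_simulation(
    seed: int = 0, n_codons: int = 1368
) -> tuple[SimConfig, FitnessLandscape]:
    """The standard simulated experiment used throughout the test suite.

    A synthetic 1368-codon ORF, the four dCas9 domain windows as ground
    truth, and a stringent gel slice retaining deletions of 1-50 codons
    (ORF lengths 3(N-50)+6 .. 3(N-1)+6 bp).  The slice plays the same role
    as gel slices in a real screen: it concentrates the library on a size
    range where a substantial share (~30%) of junction pairs falls inside
    tolerated windows, which makes recovery metrics well-posed.
    """
    rng = np.random.default_rng(seed)
    orf = random_orf(n_codons, rng)
    cfg = SimConfig(
        orf=orf,
        size_window=SizeWindow(3 * (n_codons - 50) + 6, 3 * (n_codons - 1) + 6),
        seed=seed,
    )
    return cfg, FitnessLandscape(windows=dcas9_domain_windows())


def _draw_pairs(n: int, n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n junction pairs uniformly over {(a, b): 1 <= a <= b <= N}."""
    total = deletion_count(n_codons)
    # lexicographic block a has N - a + 1 pairs
    offsets = np.cumsum(np.arange(n_codons, 0, -1))
    u = rng.integers(0, total, size=n)
    idx = np.searchsorted(offsets, u, side="right")
    prev = np.concatenate([[0], offsets])[idx]
    a = idx + 1
    b = a + (u - prev)
    return np.stack([a, b], axis=1)


def sample_library(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> Counter:
    """Sample the post-size-selection variant library.

    Junction pairs are drawn uniformly (triangular length marginal);
    draws outside the size window are rejected until
    ``n_library_variants`` variants pass.  Scar types are assigned AS/TS
    with equal probability.  Returns a Counter over
    :class:`~miser.core.DeletionVariant` (collisions accumulate abundance).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_codons = cfg.orf.n_codons
    window = cfg.size_window
    if window is not None:
        feasible = any(
            window.contains(3 * (n_codons - k) + 6) for k in range(n_codons)
        )
        if not feasible:
            raise EmptyLibraryError(
                f"window {window.min_bp}-{window.max_bp} bp excludes every variant"
            )
    library: Counter = Counter()
    need = cfg.n_library_variants
    while need > 0:
        pairs = _draw_pairs(max(need * 2, 64), n_codons, rng)
        if window is not None:
            bp = 3 * (n_codons - (pairs[:, 1] - pairs[:, 0])) + 6
            pairs = pairs[(bp >= window.min_bp) & (bp <= window.max_bp)]
        pairs = pairs[:need]
        scars = rng.integers(0, 2, size=len(pairs))
        for (a, b), s in zip(pairs.tolist(), scars.tolist()):
            library[DeletionVariant(a=int(a), b=int(b), scar_type="AS" if s == 0 else "TS")] += 1
        need = cfg.n_library_variants - sum(library.values())
    return library


def pool_counts(
    library: Counter,
    n_reads: int,
    rng: np.random.Generator,
    fitness: FitnessLandscape | None = None,
) -> Counter:
    """Multinomial pool of n_reads with probability ∝ abundance × fitness."""
    variants = sorted(library)
    if not variants:
        if n_reads:
            raise EmptyLibraryError("cannot draw reads from an empty library")
        return Counter()
    weights = np.array([library[v] for v in variants], dtype=float)
    if fitness is not None:
        weights = weights * np.array([fitness.fitness(v.a, v.b) for v in variants])
    if n_reads == 0:
        return Counter()
    draws = rng.multinomial(n_reads, weights / weights.sum())
    return Counter({v: int(c) for v, c in zip(variants, draws.tolist()) if c})


def sort_pool(
    library: Counter,
    fitness: FitnessLandscape,
    n_reads_sorted: int,
    rng: "np.random.Generator | int",
) -> Counter:
    """FACS-style fitness-weighted resampling of the library."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return pool_counts(library, n_reads_sorted, rng, fitness=fitness)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_errors(seq: str, n_err: int, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(arr), size=n_err, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def emit_reads(
    pool: Counter,
    orf: OrfRecord,
    cfg: SimConfig,
    rng: np.random.Generator,
    n_wt_reads: int = 0,
    pool_name: str = "pool",
) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) for one sequencing pool.

    Each variant read is a ``read_len`` window of the variant ORF drawn
    uniformly among windows overlapping the scar by at least one base
    (reads elsewhere on the amplicon are indistinguishable from full-length
    template and are represented by the WT read fraction).  WT reads are
    uniform windows of the reference.  I.i.d. substitution errors are
    applied at ``substitution_error_rate``; the quality string is constant.
    """
    L = cfg.read_len
    qual = "I" * L
    rate = cfg.substitution_error_rate
    counter = 0
    seq_cache: dict[tuple[int, int, str], str] = {}
    for variant in sorted(pool):
        count = pool[variant]
        key = (variant.a, variant.b, variant.scar_type)
        var_seq = seq_cache.get(key)
        if var_seq is None:
            var_seq, _ = build_variant_sequence(orf, variant)
            seq_cache[key] = var_seq
        if L > len(var_seq):
            raise MiserError(
                f"read_len {L} exceeds variant ORF length {len(var_seq)}"
            )
        scar_start = 3 * variant.a  # 0-based
        lo = max(0, scar_start - L + 1)
        hi = min(scar_start + 5, len(var_seq) - L)
        starts = rng.integers(lo, hi + 1, size=count)
        n_err = rng.binomial(L, rate, size=count) if rate > 0 else np.zeros(count, int)
        for s, e in zip(starts.tolist(), n_err.tolist()):
            seq = var_seq[s : s + L]
            if e:
                seq = _apply_errors(seq, e, rng)
            yield (
                f"{pool_name}:{variant.a}-{variant.b}:{variant.scar_type}:{counter}",
                seq,
                qual,
            )
            counter += 1
    if n_wt_reads:
        if L > len(orf.nt_seq):
            raise MiserError(f"read_len {L} exceeds reference length")
        starts = rng.integers(0, len(orf.nt_seq) - L + 1, size=n_wt_reads)
        n_err = (
            rng.binomial(L, rate, size=n_wt_reads)
            if rate > 0
            else np.zeros(n_wt_reads, int)
        )
        for s, e in zip(starts.tolist(), n_err.tolist()):
            seq = orf.nt_seq[s : s + L]
            if e:
                seq = _apply_errors(seq, e, rng)
            yield (f"{pool_name}:wt:{counter}", seq, qual)
            counter += 1


@dataclass
class EndToEndResult:
    """Planted-versus-recovered comparison for one simulated experiment."""

    cfg: SimConfig
    fitness: FitnessLandscape | None
    library: Counter
    naive: PoolCounts
    sorted: PoolCounts
    scores: CombinedScores
    regions: list[ToleratedRegion]
    jaccard: dict[tuple[int, int], float]
    rank_correlation: float
    n_well_sampled: int


def run_end_to_end(
    cfg: SimConfig,
    fitness: FitnessLandscape | None,
    caller_cfg: CallerConfig | None = None,
    score_threshold: float = 0.3,
    min_len: int = 10,
    min_support: int = 5,
    well_sampled_min: int = 10,
) -> EndToEndResult:
    """Simulate, sequence, call, score and compare against ground truth.

    ``fitness=None`` runs a neutral selection (every variant equally fit).
    Per planted window the best Jaccard overlap with any called region is
    reported; the rank correlation is Spearman's rho between combined
    scores and planted fitness over variants with a naive tally of at least
    ``well_sampled_min``.
    """
    rng = np.random.default_rng(cfg.seed)
    library = sample_library(cfg, rng)

    n_var_naive = round(cfg.n_reads_naive * (1 - cfg.wt_read_fraction))
    n_var_sorted = round(cfg.n_reads_sorted * (1 - cfg.wt_read_fraction))
    naive_pool = pool_counts(library, n_var_naive, rng)
    sorted_pool = pool_counts(library, n_var_sorted, rng, fitness=fitness)

    caller_cfg = caller_cfg or CallerConfig()
    naive_reads = emit_reads(
        naive_pool, cfg.orf, cfg, rng,
        n_wt_reads=cfg.n_reads_naive - n_var_naive, pool_name="naive",
    )
    naive_counts = count_variants(
        ((rid, seq) for rid, seq, _ in naive_reads), cfg.orf, caller_cfg
    )
    sorted_reads = emit_reads(
        sorted_pool, cfg.orf, cfg, rng,
        n_wt_reads=cfg.n_reads_sorted - n_var_sorted, pool_name="sorted",
    )
    sorted_counts = count_variants(
        ((rid, seq) for rid, seq, _ in sorted_reads), cfg.orf, caller_cfg
    )

    score_frame = enrichment_scores(naive_counts, sorted_counts)
    combined = normalize_and_combine({"slice1": score_frame}, min_overlap=1)
    regions = call_tolerated_regions(
        combined.table,
        score_threshold=score_threshold,
        min_len=min_len,
        min_support=min_support,
    )

    jaccard: dict[tuple[int, int], float] = {}
    if fitness is not None:
        for w in fitness.windows:
            jaccard[w.span] = max(
                (interval_jaccard(w.span, (r.start, r.end)) for r in regions),
                default=0.0,
            )

    rho = float("nan")
    n_well = 0
    if fitness is not None:
        naive_totals = naive_counts.totals()
        pairs = [ab for ab in combined.table.index if naive_totals.get(ab, 0) >= well_sampled_min]
        n_well = len(pairs)
        if n_well >= 3:
            f = [fitness.fitness(a, b) for a, b in pairs]
            s = combined.table.loc[pairs, "score"].to_numpy()
            rho = float(stats.spearmanr(f, s).statistic)

    return EndToEndResult(
        cfg=cfg,
        fitness=fitness,
        library=library,
        naive=naive_counts,
        sorted=sorted_counts,
        scores=combined,
        regions=regions,
        jaccard=jaccard,
        rank_correlation=rho,
        n_well_sampled=n_well,
    )
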