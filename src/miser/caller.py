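"""Call deletion coordinates from single-end reads by scar + flank matching.

A junction read looks like

    ... WT codons 1..a | GCTAGT or ACTAGC | WT codons b+1..N ...

The caller finds the 6-bp scar motif, takes ``flank_len`` nucleotides on each
side, and requires each flank to match the reference exactly (and, by
default, uniquely).  The upstream flank must end on a codon boundary (3a) and
the downstream flank must start on one (3b + 1); the gap between the two
matches is then 3(b - a).  A non-negative gap is a deletion call, a negative
gap a duplication.  Exact matching mirrors the conservative read-filtering
rule of the original screen: a sequencing error in a flank discards the read
rather than risking a wrong coordinate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

from .core import MiserError, OrfRecord, SCAR_AS, SCAR_TS, revcomp

__all__ = [
    "CallerConfig",
    "ReadCall",
    "FlankIndex",
    "find_scar",
    "call_read",
    "count_variants",
    "PoolCounts",
]

# call outcomes
DELETION = "DELETION"
DUPLICATION = "DUPLICATION"
WT_NO_SCAR = "WT_NO_SCAR"
NO_CALL = "NO_CALL"

# NO_CALL reasons
FLANK_TRUNCATED = "flank_truncated"
FLANK_MISMATCH = "flank_mismatch"
FLANK_NONUNIQUE = "flank_nonunique"
FRAME_VIOLATION = "frame_violation"
AMBIGUOUS_NATURAL_MOTIF = "ambiguous_natural_motif"
MULTIPLE_MOTIFS = "multiple_motifs"

NO_CALL_REASONS = (
    FLANK_TRUNCATED,
    FLANK_MISMATCH,
    FLANK_NONUNIQUE,
    FRAME_VIOLATION,
    AMBIGUOUS_NATURAL_MOTIF,
    MULTIPLE_MOTIFS,
)

_SCAR_TYPES = {SCAR_AS: "AS", SCAR_TS: "TS"}


@dataclass(frozen=True)
class CallerConfig:
    flank_len: int = 15
    scan_reverse_complement: bool = False
    require_unique_flank: bool = True

    def __post_init__(self) -> None:
        if self.flank_len < 8:
            raise MiserError(f"flank_len {self.flank_len} < 8")


@dataclass(frozen=True)
class ReadCall:
    read_id: str
    outcome: str  # DELETION / DUPLICATION / WT_NO_SCAR / NO_CALL
    a: int | None = None
    b: int | None = None
    scar_type: str | None = None
    reason: str | None = None


class FlankIndex:
    """Exact k-mer index of the reference for O(1) flank lookup."""

    def __init__(self, orf: OrfRecord, flank_len: int):
        self.flank_len = flank_len
        self.ref = orf.nt_seq
        positions: dict[str, list[int]] = {}
        for i in range(len(self.ref) - flank_len + 1):
            positions.setdefault(self.ref[i : i + flank_len], []).append(i)
        self._positions = positions

    def occurrences(self, kmer: str) -> list[int]:
        """0-based start offsets of ``kmer`` in the reference."""
        return self._positions.get(kmer, [])


def find_scar(read: str) -> list[tuple[int, str]]:
    """All scar-motif occurrences on the given strand, as (1-based offset, type)."""
    hits: list[tuple[int, str]] = []
    for motif, scar_type in _SCAR_TYPES.items():
        start = read.find(motif)
        while start != -1:
            hits.append((start + 1, scar_type))
            start = read.find(motif, start + 1)
    hits.sort()
    return hits


def call_read(
    read: str,
    orf: OrfRecord,
    cfg: CallerConfig | None = None,
    index: FlankIndex | None = None,
    read_id: str = "read",
) -> ReadCall:
    """Classify a single read (see module docstring for the rules).

    With ``scan_reverse_complement`` the read is re-called on its reverse
    complement whenever the forward strand yields no positive call (a
    reverse-strand junction read shows the complementary scar motif on the
    forward scan, with flanks that cannot match the sense reference).
    """
    cfg = cfg or CallerConfig()
    if index is None or index.flank_len != cfg.flank_len:
        index = FlankIndex(orf, cfg.flank_len)
    read = read.upper()
    call = _call_strand(read, orf, cfg, index, read_id)
    if cfg.scan_reverse_complement and call.outcome not in (DELETION, DUPLICATION):
        rc_call = _call_strand(revcomp(read), orf, cfg, index, read_id)
        if rc_call.outcome in (DELETION, DUPLICATION):
            return rc_call
    return call


def _call_strand(
    read: str,
    orf: OrfRecord,
    cfg: CallerConfig,
    index: FlankIndex,
    read_id: str,
) -> ReadCall:
    hits = find_scar(read)
    if not hits:
        return ReadCall(read_id, WT_NO_SCAR)
    if len(hits) > 1:
        return ReadCall(read_id, NO_CALL, reason=MULTIPLE_MOTIFS)

    offset1, scar_type = hits[0]
    motif_start = offset1 - 1  # 0-based
    fl = cfg.flank_len
    if motif_start < fl or motif_start + 6 + fl > len(read):
        return ReadCall(read_id, NO_CALL, reason=FLANK_TRUNCATED)

    up = read[motif_start - fl : motif_start]
    down = read[motif_start + 6 : motif_start + 6 + fl]
    up_occ = index.occurrences(up)
    down_occ = index.occurrences(down)
    if not up_occ or not down_occ:
        return ReadCall(read_id, NO_CALL, reason=FLANK_MISMATCH)
    if cfg.require_unique_flank and (len(up_occ) > 1 or len(down_occ) > 1):
        return ReadCall(read_id, NO_CALL, reason=FLANK_NONUNIQUE)

    candidates = []
    for u in up_occ:
        up_end = u + fl  # 0-based exclusive end == 3a for a codon-boundary match
        for d in down_occ:
            if up_end % 3 != 0 or d % 3 != 0:
                continue
            candidates.append((up_end // 3, d // 3))
    if not candidates:
        return ReadCall(read_id, NO_CALL, reason=FRAME_VIOLATION)
    if len(candidates) > 1:
        return ReadCall(read_id, NO_CALL, reason=FLANK_NONUNIQUE)

    a, b = candidates[0]
    motif = read[motif_start : motif_start + 6]
    if b - a == 2 and orf.nt_seq[3 * a : 3 * a + 6] == motif:
        # the "deleted" dicodon equals the scar: read is indistinguishable from WT
        return ReadCall(read_id, NO_CALL, reason=AMBIGUOUS_NATURAL_MOTIF)
    if b >= a:
        return ReadCall(read_id, DELETION, a=a, b=b, scar_type=scar_type)
    return ReadCall(read_id, DUPLICATION, a=a, b=b, scar_type=scar_type)


@dataclass
class PoolCounts:
    """Per-variant read tallies for one sequencing pool."""

    counts: dict[tuple[int, int], dict[str, int]] = field(default_factory=dict)
    duplications: Counter = field(default_factory=Counter)
    wt: int = 0
    no_call: Counter = field(default_factory=Counter)
    n_reads: int = 0

    def add(self, call: ReadCall) -> None:
        self.n_reads += 1
        if call.outcome == DELETION:
            per_scar = self.counts.setdefault((call.a, call.b), {"AS": 0, "TS": 0})
            per_scar[call.scar_type] += 1
        elif call.outcome == DUPLICATION:
            self.duplications[(call.a, call.b)] += 1
        elif call.outcome == WT_NO_SCAR:
            self.wt += 1
        else:
            self.no_call[call.reason] += 1

    def totals(self) -> dict[tuple[int, int], int]:
        """Scar-collapsed per-(a, b) tallies (landscape variant identity)."""
        return {ab: sc["AS"] + sc["TS"] for ab, sc in self.counts.items()}

    @property
    def n_variant_reads(self) -> int:
        return sum(sc["AS"] + sc["TS"] for sc in self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, sc["AS"], sc["TS"], sc["AS"] + sc["TS"])
            for (a, b), sc in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["a", "b", "count_AS", "count_TS", "count_total"]
        )

    def summary(self) -> dict:
        out = {
            "reads": self.n_reads,
            "deletion_calls": self.n_variant_reads,
            "duplication_calls": sum(self.duplications.values()),
            "wt_no_scar": self.wt,
        }
        for reason in NO_CALL_REASONS:
            out[f"no_call_{reason}"] = int(self.no_call.get(reason, 0))
        return out


def count_variants(
    reads: "Iterable[tuple[str, str]] | str",
    orf: OrfRecord,
    cfg: CallerConfig | None = None,
) -> PoolCounts:
    """Tally scar calls over a read stream.

    ``reads`` is either an iterable of ``(read_id, sequence)`` pairs or a
    path to a FASTQ file (plain or gzipped).  Tallies are order-invariant.
    """
    cfg = cfg or CallerConfig()
    if isinstance(reads, (str,)) or hasattr(reads, "__fspath__"):
        from .io import iter_fastq

        reads = iter_fastq(reads)
    index = FlankIndex(orf, cfg.flank_len)
    pool = PoolCounts()
    for read_id, seq in reads:
        pool.add(call_read(seq, orf, cfg, index=index, read_id=read_id))
    return pool
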