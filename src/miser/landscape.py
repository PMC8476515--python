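"""Enrichment scoring, slice normalization, triangular raster and region calling.

Scores are log10 ratios of pseudocounted variant frequencies after versus
before selection.  Slices (gel-extracted sublibraries sequenced separately)
are cross-calibrated by an affine least-squares fit on shared variants, with
the Pearson correlation reported as the QC statistic, averaged per variant,
and min-max rescaled to [0, 1] for display.  Region calling thresholds the
calibrated log10 score: it is the scale on which "x-fold enriched" means the
same thing in every run, whereas the [0, 1] rescale is display-only (its
extremes are data-dependent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import MiserError

__all__ = [
    "enrichment_scores",
    "CombinedScores",
    "normalize_and_combine",
    "OverlapError",
    "LandscapeRaster",
    "rasterize_landscape",
    "ToleratedRegion",
    "call_tolerated_regions",
    "interval_jaccard",
]


class OverlapError(MiserError):
    """Too few shared variants to cross-calibrate two slices."""


def _totals(pool) -> dict[tuple[int, int], int]:
    if hasattr(pool, "totals"):
        return pool.totals()
    return {tuple(k): int(v) for k, v in dict(pool).items()}


def enrichment_scores(
    naive,
    sorted_,
    pseudocount: float = 1.0,
    pseudocount_mode: str = "all",
) -> pd.DataFrame:
    """Per-variant log10 enrichment of sorted over naive frequencies.

    Both pools are restricted to the union of their variant sets.  With
    ``pseudocount_mode="all"`` (default) the pseudocount is added to every
    variant's count in both pools; with ``"missing_only"`` it is added only
    where a count is zero.  Frequencies are renormalized after adding, so
    each pool remains a proper distribution and every score is finite.

    Accepts :class:`~miser.caller.PoolCounts` or mappings ``(a, b) -> count``.
    Returns a DataFrame indexed by (a, b) with count, frequency and score
    columns.
    """
    n = _totals(naive)
    s = _totals(sorted_)
    union = sorted(set(n) | set(s))
    if not union:
        return pd.DataFrame(
            columns=["naive_count", "sorted_count", "naive_freq", "sorted_freq", "score"],
            index=pd.MultiIndex.from_arrays([[], []], names=["a", "b"]),
        )
    nc = np.array([n.get(v, 0) for v in union], dtype=float)
    sc = np.array([s.get(v, 0) for v in union], dtype=float)
    if pseudocount_mode == "all":
        np_ = nc + pseudocount
        sp_ = sc + pseudocount
    elif pseudocount_mode == "missing_only":
        np_ = np.where(nc == 0, pseudocount, nc)
        sp_ = np.where(sc == 0, pseudocount, sc)
    else:
        raise MiserError(f"unknown pseudocount_mode {pseudocount_mode!r}")
    nf = np_ / np_.sum()
    sf = sp_ / sp_.sum()
    frame = pd.DataFrame(
        {
            "naive_count": nc.astype(int),
            "sorted_count": sc.astype(int),
            "naive_freq": nf,
            "sorted_freq": sf,
            # difference of logs (not log of ratio) so that swapping the two
            # pools negates every score bit-exactly
            "score": np.log10(sf) - np.log10(nf),
        },
        index=pd.MultiIndex.from_tuples(union, names=["a", "b"]),
    )
    return frame


@dataclass
class CombinedScores:
    """Cross-calibrated, averaged and display-rescaled scores.

    table
        DataFrame indexed by (a, b): ``score`` (combined log10 enrichment on
        the reference slice's scale), ``score_scaled`` (min-max [0, 1]) and
        ``n_slices`` (values contributing to the mean).
    pearson
        Pearson r of each non-reference slice against the reference on
        shared variants.
    affine
        ``slice_id -> (slope, intercept)`` least-squares map onto the
        reference scale.
    """

    table: pd.DataFrame
    reference: str
    pearson: dict[str, float]
    affine: dict[str, tuple[float, float]]


def normalize_and_combine(
    scores_by_slice: Mapping[str, "pd.DataFrame | pd.Series"],
    min_overlap: int = 50,
    reference: str | None = None,
) -> CombinedScores:
    """Merge per-slice enrichment scores onto a common scale.

    Steps: (i) Pearson r on shared variants between each slice and the
    reference slice (first key by default); (ii) affine least-squares map of
    each non-reference slice onto the reference scale; (iii) per-variant
    mean where a variant has several values; (iv) min-max rescale to [0, 1]
    for display.  Raises :class:`OverlapError` when a slice shares fewer
    than ``min_overlap`` variants with the reference.
    """
    if not scores_by_slice:
        raise MiserError("no slices supplied")
    series: dict[str, pd.Series] = {}
    for slice_id, frame in scores_by_slice.items():
        s = frame["score"] if isinstance(frame, pd.DataFrame) else frame
        series[slice_id] = s.astype(float)
    if reference is None:
        reference = next(iter(series))
    if reference not in series:
        raise MiserError(f"reference slice {reference!r} not among slices")

    ref = series[reference]
    pearson: dict[str, float] = {}
    affine: dict[str, tuple[float, float]] = {}
    calibrated: dict[str, pd.Series] = {reference: ref}
    for slice_id, s in series.items():
        if slice_id == reference:
            continue
        shared = ref.index.intersection(s.index)
        if len(shared) < min_overlap:
            raise OverlapError(
                f"slice {slice_id!r} shares only {len(shared)} variants with "
                f"{reference!r} (minimum {min_overlap}); combine refused"
            )
        x = s.loc[shared].to_numpy()
        y = ref.loc[shared].to_numpy()
        pearson[slice_id] = float(stats.pearsonr(x, y)[0]) if len(shared) > 1 else float("nan")
        slope, intercept = np.polyfit(x, y, 1)
        affine[slice_id] = (float(slope), float(intercept))
        calibrated[slice_id] = slope * s + intercept

    stacked = pd.concat(calibrated.values())
    grouped = stacked.groupby(level=list(range(stacked.index.nlevels)))
    combined = grouped.mean()
    n_slices = grouped.size()

    lo, hi = float(combined.min()), float(combined.max())
    if hi > lo:
        scaled = (combined - lo) / (hi - lo)
    else:
        scaled = pd.Series(0.0, index=combined.index)
    table = pd.DataFrame(
        {"score": combined, "score_scaled": scaled, "n_slices": n_slices}
    )
    table.index.names = ["a", "b"]
    return CombinedScores(table=table, reference=reference, pearson=pearson, affine=affine)


@dataclass
class LandscapeRaster:
    """Triangular deletion landscape at exact (length, midpoint) coordinates.

    Row ``L = b - a`` (deletion length; larger deletions at the top when
    plotted), column ``c = a + b`` (twice the midpoint — the half-integer
    midpoint grid at 2x horizontal resolution makes ``(L, c) <-> (a, b)`` a
    bijection, so no two variants collide in one cell).
    """

    matrix: np.ndarray  # shape (max_L + 1, 2 * n_codons + 1); NaN = missing
    n_codons: int
    value_col: str

    @property
    def populated_cells(self) -> int:
        return int(np.count_nonzero(~np.isnan(self.matrix)))

    def variants(self):
        """De-rasterize: yield (a, b, value) for every populated cell."""
        rows, cols = np.nonzero(~np.isnan(self.matrix))
        for L, c in zip(rows.tolist(), cols.tolist()):
            a = (c - L) // 2
            b = (c + L) // 2
            yield a, b, float(self.matrix[L, c])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.matrix)
        frame.index.name = "deletion_length"
        frame.columns.name = "midpoint_x2"
        return frame

    def plot(self, path: "str | None" = None, ax=None):
        """Render the landscape (midpoint on x, deletion length on y)."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 5))
        masked = np.ma.masked_invalid(self.matrix)
        im = ax.imshow(
            masked,
            origin="lower",
            aspect="auto",
            interpolation="nearest",
            extent=(0, self.n_codons, 0, self.matrix.shape[0]),
            cmap="viridis",
        )
        ax.set_xlabel("deletion midpoint (codon)")
        ax.set_ylabel("deletion length (codons)")
        ax.figure.colorbar(im, ax=ax, label=self.value_col)
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def rasterize_landscape(
    scores: pd.DataFrame,
    value_col: str = "score_scaled",
    n_codons: int | None = None,
) -> LandscapeRaster:
    """Place each scored variant (a, b) at (row b - a, column a + b)."""
    a = scores.index.get_level_values("a").to_numpy()
    b = scores.index.get_level_values("b").to_numpy()
    values = scores[value_col].to_numpy(dtype=float)
    if n_codons is None:
        n_codons = int(b.max()) if len(b) else 1
    L = b - a
    c = a + b
    matrix = np.full((int(L.max()) + 1 if len(L) else 1, 2 * n_codons + 1), np.nan)
    matrix[L, c] = values
    return LandscapeRaster(matrix=matrix, n_codons=n_codons, value_col=value_col)


@dataclass(frozen=True)
class ToleratedRegion:
    """A merged residue interval whose deletions score above threshold."""

    start: int
    end: int
    mean_score: float
    support: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def call_tolerated_regions(
    scores: pd.DataFrame,
    score_threshold: float = 0.3,
    min_len: int = 10,
    min_support: int = 5,
    score_col: str = "score",
) -> list[ToleratedRegion]:
    """Project above-threshold deletions onto the residue axis and merge.

    Variants with ``score >= score_threshold`` and k >= 1 contribute their
    deleted span [a+1, b]; overlapping or abutting spans merge; merged
    intervals shorter than ``min_len`` or supported by fewer than
    ``min_support`` variants are dropped.  The default threshold of 0.3 on
    the log10 scale corresponds to ~2-fold enrichment.
    """
    if scores.empty:
        return []
    sel = scores[scores[score_col] >= score_threshold]
    spans = []
    for (a, b), row in sel.iterrows():
        if b > a:  # k = 0 insertions have no deleted span
            spans.append((a + 1, b, float(row[score_col])))
    spans.sort()
    regions: list[ToleratedRegion] = []
    cur_start = cur_end = None
    cur_scores: list[float] = []
    for start, end, score in spans + [(None, None, None)]:
        if cur_start is not None and (start is None or start > cur_end + 1):
            region = ToleratedRegion(
                start=cur_start,
                end=cur_end,
                mean_score=float(np.mean(cur_scores)),
                support=len(cur_scores),
            )
            if region.length >= min_len and region.support >= min_support:
                regions.append(region)
            cur_start = None
        if start is None:
            break
        if cur_start is None:
            cur_start, cur_end, cur_scores = start, end, [score]
        else:
            cur_end = max(cur_end, end)
            cur_scores.append(score)
    return regions


def interval_jaccard(x: tuple[int, int], y: tuple[int, int]) -> float:
    """Jaccard overlap of two 1-based inclusive integer intervals."""
    inter = max(0, min(x[1], y[1]) - max(x[0], y[0]) + 1)
    union = (x[1] - x[0] + 1) + (y[1] - y[0] + 1) - inter
    return inter / union if union else 0.0
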