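"""Digestion-ligation chemistry, deletion-space enumeration and construct assembly.

The deletion space of an N-codon ORF is the set of junction pairs (a, b)
with 1 <= a <= b <= N: N(N+1)/2 variants, including the N zero-length
scar-only insertions (a = b).  Pairs with b < a are duplications; they exist
in a real ligation pool but are excluded from the deletion landscape.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator

from .core import (
    CoordinateError,
    DeletionVariant,
    Duplication,
    Enzyme,
    MiserError,
    OrfRecord,
    SCAR_BY_ENZYME_ORDER,
    SCARS,
    SizeWindow,
    StackedConstruct,
    translate,
)

__all__ = [
    "ReligationError",
    "ligate_junction",
    "deletion_count",
    "enumerate_deletions",
    "build_variant_sequence",
    "stack_deletions",
    "build_stacked_sequence",
    "retained_fraction_pct",
    "size_select",
]


class ReligationError(MiserError):
    """Same enzyme on both sides would regenerate a cuttable site."""


def ligate_junction(
    upstream_enzyme: Enzyme | str,
    a: int,
    downstream_enzyme: Enzyme | str,
    b: int,
) -> DeletionVariant | Duplication:
    """Product of ligating an upstream fragment cut at ``a`` to a downstream
    fragment cut at ``b``.

    NheI-upstream/SpeI-downstream leaves the AS scar (GCTAGT); the reverse
    order leaves TS (ACTAGC).  ``b >= a`` is a deletion of codons a+1..b;
    ``b < a`` duplicates codons b+1..a and is returned as a
    :class:`~miser.core.Duplication`.
    """
    up = Enzyme.parse(upstream_enzyme)
    down = Enzyme.parse(downstream_enzyme)
    if up is down:
        raise ReligationError(
            f"{up.value} on both sides regenerates the {up.value} site"
        )
    scar = SCAR_BY_ENZYME_ORDER[(up, down)]
    if a < 1 or b < 1:
        raise CoordinateError("junction positions must be >= 1")
    if b >= a:
        return DeletionVariant(a=a, b=b, scar_type=scar.scar_type)
    return Duplication(a=a, b=b, scar_type=scar.scar_type)


def deletion_count(n_codons: int) -> int:
    """Number of distinct junction pairs: N(N+1)/2."""
    if n_codons < 1:
        raise MiserError(f"n_codons must be >= 1, got {n_codons}")
    return n_codons * (n_codons + 1) // 2


def enumerate_deletions(n_codons: int) -> Iterator[tuple[int, int]]:
    """Lazily yield every junction pair (a, b), b >= a, in lexicographic order."""
    if n_codons < 1:
        raise MiserError(f"n_codons must be >= 1, got {n_codons}")
    for a in range(1, n_codons + 1):
        for b in range(a, n_codons + 1):
            yield (a, b)


def build_variant_sequence(orf: OrfRecord, variant: DeletionVariant) -> tuple[str, str]:
    """DNA and protein of a single deletion variant.

    DNA = codons 1..a + scar + codons b+1..N; the protein is
    WT[1..a] + scar dipeptide + WT[b+1..N].
    """
    variant.validate(orf.n_codons)
    dna = (
        orf.codons(1, variant.a)
        + variant.scar.scar_nt
        + orf.codons(variant.b + 1, orf.n_codons)
    )
    return dna, translate(dna)


def build_duplication_sequence(orf: OrfRecord, dup: Duplication) -> tuple[str, str]:
    """DNA and protein of a duplication product (codons b+1..a appear twice)."""
    if dup.a > orf.n_codons:
        raise CoordinateError(f"a={dup.a} outside 1..{orf.n_codons}")
    dna = (
        orf.codons(1, dup.a)
        + dup.scar.scar_nt
        + orf.codons(dup.b + 1, orf.n_codons)
    )
    return dna, translate(dna)


def stack_deletions(
    orf: OrfRecord | int,
    spans: Iterable[tuple[int, int] | tuple[int, int, str]],
) -> StackedConstruct:
    """Combine several deletions (1-based inclusive residue spans) on one ORF.

    Spans are sorted; overlapping spans raise
    :class:`~miser.core.StackingError`.  Abutting spans (end + 1 == next
    start) are chemically legal — adjacent scars — and are kept with a
    warning.  Omitted scar types default to AS.
    """
    n_codons = orf.n_codons if isinstance(orf, OrfRecord) else int(orf)
    normalized: list[tuple[int, int, str]] = []
    for span in spans:
        if len(span) == 2:
            start, end = span  # type: ignore[misc]
            scar_type = "AS"
        else:
            start, end, scar_type = span  # type: ignore[misc]
        normalized.append((int(start), int(end), scar_type))
    normalized.sort()
    for (s1, e1, _), (s2, _, _) in zip(normalized, normalized[1:]):
        if s2 == e1 + 1:
            warnings.warn(
                f"spans {s1}-{e1} and starting {s2} abut; scars will be adjacent",
                stacklevel=2,
            )
    return StackedConstruct(n_codons=n_codons, spans=tuple(normalized))


def build_stacked_sequence(orf: OrfRecord, construct: StackedConstruct) -> tuple[str, str]:
    """DNA and protein of a stacked construct (one scar per junction)."""
    if construct.n_codons != orf.n_codons:
        raise CoordinateError("construct was built for a different ORF length")
    parts: list[str] = []
    cursor = 1  # next retained codon
    for start, end, scar_type in construct.spans:
        if start > cursor:
            parts.append(orf.codons(cursor, start - 1))
        parts.append(SCARS[scar_type].scar_nt)
        cursor = end + 1
    if cursor <= orf.n_codons:
        parts.append(orf.codons(cursor, orf.n_codons))
    dna = "".join(parts)
    return dna, translate(dna)


def retained_fraction_pct(construct: StackedConstruct) -> int:
    """Percent of original residues retained, rounded to the nearest integer."""
    return round(100 * construct.retained_fraction)


def size_select(
    variants: Iterable[DeletionVariant],
    window: SizeWindow,
    n_codons: int,
) -> list[DeletionVariant]:
    """Keep variants whose ORF length 3(N - k) + 6 falls inside the window."""
    return [v for v in variants if window.contains(v.nt_length(n_codons))]
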