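"""Recombineering oligo design for restriction-site insertion libraries.

Each oligo inserts a single 6-bp NheI or SpeI recognition site immediately
after one codon of the target ORF.  The ordered oligo carries constant
priming ends used for pool amplification; each priming end embeds a BsmbI
(CGTCTC) site oriented to cut the priming end off, so that BsmbI digestion
matures the oligo into ``upstream_arm + site + downstream_arm``.

The shipped priming-end sequences are synthetic placeholders (GC-balanced
20-mers with outward-cutting BsmbI sites); they are not the sequences used in
any published oligo pool.  Digestion is modelled at the top-strand cut point;
the 4-nt overhang chemistry of BsmbI is abstracted away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .core import (
    BSAI_SITE,
    BSMBI_SITE,
    CoordinateError,
    Enzyme,
    MiserError,
    NHEI_SITE,
    OrfRecord,
    SPEI_SITE,
    InsertionSite,
    revcomp,
)

__all__ = [
    "OligoDesignConfig",
    "RecombineeringOligo",
    "design_oligo",
    "design_library",
    "screen_conflicts",
    "digest_bsmbi",
    "simulate_recombineering_insertion",
    "RecombinationError",
]

#: 13 nt filler + CGTCTC + 1 nt spacer: BsmbI cuts the top strand one base
#: past its site, i.e. exactly at the start of the upstream homology arm.
DEFAULT_FWD_PRIME = "ATGCATCCTAGGC" + BSMBI_SITE + "A"
#: 1 nt spacer + GAGACG (BsmbI on the bottom strand) + 13 nt filler: the
#: bottom-strand cut lands exactly at the end of the downstream arm.
DEFAULT_REV_PRIME = "T" + revcomp(BSMBI_SITE) + "GCATTACGGATCC"


class RecombinationError(MiserError):
    """Homology arms absent from, or ambiguous in, the target plasmid."""


@dataclass(frozen=True)
class OligoDesignConfig:
    """Tunable oligo geometry.

    arm_len
        Homology per side in nt (default 35; must be >= 15).
    fwd_prime / rev_prime
        Constant priming ends, each containing exactly one BsmbI site cutting
        outward so digestion releases the mature insert.
    context_5 / context_3
        Vector sequence flanking the ORF.  Arms near the ORF ends extend into
        this context; without it they are truncated with a warning.
    """

    arm_len: int = 35
    fwd_prime: str = DEFAULT_FWD_PRIME
    rev_prime: str = DEFAULT_REV_PRIME
    context_5: str = ""
    context_3: str = ""

    def __post_init__(self) -> None:
        if self.arm_len < 15:
            raise MiserError(f"arm_len {self.arm_len} < 15")
        for name, prime in (("fwd_prime", self.fwd_prime), ("rev_prime", self.rev_prime)):
            n = prime.count(BSMBI_SITE) + prime.count(revcomp(BSMBI_SITE))
            if n != 1:
                raise MiserError(f"{name} must contain exactly one BsmbI site (found {n})")


@dataclass(frozen=True)
class RecombineeringOligo:
    site: InsertionSite
    upstream_arm: str
    downstream_arm: str
    fwd_prime: str
    rev_prime: str

    @property
    def mature_insert(self) -> str:
        """The recombineering-competent insert left after BsmbI digestion."""
        return self.upstream_arm + self.site.site_seq + self.downstream_arm

    @property
    def full_seq(self) -> str:
        return self.fwd_prime + self.mature_insert + self.rev_prime

    @property
    def name(self) -> str:
        return f"{self.site.enzyme.value}_{self.site.position:04d}"


def design_oligo(
    orf: OrfRecord,
    enzyme: Enzyme | str,
    position: int,
    cfg: OligoDesignConfig | None = None,
) -> RecombineeringOligo:
    """Design the oligo inserting ``enzyme``'s site after codon ``position``.

    The upstream arm ends at the last nucleotide of codon ``position``; the
    downstream arm starts at the first nucleotide of codon ``position + 1``
    (or runs into 3' vector context at the final position).
    """
    cfg = cfg or OligoDesignConfig()
    enzyme = Enzyme.parse(enzyme)
    site = InsertionSite(enzyme, position)
    site.validate(orf.n_codons)

    extended = cfg.context_5 + orf.nt_seq + cfg.context_3
    cut = len(cfg.context_5) + 3 * position  # insertion point in `extended`

    up_start = cut - cfg.arm_len
    if up_start < 0:
        warnings.warn(
            f"position {position}: upstream arm truncated to {cut} nt "
            "(no 5' context supplied)",
            stacklevel=2,
        )
        up_start = 0
    down_end = cut + cfg.arm_len
    if down_end > len(extended):
        warnings.warn(
            f"position {position}: downstream arm truncated to "
            f"{len(extended) - cut} nt (no 3' context supplied)",
            stacklevel=2,
        )
        down_end = len(extended)

    return RecombineeringOligo(
        site=site,
        upstream_arm=extended[up_start:cut],
        downstream_arm=extended[cut:down_end],
        fwd_prime=cfg.fwd_prime,
        rev_prime=cfg.rev_prime,
    )


def design_library(
    orf: OrfRecord,
    enzyme: Enzyme | str,
    cfg: OligoDesignConfig | None = None,
) -> list[RecombineeringOligo]:
    """One oligo per insertion position 1..N, in position order."""
    enzyme = Enzyme.parse(enzyme)
    return [design_oligo(orf, enzyme, pos, cfg) for pos in range(1, orf.n_codons + 1)]


#: Enzymes screened for pre-existing sites that would break the chemistry.
_SCREEN_SITES: dict[str, str] = {
    "NheI": NHEI_SITE,
    "SpeI": SPEI_SITE,
    "BsaI": BSAI_SITE,
    "BsmbI": BSMBI_SITE,
}


def screen_conflicts(seq_or_orf: OrfRecord | str) -> list[tuple[str, int, str]]:
    """Report pre-existing NheI/SpeI/BsaI/BsmbI sites in a sequence.

    Returns ``(enzyme, 1-based offset, strand)`` tuples.  Palindromic sites
    (NheI, SpeI) are reported once per occurrence on the plus strand;
    non-palindromic sites (BsaI, BsmbI) are additionally searched as their
    reverse complement and reported on the minus strand at the plus-strand
    offset of the match.
    """
    seq = seq_or_orf.nt_seq if isinstance(seq_or_orf, OrfRecord) else seq_or_orf.upper()
    hits: list[tuple[str, int, str]] = []
    for name, motif in _SCREEN_SITES.items():
        start = seq.find(motif)
        while start != -1:
            hits.append((name, start + 1, "+"))
            start = seq.find(motif, start + 1)
        rc = revcomp(motif)
        if rc != motif:
            start = seq.find(rc)
            while start != -1:
                hits.append((name, start + 1, "-"))
                start = seq.find(rc, start + 1)
    hits.sort(key=lambda h: (h[1], h[0], h[2]))
    return hits


def digest_bsmbi(full_seq: str) -> str:
    """Simulate BsmbI maturation of an ordered oligo.

    Expects exactly one plus-strand (CGTCTC) and one minus-strand (GAGACG)
    site.  The top-strand cut of the plus-strand site falls one base past the
    site; the bottom-strand site's cut is taken one base before GAGACG.
    Returns the double-cut middle fragment.
    """
    fwd = [i for i in _find_all(full_seq, BSMBI_SITE)]
    rev = [i for i in _find_all(full_seq, revcomp(BSMBI_SITE))]
    if len(fwd) != 1 or len(rev) != 1:
        raise MiserError(
            f"expected one BsmbI site per strand, found {len(fwd)}+/{len(rev)}-"
        )
    left = fwd[0] + len(BSMBI_SITE) + 1
    right = rev[0] - 1
    if left >= right:
        raise MiserError("BsmbI sites are not oriented to cut outward")
    return full_seq[left:right]


def _find_all(seq: str, motif: str) -> list[int]:
    out = []
    start = seq.find(motif)
    while start != -1:
        out.append(start)
        start = seq.find(motif, start + 1)
    return out


def _circular_find_all(plasmid: str, motif: str) -> list[int]:
    """Occurrences of ``motif`` in a circular sequence (0-based starts < len)."""
    doubled = plasmid + plasmid[: len(motif) - 1]
    return [i for i in _find_all(doubled, motif) if i < len(plasmid)]


def circular_equal(a: str, b: str) -> bool:
    """True when two sequences are identical up to rotation."""
    return len(a) == len(b) and a in b + b


def simulate_recombineering_insertion(plasmid: str, oligo: RecombineeringOligo) -> str:
    """Insert the oligo's 6-bp site into a circular plasmid between its arms.

    The plasmid must contain the arm-arm junction (upstream arm immediately
    followed by downstream arm) exactly once, circularly.  The returned
    sequence is rotated so the upstream arm starts at position 0; compare
    results with :func:`circular_equal`.
    """
    junction = oligo.upstream_arm + oligo.downstream_arm
    if not junction:
        raise RecombinationError("oligo has empty homology arms")
    hits = _circular_find_all(plasmid, junction)
    if not hits:
        raise RecombinationError("homology arm junction not found in plasmid")
    if len(hits) > 1:
        raise RecombinationError(
            f"homology arm junction found {len(hits)} times; insertion ambiguous"
        )
    start = hits[0]
    rotated = plasmid[start:] + plasmid[:start]
    return (
        oligo.upstream_arm
        + oligo.site.site_seq
        + rotated[len(oligo.upstream_arm) :]
    )
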