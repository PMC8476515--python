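"""Domain types and coordinate conventions shared by every MISER module.

A MISER (minimization by iterative size-exclusion and recombination) library
is built on a single coding sequence.  All coordinates in this package follow
one convention:

* codons are numbered 1..N (no stop codon);
* an insertion position ``i`` means "immediately after codon i", so an
  N-codon ORF has exactly N insertion positions (position N sits between the
  last codon and the stop);
* a deletion variant is a junction pair ``(a, b)`` with ``a <= b``: the
  N-terminal fragment retains codons 1..a, the C-terminal fragment retains
  codons b+1..N, and codons a+1..b are deleted (``k = b - a``; ``k = 0`` is a
  pure two-codon scar insertion);
* residue intervals are reported 1-based inclusive; any BED export converts
  to 0-based half-open nucleotide coordinates.

Cross-ligation of an NheI-cut upstream fragment to a SpeI-cut downstream
fragment leaves the 6-bp scar GCTAGT (Ala-Ser); the opposite order leaves
ACTAGC (Thr-Ser).  Neither scar is recognized by either enzyme, which is what
makes the chemistry iterable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "NHEI_SITE",
    "SPEI_SITE",
    "BSAI_SITE",
    "BSMBI_SITE",
    "SCAR_AS",
    "SCAR_TS",
    "SCARS",
    "MiserError",
    "FrameError",
    "AlphabetError",
    "InternalStopError",
    "CoordinateError",
    "StackingError",
    "Enzyme",
    "ScarJunction",
    "OrfRecord",
    "InsertionSite",
    "DeletionVariant",
    "Duplication",
    "StackedConstruct",
    "SizeWindow",
    "revcomp",
    "translate",
    "validate_orf",
]

#: 6-bp recognition sequences used by the chemistry.
NHEI_SITE = "GCTAGC"
SPEI_SITE = "ACTAGT"
BSAI_SITE = "GGTCTC"
BSMBI_SITE = "CGTCTC"

#: The two possible ligation scars (hybrid NheI/SpeI junctions).
SCAR_AS = "GCTAGT"  # Ala-Ser
SCAR_TS = "ACTAGC"  # Thr-Ser

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_DNA = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MiserError(ValueError):
    """Base class for all domain errors raised by this package."""


class FrameError(MiserError):
    """Sequence length is not a multiple of three."""


class AlphabetError(MiserError):
    """Sequence contains characters outside {A, C, G, T}."""


class InternalStopError(MiserError):
    """In-frame stop codon found before the final codon."""


class CoordinateError(MiserError):
    """Codon/junction coordinate outside the valid range."""


class StackingError(MiserError):
    """Deletion spans passed to a stacked construct overlap."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt_seq: str) -> str:
    """Translate an in-frame DNA string with the standard genetic code.

    Stop codons translate to ``*``.  Raises :class:`FrameError` if the length
    is not a multiple of three.
    """
    if len(nt_seq) % 3 != 0:
        raise FrameError(f"length {len(nt_seq)} is not a multiple of 3")
    if not nt_seq:
        return ""
    return str(Seq(nt_seq).translate())


class Enzyme(enum.Enum):
    """Restriction enzymes used in MISER construction.

    NheI (G^CTAGC) and SpeI (A^CTAGT) both leave 5'-CTAG overhangs, so any
    NheI-cut end ligates to any SpeI-cut end.  BsaI/BsmbI are the type IIS
    enzymes used for excision and oligo maturation.
    """

    NHEI = "NheI"
    SPEI = "SpeI"

    @property
    def site(self) -> str:
        return NHEI_SITE if self is Enzyme.NHEI else SPEI_SITE

    #: offset of the top-strand cut within the recognition site
    #: (both leave the 5'-CTAG overhang after one leading base).
    @property
    def cut_offset(self) -> int:
        return 1

    @classmethod
    def parse(cls, name: "str | Enzyme") -> "Enzyme":
        if isinstance(name, Enzyme):
            return name
        for enz in cls:
            if enz.value.lower() == str(name).lower():
                return enz
        raise MiserError(f"unknown enzyme {name!r} (expected NheI or SpeI)")


@dataclass(frozen=True)
class ScarJunction:
    """A 6-bp ligation scar and the dipeptide it encodes."""

    scar_type: str  # "AS" or "TS"
    scar_nt: str
    scar_aa: str

    def __post_init__(self) -> None:
        if translate(self.scar_nt) != self.scar_aa:
            raise MiserError(
                f"scar {self.scar_nt} does not translate to {self.scar_aa}"
            )
        if NHEI_SITE in self.scar_nt or SPEI_SITE in self.scar_nt:
            raise MiserError("scar must not be re-cuttable by NheI or SpeI")


#: The only two scars the chemistry can produce.
SCARS: dict[str, ScarJunction] = {
    "AS": ScarJunction("AS", SCAR_AS, "AS"),
    "TS": ScarJunction("TS", SCAR_TS, "TS"),
}

#: Scar left by (upstream enzyme, downstream enzyme) cross-ligation.
SCAR_BY_ENZYME_ORDER: dict[tuple[Enzyme, Enzyme], ScarJunction] = {
    (Enzyme.NHEI, Enzyme.SPEI): SCARS["AS"],
    (Enzyme.SPEI, Enzyme.NHEI): SCARS["TS"],
}


@dataclass(frozen=True)
class OrfRecord:
    """A validated coding sequence (sense strand, stop codon stripped)."""

    id: str
    nt_seq: str
    stop_codon: str | None = None

    @property
    def n_codons(self) -> int:
        return len(self.nt_seq) // 3

    @property
    def aa_seq(self) -> str:
        return translate(self.nt_seq)

    def codons(self, start: int, end: int) -> str:
        """Nucleotides of codons ``start..end`` (1-based inclusive)."""
        if not (0 <= start - 1 <= end <= self.n_codons):
            raise CoordinateError(f"codon range {start}..{end} outside 1..{self.n_codons}")
        return self.nt_seq[3 * (start - 1) : 3 * end]


def validate_orf(nt_seq: str, id: str = "orf") -> OrfRecord:
    """Validate a coding sequence and return an :class:`OrfRecord`.

    A stop codon at the 3' end is stripped and recorded.  Raises
    :class:`FrameError`, :class:`AlphabetError` or :class:`InternalStopError`.
    """
    if not nt_seq:
        raise MiserError("empty sequence")
    nt_seq = nt_seq.upper()
    bad = set(nt_seq) - _DNA
    if bad:
        raise AlphabetError(f"non-ACGT characters: {sorted(bad)}")
    if len(nt_seq) % 3 != 0:
        raise FrameError(f"length {len(nt_seq)} is not a multiple of 3")
    stop: str | None = None
    if nt_seq[-3:] in STOP_CODONS:
        stop = nt_seq[-3:]
        nt_seq = nt_seq[:-3]
    aa = translate(nt_seq)
    if "*" in aa:
        pos = aa.index("*") + 1
        raise InternalStopError(f"in-frame stop codon at codon {pos}")
    if len(nt_seq) // 3 < 2:
        raise MiserError("ORF must contain at least 2 codons")
    return OrfRecord(id=id, nt_seq=nt_seq, stop_codon=stop)


@dataclass(frozen=True)
class InsertionSite:
    """A restriction-site insertion immediately after codon ``position``."""

    enzyme: Enzyme
    position: int

    @property
    def site_seq(self) -> str:
        return self.enzyme.site

    def validate(self, n_codons: int) -> None:
        if not 1 <= self.position <= n_codons:
            raise CoordinateError(
                f"insertion position {self.position} outside 1..{n_codons}"
            )


@dataclass(frozen=True, order=True)
class DeletionVariant:
    """A junction pair ``(a, b)`` with ``a <= b`` plus the scar it carries.

    ``a`` is the last retained codon of the N-terminal fragment, ``b`` the
    last deleted codon (codons ``a+1..b`` are removed; ``k = b - a``).
    """

    a: int
    b: int
    scar_type: str = "AS"

    def __post_init__(self) -> None:
        if self.a < 1:
            raise CoordinateError(f"a={self.a} must be >= 1")
        if self.b < self.a:
            raise CoordinateError(f"b={self.b} < a={self.a}: use Duplication")
        if self.scar_type not in SCARS:
            raise MiserError(f"unknown scar type {self.scar_type!r}")

    @property
    def k(self) -> int:
        """Number of deleted codons."""
        return self.b - self.a

    @property
    def scar(self) -> ScarJunction:
        return SCARS[self.scar_type]

    @property
    def deleted_span(self) -> tuple[int, int] | None:
        """Deleted residue interval ``[a+1, b]`` (1-based), None when k = 0."""
        if self.k == 0:
            return None
        return (self.a + 1, self.b)

    def nt_length(self, n_codons: int) -> int:
        """Variant ORF length in bp: 3(N - k) + 6 (scar included)."""
        return 3 * (n_codons - self.k) + 6

    def protein_length(self, n_codons: int) -> int:
        """Variant protein length: N - k + 2 (two scar residues)."""
        return n_codons - self.k + 2

    def validate(self, n_codons: int) -> None:
        if self.b > n_codons:
            raise CoordinateError(f"b={self.b} outside 1..{n_codons}")


@dataclass(frozen=True)
class Duplication:
    """A ligation product whose downstream junction lies upstream (b < a).

    Codons ``b+1..a`` appear twice in the product, separated by the scar.
    """

    a: int
    b: int
    scar_type: str = "AS"

    def __post_init__(self) -> None:
        if self.b >= self.a:
            raise CoordinateError("a duplication requires b < a")
        if self.scar_type not in SCARS:
            raise MiserError(f"unknown scar type {self.scar_type!r}")

    @property
    def scar(self) -> ScarJunction:
        return SCARS[self.scar_type]

    @property
    def duplicated_span(self) -> tuple[int, int]:
        """Duplicated residue interval ``[b+1, a]`` (1-based inclusive)."""
        return (self.b + 1, self.a)


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive ORF-length window (bp) modelling a gel slice."""

    min_bp: int
    max_bp: int

    def __post_init__(self) -> None:
        if self.min_bp > self.max_bp:
            raise MiserError(f"min_bp {self.min_bp} > max_bp {self.max_bp}")

    def contains(self, length_bp: int) -> bool:
        return self.min_bp <= length_bp <= self.max_bp


@dataclass(frozen=True)
class StackedConstruct:
    """Several pairwise-disjoint deletions applied to one ORF.

    Each junction leaves one two-residue scar, so the protein length is
    ``N - sum(k_i) + 2 m`` for m junctions.
    """

    n_codons: int
    spans: tuple[tuple[int, int, str], ...] = field(default=())  # (start, end, scar_type)

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, scar_type in self.spans:
            if not 1 <= start <= end <= self.n_codons:
                raise CoordinateError(
                    f"span {start}-{end} outside 1..{self.n_codons}"
                )
            if start <= prev_end:
                raise StackingError(
                    f"span {start}-{end} overlaps a previous span (spans must be "
                    "sorted and disjoint)"
                )
            if scar_type not in SCARS:
                raise MiserError(f"unknown scar type {scar_type!r}")
            prev_end = end

    @property
    def n_junctions(self) -> int:
        return len(self.spans)

    @property
    def deleted_total(self) -> int:
        return sum(end - start + 1 for start, end, _ in self.spans)

    @property
    def protein_length(self) -> int:
        return self.n_codons - self.deleted_total + 2 * self.n_junctions

    @property
    def retained_fraction(self) -> float:
        """Fraction of original residues retained (scars excluded)."""
        return (self.n_codons - self.deleted_total) / self.n_codons
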