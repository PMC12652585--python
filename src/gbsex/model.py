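"""Core data model for GBS sex-marker screening.

The pipeline operates on a catalog of GBS tags (short restriction-fragment
loci, optionally with a consensus sequence) carrying biallelic SNP sites,
genotyped in a panel of phenotypically sexed individuals.  Everything
downstream — per-sex allele statistics, the three sex-linkage detectors,
system classification, chromosome assignment, and primer design — consumes
the types defined here.

Coordinate convention: 0-based half-open everywhere inside the package.
1-based formats (VCF, BLAST outfmt 6) are converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np


class ValidationError(ValueError):
    """An input violates a documented invariant of the data model."""


class FormatError(ValueError):
    """A file does not conform to the accepted dialect."""


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"


#: accepted tokens in sex-map files (case-insensitive)
SEX_TOKENS = {
    "m": Sex.MALE,
    "male": Sex.MALE,
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
}


class Genotype(IntEnum):
    """Diploid genotype coded as ALT-allele dosage; -1 for no call."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


@dataclass(frozen=True)
class SexMap:
    """Ordered sample → phenotypic sex assignment.

    Sample identifiers must be unique and both sexes must be represented
    by at least one individual (a frequency in one sex is meaningless
    otherwise; detectors apply their own, stricter minimum).
    """

    entries: tuple[tuple[str, Sex], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sample_id, sex in self.entries:
            if sample_id in seen:
                raise ValidationError(f"duplicate sample_id in sex map: {sample_id!r}")
            seen.add(sample_id)
            if not isinstance(sex, Sex):
                raise ValidationError(f"invalid sex label for {sample_id!r}: {sex!r}")
        for want in (Sex.MALE, Sex.FEMALE):
            if not any(sex is want for _, sex in self.entries):
                raise ValidationError(f"sex map has zero {want.name} samples")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def males(self) -> list[str]:
        return [s for s, sex in self.entries if sex is Sex.MALE]

    @property
    def females(self) -> list[str]:
        return [s for s, sex in self.entries if sex is Sex.FEMALE]

    @property
    def n_males(self) -> int:
        return len(self.males)

    @property
    def n_females(self) -> int:
        return len(self.females)

    def sex_of(self, sample_id: str) -> Sex:
        for s, sex in self.entries:
            if s == sample_id:
                return sex
        raise KeyError(sample_id)

    def as_dict(self) -> dict[str, Sex]:
        return dict(self.entries)

    def swapped(self) -> "SexMap":
        """Relabel every MALE as FEMALE and vice versa (symmetry checks)."""
        flip = {Sex.MALE: Sex.FEMALE, Sex.FEMALE: Sex.MALE}
        return SexMap(tuple((s, flip[sex]) for s, sex in self.entries))


@dataclass
class Site:
    """One biallelic SNP within a tag.

    ``genotypes`` is an int8 vector aligned with ``TagCatalog.samples``,
    holding :class:`Genotype` codes.
    """

    site_id: str
    offset: int
    ref: str
    alt: str
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"site {self.site_id}: ref == alt ({self.ref})")
        for base, label in ((self.ref, "ref"), (self.alt, "alt")):
            if len(base) != 1 or base not in "ACGTN":
                raise ValidationError(
                    f"site {self.site_id}: {label} allele {base!r} is not a single base"
                )
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)


@dataclass
class Tag:
    """One GBS tag: an assembled restriction-fragment locus."""

    tag_id: str
    sites: list[Site]
    consensus: str | None = None
    presence: np.ndarray | None = None  # per-sample bool; derived when None

    def __post_init__(self) -> None:
        offsets = [s.offset for s in self.sites]
        if len(set(offsets)) != len(offsets) or offsets != sorted(offsets):
            raise ValidationError(
                f"tag {self.tag_id}: site offsets must be unique and ascending"
            )
        if self.consensus is not None:
            for s in self.sites:
                if not 0 <= s.offset < len(self.consensus):
                    raise ValidationError(
                        f"tag {self.tag_id}: site offset {s.offset} outside consensus"
                    )

    def presence_vector(self, n_samples: int) -> np.ndarray:
        """Per-sample tag recovery: at least one called site.

        Presence is genotype-derived: with a genotype matrix as input,
        read-level absence and genotyping dropout are indistinguishable.
        An explicit presence vector, when set, must be consistent with the
        genotypes (absent ⇒ every site missing) and takes precedence.
        """
        derived = np.zeros(n_samples, dtype=bool)
        for s in self.sites:
            derived |= s.genotypes != Genotype.MISSING
        if self.presence is not None:
            pres = np.asarray(self.presence, dtype=bool)
            if pres.shape != (n_samples,):
                raise ValidationError(f"tag {self.tag_id}: presence vector wrong length")
            if np.any(derived & ~pres):
                raise ValidationError(
                    f"tag {self.tag_id}: presence False but called genotypes exist"
                )
            return pres
        return derived


@dataclass
class TagCatalog:
    """All tags plus the sample panel their genotype vectors refer to."""

    samples: list[str]
    tags: list[Tag]
    #: reader bookkeeping (dropped multi-allelic records etc.); never affects analysis
    source_stats: "ReadStats | None" = None

    def __post_init__(self) -> None:
        n = len(self.samples)
        if len(set(self.samples)) != n:
            raise ValidationError("catalog sample list contains duplicates")
        seen: set[str] = set()
        for tag in self.tags:
            if tag.tag_id in seen:
                raise ValidationError(f"duplicate tag_id: {tag.tag_id}")
            seen.add(tag.tag_id)
            for site in tag.sites:
                if site.genotypes.shape != (n,):
                    raise ValidationError(
                        f"site {site.site_id}: genotype vector length "
                        f"{site.genotypes.shape} != {n} samples"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return sum(len(t.sites) for t in self.tags)

    def iter_sites(self):
        for tag in self.tags:
            for site in tag.sites:
                yield tag, site

    def tag_by_id(self, tag_id: str) -> Tag:
        for tag in self.tags:
            if tag.tag_id == tag_id:
                return tag
        raise KeyError(tag_id)


@dataclass
class ReadStats:
    """Record accounting for a reader: kept + dropped = seen."""

    n_records: int = 0
    n_kept: int = 0
    n_dropped_multiallelic: int = 0
    n_dropped_non_snp: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_multiallelic + self.n_dropped_non_snp


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"
    UNKNOWN = "."


@dataclass(frozen=True)
class AlignmentHit:
    """One row of BLAST tabular output (outfmt 6), 1-based coordinates.

    Strand is inferred from subject coordinate order: a subject interval
    reported end-before-start is a minus-strand alignment.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(f"hit {self.query_id}: negative e-value")
        if min(self.q_start, self.q_end, self.s_start, self.s_end) < 1:
            raise ValidationError(f"hit {self.query_id}: coordinates must be >= 1")

    @property
    def strand(self) -> Strand:
        return Strand.MINUS if self.s_start > self.s_end else Strand.PLUS

    def subject_interval(self) -> tuple[int, int]:
        """Subject placement as 0-based half-open (start, end)."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi


@dataclass(frozen=True)
class GeneInterval:
    """Candidate-gene placement on the reference, 0-based half-open."""

    gene_name: str
    chrom: str
    start: int
    end: int
    strand: Strand = Strand.UNKNOWN

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"gene {self.gene_name}: start {self.start} >= end {self.end}"
            )
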