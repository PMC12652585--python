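"""Diagnostic PCR primer design for sex-specific GBS tags.

Two strategies:

* PA (presence/absence, allele-specific): both primers place a
  sex-specific variant (the Y allele in an XY system) at their 3'
  terminal base, so only the Y haplotype is amplified and males give a
  band while females give none.  The forward primer ends ON one anchor
  site; the reverse primer is the reverse complement of the template
  window starting at the other anchor, putting the complement of that
  site's Y allele at its own 3' end.
* SD (single-nucleotide dimorphism, codominant): both primers sit in
  windows free of any sex-specific variant, and the product spans at
  least one dimorphic SNP; sequencing the amplicon shows a double peak in
  the heterogametic sex and a single peak in the other.

Melting temperatures are nearest-neighbor (SantaLucia 1998 unified
parameters, 50 mM monovalent salt, 250 nM oligo).  Candidate pairs are
ranked by forward/reverse Tm balance.  In-silico PCR uses an exact
full-length binding model: real PCR tolerates internal mismatches, but the
diagnostic logic of a PA pair rests entirely on its 3' anchor, and exact
matching makes the male-only amplification property provable;
``allow_3prime_mismatch`` exists to probe how much the discrimination
depends on the terminal base.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

from .model import Tag, ValidationError


class DesignFailure(str, Enum):
    NEEDS_TWO_SNPS = "NEEDS_TWO_SNPS"
    NO_FEASIBLE_PAIR = "NO_FEASIBLE_PAIR"
    NO_CONSERVED_FLANKS = "NO_CONSERVED_FLANKS"


class PrimerDesignError(Exception):
    """Typed design failure; ``code`` tells the caller whether a fallback
    (e.g. SD instead of PA) is worth attempting."""

    def __init__(self, code: DesignFailure, message: str):
        super().__init__(message)
        self.code = code


class Mode(str, Enum):
    PA = "PA"
    SD = "SD"


@dataclass(frozen=True)
class PrimerConstraints:
    len_min: int = 18
    len_max: int = 27
    tm_min: float = 52.0
    tm_max: float = 62.0
    product_min: int = 100
    product_max: int = 300
    gc_min: float = 0.2
    gc_max: float = 0.8

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.len_min, self.len_max),
            (self.tm_min, self.tm_max),
            (self.product_min, self.product_max),
            (self.gc_min, self.gc_max),
        ):
            if lo > hi:
                raise ValidationError(f"constraint min {lo} > max {hi}")
        if self.len_min < 8:
            raise ValidationError("len_min must be >= 8")


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair; rev_seq is written 5'->3' on the minus strand.

    fwd_start / rev_end delimit the amplicon as a 0-based half-open
    interval on the tag, so product_len == rev_end - fwd_start.
    """

    locus_id: str
    mode: Mode
    fwd_seq: str
    rev_seq: str
    fwd_start: int
    rev_end: int
    product_len: int
    fwd_tm: float
    rev_tm: float
    anchored_snps: tuple[int, ...] = ()  # PA: the two 3'-anchored offsets
    spanned_snps: tuple[int, ...] = ()   # SD: dimorphic offsets inside product

    @property
    def tm_imbalance(self) -> float:
        return abs(self.fwd_tm - self.rev_tm)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def melting_temperature(seq: str) -> float:
    """Nearest-neighbor duplex Tm in deg C.

    SantaLucia 1998 unified NN parameters, 50 mM Na+, 250 nM total oligo.
    Rejects sequences shorter than 8 nt or containing ambiguity codes.
    """
    if len(seq) < 8:
        raise ValidationError(f"sequence too short for NN Tm: {len(seq)} nt")
    if set(seq) - set("ACGT"):
        raise ValidationError(f"ambiguity codes not supported: {seq!r}")
    return float(_mt.Tm_NN(seq, nn_table=_mt.DNA_NN3, Na=50, dnac1=250, dnac2=0))


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class _Candidate:
    seq: str
    start: int  # footprint on the template, 0-based half-open
    end: int
    tm: float


def _candidates_at(
    template: str,
    end3: int,
    direction: int,
    c: PrimerConstraints,
    forbidden: frozenset[int] = frozenset(),
) -> list[_Candidate]:
    """All feasible primers with their 3' end at template offset ``end3``.

    direction +1: forward primer on the plus strand, footprint
    [end3-L+1, end3+1); direction -1: reverse primer, footprint
    [end3, end3+L) and sequence reverse-complemented.
    """
    out: list[_Candidate] = []
    for L in range(c.len_min, c.len_max + 1):
        if direction > 0:
            a, b = end3 - L + 1, end3 + 1
        else:
            a, b = end3, end3 + L
        if a < 0 or b > len(template):
            continue
        if forbidden and any(a <= off < b for off in forbidden):
            continue
        window = template[a:b]
        seq = window if direction > 0 else revcomp(window)
        if not c.gc_min <= _gc(seq) <= c.gc_max:
            continue
        tm = melting_temperature(seq)
        if c.tm_min <= tm <= c.tm_max:
            out.append(_Candidate(seq, a, b, tm))
    return out


def _best_candidate_at(template, end3, direction, c, forbidden=frozenset()):
    cands = _candidates_at(template, end3, direction, c, forbidden)
    if not cands:
        return None
    mid = (c.tm_min + c.tm_max) / 2
    return min(cands, key=lambda x: abs(x.tm - mid))


def substitute(seq: str, replacements: dict[int, str]) -> str:
    """Return seq with single-base substitutions at the given offsets."""
    chars = list(seq)
    for off, base in replacements.items():
        if not 0 <= off < len(chars):
            raise ValidationError(f"substitution offset {off} outside sequence")
        chars[off] = base
    return "".join(chars)


def design_pa(
    tag: Tag,
    y_sites: list[tuple[int, str]],
    c: PrimerConstraints = PrimerConstraints(),
) -> list[PrimerPair]:
    """Allele-specific (PA) pairs, both 3' ends anchored on sex-specific
    variants of the heterogametic haplotype.

    ``y_sites`` are (offset, allele) pairs of the Y-specific bases (W in a
    ZW system).  Primer sequences are read off the Y haplotype — the
    consensus with every y allele substituted — so internal y sites inside
    a footprint are matched too.  Returns all feasible pairs, best
    Tm-balanced first.
    """
    if tag.consensus is None:
        raise ValidationError(f"tag {tag.tag_id}: consensus sequence required")
    if len(y_sites) < 2:
        raise PrimerDesignError(
            DesignFailure.NEEDS_TWO_SNPS,
            f"tag {tag.tag_id}: PA design needs >= 2 sex-specific sites, "
            f"got {len(y_sites)}",
        )
    y_hap = substitute(tag.consensus, dict(y_sites))
    pairs: list[PrimerPair] = []
    for (i, _ai), (j, _aj) in combinations(sorted(y_sites), 2):
        fwd_cands = _candidates_at(y_hap, i, +1, c)
        rev_cands = _candidates_at(y_hap, j, -1, c)
        for f in fwd_cands:
            for r in rev_cands:
                product_len = r.end - f.start
                if not c.product_min <= product_len <= c.product_max:
                    continue
                pairs.append(
                    PrimerPair(
                        locus_id=tag.tag_id,
                        mode=Mode.PA,
                        fwd_seq=f.seq,
                        rev_seq=r.seq,
                        fwd_start=f.start,
                        rev_end=r.end,
                        product_len=product_len,
                        fwd_tm=f.tm,
                        rev_tm=r.tm,
                        anchored_snps=(i, j),
                    )
                )
    if not pairs:
        raise PrimerDesignError(
            DesignFailure.NO_FEASIBLE_PAIR,
            f"tag {tag.tag_id}: no anchor pair admits primers within the "
            "length/Tm/product constraints",
        )
    return sorted(pairs, key=lambda p: (p.tm_imbalance, p.fwd_start, p.rev_end))


def design_sd(
    tag: Tag,
    dimorphic_sites: list[int],
    sex_specific_sites_all: list[int] | None = None,
    c: PrimerConstraints = PrimerConstraints(),
    max_starts: int = 30,
) -> list[PrimerPair]:
    """Codominant (SD) pairs: conserved flanks spanning >= 1 dimorphic SNP.

    Neither footprint may cover any sex-specific site; the amplicon must
    contain at least one of ``dimorphic_sites`` strictly between the two
    3' ends.  ``max_starts`` caps the number of flank positions scanned on
    each side (closest to the target region first), which bounds the Tm
    evaluations without losing short products.
    """
    if tag.consensus is None:
        raise ValidationError(f"tag {tag.tag_id}: consensus sequence required")
    if not dimorphic_sites:
        raise ValidationError(f"tag {tag.tag_id}: SD design needs >= 1 dimorphic site")
    template = tag.consensus
    forbidden = frozenset(dimorphic_sites) | frozenset(sex_specific_sites_all or ())
    d_min, d_max = min(dimorphic_sites), max(dimorphic_sites)

    fwd: list[_Candidate] = []
    for e in range(d_max - 1, -1, -1):  # forward 3' ends, rightmost first
        cand = _best_candidate_at(template, e, +1, c, forbidden)
        if cand:
            fwd.append(cand)
            if len(fwd) >= max_starts:
                break
    rev: list[_Candidate] = []
    for s in range(d_min + 1, len(template)):  # reverse 3' ends, leftmost first
        cand = _best_candidate_at(template, s, -1, c, forbidden)
        if cand:
            rev.append(cand)
            if len(rev) >= max_starts:
                break
    if not fwd or not rev:
        raise PrimerDesignError(
            DesignFailure.NO_CONSERVED_FLANKS,
            f"tag {tag.tag_id}: no conserved primer windows flank the "
            "dimorphic site(s)",
        )
    pairs: list[PrimerPair] = []
    for f in fwd:
        fwd_end3 = f.end - 1
        for r in rev:
            rev_end3 = r.start
            spanned = tuple(
                d for d in sorted(dimorphic_sites) if fwd_end3 < d < rev_end3
            )
            if not spanned:
                continue
            product_len = r.end - f.start
            if not c.product_min <= product_len <= c.product_max:
                continue
            pairs.append(
                PrimerPair(
                    locus_id=tag.tag_id,
                    mode=Mode.SD,
                    fwd_seq=f.seq,
                    rev_seq=r.seq,
                    fwd_start=f.start,
                    rev_end=r.end,
                    product_len=product_len,
                    fwd_tm=f.tm,
                    rev_tm=r.tm,
                    spanned_snps=spanned,
                )
            )
    if not pairs:
        raise PrimerDesignError(
            DesignFailure.NO_FEASIBLE_PAIR,
            f"tag {tag.tag_id}: conserved flanks exist but no pair meets the "
            "product constraints",
        )
    return sorted(pairs, key=lambda p: (p.tm_imbalance, p.fwd_start, p.rev_end))


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Product:
    template_index: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _binding_positions(template: str, site: str, free_pos: int | None) -> list[int]:
    """Start offsets where ``site`` matches exactly (optionally ignoring
    one position, for the 3'-mismatch probe)."""
    L = len(site)
    out = []
    for p in range(len(template) - L + 1):
        window = template[p : p + L]
        if window == site:
            out.append(p)
        elif free_pos is not None and all(
            window[k] == site[k] for k in range(L) if k != free_pos
        ):
            out.append(p)
    return out


def in_silico_pcr(
    templates: tuple[str, str],
    pair: PrimerPair,
    allow_3prime_mismatch: bool = False,
) -> list[Product]:
    """Predict amplicons from a pair of haplotype templates.

    A primer binds iff it matches the template exactly over its full
    length (when ``allow_3prime_mismatch`` is set, the 3' terminal base is
    exempted).  For a male in an XY system pass (X, Y); for a female
    (X, X).  Products are reported per template with plus-strand
    coordinates.
    """
    fwd_site = pair.fwd_seq
    rev_site = revcomp(pair.rev_seq)  # plus-strand footprint of the reverse primer
    Lf, Lr = len(fwd_site), len(rev_site)
    products: list[Product] = []
    for t_idx, template in enumerate(templates):
        f_pos = _binding_positions(
            template, fwd_site, Lf - 1 if allow_3prime_mismatch else None
        )
        r_pos = _binding_positions(
            template, rev_site, 0 if allow_3prime_mismatch else None
        )
        for p in f_pos:
            for q in r_pos:
                if q >= p and q + Lr >= p + Lf:
                    products.append(Product(t_idx, p, q + Lr))
    return products
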