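"""The three sex-linkage detectors and tag-level aggregation.

In a male-heterogametic (XX/XY) system a fully sex-linked SNP shows:

* FREQ — the female-majority allele (the X allele) near fixation in
  females while males, carrying one X and one Y copy, sit near 0.5:
  call when freq_F(major) >= fixation_min and
  freq_F(major) - freq_M(major) >= divergence_min.
* HET — females homozygous, males heterozygous: call when the proportion
  of homozygous females >= hom_prop_min and of heterozygous males
  >= het_prop_min.
* PA — a Y-specific fragment is recovered in males only: tag-level call
  when the tag is entirely absent in females and present in at least
  presence_prop_min of all males.

Each detector has an exact ZW mirror (swap the sexes).  All thresholds are
inclusive.  Site-level calls are lifted to their parent tag and a tag that
collects both XY- and ZW-patterned calls is AMBIGUOUS and excluded from
system classification.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction

import numpy as np
import pandas as pd

from .model import Sex, SexMap, TagCatalog, ValidationError
from .sexstats import Major, SexCounts, SiteSexStats

log = logging.getLogger(__name__)


class Method(str, Enum):
    FREQ = "FREQ"
    HET = "HET"
    PA = "PA"


class Pattern(str, Enum):
    XY = "XY"
    ZW = "ZW"


class Verdict(str, Enum):
    XY = "XY"
    ZW = "ZW"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class DiscoveryConfig:
    """Thresholds for the three detectors (all inclusive, >=)."""

    fixation_min: float = 0.95
    divergence_min: float = 0.4
    hom_prop_min: float = 0.5
    het_prop_min: float = 0.5
    presence_prop_min: float = 0.5
    min_called_per_sex: int = 2

    def __post_init__(self) -> None:
        for name in (
            "fixation_min",
            "divergence_min",
            "hom_prop_min",
            "het_prop_min",
            "presence_prop_min",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.min_called_per_sex < 1:
            raise ValidationError("min_called_per_sex must be >= 1")


@dataclass(frozen=True)
class MarkerCall:
    """One detector firing on one site (FREQ/HET) or tag (PA)."""

    tag_id: str
    site_id: str | None  # None for tag-level PA calls
    method: Method
    pattern: Pattern
    stats: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class TagClassification:
    tag_id: str
    patterns_found: frozenset[Pattern]
    methods_found: frozenset[Method]
    verdict: Verdict
    n_sites_called: dict = field(compare=False, default_factory=dict)


def _heterosex_allele(st: SiteSexStats, pattern: Pattern) -> str | None:
    """Base carried by the sex-limited chromosome (Y for XY, W for ZW).

    It is the allele enriched in the heterogametic sex relative to the
    homogametic one; None when frequencies are undefined or equal.
    """
    if st.female.freq_ref is None or st.male.freq_ref is None:
        return None
    delta = st.male.freq_ref - st.female.freq_ref  # >0: REF male-enriched
    if pattern is Pattern.ZW:
        delta = -delta
    if delta > 0:
        return st.ref
    if delta < 0:
        return st.alt
    return None


def _passes_min_called(st: SiteSexStats, cfg: DiscoveryConfig) -> bool:
    return (
        st.female.n_called >= cfg.min_called_per_sex
        and st.male.n_called >= cfg.min_called_per_sex
    )


def _dec(v: float) -> Fraction:
    """Threshold as an exact rational with decimal semantics (0.4 means
    4/10, not the nearest binary double)."""
    return Fraction(str(v))


def _freq_ref(c: SexCounts) -> Fraction:
    """Exact dosage frequency of the REF allele; boundary comparisons on
    rationals keep the inclusive thresholds exact."""
    return Fraction(2 * c.n_hom_ref + c.n_het, 2 * c.n_called)


def detect_freq(stats: list[SiteSexStats], cfg: DiscoveryConfig) -> list[MarkerCall]:
    """Allele-frequency disparity detector (site level).

    XY: the female-major allele is near-fixed in females and its
    female-minus-male frequency divergence clears divergence_min.
    ZW is the exact mirror.  Divergence is signed — it is the fixation
    allele's own frequency difference, not an absolute difference.
    """
    fixation_min = _dec(cfg.fixation_min)
    divergence_min = _dec(cfg.divergence_min)
    calls: list[MarkerCall] = []
    n_skipped = 0
    for st in stats:
        if not _passes_min_called(st, cfg):
            n_skipped += 1
            continue
        for pattern, fixed_sex, other_sex in (
            (Pattern.XY, st.female, st.male),
            (Pattern.ZW, st.male, st.female),
        ):
            fixed_ref = _freq_ref(fixed_sex)
            if fixed_ref > Fraction(1, 2):
                major = Major.REF
                f_fixed, f_other = fixed_ref, _freq_ref(other_sex)
            elif fixed_ref < Fraction(1, 2):
                major = Major.ALT
                f_fixed, f_other = 1 - fixed_ref, 1 - _freq_ref(other_sex)
            else:
                continue  # tie: no majority allele to test fixation on
            divergence = f_fixed - f_other
            if f_fixed >= fixation_min and divergence >= divergence_min:
                calls.append(
                    MarkerCall(
                        tag_id=st.tag_id,
                        site_id=st.site_id,
                        method=Method.FREQ,
                        pattern=pattern,
                        stats={
                            "fixed_allele": major.value,
                            "fixed_freq": float(f_fixed),
                            "divergence": float(divergence),
                            "sex_specific_allele": _heterosex_allele(st, pattern),
                        },
                    )
                )
    if n_skipped:
        log.info("detect_freq: skipped %d sites below min_called_per_sex", n_skipped)
    return calls


def detect_het(stats: list[SiteSexStats], cfg: DiscoveryConfig) -> list[MarkerCall]:
    """Heterozygosity-contrast detector (site level).

    XY: >= hom_prop_min of called females homozygous AND >= het_prop_min
    of called males heterozygous.  ZW is the mirror.  A site can satisfy
    both at 50/50 mixtures; both calls are emitted and resolved at tag
    level (such a tag becomes AMBIGUOUS).
    """
    hom_prop_min = _dec(cfg.hom_prop_min)
    het_prop_min = _dec(cfg.het_prop_min)
    calls: list[MarkerCall] = []
    n_skipped = 0
    for st in stats:
        if not _passes_min_called(st, cfg):
            n_skipped += 1
            continue
        for pattern, hom_sex, het_sex in (
            (Pattern.XY, st.female, st.male),
            (Pattern.ZW, st.male, st.female),
        ):
            hom_prop = Fraction(hom_sex.n_hom, hom_sex.n_called)
            het_prop = Fraction(het_sex.n_het, het_sex.n_called)
            if hom_prop >= hom_prop_min and het_prop >= het_prop_min:
                calls.append(
                    MarkerCall(
                        tag_id=st.tag_id,
                        site_id=st.site_id,
                        method=Method.HET,
                        pattern=pattern,
                        stats={
                            "hom_prop": float(hom_prop),
                            "het_prop": float(het_prop),
                            "sex_specific_allele": _heterosex_allele(st, pattern),
                        },
                    )
                )
    if n_skipped:
        log.info("detect_het: skipped %d sites below min_called_per_sex", n_skipped)
    return calls


def detect_pa(
    catalog: TagCatalog, sex_map: SexMap, cfg: DiscoveryConfig
) -> list[MarkerCall]:
    """Sex-limited presence/absence detector (tag level).

    A tag is male-specific (XY pattern) when it is recovered in zero
    females and in at least presence_prop_min of all males; the
    female-specific (ZW) call is the mirror.  "Entirely absent" is an
    exact zero — a single recovery in the other sex vetoes the call.
    Presence proportions are over all individuals of the sex, called or
    not, since absence is exactly the signal.
    """
    sex_of = sex_map.as_dict()
    male_mask = np.array([sex_of[s] is Sex.MALE for s in catalog.samples])
    female_mask = ~male_mask
    n_m = int(male_mask.sum())
    n_f = int(female_mask.sum())
    presence_prop_min = _dec(cfg.presence_prop_min)
    calls: list[MarkerCall] = []
    for tag in catalog.tags:
        pres = tag.presence_vector(catalog.n_samples)
        pres_m = int(pres[male_mask].sum())
        pres_f = int(pres[female_mask].sum())
        stats = {
            "n_present_male": pres_m,
            "n_present_female": pres_f,
            "prop_present_male": pres_m / n_m,
            "prop_present_female": pres_f / n_f,
        }
        if pres_f == 0 and Fraction(pres_m, n_m) >= presence_prop_min:
            calls.append(
                MarkerCall(tag.tag_id, None, Method.PA, Pattern.XY, stats)
            )
        elif pres_m == 0 and Fraction(pres_f, n_f) >= presence_prop_min:
            calls.append(
                MarkerCall(tag.tag_id, None, Method.PA, Pattern.ZW, stats)
            )
    return calls


def aggregate_tags(
    calls: list[MarkerCall], catalog: TagCatalog | None = None
) -> list[TagClassification]:
    """Lift site-level calls to tags and assign an XY/ZW/AMBIGUOUS verdict.

    Tags appear in catalog order when a catalog is given (tags without
    calls are omitted), else in first-call order.
    """
    by_tag: dict[str, list[MarkerCall]] = {}
    for call in calls:
        by_tag.setdefault(call.tag_id, []).append(call)
    if catalog is not None:
        order = [t.tag_id for t in catalog.tags if t.tag_id in by_tag]
    else:
        order = list(by_tag)
    out: list[TagClassification] = []
    for tag_id in order:
        tag_calls = by_tag[tag_id]
        patterns = frozenset(c.pattern for c in tag_calls)
        methods = frozenset(c.method for c in tag_calls)
        if patterns == {Pattern.XY, Pattern.ZW}:
            verdict = Verdict.AMBIGUOUS
        elif patterns == {Pattern.XY}:
            verdict = Verdict.XY
        else:
            verdict = Verdict.ZW
        n_sites = {
            m.value: len({c.site_id for c in tag_calls if c.method is m and c.site_id})
            for m in Method
        }
        out.append(TagClassification(tag_id, patterns, methods, verdict, n_sites))
    return out


def snp_method_overlap(calls: list[MarkerCall]) -> dict[str, int]:
    """SNP-level overlap accounting between the FREQ and HET detectors."""
    freq_sites = {c.site_id for c in calls if c.method is Method.FREQ and c.site_id}
    het_sites = {c.site_id for c in calls if c.method is Method.HET and c.site_id}
    return {
        "n_freq_snps": len(freq_sites),
        "n_het_snps": len(het_sites),
        "n_shared_snps": len(freq_sites & het_sites),
    }


def method_tag_sets(calls: list[MarkerCall]) -> dict[str, set[str]]:
    """Tag-id sets per method/pattern, the inputs to union accounting."""
    return {
        "freq": {c.tag_id for c in calls if c.method is Method.FREQ},
        "het": {c.tag_id for c in calls if c.method is Method.HET},
        "pa_male": {
            c.tag_id for c in calls if c.method is Method.PA and c.pattern is Pattern.XY
        },
        "pa_female": {
            c.tag_id for c in calls if c.method is Method.PA and c.pattern is Pattern.ZW
        },
    }


def calls_frame(calls: list[MarkerCall]) -> pd.DataFrame:
    """One row per call, stats flattened, for the output TSV."""
    rows = []
    for c in calls:
        row = {
            "tag_id": c.tag_id,
            "site_id": c.site_id if c.site_id else "",
            "method": c.method.value,
            "pattern": c.pattern.value,
        }
        row.update(c.stats)
        rows.append(row)
    return pd.DataFrame(rows)


def classifications_frame(classes: list[TagClassification]) -> pd.DataFrame:
    rows = []
    for tc in classes:
        rows.append(
            {
                "tag_id": tc.tag_id,
                "verdict": tc.verdict.value,
                "patterns": ",".join(sorted(p.value for p in tc.patterns_found)),
                "methods": ",".join(sorted(m.value for m in tc.methods_found)),
                **{f"n_sites_{k}": v for k, v in tc.n_sites_called.items()},
            }
        )
    return pd.DataFrame(rows)
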