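"""Per-site, per-sex allele frequencies and genotype-class counts.

These are the raw quantities all three sex-linkage detectors consume:
allele frequencies computed from genotype dosage (each called diploid
contributes two allele observations), homozygote/heterozygote class
counts, and the majority allele per sex.

No filtering happens here: sites where one sex has zero calls simply carry
UNDEFINED (None) frequencies, and the detectors decide what to skip.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .model import Genotype, Sex, SexMap, TagCatalog


class Major(str, Enum):
    """Which allele has within-sex frequency > 0.5."""

    REF = "REF"
    ALT = "ALT"
    TIE = "TIE"
    UNDEFINED = "UNDEFINED"


@dataclass(frozen=True)
class SexCounts:
    """Genotype-class tally for one sex at one site."""

    n_called: int
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    freq_ref: float | None  # None iff n_called == 0
    freq_alt: float | None

    @property
    def n_hom(self) -> int:
        return self.n_hom_ref + self.n_hom_alt

    @property
    def major_allele(self) -> Major:
        if self.freq_ref is None:
            return Major.UNDEFINED
        if self.freq_ref > 0.5:
            return Major.REF
        if self.freq_ref < 0.5:
            return Major.ALT
        return Major.TIE

    def freq_of(self, allele: Major) -> float | None:
        if allele is Major.REF:
            return self.freq_ref
        if allele is Major.ALT:
            return self.freq_alt
        raise ValueError(f"no frequency for {allele}")


@dataclass(frozen=True)
class SiteSexStats:
    site_id: str
    tag_id: str
    ref: str
    alt: str
    female: SexCounts
    male: SexCounts

    def by_sex(self, sex: Sex) -> SexCounts:
        return self.male if sex is Sex.MALE else self.female


def _count(geno: np.ndarray) -> SexCounts:
    n_hom_ref = int(np.sum(geno == Genotype.HOM_REF))
    n_het = int(np.sum(geno == Genotype.HET))
    n_hom_alt = int(np.sum(geno == Genotype.HOM_ALT))
    n_called = n_hom_ref + n_het + n_hom_alt
    if n_called == 0:
        return SexCounts(0, 0, 0, 0, None, None)
    # both frequencies from dosage directly, so REF/ALT relabeling is an
    # exact mirror (1 - freq_ref would differ in the last ulp)
    freq_ref = (2 * n_hom_ref + n_het) / (2 * n_called)
    freq_alt = (2 * n_hom_alt + n_het) / (2 * n_called)
    return SexCounts(n_called, n_hom_ref, n_het, n_hom_alt, freq_ref, freq_alt)


def compute_site_stats(catalog: TagCatalog, sex_map: SexMap) -> list[SiteSexStats]:
    """Tally genotype classes and allele frequencies per site and sex.

    MISSING genotypes are excluded from every count; freq_ref is the
    dosage-based reference-allele frequency (2·hom_ref + het) / (2·called).
    """
    sex_of = sex_map.as_dict()
    male_mask = np.array([sex_of[s] is Sex.MALE for s in catalog.samples])
    female_mask = np.array([sex_of[s] is Sex.FEMALE for s in catalog.samples])
    out: list[SiteSexStats] = []
    for tag, site in catalog.iter_sites():
        out.append(
            SiteSexStats(
                site_id=site.site_id,
                tag_id=tag.tag_id,
                ref=site.ref,
                alt=site.alt,
                female=_count(site.genotypes[female_mask]),
                male=_count(site.genotypes[male_mask]),
            )
        )
    return out


def stats_frame(stats: list[SiteSexStats]) -> pd.DataFrame:
    """Flatten stats into one row per site, for the audit TSV dump."""
    rows = []
    for st in stats:
        row: dict = {
            "site_id": st.site_id,
            "tag_id": st.tag_id,
            "ref": st.ref,
            "alt": st.alt,
        }
        for label, c in (("F", st.female), ("M", st.male)):
            row.update(
                {
                    f"n_called_{label}": c.n_called,
                    f"n_hom_ref_{label}": c.n_hom_ref,
                    f"n_het_{label}": c.n_het,
                    f"n_hom_alt_{label}": c.n_hom_alt,
                    f"freq_ref_{label}": np.nan if c.freq_ref is None else c.freq_ref,
                    f"major_{label}": c.major_allele.value,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
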