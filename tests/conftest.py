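"""Shared builders for small, fully explicit test catalogs."""
from __future__ import annotations

import numpy as np
import pytest

from gbsex.model import Genotype, Sex, SexMap, Site, Tag, TagCatalog

# genotype shorthand used throughout the tests
R, H, A, N = (
    int(Genotype.HOM_REF),
    int(Genotype.HET),
    int(Genotype.HOM_ALT),
    int(Genotype.MISSING),
)


def make_sex_map(n_males: int = 10, n_females: int = 10) -> SexMap:
    return SexMap(
        tuple((f"M{i + 1:02d}", Sex.MALE) for i in range(n_males))
        + tuple((f"F{i + 1:02d}", Sex.FEMALE) for i in range(n_females))
    )


def build_catalog(spec: dict, sex_map: SexMap) -> TagCatalog:
    """Build a catalog from {tag_id: [(offset, ref, alt, genotype-list), ...]}.

    Genotype lists are ordered males-first, matching make_sex_map.
    """
    samples = sex_map.sample_ids
    tags = []
    for tag_id, site_rows in spec.items():
        sites = [
            Site(
                site_id=f"{tag_id}:{off}",
                offset=off,
                ref=ref,
                alt=alt,
                genotypes=np.array(genos, dtype=np.int8),
            )
            for off, ref, alt, genos in site_rows
        ]
        tags.append(Tag(tag_id=tag_id, sites=sites))
    return TagCatalog(samples=list(samples), tags=tags)


def random_catalog(
    rng: np.random.Generator,
    n_tags: int = 25,
    n_males: int = 6,
    n_females: int = 6,
    p_missing: float = 0.15,
) -> tuple[TagCatalog, SexMap]:
    """Arbitrary (non-HWE) genotypes including missingness — a worst-case
    input for symmetry and oracle-equivalence properties."""
    sex_map = make_sex_map(n_males, n_females)
    n = n_males + n_females
    spec = {}
    for t in range(n_tags):
        n_sites = int(rng.integers(1, 4))
        offsets = sorted(rng.choice(200, size=n_sites, replace=False).tolist())
        rows = []
        for off in offsets:
            geno = rng.choice([R, H, A], size=n)
            geno[rng.random(n) < p_missing] = N
            rows.append((off, "A", "G", geno.tolist()))
        spec[f"tag{t}"] = rows
    return build_catalog(spec, sex_map), sex_map


@pytest.fixture
def sex_map_10_10() -> SexMap:
    return make_sex_map(10, 10)
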