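"""Forward simulation of GBS genotype catalogs under sex-linked inheritance.

The generator emulates the data a reduced-representation screen of a
male-heterogametic (or, mirrored, female-heterogametic) species produces:

* autosomal tags — SNPs in Hardy–Weinberg proportions at a uniform random
  minor-allele frequency, independent of sex;
* sex-linked tags — every homogametic individual homozygous for the
  consensus (X) allele, every heterogametic individual X/Y heterozygous,
  except that with probability ``recombination_leakage`` a heterogametic
  individual carries X/X at the whole tag (incomplete recombination
  suppression on homomorphic sex chromosomes);
* sex-limited tags — fragments carried only on the sex-limited chromosome,
  recovered in each heterogametic individual with probability
  ``presence_prob`` and never in the other sex;
* opposite-noise tags — a small number of sex-limited tags following the
  mirrored system, so a realistic screen carries a nonzero minority
  pattern.

Genotyping error (miscall to a uniformly random other state) and
missingness are then applied i.i.d.  All randomness flows from one seeded
generator: equal seeds give byte-identical catalogs.  A truth table
records every tag's class and the sex-specific allele of every sex-linked
site, for recovery scoring; sex-linked tags also come with their two
haplotype sequences for primer work.

``simulate_mapping`` fabricates the downstream confirmation inputs: a
BLAST-like best-hit table concentrating sex-patterned tags on one
chromosome and a candidate-gene interval containing a configurable number
of planted markers.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np

from .model import (
    AlignmentHit,
    GeneInterval,
    Genotype,
    Sex,
    SexMap,
    Site,
    Strand,
    Tag,
    TagCatalog,
    ValidationError,
)

BASES = np.array(list("ACGT"))
#: states a genotype can be miscalled to, indexed by true state
_OTHER_STATES = np.array([[1, 2], [0, 2], [0, 1]], dtype=np.int8)


class TagClass(str, Enum):
    AUTOSOMAL = "AUTOSOMAL"
    SEXLINKED_SNP = "SEXLINKED_SNP"
    SEXLIMITED = "SEXLIMITED"
    OPPOSITE_NOISE = "OPPOSITE_NOISE"


@dataclass
class SimConfig:
    """Study-condition knobs; defaults mirror a 10♂+10♀ GBS screen."""

    seed: int
    n_males: int = 10
    n_females: int = 10
    n_auto_tags: int = 1000
    n_sexlinked_tags: int = 50
    n_sexlimited_tags: int = 20
    n_opposite_noise_tags: int = 2
    system: str = "XY"  # "XY" or "ZW"
    tag_len: int = 300
    snp_mean: float = 1.5  # Poisson mean, floored at 1 SNP per tag
    maf_min: float = 0.05
    maf_max: float = 0.5
    genotype_error: float = 0.01
    missing_rate: float = 0.05
    recombination_leakage: float = 0.0
    presence_prob: float = 0.8
    # mapping-simulation knobs
    map_fraction: float = 0.845
    n_gene_markers: int = 4
    n_chromosomes: int = 13

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed is mandatory and must be an integer")
        for name in (
            "genotype_error",
            "missing_rate",
            "recombination_leakage",
            "presence_prob",
            "map_fraction",
            "maf_min",
            "maf_max",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_males",
            "n_females",
            "n_auto_tags",
            "n_sexlinked_tags",
            "n_sexlimited_tags",
            "n_opposite_noise_tags",
            "n_gene_markers",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.system not in ("XY", "ZW"):
            raise ValidationError(f"system must be XY or ZW, got {self.system!r}")
        if self.tag_len < 50:
            raise ValidationError("tag_len must be >= 50")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class TagTruth:
    tag_id: str
    tag_class: TagClass
    #: offset -> sex-specific allele (Y in XY mode, W in ZW), sex-linked tags only
    sex_specific_alleles: dict[int, str] = field(default_factory=dict)
    #: offset -> simulated ALT-allele frequency, HWE-genotyped sites only
    mafs: dict[int, float] = field(default_factory=dict)


@dataclass
class TruthTable:
    tags: dict[str, TagTruth]

    def ids_of(self, tag_class: TagClass) -> list[str]:
        return [t.tag_id for t in self.tags.values() if t.tag_class is tag_class]

    @property
    def sex_patterned_ids(self) -> list[str]:
        return [
            t.tag_id
            for t in self.tags.values()
            if t.tag_class is not TagClass.AUTOSOMAL
        ]


@dataclass
class SimResult:
    catalog: TagCatalog
    sex_map: SexMap
    truth: TruthTable
    #: tag_id -> (homogametic haplotype, heterogametic haplotype), sex-linked tags
    haplotypes: dict[str, tuple[str, str]]


def _apply_noise(
    geno: np.ndarray, rng: np.random.Generator, error: float, missing: float
) -> np.ndarray:
    """Miscall then drop genotypes i.i.d.; never resurrects a MISSING cell."""
    called = geno != Genotype.MISSING
    err = (rng.random(geno.shape) < error) & called
    pick = rng.integers(0, 2, size=geno.shape)
    if err.any():
        geno = geno.copy()
        geno[err] = _OTHER_STATES[geno[err], pick[err]]
    drop = (rng.random(geno.shape) < missing) & called
    if drop.any():
        geno = geno.copy()
        geno[drop] = Genotype.MISSING
    return geno


def simulate_catalog(cfg: SimConfig) -> SimResult:
    """Generate a catalog, sex map, truth table and sex-linked haplotypes.

    Genotype matrices are drawn per tag in a fixed class order (autosomal,
    sex-linked, sex-limited, opposite-noise); the heterogametic role is a
    pure relabeling, so an XY and a ZW run from the same seed mirror each
    other exactly over the sex-linked blocks when the two sexes have equal
    size.
    """
    rng = np.random.default_rng(cfg.seed)
    males = [f"M{i + 1:02d}" for i in range(cfg.n_males)]
    females = [f"F{i + 1:02d}" for i in range(cfg.n_females)]
    samples = males + females
    sex_map = SexMap(
        tuple((s, Sex.MALE) for s in males) + tuple((s, Sex.FEMALE) for s in females)
    )
    n = len(samples)
    male_idx = np.arange(cfg.n_males)
    female_idx = np.arange(cfg.n_males, n)
    if cfg.system == "XY":
        het_idx, hom_idx = male_idx, female_idx
    else:
        het_idx, hom_idx = female_idx, male_idx

    tags: list[Tag] = []
    truth: dict[str, TagTruth] = {}
    haplotypes: dict[str, tuple[str, str]] = {}
    counter = 0

    def skeleton() -> tuple[str, str, np.ndarray, list[str]]:
        """Draw tag id, consensus, SNP offsets and alt alleles."""
        nonlocal counter
        counter += 1
        tag_id = f"CLocus_{counter}"
        consensus = "".join(rng.choice(BASES, size=cfg.tag_len))
        n_snps = max(1, int(rng.poisson(cfg.snp_mean)))
        offsets = np.sort(rng.choice(cfg.tag_len, size=n_snps, replace=False))
        alts = []
        for off in offsets:
            others = [b for b in "ACGT" if b != consensus[off]]
            alts.append(others[int(rng.integers(0, 3))])
        return tag_id, consensus, offsets, alts

    def hwe_genotypes(q: float, rows: np.ndarray) -> np.ndarray:
        """ALT-dosage genotypes for the given sample rows; others MISSING."""
        geno = np.full(n, int(Genotype.MISSING), dtype=np.int8)
        geno[rows] = rng.binomial(2, q, size=len(rows)).astype(np.int8)
        return geno

    def finish_tag(tag_id, consensus, offsets, alts, geno_matrix, tclass, **tkw):
        geno_matrix = _apply_noise(
            geno_matrix, rng, cfg.genotype_error, cfg.missing_rate
        )
        sites = [
            Site(
                site_id=f"{tag_id}:{off}",
                offset=int(off),
                ref=consensus[off],
                alt=alts[k],
                genotypes=geno_matrix[k],
            )
            for k, off in enumerate(offsets)
        ]
        tags.append(Tag(tag_id=tag_id, sites=sites, consensus=consensus))
        truth[tag_id] = TagTruth(tag_id=tag_id, tag_class=tclass, **tkw)

    for _ in range(cfg.n_auto_tags):
        tag_id, consensus, offsets, alts = skeleton()
        mafs = rng.uniform(cfg.maf_min, cfg.maf_max, size=len(offsets))
        geno = np.stack(
            [hwe_genotypes(q, np.arange(n)) for q in mafs]
        )
        finish_tag(
            tag_id, consensus, offsets, alts, geno, TagClass.AUTOSOMAL,
            mafs={int(o): float(q) for o, q in zip(offsets, mafs)},
        )

    for _ in range(cfg.n_sexlinked_tags):
        tag_id, consensus, offsets, alts = skeleton()
        # consensus carries the X (homogametic) allele; alt is the Y allele
        leaked = rng.random(len(het_idx)) < cfg.recombination_leakage
        geno = np.full((len(offsets), n), int(Genotype.HOM_REF), dtype=np.int8)
        geno[:, het_idx[~leaked]] = int(Genotype.HET)
        finish_tag(
            tag_id, consensus, offsets, alts, geno, TagClass.SEXLINKED_SNP,
            sex_specific_alleles={int(o): a for o, a in zip(offsets, alts)},
        )
        het_hap = list(consensus)
        for off, a in zip(offsets, alts):
            het_hap[off] = a
        haplotypes[tag_id] = (consensus, "".join(het_hap))

    def limited_block(carrier_idx: np.ndarray, tclass: TagClass) -> None:
        for _ in range(
            cfg.n_sexlimited_tags
            if tclass is TagClass.SEXLIMITED
            else cfg.n_opposite_noise_tags
        ):
            tag_id, consensus, offsets, alts = skeleton()
            present = carrier_idx[rng.random(len(carrier_idx)) < cfg.presence_prob]
            mafs = rng.uniform(cfg.maf_min, cfg.maf_max, size=len(offsets))
            geno = np.stack([hwe_genotypes(q, present) for q in mafs])
            finish_tag(
                tag_id, consensus, offsets, alts, geno, tclass,
                mafs={int(o): float(q) for o, q in zip(offsets, mafs)},
            )

    limited_block(het_idx, TagClass.SEXLIMITED)
    limited_block(hom_idx, TagClass.OPPOSITE_NOISE)

    catalog = TagCatalog(samples=samples, tags=tags)
    return SimResult(catalog, sex_map, TruthTable(truth), haplotypes)


def simulate_mapping(
    truth: TruthTable, cfg: SimConfig
) -> tuple[list[AlignmentHit], list[GeneInterval]]:
    """Fabricate BLAST-like hits and a candidate-gene interval.

    ``map_fraction`` of the sex-patterned tags get a strong best hit on
    chr1 (always including ``n_gene_markers`` sex-linked tags placed inside
    the gene interval); the rest either get no hit or only a hit above the
    e-value ceiling.  Autosomal tags scatter over the other chromosomes.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    gene = GeneInterval("DMRT1", "chr1", 5_000_000, 5_600_000, Strand.PLUS)
    sex_ids = truth.sex_patterned_ids
    linked = truth.ids_of(TagClass.SEXLINKED_SNP)
    n_gene = min(cfg.n_gene_markers, len(linked))
    gene_tags = set(
        rng.choice(np.array(linked), size=n_gene, replace=False).tolist()
    ) if n_gene else set()
    n_map = int(round(cfg.map_fraction * len(sex_ids)))
    others = np.array([t for t in sex_ids if t not in gene_tags])
    n_extra = min(max(0, n_map - len(gene_tags)), len(others))
    extra = (
        set(rng.choice(others, size=n_extra, replace=False).tolist())
        if n_extra
        else set()
    )
    mapped = gene_tags | extra

    hits: list[AlignmentHit] = []

    def add_hit(tag_id: str, chrom: str, pos: int, e: float, bit: float) -> None:
        minus = bool(rng.random() < 0.5)
        s1, s2 = pos + 1, pos + cfg.tag_len
        if minus:
            s1, s2 = s2, s1
        hits.append(
            AlignmentHit(
                query_id=tag_id,
                subject_id=chrom,
                pct_identity=float(np.round(rng.uniform(92, 100), 1)),
                aln_len=cfg.tag_len,
                mismatches=int(rng.integers(0, 5)),
                gap_opens=0,
                q_start=1,
                q_end=cfg.tag_len,
                s_start=s1,
                s_end=s2,
                e_value=e,
                bit_score=float(np.round(bit, 1)),
            )
        )

    for tag_id in sex_ids:
        if tag_id in mapped:
            if tag_id in gene_tags:
                pos = int(rng.integers(gene.start, gene.end - cfg.tag_len))
            else:
                pos = int(rng.integers(0, 80_000_000))
                if gene.start - cfg.tag_len < pos < gene.end:
                    pos = gene.end + pos % 1_000_000  # keep decoys out of the gene
            e = float(10.0 ** rng.uniform(-80, -20))
            add_hit(tag_id, "chr1", pos, e, bit=200 + rng.uniform(0, 400))
            if rng.random() < 0.2:  # secondary, strictly worse hit
                add_hit(
                    tag_id, "chr2", int(rng.integers(0, 50_000_000)),
                    e=float(10.0 ** rng.uniform(-8, -3)), bit=50 + rng.uniform(0, 40),
                )
        else:
            if rng.random() < 0.5:
                continue  # no hit rows at all
            add_hit(
                tag_id, "chr1", int(rng.integers(0, 80_000_000)),
                e=float(10.0 ** rng.uniform(-9, -4)), bit=40 + rng.uniform(0, 40),
            )

    for tag_id in truth.ids_of(TagClass.AUTOSOMAL):
        chrom = f"chr{int(rng.integers(2, cfg.n_chromosomes + 1))}"
        add_hit(
            tag_id, chrom, int(rng.integers(0, 100_000_000)),
            e=float(10.0 ** rng.uniform(-60, -20)), bit=150 + rng.uniform(0, 300),
        )

    return hits, [gene]


def truth_frame(truth: TruthTable):
    """Flatten the truth table for the output TSV."""
    import pandas as pd

    rows = []
    for t in truth.tags.values():
        rows.append(
            {
                "tag_id": t.tag_id,
                "tag_class": t.tag_class.value,
                "sex_specific_alleles": ";".join(
                    f"{o}:{a}" for o, a in sorted(t.sex_specific_alleles.items())
                ),
                "mafs": ";".join(
                    f"{o}:{q:.4f}" for o, q in sorted(t.mafs.items())
                ),
            }
        )
    return pd.DataFrame(rows)
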