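"""Readers and writers for every on-disk format the pipeline touches.

Inputs: sex map (2-column TSV), genotypes (VCF 4.x or a Stacks-style
sumstats TSV), tag consensus sequences (FASTA), genome alignment hits
(BLAST outfmt 6), candidate-gene intervals (BED3+).

Outputs are UTF-8, LF-terminated TSV/FASTA/JSON with ``#`` comment headers
carrying the tool version and a short configuration hash, so every table is
traceable to the run that produced it.
"""
from __future__ import annotations

import hashlib
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignmentHit,
    FormatError,
    GeneInterval,
    Genotype,
    ReadStats,
    Sex,
    SexMap,
    SEX_TOKENS,
    Site,
    Strand,
    Tag,
    TagCatalog,
    ValidationError,
)

log = logging.getLogger(__name__)

TOOL = "gbsex"

_GT_CODE = {"0": Genotype.HOM_REF, "1": Genotype.HET, "2": Genotype.HOM_ALT}


def config_hash(config: dict | None) -> str:
    """Short stable hash of a configuration mapping, for output headers."""
    payload = yaml.safe_dump(config or {}, sort_keys=True).encode()
    return hashlib.sha1(payload).hexdigest()[:8]


def _header_lines(kind: str, config: dict | None = None) -> list[str]:
    from . import __version__

    return [
        f"# {TOOL} v{__version__} {kind}",
        f"# config_hash={config_hash(config)}",
    ]


# ---------------------------------------------------------------------------
# sex map
# ---------------------------------------------------------------------------

def read_sex_map(path: str | Path) -> SexMap:
    """Read a 2-column TSV ``sample_id<TAB>sex`` (sex in M/F/male/female).

    Lines starting with ``#`` are ignored; file order is preserved.
    """
    entries: list[tuple[str, Sex]] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            sample_id, token = fields[0].strip(), fields[1].strip()
            if sample_id in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate sample_id {sample_id!r}"
                )
            seen.add(sample_id)
            sex = SEX_TOKENS.get(token.lower())
            if sex is None:
                raise FormatError(
                    f"{path}:{lineno}: unknown sex token {token!r} "
                    "(accepted: M, F, male, female)"
                )
            entries.append((sample_id, sex))
    if not entries:
        raise FormatError(f"{path}: empty sex map")
    return SexMap(tuple(entries))  # raises if a sex is unrepresented


def write_sex_map(path: str | Path, sex_map: SexMap) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in _header_lines("sex_map"):
            fh.write(line + "\n")
        for sample_id, sex in sex_map.entries:
            fh.write(f"{sample_id}\t{sex.value}\n")


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    sex_map: SexMap,
    tag_regex: str | None = None,
) -> TagCatalog:
    """Read biallelic SNPs from a VCF 4.x into a :class:`TagCatalog`.

    Default dialect: one tag per CHROM value (Stacks de novo exports each
    locus as its own contig).  ``tag_regex`` optionally overrides grouping:
    it is matched against the record ID and group(1) becomes the tag id.

    Multi-allelic and non-SNP records are dropped with a logged count.
    Phased and unphased genotypes are treated identically; ``./.`` maps to
    MISSING.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    missing = [s for s in sex_map.sample_ids if s not in vcf_samples]
    if missing:
        raise ValidationError(
            f"{path}: sex-map samples absent from VCF: {', '.join(missing)}"
        )
    col = np.array([vcf_samples.index(s) for s in sex_map.sample_ids])
    pattern = re.compile(tag_regex) if tag_regex else None

    stats = ReadStats()
    # cyvcf2 gts012: 0=HOM_REF 1=HET 2=HOM_ALT 3=UNKNOWN
    decode = np.array(
        [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING],
        dtype=np.int8,
    )
    tag_sites: dict[str, list[Site]] = {}
    for rec in vcf:
        stats.n_records += 1
        if len(rec.ALT) != 1:
            stats.n_dropped_multiallelic += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGTN" or alt not in "ACGTN":
            stats.n_dropped_non_snp += 1
            continue
        if pattern is not None:
            m = pattern.match(rec.ID or "")
            if not m:
                raise FormatError(
                    f"{path}: record ID {rec.ID!r} does not match tag_regex"
                )
            tag_id = m.group(1)
        else:
            tag_id = rec.CHROM
        offset = rec.POS - 1
        site_id = rec.ID if rec.ID not in (None, ".", "") else f"{tag_id}:{offset}"
        geno = decode[np.asarray(rec.gt_types)[col]]
        tag_sites.setdefault(tag_id, []).append(
            Site(site_id=site_id, offset=offset, ref=ref, alt=alt, genotypes=geno)
        )
        stats.n_kept += 1
    if stats.n_kept == 0:
        raise FormatError(f"{path}: no biallelic SNP records parsed")
    if stats.n_dropped:
        log.info("%s: dropped %d multi-allelic and %d non-SNP records",
                 path, stats.n_dropped_multiallelic, stats.n_dropped_non_snp)
    tags = [
        Tag(tag_id=t, sites=sorted(sites, key=lambda s: s.offset))
        for t, sites in tag_sites.items()
    ]
    return TagCatalog(samples=list(sex_map.sample_ids), tags=tags, source_stats=stats)


def read_sumstats_tsv(path: str | Path, sex_map: SexMap) -> TagCatalog:
    """Read the tabular genotype dialect: one row per SNP site.

    Columns: ``locus_id  site_offset  ref  alt  <sample1> ... <sampleN>``
    with genotypes coded 0 (hom ref) / 1 (het) / 2 (hom alt) / NA.
    A header row is required; ``#`` comment lines are ignored.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["locus_id", "site_offset", "ref", "alt"]
    if list(df.columns[:4]) != required:
        raise FormatError(
            f"{path}: first four columns must be {required}, got {list(df.columns[:4])}"
        )
    if df.empty:
        raise FormatError(f"{path}: no genotype rows after header")
    sample_cols = list(df.columns[4:])
    missing = [s for s in sex_map.sample_ids if s not in sample_cols]
    if missing:
        raise ValidationError(
            f"{path}: sex-map samples absent from genotype table: {', '.join(missing)}"
        )

    col_of = {name: i for i, name in enumerate(df.columns)}
    sample_pos = [col_of[s] for s in sex_map.sample_ids]

    stats = ReadStats(n_records=len(df))
    tag_sites: dict[str, list[Site]] = {}
    for row_i, row in enumerate(df.to_numpy(dtype=object), start=2):
        locus_id, offset_s, ref, alt = row[0], row[1], row[2], row[3]
        geno = np.empty(len(sex_map.sample_ids), dtype=np.int8)
        for k, (sample, pos) in enumerate(zip(sex_map.sample_ids, sample_pos)):
            token = str(row[pos]).strip()
            if token.upper() in ("NA", "", "NAN", "."):
                geno[k] = Genotype.MISSING
            elif token in _GT_CODE:
                geno[k] = _GT_CODE[token]
            else:
                raise FormatError(
                    f"{path}: row {row_i}, sample {sample!r}: "
                    f"invalid genotype code {token!r} (expected 0/1/2/NA)"
                )
        offset = int(offset_s)
        tag_sites.setdefault(str(locus_id), []).append(
            Site(
                site_id=f"{locus_id}:{offset}",
                offset=offset,
                ref=str(ref),
                alt=str(alt),
                genotypes=geno,
            )
        )
        stats.n_kept += 1
    tags = [
        Tag(tag_id=t, sites=sorted(sites, key=lambda s: s.offset))
        for t, sites in tag_sites.items()
    ]
    return TagCatalog(samples=list(sex_map.sample_ids), tags=tags, source_stats=stats)


def write_sumstats_tsv(
    path: str | Path, catalog: TagCatalog, config: dict | None = None
) -> None:
    """Write the catalog in the tabular genotype dialect (round-trippable)."""
    code = {
        int(Genotype.HOM_REF): "0",
        int(Genotype.HET): "1",
        int(Genotype.HOM_ALT): "2",
        int(Genotype.MISSING): "NA",
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in _header_lines("genotypes", config):
            fh.write(line + "\n")
        fh.write("\t".join(["locus_id", "site_offset", "ref", "alt"] + catalog.samples))
        fh.write("\n")
        for tag, site in catalog.iter_sites():
            row = [tag.tag_id, str(site.offset), site.ref, site.alt]
            row += [code[int(g)] for g in site.genotypes]
            fh.write("\t".join(row) + "\n")


def write_vcf(path: str | Path, catalog: TagCatalog, config: dict | None = None) -> None:
    """Write the catalog as a minimal VCF 4.2 (one contig per tag, GT only)."""
    gt = {
        int(Genotype.HOM_REF): "0/0",
        int(Genotype.HET): "0/1",
        int(Genotype.HOM_ALT): "1/1",
        int(Genotype.MISSING): "./.",
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        from . import __version__

        fh.write(f"##source={TOOL} v{__version__} config_hash={config_hash(config)}\n")
        for tag in catalog.tags:
            length = len(tag.consensus) if tag.consensus else (
                max((s.offset for s in tag.sites), default=0) + 1
            )
            fh.write(f"##contig=<ID={tag.tag_id},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(catalog.samples)
            + "\n"
        )
        for tag, site in catalog.iter_sites():
            cells = [
                tag.tag_id,
                str(site.offset + 1),
                site.site_id,
                site.ref,
                site.alt,
                ".",
                "PASS",
                ".",
                "GT",
            ] + [gt[int(g)] for g in site.genotypes]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# consensus sequences
# ---------------------------------------------------------------------------

def attach_consensus(catalog: TagCatalog, fasta_path: str | Path) -> int:
    """Attach tag consensus sequences from a FASTA keyed by tag_id.

    Returns the number of tags that received a sequence.  Records whose ID
    matches no tag are ignored; a consensus shorter than a tag's rightmost
    site is rejected.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    n = 0
    for tag in catalog.tags:
        seq = seqs.get(tag.tag_id)
        if seq is None:
            continue
        for site in tag.sites:
            if site.offset >= len(seq):
                raise ValidationError(
                    f"tag {tag.tag_id}: consensus length {len(seq)} "
                    f"< site offset {site.offset}"
                )
        tag.consensus = seq
        n += 1
    return n


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# alignment hits and gene intervals
# ---------------------------------------------------------------------------

def read_blast_tab(path: str | Path) -> list[AlignmentHit]:
    """Parse standard 12-column BLAST outfmt 6 (strict numeric dialect)."""
    hits: list[AlignmentHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_len=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_tab(path: str | Path, hits: list[AlignmentHit]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, h.pct_identity, h.aln_len,
                        h.mismatches, h.gap_opens, h.q_start, h.q_end,
                        h.s_start, h.s_end, h.e_value, h.bit_score,
                    )
                )
                + "\n"
            )


_BED_STRANDS = {"+": Strand.PLUS, "-": Strand.MINUS, ".": Strand.UNKNOWN}


def read_bed(path: str | Path) -> list[GeneInterval]:
    """Read BED3+ gene intervals (0-based half-open, name in column 4)."""
    intervals: list[GeneInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else f"feature_{lineno}"
            strand = _BED_STRANDS.get(fields[5], Strand.UNKNOWN) if len(fields) > 5 else Strand.UNKNOWN
            intervals.append(GeneInterval(name, chrom, start, end, strand))
    return intervals


def write_bed(path: str | Path, intervals: list[GeneInterval]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in intervals:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_name}\t0\t{g.strand.value}\n"
            )


# ---------------------------------------------------------------------------
# tabular result writers
# ---------------------------------------------------------------------------

def write_table(
    path: str | Path, df: pd.DataFrame, kind: str, config: dict | None = None
) -> None:
    """Write a result table as TSV with the standard comment header."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in _header_lines(kind, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
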