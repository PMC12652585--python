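"""Chromosome assignment from BLAST hits and candidate-gene colocalization.

Each marker keeps its single best alignment (smallest e-value, ties broken
by bit score and then input order — BLAST output order is not total, so a
deterministic tie-break is required for reproducibility).  A best hit
worse than the e-value ceiling leaves the marker FILTERED; a marker with
no hit rows at all is UNMAPPED.  Colocalization intersects marker
placements with gene intervals on 0-based half-open coordinates; genes
whose intervals pass the filter on more than one chromosome are flagged
multi-locus and excluded, mirroring the exclusion of candidates with
ambiguous chromosomal localization.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .classification import round_half_even_pct
from .model import AlignmentHit, GeneInterval, Strand

DEFAULT_E_MAX = 1e-10


class MapStatus(str, Enum):
    MAPPED = "MAPPED"
    FILTERED = "FILTERED"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class MappedMarker:
    tag_id: str
    status: MapStatus
    chrom: str | None = None
    start: int | None = None  # 0-based half-open subject interval
    end: int | None = None
    strand: Strand | None = None
    e_value: float | None = None
    bit_score: float | None = None


def assign_chromosomes(
    tags: list[str] | set[str],
    hits: list[AlignmentHit],
    e_max: float = DEFAULT_E_MAX,
) -> list[MappedMarker]:
    """Best-hit chromosome assignment for every tag in ``tags``.

    Tags are reported in the given order (sets are sorted); hits for
    queries outside ``tags`` are ignored.
    """
    order = sorted(tags) if isinstance(tags, (set, frozenset)) else list(tags)
    wanted = set(order)
    best: dict[str, tuple[float, float, int, AlignmentHit]] = {}
    for idx, hit in enumerate(hits):
        if hit.query_id not in wanted:
            continue
        key = (hit.e_value, -hit.bit_score, idx)
        prev = best.get(hit.query_id)
        if prev is None or key < prev[:3]:
            best[hit.query_id] = (*key, hit)

    out: list[MappedMarker] = []
    for tag_id in order:
        entry = best.get(tag_id)
        if entry is None:
            out.append(MappedMarker(tag_id, MapStatus.UNMAPPED))
            continue
        hit = entry[3]
        status = MapStatus.MAPPED if hit.e_value <= e_max else MapStatus.FILTERED
        start, end = hit.subject_interval()
        out.append(
            MappedMarker(
                tag_id=tag_id,
                status=status,
                chrom=hit.subject_id,
                start=start,
                end=end,
                strand=hit.strand,
                e_value=hit.e_value,
                bit_score=hit.bit_score,
            )
        )
    return out


def chromosome_summary(mapped: list[MappedMarker]) -> pd.DataFrame:
    """Per-chromosome counts of MAPPED markers.

    Percentages use the full input size (MAPPED + FILTERED + UNMAPPED) as
    denominator, one decimal, round-half-even; rows sorted by descending
    count then chromosome name.  Empty frame when nothing mapped.
    """
    total = len(mapped)
    counts: dict[str, int] = {}
    for m in mapped:
        if m.status is MapStatus.MAPPED:
            counts[m.chrom] = counts.get(m.chrom, 0) + 1
    rows = [
        {"chrom": chrom, "n": n, "pct": round_half_even_pct(n, total, 1)}
        for chrom, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["chrom", "n", "pct"])


def multi_locus_genes(genes: list[GeneInterval]) -> set[str]:
    """Gene names whose intervals fall on more than one chromosome."""
    chroms: dict[str, set[str]] = {}
    for g in genes:
        chroms.setdefault(g.gene_name, set()).add(g.chrom)
    return {name for name, cs in chroms.items() if len(cs) > 1}


@dataclass(frozen=True)
class ColocPair:
    tag_id: str
    gene_name: str
    overlap_bp: int = 0  # > 0 when intervals intersect
    gap_bp: int = 0      # > 0 when disjoint but within max_gap


def gene_colocalization(
    mapped: list[MappedMarker],
    genes: list[GeneInterval],
    max_gap: int = 0,
) -> list[ColocPair]:
    """All (marker, gene) pairs that overlap, or lie within ``max_gap`` bp.

    Only MAPPED markers participate; multi-locus genes are excluded.
    Strand is ignored — colocalization is positional.
    """
    excluded = multi_locus_genes(genes)
    usable = [g for g in genes if g.gene_name not in excluded]
    pairs: list[ColocPair] = []
    for m in mapped:
        if m.status is not MapStatus.MAPPED:
            continue
        for g in usable:
            if g.chrom != m.chrom:
                continue
            overlap = min(m.end, g.end) - max(m.start, g.start)
            if overlap > 0:
                pairs.append(ColocPair(m.tag_id, g.gene_name, overlap_bp=overlap))
            elif max_gap > 0:
                gap = -overlap
                if gap <= max_gap:
                    pairs.append(ColocPair(m.tag_id, g.gene_name, gap_bp=gap))
    return pairs


def mapped_frame(mapped: list[MappedMarker]) -> pd.DataFrame:
    rows = []
    for m in mapped:
        rows.append(
            {
                "tag_id": m.tag_id,
                "status": m.status.value,
                "chrom": m.chrom or "",
                "start": "" if m.start is None else m.start,
                "end": "" if m.end is None else m.end,
                "strand": m.strand.value if m.strand else "",
                "e_value": "" if m.e_value is None else m.e_value,
                "bit_score": "" if m.bit_score is None else m.bit_score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["tag_id", "status", "chrom", "start", "end", "strand", "e_value", "bit_score"],
    )


def coloc_frame(pairs: list[ColocPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tag_id": p.tag_id,
                "gene_name": p.gene_name,
                "overlap_bp": p.overlap_bp,
                "gap_bp": p.gap_bp,
            }
            for p in pairs
        ],
        columns=["tag_id", "gene_name", "overlap_bp", "gap_bp"],
    )
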