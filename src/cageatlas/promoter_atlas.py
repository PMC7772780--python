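"""Gene assignment, naming, and classification of consensus promoters.

Consensus clusters are assigned to genes by strand-matched overlap with
the gene span (extended upstream to catch promoters just 5' of the
annotated start), numbered p1..pN per gene in the gene's transcriptional
orientation, placed relative to the transcript structure (5'UTR, coding
exon, intron, or flank), and classified by cross-tissue expression
breadth:

* non-ubiquitous:          median tpm across tissues < 0.2
* ubiquitous, non-uniform: max tpm > 10 x median
* ubiquitous, uniform:     max tpm <= 10 x median
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .consensus_promoters import ConsensusCluster
from .io_formats import GeneModel, TranscriptModel
from .utr_toolkit import gc_content

DEFAULT_UPSTREAM_FLANK = 500


class PositionClass(str, Enum):
    FIVE_PRIME_UTR = "five_prime_utr"
    CODING_EXON = "coding_exon"
    EXON = "exon"  # exonic hit on a non-coding transcript
    INTRON = "intron"
    FLANK = "intergenic/flank"


class BreadthClass(str, Enum):
    NON_UBIQUITOUS = "non_ubiquitous"
    UBIQUITOUS_UNIFORM = "ubiquitous_uniform"
    UBIQUITOUS_NONUNIFORM = "ubiquitous_nonuniform"


@dataclass(frozen=True)
class BreadthThresholds:
    median_floor: float = 0.2  # tpm below which a promoter is not broadly used
    fold: float = 10.0  # max/median ratio separating uniform from non-uniform

    def __post_init__(self) -> None:
        if self.median_floor <= 0 or self.fold <= 1:
            raise ValueError("median_floor must be > 0 and fold > 1")


@dataclass
class PromoterRecord:
    consensus: ConsensusCluster
    gene_id: str | None = None
    name: str | None = None
    position_class: PositionClass | None = None
    gc: float | None = None
    breadth_class: BreadthClass | None = None
    overlap_bp: int = 0


def assign_to_genes(
    consensus: list[ConsensusCluster],
    genes: list[GeneModel],
    upstream_flank: int = DEFAULT_UPSTREAM_FLANK,
) -> list[PromoterRecord]:
    """Assign each consensus cluster to the gene it overlaps most.

    A gene qualifies when strands match and the cluster span intersects the
    gene span extended by ``upstream_flank`` on the gene's 5' side.  Among
    qualifying genes the largest overlap wins (ties: lexicographically
    smallest gene_id).  Clusters with no qualifying gene stay unassigned.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        lo, hi = g.span
        if g.strand == "+":
            lo = max(0, lo - upstream_flank)
        else:
            hi = hi + upstream_flank
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(lo, hi, g)
    out = []
    for c in consensus:
        rec = PromoterRecord(consensus=c)
        tree = trees.get((c.chrom, c.strand))
        if tree is not None:
            best = None  # (-overlap, gene_id, gene)
            for iv in tree.overlap(c.start, c.end):
                overlap = min(c.end, iv.end) - max(c.start, iv.begin)
                key = (-overlap, iv.data.gene_id, iv.data)
                if best is None or key[:2] < best[:2]:
                    best = key
            if best is not None:
                rec.gene_id = best[2].gene_id
                rec.overlap_bp = -best[0]
        out.append(rec)
    return out


def name_promoters(records: list[PromoterRecord], genes: list[GeneModel]) -> list[PromoterRecord]:
    """Number promoters p1..pN per gene, 5'->3' in the gene's orientation."""
    strand_of = {g.gene_id: g.strand for g in genes}
    per_gene: dict[str, list[PromoterRecord]] = {}
    for rec in records:
        if rec.gene_id is not None:
            per_gene.setdefault(rec.gene_id, []).append(rec)
    for gene_id, recs in per_gene.items():
        reverse = strand_of.get(gene_id, "+") == "-"
        recs.sort(key=lambda r: r.consensus.start, reverse=reverse)
        for k, rec in enumerate(recs, start=1):
            rec.name = f"p{k}.{gene_id}"
    return records


def classify_position(
    record: PromoterRecord, transcript: TranscriptModel
) -> PositionClass:
    """Place a promoter relative to a transcript by its span midpoint.

    Midpoint inside an exon and 5' of the CDS start -> 5'UTR; inside an
    exon at/after the CDS start -> coding exon; between exons -> intron;
    outside the transcript span -> intergenic/flank.  Non-coding
    transcripts have no 5'UTR, so exonic hits report the plain "exon"
    class.
    """
    c = record.consensus
    mid = (c.start + c.end - 1) // 2
    lo, hi = transcript.span
    if not lo <= mid < hi:
        record.position_class = PositionClass.FLANK
        return record.position_class
    offset = transcript.genomic_to_transcript(mid)
    if offset is None:
        record.position_class = PositionClass.INTRON
    elif transcript.cds_start is None:
        record.position_class = PositionClass.EXON
    elif offset < transcript.cds_start:
        record.position_class = PositionClass.FIVE_PRIME_UTR
    else:
        record.position_class = PositionClass.CODING_EXON
    return record.position_class


def classify_breadth(
    expression: dict[str, float],
    thresholds: BreadthThresholds = BreadthThresholds(),
) -> BreadthClass:
    """Three-way expression-breadth call from a tissue -> tpm profile.

    median < median_floor -> non-ubiquitous; otherwise max > fold * median
    -> ubiquitous non-uniform, else ubiquitous uniform (ties at exactly
    fold * median count as uniform).
    """
    if not expression:
        raise ValueError("empty expression profile")
    values = list(expression.values())
    med = statistics.median(values)
    if med < thresholds.median_floor:
        return BreadthClass.NON_UBIQUITOUS
    if max(values) > thresholds.fold * med:
        return BreadthClass.UBIQUITOUS_NONUNIFORM
    return BreadthClass.UBIQUITOUS_UNIFORM


def width_summaries(
    groups: dict[str, list[tuple[int, int]]]
) -> dict[str, dict]:
    """Per-group interval-width medians (widths = end - start)."""
    out = {}
    for label, intervals in groups.items():
        if not intervals:
            raise ValueError(f"empty group {label!r}")
        widths = [e - s for s, e in intervals]
        out[label] = {"median": statistics.median(widths), "widths": widths}
    return out


def build_atlas(
    consensus: list[ConsensusCluster],
    genes: list[GeneModel],
    genome=None,
    thresholds: BreadthThresholds = BreadthThresholds(),
    upstream_flank: int = DEFAULT_UPSTREAM_FLANK,
    assigned_only: bool = True,
) -> pd.DataFrame:
    """Full promoter atlas: assignment, naming, position, GC, breadth.

    ``genome`` is any mapping chrom -> sequence (e.g. a pyfaidx.Fasta);
    when None, GC is left unset.  Returns one row per promoter (assigned
    promoters only unless ``assigned_only`` is False).
    """
    records = assign_to_genes(consensus, genes, upstream_flank)
    name_promoters(records, genes)
    tx_of = {g.gene_id: g.longest_transcript() for g in genes if g.transcripts}
    rows = []
    for rec in records:
        if rec.gene_id is None and assigned_only:
            continue
        c = rec.consensus
        if rec.gene_id is not None and rec.gene_id in tx_of:
            classify_position(rec, tx_of[rec.gene_id])
        else:
            rec.position_class = PositionClass.FLANK
        if genome is not None:
            seq = str(genome[c.chrom][c.start : c.end])
            rec.gc = gc_content(seq)
        rec.breadth_class = classify_breadth(c.expression, thresholds)
        prof = list(c.expression.values())
        rows.append(
            {
                "name": rec.name,
                "gene_id": rec.gene_id,
                "consensus_id": c.consensus_id,
                "chrom": c.chrom,
                "strand": c.strand,
                "start": c.start,
                "end": c.end,
                "width_bp": c.width,
                "dominant_pos": c.dominant_pos,
                "position_class": rec.position_class.value,
                "gc": rec.gc,
                "breadth_class": rec.breadth_class.value,
                "median_tpm": float(np.median(prof)) if prof else np.nan,
                "max_tpm": float(np.max(prof)) if prof else np.nan,
            }
        )
    return pd.DataFrame(rows)
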