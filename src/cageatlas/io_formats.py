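"""Readers and writers for the pipeline's file formats.

CAGE transcription start sites (CTSS) arrive as 4-column BED-like text
(chrom, position, strand, tag count), gene models as GTF, sequences as
FASTA, and results leave as TSV/BED6/Newick.  All coordinates are held
internally as 0-based half-open intervals; GTF's 1-based closed exons are
converted at the boundary and converted back on export, so the two
conventions never mix inside the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cageatlas")

CTSS_COLUMNS = ["chrom", "pos", "strand", "raw_count"]
PROMOTER_TABLE_COLUMNS = ["name", "width_bp", "position", "gc", "distribution"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def setup_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CTSSTable:
    """Per-sample CAGE tag start positions.

    ``data`` has columns chrom, pos (0-based), strand ('+'/'-'), raw_count
    and, after normalization, norm_tpm.  (chrom, pos, strand) is unique and
    the frame is sorted by (chrom, strand, pos).
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CTSS_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"CTSS table missing columns: {missing}")
        if "norm_tpm" not in self.data.columns:
            self.data["norm_tpm"] = np.nan

    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_normalized(self) -> bool:
        return len(self.data) == 0 or bool(self.data["norm_tpm"].notna().all())


@dataclass
class TranscriptModel:
    """Ordered exon chain plus CDS start, in transcript orientation.

    ``exons`` are 0-based half-open genomic intervals listed 5'->3' of the
    transcript (so descending genomic start on the minus strand).
    ``cds_start`` is the transcript-relative offset of the first CDS base
    (equivalently, the 5'UTR leader length); ``None`` marks non-coding.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(
                f"exons of {self.transcript_id} not in transcript orientation"
            )
        n = self.length
        if self.cds_start is not None and not 0 <= self.cds_start < n:
            raise ValueError(
                f"cds_start {self.cds_start} outside transcript of length {n}"
            )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Transcript-relative offset of a genomic position, or None if intronic."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos < e:
                if self.strand == "+":
                    return offset + (gpos - s)
                return offset + (e - 1 - gpos)
            offset += e - s
        return None

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals in transcript order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return out


@dataclass
class GeneModel:
    """All transcripts of a gene plus the covering genomic span."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.span
        for tx in self.transcripts:
            s, e = tx.span
            if s < lo or e > hi:
                raise ValueError(
                    f"transcript {tx.transcript_id} outside span of {self.gene_id}"
                )

    def longest_transcript(self) -> TranscriptModel:
        return max(self.transcripts, key=lambda t: (t.length, t.transcript_id))


# ---------------------------------------------------------------------------
# CTSS I/O
# ---------------------------------------------------------------------------


def parse_ctss(path: str | Path, sample_id: str, one_based: bool = False) -> CTSSTable:
    """Read a 4-column CTSS file (chrom, pos, strand, count).

    Positions are taken as 0-based unless ``one_based`` is set (some CTSS
    dialects are 1-based).  Records come back sorted by (chrom, strand, pos).
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, pos_s, strand, count_s = parts[:4]
            try:
                pos = int(pos_s)
                count = int(count_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field: {exc}") from None
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            if count < 1:
                raise FormatError(f"{path}:{lineno}: tag count {count} < 1")
            if one_based:
                pos -= 1
            if pos < 0:
                raise FormatError(f"{path}:{lineno}: negative position {pos}")
            rows.append((chrom, pos, strand, count))
    df = pd.DataFrame(rows, columns=CTSS_COLUMNS)
    if df.duplicated(["chrom", "pos", "strand"]).any():
        dup = df[df.duplicated(["chrom", "pos", "strand"])].iloc[0]
        raise FormatError(
            f"{path}: duplicate CTSS at {dup.chrom}:{dup.pos}:{dup.strand}"
        )
    df = df.sort_values(["chrom", "strand", "pos"], kind="mergesort").reset_index(drop=True)
    return CTSSTable(sample_id=sample_id, data=df)


def write_ctss(table: CTSSTable, path: str | Path, with_tpm: bool = False) -> None:
    """Write a CTSS table; ``with_tpm`` appends the normalized tpm column."""
    cols = CTSS_COLUMNS + (["norm_tpm"] if with_tpm else [])
    table.data[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def parse_gtf_transcripts(path: str | Path) -> list[GeneModel]:
    """Load gene/transcript/exon/CDS structure from a GTF file.

    GTF's 1-based closed exon [s, e] becomes the internal 0-based half-open
    [s-1, e).  Minus-strand exon chains are ordered 5'->3' of the transcript
    and cds_start is the transcript-relative offset of the most 5' CDS base.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_ids = feat.attributes.get("transcript_id")
        if not tx_ids:
            raise FormatError(f"{path}: {feat.featuretype} without transcript_id")
        gene_ids = feat.attributes.get("gene_id") or tx_ids
        key = tx_ids[0]
        rec = per_tx.setdefault(
            key,
            {
                "gene_id": gene_ids[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "cds": [],
            },
        )
        iv = (feat.start - 1, feat.end)  # GTF 1-based closed -> 0-based half-open
        rec["exons" if feat.featuretype == "exon" else "cds"].append(iv)

    genes: dict[str, GeneModel] = {}
    for tx_id, rec in per_tx.items():
        exons = sorted(rec["exons"])
        if rec["strand"] == "-":
            exons = exons[::-1]
        tx = TranscriptModel(
            gene_id=rec["gene_id"],
            transcript_id=tx_id,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=exons,
            cds_start=None,
        )
        if rec["cds"]:
            if rec["strand"] == "+":
                first_cds = min(s for s, _ in rec["cds"])
            else:
                first_cds = max(e for _, e in rec["cds"]) - 1
            offset = tx.genomic_to_transcript(first_cds)
            if offset is None:
                raise FormatError(f"{path}: CDS of {tx_id} not inside its exons")
            tx.cds_start = offset
        gm = genes.get(rec["gene_id"])
        if gm is None:
            genes[rec["gene_id"]] = GeneModel(
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                span=tx.span,
                transcripts=[tx],
            )
        else:
            s, e = tx.span
            gm.span = (min(gm.span[0], s), max(gm.span[1], e))
            gm.transcripts.append(tx)
    return list(genes.values())


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back out as GTF (exon and CDS features)."""
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                attrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                )
                for s, e in sorted(tx.exons):
                    fh.write(
                        f"{tx.chrom}\tcageatlas\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                    )
                if tx.cds_start is not None:
                    for s, e in _cds_genomic_intervals(tx):
                        fh.write(
                            f"{tx.chrom}\tcageatlas\tCDS\t{s + 1}\t{e}\t.\t{tx.strand}\t0\t{attrs}\n"
                        )


def _cds_genomic_intervals(tx: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic intervals of the CDS portion (from cds_start to transcript end)."""
    out = []
    offset = 0
    for s, e in tx.exons:
        length = e - s
        lo = max(tx.cds_start - offset, 0)
        if lo < length:
            if tx.strand == "+":
                out.append((s + lo, e))
            else:
                out.append((s, e - lo))
        offset += length
    return sorted(out)


# ---------------------------------------------------------------------------
# Promoter report table (Table-1-style)
# ---------------------------------------------------------------------------


def write_promoter_table(records: Sequence[dict], path: str | Path) -> None:
    """Write the promoter characteristics report.

    Each record needs name, width_bp, position, gc and distribution; the file
    round-trips losslessly through :func:`read_promoter_table`.
    """
    for i, rec in enumerate(records):
        for col in PROMOTER_TABLE_COLUMNS:
            if rec.get(col) is None:
                raise ValueError(f"record {i} missing required field {col!r}")
    df = pd.DataFrame(list(records), columns=PROMOTER_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_promoter_table(path: str | Path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "position": str, "distribution": str})
    if list(df.columns) != PROMOTER_TABLE_COLUMNS:
        raise FormatError(f"{path}: unexpected promoter table header {list(df.columns)}")
    out = df.to_dict("records")
    for rec in out:
        rec["width_bp"] = int(rec["width_bp"])
        rec["gc"] = float(rec["gc"])
    return out


# ---------------------------------------------------------------------------
# BED6 export
# ---------------------------------------------------------------------------


def write_bed6(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end, name, score, strand) tuples as BED6.

    Scores are clipped to the BED convention's 0..1000 range.
    """
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            score = int(min(1000, max(0, round(score))))
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA; returns (taxa, rows) with equal-length rows."""
    from Bio import SeqIO

    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    if rows and len({len(r) for r in rows}) != 1:
        raise FormatError(f"{path}: alignment rows have unequal lengths")
    return taxa, rows


# ---------------------------------------------------------------------------
# Config plumbing
# ---------------------------------------------------------------------------


def load_config_file(path: str | Path) -> dict:
    """Read a YAML config file of flat key: value overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data
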