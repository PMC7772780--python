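"""Distance clustering of CTSS positions into per-sample tag clusters.

Within each (chromosome, strand), consecutive tag start sites whose
positional gap is at most ``max_dist`` (default 20 bp) are merged
transitively — single-linkage clustering on the line.  Each cluster
carries its dominant (highest-signal) position, total signal, and the
positions at which the running signal reaches the 0.1 and 0.9 quantiles;
the interquantile width is a robust promoter-width measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CTSSTable

DEFAULT_MAX_DIST = 20
DEFAULT_Q_LOW = 0.1
DEFAULT_Q_UP = 0.9


@dataclass
class TagCluster:
    sample_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span over member CTSS
    end: int
    dominant_pos: int
    total_tpm: float
    q_low_pos: int
    q_high_pos: int
    iq_width: int
    n_ctss: int
    q_low: float = DEFAULT_Q_LOW
    q_up: float = DEFAULT_Q_UP

    def __post_init__(self) -> None:
        if not (self.start <= self.q_low_pos <= self.q_high_pos < self.end):
            raise ValueError("quantile positions outside cluster span")
        if not self.start <= self.dominant_pos < self.end:
            raise ValueError("dominant position outside cluster span")
        if self.total_tpm <= 0:
            raise ValueError("cluster with non-positive total signal")


def compute_quantiles(
    positions: np.ndarray,
    tpms: np.ndarray,
    q_low: float = DEFAULT_Q_LOW,
    q_up: float = DEFAULT_Q_UP,
) -> tuple[int, int, int]:
    """Quantile positions of a cluster's cumulative signal.

    ``q_low_pos`` is the smallest member position at which the running tpm
    sum (in ascending genomic order) reaches q_low * total; ``q_high_pos``
    the smallest reaching q_up * total.  Returns (q_low_pos, q_high_pos,
    interquantile width).
    """
    positions = np.asarray(positions)
    tpms = np.asarray(tpms, dtype=float)
    if positions.size == 0:
        raise ValueError("empty cluster")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    total = tpms.sum()
    if total <= 0:
        raise ValueError("cluster with non-positive total signal")
    cum = np.cumsum(tpms)
    i_low = int(np.searchsorted(cum, q_low * total - 1e-12 * total))
    i_high = int(np.searchsorted(cum, q_up * total - 1e-12 * total))
    q_low_pos = int(positions[i_low])
    q_high_pos = int(positions[i_high])
    return q_low_pos, q_high_pos, q_high_pos - q_low_pos + 1


def cluster_ctss(
    ctss: CTSSTable,
    max_dist: int = DEFAULT_MAX_DIST,
    q_low: float = DEFAULT_Q_LOW,
    q_up: float = DEFAULT_Q_UP,
) -> list[TagCluster]:
    """Single-linkage distance clustering of a normalized CTSS table.

    Every CTSS record ends up in exactly one cluster; clusters on one
    (chrom, strand) are separated by gaps > max_dist.  Output is sorted by
    (chrom, strand, start).  Dominant-position ties go to the most 5'
    position in transcript orientation (lowest coordinate on '+', highest
    on '-').
    """
    if not ctss.is_normalized:
        raise ValueError(f"sample {ctss.sample_id}: norm_tpm unset; normalize first")
    out: list[TagCluster] = []
    df = ctss.data.sort_values(["chrom", "strand", "pos"], kind="mergesort")
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        pos = grp["pos"].to_numpy()
        tpm = grp["norm_tpm"].to_numpy(dtype=float)
        # break where the gap to the previous CTSS exceeds max_dist
        breaks = np.flatnonzero(np.diff(pos) > max_dist) + 1
        for seg_pos, seg_tpm in zip(np.split(pos, breaks), np.split(tpm, breaks)):
            if strand == "+":
                dom_idx = int(np.argmax(seg_tpm))  # first max = most 5'
            else:
                dom_idx = len(seg_tpm) - 1 - int(np.argmax(seg_tpm[::-1]))
            ql, qh, iqw = compute_quantiles(seg_pos, seg_tpm, q_low, q_up)
            out.append(
                TagCluster(
                    sample_id=ctss.sample_id,
                    chrom=str(chrom),
                    strand=str(strand),
                    start=int(seg_pos[0]),
                    end=int(seg_pos[-1]) + 1,
                    dominant_pos=int(seg_pos[dom_idx]),
                    total_tpm=float(seg_tpm.sum()),
                    q_low_pos=ql,
                    q_high_pos=qh,
                    iq_width=iqw,
                    n_ctss=len(seg_pos),
                    q_low=q_low,
                    q_up=q_up,
                )
            )
    return out


def clusters_to_frame(clusters: list[TagCluster]) -> pd.DataFrame:
    """Tabular view of tag clusters (one row per cluster)."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "chrom": c.chrom,
                "strand": c.strand,
                "start": c.start,
                "end": c.end,
                "dominant_pos": c.dominant_pos,
                "total_tpm": c.total_tpm,
                "q_low_pos": c.q_low_pos,
                "q_high_pos": c.q_high_pos,
                "iq_width": c.iq_width,
                "n_ctss": c.n_ctss,
            }
            for c in clusters
        ]
    )


def clusters_to_bed6(clusters: list[TagCluster]) -> list[tuple]:
    """BED6 rows (name = sample:index, score = clipped total tpm)."""
    return [
        (c.chrom, c.start, c.end, f"{c.sample_id}:{i}", c.total_tpm, c.strand)
        for i, c in enumerate(clusters)
    ]
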