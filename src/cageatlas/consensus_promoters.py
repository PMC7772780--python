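"""Cross-sample aggregation of tag clusters into consensus promoters.

Tag clusters reaching a minimum signal (total tpm >= 2 by default) in at
least one sample are projected as their interquantile ranges; ranges on
one (chromosome, strand) lying within ``agg_dist`` (default 100 bp) of
each other are merged transitively.  The merged spans are the consensus
clusters — the pipeline's operational promoters — and each gets a
per-tissue expression vector recomputed from the normalized CTSS signal
falling inside its span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CTSSTable
from .tss_clustering import TagCluster

DEFAULT_TPM_THRESHOLD = 2.0
DEFAULT_AGG_DIST = 100


@dataclass
class ConsensusCluster:
    consensus_id: str
    chrom: str
    strand: str
    start: int
    end: int
    expression: dict[str, float] = field(default_factory=dict)
    dominant_pos: int | None = None  # pooled-signal peak, set with expression

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


def aggregate_clusters(
    cluster_lists: list[list[TagCluster]],
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
    agg_dist: int = DEFAULT_AGG_DIST,
) -> list[ConsensusCluster]:
    """Merge qualifying per-sample tag clusters into consensus clusters.

    A tag cluster qualifies when its total tpm >= tpm_threshold.  Its
    closed interquantile range [q_low_pos, q_high_pos] is the merge unit;
    ranges whose gap is <= agg_dist merge transitively and the consensus
    span is the half-open union of the merged ranges.  Empty input yields
    empty output.
    """
    rows = []
    conventions = set()
    for clusters in cluster_lists:
        for c in clusters:
            conventions.add((c.q_low, c.q_up))
            if c.total_tpm >= tpm_threshold:
                rows.append((c.chrom, c.strand, c.q_low_pos, c.q_high_pos))
    if len(conventions) > 1:
        raise ValueError(f"mixed quantile conventions across inputs: {conventions}")
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["chrom", "strand", "lo", "hi"])
    out: list[ConsensusCluster] = []
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values(["lo", "hi"], kind="mergesort")
        lo = grp["lo"].to_numpy()
        hi = np.maximum.accumulate(grp["hi"].to_numpy())
        # new consensus whenever this range starts > agg_dist past the
        # running right edge of the previous ones
        breaks = np.flatnonzero(lo[1:] - hi[:-1] > agg_dist) + 1
        seg_ids = np.zeros(len(lo), dtype=int)
        seg_ids[breaks] = 1
        seg_ids = np.cumsum(seg_ids)
        for seg in range(seg_ids[-1] + 1):
            m = seg_ids == seg
            start = int(lo[m].min())
            end = int(hi[m].max()) + 1  # closed ranges -> half-open span
            out.append(
                ConsensusCluster(
                    consensus_id="",
                    chrom=str(chrom),
                    strand=str(strand),
                    start=start,
                    end=end,
                )
            )
    out.sort(key=lambda c: (c.chrom, c.strand, c.start))
    for i, c in enumerate(out, start=1):
        c.consensus_id = f"CC{i:05d}"
    return out


def expression_matrix(
    consensus: list[ConsensusCluster],
    tables: list[CTSSTable],
) -> list[ConsensusCluster]:
    """Fill per-tissue expression from normalized CTSS inside each span.

    expression[tissue] = sum of that tissue's norm_tpm at positions within
    the consensus span on the matching strand (0 when no tags fall inside).
    Also records the pooled-signal dominant position of each consensus
    cluster.  Sample ids must be unique (they label the tissues).
    """
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate tissue labels: {ids}")
    for c in consensus:
        c.expression = {t.sample_id: 0.0 for t in tables}

    by_key: dict[tuple[str, str], list[ConsensusCluster]] = {}
    for c in consensus:
        by_key.setdefault((c.chrom, c.strand), []).append(c)
    for key in by_key:
        by_key[key].sort(key=lambda c: c.start)

    pooled: dict[int, dict[int, float]] = {id(c): {} for c in consensus}
    for table in tables:
        if not table.is_normalized:
            raise ValueError(f"sample {table.sample_id} not normalized")
        for (chrom, strand), grp in table.data.groupby(["chrom", "strand"], sort=False):
            clusters = by_key.get((str(chrom), str(strand)))
            if not clusters:
                continue
            pos = grp["pos"].to_numpy()
            tpm = grp["norm_tpm"].to_numpy(dtype=float)
            order = np.argsort(pos, kind="mergesort")
            pos, tpm = pos[order], tpm[order]
            cum = np.concatenate([[0.0], np.cumsum(tpm)])
            starts = np.array([c.start for c in clusters])
            ends = np.array([c.end for c in clusters])
            i0 = np.searchsorted(pos, starts, side="left")
            i1 = np.searchsorted(pos, ends, side="left")
            sums = cum[i1] - cum[i0]
            for c, a, b, s in zip(clusters, i0, i1, sums):
                if s > 0:
                    c.expression[table.sample_id] = c.expression[table.sample_id] + float(s)
                    acc = pooled[id(c)]
                    for p, v in zip(pos[a:b], tpm[a:b]):
                        acc[int(p)] = acc.get(int(p), 0.0) + float(v)
    for c in consensus:
        acc = pooled[id(c)]
        if acc:
            best = max(acc.items(), key=lambda kv: (kv[1], -kv[0] if c.strand == "+" else kv[0]))
            c.dominant_pos = best[0]
    return consensus


def consensus_to_frame(consensus: list[ConsensusCluster]) -> pd.DataFrame:
    """Expression matrix view: one row per consensus cluster."""
    rows = []
    for c in consensus:
        row = {
            "consensus_id": c.consensus_id,
            "chrom": c.chrom,
            "strand": c.strand,
            "start": c.start,
            "end": c.end,
            "width": c.width,
            "dominant_pos": c.dominant_pos,
        }
        row.update(c.expression)
        rows.append(row)
    return pd.DataFrame(rows)
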