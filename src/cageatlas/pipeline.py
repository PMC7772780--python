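"""End-to-end orchestration: normalize -> cluster -> consensus -> atlas.

Also provides the scored self-test that matches a recovered promoter
atlas against the synthetic generator's planted truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cage_normalization import NormalizationConfig, fit_power_law, normalize_to_reference
from .consensus_promoters import (
    aggregate_clusters,
    consensus_to_frame,
    expression_matrix,
)
from .io_formats import CTSSTable, parse_ctss, parse_gtf_transcripts, write_bed6, write_ctss
from .promoter_atlas import BreadthThresholds, build_atlas
from .tss_clustering import cluster_ctss, clusters_to_bed6
from .synthetic_data import SyntheticTruth

logger = logging.getLogger("cageatlas")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the promoter-discovery pipeline."""

    alpha_ref: float = 1.14  # reference power-law slope
    total_T: float = 1e7  # reference total tag count
    fit_min_count: float = 2  # smallest count used in the power-law fit
    fit_min_revcum: int = 100  # tail guard of the power-law fit
    max_dist: int = 20  # CTSS clustering distance (bp)
    q_low: float = 0.1  # lower signal quantile of a tag cluster
    q_up: float = 0.9  # upper signal quantile
    tpm_threshold: float = 2.0  # tag-cluster signal floor for consensus
    agg_dist: int = 100  # consensus aggregation distance (bp)
    median_floor: float = 0.2  # breadth rule: median tpm below -> non-ubiquitous
    fold: float = 10.0  # breadth rule: max/median above -> non-uniform
    upstream_flank: int = 500  # gene-assignment upstream extension (bp)
    bootstrap_B: int = 100  # bootstrap pseudoreplicates for trees
    seed: int = 0
    ctss_one_based: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.q_low < self.q_up <= 1:
            raise ValueError("need 0 <= q_low < q_up <= 1")
        for name in ("alpha_ref", "total_T", "max_dist", "tpm_threshold",
                     "agg_dist", "median_floor", "fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def norm(self) -> NormalizationConfig:
        return NormalizationConfig(
            alpha_ref=self.alpha_ref,
            total_T=self.total_T,
            fit_min_count=self.fit_min_count,
            fit_min_revcum=self.fit_min_revcum,
        )

    @property
    def breadth(self) -> BreadthThresholds:
        return BreadthThresholds(median_floor=self.median_floor, fold=self.fold)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def run_pipeline(
    ctss_by_tissue: dict[str, str | Path | CTSSTable],
    gtf: str | Path | None = None,
    fasta=None,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """Run the whole promoter-discovery pipeline.

    ``ctss_by_tissue`` maps tissue labels to CTSS file paths (or already
    parsed tables).  ``fasta`` is any chrom -> sequence mapping (e.g.
    pyfaidx.Fasta).  Returns a dict with the normalized tables, tag
    clusters, consensus clusters, and the atlas DataFrame; when
    ``out_dir`` is set the standard output files are written as well.
    """
    if len(ctss_by_tissue) < 2:
        raise ValueError("need >= 2 tissues: expression breadth is undefined")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    normalized: dict[str, CTSSTable] = {}
    for tissue, src in ctss_by_tissue.items():
        table = (
            src
            if isinstance(src, CTSSTable)
            else parse_ctss(src, tissue, one_based=config.ctss_one_based)
        )
        try:
            fit = fit_power_law(table, config.norm)
            normalized[tissue] = normalize_to_reference(table, fit, config.norm)
            logger.info(
                "normalize %s: %d positions, alpha=%.3f", tissue, len(table), fit.alpha_s
            )
        except Exception as exc:
            raise RuntimeError(f"stage normalize, tissue {tissue}: {exc}") from exc
        if out is not None:
            write_ctss(normalized[tissue], out / f"{tissue}.normalized.ctss", with_tpm=True)

    cluster_lists = []
    for tissue, table in normalized.items():
        try:
            clusters = cluster_ctss(table, config.max_dist, config.q_low, config.q_up)
        except Exception as exc:
            raise RuntimeError(f"stage cluster, tissue {tissue}: {exc}") from exc
        logger.info("cluster %s: %d tag clusters", tissue, len(clusters))
        cluster_lists.append(clusters)
        if out is not None:
            write_bed6(clusters_to_bed6(clusters), out / f"{tissue}.clusters.bed")

    try:
        consensus = aggregate_clusters(cluster_lists, config.tpm_threshold, config.agg_dist)
        expression_matrix(consensus, list(normalized.values()))
    except Exception as exc:
        raise RuntimeError(f"stage consensus: {exc}") from exc
    logger.info("consensus: %d clusters", len(consensus))
    if out is not None:
        consensus_to_frame(consensus).to_csv(out / "consensus.tsv", sep="\t", index=False)
        write_bed6(
            [
                (c.chrom, c.start, c.end, c.consensus_id, max(c.expression.values(), default=0), c.strand)
                for c in consensus
            ],
            out / "consensus.bed",
        )

    atlas = None
    genes = []
    if gtf is not None:
        try:
            genes = parse_gtf_transcripts(gtf)
            atlas = build_atlas(
                consensus,
                genes,
                genome=fasta,
                thresholds=config.breadth,
                upstream_flank=config.upstream_flank,
            )
        except Exception as exc:
            raise RuntimeError(f"stage atlas: {exc}") from exc
        logger.info("atlas: %d assigned promoters", len(atlas))
        if out is not None:
            atlas.to_csv(out / "atlas.tsv", sep="\t", index=False)

    if out is not None:
        run_log = {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "tissues": sorted(ctss_by_tissue.keys()),
            "n_consensus": len(consensus),
            "n_atlas": 0 if atlas is None else int(len(atlas)),
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))

    return {
        "normalized": normalized,
        "clusters": cluster_lists,
        "consensus": consensus,
        "atlas": atlas,
        "genes": genes,
    }


def score_against_truth(
    atlas: pd.DataFrame,
    truth: SyntheticTruth,
    tol_bp: int = 10,
    min_truth_tpm: float | None = None,
) -> dict:
    """Match recovered promoters to planted centers and score recovery.

    Matching is one-to-one nearest-first on |dominant position - planted
    center| within ``tol_bp`` on the same chromosome and strand.  With
    ``min_truth_tpm`` set, recall is computed over planted promoters whose
    maximum expected tpm reaches that floor.  Vacuously empty problems
    score 1.0 throughout.
    """
    planted = truth.promoters
    if min_truth_tpm is not None and len(planted):
        tpm_cols = [f"tpm_{t}" for t in truth.tissues]
        planted = planted[planted[tpm_cols].max(axis=1) >= min_truth_tpm]
    planted = planted.reset_index(drop=True)

    if len(planted) == 0 and (atlas is None or len(atlas) == 0):
        return {
            "recall": 1.0,
            "precision": 1.0,
            "mean_abs_position_error_bp": 0.0,
            "category_agreement": 1.0,
            "n_matched": 0,
            "n_planted": 0,
            "n_recovered": 0,
        }

    recovered = atlas if atlas is not None else pd.DataFrame()
    pairs = []  # (distance, planted_idx, recovered_idx)
    for pi, prow in planted.iterrows():
        for ri, rrow in recovered.iterrows():
            if rrow["chrom"] != prow["chrom"] or rrow["strand"] != prow["strand"]:
                continue
            dom = rrow["dominant_pos"]
            if pd.isna(dom):
                continue
            dist = abs(int(dom) - int(prow["center"]))
            if dist <= tol_bp:
                pairs.append((dist, pi, ri))
    pairs.sort()
    matched_planted: dict[int, int] = {}
    used_recovered: set[int] = set()
    for dist, pi, ri in pairs:
        if pi in matched_planted or ri in used_recovered:
            continue
        matched_planted[pi] = ri
        used_recovered.add(ri)

    n_matched = len(matched_planted)
    errors = []
    agree = 0
    for pi, ri in matched_planted.items():
        errors.append(abs(int(recovered.loc[ri, "dominant_pos"]) - int(planted.loc[pi, "center"])))
        if recovered.loc[ri, "breadth_class"] == planted.loc[pi, "category"]:
            agree += 1
    return {
        "recall": n_matched / len(planted) if len(planted) else 1.0,
        "precision": n_matched / len(recovered) if len(recovered) else 1.0,
        "mean_abs_position_error_bp": float(np.mean(errors)) if errors else 0.0,
        "category_agreement": agree / n_matched if n_matched else 1.0,
        "n_matched": n_matched,
        "n_planted": int(len(planted)),
        "n_recovered": int(len(recovered)),
    }
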