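"""Synthetic multi-tissue CAGE experiments and toy UTR loci with ground truth.

The generator emulates the statistical structure of a multi-tissue CAGE
study: per-sample tag counts with a heavy power-law marginal, tag start
sites scattered around planted promoter centers with a discrete-Laplace
kernel, tissue expression profiles drawn from the three breadth
categories, and toy multi-exon genes whose spliced leaders contain
exactly a planted set of uORFs and whose splice junctions are canonical
with a chosen probability.  Every output is a pure function of the
configuration (including its seed).

Planted promoter strengths are calibrated through the normalization
model itself: for each sample the background tag counts are drawn first,
the sample's power law is fitted, and the raw count whose normalized
value equals the promoter's expected tpm is planted (Poisson-perturbed
when noise is on).  Truth categories are computed by applying the
breadth rule to the expected (noise-free) profiles, so category recovery
is a well-posed statistic.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cage_normalization import (
    NormalizationConfig,
    fit_power_law_values,
    inverse_normalized_counts,
    sample_discrete_power_law,
)
from .io_formats import (
    CTSSTable,
    GeneModel,
    TranscriptModel,
    write_ctss,
    write_fasta,
    write_gtf,
)
from .promoter_atlas import BreadthClass, BreadthThresholds, classify_breadth
from .utr_toolkit import ORFRecord, SpliceJunction

DEFAULT_TISSUES = (
    "kidney",
    "intestine",
    "heart",
    "lung",
    "bone_marrow",
    "liver",
    "brain",
    "spleen",
)

NON_A = np.array(list("CGT"))


def child_seed(seed: int, name: str) -> int:
    """Stable per-stage child seed (crc32 of the stage name, xor master)."""
    return (zlib.crc32(name.encode()) ^ seed) % (2**31)


@dataclass
class SimConfig:
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_genes: int = 50
    promoters_per_gene: tuple[int, int] = (1, 3)  # inclusive range, <= 8
    category_mix: dict[str, float] = field(
        default_factory=lambda: {
            BreadthClass.NON_UBIQUITOUS.value: 0.4,
            BreadthClass.UBIQUITOUS_UNIFORM.value: 0.3,
            BreadthClass.UBIQUITOUS_NONUNIFORM.value: 0.3,
        }
    )
    base_tpm: float = 100.0  # typical expressed-promoter strength
    count_alpha: float = 1.14  # power-law exponent of per-position counts
    pos_spread: float = 2.0  # discrete-Laplace scale of TSS scatter (bp)
    noise: bool = True  # Poisson noise on planted raw counts
    seed: int = 0
    # genome / background layout
    n_chroms: int = 4
    chrom_length: int = 5_000_000
    background_positions: int = 8_000  # per sample
    promoter_spacing: int = 600  # between promoters of one gene (bp)
    min_spacing: int = 41  # must exceed 2 x clustering max_dist
    # background tags are kept this far from planted centers so every
    # planted promoter owns exactly one consensus cluster (identifiable
    # truth); real CAGE has no such guarantee (see docs/methods.md)
    clear_margin: int = 150
    norm: NormalizationConfig = field(default_factory=NormalizationConfig)

    def __post_init__(self) -> None:
        mix = sum(self.category_mix.values())
        if abs(mix - 1.0) > 1e-9:
            raise ValueError(f"category_mix sums to {mix}, expected 1")
        if self.pos_spread < 0:
            raise ValueError("pos_spread must be >= 0")
        lo, hi = self.promoters_per_gene
        if not 1 <= lo <= hi <= 8:
            raise ValueError("promoters_per_gene must be within 1..8")
        if self.promoter_spacing <= self.min_spacing:
            raise ValueError(
                f"promoter spacing {self.promoter_spacing} <= {self.min_spacing} "
                "(2 x clustering distance): planted truth would be unidentifiable"
            )


@dataclass
class SyntheticTruth:
    """Planted promoters (with expected profiles) and gene models."""

    promoters: pd.DataFrame  # gene_id, chrom, strand, center, category, tpm_<tissue>...
    genes: list[GeneModel]
    tissues: tuple[str, ...]

    def expected_profile(self, idx: int) -> dict[str, float]:
        row = self.promoters.iloc[idx]
        return {t: float(row[f"tpm_{t}"]) for t in self.tissues}


# ---------------------------------------------------------------------------
# expression profiles
# ---------------------------------------------------------------------------


def _draw_profile(
    category: str, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    n = len(cfg.tissues)
    base = cfg.base_tpm
    if category == BreadthClass.NON_UBIQUITOUS.value:
        values = np.zeros(n)
        k = int(rng.integers(1, min(3, n // 2 + 1)))
        idx = rng.choice(n, size=k, replace=False)
        values[idx] = base * rng.lognormal(0.0, 0.4, size=k)
    elif category == BreadthClass.UBIQUITOUS_UNIFORM.value:
        values = base * rng.lognormal(0.0, 0.25, size=n)
    else:  # ubiquitous non-uniform: one tissue spikes far above the rest
        values = base * rng.lognormal(0.0, 0.25, size=n)
        values[rng.integers(n)] *= 30.0
    return values


def draw_expected_profile(
    category: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    thresholds: BreadthThresholds = BreadthThresholds(),
    max_tries: int = 100,
) -> np.ndarray:
    """Expected tpm profile whose breadth class equals ``category``."""
    for _ in range(max_tries):
        values = _draw_profile(category, cfg, rng)
        profile = dict(zip(cfg.tissues, values))
        if classify_breadth(profile, thresholds).value == category:
            return values
    raise RuntimeError(f"could not draw a consistent {category} profile")


# ---------------------------------------------------------------------------
# gene / promoter layout
# ---------------------------------------------------------------------------


def _make_gene(
    gene_id: str, chrom: str, strand: str, tss: int, n_promoters: int, cfg: SimConfig
) -> tuple[GeneModel, list[int]]:
    """Toy 3-exon gene anchored at ``tss`` plus its promoter centers.

    Promoter k sits ``k * promoter_spacing`` downstream of the TSS in the
    gene's orientation, so successive promoters land in the 5'UTR, intron
    or coding exons of the model transcript.
    """
    max_off = cfg.promoter_spacing * (n_promoters - 1)
    tx_len = max(2400, max_off + cfg.promoter_spacing)
    offsets = [(0, 400), (900, 1300), (1800, tx_len)]
    if strand == "+":
        exons = [(tss + a, tss + b) for a, b in offsets]
        centers = [tss + k * cfg.promoter_spacing for k in range(n_promoters)]
    else:
        exons = [(tss - b, tss - a) for a, b in offsets]
        centers = [tss - k * cfg.promoter_spacing for k in range(n_promoters)]
    tx = TranscriptModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=200,
    )
    gene = GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, span=tx.span, transcripts=[tx]
    )
    return gene, centers


def plan_experiment(cfg: SimConfig) -> SyntheticTruth:
    """Lay out genes and promoters and draw their expected profiles."""
    rng = np.random.default_rng(child_seed(cfg.seed, "plan"))
    categories = list(cfg.category_mix.keys())
    probs = np.array([cfg.category_mix[c] for c in categories])
    genes = []
    rows = []
    genes_per_chrom = -(-cfg.n_genes // cfg.n_chroms)
    stride = cfg.chrom_length // (genes_per_chrom + 1)
    pad = 8 * cfg.promoter_spacing + 4000
    if stride < 2 * pad:
        raise ValueError("chromosomes too short for the requested gene count")
    lo, hi = cfg.promoters_per_gene
    for g in range(cfg.n_genes):
        chrom = f"chr{g % cfg.n_chroms + 1}"
        slot = g // cfg.n_chroms
        anchor = (slot + 1) * stride
        strand = "+" if rng.random() < 0.5 else "-"
        tss = anchor if strand == "+" else anchor + pad // 2
        n_prom = int(rng.integers(lo, hi + 1))
        gene, centers = _make_gene(f"G{g + 1:03d}", chrom, strand, tss, n_prom, cfg)
        genes.append(gene)
        for center in centers:
            category = categories[rng.choice(len(categories), p=probs)]
            values = draw_expected_profile(category, cfg, rng)
            row = {
                "gene_id": gene.gene_id,
                "chrom": chrom,
                "strand": strand,
                "center": center,
                "category": category,
            }
            row.update({f"tpm_{t}": v for t, v in zip(cfg.tissues, values)})
            rows.append(row)
    promoters = pd.DataFrame(rows)
    _check_identifiability(promoters, cfg)
    return SyntheticTruth(promoters=promoters, genes=genes, tissues=cfg.tissues)


def _check_identifiability(promoters: pd.DataFrame, cfg: SimConfig) -> None:
    for (_, _), grp in promoters.groupby(["chrom", "strand"]):
        centers = np.sort(grp["center"].to_numpy())
        gaps = np.diff(centers)
        if len(gaps) and gaps.min() <= cfg.min_spacing:
            raise ValueError(
                f"planted promoters {gaps.min()} bp apart; need > {cfg.min_spacing}"
            )


# ---------------------------------------------------------------------------
# tag generation
# ---------------------------------------------------------------------------


def _discrete_laplace(rng: np.random.Generator, scale: float, size: int) -> np.ndarray:
    """Symmetric integer displacements, P(d) proportional to q^|d|."""
    if scale == 0:
        return np.zeros(size, dtype=np.int64)
    q = np.exp(-1.0 / scale)
    p = 1.0 - q
    return (rng.geometric(p, size) - rng.geometric(p, size)).astype(np.int64)


def _simulate_sample(
    tissue: str, truth: SyntheticTruth, cfg: SimConfig, rng: np.random.Generator
) -> CTSSTable:
    # background: power-law counts at uniform positions genome-wide,
    # excluding the protective margin around planted centers
    n_bg = cfg.background_positions
    bg_chrom = rng.integers(1, cfg.n_chroms + 1, size=n_bg)
    bg_pos = rng.integers(0, cfg.chrom_length, size=n_bg)
    bg_strand = rng.choice(["+", "-"], size=n_bg)
    bg_count = sample_discrete_power_law(n_bg, cfg.count_alpha, rng)
    centers_by_chrom = {
        chrom: np.sort(grp["center"].to_numpy())
        for chrom, grp in truth.promoters.groupby("chrom")
    }
    keep = np.ones(n_bg, dtype=bool)
    for i, (c, p) in enumerate(zip(bg_chrom, bg_pos)):
        centers = centers_by_chrom.get(f"chr{c}")
        if centers is not None and len(centers):
            k = np.searchsorted(centers, p)
            near = min(
                abs(int(p) - int(centers[j]))
                for j in (k - 1, k)
                if 0 <= j < len(centers)
            )
            if near <= cfg.clear_margin:
                keep[i] = False
    bg_chrom, bg_pos, bg_strand, bg_count = (
        bg_chrom[keep], bg_pos[keep], bg_strand[keep], bg_count[keep],
    )

    fit = fit_power_law_values(
        bg_count,
        fit_min_count=cfg.norm.fit_min_count,
        fit_min_revcum=cfg.norm.fit_min_revcum,
    )

    counts: dict[tuple[str, int, str], int] = {}
    for c, p, s, x in zip(bg_chrom, bg_pos, bg_strand, bg_count):
        key = (f"chr{c}", int(p), str(s))
        counts[key] = counts.get(key, 0) + int(x)

    col = f"tpm_{tissue}"
    for _, prom in truth.promoters.iterrows():
        tpm = float(prom[col])
        if tpm <= 0:
            continue
        ref_count = tpm * cfg.norm.total_T / 1e6
        raw_total = float(inverse_normalized_counts(np.array([ref_count]), fit, cfg.norm)[0])
        n_tags = int(rng.poisson(raw_total)) if cfg.noise else max(1, int(round(raw_total)))
        if n_tags < 1:
            continue
        disp = _discrete_laplace(rng, cfg.pos_spread, n_tags)
        positions, per_pos = np.unique(prom["center"] + disp, return_counts=True)
        for p, k in zip(positions, per_pos):
            key = (str(prom["chrom"]), int(p), str(prom["strand"]))
            counts[key] = counts.get(key, 0) + int(k)

    rows = [(c, p, s, n) for (c, p, s), n in counts.items()]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "raw_count"])
    df = df.sort_values(["chrom", "strand", "pos"], kind="mergesort").reset_index(drop=True)
    return CTSSTable(sample_id=tissue, data=df)


def simulate_ctss_experiment(
    cfg: SimConfig, out_dir: str | Path | None = None
) -> tuple[dict[str, CTSSTable], SyntheticTruth]:
    """Full multi-tissue CAGE simulation.

    Returns one CTSS table per tissue plus the planted truth; when
    ``out_dir`` is given, also writes ``<tissue>.ctss`` files, the truth
    table, the toy genome FASTA and the gene models as GTF.
    """
    truth = plan_experiment(cfg)
    tables = {}
    for tissue in cfg.tissues:
        rng = np.random.default_rng(child_seed(cfg.seed, f"sample:{tissue}"))
        tables[tissue] = _simulate_sample(tissue, truth, cfg, rng)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for tissue, table in tables.items():
            write_ctss(table, out / f"{tissue}.ctss")
        truth.promoters.to_csv(out / "truth_promoters.tsv", sep="\t", index=False)
        write_gtf(truth.genes, out / "genes.gtf")
        write_fasta(simulate_genome(cfg), out / "genome.fa")
    return tables, truth


def simulate_genome(cfg: SimConfig) -> dict[str, str]:
    """Uniform-random ACGT chromosomes matching the experiment layout."""
    rng = np.random.default_rng(child_seed(cfg.seed, "genome"))
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        f"chr{i + 1}": bases[rng.integers(0, 4, size=cfg.chrom_length)]
        .tobytes()
        .decode("ascii")
        for i in range(cfg.n_chroms)
    }


# ---------------------------------------------------------------------------
# toy UTR locus with planted uORFs and splice junctions
# ---------------------------------------------------------------------------


@dataclass
class UTRLocusTruth:
    leader_seq: str
    uorfs: list[ORFRecord]
    junctions: list[SpliceJunction]
    junction_canonical: list[bool]
    gc: float


def _non_a_run(rng: np.random.Generator, n: int) -> str:
    """ATG-free filler: no adenines at all, so no start or stop codons."""
    return "".join(NON_A[rng.integers(0, 3, size=n)])


def _planted_orf(rng: np.random.Generator, aa_length: int) -> str:
    """ATG + (aa_length - 1) A-free codons + TAG.

    A-free interior codons can be neither stops nor starts, and the TAG
    stop cannot seed a spurious ATG in any frame, so the planted ORFs are
    the only ORFs in the leader.
    """
    if aa_length < 1:
        raise ValueError("uORF length must be >= 1 aa")
    return "ATG" + _non_a_run(rng, 3 * (aa_length - 1)) + "TAG"


def simulate_utr_locus(
    planted_uorf_lengths: list[int],
    canonical_fraction: float = 1.0,
    leader_len: int | None = None,
    n_exons: int = 3,
    intron_len: int = 80,
    cds_aa: int = 30,
    seed: int = 0,
) -> tuple[dict[str, str], GeneModel, UTRLocusTruth]:
    """Toy multi-exon gene whose spliced leader contains exactly the
    planted uORFs.

    Returns (genome dict, gene model, truth).  The leader background is
    adenine-free, so the planted ATGs are the only ORF starts;
    ``canonical_fraction`` is the probability that each intron follows
    the GT/AG rule (non-canonical introns get CT..AC ends).
    """
    rng = np.random.default_rng(seed)
    orfs = [_planted_orf(rng, aa) for aa in planted_uorf_lengths]
    spacer = 10
    needed = sum(len(o) for o in orfs) + spacer * (len(orfs) + 1)
    if leader_len is None:
        leader_len = needed
    if leader_len < needed:
        raise ValueError(
            f"cannot pack uORFs of total {needed} nt into a {leader_len} nt leader"
        )
    slack = leader_len - needed
    pieces = [_non_a_run(rng, spacer + (slack if len(orfs) == 0 else 0))]
    for k, orf in enumerate(orfs):
        pieces.append(orf)
        extra = slack if k == len(orfs) - 1 else 0
        pieces.append(_non_a_run(rng, spacer + extra))
    leader = "".join(pieces)
    assert len(leader) == leader_len

    expected = []
    pos = 0
    for aa, orf in zip(planted_uorf_lengths, orfs):
        start = leader.index(orf, pos)
        expected.append(ORFRecord(start_offset=start, aa_length=aa, has_stop=True))
        pos = start + 1
    expected.sort(key=lambda o: o.start_offset)

    cds = "ATG" + _non_a_run(rng, 3 * (cds_aa - 1)) + "TAG"
    spliced = leader + cds

    # split the spliced sequence into n_exons pieces; introns in between
    if n_exons < 1:
        raise ValueError("need >= 1 exon")
    cut_len = len(spliced) // n_exons
    exon_seqs = [
        spliced[i * cut_len : (i + 1) * cut_len if i < n_exons - 1 else len(spliced)]
        for i in range(n_exons)
    ]
    canonical_flags = [bool(rng.random() < canonical_fraction) for _ in range(n_exons - 1)]
    intron_seqs = []
    for canon in canonical_flags:
        inner = _non_a_run(rng, intron_len - 4)
        intron_seqs.append(("GT" + inner + "AG") if canon else ("CT" + inner + "AC"))

    flank = _non_a_run(rng, 100)
    genome_seq = [flank]
    exons = []
    offset = len(flank)
    for i, ex in enumerate(exon_seqs):
        exons.append((offset, offset + len(ex)))
        genome_seq.append(ex)
        offset += len(ex)
        if i < n_exons - 1:
            genome_seq.append(intron_seqs[i])
            offset += len(intron_seqs[i])
    genome_seq.append(_non_a_run(rng, 100))
    chrom = "toy1"
    genome = {chrom: "".join(genome_seq)}

    tx = TranscriptModel(
        gene_id="TOY",
        transcript_id="TOY.t1",
        chrom=chrom,
        strand="+",
        exons=exons,
        cds_start=leader_len,
    )
    gene = GeneModel(
        gene_id="TOY", chrom=chrom, strand="+", span=tx.span, transcripts=[tx]
    )
    junctions = [
        SpliceJunction(
            intron_id=f"intron{k + 1}",
            donor_seq=seq[:10],
            acceptor_seq=seq[-15:],
        )
        for k, seq in enumerate(intron_seqs)
    ]
    from .utr_toolkit import gc_content

    truth = UTRLocusTruth(
        leader_seq=leader,
        uorfs=expected,
        junctions=junctions,
        junction_canonical=canonical_flags,
        gc=gc_content(leader),
    )
    return genome, gene, truth
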