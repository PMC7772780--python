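# cageatlas

Alternate-promoter discovery from multi-tissue CAGE data, with the
downstream analyses that make promoter choice interpretable: 5'UTR
translatability metrics and distance-based phylogenetics.

Cap analysis of gene expression (CAGE) sequences the capped 5' ends of
Pol II transcripts, producing single-base tag counts at transcription
start sites (CTSS). Genes are typically driven by several discrete TSS
clusters — alternate promoters — whose usage varies across tissues.
Because alternate promoters can swap in different 5'UTR leaders, they
tune not just transcription but translation: leader length, GC content,
and upstream ORFs (uORFs) all modulate ribosome loading on the main ORF.
`cageatlas` is aimed at analysts who want to reproduce this style of
promoter-centric analysis on CTSS-level data, or to validate such a
pipeline end to end against simulations with known ground truth.

## The method

1. **Power-law normalization.** The reverse-cumulative tag-count
   distribution of a CAGE library is approximately a power law,
   revcum(x) ≈ c·x^(−α). Each sample's (α_s, c_s) is fitted by OLS in
   log–log space and counts are rank-matched onto a shared reference law
   (α_ref = 1.14, total tag count T = 10^7):

   z(x) = (c_s·x^(−α_s) / c_ref)^(−1/α_ref),   tpm = z·10^6 / T

2. **Tag clustering.** Within each (chromosome, strand), CTSS with
   positional gaps ≤ 20 bp merge transitively into tag clusters, each
   carrying its dominant position, total tpm, and the 0.1–0.9
   cumulative-signal quantile positions (interquantile width).
3. **Consensus promoters.** Tag clusters with ≥ 2 tpm in at least one
   sample are projected as interquantile ranges; ranges within 100 bp
   merge across samples into consensus clusters, the operational
   promoters, each with a per-tissue expression vector.
4. **Atlas.** Consensus clusters are assigned to genes by strand-matched
   overlap, named p1..pN in 5'→3' order, placed relative to transcript
   structure (5'UTR / coding exon / intron / flank), and classified by
   expression breadth: median < 0.2 tpm → non-ubiquitous; max > 10× the
   median → ubiquitous non-uniform; otherwise ubiquitous uniform.
5. **UTR toolkit.** Spliced 5'UTR leaders are reconstructed from
   transcript models; uORFs (ATG in the leader, translated in frame to
   the first stop), longest ORFs, GC content, and canonical GT/AG splice
   junctions are reported.
6. **Trees.** p-distances from alignments, Saitou–Nei neighbor joining,
   and bootstrap split support from column resampling, with Newick I/O.

A first-class synthetic-data generator plants promoters with known
centers, tissue profiles, and breadth categories (plus toy genomes with
planted uORFs and splice junctions), so every stage is testable without
downloads.

## Worked example

```python
import cageatlas as ca

cfg = ca.SimConfig(n_genes=50, seed=17)           # 8 tissues, noise on
tables, truth = ca.simulate_ctss_experiment(cfg)
res = ca.run_pipeline(tables, config=ca.PipelineConfig())
atlas = ca.build_atlas(res["consensus"], truth.genes)
print(ca.score_against_truth(atlas, truth, tol_bp=10, min_truth_tpm=2))
```

prints

```
{'recall': 1.0, 'precision': 0.3592592592592593, 'mean_abs_position_error_bp': 0.4329896907216495,
 'category_agreement': 1.0, 'n_matched': 97, 'n_planted': 97, 'n_recovered': 270}
```

Every planted promoter whose strongest tissue reaches 2 tpm was
recovered, with the recovered dominant position on average 0.43 bp from
the planted center, and the measured breadth class agreed with the
planted category for all matches. Precision is lower by design: the
simulation scatters power-law background transcription across the
genome, and at desk-scale library depths single background tags exceed
the 2-tpm consensus threshold, so many background consensus clusters
fall within gene spans (see `docs/methods.md`).

The same pipeline is available from the shell:

```sh
cageatlas simulate --seed 17 --out sim/
cageatlas run-all --ctss sim/kidney.ctss --ctss sim/intestine.ctss ... \
    --gtf sim/genes.gtf --fasta sim/genome.fa --out-dir run/
cageatlas score --atlas run/atlas.tsv --truth sim/truth_promoters.tsv
```

plus `normalize`, `cluster`, `consensus`, `atlas`, `utr`, `splice-check`
and `phylo` subcommands for the individual stages.

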