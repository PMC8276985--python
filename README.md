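# embryoatlas

Cell-type annotation and regulatory analysis for single-nucleus RNA-seq of
early plant embryos — with a fully ground-truthed synthetic data generator,
so every stage of the pipeline is testable end to end without external
data.

Early embryos are tiny, transient and buried in maternal tissue: the few
hundred nuclei one can sort are contaminated by surrounding seed tissue,
unsupervised clustering cannot resolve the briefly existing cell types, and
no large annotated atlas exists to train on. This package implements the
alternative strategy: lean on a small curated panel of marker genes whose
presence/absence per cell type is known, score every nucleus against that
panel with an exact test, and build everything else — clustering,
decontamination, per-cluster gene ranking, gene-set screens and promoter
motif analysis — on top of those scores. It is intended for computational
biologists analysing plate-based snRNA-seq of globular-stage embryos or any
comparable low-n, high-contamination, marker-panel setting.

## The statistics at the core

**Cell-type score.** For a cell type *t* with positive markers *P_t* (genes
recorded as strongly or weakly expressed in *t*) and negative markers *N_t*
(recorded as not expressed), take the non-informative genes out and let
*N = |P_t| + |N_t|* be the test population and *K = |P_t|*. A nucleus
detecting *n* of the population genes (value ≥ 1), *k* of them positive
markers, gets the score

    S_t = sign(k − nK/N) · (−log10 P),

where *P* is the two-tailed hypergeometric probability (minimum-likelihood
construction: the total probability of all outcomes no more likely than
*k*). Nuclei are clustered in this score space (Leiden on a shared-nearest-
neighbour graph by default; k-means optionally) and clusters are labelled
by the majority best-scoring cell type. Contaminant libraries are removed
cluster-wise by comparing median embryo-panel and contaminant-panel scores.

**Enrichment magnitude.** For the expressed-gene population *G*
(nuclear-encoded, Pol II-transcribed, detected in ≥ 10% of nuclei of ≥ 1
cluster), each cluster *C* is compared with the unweighted mean of the
other clusters *O* on mean CPM *M_iC* and detection proportion *p_iC*:

    F_iC = log2((M_iC + c) / (M_iO + c)),    D_iC = p_iC − p_iO,
    E_iC = z(F_C)_i + z(D_C)_i,

with pseudocount *c* = 1 CPM and per-cluster z-scaling across genes
(population σ). Genes are ranked by *E* within each cluster; the first and
last 250 form the top-/bottom-ranked lists. Downstream screens test gene
sets in the top lists (two-tailed hypergeometric), compare conservation
scores (two-sample KS), apply E/detection thresholds, and Spearman-correlate
cluster profiles with bulk references.

**Motif regulatory analysis.** Promoters are the 600-nt window from 500 bp
upstream to 100 bp downstream of the TSS (strand-aware, clipped at contig
ends). PWMs are scanned on both strands by log-odds score (hit = ≥ 80% of
the maximum attainable score); per cluster, motif presence in top-ranked
promoters is tested against the bottom-ranked background by a one-sided
Fisher exact test with BH correction across motifs. Motifs significant
anywhere collapse into families (max rule), and candidate regulators are
nominated by Pearson-correlating each family's enrichment profile across
clusters with TF expression-enrichment profiles (|r| > 0.5).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data with planted truth (each step writes its tables under `results/`):

```sh
python analysis/01_simulate_dataset.py
python analysis/02_qc_normalise.py
python analysis/03_score_and_cluster.py
python analysis/04_rank_enrichment.py
python analysis/05_gene_set_screens.py
python analysis/06_motif_regulators.py
```

which prints, step by step:

```
simulated 2000 genes x 450 nuclei (90 contaminant libraries planted)
retained 437/450 nuclei (97%); 13 failed the read filter, 0 the detected-gene filter
pass 1: dropped clusters ['c0'] (87 nuclei)
pass 2: 9 clusters over 350 retained nuclei; labels: ['type1', ..., 'type9']
cluster-label accuracy vs planted truth: 100.0%
contaminant recall: 96.7%
|G| = 1894 expressed genes ranked in 9 clusters
marker coverage: 360/360 (100.0%) planted markers appear in >= 1 top-250 list
type1_markers: enriched in 1 and depleted in 6 of 9 clusters (P <= 0.05)
broadly_expressed_control: enriched in 0 and depleted in 0 of 9 clusters
conservation: 0/9 clusters significant (no structure planted, expect ~0)
reference correlation: 9/9 clusters best-match the pseudo-bulk of their own lineage group
planted motif M000 (cluster c0, label type1): significant in ['c0']
family FAM00: best candidate regulator g00030 (r = 0.93, positive; planted TF: g00030)
```

Read top to bottom: the simulator plants nine cell types plus seed-coat
contaminants; QC removes shallow libraries; the decontamination pass drops
the contaminant-dominated cluster and the cell-type pass recovers all nine
types perfectly; every planted marker surfaces in its home cluster's
top-250; the gene-set, conservation and reference-correlation screens behave
exactly as the planted truth dictates; and the motif stage finds the planted
promoter motif only where it was planted, nominating the planted TF as the
regulator.

The same stages are scriptable via the `atlas` CLI (`atlas simulate`,
`atlas qc`, `atlas score`, `atlas decontaminate`, `atlas enrich`,
`atlas settest`, `atlas screen`, `atlas motifs`) or the library API
(`embryoatlas.pipeline.run_expression_pipeline`).

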