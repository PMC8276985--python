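# Methods

## Marker-panel cell-type scoring

The scoring model treats a nucleus's detected genes as a draw without
replacement from the marker-reference population of a cell type. For type
*t*, the population is the non-NA reference genes (positives *P_t* = genes
labelled `s` or `w`, pooled; negatives = genes labelled `n`); NA entries are
excluded from that type's test entirely. With population size *N*,
*K = |P_t|* successes, *n* detected population genes and *k* detected
positives, the two-tailed P-value is the minimum-likelihood construction:
the sum of pmf(x) over all achievable *x* with pmf(x) ≤ pmf(k) (the same
convention scipy uses for two-sided Fisher tests), floored at 1e-300 so the
−log10 transform stays finite. The score is signed by *k − nK/N*, so a
nucleus depleted of a type's markers is pushed away from that type; a
nucleus detecting nothing (n = 0) scores exactly 0 — uninformative, not an
error. An exhaustive-enumeration oracle covers every (N ≤ 30, K, n, k) in
the test suite.

Assumptions worth stating: detection is binary at value ≥ 1 (raw counts
preferred; TPM-like inputs are accepted with the same threshold), marker
labels `s` and `w` carry equal weight in the test, and the per-type
populations are conditionally independent given the detected-gene set (the
nine scores of a nucleus are correlated through *n*; they are used jointly
only as clustering coordinates, never as joint inference).

## Clustering and decontamination

Clustering runs in score space, not expression space. The default is Leiden
community detection (resolution 1.0, RBConfiguration objective) on an
unweighted shared-nearest-neighbour graph (k = 15 Euclidean neighbours),
seeded and deterministic; an integer argument selects k-means instead. A 2-D
embedding (PCA default, UMAP optional) is produced for visualisation only
and never feeds statistics. Clusters are labelled by the strict-majority
(> 50%) best-scoring cell type of their members, else "mixed".

Decontamination is cluster-level and runs as a separate first pass: nuclei
are clustered on the concatenation of embryo-panel and contaminant-panel
scores, and a cluster is dropped when the median contaminant score of its
members exceeds their median embryo score (each nucleus's panel score being
its best score over that panel's types). The retained nuclei are then
re-scored and re-clustered on the embryo panel alone. The two-pass design
exists because contaminant nuclei are *flat* in embryo-score space and
otherwise co-cluster with low-quality embryonic nuclei; adding the
contaminant dimension separates them. An optional quality filter drops
clusters whose median detected-gene count falls below half the global
median.

## Enrichment magnitude

For each gene *i* in the expressed population *G* and cluster *C*:
*F_iC* = log2((M_iC + c)/(outgroup mean M + c)) with pseudocount *c* = 1 CPM
(the data contain exact zeros and no zero-handling rule is canonical; the
pseudocount is configurable and F is invariant to global CPM rescaling only
when *c* is rescaled with it); *D_iC* = p_iC − outgroup mean p. The outgroup
aggregate is the unweighted mean of the other clusters' per-cluster profiles
(size-weighted "pooled" aggregation is available for sensitivity analysis).
Both vectors are centred and scaled per cluster across genes using the
population (ddof = 0) standard deviation — immaterial at |G| ≈ 10³–10⁴ — and
summed: E = z(F) + z(D). A zero-variance component contributes zero rather
than NaN. Two identities follow by construction and are asserted on every
simulated dataset: per-cluster ΣE = 0 (tolerance 1e-9), and with exactly two
clusters E_iA = −E_iB.

Ranking is by E descending with gene id ascending as the tie-break, making
top-/bottom-k lists deterministic; k defaults to 250 and the lists overlap
(with a warning) only when 2k exceeds |G|. The "≥ 10% of nuclei" detection
gate uses ceil(0.1·|C|) so it can never be met by strictly fewer nuclei, and
report percentages round half-up.

## Gene-set and conservation screens

Set over/under-representation in a top list uses the same two-tailed
hypergeometric engine (population G, successes = set ∩ G, draw = top list),
reporting fold = k/kE with kE = |top|·|set ∩ G|/|G|. Raw P is flagged at
α = 0.05; BH q-values across clusters are reported alongside but do not
drive the flag.

The conservation screen reports two things: a z-score of the top-list mean
against the mean of all expressed genes, z = (mean(top) − mean(G)) /
(sd(G)/√|top|) — the standard-error form; the population-sd alternative
would simply shrink z by √|top| — and a two-sided two-sample
Kolmogorov–Smirnov test. The KS comparison is made between the top list and
the *complementary* expressed genes rather than the full superset: comparing
a subset against a set containing it is conservative under the null
(measured rejection ≈ 0.02 at α = 0.05 for 250-of-2000 subsets), while the
disjoint comparison is calibrated (≈ 0.05, verified over 1000 replicates in
the test suite). Genes without a conservation score are dropped with a
warning; fewer than five scored genes on either side is an error.

Threshold screens use ≥ semantics on both E and detection proportion, so a
gene sitting exactly on a threshold is retained. Reference correlation is
Spearman's ρ with mid-ranked ties on the gene intersection (≥ 10 shared
genes required).

## Promoters and motifs

Promoter windows are [TSS − 500, TSS + 100) on the plus strand and the
strand-mirrored [TSS − 99, TSS + 501) on the minus strand — 0-based
half-open throughout, GFF3's 1-based inclusive coordinates converted on
read — clipped at contig ends and reverse-complemented on the minus strand
so position 0 is always the most upstream promoter base. The TSS comes from
a user-supplied table (e.g. 5'-end sequencing summaries) when present,
otherwise the most upstream annotated transcript 5' end.

PWM scanning is an in-repo log-odds scanner rather than a wrapper around an
external motif tool: probabilities are floored at 1e-9 inside the log (so
point-mass consensus matrices stay finite), N bases contribute zero
log-odds, both strands are scanned (reverse-strand hits reported at their
forward-strand start), and a window is a hit at ≥ 80% of the motif's
maximum attainable score by default (threshold and background are
configurable; uniform background default). Presence/absence per promoter
feeds a one-sided Fisher exact test of top-ranked vs bottom-ranked
promoters per cluster, BH-corrected across motifs within the cluster
(q ≤ 0.05). Using the bottom-ranked promoters as background controls for
sequence composition shared across the cohort. Family collapsing takes the
max −log10 P and max presence fraction over member motifs significant in at
least one cluster; a motif without family annotation becomes a warned
singleton family. Candidate-regulator nomination computes Pearson's r
between a family's −log10 P profile and each candidate TF's E profile
across clusters (no rank transform), classifying at |r| > 0.5 and flagging
the strongest |r| per family; zero-variance profiles are reported as
degenerate rather than correlated.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical regime the pipeline assumes: ~9
cell types × ~50 nuclei, thousands of genes with sparse detection, curated
type-specific marker panels, a contaminant tissue mixed in at the library
level, and promoters with planted motif occurrences.

Counts are gamma-Poisson: gene baselines are log-normal(0, 1) (marker genes
log-normal(0, 0.4) — curated panels are built from reliably detectable
genes, so their baselines are typical but low-variance); per nucleus, the
type profile is renormalised to a log-normal library size (CV 0.3, mean
2000 counts, inflated by 1/(1−dropout) so realised depth centres on the
target) and drawn NB with dispersion 0.3, then thinned by independent
Bernoulli dropout (rate 0.3). At this depth a typical library detects ~700
of 2000 genes — the same ~35% sparse-detection regime, scaled down, as a
real few-thousand-genes-per-library experiment over a 25k-gene
transcriptome.

Markers are *type-specific in both directions*: a strong marker is
`marker_fold` (default 8) above baseline in its home type and suppressed by
the reciprocal 1/fold elsewhere, because the reference records those genes
as "not expressed" in other types — planting them at baseline elsewhere
would contradict the reference the scorer is given. Weak markers get half
the fold-up, 1 + (fold − 1)/2, so `marker_fold = 1` plants no signal in
either direction. Default panel size is 40 markers per type, the scale of
real curated panels (tens of positives per type). The contaminant
("seed-coat") pseudo-type is an extra marker block with the same structure.
10% of non-marker reference labels are masked NA. Gene-level draws
(baselines, roles) and nucleus-level draws (assignments, depths, counts)
use separate seeded substreams, so the planted gene truth is identical
across cohort sizes at a fixed seed; all randomness descends from the
single config seed.

Promoter simulation gives each gene its own contig (alternating strands), a
uniform-random 600-nt promoter, and — for clusters named in the plant map —
an exact consensus occurrence in a configurable fraction (default 0.6) of
that cluster's genes at a uniform offset.

What the generator does **not** emulate, and hence what green tests do not
establish for real data: batch/plate effects beyond labels, ambient RNA
within otherwise-embryonic libraries (contamination is all-or-nothing per
nucleus), gene–gene correlation beyond the marker blocks, UMI structure,
marker panels with errors or cross-reactive genes, promoter base
composition bias, and degenerate motif occurrences (plants are exact
consensus). Recovery rates near 100% on synthetic data say the pipeline's
machinery is correct under its own assumptions, not that real embryos
separate this cleanly.

## Problem sizes and runtime choices

The study-condition simulation is 9 types × 50 nuclei × 2000 genes
(seed 7); the acceptance script and test suite run it with and without 20%
contamination. Oracle sweeps enumerate every hypergeometric configuration
to N = 30; motif null calibration uses 50 motifs × 20 replicate clusters of
100 + 100 random promoters (1000 motif–cluster tests); conservation null
calibration uses 1000 replicates of 250-gene draws from a 2000-gene
population. The full test suite runs in ~1.5 minutes and the acceptance
script in under one minute on a single CPU.

## Known limitations

Cluster-level decontamination cannot rescue a contaminant nucleus that
lands inside a healthy embryonic cluster (or vice versa); with the default
regime the leakage is ≈ 0 but it grows as marker folds shrink. The
minimum-likelihood two-tailed P is one of several defensible two-sided
conventions; alternatives (doubling the smaller tail) differ in the third
significant figure at these panel sizes. The Fisher-based motif test is a
presence/absence screen: it does not model occurrence counts, hit strength
or positional bias, and its power depends on the 80%-of-max hit threshold
for degenerate motifs.
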