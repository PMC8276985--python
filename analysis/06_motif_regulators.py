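#!/usr/bin/env python
"""Promoter motif enrichment and candidate-regulator nomination.

Generates a toy genome in which a fraction (0.6) of one cluster's
top-ranked gene promoters carry an exact consensus occurrence of one motif,
writes the motif library (MEME minimal format), genome FASTA and GFF3,
re-extracts the promoters (500 bp upstream to 100 bp downstream of the
TSS, strand-aware), tests every motif for overrepresentation in top- vs
bottom-ranked promoters per cluster (one-sided Fisher, BH within cluster),
collapses significant motifs into families (max rule) and Pearson-
correlates family enrichment with candidate TF expression enrichment
across clusters. The planted TF is a marker gene of the planted cluster's
cell type, so its expression tracks the planting. Outputs under
results/motifs/.
"""

from pathlib import Path

import pandas as pd

from embryoatlas.motifs import (collapse_families, correlate_tf_expression,
                                extract_promoters, motif_enrichment,
                                synthetic_motif_set, write_annotations,
                                write_meme)
from embryoatlas.simulate import simulate_promoters, write_fasta

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 7
PLANTED_MOTIF = "M000"


def main() -> None:
    out = ROOT / "motifs"
    out.mkdir(parents=True, exist_ok=True)

    tops = {p.stem[4:]: p.read_text().split()
            for p in (ROOT / "enrichment").glob("top_*.txt")}
    bottoms = {p.stem[7:]: p.read_text().split()
               for p in (ROOT / "enrichment").glob("bottom_*.txt")}
    long = pd.read_csv(ROOT / "enrichment" / "enrichment.tsv", sep="\t")
    E = long.pivot(index="gene_id", columns="cluster", values="E")
    labels = pd.read_csv(ROOT / "clustering" / "clusters.tsv", sep="\t", index_col=0)
    label_of = labels.drop_duplicates("cluster").set_index("cluster")["label"]

    planted_cluster = sorted(tops)[0]
    motif_set = synthetic_motif_set(12, seed=SEED)
    # nominate a real expressed gene as the planted motif's TF: a top-ranked
    # gene of the planted cluster, so its E profile tracks the planting
    tf_gene = tops[planted_cluster][0]
    motif_set.motifs[PLANTED_MOTIF].tf = tf_gene

    gene_sets = {}
    for c in tops:
        gene_sets[c] = tops[c]
        gene_sets[f"{c}__bottom"] = bottoms[c]
    genome, gff, ptruth = simulate_promoters(gene_sets, motif_set,
                                             {planted_cluster: PLANTED_MOTIF},
                                             seed=SEED, plant_fraction=0.6)
    write_fasta(genome, out / "genome.fa")
    (out / "genes.gff3").write_text(gff)
    write_meme(motif_set, out / "motifs.meme")
    write_annotations(motif_set, out / "motif_annotations.tsv")
    ptruth.occurrences.to_csv(out / "planted_occurrences.tsv", sep="\t", index=False)

    results = []
    for c in sorted(tops):
        top_prom = extract_promoters(tops[c], out / "genes.gff3", out / "genome.fa")
        bot_prom = extract_promoters(bottoms[c], out / "genes.gff3", out / "genome.fa")
        results.append(motif_enrichment(top_prom.sequences, bot_prom.sequences,
                                        motif_set, alpha=0.05, cluster=c))
        if c == planted_cluster:
            top_prom.write_bed(out / f"promoters_{c}.bed")
    results = pd.concat(results, ignore_index=True)
    results.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)

    planted_rows = results[results["motif_id"] == PLANTED_MOTIF]
    sig = planted_rows.loc[planted_rows["significant"], "cluster"].tolist()
    print(f"planted motif {PLANTED_MOTIF} (cluster {planted_cluster}, "
          f"label {label_of[planted_cluster]}): significant in {sig}")

    fams = collapse_families(results, motif_set)
    fams.to_csv(out / "family_enrichment.tsv", sep="\t", index=False)
    fam_matrix = fams.pivot(index="family", columns="cluster",
                            values="neglog10_p").fillna(0.0)
    fam_matrix = fam_matrix.reindex(columns=E.columns, fill_value=0.0)

    planted_family = motif_set.motifs[PLANTED_MOTIF].family
    # decoy candidates: top genes of OTHER clusters, whose expression
    # enrichment peaks elsewhere
    decoys = [tops[c][0] for c in sorted(tops) if c != planted_cluster]
    candidates = {planted_family: [tf_gene] + decoys}
    corr = correlate_tf_expression(fam_matrix, E, candidates)
    corr.to_csv(out / "tf_correlation.tsv", sep="\t", index=False)
    best = corr.loc[corr["best"]]
    if len(best):
        b = best.iloc[0]
        print(f"family {planted_family}: best candidate regulator {b['tf']} "
              f"(r = {b['r']:.2f}, {b['classification']}; planted TF: {tf_gene})")


if __name__ == "__main__":
    main()
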