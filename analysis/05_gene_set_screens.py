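#!/usr/bin/env python
"""Gene-set statistics over the ranked lists.

Four screens: (1) over/under-representation of gene sets in each cluster's
top-ranked genes — one cell type's marker panel (expected enriched in its
home cluster, depleted elsewhere) and a random broadly expressed control
set (expected null everywhere); (2) conservation-score distribution tests
per cluster (no conservation structure is planted, so these should stay
null); (3) threshold screens at E >= 2.5 and at E >= 2 with >= 10%
detection; (4) Spearman correlation of cluster profiles against pseudo-bulk
references built from the planted truth (embryo-proper-like = types 1-6,
suspensor-like = types 7-9). Outputs under results/gene_sets/.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from embryoatlas.enrichment import EnrichmentTable, cluster_profiles
from embryoatlas.ingest import ExpressionMatrix, compute_cpm, read_expression
from embryoatlas.scoring import MarkerReference
from embryoatlas.setstats import (GeneSet, conservation_test,
                                  reference_correlation, set_enrichment_all,
                                  threshold_screen)

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_table(path: Path) -> EnrichmentTable:
    long = pd.read_csv(path, sep="\t")
    frames = {c: long.pivot(index="gene_id", columns="cluster", values=c)
              for c in ["M", "p", "F", "D", "zF", "zD", "E"]}
    return EnrichmentTable(**frames, pseudocount=1.0)


def main() -> None:
    out = ROOT / "gene_sets"
    out.mkdir(parents=True, exist_ok=True)
    warnings.filterwarnings("ignore", message=".*unscored.*")

    table = load_table(ROOT / "enrichment" / "enrichment.tsv")
    G = sorted(table.genes)
    tops = {p.stem[4:]: p.read_text().split()
            for p in (ROOT / "enrichment").glob("top_*.txt")}

    ref = MarkerReference.read_tsv(ROOT / "data" / "markers_embryo.tsv")
    first_type = ref.cell_types[0]
    marker_set = GeneSet(f"{first_type}_markers",
                         [g for g in ref.positive_set(first_type) if g in set(G)])
    all_markers = {g for t in ref.cell_types for g in ref.positive_set(t)}
    rng = np.random.default_rng(0)
    non_marker = sorted(set(G) - all_markers)
    housekeeping = GeneSet("broadly_expressed_control",
                           rng.choice(non_marker, 150, replace=False))

    for gs in (marker_set, housekeeping):
        df = set_enrichment_all(tops, gs, G)
        df.to_csv(out / f"set_test_{gs.name}.tsv", sep="\t")
        n_enr = int((df["significant"] & (df["direction"] == "enriched")).sum())
        n_dep = int((df["significant"] & (df["direction"] == "depleted")).sum())
        print(f"{gs.name}: enriched in {n_enr} and depleted in {n_dep} "
              f"of {len(df)} clusters (P <= 0.05)")

    # conservation tests: scores are simulated without cluster structure
    m = read_expression(ROOT / "qc" / "qc.mtx", fmt="mtx",
                        gene_meta=ROOT / "qc" / "qc.gene_meta.tsv")
    scores = m.gene_meta["conservation_score"]
    rows = []
    for c, top in tops.items():
        r = conservation_test(top, scores, G)
        rows.append({"cluster": c, "z": r.z, "ks_D": r.ks_D, "p": r.p})
    cons = pd.DataFrame(rows).set_index("cluster")
    cons.to_csv(out / "conservation_tests.tsv", sep="\t")
    print(f"conservation: {(cons['p'] <= 0.05).sum()}/{len(cons)} clusters "
          "significant (no structure planted, expect ~0)")

    # threshold screens on the marker set
    for min_e, min_frac, name in [(2.5, 0.0, "screen_E2.5"),
                                  (2.0, 0.10, "screen_E2_detect10")]:
        hits = threshold_screen(table, marker_set, min_E=min_e,
                                min_detect_frac=min_frac)
        hits.to_csv(out / f"{name}.tsv", sep="\t")
        print(f"{name}: {len(hits)}/{len(marker_set.members)} set members pass")

    # pseudo-bulk reference correlation
    truth = pd.read_csv(ROOT / "data" / "truth.tsv", sep="\t",
                        index_col=0)["true_type"]
    assignment = pd.read_csv(ROOT / "clustering" / "clusters.tsv", sep="\t",
                             index_col=0)["cluster"].astype(str)
    mg = ExpressionMatrix(m.values.loc[G, assignment.index],
                          m.nucleus_meta.loc[assignment.index],
                          m.gene_meta.loc[G], [])
    cpm = compute_cpm(mg)
    Mprof, _ = cluster_profiles(cpm, assignment, detection_source=mg)
    shared = truth.loc[assignment.index]
    ep_types = {f"type{i+1}" for i in range(6)}
    reference = pd.DataFrame({
        "embryo_proper_bulk": cpm.values.loc[:, shared.isin(ep_types).to_numpy()].mean(axis=1),
        "suspensor_bulk": cpm.values.loc[:, (~shared.isin(ep_types)).to_numpy()].mean(axis=1),
    })
    rho = reference_correlation(Mprof, reference)
    rho.to_csv(out / "reference_correlation.tsv", sep="\t")
    labels = pd.read_csv(ROOT / "clustering" / "clusters.tsv", sep="\t",
                         index_col=0)
    label_of = labels.drop_duplicates("cluster").set_index("cluster")["label"]
    best = rho.idxmax(axis=1)
    agree = sum((label_of[c] in ep_types) == (best[c] == "embryo_proper_bulk")
                for c in rho.index)
    print(f"reference correlation: {agree}/{len(rho)} clusters best-match "
          "the pseudo-bulk of their own lineage group")


if __name__ == "__main__":
    main()
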