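"""End-to-end orchestration of the expression pipeline.

Two clustering passes mirror the analysis design: a decontamination pass
clusters all libraries in the combined embryo + contaminant score space and
drops clusters dominated by the contaminant panel; a cell-type pass then
re-clusters the retained nuclei on embryo cell-type scores only, labels the
clusters, and computes per-cluster profiles and ranked gene enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .enrichment import EnrichmentTable, cluster_profiles, enrichment_scores, rank_genes
from .ingest import ExpressionMatrix, compute_cpm, expressed_gene_set
from .scoring import (CellTypeScoreMatrix, ClusterModel, MarkerReference,
                      cluster_scores, flag_contaminants, score_matrix)
from .simulate import (GroundTruth, SimulationConfig, generate_contaminant_reference,
                       generate_reference, simulate_counts)


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix          # retained nuclei, all genes
    scores: CellTypeScoreMatrix       # embryo panel scores of retained nuclei
    clusters: ClusterModel            # cell-type clustering of retained nuclei
    contamination_clusters: ClusterModel
    contamination_report: pd.DataFrame
    dropped_nuclei: list[str]
    expressed_genes: list[str]
    table: EnrichmentTable
    top_bottom: dict                  # cluster -> {"top": [...], "bottom": [...]}

    def cluster_of_label(self) -> dict:
        """Invert cluster labels (only meaningful when labels are unique)."""
        return {lab: cid for cid, lab in self.clusters.labels.items()}


def run_expression_pipeline(m: ExpressionMatrix, embryo_ref: MarkerReference,
                            contam_ref: MarkerReference | None = None,
                            resolution: float = 1.0, seed: int = 0,
                            k_top: int = 250, min_frac: float = 0.10,
                            pseudocount: float = 1.0) -> PipelineResult:
    """Score, decontaminate, cluster, and rank genes for one dataset."""
    s_emb = score_matrix(m, embryo_ref)
    if contam_ref is not None:
        s_con = score_matrix(m, contam_ref)
        combined = CellTypeScoreMatrix(
            pd.concat([s_emb.scores, s_con.scores], axis=1),
            s_emb.detected_marker_counts)
        pass1 = cluster_scores(combined, resolution, seed=seed)
        kept, report = flag_contaminants(m, embryo_ref, contam_ref, pass1)
        retained = list(kept.assignment.index)
    else:
        pass1 = ClusterModel(pd.Series("c0", index=m.values.columns))
        report = pd.DataFrame()
        retained = list(m.values.columns)
    dropped = [n for n in m.values.columns if n not in set(retained)]

    m_ret = ExpressionMatrix(m.values[retained], m.nucleus_meta.loc[retained],
                             m.gene_meta.copy(), list(m.log))
    scores = CellTypeScoreMatrix(s_emb.scores.loc[retained],
                                 s_emb.detected_marker_counts.loc[retained])
    clusters = cluster_scores(scores, resolution, seed=seed)

    G = expressed_gene_set(m_ret, clusters, min_frac=min_frac)
    mg = ExpressionMatrix(m_ret.values.loc[G], m_ret.nucleus_meta,
                          m_ret.gene_meta.loc[G], list(m_ret.log))
    cpm = compute_cpm(mg)
    M, p = cluster_profiles(cpm, clusters, detection_source=mg)
    k_eff = min(k_top, len(G))
    table = enrichment_scores(M, p, pseudocount=pseudocount)
    top_bottom = rank_genes(table, k=k_eff)
    return PipelineResult(matrix=m_ret, scores=scores, clusters=clusters,
                          contamination_clusters=pass1,
                          contamination_report=report, dropped_nuclei=dropped,
                          expressed_genes=G, table=table, top_bottom=top_bottom)


def simulate_and_run(config: SimulationConfig, resolution: float = 1.0,
                     cluster_seed: int = 0, k_top: int = 250,
                     ) -> tuple[PipelineResult, GroundTruth, MarkerReference, pd.DataFrame]:
    """Simulate a dataset under ``config`` and run the full pipeline on it.

    Returns (result, truth, embryo reference, true marker roles).
    """
    ref, roles = generate_reference(config)
    m, truth = simulate_counts(ref, config)
    contam_ref = (generate_contaminant_reference(config)
                  if config.contamination_fraction > 0 else None)
    res = run_expression_pipeline(m, ref, contam_ref, resolution=resolution,
                                  seed=cluster_seed, k_top=k_top)
    return res, truth, ref, roles
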