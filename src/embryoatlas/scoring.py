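"""Marker-panel cell-type scoring, clustering and contaminant flagging.

Each nucleus is scored against a curated marker reference: a gene x
cell-type table whose entries say whether a gene is strongly expressed
(``s``), weakly expressed (``w``), not expressed (``n``) or non-informative
(``NA``) in that cell type. Strong and weak markers are pooled as the
positive set of a type, ``n`` genes are its negative set, and a two-tailed
hypergeometric test asks whether the markers a nucleus detects are enriched
or depleted for the type's positives. The signed -log10 P-values form a
nucleus x cell-type score matrix which is then embedded and clustered;
clusters are labelled by the majority best-scoring cell type of their
member nuclei.

Contaminant libraries (e.g. seed-coat nuclei carried through sorting) are
flagged at the cluster level by scoring every nucleus against both an
embryo panel and a contaminant panel and dropping clusters whose nuclei
look more like the contaminant tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import DETECTION_MIN, ExpressionMatrix
from .stats import signed_log10_hypergeom

VALID_LABELS = {"s", "w", "n", "NA"}
POSITIVE_LABELS = ("s", "w")


@dataclass
class MarkerReference:
    """Gene x cell-type marker label matrix over {s, w, n, NA}.

    Positive markers of a type are the genes labelled ``s`` or ``w``;
    negative markers are the genes labelled ``n``; ``NA`` genes are
    uninformative for that type and excluded from its test population.
    """

    labels: pd.DataFrame  # genes x cell types, values in VALID_LABELS

    def __post_init__(self) -> None:
        bad = set(np.unique(self.labels.to_numpy().astype(str))) - VALID_LABELS
        if bad:
            raise ValueError(f"invalid marker labels: {sorted(bad)}")
        if self.labels.index.duplicated().any():
            raise ValueError("duplicate gene ids in marker reference")

    @property
    def cell_types(self) -> list[str]:
        return list(self.labels.columns)

    @property
    def genes(self) -> pd.Index:
        return self.labels.index

    def positive_set(self, cell_type: str) -> list[str]:
        col = self.labels[cell_type]
        return list(col.index[col.isin(POSITIVE_LABELS)])

    def negative_set(self, cell_type: str) -> list[str]:
        col = self.labels[cell_type]
        return list(col.index[col == "n"])

    def population(self, cell_type: str) -> list[str]:
        """Non-NA genes for a type: the hypergeometric population."""
        col = self.labels[cell_type]
        return list(col.index[col != "NA"])

    def counts(self) -> pd.DataFrame:
        """Per-type positive / negative / NA marker counts."""
        rows = {}
        for t in self.cell_types:
            col = self.labels[t]
            rows[t] = {
                "n_positive": int(col.isin(POSITIVE_LABELS).sum()),
                "n_negative": int((col == "n").sum()),
                "n_na": int((col == "NA").sum()),
            }
        return pd.DataFrame(rows).T

    # -- IO -----------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path: str | Path) -> "MarkerReference":
        """Read a long-format TSV with columns gene_id, cell_type, label."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        wide = df.pivot(index="gene_id", columns="cell_type", values="label")
        wide = wide.fillna("NA")
        return cls(wide)

    def write_tsv(self, path: str | Path) -> None:
        long = self.labels.stack().rename("label").reset_index()
        long.columns = ["gene_id", "cell_type", "label"]
        long.to_csv(path, sep="\t", index=False)


def intersect_reference(ref: MarkerReference, expressed) -> MarkerReference:
    """Restrict a marker reference to an expressed-gene set.

    Raises if any cell type loses all its positive markers (the type would
    become unscorable) or if the intersection is empty.
    """
    expressed = pd.Index(expressed)
    if len(expressed) == 0:
        raise ValueError("expressed gene set is empty")
    keep = ref.genes.intersection(expressed)
    if len(keep) == 0:
        raise ValueError("no marker reference gene is expressed")
    out = MarkerReference(ref.labels.loc[keep])
    for t in out.cell_types:
        if len(out.positive_set(t)) == 0:
            raise ValueError(f"cell type {t!r} has no positive markers after "
                             "intersection with expressed genes")
    return out


def celltype_score(detected_genes, ref: MarkerReference, cell_type: str) -> float:
    """Signed -log10 two-tailed hypergeometric cell-type score of one nucleus.

    Population: the non-NA reference genes of ``cell_type`` (size N);
    successes: its positive markers (K); draw: the detected reference genes
    within the population (n); observed: detected positive markers (k).
    Positive scores mean the nucleus detects more positive markers than
    expected by chance, negative scores fewer. n = 0 (nothing detected)
    gives score 0: the test is uninformative, not an error.
    """
    pop = set(ref.population(cell_type))
    pos = set(ref.positive_set(cell_type))
    if len(pos) == 0:
        raise ValueError(f"cell type {cell_type!r} has no positive markers")
    det = set(detected_genes) & pop
    N, K, n, k = len(pop), len(pos), len(det), len(det & pos)
    return signed_log10_hypergeom(k, N, K, n)


@dataclass
class CellTypeScoreMatrix:
    """Nucleus x cell-type signed score matrix with per-nucleus best type."""

    scores: pd.DataFrame  # nuclei x cell types
    detected_marker_counts: pd.Series  # per nucleus, detected reference genes

    @property
    def argmax_type(self) -> pd.Series:
        return self.scores.idxmax(axis=1)

    def write_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t")


def score_matrix(m: ExpressionMatrix, ref: MarkerReference) -> CellTypeScoreMatrix:
    """Score every nucleus against every cell type of the reference.

    Detection of a reference gene means raw value >= 1 in that nucleus.
    The computation is vectorised per type: with N and K fixed, the score
    depends only on the (n, k) pair, which is cached.
    """
    genes = ref.genes.intersection(m.values.index)
    if len(genes) == 0:
        raise ValueError("no marker reference gene present in the matrix")
    ref = MarkerReference(ref.labels.loc[genes])
    detected = (m.values.loc[genes] >= DETECTION_MIN).to_numpy().astype(np.int64)

    out = np.zeros((m.n_nuclei, len(ref.cell_types)))
    for j, t in enumerate(ref.cell_types):
        pop_mask = (ref.labels[t] != "NA").to_numpy()
        pos_mask = ref.labels[t].isin(POSITIVE_LABELS).to_numpy()
        N, K = int(pop_mask.sum()), int(pos_mask.sum())
        if K == 0:
            raise ValueError(f"cell type {t!r} has no positive markers")
        ns = pop_mask @ detected
        ks = pos_mask @ detected
        cache: dict[tuple[int, int], float] = {}
        for i, (n, k) in enumerate(zip(ns, ks)):
            key = (int(n), int(k))
            if key not in cache:
                cache[key] = signed_log10_hypergeom(key[1], N, K, key[0])
            out[i, j] = cache[key]
    scores = pd.DataFrame(out, index=m.values.columns, columns=ref.cell_types)
    counts = pd.Series(detected.sum(axis=0), index=m.values.columns, name="detected_markers")
    return CellTypeScoreMatrix(scores, counts)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Partition of nuclei into clusters with per-cluster cell-type labels."""

    assignment: pd.Series  # nucleus -> cluster id (str)
    labels: dict = field(default_factory=dict)  # cluster id -> cell type / "mixed"
    embedding: pd.DataFrame | None = None  # 2-D, visualisation only

    def __post_init__(self) -> None:
        self.assignment = self.assignment.astype(str)

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(self.assignment.unique())

    @property
    def sizes(self) -> pd.Series:
        return self.assignment.value_counts()

    def members(self, cluster_id: str) -> list[str]:
        return list(self.assignment.index[self.assignment == str(cluster_id)])

    def subset(self, keep_clusters) -> "ClusterModel":
        keep_clusters = {str(c) for c in keep_clusters}
        mask = self.assignment.isin(keep_clusters)
        return ClusterModel(self.assignment[mask],
                            {c: l for c, l in self.labels.items() if c in keep_clusters},
                            None if self.embedding is None else self.embedding[mask.to_numpy()])

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"cluster": self.assignment})
        df["label"] = df["cluster"].map(self.labels)
        df.to_csv(path, sep="\t", index_label="nucleus_id")


def majority_labels(assignment: pd.Series, nucleus_type: pd.Series) -> dict:
    """Label each cluster by the > 50% majority of member labels, else "mixed"."""
    out = {}
    for cid in sorted(assignment.unique()):
        members = assignment.index[assignment == cid]
        counts = nucleus_type.loc[members].value_counts()
        if len(counts) and counts.iloc[0] > 0.5 * len(members):
            out[str(cid)] = str(counts.index[0])
        else:
            out[str(cid)] = "mixed"
    return out


def cluster_scores(s: CellTypeScoreMatrix, k_or_resolution: float = 1.0,
                   seed: int = 0, n_neighbors: int = 15) -> ClusterModel:
    """Cluster nuclei in cell-type score space.

    An integer argument requests k-means with that many clusters; a float
    requests graph-based community detection (shared-nearest-neighbour
    graph + Leiden) at that resolution. Both are deterministic for a fixed
    seed. Clusters are labelled by the majority best-scoring cell type of
    their nuclei.
    """
    X = s.scores.to_numpy()
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nuclei to cluster")
    if isinstance(k_or_resolution, (int, np.integer)) and not isinstance(k_or_resolution, bool):
        k = int(k_or_resolution)
        if k > n:
            raise ValueError(f"{k} clusters requested for {n} nuclei")
        from sklearn.cluster import KMeans
        ids = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
    else:
        ids = _leiden(X, resolution=float(k_or_resolution), seed=seed,
                      n_neighbors=min(n_neighbors, n - 1))
    assignment = pd.Series([f"c{i}" for i in ids], index=s.scores.index, name="cluster")
    labels = majority_labels(assignment, s.argmax_type)
    return ClusterModel(assignment, labels)


def _leiden(X: np.ndarray, resolution: float, seed: int, n_neighbors: int) -> np.ndarray:
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = igraph.Graph(n=X.shape[0], edges=sorted(edges))
    part = leidenalg.find_partition(g, leidenalg.RBConfigurationVertexPartition,
                                    resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership)


def embed_scores(s: CellTypeScoreMatrix, method: str = "pca",
                 seed: int = 0) -> pd.DataFrame:
    """2-D embedding of the score matrix, for visualisation only."""
    X = s.scores.to_numpy()
    if method == "umap":
        import umap
        emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(X)
    elif method == "pca":
        from sklearn.decomposition import PCA
        emb = PCA(n_components=2, random_state=seed).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(emb, index=s.scores.index, columns=["dim1", "dim2"])


# ---------------------------------------------------------------------------
# contaminant and low-quality cluster removal
# ---------------------------------------------------------------------------

def flag_contaminants(m: ExpressionMatrix, embryo_ref: MarkerReference,
                      contam_ref: MarkerReference,
                      clusters: ClusterModel) -> tuple[ClusterModel, pd.DataFrame]:
    """Drop clusters whose nuclei resemble the contaminant panel.

    Every nucleus gets an embryo-panel score (its best score over embryo
    cell types) and a contaminant-panel score (best over contaminant
    types). A cluster is dropped when the median contaminant score of its
    nuclei exceeds their median embryo score. Returns the retained model
    and a per-cluster report of both medians and the decision.
    """
    emb = score_matrix(m, embryo_ref).scores.max(axis=1)
    con = score_matrix(m, contam_ref).scores.max(axis=1)
    rows = []
    for cid in clusters.cluster_ids:
        members = clusters.members(cid)
        med_e = float(emb.loc[members].median())
        med_c = float(con.loc[members].median())
        rows.append({"cluster": cid, "n_nuclei": len(members),
                     "median_embryo_score": med_e,
                     "median_contaminant_score": med_c,
                     "drop": med_c > med_e})
    report = pd.DataFrame(rows).set_index("cluster")
    kept = clusters.subset(report.index[~report["drop"]])
    return kept, report


def drop_low_quality_clusters(m: ExpressionMatrix, clusters: ClusterModel,
                              factor: float = 0.5) -> tuple[ClusterModel, pd.DataFrame]:
    """Drop clusters whose median detected-gene count falls below
    ``factor`` x the global median (libraries from fragmented or
    aggregated nuclei show up as whole clusters of shallow libraries)."""
    dg = m.nucleus_meta["detected_genes"]
    global_med = float(dg.median())
    rows = []
    for cid in clusters.cluster_ids:
        med = float(dg.loc[clusters.members(cid)].median())
        rows.append({"cluster": cid, "median_detected_genes": med,
                     "drop": med < factor * global_med})
    report = pd.DataFrame(rows).set_index("cluster")
    kept = clusters.subset(report.index[~report["drop"]])
    return kept, report
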