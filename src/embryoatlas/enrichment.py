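"""Ranked gene enrichment per cluster.

For the expressed-gene population G, each cluster C is compared against the
unweighted mean of all other clusters (the outgroup O) on two axes: the
log2 fold change of mean CPM, F_iC = log2((M_iC + c) / (mean_O M_i + c))
with pseudocount c, and the difference in detection proportion,
D_iC = p_iC - mean_O p_i. Within each cluster both vectors are z-scaled
across genes (centred, divided by the population standard deviation) and
summed into the enrichment magnitude E_iC = z(F)_iC + z(D)_iC. Genes are
ranked by E within each cluster; the first and last k (default 250) form
the top- and bottom-ranked gene lists used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import DETECTION_MIN, ExpressionMatrix


def cluster_profiles(cpm: ExpressionMatrix, clusters,
                     detection_source: ExpressionMatrix | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster mean CPM (M_iC) and detection proportion (p_iC).

    Detection is evaluated on ``detection_source`` (the raw count matrix)
    when given, else on ``cpm`` itself; a gene is detected at value >= 1.
    Returns two gene x cluster frames.
    """
    assignment = pd.Series(getattr(clusters, "assignment", clusters))
    missing = cpm.values.columns.difference(assignment.index)
    if len(missing):
        raise ValueError(f"nuclei without cluster assignment: {list(missing)[:5]}")
    det_vals = (detection_source or cpm).values
    if not det_vals.columns.equals(cpm.values.columns):
        det_vals = det_vals.loc[:, cpm.values.columns]
    M, p = {}, {}
    for cid, members in assignment.groupby(assignment).groups.items():
        members = [x for x in members if x in cpm.values.columns]
        if len(members) == 0:
            raise ValueError(f"cluster {cid!r} is empty")
        M[str(cid)] = cpm.values[members].mean(axis=1)
        p[str(cid)] = (det_vals[members] >= DETECTION_MIN).mean(axis=1)
    return pd.DataFrame(M), pd.DataFrame(p)


@dataclass
class EnrichmentTable:
    """Per-gene, per-cluster enrichment components and magnitudes."""

    M: pd.DataFrame   # mean CPM
    p: pd.DataFrame   # detection proportion
    F: pd.DataFrame   # log2 fold change vs outgroup mean
    D: pd.DataFrame   # detection-proportion difference vs outgroup mean
    zF: pd.DataFrame
    zD: pd.DataFrame
    E: pd.DataFrame   # zF + zD
    pseudocount: float

    @property
    def genes(self) -> pd.Index:
        return self.E.index

    @property
    def clusters(self) -> list[str]:
        return list(self.E.columns)

    def ranks(self) -> pd.DataFrame:
        """Per-cluster rank (1 = most enriched), ties broken by gene id."""
        out = {}
        for c in self.clusters:
            order = self._ordered_genes(c)
            out[c] = pd.Series(np.arange(1, len(order) + 1), index=order)
        return pd.DataFrame(out).loc[self.genes]

    def _ordered_genes(self, cluster: str) -> pd.Index:
        df = pd.DataFrame({"E": self.E[cluster]})
        df = df.sort_index().sort_values("E", ascending=False, kind="mergesort")
        return df.index

    def to_long(self) -> pd.DataFrame:
        frames = []
        for name, df in [("M", self.M), ("p", self.p), ("F", self.F),
                         ("D", self.D), ("zF", self.zF), ("zD", self.zD),
                         ("E", self.E)]:
            frames.append(df.stack().rename(name))
        long = pd.concat(frames, axis=1).reset_index()
        long.columns = ["gene_id", "cluster"] + [f.name for f in frames]
        return long

    def write_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def _zscale(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scaling with the population standard deviation.

    A zero-variance column is mapped to all-zero rather than NaN: with no
    spread there is no deviation to measure.
    """
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    z = (df - mu).div(sd.replace(0.0, np.inf), axis=1)
    return z


def enrichment_scores(M: pd.DataFrame, p: pd.DataFrame,
                      pseudocount: float = 1.0,
                      outgroup: str = "mean",
                      sizes: pd.Series | None = None) -> EnrichmentTable:
    """Enrichment magnitude E_iC for every gene and cluster.

    ``outgroup="mean"`` (default) aggregates the other clusters by the
    unweighted mean of their per-cluster profiles. ``outgroup="pooled"``
    weights each outgroup cluster by its nucleus count (``sizes``), i.e.
    profiles as if the outgroup nuclei were pooled; offered for
    sensitivity analysis.
    """
    if M.shape[1] < 2:
        raise ValueError("need at least 2 clusters to form an outgroup")
    if M.shape[0] < 2:
        raise ValueError("need at least 2 genes to z-scale")
    if outgroup == "mean":
        w = pd.Series(1.0, index=M.columns)
    elif outgroup == "pooled":
        if sizes is None:
            raise ValueError("outgroup='pooled' requires cluster sizes")
        w = sizes.reindex(M.columns).astype(float)
        if w.isna().any():
            raise ValueError("sizes missing for some clusters")
    else:
        raise ValueError(f"unknown outgroup mode {outgroup!r}")
    wv = w.to_numpy()
    # weighted mean over the other clusters = (total - own) / (weight sum - own weight)
    M_out = ((M.to_numpy() * wv).sum(axis=1)[:, None] - M.to_numpy() * wv) / (wv.sum() - wv)
    p_out = ((p.to_numpy() * wv).sum(axis=1)[:, None] - p.to_numpy() * wv) / (wv.sum() - wv)
    F = pd.DataFrame(np.log2((M.to_numpy() + pseudocount) / (M_out + pseudocount)),
                     index=M.index, columns=M.columns)
    D = pd.DataFrame(p.to_numpy() - p_out, index=p.index, columns=p.columns)
    zF, zD = _zscale(F), _zscale(D)
    return EnrichmentTable(M=M, p=p, F=F, D=D, zF=zF, zD=zD, E=zF + zD,
                           pseudocount=pseudocount)


def rank_genes(table: EnrichmentTable, k: int = 250) -> dict[str, dict[str, list[str]]]:
    """Top-k and bottom-k ranked genes per cluster.

    Ordering is E descending with gene id ascending as the tie-break, so
    the lists are deterministic. Top = first k, bottom = last k of the
    ranking. Lists overlap (with a warning) when 2k exceeds |G|.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(table.genes)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} ranked genes")
    if 2 * k > n:
        warnings.warn(f"top and bottom lists overlap: 2k={2 * k} > |G|={n}")
    out = {}
    for c in table.clusters:
        order = table._ordered_genes(c)
        out[c] = {"top": list(order[:k]), "bottom": list(order[-k:])}
    return out


def reference_coverage(ref_genes, top_lists: dict) -> tuple[int, int, float]:
    """How many reference genes appear in at least one cluster's top list.

    Returns (covered count, evaluable count, percentage rounded to one
    decimal place).
    """
    ref = set(ref_genes)
    if not ref:
        raise ValueError("empty reference gene set")
    union_top = set()
    for lists in top_lists.values():
        union_top |= set(lists["top"] if isinstance(lists, dict) else lists)
    covered = len(ref & union_top)
    pct = round(100.0 * covered / len(ref), 1)
    return covered, len(ref), pct
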