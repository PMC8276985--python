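"""Downstream statistics on the per-cluster ranked gene lists.

Covers four screens: over/under-representation of a curated gene set (e.g.
embryo-defective genes) among a cluster's top-ranked genes; distribution
tests on per-gene conservation scores; threshold screens that pick out set
members with high enrichment magnitude in at least one cluster; and
Spearman correlation of cluster mean-expression profiles against published
bulk reference transcriptomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from .enrichment import EnrichmentTable
from .stats import bh_adjust, hypergeom_two_tailed


@dataclass
class GeneSet:
    name: str
    members: frozenset

    def __init__(self, name: str, members) -> None:
        self.name = name
        self.members = frozenset(members)
        if not self.members:
            raise ValueError(f"gene set {name!r} is empty")

    @classmethod
    def read(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        """One gene id per line."""
        path = Path(path)
        ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
        return cls(name or path.stem, ids)


@dataclass
class SetTestResult:
    """Two-tailed hypergeometric test of a gene set within a top list."""

    cluster: str
    k: int                 # set members observed in the top list
    k_expected: float      # |top| * |set & G| / |G|
    fold: float
    p: float
    direction: str         # "enriched" | "depleted"
    significant: bool
    q: float | None = None


def set_enrichment(top_list, gene_set: GeneSet, population,
                   alpha: float = 0.05, cluster: str = "") -> SetTestResult:
    """Is ``gene_set`` over- or under-represented in a cluster's top list?

    Population: the expressed genes G; successes: set members within G;
    draw: the top list. Two-tailed P by the same minimum-likelihood
    hypergeometric engine used for cell-type scoring.
    """
    G = set(population)
    top = set(top_list) & G
    members = gene_set.members & G
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} does not intersect the population")
    N, K, n = len(G), len(members), len(top)
    k = len(top & members)
    kE = n * K / N
    p = hypergeom_two_tailed(k, N, K, n)
    direction = "depleted" if k < kE else "enriched"
    return SetTestResult(cluster=cluster, k=k, k_expected=kE,
                         fold=(k / kE if kE > 0 else np.inf), p=p,
                         direction=direction, significant=bool(p <= alpha))


def set_enrichment_all(top_lists: dict, gene_set: GeneSet, population,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-cluster set tests with BH q-values reported alongside raw P.

    Significance is flagged on raw P at ``alpha`` (the q column is
    informational).
    """
    results = []
    for c, lists in top_lists.items():
        top = lists["top"] if isinstance(lists, dict) else lists
        results.append(set_enrichment(top, gene_set, population, alpha, cluster=c))
    df = pd.DataFrame([vars(r) for r in results]).set_index("cluster")
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


@dataclass
class ConservationTestResult:
    z: float            # (mean(top) - mean(G)) / (sd(G) / sqrt(|top|))
    ks_D: float
    p: float            # two-sided KS P
    n_top: int
    n_population: int


def conservation_test(top_list, scores: pd.Series, population) -> ConservationTestResult:
    """Do top-ranked genes deviate in conservation score from expressed genes?

    The z-score places the top-list mean against the mean of ALL expressed
    genes (population sd over sqrt(|top|)), matching the "deviation from
    the mean" rendering. The two-sided two-sample Kolmogorov-Smirnov test
    compares the top-list scores against the remaining expressed genes
    (population minus the top list): making the two samples disjoint keeps
    the null P-value calibrated, which a subset-vs-superset comparison is
    not. Genes lacking a score are dropped with a warning.
    """
    scores = scores.dropna()
    pop = [g for g in population if g in scores.index]
    top_set = set(top_list)
    top = [g for g in top_list if g in scores.index]
    rest = [g for g in pop if g not in top_set]
    n_miss_pop = len(set(population)) - len(pop)
    n_miss_top = len(top_set) - len(top)
    if n_miss_pop or n_miss_top:
        warnings.warn(f"dropping unscored genes: {n_miss_top} of the top list, "
                      f"{n_miss_pop} of the population")
    if len(top) < 5 or len(rest) < 5:
        raise ValueError("fewer than 5 scored genes in the top list or the "
                         "rest of the population")
    if len(pop) < 0.9 * len(set(population)) or len(top) < 0.9 * len(top_set):
        warnings.warn("conservation scores cover < 90% of a gene list; "
                      "interpret with caution")
    s_top = scores.loc[top].to_numpy()
    s_pop = scores.loc[pop].to_numpy()
    s_rest = scores.loc[rest].to_numpy()
    sd = s_pop.std(ddof=0)
    z = float((s_top.mean() - s_pop.mean()) / (sd / np.sqrt(len(s_top)))) if sd > 0 else 0.0
    ks = _st.ks_2samp(s_top, s_rest, alternative="two-sided")
    return ConservationTestResult(z=z, ks_D=float(ks.statistic), p=float(ks.pvalue),
                                  n_top=len(s_top), n_population=len(s_pop))


def threshold_screen(table: EnrichmentTable, gene_set: GeneSet, min_E: float,
                     min_detect_frac: float = 0.10,
                     min_clusters: int = 1) -> pd.DataFrame:
    """Set members with E >= min_E and detection >= min_detect_frac in
    enough clusters.

    A gene qualifies in a cluster when BOTH its enrichment magnitude and
    its detection proportion clear their thresholds there (">=" semantics:
    a gene sitting exactly on a threshold is kept). Returns one row per
    retained gene with the qualifying clusters.
    """
    genes = [g for g in sorted(gene_set.members) if g in table.genes]
    if not genes:
        warnings.warn(f"gene set {gene_set.name!r} is disjoint from the table")
        return pd.DataFrame(columns=["gene_id", "n_clusters", "clusters", "max_E"]
                            ).set_index("gene_id")
    E = table.E.loc[genes]
    p = table.p.loc[genes]
    ok = (E >= min_E) & (p >= min_detect_frac)
    rows = []
    for g in genes:
        quals = list(ok.columns[ok.loc[g]])
        if len(quals) >= min_clusters:
            rows.append({"gene_id": g, "n_clusters": len(quals),
                         "clusters": ",".join(quals),
                         "max_E": float(E.loc[g].max())})
    return pd.DataFrame(rows, columns=["gene_id", "n_clusters", "clusters", "max_E"]
                        ).set_index("gene_id")


def reference_correlation(profiles: pd.DataFrame,
                          reference: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of cluster mean expression vs bulk references.

    ``profiles``: gene x cluster mean expression; ``reference``: gene x
    reference-sample expression. Correlations are computed on the gene
    intersection with mid-ranked ties; requires >= 10 shared genes.
    """
    shared = profiles.index.intersection(reference.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need >= 10")
    out = pd.DataFrame(index=profiles.columns, columns=reference.columns, dtype=float)
    for c in profiles.columns:
        for r in reference.columns:
            rho = _st.spearmanr(profiles.loc[shared, c], reference.loc[shared, r])[0]
            out.loc[c, r] = float(rho)
    return out
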