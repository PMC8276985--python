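"""Expression-table ingestion, quality control and CPM normalisation.

The pipeline's in-memory container is :class:`ExpressionMatrix`: a gene x
nucleus table of non-negative values (raw counts preferred, TPM-like values
accepted) together with per-nucleus metadata (plate, aligned reads, detected
genes) and per-gene annotation (nuclear-encoded flag, Pol II flag, optional
conservation score). Library-level QC keeps nuclei with enough aligned reads
and detected genes; gene-level QC keeps genes seen in enough nuclei.
"Detected" means value >= 1 throughout.

Filters are idempotent and are applied nuclei-first, then genes; every
filter appends one line to the matrix's provenance log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: a gene is "detected" in a nucleus when its value is at least this
DETECTION_MIN = 1.0


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class FormatError(ValueError):
    """Raised when an input table violates the container invariants."""


@dataclass
class ExpressionMatrix:
    """Gene x nucleus expression values with nucleus and gene metadata.

    ``values`` is indexed by gene id (rows) and nucleus id (columns). The
    metadata frames are keyed by the same ids. ``log`` records the filters
    applied so far, in order.
    """

    values: pd.DataFrame
    nucleus_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].tolist()
            raise FormatError(f"duplicate nucleus ids: {dups[:5]}")
        arr = v.to_numpy()
        if (arr < 0).any():
            g, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative value at gene {v.index[g]!r}, nucleus {v.columns[c]!r}")
        if not self.nucleus_meta.index.equals(v.columns):
            missing = v.columns.difference(self.nucleus_meta.index).tolist()
            raise FormatError(f"nucleus_meta does not match matrix columns; "
                              f"missing {missing[:5]}")
        if not self.gene_meta.index.equals(v.index):
            missing = v.index.difference(self.gene_meta.index).tolist()
            raise FormatError(f"gene_meta does not match matrix rows; "
                              f"missing {missing[:5]}")

    # -- derived metadata --------------------------------------------------
    def recompute_detected_genes(self) -> pd.Series:
        """Per-nucleus count of genes with value >= DETECTION_MIN."""
        return (self.values >= DETECTION_MIN).sum(axis=0).astype(int)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_nuclei(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.nucleus_meta.copy(),
                                self.gene_meta.copy(), list(self.log))

    def to_anndata(self):
        """Nucleus x gene AnnData view (the single-cell ecosystem convention)."""
        import anndata as ad
        return ad.AnnData(X=self.values.to_numpy().T.astype(float),
                          obs=self.nucleus_meta.copy(),
                          var=self.gene_meta.copy())


@dataclass
class QCReport:
    """Summary of a nucleus-level QC pass."""

    n_input: int
    n_retained: int
    removed_low_reads: int
    removed_low_genes: int

    @property
    def retention_pct(self) -> float:
        return 100.0 * self.n_retained / self.n_input if self.n_input else 0.0

    @property
    def retention_pct_rounded(self) -> float:
        """Retention as an integer percentage, rounded half-up."""
        return _round_half_up(self.retention_pct)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "retention_pct": self.retention_pct,
            "retention_pct_rounded": self.retention_pct_rounded,
            "removed_low_reads": self.removed_low_reads,
            "removed_low_genes": self.removed_low_genes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DEFAULT_GENE_META = {"nuclear_encoded": True, "polII": True,
                      "conservation_score": np.nan}


def _complete_meta(values: pd.DataFrame,
                   nucleus_meta: pd.DataFrame | None,
                   gene_meta: pd.DataFrame | None) -> tuple[pd.DataFrame, pd.DataFrame]:
    if nucleus_meta is None:
        nucleus_meta = pd.DataFrame(index=values.columns)
    else:
        nucleus_meta = nucleus_meta.reindex(values.columns)
    if "plate" not in nucleus_meta:
        nucleus_meta["plate"] = "plate1"
    if "detected_genes" not in nucleus_meta or nucleus_meta["detected_genes"].isna().any():
        nucleus_meta["detected_genes"] = (values >= DETECTION_MIN).sum(axis=0).astype(int)
    if "aligned_reads" not in nucleus_meta or nucleus_meta["aligned_reads"].isna().any():
        # recomputable fallback: total signal per nucleus
        nucleus_meta["aligned_reads"] = values.sum(axis=0).round().astype(int)
    nucleus_meta["aligned_reads"] = nucleus_meta["aligned_reads"].astype(int)
    nucleus_meta["detected_genes"] = nucleus_meta["detected_genes"].astype(int)

    if gene_meta is None:
        gene_meta = pd.DataFrame(index=values.index)
    else:
        gene_meta = gene_meta.reindex(values.index)
    for col, default in _DEFAULT_GENE_META.items():
        if col not in gene_meta:
            gene_meta[col] = default
    return nucleus_meta, gene_meta


def read_expression(path: str | Path, fmt: str = "tsv",
                    nucleus_meta: str | Path | pd.DataFrame | None = None,
                    gene_meta: str | Path | pd.DataFrame | None = None,
                    ) -> ExpressionMatrix:
    """Read an expression table from TSV (genes as rows) or MatrixMarket.

    For ``fmt="mtx"`` the two sidecar id files ``<stem>.genes.tsv`` and
    ``<stem>.nuclei.tsv`` (one id per line) must sit next to the matrix.
    Metadata may be passed as TSV paths or frames; missing recomputable
    fields (detected genes, aligned reads) are derived from the matrix.
    """
    path = Path(path)
    if fmt == "tsv":
        values = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "mtx":
        from scipy.io import mmread
        mat = mmread(path)
        genes = pd.read_csv(path.with_suffix("").with_suffix(".genes.tsv"),
                            sep="\t", header=None)[0].astype(str)
        nuclei = pd.read_csv(path.with_suffix("").with_suffix(".nuclei.tsv"),
                             sep="\t", header=None)[0].astype(str)
        dense = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
        if dense.shape != (len(genes), len(nuclei)):
            raise FormatError(f"matrix shape {dense.shape} does not match "
                              f"{len(genes)} genes x {len(nuclei)} nuclei")
        values = pd.DataFrame(dense, index=genes, columns=nuclei)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)

    if isinstance(nucleus_meta, (str, Path)):
        nucleus_meta = pd.read_csv(nucleus_meta, sep="\t", index_col=0)
        nucleus_meta.index = nucleus_meta.index.astype(str)
    if isinstance(gene_meta, (str, Path)):
        gene_meta = pd.read_csv(gene_meta, sep="\t", index_col=0)
        gene_meta.index = gene_meta.index.astype(str)
    nmeta, gmeta = _complete_meta(values, nucleus_meta, gene_meta)
    m = ExpressionMatrix(values, nmeta, gmeta)
    m.log.append(f"read_expression(path={path.name}, fmt={fmt})")
    return m


def write_expression(m: ExpressionMatrix, out_dir: str | Path,
                     fmt: str = "mtx", prefix: str = "counts") -> None:
    """Write the matrix plus metadata TSVs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        m.values.to_csv(out / f"{prefix}.tsv", sep="\t")
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix
        mmwrite(str(out / f"{prefix}.mtx"), csr_matrix(m.values.to_numpy()))
        (out / f"{prefix}.genes.tsv").write_text("\n".join(m.values.index) + "\n")
        (out / f"{prefix}.nuclei.tsv").write_text("\n".join(m.values.columns) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    m.nucleus_meta.to_csv(out / f"{prefix}.nucleus_meta.tsv", sep="\t")
    m.gene_meta.to_csv(out / f"{prefix}.gene_meta.tsv", sep="\t")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def qc_filter_nuclei(m: ExpressionMatrix, min_reads: int = 100_000,
                     min_genes: int = 1000) -> tuple[ExpressionMatrix, QCReport]:
    """Drop low-quality nuclei.

    A nucleus is retained when it has at least ``min_reads`` aligned reads
    AND at least ``min_genes`` detected genes; a nucleus failing either
    bound is excluded (strictly-below-threshold semantics, so a library
    with 99,999 reads fails a 100,000-read bound).
    """
    meta = m.nucleus_meta
    for col in ("aligned_reads", "detected_genes"):
        if col not in meta or meta[col].isna().any():
            bad = meta.index[meta[col].isna()].tolist() if col in meta else list(meta.index)
            raise FormatError(f"nuclei missing {col}: {bad[:5]}")
    ok_reads = meta["aligned_reads"] >= min_reads
    ok_genes = meta["detected_genes"] >= min_genes
    keep = ok_reads & ok_genes
    report = QCReport(
        n_input=int(len(keep)),
        n_retained=int(keep.sum()),
        removed_low_reads=int((~ok_reads).sum()),
        removed_low_genes=int((~ok_genes).sum()),
    )
    out = ExpressionMatrix(m.values.loc[:, keep], meta.loc[keep],
                           m.gene_meta.copy(), list(m.log))
    out.log.append(f"qc_filter_nuclei(min_reads={min_reads}, min_genes={min_genes}): "
                   f"{report.n_retained}/{report.n_input} retained")
    return out, report


def filter_genes_min_nuclei(m: ExpressionMatrix, min_nuclei: int,
                            min_value: float = DETECTION_MIN) -> ExpressionMatrix:
    """Keep genes with value >= ``min_value`` in at least ``min_nuclei`` nuclei."""
    if min_nuclei < 1:
        raise ValueError("min_nuclei must be >= 1")
    if min_nuclei > m.n_nuclei:
        import warnings
        warnings.warn(f"min_nuclei={min_nuclei} exceeds the {m.n_nuclei} nuclei "
                      "present; returning an empty gene set")
    n_hit = (m.values >= min_value).sum(axis=1)
    keep = n_hit >= min_nuclei
    out = ExpressionMatrix(m.values.loc[keep], m.nucleus_meta.copy(),
                           m.gene_meta.loc[keep], list(m.log))
    out.log.append(f"filter_genes_min_nuclei(min_nuclei={min_nuclei}, "
                   f"min_value={min_value}): {int(keep.sum())}/{len(keep)} genes kept")
    return out


def expressed_gene_set(m: ExpressionMatrix, clusters,
                       min_frac: float = 0.10) -> list[str]:
    """Expressed-gene population G for enrichment ranking.

    G = nuclear-encoded, Pol II-transcribed genes detected (raw value >= 1)
    in at least ceil(min_frac * |C|) nuclei of at least one cluster. The
    ceiling guarantees that "at least 10% of nuclei" can never be satisfied
    by strictly fewer nuclei.

    ``clusters`` may be a ClusterModel, a mapping, or a pandas Series of
    nucleus -> cluster id covering every nucleus in the matrix.
    """
    assignment = getattr(clusters, "assignment", clusters)
    assignment = pd.Series(assignment)
    missing = m.values.columns.difference(assignment.index)
    if len(missing):
        raise ValueError(f"nuclei without a cluster assignment: {list(missing)[:5]}")
    detected = m.values >= DETECTION_MIN
    flags = m.gene_meta["nuclear_encoded"].astype(bool) & m.gene_meta["polII"].astype(bool)
    hit = pd.Series(False, index=m.values.index)
    for cid, members in assignment.groupby(assignment).groups.items():
        members = [x for x in members if x in m.values.columns]
        if len(members) == 0:
            raise ValueError(f"cluster {cid!r} has no nuclei in the matrix")
        need = int(np.ceil(min_frac * len(members)))
        hit |= detected[members].sum(axis=1) >= need
    return sorted(m.values.index[hit & flags])


def compute_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million normalisation: CPM_ij = value_ij / colsum_j * 1e6."""
    colsums = m.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum nuclei cannot be normalised: {list(zero.index)[:5]}")
    cpm = m.values / colsums * 1e6
    out = ExpressionMatrix(cpm, m.nucleus_meta.copy(), m.gene_meta.copy(), list(m.log))
    out.log.append("compute_cpm")
    return out
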