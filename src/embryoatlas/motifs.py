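"""Promoter extraction, PWM scanning and motif-family regulatory analysis.

Promoters are the 600-nt window from 500 bp upstream to 100 bp downstream
of each gene's TSS (strand-aware, clipped at contig ends). Position weight
matrices in MEME minimal format are scanned over both strands by log-odds
score; a promoter "contains" a motif when some window reaches a fraction of
the motif's maximum attainable score. Per cluster, motif presence in the
top-ranked gene promoters is tested against the bottom-ranked promoters by
a one-sided Fisher exact test with BH correction across motifs; motifs
significant somewhere are collapsed to families (max rule), and candidate
regulators are nominated by Pearson-correlating each family's enrichment
profile across clusters with member TFs' expression-enrichment profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from .stats import bh_adjust, fisher_one_sided_greater

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGT"
_COMP_TRANSLATE = str.maketrans("ACGTN", "TGCAN")

#: probability floor inside log-odds so point-mass PWMs stay finite
_LOG_EPS = 1e-9


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP_TRANSLATE)[::-1]


# ---------------------------------------------------------------------------
# motif containers and MEME IO
# ---------------------------------------------------------------------------

@dataclass
class Motif:
    """A position weight matrix with TF annotation."""

    motif_id: str
    matrix: np.ndarray  # L x 4 probabilities (A, C, G, T)
    tf: str = ""
    family: str = ""
    subfamily: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id}: matrix must be L x 4")
        if self.length < 4:
            raise ValueError(f"motif {self.motif_id}: length {self.length} < 4")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"motif {self.motif_id}: PWM rows must sum to 1")
        if np.any(self.matrix.max(axis=1) <= 0):
            raise ValueError(f"motif {self.motif_id}: degenerate zero column")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass
class MotifSet:
    motifs: dict[str, Motif]
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-6 or (self.background <= 0).any():
            raise ValueError("background frequencies must be positive and sum to 1")

    def __len__(self) -> int:
        return len(self.motifs)

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for mid, m in self.motifs.items():
            fam = m.family
            if not fam:
                warnings.warn(f"motif {mid} lacks a family annotation; "
                              "treated as its own singleton family")
                fam = f"singleton_{mid}"
            out.setdefault(fam, []).append(mid)
        return out


def read_meme(path: str | Path,
              annotations: str | Path | pd.DataFrame | None = None) -> MotifSet:
    """Read MEME minimal-format motifs plus an optional annotation TSV
    (columns: motif_id, tf, family, subfamily)."""
    import Bio.motifs as _bm
    with open(path) as fh:
        record = _bm.parse(fh, "minimal")
    if isinstance(annotations, (str, Path)):
        annotations = pd.read_csv(annotations, sep="\t", dtype=str).set_index("motif_id")
    elif isinstance(annotations, pd.DataFrame) and annotations.index.name != "motif_id":
        annotations = annotations.set_index("motif_id")
    motifs = {}
    for m in record:
        mat = np.array([[m.pwm[b][i] for b in _BASES] for i in range(m.length)])
        ann = {}
        if annotations is not None and m.name in annotations.index:
            row = annotations.loc[m.name]
            ann = {"tf": row.get("tf", ""), "family": row.get("family", ""),
                   "subfamily": row.get("subfamily", "")}
        motifs[m.name] = Motif(m.name, mat, **ann)
    bg = record.background or {b: 0.25 for b in _BASES}
    return MotifSet(motifs, np.array([bg[b] for b in _BASES]))


def write_meme(motif_set: MotifSet, path: str | Path) -> None:
    """Write MEME minimal format (readable by the MEME suite and Biopython)."""
    bg = motif_set.background
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
             "Background letter frequencies",
             " ".join(f"{b} {f:.5f}" for b, f in zip(_BASES, bg)), ""]
    for mid, m in motif_set.motifs.items():
        lines.append(f"MOTIF {mid} {m.tf or mid}")
        lines.append(f"letter-probability matrix: alength= 4 w= {m.length} "
                     f"nsites= 20 E= 0")
        for row in m.matrix:
            lines.append(" ".join(f"{x:.6f}" for x in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_annotations(motif_set: MotifSet, path: str | Path) -> None:
    rows = [{"motif_id": mid, "tf": m.tf, "family": m.family,
             "subfamily": m.subfamily} for mid, m in motif_set.motifs.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def synthetic_motif_set(n_motifs: int, seed: int, lengths=(6, 8, 10),
                        sharpness: float = 0.85,
                        tfs_per_family: int = 2) -> MotifSet:
    """Random informative PWMs with TF/family annotations, for simulation.

    Each motif has one dominant base per position (probability
    ``sharpness``, remainder spread evenly). Motifs are grouped into
    families; every motif is attributed to a TF gene id ``TF_<motif>``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    motifs = {}
    for i in range(n_motifs):
        L = int(rng.choice(lengths))
        mat = np.full((L, 4), (1.0 - sharpness) / 3.0)
        dom = rng.integers(0, 4, size=L)
        mat[np.arange(L), dom] = sharpness
        mid = f"M{i:03d}"
        fam = f"FAM{i // tfs_per_family:02d}"
        motifs[mid] = Motif(mid, mat, tf=f"TF_{mid}", family=fam,
                            subfamily=f"{fam}_sub")
    return MotifSet(motifs)


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------

UPSTREAM = 500
DOWNSTREAM = 100


@dataclass
class PromoterSet:
    """Strand-aware promoter windows with their genome sequences.

    ``table`` has one row per extracted gene (contig, strand, tss, start,
    end, clipped); ``sequences`` maps gene id to the promoter sequence
    oriented so position 0 is the most upstream base. ``skipped`` lists
    genes that could not be located in the annotation.
    """

    table: pd.DataFrame
    sequences: dict[str, str]
    skipped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequences)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g, row in self.table.iterrows():
                fh.write(f"{row.contig}\t{row.start}\t{row.end}\t{g}\t0\t{row.strand}\n")

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g, seq in self.sequences.items():
                fh.write(f">{g}\n{seq}\n")


def promoter_interval(tss: int, strand: str, contig_len: int,
                      upstream: int = UPSTREAM, downstream: int = DOWNSTREAM,
                      ) -> tuple[int, int, bool]:
    """0-based half-open promoter window around a 0-based TSS.

    Plus strand: [tss - upstream, tss + downstream); minus strand the
    mirror image [tss - downstream + 1, tss + upstream + 1). Clipped to
    the contig; the flag reports whether clipping occurred.
    """
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
    elif strand == "-":
        lo, hi = tss - downstream + 1, tss + upstream + 1
    else:
        raise ValueError(f"invalid strand {strand!r}")
    clipped = lo < 0 or hi > contig_len
    return max(lo, 0), min(hi, contig_len), clipped


def extract_promoters(genes, gff3_path: str | Path, fasta_path: str | Path,
                      tss_table: pd.DataFrame | str | Path | None = None,
                      upstream: int = UPSTREAM, downstream: int = DOWNSTREAM,
                      ) -> PromoterSet:
    """Extract promoter windows for ``genes`` from a genome + GFF3.

    The TSS is taken from ``tss_table`` (columns gene_id, contig, position
    [0-based], strand) when the gene is listed there; otherwise the most
    upstream annotated 5' end of the gene's transcripts (the gene feature
    itself when no transcripts are annotated). Genes absent from the
    annotation are reported in ``skipped`` rather than failing the run.
    Minus-strand sequences are reverse-complemented so that position 0 is
    the most upstream promoter base for every gene.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    if isinstance(tss_table, (str, Path)):
        tss_table = pd.read_csv(tss_table, sep="\t", dtype={"gene_id": str})
    tss_lookup = {}
    if tss_table is not None:
        for _, r in tss_table.iterrows():
            tss_lookup[str(r["gene_id"])] = (str(r["contig"]), int(r["position"]),
                                             str(r["strand"]))

    rows, seqs, skipped = {}, {}, []
    for gene in genes:
        if gene in tss_lookup:
            contig, tss, strand = tss_lookup[gene]
        else:
            try:
                feat = db[gene]
            except gffutils.FeatureNotFoundError:
                skipped.append(gene)
                continue
            contig, strand = feat.seqid, feat.strand
            children = list(db.children(feat, featuretype=("mRNA", "transcript")))
            feats = children or [feat]
            if strand == "+":
                tss = min(f.start for f in feats) - 1  # GFF3 1-based -> 0-based
            else:
                tss = max(f.end for f in feats) - 1
        contig_len = len(fa[contig])
        lo, hi, clipped = promoter_interval(tss, strand, contig_len,
                                            upstream, downstream)
        seq = fa[contig][lo:hi]
        if strand == "-":
            seq = reverse_complement(seq)
        rows[gene] = {"contig": contig, "strand": strand, "tss": tss,
                      "start": lo, "end": hi, "clipped": clipped}
        seqs[gene] = seq
    if skipped:
        warnings.warn(f"{len(skipped)} genes absent from the annotation were skipped")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene_id"
    return PromoterSet(table, seqs, skipped)


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_ENCODE_LUT = np.full(128, 4, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to indices A=0 C=1 G=2 T=3, anything else = 4 (N)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[arr]


def _logodds(motif: Motif, background: np.ndarray) -> np.ndarray:
    """5 x L log2-odds lookup; the 5th row (N) contributes zero."""
    probs = np.clip(motif.matrix.T, _LOG_EPS, None)  # 4 x L
    lo = np.log2(probs / background[:, None])
    return np.vstack([lo, np.zeros((1, motif.length))])


def scan_motif(motif: Motif, sequence: str, background=None,
               threshold_frac: float = 0.8) -> pd.DataFrame:
    """Scan one sequence on both strands; return hit positions and scores.

    A window is a hit when its log-odds score reaches ``threshold_frac``
    times the motif's maximum attainable score. N bases contribute zero
    log-odds. Reverse-strand hits are reported at their forward-strand
    start position.
    """
    background = np.full(4, 0.25) if background is None else np.asarray(background)
    L = motif.length
    if len(sequence) < L:
        return pd.DataFrame(columns=["position", "strand", "score"])
    lut = _logodds(motif, background)
    max_score = lut[:4].max(axis=0).sum()
    thr = threshold_frac * max_score
    codes = _encode(sequence.upper())
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    pos_idx = np.arange(L)
    fwd = lut[win, pos_idx].sum(axis=1)
    # reverse-complement the PWM instead of the sequence: complement base
    # rows, reverse positions (N row maps to itself)
    lut_rc = lut[[3, 2, 1, 0, 4]][:, ::-1]
    rev = lut_rc[win, pos_idx].sum(axis=1)
    rows = []
    for strand, scores in (("+", fwd), ("-", rev)):
        for i in np.flatnonzero(scores >= thr):
            rows.append({"position": int(i), "strand": strand,
                         "score": float(scores[i])})
    return pd.DataFrame(rows, columns=["position", "strand", "score"])


def presence_matrix(motif_set: MotifSet, sequences: dict[str, str],
                    threshold_frac: float = 0.8) -> pd.DataFrame:
    """Gene x motif boolean presence matrix (>= 1 hit on either strand).

    Scanning is vectorised across all equal-length sequences at once.
    """
    ids = list(sequences)
    by_len: dict[int, list[str]] = {}
    for g in ids:
        by_len.setdefault(len(sequences[g]), []).append(g)
    out = pd.DataFrame(False, index=pd.Index(ids, name="gene_id"),
                       columns=list(motif_set.motifs))
    for length, group in by_len.items():
        codes = np.stack([_encode(sequences[g].upper()) for g in group])
        for mid, motif in motif_set.motifs.items():
            L = motif.length
            if length < L:
                continue
            lut = _logodds(motif, motif_set.background)
            thr = threshold_frac * lut[:4].max(axis=0).sum()
            win = np.lib.stride_tricks.sliding_window_view(codes, L, axis=1)
            pos_idx = np.arange(L)
            fwd = lut[win, pos_idx].sum(axis=2)
            lut_rc = lut[[3, 2, 1, 0, 4]][:, ::-1]
            rev = lut_rc[win, pos_idx].sum(axis=2)
            hit = (fwd >= thr).any(axis=1) | (rev >= thr).any(axis=1)
            out.loc[group, mid] = hit
    return out


# ---------------------------------------------------------------------------
# enrichment, family collapsing, TF correlation
# ---------------------------------------------------------------------------

def motif_enrichment(top_promoters: dict[str, str], bottom_promoters: dict[str, str],
                     motif_set: MotifSet, alpha: float = 0.05,
                     threshold_frac: float = 0.8, cluster: str = "") -> pd.DataFrame:
    """Motif overrepresentation in top- vs bottom-ranked promoters.

    One-sided Fisher exact test per motif on presence/absence counts,
    BH-corrected across motifs; significant = q <= alpha. The bottom-ranked
    promoters act as the background set.
    """
    if not top_promoters or not bottom_promoters:
        raise ValueError("both promoter sets must be nonempty")
    if set(top_promoters) == set(bottom_promoters):
        raise ValueError("top and bottom promoter sets are identical")
    pres_top = presence_matrix(motif_set, top_promoters, threshold_frac)
    pres_bot = presence_matrix(motif_set, bottom_promoters, threshold_frac)
    n_top, n_bot = len(pres_top), len(pres_bot)
    rows = []
    for mid in motif_set.motifs:
        a = int(pres_top[mid].sum())
        c = int(pres_bot[mid].sum())
        p = fisher_one_sided_greater(a, n_top - a, c, n_bot - c)
        rows.append({"motif_id": mid, "cluster": cluster,
                     "family": motif_set.motifs[mid].family,
                     "tf": motif_set.motifs[mid].tf,
                     "present_top": a, "present_bottom": c,
                     "frac_top": a / n_top, "frac_bottom": c / n_bot,
                     "p": p})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["neglog10_p"] = -np.log10(np.clip(df["p"], 1e-300, None))
    df["significant"] = df["q"] <= alpha
    return df


def collapse_families(results: pd.DataFrame, motif_set: MotifSet) -> pd.DataFrame:
    """Collapse motif-level enrichment to family level, per cluster.

    Only motifs significant in at least one cluster are carried into
    families. Family significance takes the max -log10 P over member
    motifs; family presence takes the max member presence fraction.
    """
    res = results.copy()
    fam_of = {}
    for mid, m in motif_set.motifs.items():
        fam_of[mid] = m.family or f"singleton_{mid}"
        if not m.family:
            warnings.warn(f"motif {mid} lacks a family; using a singleton family")
    res["family"] = res["motif_id"].map(fam_of)
    keep_motifs = set(res.loc[res["significant"], "motif_id"])
    res = res[res["motif_id"].isin(keep_motifs)]
    if res.empty:
        return pd.DataFrame(columns=["family", "cluster", "neglog10_p",
                                     "frac_top", "best_motif", "significant"])
    rows = []
    for (fam, cl), grp in res.groupby(["family", "cluster"]):
        best = grp.loc[grp["neglog10_p"].idxmax()]
        rows.append({"family": fam, "cluster": cl,
                     "neglog10_p": float(grp["neglog10_p"].max()),
                     "frac_top": float(grp["frac_top"].max()),
                     "best_motif": best["motif_id"],
                     "significant": bool(grp["significant"].any())})
    return pd.DataFrame(rows)


def correlate_tf_expression(family_enrichment: pd.DataFrame, tf_E: pd.DataFrame,
                            candidates: dict[str, list[str]],
                            r_threshold: float = 0.5) -> pd.DataFrame:
    """Correlate motif-family enrichment with candidate TF expression.

    ``family_enrichment``: family x cluster -log10 P matrix; ``tf_E``:
    gene x cluster enrichment magnitudes; ``candidates``: family ->
    candidate TF gene ids (database TFs plus same-subfamily TFs missing
    from the database). Pearson r across clusters classifies candidates as
    positive (r > threshold), negative (r < -threshold) or uncorrelated;
    the strongest |r| candidate per family is flagged ``best``.
    """
    clusters = list(family_enrichment.columns)
    if len(clusters) < 3:
        raise ValueError("need >= 3 clusters to correlate profiles")
    rows = []
    for fam, tf_ids in candidates.items():
        if fam not in family_enrichment.index:
            continue
        fvec = family_enrichment.loc[fam, clusters].to_numpy(dtype=float)
        for tf in tf_ids:
            if tf not in tf_E.index:
                continue
            evec = tf_E.loc[tf, clusters].to_numpy(dtype=float)
            if np.std(fvec) == 0 or np.std(evec) == 0:
                rows.append({"family": fam, "tf": tf, "r": np.nan,
                             "classification": "degenerate"})
                continue
            r = float(_st.pearsonr(fvec, evec)[0])
            cls = ("positive" if r > r_threshold
                   else "negative" if r < -r_threshold else "uncorrelated")
            rows.append({"family": fam, "tf": tf, "r": r, "classification": cls})
    df = pd.DataFrame(rows, columns=["family", "tf", "r", "classification"])
    df["best"] = False
    for fam, grp in df.groupby("family"):
        finite = grp.dropna(subset=["r"])
        if len(finite):
            df.loc[finite["r"].abs().idxmax(), "best"] = True
    return df
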