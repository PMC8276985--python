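"""Ground-truthed synthetic data for the whole pipeline.

The generator emulates the data regime the analysis is built for: a few
hundred single-nucleus libraries spread over ~9 embryonic cell types, a few
thousand detectable genes, sparse over-dispersed counts, and a minority of
libraries that are really contaminant (seed-coat-like) nuclei carried
through sorting. Counts follow a gamma-Poisson (negative binomial) model
with log-normally distributed gene baselines and independent Bernoulli
dropout; marker genes are type-specific — raised in their home type's
profile and suppressed elsewhere, matching the reference that records them
as not expressed in other types. All randomness flows from the single
integer seed in the config, so generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ingest import DETECTION_MIN, ExpressionMatrix
from .scoring import MarkerReference

CONTAMINANT_TYPE = "contaminant"
CONTAMINANT_PANEL = "seed_coat"

#: simulated sequencing reads per transcript count (metadata scaling only)
READS_PER_COUNT = 100


@dataclass
class SimulationConfig:
    """Parameters of the synthetic snRNA-seq experiment.

    Defaults mirror the target regime: nine embryonic cell types, ~50
    nuclei per type, an 8-fold marker up-regulation, 30% dropout and 20%
    contaminant libraries.
    """

    n_cell_types: int = 9
    nuclei_per_type: int = 50
    n_genes: int = 2000
    markers_per_type: int = 40
    marker_fold: float = 8.0
    library_size_mean: float = 2000.0
    nb_dispersion: float = 0.3
    dropout_rate: float = 0.3
    contamination_fraction: float = 0.2
    na_fraction: float = 0.1          # fraction of non-marker labels masked NA
    weak_fraction: float = 0.4        # fraction of planted markers labelled weak
    organelle_fraction: float = 0.03  # genes flagged organelle-encoded
    non_polii_fraction: float = 0.03  # genes flagged not Pol II-transcribed
    depth_multiplier: dict = field(default_factory=dict)  # per-type library depth
    plates_of: int = 96
    seed: int = 7

    def validate(self) -> None:
        blocks = self.n_cell_types + (1 if self.contamination_fraction > 0 else 0)
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError("markers_per_type x n_cell_types exceeds n_genes")
        if self.markers_per_type * blocks > self.n_genes:
            raise ValueError("not enough genes for a contaminant marker block")
        for name in ("dropout_rate", "contamination_fraction", "na_fraction",
                     "weak_fraction", "organelle_fraction", "non_polii_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("marker_fold", "library_size_mean", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


@dataclass
class GroundTruth:
    """Planted truth of a simulation run."""

    nucleus_type: pd.Series          # nucleus -> cell type or "contaminant"
    marker_roles: pd.DataFrame       # gene x type labels in {s, w, n} (no NA mask)

    def write_tsv(self, path: str | Path) -> None:
        self.nucleus_type.rename("true_type").to_csv(path, sep="\t",
                                                     index_label="nucleus_id")


def _type_names(config: SimulationConfig) -> list[str]:
    return [f"type{t + 1}" for t in range(config.n_cell_types)]


def _gene_ids(config: SimulationConfig) -> list[str]:
    return [f"g{i:05d}" for i in range(config.n_genes)]


def _marker_blocks(config: SimulationConfig) -> dict[str, list[int]]:
    """Disjoint gene-index blocks planted as markers, one per type, plus a
    contaminant block when contamination is enabled."""
    names = _type_names(config)
    if config.contamination_fraction > 0:
        names = names + [CONTAMINANT_PANEL]
    k = config.markers_per_type
    return {name: list(range(t * k, (t + 1) * k)) for t, name in enumerate(names)}


def _role_matrix(config: SimulationConfig, rng: np.random.Generator,
                 panel_names: list[str]) -> pd.DataFrame:
    """True marker roles in {s, w, n} for the given panels (no NA masking)."""
    genes = _gene_ids(config)
    blocks = _marker_blocks(config)
    roles = pd.DataFrame("n", index=pd.Index(genes, name="gene_id"),
                         columns=panel_names)
    for name in panel_names:
        idx = blocks[name]
        n_weak = int(round(config.weak_fraction * len(idx)))
        weak = rng.choice(idx, size=n_weak, replace=False) if n_weak else []
        for i in idx:
            roles.iloc[i, roles.columns.get_loc(name)] = "w" if i in set(weak) else "s"
    return roles


def generate_reference(config: SimulationConfig) -> tuple[MarkerReference, pd.DataFrame]:
    """Marker reference for the embryonic cell types.

    Each type gets ``markers_per_type`` positive labels (strong or weak);
    every other gene is a negative ("n") except a random ``na_fraction``
    masked to NA (non-informative). Returns the reference together with the
    unmasked true role matrix.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    roles = _role_matrix(config, rng, _type_names(config))
    labels = roles.copy()
    if config.na_fraction > 0:
        mask = (rng.random(labels.shape) < config.na_fraction) & (roles == "n").to_numpy()
        labels = labels.mask(mask, "NA")
    return MarkerReference(labels), roles


def generate_contaminant_reference(config: SimulationConfig) -> MarkerReference:
    """One-panel marker reference for the contaminant (seed-coat-like) tissue."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    roles = _role_matrix(config, rng, [CONTAMINANT_PANEL])
    return MarkerReference(roles)


def _fold_profile(config: SimulationConfig, roles: pd.DataFrame,
                  n_genes: int, blocks: dict[str, list[int]],
                  profile_of: str) -> np.ndarray:
    """Per-gene expression fold change for one cell type's profile.

    Marker genes are type-specific, matching the reference semantics
    (expressed in the home type, "not expressed" elsewhere): in its home
    profile a strong marker is raised ``marker_fold``-fold over baseline
    and a weak marker by half that fold-up (1 + (fold - 1)/2); in every
    other profile the gene is suppressed by the reciprocal of its home
    fold. With marker_fold = 1 both directions collapse to 1 and no signal
    is planted. Non-marker genes sit at baseline in every profile.
    """
    fold = np.ones(n_genes)
    s_fold = config.marker_fold
    w_fold = 1.0 + (config.marker_fold - 1.0) / 2.0
    for name, idx in blocks.items():
        if name not in roles.columns:
            continue
        col = roles[name]
        for i in idx:
            home = w_fold if col.iloc[i] == "w" else s_fold
            fold[i] = home if name == profile_of else 1.0 / home
    return fold


def simulate_counts(reference: MarkerReference, config: SimulationConfig,
                    ) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the gene x nucleus count matrix with planted truth.

    Gene baselines are log-normal; per nucleus, expected counts are the
    type profile renormalised to the nucleus library size (inflated by
    1/(1-dropout) so realised depth is centred on ``library_size_mean``),
    counts are gamma-Poisson with dispersion ``nb_dispersion`` and then
    thinned by independent Bernoulli dropout.
    """
    config.validate()
    # gene-level draws (baselines) and nucleus-level draws (assignments,
    # depths, counts) use separate substreams so the planted gene truth is
    # identical across cohort sizes for a fixed seed
    gene_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9]))
    genes = _gene_ids(config)
    types = _type_names(config)
    blocks = _marker_blocks(config)
    G = config.n_genes

    total = config.n_cell_types * config.nuclei_per_type
    n_contam = int(round(config.contamination_fraction * total))
    truth_types = []
    for i in range(total - n_contam):
        truth_types.append(types[i % config.n_cell_types])
    truth_types += [CONTAMINANT_TYPE] * n_contam
    truth_types = list(rng.permutation(truth_types))
    nuclei = [f"n{i:04d}" for i in range(total)]
    nucleus_type = pd.Series(truth_types, index=pd.Index(nuclei, name="nucleus_id"))

    # true marker roles for both the embryo panels and the contaminant panel
    panels = types + ([CONTAMINANT_PANEL] if n_contam or config.contamination_fraction > 0 else [])
    roles_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    roles = _role_matrix(config, roles_rng, types)
    if config.contamination_fraction > 0:
        con_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        roles[CONTAMINANT_PANEL] = _role_matrix(config, con_rng,
                                                [CONTAMINANT_PANEL])[CONTAMINANT_PANEL]

    baseline = gene_rng.lognormal(mean=0.0, sigma=1.0, size=G)
    # curated marker panels are built from reliably detectable genes, so
    # planted marker genes get low-variance baselines
    marker_baseline = gene_rng.lognormal(mean=0.0, sigma=0.4, size=G)
    all_marker_idx = sorted({i for idx in blocks.values() for i in idx})
    baseline[all_marker_idx] = marker_baseline[all_marker_idx]

    # per-type relative expression profiles (columns sum to 1)
    profiles = {}
    for name in panels:
        w = baseline * _fold_profile(config, roles, G, blocks, name)
        profiles[name] = w / w.sum()

    # library sizes: log-normal around the configured mean, optional per-type depth
    sigma = 0.3
    lib = rng.lognormal(np.log(config.library_size_mean) - sigma ** 2 / 2,
                        sigma, size=total)
    mult = np.array([config.depth_multiplier.get(t, 1.0) for t in truth_types])
    lib = lib * mult

    profile_of = [CONTAMINANT_PANEL if t == CONTAMINANT_TYPE else t for t in truth_types]
    P = np.column_stack([profiles[p] for p in profile_of])  # genes x nuclei
    keep = 1.0 - config.dropout_rate
    mu = P * lib / max(keep, 1e-12)
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, mu * config.nb_dispersion)
    counts = rng.poisson(lam)
    if config.dropout_rate > 0:
        counts = counts * (rng.random(counts.shape) >= config.dropout_rate)

    values = pd.DataFrame(counts.astype(int), index=pd.Index(genes, name="gene_id"),
                          columns=pd.Index(nuclei, name="nucleus_id"))

    colsum = values.sum(axis=0)
    nucleus_meta = pd.DataFrame({
        "plate": [f"p{i // config.plates_of + 1}" for i in range(total)],
        "aligned_reads": (colsum * READS_PER_COUNT).astype(int),
        "detected_genes": (values >= DETECTION_MIN).sum(axis=0).astype(int),
    }, index=values.columns)

    flag_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    marker_idx = {i for idx in blocks.values() for i in idx}
    non_marker = np.array([i not in marker_idx for i in range(G)])
    organelle = (flag_rng.random(G) < config.organelle_fraction) & non_marker
    non_polii = (flag_rng.random(G) < config.non_polii_fraction) & non_marker & ~organelle
    gene_meta = pd.DataFrame({
        "nuclear_encoded": ~organelle,
        "polII": ~non_polii,
        "conservation_score": np.clip(flag_rng.normal(0.5, 0.15, G), 0.0, 1.0),
    }, index=values.index)

    m = ExpressionMatrix(values, nucleus_meta, gene_meta)
    m.log.append(f"simulate_counts(seed={config.seed})")
    return m, GroundTruth(nucleus_type, roles)


# ---------------------------------------------------------------------------
# promoters with planted motifs
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")

PROMOTER_LEN = 600
_CONTIG_LEN = 1300


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class PromoterTruth:
    """Planted motif occurrences and the generated promoter sequences."""

    occurrences: pd.DataFrame  # columns: gene_id, cluster, motif_id, offset
    promoters: dict = field(default_factory=dict)  # gene_id -> 600-nt sequence

    def planted_genes(self, cluster: str) -> set[str]:
        df = self.occurrences
        return set(df.loc[df["cluster"] == cluster, "gene_id"])


def simulate_promoters(top_gene_sets: dict, motif_set, plant_map: dict,
                       seed: int, plant_fraction: float = 0.6,
                       ) -> tuple[dict, str, PromoterTruth]:
    """Build a toy genome whose promoters carry planted motif occurrences.

    Each gene sits on its own contig; the 600-nt promoter (500 bp upstream
    through 100 bp downstream of the TSS) is uniform-random sequence except
    that, for clusters named in ``plant_map``, a ``plant_fraction`` of the
    cluster's genes receive one exact consensus occurrence of the mapped
    motif at a random offset. Strands alternate between genes to exercise
    the reverse-complement path.

    Returns (contig -> sequence dict, GFF3 text, PromoterTruth).
    """
    if not 0.0 <= plant_fraction <= 1.0:
        raise ValueError(f"plant_fraction={plant_fraction} outside [0, 1]")
    for cluster, motif_id in plant_map.items():
        if motif_id not in motif_set.motifs:
            raise ValueError(f"planted motif {motif_id!r} not in motif set")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))

    genome: dict[str, str] = {}
    promoters: dict[str, str] = {}
    gff_lines = ["##gff-version 3"]
    occ_rows = []
    seen: set[str] = set()
    ordered = []
    for cluster, genes in top_gene_sets.items():
        for g in genes:
            if g not in seen:
                seen.add(g)
                ordered.append((g, cluster))

    for gi, (gene, cluster) in enumerate(ordered):
        promoter = "".join(rng.choice(_BASES, size=PROMOTER_LEN))
        motif_id = plant_map.get(cluster)
        if motif_id is not None and rng.random() < plant_fraction:
            cons = motif_set.motifs[motif_id].consensus
            off = int(rng.integers(0, PROMOTER_LEN - len(cons) + 1))
            promoter = promoter[:off] + cons + promoter[off + len(cons):]
            occ_rows.append({"gene_id": gene, "cluster": cluster,
                             "motif_id": motif_id, "offset": off})
        promoters[gene] = promoter
        filler = "".join(rng.choice(_BASES, size=_CONTIG_LEN - PROMOTER_LEN))
        contig = f"ctg_{gene}"
        strand = "+" if gi % 2 == 0 else "-"
        if strand == "+":
            # TSS at 0-based 500; promoter occupies [0, 600)
            genome[contig] = promoter + filler
            start, end = 501, 1100  # 1-based inclusive gene body
        else:
            # TSS at 0-based 799; promoter [700, 1300) holds the reverse
            # complement so that reading 5'->3' on the minus strand gives
            # the generated promoter
            genome[contig] = filler + _revcomp(promoter)
            start, end = 300, 800
        gff_lines.append("\t".join([contig, "sim", "gene", str(start), str(end),
                                    ".", strand, ".", f"ID={gene}"]))
        gff_lines.append("\t".join([contig, "sim", "mRNA", str(start), str(end),
                                    ".", strand, ".", f"ID={gene}.1;Parent={gene}"]))

    occurrences = pd.DataFrame(occ_rows, columns=["gene_id", "cluster",
                                                  "motif_id", "offset"])
    truth = PromoterTruth(occurrences, promoters)
    return genome, "\n".join(gff_lines) + "\n", truth


def write_fasta(genome: dict, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
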