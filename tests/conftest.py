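import numpy as np
import pandas as pd
import pytest

from embryoatlas.ingest import ExpressionMatrix
from embryoatlas.pipeline import simulate_and_run
from embryoatlas.simulate import SimulationConfig, generate_reference, simulate_counts


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """The study-condition simulation: 9 types, 50 nuclei/type, fold 8,
    30% dropout, 20% contamination, seed 7."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast 5-type dataset for unit-level checks."""
    return SimulationConfig(n_cell_types=5, nuclei_per_type=20, n_genes=600,
                            markers_per_type=25, contamination_fraction=0.0,
                            seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ref, roles = generate_reference(small_config)
    m, truth = simulate_counts(ref, small_config)
    return m, truth, ref, roles


@pytest.fixture(scope="session")
def pipeline_clean():
    """Full pipeline on the contamination-free study-condition dataset."""
    cfg = SimulationConfig(contamination_fraction=0.0)
    return simulate_and_run(cfg)


@pytest.fixture(scope="session")
def pipeline_contaminated():
    """Full pipeline on the 20%-contaminated study-condition dataset."""
    cfg = SimulationConfig()
    return simulate_and_run(cfg)


def toy_matrix(values: np.ndarray, genes=None, nuclei=None,
               gene_meta: pd.DataFrame | None = None,
               nucleus_meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Small helper to build an ExpressionMatrix from a dense array."""
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    nuclei = nuclei or [f"n{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                      columns=pd.Index(nuclei, name="nucleus_id"))
    if nucleus_meta is None:
        nucleus_meta = pd.DataFrame({
            "plate": "p1",
            "aligned_reads": df.sum(axis=0).astype(int),
            "detected_genes": (df >= 1).sum(axis=0).astype(int),
        }, index=df.columns)
    if gene_meta is None:
        gene_meta = pd.DataFrame({"nuclear_encoded": True, "polII": True,
                                  "conservation_score": np.nan}, index=df.index)
    return ExpressionMatrix(df, nucleus_meta, gene_meta)
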