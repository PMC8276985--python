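"""Marker-panel scoring, clustering, labelling and contaminant flagging."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from embryoatlas.scoring import (CellTypeScoreMatrix, ClusterModel,
                                 MarkerReference, celltype_score,
                                 cluster_scores, drop_low_quality_clusters,
                                 embed_scores, flag_contaminants,
                                 intersect_reference, majority_labels,
                                 score_matrix)
from conftest import toy_matrix


def ref_from_dict(d: dict) -> MarkerReference:
    return MarkerReference(pd.DataFrame(d))


# ---------------------------------------------------------------------------
# reference handling
# ---------------------------------------------------------------------------

def test_marker_reference_sets_and_invariants():
    ref = ref_from_dict({"t1": pd.Series({"a": "s", "b": "w", "c": "n", "d": "NA"})})
    assert ref.positive_set("t1") == ["a", "b"]
    assert ref.negative_set("t1") == ["c"]
    assert ref.population("t1") == ["a", "b", "c"]
    assert not set(ref.positive_set("t1")) & set(ref.negative_set("t1"))


def test_invalid_label_rejected():
    with pytest.raises(ValueError, match="invalid marker labels"):
        ref_from_dict({"t1": pd.Series({"a": "strong"})})


def test_reference_tsv_roundtrip(tmp_path):
    ref = ref_from_dict({"t1": pd.Series({"a": "s", "b": "n", "c": "NA"}),
                         "t2": pd.Series({"a": "n", "b": "w", "c": "s"})})
    ref.write_tsv(tmp_path / "ref.tsv")
    back = MarkerReference.read_tsv(tmp_path / "ref.tsv")
    pd.testing.assert_frame_equal(back.labels.sort_index(),
                                  ref.labels.sort_index(), check_names=False)


def test_intersect_identity_and_counts():
    ref = ref_from_dict({"t1": pd.Series({"a": "s", "b": "n", "c": "n", "d": "w"})})
    same = intersect_reference(ref, ["a", "b", "c", "d"])
    pd.testing.assert_frame_equal(same.labels, ref.labels)
    sub = intersect_reference(ref, ["a", "b"])
    assert list(sub.genes) == ["a", "b"]
    counts = sub.counts()
    assert counts.loc["t1", "n_positive"] == 1
    assert counts.loc["t1", "n_negative"] == 1


def test_intersect_disjoint_or_unscorable_type_errors():
    ref = ref_from_dict({"t1": pd.Series({"a": "s", "b": "n"})})
    with pytest.raises(ValueError, match="no marker reference gene"):
        intersect_reference(ref, ["zzz"])
    with pytest.raises(ValueError, match="no positive markers"):
        intersect_reference(ref, ["b"])


def test_printed_marker_partition_recounted_after_intersection():
    """A 174-gene panel whose printed per-type partition over the 135
    expressed genes is reproduced by intersect_reference recounting:
    positives (56..29) + negatives (79..98) with the remainder NA."""
    types = ["upd", "lpd", "smi", "uip", "vas", "grd", "qc", "col", "sus"]
    pos = [56, 52, 38, 43, 62, 43, 56, 51, 29]
    neg = [79, 83, 97, 92, 73, 92, 79, 84, 98]
    genes = [f"m{i:03d}" for i in range(174)]
    expressed = genes[:135]
    labels = pd.DataFrame("NA", index=pd.Index(genes, name="gene_id"), columns=types)
    rng = np.random.default_rng(0)
    for t, np_, nn in zip(types, pos, neg):
        perm = rng.permutation(135)
        labels.loc[[expressed[i] for i in perm[:np_]], t] = "s"
        labels.loc[[expressed[i] for i in perm[np_:np_ + nn]], t] = "n"
    ref = intersect_reference(MarkerReference(labels), expressed)
    counts = ref.counts()
    assert list(counts["n_positive"]) == pos
    assert list(counts["n_negative"]) == neg
    assert counts.loc["sus", "n_na"] == 135 - 29 - 98  # sus keeps 8 NA


# ---------------------------------------------------------------------------
# single-nucleus score
# ---------------------------------------------------------------------------

def enum_two_tailed(k, N, K, n):
    xs = range(max(0, n - (N - K)), min(n, K) + 1)
    pmf = {x: comb(K, x, exact=True) * comb(N - K, n - x, exact=True)
           / comb(N, n, exact=True) for x in xs}
    return min(sum(v for v in pmf.values() if v <= pmf[k] * (1 + 1e-12)), 1.0)


def test_score_enumeration_example_N10_K4_n5_k4():
    # population of 10 reference genes, 4 positives; nucleus detects 5 of
    # the population including all 4 positives
    genes = [f"g{i}" for i in range(10)]
    labels = pd.Series(["s"] * 4 + ["n"] * 6, index=genes)
    ref = ref_from_dict({"t": labels})
    detected = genes[:4] + [genes[5]]
    score = celltype_score(detected, ref, "t")
    expected = -np.log10(enum_two_tailed(4, 10, 4, 5))
    assert score == pytest.approx(expected, rel=1e-9)
    assert score > 0


def test_score_zero_when_everything_detected():
    genes = [f"g{i}" for i in range(12)]
    ref = ref_from_dict({"t": pd.Series(["s"] * 5 + ["n"] * 7, index=genes)})
    assert celltype_score(genes, ref, "t") == 0.0


def test_score_zero_at_expectation_and_on_empty_draw():
    genes = [f"g{i}" for i in range(10)]
    ref = ref_from_dict({"t": pd.Series(["s"] * 5 + ["n"] * 5, index=genes)})
    # detect 2 positives of 4 drawn: k = nK/N = 4*5/10 = 2 exactly
    assert celltype_score(genes[:2] + genes[5:7], ref, "t") == 0.0
    assert celltype_score([], ref, "t") == 0.0


def test_score_sign_flips_when_positive_and_negative_sets_swap():
    genes = [f"g{i}" for i in range(10)]
    ref = ref_from_dict({"t": pd.Series(["s"] * 4 + ["n"] * 6, index=genes)})
    swapped = ref_from_dict({"t": pd.Series(["n"] * 4 + ["s"] * 6, index=genes)})
    detected = genes[:4] + [genes[5]]
    s1 = celltype_score(detected, ref, "t")
    s2 = celltype_score(detected, swapped, "t")
    assert s1 == pytest.approx(-s2, rel=1e-9)


def test_type_without_positives_errors():
    ref = ref_from_dict({"t": pd.Series({"a": "n", "b": "n"})})
    with pytest.raises(ValueError, match="no positive markers"):
        celltype_score(["a"], ref, "t")


# ---------------------------------------------------------------------------
# score matrix
# ---------------------------------------------------------------------------

def _planted_matrix_and_ref():
    genes = [f"g{i}" for i in range(12)]
    ref = ref_from_dict({
        "t1": pd.Series(["s"] * 4 + ["n"] * 8, index=genes),
        "t2": pd.Series(["n"] * 4 + ["s"] * 4 + ["n"] * 4, index=genes),
    })
    vals = np.zeros((12, 4))
    vals[:4, :2] = 5.0   # nuclei 0,1 express exactly t1 positives
    vals[4:8, 2:] = 5.0  # nuclei 2,3 express exactly t2 positives
    return toy_matrix(vals, genes=genes), ref


def test_planted_nuclei_get_their_type_as_argmax():
    m, ref = _planted_matrix_and_ref()
    s = score_matrix(m, ref)
    assert list(s.argmax_type) == ["t1", "t1", "t2", "t2"]
    assert s.scores.shape == (4, 2)


def test_score_matrix_shape_matches_cohort():
    # 486 nuclei x 9 cell types, the target analysis shape
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(90)]
    labels = {f"t{j}": pd.Series(["n"] * 90, index=genes) for j in range(9)}
    for j in range(9):
        labels[f"t{j}"].iloc[10 * j:10 * (j + 1)] = "s"
    ref = MarkerReference(pd.DataFrame(labels))
    m = toy_matrix(rng.poisson(0.5, size=(90, 486)), genes=genes)
    s = score_matrix(m, ref)
    assert s.scores.shape == (486, 9)


def test_score_matrix_invariant_to_gene_and_nucleus_order():
    m, ref = _planted_matrix_and_ref()
    s1 = score_matrix(m, ref).scores
    rng = np.random.default_rng(1)
    gperm = rng.permutation(m.values.index)
    nperm = rng.permutation(m.values.columns)
    m2 = toy_matrix(m.values.loc[gperm, nperm].to_numpy(), genes=list(gperm),
                    nuclei=list(nperm))
    s2 = score_matrix(m2, ref).scores
    pd.testing.assert_frame_equal(s1, s2.loc[s1.index], check_names=False)


# ---------------------------------------------------------------------------
# clustering and labelling
# ---------------------------------------------------------------------------

def test_two_separated_types_give_two_correct_clusters():
    rng = np.random.default_rng(2)
    a = rng.normal([6, 0], 0.3, size=(20, 2))
    b = rng.normal([0, 6], 0.3, size=(20, 2))
    scores = pd.DataFrame(np.vstack([a, b]), columns=["t1", "t2"],
                          index=[f"n{i}" for i in range(40)])
    s = CellTypeScoreMatrix(scores, pd.Series(1, index=scores.index))
    model = cluster_scores(s, 2, seed=0)  # k-means, k=2
    assert len(model.cluster_ids) == 2
    assert sorted(model.labels.values()) == ["t1", "t2"]
    leiden = cluster_scores(s, 1.0, seed=0)
    assert sorted(set(leiden.labels.values())) == ["t1", "t2"]


def test_same_seed_same_assignment():
    rng = np.random.default_rng(3)
    scores = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"),
                          index=[f"n{i}" for i in range(50)])
    s = CellTypeScoreMatrix(scores, pd.Series(1, index=scores.index))
    m1 = cluster_scores(s, 1.0, seed=4)
    m2 = cluster_scores(s, 1.0, seed=4)
    pd.testing.assert_series_equal(m1.assignment, m2.assignment)


def test_more_clusters_than_nuclei_rejected():
    scores = pd.DataFrame(np.eye(3), columns=list("abc"),
                          index=["n0", "n1", "n2"])
    s = CellTypeScoreMatrix(scores, pd.Series(1, index=scores.index))
    with pytest.raises(ValueError, match="clusters requested"):
        cluster_scores(s, 5, seed=0)


def test_majority_labels_require_strict_majority():
    assignment = pd.Series({"n0": "c0", "n1": "c0", "n2": "c0", "n3": "c0",
                            "n4": "c1", "n5": "c1"})
    argmax = pd.Series({"n0": "t1", "n1": "t1", "n2": "t1", "n3": "t2",
                        "n4": "t1", "n5": "t2"})
    labels = majority_labels(assignment, argmax)
    assert labels["c0"] == "t1"       # 3/4 > 50%
    assert labels["c1"] == "mixed"    # 1/1 tie


def test_embedding_shape_and_determinism():
    rng = np.random.default_rng(6)
    scores = pd.DataFrame(rng.normal(size=(30, 4)),
                          index=[f"n{i}" for i in range(30)],
                          columns=list("abcd"))
    s = CellTypeScoreMatrix(scores, pd.Series(1, index=scores.index))
    e1 = embed_scores(s, method="pca", seed=0)
    e2 = embed_scores(s, method="pca", seed=0)
    assert e1.shape == (30, 2)
    pd.testing.assert_frame_equal(e1, e2)


# ---------------------------------------------------------------------------
# contaminant and low-quality cluster removal
# ---------------------------------------------------------------------------

def test_pure_contaminant_cluster_dropped():
    genes = [f"g{i}" for i in range(8)]
    embryo = ref_from_dict({"t1": pd.Series(["s"] * 4 + ["n"] * 4, index=genes)})
    contam = ref_from_dict({"sc": pd.Series(["n"] * 4 + ["s"] * 4, index=genes)})
    vals = np.zeros((8, 6))
    vals[:4, :3] = 5.0   # embryonic nuclei
    vals[4:, 3:] = 5.0   # seed-coat nuclei
    m = toy_matrix(vals, genes=genes)
    clusters = ClusterModel(pd.Series(["e"] * 3 + ["s"] * 3,
                                      index=m.values.columns))
    kept, report = flag_contaminants(m, embryo, contam, clusters)
    assert report.loc["s", "drop"] and not report.loc["e", "drop"]
    assert set(kept.assignment.unique()) == {"e"}


def test_no_contamination_no_cluster_dropped(pipeline_clean):
    res, truth, ref, _ = pipeline_clean
    from embryoatlas.simulate import SimulationConfig, generate_contaminant_reference
    contam_ref = generate_contaminant_reference(SimulationConfig(seed=7))
    _, report = flag_contaminants(res.matrix, ref, contam_ref, res.clusters)
    assert not report["drop"].any()


def test_low_quality_cluster_filter_drops_shallow_cluster():
    vals = np.zeros((10, 8))
    vals[:, :4] = 5.0          # deep nuclei detect all genes
    vals[0, 4:] = 5.0          # shallow nuclei detect one gene
    m = toy_matrix(vals)
    clusters = ClusterModel(pd.Series(["deep"] * 4 + ["shallow"] * 4,
                                      index=m.values.columns))
    kept, report = drop_low_quality_clusters(m, clusters, factor=0.5)
    assert report.loc["shallow", "drop"] and not report.loc["deep", "drop"]
    assert set(kept.assignment.unique()) == {"deep"}
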