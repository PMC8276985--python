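"""Promoter extraction, PWM scanning, motif enrichment and TF correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from embryoatlas.motifs import (Motif, MotifSet, collapse_families,
                                correlate_tf_expression, extract_promoters,
                                motif_enrichment, presence_matrix,
                                promoter_interval, read_meme,
                                reverse_complement, scan_motif,
                                synthetic_motif_set, write_annotations,
                                write_meme)
from embryoatlas.simulate import simulate_promoters, write_fasta


def consensus_motif(seq: str, motif_id="M0", **kw) -> Motif:
    mat = np.zeros((len(seq), 4))
    for i, b in enumerate(seq):
        mat[i, "ACGT".index(b)] = 1.0
    return Motif(motif_id, mat, **kw)


# ---------------------------------------------------------------------------
# containers and IO
# ---------------------------------------------------------------------------

def test_pwm_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        Motif("bad", np.full((5, 4), 0.3))
    with pytest.raises(ValueError, match="length"):
        Motif("short", np.full((3, 4), 0.25))
    ok = Motif("ok", np.full((6, 4), 0.25))
    assert ok.length == 6


def test_meme_roundtrip(tmp_path):
    ms = synthetic_motif_set(4, seed=2)
    write_meme(ms, tmp_path / "motifs.meme")
    write_annotations(ms, tmp_path / "motifs.tsv")
    back = read_meme(tmp_path / "motifs.meme", tmp_path / "motifs.tsv")
    assert set(back.motifs) == set(ms.motifs)
    for mid in ms.motifs:
        np.testing.assert_allclose(back.motifs[mid].matrix,
                                   ms.motifs[mid].matrix, atol=1e-5)
        assert back.motifs[mid].family == ms.motifs[mid].family
        assert back.motifs[mid].tf == ms.motifs[mid].tf


# ---------------------------------------------------------------------------
# promoter windows
# ---------------------------------------------------------------------------

def test_plus_strand_window_500_up_100_down():
    assert promoter_interval(10_000, "+", 1_000_000) == (9500, 10100, False)


def test_minus_strand_window_is_the_mirror():
    assert promoter_interval(10_000, "-", 1_000_000) == (9901, 10501, False)


def test_window_clipped_at_contig_start():
    lo, hi, clipped = promoter_interval(120, "+", 1000)
    assert (lo, hi) == (0, 220) and clipped


def _write_toy_genome(tmp_path):
    # one plus-strand and one minus-strand gene on a 1300-bp contig each
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    plus = "".join(rng.choice(bases, 1300))
    minus = "".join(rng.choice(bases, 1300))
    write_fasta({"c_plus": plus, "c_minus": minus}, tmp_path / "g.fa")
    gff = "\n".join([
        "##gff-version 3",
        "c_plus\tsim\tgene\t501\t1100\t.\t+\t.\tID=gp",
        "c_plus\tsim\tmRNA\t501\t1100\t.\t+\t.\tID=gp.1;Parent=gp",
        "c_minus\tsim\tgene\t300\t800\t.\t-\t.\tID=gm",
        "c_minus\tsim\tmRNA\t300\t800\t.\t-\t.\tID=gm.1;Parent=gm",
    ]) + "\n"
    (tmp_path / "g.gff3").write_text(gff)
    return plus, minus


def test_extract_promoters_strand_aware(tmp_path):
    plus, minus = _write_toy_genome(tmp_path)
    ps = extract_promoters(["gp", "gm", "absent"], tmp_path / "g.gff3",
                           tmp_path / "g.fa")
    assert ps.skipped == ["absent"]
    # plus: TSS 0-based 500, window [0, 600)
    assert ps.table.loc["gp", ["start", "end"]].tolist() == [0, 600]
    assert ps.sequences["gp"] == plus[0:600]
    # minus: TSS 0-based 799, window [700, 1300), reverse-complemented
    assert ps.table.loc["gm", ["start", "end"]].tolist() == [700, 1300]
    assert ps.sequences["gm"] == reverse_complement(minus[700:1300])
    assert all(len(s) == 600 for s in ps.sequences.values())


def test_tss_table_overrides_annotation(tmp_path):
    plus, _ = _write_toy_genome(tmp_path)
    tss = pd.DataFrame([{"gene_id": "gp", "contig": "c_plus",
                         "position": 700, "strand": "+"}])
    ps = extract_promoters(["gp"], tmp_path / "g.gff3", tmp_path / "g.fa",
                           tss_table=tss)
    assert ps.table.loc["gp", ["start", "end"]].tolist() == [200, 800]
    assert ps.sequences["gp"] == plus[200:800]


def test_promoters_roundtrip_through_simulator(tmp_path):
    ms = synthetic_motif_set(2, seed=3)
    tops = {"c1": [f"g{i}" for i in range(10)]}
    genome, gff, _ = simulate_promoters(tops, ms, {}, seed=3)
    write_fasta(genome, tmp_path / "g.fa")
    (tmp_path / "g.gff3").write_text(gff)
    ps = extract_promoters(tops["c1"], tmp_path / "g.gff3", tmp_path / "g.fa")
    assert len(ps) == 10 and all(len(s) == 600 for s in ps.sequences.values())


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_consensus_hits_found_on_both_strands():
    m = consensus_motif("ACGTAC")
    seq = "T" * 20 + "ACGTAC" + "T" * 20 + reverse_complement("ACGTAC") + "T" * 8
    hits = scan_motif(m, seq, threshold_frac=1.0)
    assert set(zip(hits["position"], hits["strand"])) == {(20, "+"), (46, "-")}


def test_all_n_sequence_has_no_hits():
    m = consensus_motif("ACGTAC")
    assert scan_motif(m, "N" * 100, threshold_frac=0.5).empty


def test_scan_on_reverse_complement_gives_same_presence():
    rng = np.random.default_rng(4)
    ms = synthetic_motif_set(6, seed=4)
    bases = np.array(list("ACGT"))
    for trial in range(5):
        seq = "".join(rng.choice(bases, 300))
        for motif in ms.motifs.values():
            fwd = not scan_motif(motif, seq, threshold_frac=0.8).empty
            rev = not scan_motif(motif, reverse_complement(seq),
                                 threshold_frac=0.8).empty
            assert fwd == rev


def test_presence_matrix_agrees_with_per_sequence_scan():
    rng = np.random.default_rng(5)
    ms = synthetic_motif_set(5, seed=5)
    bases = np.array(list("ACGT"))
    seqs = {f"g{i}": "".join(rng.choice(bases, 200)) for i in range(20)}
    pm = presence_matrix(ms, seqs, threshold_frac=0.8)
    for g, s in seqs.items():
        for mid, motif in ms.motifs.items():
            assert pm.loc[g, mid] == (not scan_motif(
                motif, s, ms.background, threshold_frac=0.8).empty)


def test_chance_presence_rate_matches_closed_form():
    """Exact-consensus presence in uniform random 600-mers follows
    1 - (1 - 2*0.25^L)^(600-L+1) for a non-palindromic consensus."""
    m = consensus_motif("ACGTACGG")
    rng = np.random.default_rng(6)
    bases = np.array(list("ACGT"))
    n = 4000
    codes = rng.integers(0, 4, size=(n, 600))
    seqs = {f"g{i}": "".join(bases[codes[i]]) for i in range(n)}
    pm = presence_matrix(MotifSet({"M0": m}), seqs, threshold_frac=1.0)
    rate = pm["M0"].mean()
    expected = 1 - (1 - 2 * 0.25 ** 8) ** 593
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(rate - expected) < 3 * se


# ---------------------------------------------------------------------------
# enrichment and families
# ---------------------------------------------------------------------------

def _promoters_with_presence(n_with, n_total, motif, seed):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    cons = motif.consensus
    out = {}
    for i in range(n_total):
        # build from a 3-letter alphabet so the consensus cannot occur by
        # chance, then plant it explicitly in the first n_with promoters
        s = "".join(rng.choice(bases[:3], 300))
        if i < n_with:
            off = int(rng.integers(0, 300 - len(cons)))
            s = s[:off] + cons + s[off + len(cons):]
        out[f"g{seed}_{i}"] = s
    return out


def test_equal_presence_is_not_significant():
    ms = MotifSet({"M0": consensus_motif("ACGTACGT")})
    top = _promoters_with_presence(15, 25, ms.motifs["M0"], seed=1)
    bot = _promoters_with_presence(15, 25, ms.motifs["M0"], seed=2)
    res = motif_enrichment(top, bot, ms, threshold_frac=1.0)
    assert res.loc[0, "p"] >= 0.5
    assert not res.loc[0, "significant"]


def test_fisher_p_matches_hypergeometric_tail():
    ms = MotifSet({"M0": consensus_motif("ACGTACGT")})
    top = _promoters_with_presence(30, 250, ms.motifs["M0"], seed=3)
    bot = _promoters_with_presence(10, 250, ms.motifs["M0"], seed=4)
    res = motif_enrichment(top, bot, ms, threshold_frac=1.0)
    assert res.loc[0, "present_top"] == 30 and res.loc[0, "present_bottom"] == 10
    oracle = float(sps.hypergeom.sf(29, 500, 40, 250))
    assert res.loc[0, "p"] == pytest.approx(oracle, rel=1e-9)


def test_identical_sets_rejected():
    ms = MotifSet({"M0": consensus_motif("ACGTACGT")})
    proms = _promoters_with_presence(5, 10, ms.motifs["M0"], seed=5)
    with pytest.raises(ValueError, match="identical"):
        motif_enrichment(proms, proms, ms)


def test_family_collapse_takes_member_maximum():
    ms = MotifSet({
        "M0": consensus_motif("ACGTAC", "M0", tf="TF0", family="F0"),
        "M1": consensus_motif("TTGACC", "M1", tf="TF1", family="F0"),
        "M2": consensus_motif("CACGTG", "M2", tf="TF2", family="F1"),
    })
    res = pd.DataFrame([
        {"motif_id": "M0", "cluster": "A", "neglog10_p": 3.0, "frac_top": 0.2,
         "significant": True},
        {"motif_id": "M1", "cluster": "A", "neglog10_p": 5.0, "frac_top": 0.1,
         "significant": True},
        {"motif_id": "M2", "cluster": "A", "neglog10_p": 1.0, "frac_top": 0.3,
         "significant": False},
    ])
    fam = collapse_families(res, ms).set_index("family")
    assert fam.loc["F0", "neglog10_p"] == 5.0
    assert fam.loc["F0", "frac_top"] == 0.2
    assert fam.loc["F0", "best_motif"] == "M1"
    assert "F1" not in fam.index  # no member significant anywhere


def test_family_collapse_matches_groupby_max_brute_force():
    rng = np.random.default_rng(7)
    ms = synthetic_motif_set(8, seed=7, tfs_per_family=2)
    rows = []
    for mid in ms.motifs:
        for cl in ["A", "B", "C"]:
            rows.append({"motif_id": mid, "cluster": cl,
                         "neglog10_p": float(rng.random() * 6),
                         "frac_top": float(rng.random()),
                         "significant": bool(rng.random() < 0.5)})
    res = pd.DataFrame(rows)
    fam = collapse_families(res, ms)
    sig = {r["motif_id"] for _, r in res.iterrows() if r["significant"]}
    for _, row in fam.iterrows():
        members = [mid for mid, m in ms.motifs.items()
                   if m.family == row["family"] and mid in sig]
        grp = res[(res["motif_id"].isin(members)) & (res["cluster"] == row["cluster"])]
        assert row["neglog10_p"] == grp["neglog10_p"].max()
        assert row["frac_top"] == grp["frac_top"].max()


def test_singleton_family_for_unannotated_motif():
    ms = MotifSet({"M0": consensus_motif("ACGTAC", "M0")})  # no family
    res = pd.DataFrame([{"motif_id": "M0", "cluster": "A", "neglog10_p": 4.0,
                         "frac_top": 0.5, "significant": True}])
    with pytest.warns(UserWarning, match="singleton"):
        fam = collapse_families(res, ms)
    assert list(fam["family"]) == ["singleton_M0"]


# ---------------------------------------------------------------------------
# TF correlation
# ---------------------------------------------------------------------------

def test_proportional_and_negated_tf_vectors():
    fam = pd.DataFrame({"c1": [1.0], "c2": [4.0], "c3": [2.0], "c4": [6.0]},
                       index=["F0"])
    tf_E = pd.DataFrame({
        "c1": [2.0, -1.0, 1.0], "c2": [8.0, -4.0, 1.0],
        "c3": [4.0, -2.0, 1.0], "c4": [12.0, -6.0, 1.0]},
        index=["TFpos", "TFneg", "TFflat"])
    out = correlate_tf_expression(fam, tf_E,
                                  {"F0": ["TFpos", "TFneg", "TFflat"]})
    out = out.set_index("tf")
    assert out.loc["TFpos", "r"] == pytest.approx(1.0)
    assert out.loc["TFpos", "classification"] == "positive"
    assert out.loc["TFneg", "r"] == pytest.approx(-1.0)
    assert out.loc["TFneg", "classification"] == "negative"
    assert out.loc["TFflat", "classification"] == "degenerate"
    assert out.loc[out["best"], :].index.tolist() in (["TFpos"], ["TFneg"])


def test_pearson_matches_covariance_formula_on_5_cluster_toy():
    fam = pd.DataFrame({"c1": [0.5], "c2": [3.0], "c3": [1.0],
                        "c4": [2.0], "c5": [0.1]}, index=["F0"])
    tf_E = pd.DataFrame({"c1": [1.0], "c2": [2.0], "c3": [0.5],
                         "c4": [2.5], "c5": [0.2]}, index=["TF0"])
    out = correlate_tf_expression(fam, tf_E, {"F0": ["TF0"]})
    x = fam.loc["F0"].to_numpy()
    y = tf_E.loc["TF0"].to_numpy()
    oracle = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
    assert out.loc[0, "r"] == pytest.approx(oracle, rel=1e-12)


def test_fewer_than_three_clusters_rejected():
    fam = pd.DataFrame({"c1": [1.0], "c2": [2.0]}, index=["F0"])
    tf_E = pd.DataFrame({"c1": [1.0], "c2": [2.0]}, index=["TF0"])
    with pytest.raises(ValueError, match="3 clusters"):
        correlate_tf_expression(fam, tf_E, {"F0": ["TF0"]})
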