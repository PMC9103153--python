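import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cernet import (
    ExpressionMatrix,
    TargetMap,
    benjamini_hochberg,
    candidate_mirnas,
    correlate_with_lnc,
    intersect_targets,
    mirna_enrichment,
    rank_target_genes,
    read_network,
    restrict_to_measured,
    select_network,
    welch_t_test,
    write_network,
)


def bruteforce_pearson(x, y):
    """Plain covariance / sigma*sigma formula, no library calls."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


def bruteforce_welch(x, y):
    """Textbook Welch t, Satterthwaite df, two-sided p via the t survival fn."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df, 2.0 * tdist.sf(abs(t), df)


def bruteforce_bh(p):
    """min-over-suffix definition evaluated directly."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_idx, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestCorrelateWithLnc:
    def test_perfect_linear_relations(self, small_matrix):
        corr = correlate_with_lnc(small_matrix).set_index("gene_id")
        assert corr.at["SHIFT", "r"] == pytest.approx(1.0)
        assert corr.at["SHIFT", "p"] == 0.0
        assert corr.at["NEG", "r"] == pytest.approx(-1.0)
        assert "LNC" not in corr.index

    def test_matches_direct_formula_on_random_rows(self):
        rng = np.random.default_rng(3)
        lnc = rng.standard_normal(20)
        rows = rng.standard_normal((30, 20))
        data = pd.DataFrame(
            np.vstack([lnc, rows]),
            index=["LNC"] + [f"G{i}" for i in range(30)],
            columns=[f"S{i}" for i in range(20)],
        )
        corr = correlate_with_lnc(ExpressionMatrix(data=data, lnc_id="LNC"))
        for gene, r in zip(corr["gene_id"], corr["r"]):
            i = int(gene[1:])
            assert r == pytest.approx(bruteforce_pearson(rows[i], lnc), abs=1e-12)

    def test_pairwise_complete_pairs_and_exclusions(self, caplog):
        lnc = [1.0, 2.0, 3.0, 4.0, 5.0]
        sparse = [1.0, 2.0, np.nan, np.nan, np.nan]  # 2 pairs -> excluded
        partial = [2.0, 4.0, 6.0, np.nan, np.nan]    # 3 pairs, exact linear
        data = pd.DataFrame(
            [lnc, sparse, partial],
            index=["LNC", "SPARSE", "PARTIAL"],
            columns=[f"S{i}" for i in range(5)],
        )
        with caplog.at_level("INFO", logger="cernet"):
            corr = correlate_with_lnc(ExpressionMatrix(data=data, lnc_id="LNC"))
        assert corr["gene_id"].tolist() == ["PARTIAL"]
        assert corr.iloc[0]["n"] == 3
        assert corr.iloc[0]["r"] == pytest.approx(1.0)
        assert any("SPARSE" in r.message for r in caplog.records)

    def test_constant_lnc_row_is_hard_error(self):
        data = pd.DataFrame(
            [[1.0] * 5, [1, 2, 3, 4, 5]], index=["LNC", "G"], columns=list("abcde")
        )
        with pytest.raises(ValueError, match="constant"):
            correlate_with_lnc(ExpressionMatrix(data=data, lnc_id="LNC"))

    def test_p_equals_t_transform(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(5)
        lnc = rng.standard_normal(15)
        g = rng.standard_normal(15)
        data = pd.DataFrame(
            np.vstack([lnc, g]), index=["LNC", "G"], columns=[f"S{i}" for i in range(15)]
        )
        corr = correlate_with_lnc(ExpressionMatrix(data=data, lnc_id="LNC"))
        r_ref, p_ref = pearsonr(g, lnc)
        assert corr.iloc[0]["r"] == pytest.approx(r_ref, abs=1e-12)
        assert corr.iloc[0]["p"] == pytest.approx(p_ref, rel=1e-10)


class TestWelch:
    def test_identical_samples_give_t0_p1(self):
        x = [1.0, 2.0, 3.0, 4.0]
        t, df, p = welch_t_test(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_shift_and_antisymmetry(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [11.0, 12.0, 13.0, 14.0]
        t_xy, _, _ = welch_t_test(x, y)
        t_yx, _, _ = welch_t_test(y, x)
        assert t_xy < 0
        assert t_xy == pytest.approx(-t_yx, abs=1e-14)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(17)
        x, y = rng.standard_normal(8), 0.5 + rng.standard_normal(12) * 2.0
        t, df, p = welch_t_test(x, y)
        t0, df0, p0 = bruteforce_welch(x, y)
        assert t == pytest.approx(t0, abs=1e-10)
        assert df == pytest.approx(df0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_one_constant_sample_is_computed_normally(self):
        t, df, p = welch_t_test([2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isfinite(t) and np.isfinite(p)
        assert df == pytest.approx(3.0)  # Satterthwaite collapses to n2 - 1

    def test_both_constant_equal_means_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            welch_t_test([2.0, 2.0], [2.0, 2.0])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="2 observations"):
            welch_t_test([1.0], [1.0, 2.0])


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, -0.1])

    def test_matches_suffix_min_oracle_on_random_vectors(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            p = rng.random(int(rng.integers(1, 13)))
            np.testing.assert_allclose(
                benjamini_hochberg(p), bruteforce_bh(p), atol=1e-12
            )

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_sorted_adjusted_values_are_monotone(self, pvals):
        q = benjamini_hochberg(pvals)
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q >= np.asarray(pvals) - 1e-15)


def _screen(dataset, alpha=0.05):
    matrix, binding, predictions, truth = dataset
    tmap = restrict_to_measured(
        intersect_targets(predictions, candidate_mirnas(binding, matrix.lnc_id), 2),
        matrix,
    )
    corr = correlate_with_lnc(matrix)
    enr = mirna_enrichment(corr, tmap, alpha=alpha)
    return matrix, tmap, corr, enr, truth


class TestEnrichment:
    def test_targets_equal_background_give_t0_p1(self):
        rng = np.random.default_rng(1)
        corr = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "r": rng.uniform(-1, 1, 10),
                "n": 20,
                "p": rng.random(10),
            }
        )
        tmap = TargetMap(entries={"m1": {f"g{i}" for i in range(10)}})
        enr = mirna_enrichment(corr, tmap)
        assert enr.iloc[0]["t"] == 0.0
        assert enr.iloc[0]["p"] == pytest.approx(1.0)
        assert not enr.iloc[0]["significant"]  # direction requirement unmet

    def test_background_smaller_than_two_is_error(self):
        corr = pd.DataFrame({"gene_id": ["g0"], "r": [0.5], "n": [20], "p": [0.02]})
        with pytest.raises(ValueError, match="background"):
            mirna_enrichment(corr, TargetMap(entries={"m1": {"g0"}}))

    def test_planted_mirnas_beat_background_on_default_fixture(
        self, default_sponge_dataset
    ):
        _, _, _, enr, truth = _screen(default_sponge_dataset)
        planted = enr[enr["mirna_id"].isin(truth.sponged_mirnas)]
        assert len(planted) == len(truth.sponged_mirnas)
        assert (planted["mean_abs_r_targets"] > planted["mean_abs_r_background"]).all()
        assert planted["significant"].all()

    def test_adjusted_p_never_below_raw_p(self, default_sponge_dataset):
        _, _, _, enr, _ = _screen(default_sponge_dataset)
        assert (enr["p_adj"] >= enr["p"] - 1e-15).all()

    def test_raising_alpha_never_removes_a_significant_mirna(
        self, default_sponge_dataset
    ):
        _, _, _, enr_low, _ = _screen(default_sponge_dataset, alpha=0.01)
        _, _, _, enr_high, _ = _screen(default_sponge_dataset, alpha=0.10)
        low = set(enr_low.loc[enr_low["significant"], "mirna_id"])
        high = set(enr_high.loc[enr_high["significant"], "mirna_id"])
        assert low <= high


class TestNetwork:
    def test_no_significant_mirna_gives_lnc_only_network(self):
        enr = pd.DataFrame(
            {
                "mirna_id": ["m1"], "n_targets": [5], "mean_abs_r_targets": [0.1],
                "mean_abs_r_background": [0.2], "t": [-1.0], "df": [8.0],
                "p": [0.4], "p_adj": [0.4], "significant": [False],
            }
        )
        corr = pd.DataFrame({"gene_id": ["g1"], "r": [0.9], "n": [20], "p": [0.001]})
        net = select_network(enr, corr, TargetMap(entries={"m1": {"g1"}}), lnc_id="L")
        assert net.n_nodes == 1 and len(net.edges) == 0

    def test_single_mirna_with_three_qualifying_targets(self):
        enr = pd.DataFrame(
            {
                "mirna_id": ["m1"], "n_targets": [4], "mean_abs_r_targets": [0.6],
                "mean_abs_r_background": [0.2], "t": [5.0], "df": [8.0],
                "p": [0.001], "p_adj": [0.002], "significant": [True],
            }
        )
        corr = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "gneg", "gns"],
                "r": [0.9, 0.8, 0.7, -0.9, 0.5],
                "n": 20,
                "p": [1e-4, 1e-4, 1e-4, 1e-4, 0.5],
            }
        )
        tmap = TargetMap(entries={"m1": {"g1", "g2", "g3", "gneg", "gns"}})
        net = select_network(enr, corr, tmap, alpha=0.05, lnc_id="L")
        # negative-r and non-significant-p targets are excluded from gene nodes
        assert net.gene_table["gene_id"].tolist() == ["g1", "g2", "g3"]
        assert net.n_nodes == 5
        kinds = net.edges["kind"].value_counts().to_dict()
        assert kinds == {"target": 3, "sponge": 1}

    def test_rank_ties_break_lexicographically(self):
        enr = pd.DataFrame(
            {
                "mirna_id": ["m1"], "n_targets": [2], "mean_abs_r_targets": [0.6],
                "mean_abs_r_background": [0.2], "t": [5.0], "df": [8.0],
                "p": [0.001], "p_adj": [0.002], "significant": [True],
            }
        )
        corr = pd.DataFrame(
            {"gene_id": ["gb", "ga"], "r": [0.7, 0.7], "n": 20, "p": [1e-4, 1e-4]}
        )
        net = select_network(enr, corr, TargetMap(entries={"m1": {"ga", "gb"}}), lnc_id="L")
        ranked = rank_target_genes(net, k=10)
        assert ranked["gene_id"].tolist() == ["ga", "gb"]
        with pytest.raises(ValueError):
            rank_target_genes(net, k=0)

    def test_planted_positive_effect_genes_are_recovered(self, default_sponge_dataset):
        matrix, tmap, corr, enr, truth = _screen(default_sponge_dataset)
        net = select_network(enr, corr, tmap, lnc_id=matrix.lnc_id)
        gene_nodes = set(net.gene_table["gene_id"])
        sig = set(net.mirna_table["mirna_id"])
        lookup = corr.set_index("gene_id")
        for gene, has_effect in truth.effect.items():
            if not has_effect or gene not in lookup.index:
                continue
            mirna = next(
                m for m, gs in truth.target_assignments.items() if gene in gs
            )
            if mirna in sig and lookup.at[gene, "p"] < 0.05 and lookup.at[gene, "r"] > 0:
                assert gene in gene_nodes

    def test_write_read_round_trip_preserves_topology(
        self, default_sponge_dataset, tmp_path
    ):
        matrix, tmap, corr, enr, _ = _screen(default_sponge_dataset)
        net = select_network(enr, corr, tmap, lnc_id=matrix.lnc_id)
        paths = write_network(net, tmp_path / "net")
        g = read_network(tmp_path / "net")
        expected_edges = {(r.source, r.target) for r in net.edges.itertuples(index=False)}
        assert set(g.edges()) == expected_edges
        nodes = pd.read_csv(paths["nodes"], sep="\t")
        assert len(nodes) == net.n_nodes

    def test_empty_network_writes_valid_header_only_tables(self, tmp_path):
        enr = pd.DataFrame(
            {
                "mirna_id": ["m1"], "n_targets": [5], "mean_abs_r_targets": [0.1],
                "mean_abs_r_background": [0.2], "t": [-1.0], "df": [8.0],
                "p": [0.4], "p_adj": [0.4], "significant": [False],
            }
        )
        corr = pd.DataFrame({"gene_id": ["g1"], "r": [0.9], "n": [20], "p": [0.001]})
        net = select_network(enr, corr, TargetMap(entries={"m1": {"g1"}}), lnc_id="L")
        paths = write_network(net, tmp_path / "empty")
        edges = pd.read_csv(paths["edges"], sep="\t")
        assert len(edges) == 0
        assert list(edges.columns) == ["source", "target", "kind"]
        assert read_network(tmp_path / "empty").number_of_nodes() == 1
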