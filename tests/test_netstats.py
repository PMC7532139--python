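"""Network aggregation, drug-by-time statistics, edge thresholding, AUC."""

import numpy as np
import pandas as pd
import pytest

from sdefc import (
    ConnectivityMatrix,
    NetworkScheme,
    aggregate_networks,
    anova_table,
    auc_drug_strength,
    change_vs_auc,
    contrast_t_matrix,
    edge_threshold_contrast,
    holm_bonferroni,
    network_summary_table,
    paired_contrast,
    rm_anova_2x2,
)
from sdefc.design import CELLS, DEFAULT_NETWORKS


def _zmat(values, node_ids, meta=None):
    return ConnectivityMatrix(values=values, measure="sfc_z", node_ids=node_ids,
                              meta=meta or {})


def _filled(scheme, fill, rng=None):
    n = scheme.n_nodes
    vals = np.full((n, n), float(fill))
    if rng is not None:
        noise = rng.standard_normal((n, n)) * 0.01
        vals += (noise + noise.T) / 2
    np.fill_diagonal(vals, np.nan)
    return _zmat(vals, scheme.node_ids)


class TestAggregateNetworks:
    def test_default_scheme_yields_36_interactions(self, scheme8, rng):
        out = aggregate_networks(_filled(scheme8, 0.3, rng), scheme8)
        assert len(out) == 36
        assert sum(k.startswith("within:") for k in out.index) == 8
        assert sum(k.startswith("between:") for k in out.index) == 28

    def test_constant_edges_give_constant_means(self, scheme8):
        out = aggregate_networks(_filled(scheme8, 0.42), scheme8)
        assert np.allclose(out.to_numpy(), 0.42)

    def test_unbalanced_edge_counts(self):
        # networks of 3 and 2 nodes: 3, 1 and 6 edges respectively
        scheme = NetworkScheme(
            node_to_network={"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"},
            networks=("A", "B"),
        )
        idx = scheme.edge_interaction_index(scheme.node_ids)
        assert len(idx[("within", "A")]) == 3
        assert len(idx[("within", "B")]) == 1
        assert len(idx[("between", "A", "B")]) == 6

    def test_raw_r_scale_rejected(self, scheme8):
        n = scheme8.n_nodes
        cm = ConnectivityMatrix(values=np.eye(n), measure="sfc_r",
                                node_ids=scheme8.node_ids)
        with pytest.raises(ValueError, match="Fisher-z"):
            aggregate_networks(cm, scheme8)

    def test_aggregation_linearity(self, scheme8, rng):
        cm = _filled(scheme8, 0.2, rng)
        out1 = aggregate_networks(cm, scheme8)
        cm3 = _zmat(cm.values * 3.0, scheme8.node_ids)
        out3 = aggregate_networks(cm3, scheme8)
        assert np.allclose(out3.to_numpy(), 3.0 * out1.to_numpy())

    def test_flagged_edges_excluded_from_mean(self):
        scheme = NetworkScheme.balanced(3, DEFAULT_NETWORKS[:2])
        n = scheme.n_nodes
        vals = np.full((n, n), 0.5)
        vals[0, 1] = vals[1, 0] = np.nan  # one of three within-MF edges flagged
        np.fill_diagonal(vals, np.nan)
        out = aggregate_networks(_zmat(vals, scheme.node_ids), scheme)
        assert out["within:MF"] == pytest.approx(0.5)


class TestRmAnova:
    def test_identical_cells_give_zero_F(self):
        vals = np.tile(np.arange(1.0, 6.0)[:, None], (1, 4))
        res = rm_anova_2x2(vals)
        assert all(r.statistic == 0.0 for r in res.values())

    def test_F_equals_squared_paired_t(self, rng):
        vals = rng.standard_normal((12, 4))
        res = rm_anova_2x2(vals)
        pl_f, pl_s, dr_f, dr_s = vals.T
        inter = paired_contrast(dr_f - dr_s, pl_f - pl_s)
        assert res["interaction"].statistic == pytest.approx(
            inter.statistic**2, abs=1e-10)
        drug = paired_contrast((dr_f + dr_s) / 2, (pl_f + pl_s) / 2)
        assert res["drug"].statistic == pytest.approx(drug.statistic**2, abs=1e-10)

    def test_matches_pingouin_oracle(self, rng):
        """Cross-check F and p against pingouin's repeated-measures ANOVA
        on the same data."""
        pingouin = pytest.importorskip("pingouin")
        vals = rng.standard_normal((10, 4)) + np.array([0.3, 0.0, -0.2, 0.1])
        res = rm_anova_2x2(vals)
        rows = []
        for pid in range(10):
            for k, (drug, half) in enumerate(CELLS):
                rows.append({"pid": pid, "drug": drug, "half": half,
                             "y": vals[pid, k]})
        df = pd.DataFrame(rows)
        pg = pingouin.rm_anova(data=df, dv="y", within=["drug", "half"],
                               subject="pid", detailed=True)
        pg = pg.set_index("Source")
        assert res["drug"].statistic == pytest.approx(pg.loc["drug", "F"], rel=1e-8)
        assert res["time"].statistic == pytest.approx(pg.loc["half", "F"], rel=1e-8)
        assert res["interaction"].statistic == pytest.approx(
            pg.loc["drug * half", "F"], rel=1e-8)
        assert res["interaction"].p == pytest.approx(
            pg.loc["drug * half", "p_unc"], rel=1e-8)
        assert res["drug"].p == pytest.approx(pg.loc["drug", "p_unc"], rel=1e-8)

    def test_partial_eta_squared_formula(self, rng):
        res = rm_anova_2x2(rng.standard_normal((8, 4)))
        for r in res.values():
            assert r.effect_size == pytest.approx(r.statistic / (r.statistic + 7))

    def test_type_one_error_calibrated(self):
        """Under a pure-noise null, the interaction test rejects at ~alpha."""
        rng = np.random.default_rng(99)
        n_sims, alpha = 600, 0.05
        rejections = 0
        for _ in range(n_sims):
            res = rm_anova_2x2(rng.standard_normal((8, 4)))
            rejections += res["interaction"].p < alpha
        rate = rejections / n_sims
        assert rate == pytest.approx(alpha, abs=0.03)

    def test_constant_nonzero_contrast_fails(self):
        vals = np.column_stack([np.arange(5.0)] * 3 + [np.arange(5.0) + 1.0])
        with pytest.raises(ValueError, match="zero-variance"):
            rm_anova_2x2(vals)


class TestPairedContrast:
    def test_hand_computed_example(self):
        res = paired_contrast(np.array([2.0, 3, 4, 5]), np.array([1.0, 1, 1, 1]))
        assert res.statistic == pytest.approx(3.873, abs=1e-3)
        assert res.effect_size == pytest.approx(1.936, abs=1e-3)
        assert res.ci[0] < 2.5 < res.ci[1]

    def test_balanced_differences_give_zero(self, rng):
        # mean-zero differences -> t = 0 (a == b exactly is the
        # zero-variance error case, tested below)
        a = rng.standard_normal(6)
        b = a + np.array([0.1, -0.1, 0.1, -0.1, 0.1, -0.1])
        res = paired_contrast(a, b)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        r1, r2 = paired_contrast(a, b), paired_contrast(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.effect_size == pytest.approx(-r2.effect_size)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_contrast(np.array([1.0, 2, 3]), np.array([0.0, 1, 2]))


class TestHolmBonferroni:
    def test_all_ones_reject_nothing(self):
        rej, _ = holm_bonferroni(np.ones(10))
        assert not rej.any()

    def test_single_pvalue_unchanged(self):
        rej, corr = holm_bonferroni([0.04])
        assert rej[0] and corr[0] == pytest.approx(0.04)

    def test_hand_stepped_example(self):
        rej, corr = holm_bonferroni([0.001, 0.02, 0.04])
        assert rej.all()
        assert np.allclose(corr, [0.003, 0.04, 0.04])

    def test_dominates_bonferroni(self, rng):
        """Holm rejections are a superset of plain Bonferroni's on 1000
        random p-vectors."""
        for _ in range(1000):
            m = rng.integers(2, 20)
            p = rng.uniform(0, 0.2, m)
            holm_rej, _ = holm_bonferroni(p)
            bonf_rej = p < 0.05 / m
            assert np.all(holm_rej | ~bonf_rej)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])


class TestEdgeThreshold:
    def _study_matrices(self, scheme, rng, within_mu=0.6, effect=0.0):
        """12-participant z-matrix set: strong within-network baseline plus
        an optional drug-first shift."""
        n = scheme.n_nodes
        idx = scheme.edge_interaction_index(scheme.node_ids)
        iu, ju = np.triu_indices(n, k=1)
        within = np.zeros(len(iu), dtype=bool)
        for net in scheme.networks:
            within[idx[("within", net)]] = True
        mats = {}
        for p in range(12):
            for drug, half in CELLS:
                edges = rng.standard_normal(len(iu)) * 0.1
                edges[within] += within_mu
                if (drug, half) == ("drug", "first"):
                    edges[within] -= effect
                vals = np.full((n, n), np.nan)
                vals[iu, ju] = edges
                vals[ju, iu] = edges
                mats[(f"p{p:02d}", drug, half)] = _zmat(vals, scheme.node_ids)
        return mats, within

    def test_bonferroni_threshold_at_full_scale(self):
        from sdefc import n_edges

        assert 0.05 / n_edges(268) == pytest.approx(1.3975e-6, rel=1e-3)

    def test_all_zero_data_keeps_nothing(self):
        import warnings

        scheme = NetworkScheme.balanced(3, DEFAULT_NETWORKS[:3])
        n = scheme.n_nodes
        vals = np.zeros((n, n))
        np.fill_diagonal(vals, np.nan)
        mats = {(f"p{p}", drug, half): _zmat(vals.copy(), scheme.node_ids)
                for p in range(12) for drug, half in CELLS}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # t of constant zeros is nan
            res = edge_threshold_contrast(mats)
        assert res["stage1_union"].size == 0
        assert all(len(df) == 0 for df in res["stage2"].values())

    def test_within_network_truth_survives(self, rng):
        scheme = NetworkScheme.balanced(3, DEFAULT_NETWORKS[:3])
        mats, within = self._study_matrices(scheme, rng, within_mu=0.6, effect=0.3)
        res = edge_threshold_contrast(mats)
        survivors = res["stage1_union"]
        assert survivors.size >= 9  # all 9 true within-network edges
        # survivors predominantly within-network
        assert within[survivors].mean() >= 0.8
        # the injected drug-first reduction shows in stage 2
        first = res["stage2"]["first"]
        assert (first["direction"] == "drug<placebo").sum() > 0


class TestSummaryAndTMatrix:
    def test_summary_table_shape(self, scheme8, rng):
        mats = {}
        for p in ("p1", "p2", "p3", "p4"):
            for drug, half in CELLS:
                mats[(p, drug, half)] = _filled(scheme8, 0.2, rng)
        summary = network_summary_table(mats, scheme8)
        assert len(summary) == 4 * 4 * 36
        table = anova_table(summary)
        assert len(table) == 36 * 3
        assert (table["corrected_p"] >= table["p"] - 1e-12).all()

    def test_contrast_t_matrix_symmetric(self, scheme8, rng):
        mats = {}
        for p in ("p1", "p2", "p3", "p4", "p5"):
            for drug, half in CELLS:
                mats[(p, drug, half)] = _filled(scheme8, 0.2, rng)
        summary = network_summary_table(mats, scheme8)
        tm = contrast_t_matrix(summary, scheme8, "first")
        assert tm.shape == (8, 8)
        assert np.allclose(tm.to_numpy(), tm.to_numpy().T, equal_nan=True)
        assert np.isfinite(np.diag(tm.to_numpy())).all()


class TestAucAndCorrelation:
    def test_constant_rating_rectangle(self):
        t = [1, 2, 3, 4, 5, 10, 15, 20]
        assert auc_drug_strength(t, [10] * 8) == pytest.approx(190.0)

    def test_zero_ratings(self):
        assert auc_drug_strength([1, 5, 10, 20], [0, 0, 0, 0]) == 0.0

    def test_piecewise_trapezoid(self):
        t = [1, 2, 3, 4, 5, 10, 15, 20]
        r = [10, 10, 10, 10, 10, 0, 0, 0]
        assert auc_drug_strength(t, r) == pytest.approx(65.0)

    def test_truncation_interpolates_at_t_max(self):
        # ratings bracket t_max: curve interpolated at the boundary
        assert auc_drug_strength([1, 10, 30], [10, 10, 10], t_max=20) == pytest.approx(190.0)

    def test_perfect_correlations(self, rng):
        x = rng.standard_normal(12)
        assert change_vs_auc(x, x).statistic == pytest.approx(1.0)
        assert change_vs_auc(x, -x).statistic == pytest.approx(-1.0)

    def test_known_coupling_recovered(self):
        """Mean estimated r over many 12-participant draws recovers a true
        correlation of -0.5."""
        rng = np.random.default_rng(4)
        L = np.linalg.cholesky(np.array([[1.0, -0.5], [-0.5, 1.0]]))
        est = []
        for _ in range(300):
            xy = rng.standard_normal((12, 2)) @ L.T
            est.append(change_vs_auc(xy[:, 0], xy[:, 1]).statistic)
        assert np.mean(est) == pytest.approx(-0.5, abs=0.1)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            change_vs_auc(np.ones(8), rng.standard_normal(8))
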