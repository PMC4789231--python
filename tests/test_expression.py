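"""Normalization, per-probe ANOVA/Tukey, FDR and tier-classification tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import studentized_range

from srfepi import simdata
from srfepi.expression import (
    ClassificationThresholds,
    ExpressionMatrix,
    TIER_COLUMNS,
    bh_fdr,
    classify,
    fit_two_way_anova,
    log2_transform,
    quantile_normalize,
    tier_report,
    validate_sample_sheet,
)


def _matrix(values, scale="linear", columns=None):
    arr = np.asarray(values, dtype=float)
    cols = columns or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])], columns=cols),
        scale=scale,
    )


def _sheet(ns):
    rows = []
    for (g, t), n in ns.items():
        for i in range(n):
            rows.append((f"{g}_{t}_{i}", g, t))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "treatment"])


def _design_matrix(ns):
    cols, data = [], []
    for (g, t), n in ns.items():
        cols += [f"{g}_{t}_{i}" for i in range(n)]
    return cols


class TestQuantileNormalize:
    def test_hand_computed_example(self):
        m = _matrix(np.array([[1, 4], [2, 2], [3, 6]]))
        out = quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out[:, 1], [3.0, 1.5, 4.5])

    def test_identical_columns_are_fixed_points(self):
        col = np.array([5.0, 1.0, 3.0, 2.0])
        m = _matrix(np.column_stack([col, col, col]))
        np.testing.assert_allclose(
            quantile_normalize(m).values.to_numpy(), m.values.to_numpy()
        )

    def test_columns_share_sorted_vector_and_rank_order(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=(50, 6))
        m = _matrix(x)
        out = quantile_normalize(m).values.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, 6):
            np.testing.assert_array_equal(sorted_cols[:, 0], sorted_cols[:, j])
            # within-column rank order preserved
            assert (np.argsort(out[:, j]) == np.argsort(x[:, j])).all()

    def test_rejects_log2_scale_and_single_column(self):
        with pytest.raises(ValueError):
            quantile_normalize(_matrix([[1.0], [2.0]]))
        with pytest.raises(ValueError):
            quantile_normalize(
                ExpressionMatrix(pd.DataFrame({"a": [1.0], "b": [2.0]}), scale="log2")
            )


class TestLog2:
    def test_elementwise_and_round_trip(self):
        m = _matrix([[8.0, 1.0], [2.0, 4.0]])
        out = log2_transform(m)
        assert out.scale == "log2"
        np.testing.assert_allclose(out.values.to_numpy(), [[3, 0], [1, 2]])
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 3))
        np.testing.assert_allclose(
            log2_transform(_matrix(2.0**x)).values.to_numpy(), x
        )

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            _matrix([[1.0, -2.0]])


class TestAnova:
    NS_BALANCED = {("CTR", "saline"): 3, ("CTR", "KA"): 3, ("KO", "saline"): 3, ("KO", "KA"): 3}
    NS_UNBALANCED = {("CTR", "saline"): 3, ("CTR", "KA"): 4, ("KO", "saline"): 2, ("KO", "KA"): 5}

    def _stats_vs_oracle(self, ns, n_probes, seed):
        """Compare against statsmodels OLS (Type II) + scipy studentized range."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(seed)
        sheet = _sheet(ns)
        n = len(sheet)
        y = rng.normal(7.0, 1.0, size=(n_probes, n))
        m = ExpressionMatrix(
            pd.DataFrame(y, index=[f"p{i}" for i in range(n_probes)], columns=sheet["sample_id"]),
            scale="log2",
        )
        stats = fit_two_way_anova(m, sheet)
        dfe = n - 4
        for i in range(n_probes):
            df = sheet.assign(y=y[i])
            fit = smf.ols("y ~ C(genotype) * C(treatment)", data=df).fit()
            tab = anova_lm(fit, typ=2)
            row = stats.iloc[i]
            assert row["F_genotype"] == pytest.approx(tab.loc["C(genotype)", "F"], abs=1e-8)
            assert row["p_genotype"] == pytest.approx(tab.loc["C(genotype)", "PR(>F)"], abs=1e-8)
            assert row["F_treatment"] == pytest.approx(tab.loc["C(treatment)", "F"], abs=1e-8)
            assert row["F_interaction"] == pytest.approx(
                tab.loc["C(genotype):C(treatment)", "F"], abs=1e-8
            )
            assert row["p_interaction"] == pytest.approx(
                tab.loc["C(genotype):C(treatment)", "PR(>F)"], abs=1e-8
            )
            mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
            cells = {
                (g, t): df[(df.genotype == g) & (df.treatment == t)]["y"]
                for g, t in ns
            }
            for col, (c1, c2) in {
                "p_tukey_ctrka_ctrsal": (("CTR", "KA"), ("CTR", "saline")),
                "p_tukey_ctrka_koka": (("CTR", "KA"), ("KO", "KA")),
                "p_tukey_koka_kosal": (("KO", "KA"), ("KO", "saline")),
            }.items():
                d = abs(cells[c1].mean() - cells[c2].mean())
                se = np.sqrt(mse / 2 * (1 / len(cells[c1]) + 1 / len(cells[c2])))
                p_ref = studentized_range.sf(d / se, 4, dfe)
                assert row[col] == pytest.approx(p_ref, abs=1e-8)

    def test_matches_least_squares_oracle_balanced(self):
        self._stats_vs_oracle(self.NS_BALANCED, 25, seed=10)

    def test_matches_least_squares_oracle_unbalanced(self):
        self._stats_vs_oracle(self.NS_UNBALANCED, 25, seed=11)

    def test_pure_main_effect_gives_null_interaction(self):
        # identical values within each cell, pure treatment effect
        sheet = _sheet(self.NS_BALANCED)
        y = np.where(sheet["treatment"].to_numpy() == "KA", 9.0, 7.0)[None, :]
        m = ExpressionMatrix(
            pd.DataFrame(y, index=["p0"], columns=sheet["sample_id"]), scale="log2"
        )
        stats = fit_two_way_anova(m, sheet)
        assert stats.loc["p0", "F_interaction"] == 0.0
        assert stats.loc["p0", "p_interaction"] == pytest.approx(1.0)
        assert bool(stats.loc["p0", "degenerate"])
        # the treatment effect itself is flagged significant (p -> 0)
        assert stats.loc["p0", "p_treatment"] == 0.0

    def test_equal_cell_means_give_tukey_p_one(self):
        sheet = _sheet(self.NS_BALANCED)
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 0.5, 3)
        y = np.zeros(len(sheet))
        for cell in self.NS_BALANCED:
            mask = (sheet.genotype == cell[0]) & (sheet.treatment == cell[1])
            y[mask.to_numpy()] = 7.0 + noise  # same sample values in every cell
        m = ExpressionMatrix(
            pd.DataFrame(y[None, :], index=["p0"], columns=sheet["sample_id"]),
            scale="log2",
        )
        stats = fit_two_way_anova(m, sheet)
        for col in ("p_tukey_ctrka_ctrsal", "p_tukey_ctrka_koka", "p_tukey_koka_kosal"):
            assert stats.loc["p0", col] == pytest.approx(1.0)

    def test_fold_changes_are_geometric(self):
        sheet = _sheet(self.NS_BALANCED)
        y = np.zeros(len(sheet))
        means = {("CTR", "saline"): 7, ("CTR", "KA"): 9, ("KO", "saline"): 7, ("KO", "KA"): 7}
        rng = np.random.default_rng(3)
        for cell, mu in means.items():
            mask = ((sheet.genotype == cell[0]) & (sheet.treatment == cell[1])).to_numpy()
            y[mask] = mu + rng.normal(0, 1e-9, mask.sum())
        m = ExpressionMatrix(
            pd.DataFrame(y[None, :], index=["p0"], columns=sheet["sample_id"]), scale="log2"
        )
        stats = fit_two_way_anova(m, sheet)
        assert stats.loc["p0", "fc_ctr"] == pytest.approx(4.0)
        assert stats.loc["p0", "fc_geno"] == pytest.approx(0.25)
        assert stats.loc["p0", "fc_ko"] == pytest.approx(1.0)
        # FC_geno is the reciprocal of the CTR-KA / KO-KA fold
        assert stats.loc["p0", "fc_geno"] == pytest.approx(
            1.0 / 2 ** (stats.loc["p0", "mean_ctr_ka"] - stats.loc["p0", "mean_ko_ka"])
        )

    def test_requires_two_samples_per_cell(self):
        ns = dict(self.NS_BALANCED)
        ns[("KO", "KA")] = 1
        sheet = _sheet(ns)
        y = np.zeros((1, len(sheet)))
        m = ExpressionMatrix(
            pd.DataFrame(y, index=["p0"], columns=sheet["sample_id"]), scale="log2"
        )
        with pytest.raises(ValueError):
            fit_two_way_anova(m, sheet)

    def test_empty_cell_rejected(self):
        sheet = _sheet({("CTR", "saline"): 2, ("CTR", "KA"): 2, ("KO", "saline"): 2})
        with pytest.raises(ValueError):
            validate_sample_sheet(sheet)


class TestBhFdr:
    def test_hand_computed_examples(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30)
    )
    def test_stepup_properties(self, ps):
        q = bh_fdr(ps)
        assert (q >= np.asarray(ps) - 1e-15).all()
        assert (q <= 1.0 + 1e-15).all()
        # monotone in p-value rank
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()


def _stats_row(**kw):
    base = dict(
        mean_ctr_saline=7, mean_ctr_ka=7, mean_ko_saline=7, mean_ko_ka=7,
        F_genotype=0, p_genotype=1, F_treatment=0, p_treatment=1,
        F_interaction=0, p_interaction=1, q_interaction=1,
        p_tukey_ctrka_ctrsal=1, p_tukey_ctrka_koka=1, p_tukey_koka_kosal=1,
        fc_ctr=1.0, fc_geno=1.0, fc_ko=1.0, degenerate=False,
    )
    base.update(kw)
    return base


class TestClassify:
    def test_thresholds_are_strict(self):
        stats = pd.DataFrame(
            [_stats_row(fc_ctr=1.5, p_tukey_ctrka_ctrsal=0.001)], index=["p0"]
        )
        cls = classify(stats)
        assert not cls.probes.loc["p0", "ka_responsive"]

    def test_all_filters_cleared(self):
        stats = pd.DataFrame(
            [
                _stats_row(
                    fc_ctr=4.0, fc_geno=0.25,
                    p_tukey_ctrka_ctrsal=1e-6, p_tukey_ctrka_koka=1e-6,
                    p_interaction=1e-8, q_interaction=0.001,
                )
            ],
            index=["p0"],
        )
        row = classify(stats).probes.loc["p0"]
        assert row["srf_dependent_up"] and row["heatmap_up"]
        assert row["ka_responsive"] and row["genotype_differential"]
        assert not row["srf_dependent_down"]

    def test_tier_nesting_invariants_on_simulation(self):
        cfg = simdata.SimConfig(seed=9, n_probes=400, n_planted_up=12, n_planted_down=8)
        sim = simdata.simulate_expression(cfg)
        logged = log2_transform(quantile_normalize(sim.matrix))
        cls = classify(fit_two_way_anova(logged, sim.sample_sheet), sim.probe_gene_map)
        p = cls.probes
        assert not (p["srf_dependent_up"] & p["srf_dependent_down"]).any()
        assert (p["heatmap_up"] <= p["srf_dependent_up"]).all()
        assert (p["heatmap_down"] <= p["srf_dependent_down"]).all()

    def test_unmapped_probe_retained_and_flagged(self):
        stats = pd.DataFrame([_stats_row(), _stats_row()], index=["p0", "p1"])
        cls = classify(stats, pd.Series({"p0": "gene_a"}))
        assert bool(cls.probes.loc["p1", "unmapped"])
        assert list(cls.genes.index) == ["gene_a"]

    def test_planted_classification_matches_truth(self):
        cfg = simdata.SimConfig(seed=21, n_probes=1200, n_planted_up=40, n_planted_down=25)
        sim = simdata.simulate_expression(cfg)
        logged = log2_transform(quantile_normalize(sim.matrix))
        cls = classify(fit_two_way_anova(logged, sim.sample_sheet), sim.probe_gene_map)
        up = set(cls.probes.index[cls.probes["srf_dependent_up"]])
        down = set(cls.probes.index[cls.probes["srf_dependent_down"]])
        assert up == set(sim.truth.index[sim.truth == "up"])
        assert down == set(sim.truth.index[sim.truth == "down"])


class TestTierReport:
    def _fake_classification(self, n_ka, n_both):
        n = max(n_ka, 1)
        probes = pd.DataFrame(
            {c: np.zeros(n, dtype=bool) for c in TIER_COLUMNS},
            index=[f"p{i}" for i in range(n)],
        )
        probes.loc[probes.index[:n_ka], "ka_responsive"] = True
        probes.loc[probes.index[:n_both], "genotype_differential"] = True
        probes.insert(0, "gene_id", probes.index)
        probes["unmapped"] = False
        genes = probes.groupby("gene_id")[list(TIER_COLUMNS)].any()
        from srfepi.expression import ClassificationResult

        return ClassificationResult(probes=probes, genes=genes)

    def test_remainder_of_printed_pool_sizes(self):
        report = tier_report(self._fake_classification(3241, 729))
        assert report["remainder_count"] == 2512
        assert report["remainder_pct"] == 77.5

    def test_zero_remainder(self):
        report = tier_report(self._fake_classification(10, 10))
        assert report["remainder_count"] == 0
        assert report["remainder_pct"] == 0.0

    def test_disjoint_and_empty(self):
        report = tier_report(self._fake_classification(4, 0))
        assert report["remainder_count"] == 4
        assert report["remainder_pct"] == 100.0
        report = tier_report(self._fake_classification(0, 0))
        assert report["remainder_pct"] is None


def test_null_simulation_controls_false_srf_calls():
    """Under the global null, SRF-dependent calls stay within the FDR level."""
    fdps = []
    for seed in range(50):
        cfg = simdata.SimConfig(
            seed=1000 + seed, n_probes=400, n_planted_up=0, n_planted_down=0
        )
        sim = simdata.simulate_expression(cfg)
        logged = log2_transform(sim.matrix)
        stats = fit_two_way_anova(logged, sim.sample_sheet)
        cls = classify(stats, sim.probe_gene_map)
        n_calls = int(
            (cls.probes["srf_dependent_up"] | cls.probes["srf_dependent_down"]).sum()
        )
        fdps.append(1.0 if n_calls else 0.0)  # every call is false under the null
    mean_fdp = float(np.mean(fdps))
    mc_se = float(np.std(fdps, ddof=1) / np.sqrt(len(fdps))) if np.std(fdps) else 0.0
    assert mean_fdp <= 0.01 + 3 * mc_se
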