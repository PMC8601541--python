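import numpy as np
import pandas as pd
import pytest
from itertools import combinations
from scipy import stats as sps

import microbench as mb
from microbench.design import build_design
from microbench.otu import benjamini_hochberg, _fit_pls, _vip_from_pls


def _df(arr, prefix="o"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestRankTable:
    def test_average_ties(self):
        stats = pd.Series([0.001, 0.5, 0.001], index=list("abc"))
        rt = mb.rank_table(stats, "lower")
        assert list(rt.table["rank"]) == [1.5, 3.0, 1.5]

    def test_p_threshold_flags(self):
        stats = pd.Series([0.005, 0.02], index=list("ab"))
        rt = mb.rank_table(stats, "lower", p_threshold=0.01)
        assert list(rt.table["significant"]) == [True, False]

    def test_higher_polarity_rank_order(self):
        stats = pd.Series([5.0, 1.0, 3.0], index=list("abc"))
        rt = mb.rank_table(stats, "higher")
        assert list(rt.table["rank"]) == [1.0, 3.0, 2.0]

    def test_missing_statistic_errors(self):
        stats = pd.Series([0.1, np.nan], index=list("ab"))
        with pytest.raises(ValueError, match="b"):
            mb.rank_table(stats, "lower")


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    p = rng.uniform(size=25)
    ours = benjamini_hochberg(p)
    ref = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, ref, atol=1e-12)


class TestSimper:
    def test_symmetric_disjoint_case(self):
        rel = _df([[1, 0], [1, 0], [0, 1], [0, 1]])
        groups = pd.Series(["A", "A", "B", "B"], index=rel.index)
        rt = mb.simper(rel, groups, ("A", "B"), n_perm=19, seed=0)
        assert np.allclose(rt.table["contribution"], 0.5)

    def test_contributions_decompose_mean_bray_curtis(self):
        rng = np.random.default_rng(2)
        rel = _df(rng.dirichlet(np.ones(6), size=8))
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=rel.index)
        rt = mb.simper(rel, groups, ("A", "B"), n_perm=9, seed=0)
        bc = mb.distance(rel, "bray-curtis").values
        mean_bc = bc[:4, 4:].mean()
        assert rt.table["contribution"].sum() == pytest.approx(mean_bc, abs=1e-9)

    def test_exact_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(4)
        rel = _df(rng.dirichlet(np.ones(4), size=6))
        groups = pd.Series(list("AAABBB"), index=rel.index)
        rt = mb.simper(rel, groups, ("A", "B"), n_perm="exact")
        X = rel.to_numpy()

        def contrib(a_idx):
            b_idx = [i for i in range(6) if i not in a_idx]
            vals = []
            for k in a_idx:
                for l in b_idx:
                    vals.append(np.abs(X[k] - X[l]) / (X[k].sum() + X[l].sum()))
            return np.mean(vals, axis=0)

        obs = contrib((0, 1, 2))
        ge = np.zeros(4)
        count = 0
        for c in combinations(range(6), 3):
            ge += contrib(c) >= obs - 1e-15
            count += 1
        p_oracle = ge / count
        assert np.allclose(rt.table["statistic"].to_numpy(), p_oracle, atol=1e-12)

    def test_small_group_errors(self):
        rel = _df([[1, 0], [0, 1], [0.5, 0.5]])
        groups = pd.Series(["A", "B", "B"], index=rel.index)
        with pytest.raises(ValueError):
            mb.simper(rel, groups, ("A", "B"))


class TestRotation:
    def _one_factor(self, n=12, m=5, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        meta = pd.DataFrame({"g": ["A"] * (n // 2) + ["B"] * (n // 2)}, index=idx)
        X = rng.normal(size=(n, m))
        X[: n // 2, 0] += shift
        return pd.DataFrame(X, index=idx), meta

    def test_single_otu_raw_p_is_classical_anova(self):
        X, meta = self._one_factor(m=1, seed=1, shift=1.0)
        D = build_design(meta, "g")
        rt = mb.rotation_pvalues(X, D, "g", n_rot=49, seed=0)
        ref = sps.f_oneway(X.iloc[:6, 0], X.iloc[6:, 0]).pvalue
        assert rt.table["statistic"].iloc[0] == pytest.approx(ref, rel=1e-9)

    def test_adjusted_geq_raw(self):
        X, meta = self._one_factor(m=8, seed=2, shift=1.5)
        D = build_design(meta, "g")
        rt = mb.rotation_pvalues(X, D, "g", n_rot=199, seed=0)
        assert (rt.table["adj_p"] >= rt.table["statistic"] - 1e-12).all()

    def test_null_raw_pvalues_uniform(self):
        # pooled raw p-values over repeated null draws are U(0,1)
        ps = []
        for k in range(60):
            X, meta = self._one_factor(m=6, seed=100 + k)
            D = build_design(meta, "g")
            rt = mb.rotation_pvalues(X, D, "g", n_rot=9, seed=k)
            ps.extend(rt.table["statistic"])
        stat = sps.kstest(ps, "uniform")
        assert stat.pvalue > 0.01

    def test_adjusts_for_nuisance_terms(self):
        # a strong nuisance (dose) effect must not inflate the diet term
        rng = np.random.default_rng(3)
        idx = [f"s{i}" for i in range(16)]
        meta = pd.DataFrame({"diet": list("AB") * 8,
                             "dose": ["lo"] * 8 + ["hi"] * 8}, index=idx)
        X = rng.normal(size=(16, 5))
        X[np.asarray(meta["dose"] == "hi")] += 5.0
        D = build_design(meta, "diet + dose")
        rt = mb.rotation_pvalues(pd.DataFrame(X, index=idx), D, "diet",
                                 n_rot=49, seed=0)
        assert (rt.table["statistic"] > 0.01).all()


class TestPls:
    def test_vip_normalization(self):
        rng = np.random.default_rng(5)
        X = _df(rng.normal(size=(20, 12)))
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=X.index)
        vip, _ = mb.plsda_vip(X, labels, ("A", "B"), n_components=3)
        assert (vip ** 2).sum() == pytest.approx(12, abs=1e-6)

    def test_informative_variable_has_max_vip(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(24, 10))
        y = np.array([1.0] * 12 + [-1.0] * 12)
        X[:, 4] += 2 * y
        Xdf = _df(X)
        labels = pd.Series(np.where(y > 0, "A", "B"), index=Xdf.index)
        vip, coef = mb.plsda_vip(Xdf, labels, ("A", "B"), n_components=1)
        assert vip.idxmax() == "o4"
        assert coef.abs().idxmax() == "o4"

    def test_one_component_vip_closed_form(self):
        # with one component VIP_j = sqrt(m) * |w_j| / ||w|| and the PLS
        # weight vector is proportional to X_c' y_c
        X = _df([[1.0, 0.5, 0.2], [2.0, 0.1, 0.4], [3.0, 0.9, 0.1], [4.0, 0.3, 0.6]])
        labels = pd.Series(["A", "A", "B", "B"], index=X.index)
        y = np.array([1.0, 1.0, -1.0, -1.0])
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        w = Xc.T @ (y - y.mean())
        expected = np.sqrt(3) * np.abs(w) / np.linalg.norm(w)
        vip, _ = mb.plsda_vip(X, labels, ("A", "B"), n_components=1)
        assert np.allclose(vip.to_numpy(), expected, atol=1e-9)

    def test_component_truncation_warns(self, caplog):
        rng = np.random.default_rng(7)
        X = _df(rng.normal(size=(4, 6)))
        labels = pd.Series(["A", "A", "B", "B"], index=X.index)
        with caplog.at_level("WARNING", logger="microbench"):
            mb.plsda_vip(X, labels, ("A", "B"), n_components=10)
        assert any("truncated" in r.message for r in caplog.records)


class TestUve:
    def test_deterministic_in_seed(self):
        rng = np.random.default_rng(8)
        X = _df(rng.normal(size=(16, 10)))
        labels = pd.Series(["A"] * 8 + ["B"] * 8, index=X.index)
        a = mb.uve_select(X, labels, ("A", "B"), n_rep=10, seed=3, n_components=2)
        b = mb.uve_select(X, labels, ("A", "B"), n_rep=10, seed=3, n_components=2)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_pure_noise_selects_nothing(self):
        rng = np.random.default_rng(9)
        X = _df(rng.normal(size=(16, 15)))
        labels = pd.Series(["A"] * 8 + ["B"] * 8, index=X.index)
        rt = mb.uve_select(X, labels, ("A", "B"), n_rep=30, seed=0, n_components=2)
        assert rt.significant.sum() == 0

    def test_planted_strong_effect_selected(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 15))
        X[:10, 3] += 4.0
        Xdf = _df(X)
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=Xdf.index)
        rt = mb.uve_select(Xdf, labels, ("A", "B"), n_rep=40, seed=0, n_components=2)
        assert rt.table.loc["o3", "selection_freq"] >= 0.95
        assert rt.table.loc["o3", "significant"]


class TestAncom:
    def _shifted(self, m=6, n=20, shift=3.0, seed=11):
        rng = np.random.default_rng(seed)
        L = rng.normal(0.0, 0.1, size=(n, m))
        L[n // 2:, 0] += shift  # only OTU 0 changes between the groups
        X = np.exp(L)
        rel = X / X.sum(axis=1, keepdims=True)
        labels = pd.Series(["A"] * (n // 2) + ["B"] * (n // 2),
                           index=[f"s{i}" for i in range(n)])
        return _df(rel), labels

    def test_single_shifted_otu_w_construction(self):
        rel, labels = self._shifted()
        rt = mb.ancom_w(rel, labels)
        W = rt.table["statistic"]
        m = rel.shape[1]
        assert W["o0"] == m - 1
        assert (W.drop("o0") == 1).all()

    def test_matches_pairwise_brute_force(self):
        rel, labels = self._shifted(m=5, shift=1.0, seed=12)
        rt = mb.ancom_w(rel, labels)
        L = np.log(rel.to_numpy())
        m = rel.shape[1]
        W = np.zeros(m, dtype=int)
        for i in range(m):
            ps = []
            for j in range(m):
                if j == i:
                    continue
                y = L[:, i] - L[:, j]
                ps.append(sps.f_oneway(y[:10], y[10:]).pvalue)
            q = benjamini_hochberg(np.asarray(ps))
            W[i] = int((q <= 0.05).sum())
        assert np.array_equal(rt.table["statistic"].to_numpy().astype(int), W)

    def test_w_bounds(self):
        rel, labels = self._shifted(m=7, shift=0.5, seed=13)
        rt = mb.ancom_w(rel, labels)
        W = rt.table["statistic"]
        assert ((W >= 0) & (W <= rel.shape[1] - 1)).all()

    def test_invariant_to_per_sample_scaling(self):
        rel, labels = self._shifted(seed=14)
        scales = np.random.default_rng(0).uniform(0.5, 3.0, size=rel.shape[0])
        scaled = rel.mul(scales, axis=0)
        a = mb.ancom_w(rel, labels)
        b = mb.ancom_w(scaled, labels)
        assert np.allclose(a.table["statistic"], b.table["statistic"])

    def test_requires_three_otus(self):
        rel, labels = self._shifted(m=2)
        with pytest.raises(ValueError):
            mb.ancom_w(rel, labels)


class TestDirichletClr:
    def _toy(self, scale=1, n=10, m=6, seed=15):
        rng = np.random.default_rng(seed)
        counts = rng.integers(5, 200, size=(n, m)) * scale
        counts[: n // 2, 0] *= 4
        idx = [f"s{i}" for i in range(n)]
        meta = pd.DataFrame({"g": ["A"] * (n // 2) + ["B"] * (n // 2)}, index=idx)
        return pd.DataFrame(counts, index=idx, columns=[f"o{j}" for j in range(m)]), meta

    def test_concentrates_to_point_estimate_p(self):
        counts, meta = self._toy(scale=1000)
        D = build_design(meta, "g")
        rt = mb.dirichlet_clr_test(counts, D, n_mc=64, seed=0)
        # oracle: classical F-test on the clr of the posterior-mean composition
        comp = (counts + 0.5).div((counts + 0.5).sum(axis=1), axis=0)
        Z = np.log(comp) - np.log(comp).mean(axis=1).to_numpy()[:, None]
        ps = [sps.f_oneway(Z.iloc[:5, j], Z.iloc[5:, j]).pvalue
              for j in range(counts.shape[1])]
        assert np.allclose(rt.table["statistic"], ps, atol=0.01)

    def test_bh_geq_raw(self):
        counts, meta = self._toy()
        D = build_design(meta, "g")
        rt = mb.dirichlet_clr_test(counts, D, n_mc=32, seed=1)
        assert (rt.table["expected_bh_p"] >= rt.table["statistic"] - 1e-12).all()

    def test_deterministic_in_seed(self):
        counts, meta = self._toy()
        D = build_design(meta, "g")
        a = mb.dirichlet_clr_test(counts, D, n_mc=16, seed=7)
        b = mb.dirichlet_clr_test(counts, D, n_mc=16, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestNbGlm:
    def test_size_factors_hand_example(self):
        counts = pd.DataFrame(
            {"o1": [2, 4, 6, 8], "o2": [4, 8, 12, 16]},
            index=[f"s{i}" for i in range(4)],
        )
        sf = mb.size_factors(counts)
        expected = np.array([1, 2, 3, 4], dtype=float)
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(sf.to_numpy(), expected, atol=1e-12)

    def test_size_factor_fallback_without_allpositive_otu(self, caplog):
        counts = pd.DataFrame(
            {"o1": [0, 4, 6, 8], "o2": [4, 0, 12, 16], "o3": [3, 5, 0, 9]},
            index=[f"s{i}" for i in range(4)],
        )
        with caplog.at_level("WARNING", logger="microbench"):
            sf = mb.size_factors(counts)
        assert np.all(np.isfinite(sf))
        assert any("positive" in r.message for r in caplog.records)

    def test_identical_groups_null_behavior(self):
        rng = np.random.default_rng(16)
        idx = [f"s{i}" for i in range(20)]
        counts = pd.DataFrame(rng.poisson(50, size=(20, 8)), index=idx,
                              columns=[f"o{j}" for j in range(8)])
        meta = pd.DataFrame({"g": ["A"] * 10 + ["B"] * 10}, index=idx)
        rt = mb.nbglm_test(counts, meta, "g", contrast=("g", "A", "B"))
        assert rt.table["log2fc"].abs().mean() < 0.2
        assert rt.table["statistic"].min() > 0.001

    def test_zero_dispersion_limit_matches_poisson_wald(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        idx = [f"s{i}" for i in range(16)]
        counts = pd.DataFrame(rng.poisson(30, size=(16, 4)), index=idx,
                              columns=[f"o{j}" for j in range(4)])
        counts.iloc[:8, 0] = rng.poisson(60, size=8)
        meta = pd.DataFrame({"g": ["A"] * 8 + ["B"] * 8}, index=idx)
        rt = mb.nbglm_test(counts, meta, "g", contrast=("g", "A", "B"),
                           dispersion=1e-10)
        sf = mb.size_factors(counts).to_numpy()
        n = 16
        D = build_design(meta, "g")
        X = np.hstack([np.ones((n, 1)) / np.sqrt(n), D.sequential_basis(0)])
        c = X[:8].mean(axis=0) - X[8:].mean(axis=0)
        for j, otu in enumerate(counts.columns):
            res = sm.GLM(counts[otu].to_numpy(dtype=float), X,
                         family=sm.families.Poisson(),
                         offset=np.log(sf)).fit()
            z = (c @ res.params) / np.sqrt(c @ res.cov_params() @ c)
            p_ref = 2 * sps.norm.sf(abs(z))
            assert rt.table.loc[otu, "statistic"] == pytest.approx(p_ref, abs=1e-5)

    def test_wald_matches_statsmodels_nb_at_fixed_dispersion(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(18)
        idx = [f"s{i}" for i in range(20)]
        lam = rng.gamma(2.0, 20.0, size=(20, 5))
        counts = pd.DataFrame(rng.poisson(lam), index=idx,
                              columns=[f"o{j}" for j in range(5)])
        meta = pd.DataFrame({"g": ["A"] * 10 + ["B"] * 10}, index=idx)
        rt = mb.nbglm_test(counts, meta, "g", contrast=("g", "A", "B"),
                           dispersion=0.5)
        sf = mb.size_factors(counts).to_numpy()
        D = build_design(meta, "g")
        X = np.hstack([np.ones((20, 1)) / np.sqrt(20), D.sequential_basis(0)])
        c = X[:10].mean(axis=0) - X[10:].mean(axis=0)
        for otu in counts.columns:
            res = sm.GLM(counts[otu].to_numpy(dtype=float), X,
                         family=sm.families.NegativeBinomial(alpha=0.5),
                         offset=np.log(sf)).fit()
            z_ref = (c @ res.params) / np.sqrt(c @ res.cov_params() @ c)
            assert rt.table.loc[otu, "wald_z"] == pytest.approx(z_ref, abs=1e-4)
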