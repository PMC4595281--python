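"""Statistical layer: ANOVA oracles, t/Wilcoxon, stepwise, permutation FWE."""

import numpy as np
import pandas as pd
import pytest

from hemiscope import (
    BetaVolume,
    one_sample_wilcoxon,
    rm_anova,
    stepwise_regression,
    t_tests,
    voxelwise_group_ttest,
)


def tidy(Y, within_levels, groups=None):
    """Long-format table from a subjects x cells matrix."""
    rows = []
    n, L = Y.shape
    cells = [(i, j) for i in range(within_levels[0]) for j in range(within_levels[1])]
    for s in range(n):
        for c, (i, j) in enumerate(cells):
            rows.append(
                dict(
                    subject=f"S{s}",
                    A=f"a{i}",
                    B=f"b{j}",
                    group=(groups[s] if groups is not None else "all"),
                    y=Y[s, c],
                )
            )
    return pd.DataFrame(rows)


def yates_within_oracle(X):
    """Independent sums-of-squares for a two-way within design.

    X has shape (subjects, a, b); returns {effect: (F, df1, df2)} computed
    from the classical mean decompositions.
    """
    n, a, b = X.shape
    gm = X.mean()
    m_s = X.mean(axis=(1, 2))
    m_a = X.mean(axis=(0, 2))
    m_b = X.mean(axis=(0, 1))
    m_sa = X.mean(axis=2)
    m_sb = X.mean(axis=1)
    m_ab = X.mean(axis=0)
    ss_a = n * b * ((m_a - gm) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2).sum()
    ss_b = n * a * ((m_b - gm) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    resid = (
        X
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - gm
    )
    ss_abs = (resid**2).sum()
    return {
        "A": (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1))),
        "B": (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1))),
        "A:B": (
            (ss_ab / ((a - 1) * (b - 1)))
            / (ss_abs / ((a - 1) * (b - 1) * (n - 1)))
        ),
    }


class TestRmAnova:
    def test_matches_yates_oracle_to_six_decimals(self, rng):
        n, a, b = 8, 3, 4
        X = rng.normal(size=(n, a, b)) + rng.normal(size=(n, 1, 1))
        table = tidy(X.reshape(n, a * b), (a, b))
        got = {r.effect: r.F for r in rm_anova(table, "y", ["A", "B"])}
        expected = yates_within_oracle(X)
        for eff, f_exp in expected.items():
            assert got[eff] == pytest.approx(f_exp, abs=1e-6), eff

    def test_matches_pingouin_mixed_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        n, a = 12, 4
        Y = rng.normal(size=(n, a))
        groups = ["patient"] * 6 + ["control"] * 6
        rows = [
            dict(subject=f"S{s}", w=f"l{j}", group=groups[s], y=Y[s, j])
            for s in range(n)
            for j in range(a)
        ]
        df = pd.DataFrame(rows)
        mine = {
            r.effect: (r.F, r.p)
            for r in rm_anova(df, "y", ["w"], between="group")
        }
        aov = pg.mixed_anova(
            data=df, dv="y", within="w", subject="subject", between="group"
        ).set_index("Source")
        for src, eff in [("group", "group"), ("w", "w"), ("Interaction", "group:w")]:
            assert mine[eff][0] == pytest.approx(aov.loc[src, "F"], abs=1e-6)
            assert mine[eff][1] == pytest.approx(aov.loc[src, "p_unc"], abs=1e-6)

    def test_group_interaction_invariant_to_subject_constants(self, rng):
        n, a = 10, 3
        Y = rng.normal(size=(n, a))
        groups = ["p"] * 5 + ["c"] * 5
        rows = lambda mat: pd.DataFrame(
            [
                dict(subject=f"S{s}", w=f"l{j}", group=groups[s], y=mat[s, j])
                for s in range(n)
                for j in range(a)
            ]
        )
        f1 = {r.effect: r.F for r in rm_anova(rows(Y), "y", ["w"], between="group")}
        shifted = Y + rng.normal(size=(n, 1)) * 10
        f2 = {
            r.effect: r.F
            for r in rm_anova(rows(shifted), "y", ["w"], between="group")
        }
        assert f1["group:w"] == pytest.approx(f2["group:w"])
        assert f1["w"] == pytest.approx(f2["w"])

    def test_constant_dv_warns_with_zero_f(self):
        df = pd.DataFrame(
            [
                dict(subject=f"S{s}", w=f"l{j}", y=1.0)
                for s in range(4)
                for j in range(3)
            ]
        )
        with pytest.warns(UserWarning, match="zero error variance"):
            res = rm_anova(df, "y", ["w"])
        assert all(r.F == 0.0 for r in res)

    def test_missing_cells_listed(self):
        df = pd.DataFrame(
            [
                dict(subject=f"S{s}", w=f"l{j}", y=float(s + j))
                for s in range(4)
                for j in range(3)
            ]
        )
        df = df[~((df.subject == "S2") & (df.w == "l1"))]
        with pytest.raises(ValueError, match="S2"):
            rm_anova(df, "y", ["w"])

    def test_gg_correction_shrinks_dfs(self, rng):
        n, a = 10, 5
        base = rng.normal(size=(n, 1))
        Y = base + rng.normal(size=(n, a)) * np.linspace(0.2, 3.0, a)
        df = pd.DataFrame(
            [
                dict(subject=f"S{s}", w=f"l{j}", y=Y[s, j])
                for s in range(n)
                for j in range(a)
            ]
        )
        plain = {r.effect: r for r in rm_anova(df, "y", ["w"])}
        gg = {r.effect: r for r in rm_anova(df, "y", ["w"], gg_correction=True)}
        assert gg["w"].df_num < plain["w"].df_num
        assert gg["w"].F == pytest.approx(plain["w"].F)


class TestTTests:
    def test_identical_samples_paired_t_zero(self):
        t, df, p = t_tests(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]), paired=True)
        assert t == 0.0 and p == 1.0

    def test_one_sample_at_null_value(self):
        t, df, p = t_tests(np.array([1.0, 2.0, 3.0]), mu=2.0)
        assert t == 0.0 and df == 2

    def test_independent_matches_hand_computation(self):
        # means 2.5 vs 5, pooled variance 25/6 -> t = -sqrt(3) exactly
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0, 8.0])
        t, df, p = t_tests(a, b)
        assert t == pytest.approx(-np.sqrt(3.0), abs=1e-4)
        assert df == 6

    def test_missing_values_dropped_pairwise(self):
        a = np.array([1.0, np.nan, 3.0, 4.0])
        b = np.array([1.0, 2.0, np.nan, 4.0])
        t, df, p = t_tests(a, b, paired=True)
        assert df == 1  # only 2 complete pairs

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            t_tests(np.array([np.nan, np.nan]))


class TestWilcoxon:
    def test_symmetric_sample_large_p(self):
        x = np.array([-3.0, -2, -1, 1, 2, 3]) + 10.0
        _, p = one_sample_wilcoxon(x, 10.0)
        assert p > 0.5

    def test_uniform_deficit_tiny_p(self):
        x = 50.0 - np.arange(1.0, 21.0)  # all strictly below 57
        _, p = one_sample_wilcoxon(x, 57.0)
        assert p == pytest.approx(2.0 / 2**20, rel=1e-6)  # exact enumeration

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            one_sample_wilcoxon(np.full(5, 57.0), 57.0)


def forward_selection_oracle(X, y, p_enter):
    """Exhaustive forward enumeration via statsmodels partial t-tests."""
    import statsmodels.api as sm

    model = []
    while True:
        best, best_p = None, np.inf
        for j in range(X.shape[1]):
            if j in model:
                continue
            design = sm.add_constant(X[:, model + [j]])
            fit = sm.OLS(y, design).fit()
            p = fit.pvalues[-1]
            if p < best_p:
                best, best_p = j, p
        if best is None or best_p >= p_enter:
            return model
        model.append(best)


class TestStepwise:
    def test_planted_predictor_selected_exactly(self, rng):
        X = rng.normal(size=(30, 4))
        y = 2.0 * X[:, 2] + rng.normal(0, 0.5, 30)
        res = stepwise_regression(X, y)
        assert res.selected == ["x2"]
        assert res.coefficients["x2"] == pytest.approx(2.0, abs=0.3)
        assert all(p < 0.05 for p in res.pvalues.values())

    def test_matches_forward_enumeration_oracle(self, rng):
        for trial in range(5):
            X = rng.normal(size=(25, 4))
            beta = np.array([1.5, 0.0, 0.8, 0.0])
            y = X @ beta + rng.normal(0, 1.0, 25)
            # p_out = p_in degenerates to pure forward selection
            res = stepwise_regression(X, y, p_in=0.05, p_out=0.05)
            oracle = forward_selection_oracle(X, y, p_enter=0.05)
            assert res.selected == [f"x{j}" for j in oracle]

    def test_permissive_thresholds_saturate(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        res = stepwise_regression(X, y, p_in=1.0, p_out=1.0)
        assert sorted(res.selected) == ["x0", "x1", "x2"]

    def test_collinear_candidate_skipped(self, rng):
        x0 = rng.normal(size=25)
        X = np.column_stack([x0, x0 * 2.0, rng.normal(size=25)])
        y = 3.0 * x0 + rng.normal(0, 0.5, 25)
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_regression(X, y)
        assert "x0" in res.selected and "x1" not in res.selected

    def test_zero_variance_outcome_gives_empty_model(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.warns(UserWarning, match="zero variance"):
            res = stepwise_regression(X, np.full(20, 57.0))
        assert res.selected == []


class TestVoxelwise:
    @staticmethod
    def _volumes(rng, n, shape=(6, 6, 6), shift=0.0, mask=None):
        out = []
        for i in range(n):
            data = rng.normal(size=shape)
            if shift and mask is not None:
                data[mask] += shift
            out.append(BetaVolume(data=data, affine=np.diag([2.0, 2, 2, 1])))
        return out

    def test_identical_groups_empty_map(self, rng):
        vols = self._volumes(rng, 6)
        vols = vols + [BetaVolume(v.data.copy(), v.affine.copy()) for v in vols]
        groups = ["a"] * 6 + ["b"] * 6
        res = voxelwise_group_ttest(vols, groups, fwhm_mm=0, n_perm=100, seed=0)
        assert not res.sig_mask.any()
        assert np.all(res.tmap == 0)

    def test_planted_effect_survives_correction(self, rng):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        a = self._volumes(rng, 8, shift=5.0, mask=mask)
        b = self._volumes(rng, 8)
        res = voxelwise_group_ttest(
            a + b, ["a"] * 8 + ["b"] * 8, fwhm_mm=0, n_perm=300, seed=1
        )
        assert res.sig_mask[mask].any()
        assert res.metadata["correction"].startswith("permutation")

    def test_familywise_error_controlled_under_null(self):
        # exchangeable null: any-voxel rejection rate stays near alpha
        rng = np.random.default_rng(7)
        n_rep, hits = 500, 0
        for _ in range(n_rep):
            vols = self._volumes(rng, 10, shape=(5, 5, 5))
            res = voxelwise_group_ttest(
                vols, ["a"] * 5 + ["b"] * 5, fwhm_mm=0, n_perm=100,
                alpha=0.05, seed=int(rng.integers(2**31)),
            )
            hits += res.sig_mask.any()
        assert hits / n_rep <= 0.05 + 0.02

    def test_grid_mismatch_rejected(self, rng):
        vols = self._volumes(rng, 2) + self._volumes(rng, 2, shape=(5, 5, 5))
        with pytest.raises(ValueError, match="common grid"):
            voxelwise_group_ttest(vols, ["a", "a", "b", "b"], n_perm=100)
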