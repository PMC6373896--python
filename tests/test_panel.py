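"""Within-between estimator algebra, equivalences and inference."""

import numpy as np
import pandas as pd
import pytest

from affectprice.panel import (
    DesignSpec,
    ModelFit,
    RankError,
    SpecificationError,
    decompose_within_between,
    fit_correlated_re,
    fit_fixed_effects,
    fit_pooled_ols,
    fit_random_effects,
    fit_wb_random,
    wald_equal_effects,
)
from affectprice.synthetic import simulate_panel

SPEC = DesignSpec(outcome="theta", level1=("alcohol_gday", "ln_income"))


@pytest.fixture(scope="module")
def panel():
    return simulate_panel(800, 2, sigma_v=0.5, sigma_eps=0.5, mundlak_rho=0.3, seed=2)


class TestDecomposition:
    def test_two_wave_arithmetic(self):
        df = pd.DataFrame(
            {"participant_id": [0, 0], "theta": [0.0, 1.0], "alcohol_gday": [10.0, 20.0],
             "ln_income": [10.0, 10.5]}
        )
        aug = decompose_within_between(df, SPEC)
        assert aug["alcohol_gday:within"].tolist() == [-5.0, 5.0]
        assert aug["alcohol_gday:between"].tolist() == [15.0, 15.0]

    def test_demeaned_columns_sum_to_zero_within_clusters(self, panel):
        aug = decompose_within_between(panel, SPEC)
        sums = aug.groupby("participant_id")["alcohol_gday:within"].sum()
        assert np.abs(sums).max() < 1e-9

    def test_within_orthogonal_to_between_within_clusters(self, panel):
        aug = decompose_within_between(panel, SPEC)
        dots = (aug["alcohol_gday:within"] * aug["alcohol_gday:between"]).groupby(
            aug["participant_id"]
        ).sum()
        assert np.abs(dots).max() < 1e-8

    def test_constant_level1_variable_rejected(self, panel):
        df = panel.assign(flat=1.0)
        with pytest.raises(SpecificationError, match="flat"):
            decompose_within_between(
                df, DesignSpec(outcome="theta", level1=("flat",))
            )

    def test_level2_variable_varying_within_cluster_rejected(self, panel):
        df = panel.assign(bad=np.arange(len(panel), dtype=float))
        with pytest.raises(SpecificationError, match="bad"):
            decompose_within_between(
                df, DesignSpec(outcome="theta", level1=("alcohol_gday",), level2=("bad",))
            )


class TestEquivalences:
    def test_within_between_beta_w_equals_fixed_effects(self, panel):
        """The estimator's central property: beta^w from the within-between
        random model is identical to the fixed-effects estimate."""
        wb = fit_wb_random(panel, SPEC)
        fe = fit_fixed_effects(panel, SPEC)
        rel = np.abs(wb.beta_within.to_numpy() - fe.params.to_numpy()) / np.abs(
            fe.params.to_numpy()
        )
        assert rel.max() < 1e-6

    def test_correlated_re_reparameterization(self, panel):
        """Mundlak form: beta on raw x equals beta^w; beta on x-bar equals
        beta^b - beta^w; recovered to 1e-8."""
        wb = fit_wb_random(panel, SPEC)
        cre = fit_correlated_re(panel, SPEC)
        for v in SPEC.level1:
            assert cre.params[v] == pytest.approx(wb.beta_within[v], abs=1e-8)
            assert cre.params[f"{v}:between"] + cre.params[v] == pytest.approx(
                wb.beta_between[v], abs=1e-8
            )

    def test_fixed_effects_equals_first_differences_two_waves(self):
        df = simulate_panel(400, 2, seed=9)
        fe = fit_fixed_effects(df, DesignSpec(outcome="theta", level1=("alcohol_gday",)))
        wide = df.pivot(index="participant_id", columns="wave")
        dy = (wide["theta"][1] - wide["theta"][0]).to_numpy()
        dx = (wide["alcohol_gday"][1] - wide["alcohol_gday"][0]).to_numpy()
        slope = float(dx @ dy / (dx @ dx))
        assert fe.params["alcohol_gday:within"] == pytest.approx(slope, rel=1e-10)

    def test_fixed_effects_invariant_to_cluster_shifts(self, panel):
        fe = fit_fixed_effects(panel, SPEC)
        shifted = panel.copy()
        shifts = {pid: 5.0 * np.sin(pid) for pid in shifted["participant_id"].unique()}
        shifted["theta"] = shifted["theta"] + shifted["participant_id"].map(shifts)
        fe2 = fit_fixed_effects(shifted, SPEC)
        assert np.allclose(fe.params.to_numpy(), fe2.params.to_numpy(), atol=1e-10)

    def test_fixed_effects_rejects_level2(self, panel):
        df = panel.copy()
        df["grp"] = (df["participant_id"] % 2).astype(float)
        with pytest.raises(SpecificationError):
            fit_fixed_effects(
                df, DesignSpec(outcome="theta", level1=SPEC.level1, level2=("grp",))
            )

    def test_zero_sigma_v_reduces_to_pooled_least_squares(self):
        df = simulate_panel(600, 2, sigma_v=0.0, sigma_eps=0.5, seed=4)
        wb = fit_wb_random(df, SPEC)
        assert wb.boundary or wb.sigma_v2 < 1e-3
        aug = decompose_within_between(df, SPEC)
        cols = ["alcohol_gday:within", "ln_income:within", "alcohol_gday:between", "ln_income:between"]
        X = np.column_stack([np.ones(len(aug))] + [aug[c] for c in cols])
        ols = np.linalg.lstsq(X, aug["theta"].to_numpy(), rcond=None)[0]
        if wb.boundary:
            assert np.allclose(wb.params.to_numpy(), ols, atol=1e-8)
        else:
            assert np.allclose(wb.params.to_numpy(), ols, atol=1e-3)


class TestLikelihood:
    def test_marginal_loglik_matches_statsmodels(self, panel):
        """ML log-likelihood agrees with an independent mixed-model
        implementation to 1e-6 on the same augmented design."""
        smf = pytest.importorskip("statsmodels.formula.api")
        aug = decompose_within_between(panel, SPEC).rename(
            columns={
                "alcohol_gday:within": "acw",
                "alcohol_gday:between": "acb",
                "ln_income:within": "lyw",
                "ln_income:between": "lyb",
            }
        )
        ours = fit_wb_random(panel, SPEC)
        ref = smf.mixedlm(
            "theta ~ acw + acb + lyw + lyb", aug, groups=aug["participant_id"]
        ).fit(reml=False)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)
        params = ref.params
        assert ours.params["alcohol_gday:within"] == pytest.approx(params["acw"], rel=1e-5)
        assert ours.params["ln_income:between"] == pytest.approx(params["lyb"], rel=1e-5)

    def test_invariant_to_cluster_relabeling_and_row_order(self, panel):
        base = fit_wb_random(panel, SPEC)
        rng = np.random.default_rng(0)
        relabel = dict(
            zip(
                panel["participant_id"].unique(),
                rng.permutation(panel["participant_id"].nunique()) + 10_000,
            )
        )
        shuffled = panel.assign(participant_id=panel["participant_id"].map(relabel))
        shuffled = shuffled.sample(frac=1.0, random_state=1)
        other = fit_wb_random(shuffled, SPEC)
        assert other.loglik == pytest.approx(base.loglik, abs=1e-8)
        assert np.allclose(
            other.params.to_numpy(), base.params.to_numpy(), atol=1e-8
        )

    def test_z_statistics_consistent_with_covariance_diagonal(self, panel):
        fit = fit_wb_random(panel, SPEC)
        manual = fit.params / np.sqrt(np.diag(fit.cov.to_numpy()))
        assert np.allclose(fit.zstats.to_numpy(), manual.to_numpy(), rtol=1e-12)

    def test_rank_deficient_design_names_columns(self, panel):
        df = panel.copy()
        df["dup"] = df["alcohol_gday"] * 2.0
        with pytest.raises(RankError) as err:
            fit_wb_random(df, DesignSpec(outcome="theta", level1=("alcohol_gday", "dup")))
        assert any("dup" in c or "alcohol" in c for c in err.value.columns)


class TestRandomEffects:
    def test_null_heterogeneity_re_close_to_wb(self):
        """With no covariate-intercept correlation, RE and the two
        within-between components agree within Monte-Carlo error."""
        est = []
        for seed in range(30):
            df = simulate_panel(
                1000,
                2,
                beta_within={"alcohol_gday": 0.02, "ln_income": -0.15},
                beta_between={"alcohol_gday": 0.02, "ln_income": -0.15},
                mundlak_rho=0.0,
                seed=seed,
            )
            re = fit_random_effects(df, SPEC)
            wb = fit_wb_random(df, SPEC)
            est.append(
                [re.params["alcohol_gday"], wb.beta_within["alcohol_gday"], wb.beta_between["alcohol_gday"]]
            )
        est = np.asarray(est)
        mcse = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert abs(est[:, 0].mean() - 0.02) < 3 * mcse[0]
        assert abs(est[:, 1].mean() - 0.02) < 3 * mcse[1]
        assert abs(est[:, 2].mean() - 0.02) < 3 * mcse[2]


class TestWald:
    @staticmethod
    def _constructed_fit(b_w, b_b, cov):
        idx = pd.Index(["x:within", "x:between"])
        return ModelFit(
            model_kind="wb_random",
            params=pd.Series([b_w, b_b], index=idx),
            cov=pd.DataFrame(cov, index=idx, columns=idx),
            sigma_v2=0.1,
            sigma_eps2=0.1,
            loglik=0.0,
            n_obs=10,
            n_clusters=5,
            spec=DesignSpec(outcome="y", level1=("x",)),
        )

    def test_equal_effects_give_zero_statistic(self):
        fit = self._constructed_fit(0.5, 0.5, np.eye(2) * 0.01)
        res = wald_equal_effects(fit, ["x"])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_single_variable_matches_z_squared(self):
        cov = np.array([[0.04, 0.01], [0.01, 0.09]])
        fit = self._constructed_fit(0.2, 0.7, cov)
        res = wald_equal_effects(fit, ["x"])
        se_diff = np.sqrt(0.04 + 0.09 - 2 * 0.01)
        assert res.statistic == pytest.approx(((0.7 - 0.2) / se_diff) ** 2, rel=1e-12)
        assert res.df == 1

    def test_absent_variable_raises(self, panel):
        fit = fit_wb_random(panel, SPEC)
        with pytest.raises(KeyError, match="townsend"):
            wald_equal_effects(fit, ["townsend"])


def test_pooled_ols_reports_between_labels():
    df = simulate_panel(300, 1, seed=6)
    fit = fit_pooled_ols(df, SPEC)
    assert "alcohol_gday:between" in fit.params.index
    assert fit.model_kind == "pooled_ols"
    assert fit.n_clusters == fit.n_obs
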