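"""The inferential battery: t tests, correlations, Friedman, Bonferroni
post hocs, repeated-measures ANOVA with sphericity handling, and the
dual-modality mixed model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualnback import (
    bonferroni_pairwise,
    friedman,
    format_p,
    mixed_model,
    one_sample_t,
    pearson_test,
    rm_anova,
)
from dualnback.inference import _gg_epsilon


class TestOneSampleT:
    def test_matches_scipy_on_raw_values(self, rng):
        x = rng.normal(0.2, 1.0, size=31)
        res = one_sample_t(values=x)
        ref = stats.ttest_1samp(x, 0.0)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.df == 30

    def test_summary_and_raw_forms_agree(self, rng):
        x = rng.normal(size=25)
        raw = one_sample_t(values=x)
        summ = one_sample_t(mean=x.mean(), sd=x.std(ddof=1), n=25)
        assert raw.statistic == pytest.approx(summ.statistic)
        assert raw.p_value == pytest.approx(summ.p_value)

    def test_zero_mean_gives_p_one(self):
        assert one_sample_t(mean=0.0, sd=1.0, n=31).p_value == 1.0

    def test_degenerate_sd_conventions(self):
        assert one_sample_t(mean=0.5, sd=0.0, n=10).p_value == 0.0
        assert one_sample_t(mean=0.0, sd=0.0, n=10).p_value == 1.0

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            one_sample_t(values=[1.0])


class TestPearson:
    def test_matches_scipy_on_raw_vectors(self, rng):
        x = rng.normal(size=31)
        y = 0.5 * x + rng.normal(size=31)
        res = pearson_test(x, y)
        ref = stats.pearsonr(x, y)
        assert res.extras["r"] == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.df == 29

    def test_collinear_vectors(self):
        x = np.arange(10.0)
        res = pearson_test(x, 2 * x + 1)
        assert res.extras["r"] == pytest.approx(1.0)
        assert res.p_value < 1e-30

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_test(np.ones(10), np.arange(10.0))


class TestFriedman:
    def test_maximal_separation_closed_form(self):
        # identical ordering in every row: chi2 = n(k-1) * 12 * var-term = 40
        m = np.tile(np.arange(5.0), (10, 1))
        res = friedman(m)
        assert res.statistic == pytest.approx(40.0)
        assert res.p_value < 0.0005

    def test_fully_tied_rows(self):
        m = np.ones((8, 5)) * np.arange(8)[:, None]
        res = friedman(m)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_agrees_with_scipy(self, rng):
        m = rng.normal(size=(12, 4))
        mine = friedman(m)
        ref = stats.friedmanchisquare(*m.T)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)

    def test_monotone_transform_invariance(self, rng):
        m = rng.normal(size=(9, 5))
        a = friedman(m)
        b = friedman(np.exp(3 * m))
        assert a.statistic == pytest.approx(b.statistic)

    def test_incomplete_rows_dropped_with_warning(self, rng):
        m = rng.normal(size=(10, 3))
        m[2, 1] = np.nan
        with pytest.warns(UserWarning):
            res = friedman(m)
        assert res.extras["n"] == 9


class TestBonferroni:
    def test_five_levels_give_ten_comparisons(self, rng):
        wide = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        results = bonferroni_pairwise(wide)
        assert len(results) == 10
        for res in results:
            assert res.adjustment == "bonferroni"
            assert res.p_value >= res.extras["p_raw"]
            assert res.p_value <= 1.0
            assert res.p_value == pytest.approx(
                min(1.0, 10 * res.extras["p_raw"])
            )

    def test_adjustment_arithmetic(self, rng):
        wide = pd.DataFrame(rng.normal(size=(15, 2)), columns=["a", "b"])
        res = bonferroni_pairwise(wide, m=10)[0]
        assert res.p_value == pytest.approx(min(1.0, 10 * res.extras["p_raw"]))


def _long(wide, subject="subject"):
    df = pd.DataFrame(wide, columns=[f"c{j}" for j in range(wide.shape[1])])
    df[subject] = np.arange(len(df))
    return df.melt(id_vars=subject, var_name="cond", value_name="y")


class TestRmAnova:
    def test_two_levels_equal_paired_t_squared(self, rng):
        wide = rng.normal(size=(15, 2)) + rng.normal(size=(15, 1))
        wide[:, 1] += 0.4
        res = rm_anova(_long(wide), "y", "cond", "subject")[0]
        t = one_sample_t(values=wide[:, 1] - wide[:, 0])
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-6)
        assert res.p_value == pytest.approx(t.p_value, rel=1e-6)
        assert res.extras["epsilon"] == 1.0

    def test_compound_symmetry_epsilon_near_one(self, rng):
        subj = rng.normal(size=(200, 1))
        wide = subj + rng.normal(size=(200, 5))
        plain = rm_anova(_long(wide), "y", "cond", "subject")[0]
        forced = rm_anova(
            _long(wide), "y", "cond", "subject", correction="always"
        )[0]
        assert plain.extras["epsilon"] > 0.9
        assert forced.p_value == pytest.approx(plain.extras["p_unc"], abs=0.02)

    def test_constant_response(self):
        wide = np.ones((10, 5))
        res = rm_anova(_long(wide), "y", "cond", "subject")[0]
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_gg_epsilon_bounds(self, rng):
        for k in (3, 4, 5):
            for _ in range(20):
                wide = rng.normal(size=(12, k)) @ rng.normal(size=(k, k))
                eps = _gg_epsilon(wide)
                assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_gg_correction_applied_when_sphericity_violated(self, rng):
        # strongly heteroscedastic columns violate sphericity
        base = rng.normal(size=(40, 1))
        wide = np.hstack(
            [base + rng.normal(scale=s, size=(40, 1)) for s in (0.1, 0.1, 0.2, 2.0, 4.0)]
        )
        res = rm_anova(_long(wide), "y", "cond", "subject")[0]
        if res.extras["mauchly_p"] < 0.05:
            assert res.adjustment == "greenhouse_geisser"
            assert res.extras["epsilon"] < 1.0
            assert res.df[0] == pytest.approx(4.0 * res.extras["epsilon"])

    def test_covariates_route_to_mixed_model(self, rng):
        wide = rng.normal(size=(25, 5)) + rng.normal(size=(25, 1))
        long = _long(wide)
        long["age"] = np.repeat(rng.normal(31, 6, 25), 5)
        results = rm_anova(long, "y", "cond", "subject", covariates=["age"])
        labels = [r.effect_label for r in results]
        assert any("cond" in lab for lab in labels)
        assert any("age" in lab for lab in labels)


class TestMixedModel:
    @staticmethod
    def _simulate(n_subjects, modality_offset=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            u = rng.normal()
            age = rng.normal(31, 6)
            vol = rng.normal()
            sex = "female" if rng.uniform() < 0.5 else "male"
            for c in ("silence", "pure_tone_240Hz", "BB_10Hz", "BB_16Hz", "BB_40Hz"):
                for m in ("visuospatial", "auditory_verbal"):
                    rows.append(
                        dict(
                            subject_id=f"S{s}", condition=c, modality=m,
                            sex=sex, age=age, volume=vol,
                            value=u
                            + modality_offset * (m == "auditory_verbal")
                            + rng.normal(scale=0.5),
                        )
                    )
        return pd.DataFrame(rows)

    def test_detects_pure_modality_offset(self):
        data = self._simulate(200, modality_offset=0.3, seed=3)
        results = {r.effect_label: r for r in mixed_model(data)}
        modality = next(
            v for k, v in results.items() if "modality" in k and ":" not in k
        )
        condition = next(
            v for k, v in results.items() if "condition" in k and ":" not in k
        )
        interaction = next(v for k, v in results.items() if ":" in k)
        assert modality.p_value < 1e-6
        assert condition.p_value > 0.05
        assert interaction.p_value > 0.05

    def test_two_condition_design_agrees_with_paired_t(self):
        rng = np.random.default_rng(8)
        n = 200
        u = rng.normal(size=n)
        a = u + rng.normal(scale=0.7, size=n)
        b = u + 0.2 + rng.normal(scale=0.7, size=n)
        rows = []
        for i in range(n):
            rows.append(dict(subject_id=i, condition="silence",
                             modality="visuospatial", value=a[i]))
            rows.append(dict(subject_id=i, condition="BB_10Hz",
                             modality="visuospatial", value=b[i]))
        data = pd.DataFrame(rows)
        results = mixed_model(data, covariates=())
        cond = next(r for r in results if "condition" in r.effect_label)
        t = one_sample_t(values=b - a)
        # Wald chi2 on 1 df vs paired t^2
        assert cond.statistic == pytest.approx(t.statistic**2, rel=0.05)

    def test_degenerate_random_effect_matches_ols(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        data = self._simulate(80, modality_offset=0.4, seed=5)
        # remove the subject effect entirely
        data["value"] = rng.normal(size=len(data)) + 0.4 * (
            data["modality"] == "auditory_verbal"
        )
        results = mixed_model(data, covariates=())
        ols = smf.ols(
            "value ~ C(condition, Treatment('silence')) * "
            "C(modality, Treatment('visuospatial'))",
            data,
        ).fit()
        modality = next(
            r for r in results if "modality" in r.effect_label and ":" not in r.effect_label
        )
        ref = ols.wald_test_terms(scalar=True).table
        ref_stat = ref.loc[
            [i for i in ref.index if "modality" in i and ":" not in i][0], "statistic"
        ]
        assert modality.statistic == pytest.approx(ref_stat, rel=0.05)


def test_p_value_display_convention():
    assert format_p(0.0004) == "<0.0005"
    assert format_p(0.0506) == "0.051"
    assert format_p(np.nan) == ""
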