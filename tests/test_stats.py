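"""Staged inference: assumption gates, factorial ANOVA with the interaction
drop rule, repeated-measures mixed models, Tukey contrasts and summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aquamet import (
    EndpointTable,
    assumption_gate,
    factorial_anova,
    group_summary,
    letter_display,
    repeated_measures_lmm,
    tukey_contrasts,
)
from helpers import anova_2x2_by_hand


def make_table(values, treatments, sexes, ids=None):
    df = pd.DataFrame(
        {
            "fish_id": ids if ids is not None else [f"f{i}" for i in range(len(values))],
            "treatment": treatments,
            "sex": sexes,
            "value": values,
        }
    )
    return EndpointTable(df, "endpoint")


def balanced_2x2(cell_means, n, noise_sd, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for (t, s), mu in cell_means.items():
        for i in range(n):
            rows.append({"fish_id": f"{t}-{s}-{i}", "treatment": t, "sex": s,
                         "value": mu + rng.normal(0, noise_sd)})
    return EndpointTable(pd.DataFrame(rows), "endpoint")


class TestAssumptionGate:
    def test_normal_sample_passes_untouched(self):
        x = np.random.default_rng(42).normal(10, 1, 50)
        g = assumption_gate(x)
        assert g.transform == "none"
        assert g.shapiro_p >= 0.05

    def test_lognormal_fails_then_passes_after_log10(self):
        x = 10 ** np.random.default_rng(7).normal(1.0, 0.5, 50)
        g = assumption_gate(x)
        assert g.transform == "log10"
        assert g.shapiro_p < 0.05 <= g.shapiro_p_after

    def test_constant_sample_degenerate(self):
        g = assumption_gate(np.full(20, 3.0))
        assert any("degenerate" in f for f in g.flags)
        assert np.isnan(g.shapiro_p)

    def test_nonpositive_values_cannot_transform(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 30) ** 3, [-5.0]])  # skewed, has negatives
        g = assumption_gate(x)
        if g.shapiro_p < 0.05:
            assert any("impossible" in f for f in g.flags)

    def test_shapiro_calibration_at_alpha(self):
        """Rejection rate of a true-normal sample ~ alpha across seeds."""
        rej = 0
        n_rep = 200
        for seed in range(n_rep):
            x = np.random.default_rng(seed).normal(10, 1, 50)
            rej += assumption_gate(x).transform == "log10"
        assert 0.01 <= rej / n_rep <= 0.10


class TestFactorialANOVA:
    def test_null_data_all_f_zero(self):
        """Equal cell means, zero noise: every effect SS is 0 -> F = 0."""
        cells = {(t, s): 5.0 for t in ("sham", "ligated") for s in ("female", "male")}
        table = balanced_2x2(cells, n=3, noise_sd=0.0, seed=0)
        res = factorial_anova(table)
        for term in res.terms:
            assert term.statistic == 0.0
            assert term.p == 1.0

    def test_hand_computed_oracle(self):
        """Balanced 2x2 with n=3 integer-valued cells: F statistics must
        match the textbook sums-of-squares computation (balance also makes
        type II = type III exactly)."""
        vals = [3, 4, 5, 6, 7, 8, 2, 3, 4, 9, 10, 11]
        treatments = ["sham"] * 6 + ["ligated"] * 6
        sexes = (["female"] * 3 + ["male"] * 3) * 2
        table = make_table(vals, treatments, sexes)
        res = factorial_anova(table)
        hand = anova_2x2_by_hand(table.data)
        by_hand_terms = {"treatment", "sex"}
        got = {t.term: t.statistic for t in res.terms}
        # interaction significant here? check both paths coherently
        inter = res.term("treatment:sex")
        assert inter.statistic == pytest.approx(hand["treatment:sex"], rel=1e-9)
        for term in by_hand_terms:
            assert got[term] == pytest.approx(hand[term], rel=1e-9)

    def test_interaction_drop_rule(self):
        """Additive truth: the interaction is dropped and main effects are
        reported from the additive type II fit."""
        cells = {("sham", "female"): 10.0, ("sham", "male"): 12.0,
                 ("ligated", "female"): 8.0, ("ligated", "male"): 10.0}
        table = balanced_2x2(cells, n=8, noise_sd=1.0, seed=3)
        res = factorial_anova(table)
        assert res.anova_type == "II"
        assert any("interaction dropped" in f for f in res.flags)
        assert res.term("treatment").p < 0.05
        assert res.term("sex").p < 0.05

    def test_interaction_nonsignificant_rate_under_additive_truth(self):
        """Simulation calibration: with purely additive truth the
        interaction survives the drop rule rarely (~alpha)."""
        cells = {("sham", "female"): 10.0, ("sham", "male"): 12.0,
                 ("ligated", "female"): 8.0, ("ligated", "male"): 10.0}
        kept = 0
        n_rep = 100
        for seed in range(n_rep):
            res = factorial_anova(balanced_2x2(cells, n=6, noise_sd=1.0, seed=seed))
            kept += res.anova_type == "III"
        assert kept / n_rep <= 0.10

    def test_type2_equals_type3_on_balanced_design(self):
        """On a balanced design the two ANOVA types coincide exactly."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        cells = {("sham", "female"): 10.0, ("sham", "male"): 11.5,
                 ("ligated", "female"): 9.0, ("ligated", "male"): 12.0}
        table = balanced_2x2(cells, n=5, noise_sd=1.0, seed=9)
        full = smf.ols("value ~ C(treatment, Sum) * C(sex, Sum)", data=table.data).fit()
        t3 = anova_lm(full, typ=3).drop(index="Intercept")
        t2 = anova_lm(full, typ=2)
        for name in t2.index[:-1]:
            assert t2.loc[name, "F"] == pytest.approx(t3.loc[name, "F"], rel=1e-9)

    def test_empty_cell_is_an_error(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        table = make_table(vals, ["sham"] * 4 + ["ligated"] * 2,
                           ["female", "female", "male", "male", "female", "female"])
        with pytest.raises(ValueError, match="cell"):
            factorial_anova(table)


def lmm_data(n_fish_per_group=8, time_effect=(0.0, 0.0, 0.0, 0.0),
             treatment_effect=0.0, fish_sd=1.0, resid_sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    times = ["0", "15", "60", "rest"]
    rows = []
    for treat in ("sham", "ligated"):
        for sex in ("female", "male"):
            for i in range(n_fish_per_group // 2):
                fid = f"{treat}-{sex}-{i}"
                b = rng.normal(0, fish_sd)
                for tp, te in zip(times, time_effect):
                    mu = 30.0 + te + (treatment_effect if treat == "ligated" else 0.0)
                    rows.append({"fish_id": fid, "treatment": treat, "sex": sex,
                                 "time_point": tp,
                                 "value": mu + b + rng.normal(0, resid_sd)})
    return EndpointTable(pd.DataFrame(rows), "pvo2")


class TestRepeatedMeasuresLMM:
    def test_zero_between_fish_variance_falls_back_to_ols(self):
        table = lmm_data(fish_sd=0.0, resid_sd=1.0, seed=1)
        res = repeated_measures_lmm(table)
        assert any("singular" in f for f in res.flags)
        assert "OLS" in res.model

    def test_time_effect_detected_treatment_null_calibrated(self):
        """Strong pure time effect: the time term is significant; the null
        treatment term rejects at ~alpha across replicates."""
        hits_time, hits_treat, n_rep = 0, 0, 40
        for seed in range(n_rep):
            table = lmm_data(time_effect=(6.0, 3.0, 1.0, 0.0), fish_sd=1.5,
                             resid_sd=1.0, seed=seed)
            res = repeated_measures_lmm(table)
            terms = {t.term: t for t in res.terms if t.kind == "chi2"}
            hits_time += terms["time_point"].p < 0.05
            hits_treat += terms["treatment"].p < 0.05
        assert hits_time == n_rep
        assert hits_treat / n_rep <= 0.15

    def test_treatment_effect_power_at_study_scale(self):
        """Recovery-PvO2-sized treatment effect (sham ~8 Torr above ligated
        early in recovery, fish sd 4, residual 4, n=15/group): detected in
        >=80% of replicates."""
        hits, n_rep = 0, 25
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            rows = []
            sham = {"0": 25.2, "15": 35.7, "60": 34.5, "rest": 33.9}
            lig = {"0": 21.3, "15": 23.0, "60": 33.1, "rest": 31.0}
            for treat, means in (("sham", sham), ("ligated", lig)):
                for i in range(15):
                    fid = f"{treat}-{i}"
                    b = rng.normal(0, 4.0)
                    sex = "female" if i % 2 else "male"
                    for tp, mu in means.items():
                        rows.append({"fish_id": fid, "treatment": treat,
                                     "sex": sex, "time_point": tp,
                                     "value": mu + b + rng.normal(0, 4.0)})
            res = repeated_measures_lmm(EndpointTable(pd.DataFrame(rows), "pvo2"))
            terms = {t.term: t for t in res.terms if t.kind == "chi2"}
            hits += terms["treatment"].p < 0.05
        assert hits / n_rep >= 0.80

    def test_bic_selection_invariant_to_rescaling(self):
        """Multiplying the response by c > 0 shifts every candidate's ML
        log-likelihood by -n log c, so BIC ranking (and the selected fixed
        structure) is unchanged."""
        import statsmodels.formula.api as smf

        table = lmm_data(time_effect=(4.0, 2.0, 1.0, 0.0), fish_sd=1.0, seed=5)
        df = table.data
        c = 7.3
        f = "value ~ C(treatment, Sum) + C(sex, Sum) + C(time_point, Sum)"
        r1 = smf.mixedlm(f, data=df, groups=df["fish_id"]).fit(reml=False)
        df2 = df.assign(value=df["value"] * c)
        r2 = smf.mixedlm(f, data=df2, groups=df2["fish_id"]).fit(reml=False)
        n = len(df)
        assert r2.llf == pytest.approx(r1.llf - n * np.log(c), rel=1e-6)
        res1 = repeated_measures_lmm(table)
        res2 = repeated_measures_lmm(EndpointTable(df2, "pvo2"))
        assert res1.model == res2.model


class TestTukey:
    def test_two_levels_equals_unadjusted_p(self):
        """k=2: the studentized-range adjustment reduces to the ordinary
        two-sided t test."""
        table = lmm_data(treatment_effect=-3.0, fish_sd=0.0, resid_sd=2.0, seed=2)
        df = table.data[table.data.time_point == "0"].copy()
        import statsmodels.formula.api as smf

        fit = smf.ols("value ~ C(treatment, Sum)", data=df).fit()
        from aquamet.stats import StatResult

        res = StatResult(model="m", anova_type="II", terms=[], _fit=fit,
                         _df_den=float(fit.df_resid))
        out = tukey_contrasts(res, "treatment", data=df)
        row = out.contrasts.iloc[0]
        t_stat = row.estimate / row.se
        p_t = 2 * sps.t.sf(abs(t_stat), fit.df_resid)
        assert row.p_tukey == pytest.approx(p_t, rel=1e-6)

    def test_null_contrasts_nonsignificant(self):
        """Five identical-mean time points, tiny noise around a flat truth:
        no contrast is significant and all levels share a letter."""
        rng = np.random.default_rng(4)
        rows = []
        for i in range(10):
            for tp in ("0", "15", "60", "rest", "ctmax"):
                rows.append({"fish_id": f"f{i}", "treatment": "sham",
                             "sex": "female" if i % 2 else "male",
                             "time_point": tp, "value": 10 + rng.normal(0, 1.0)})
        df = pd.DataFrame(rows)
        import statsmodels.formula.api as smf

        fit = smf.ols("value ~ C(time_point, Sum)", data=df).fit()
        from aquamet.stats import StatResult

        res = StatResult(model="m", anova_type="II", terms=[], _fit=fit,
                         _df_den=float(fit.df_resid))
        out = tukey_contrasts(res, "time_point", data=df)
        assert (out.contrasts.p_tukey > 0.05).all()
        assert len(set(out.letters.values())) == 1

    def test_three_group_hsd_matches_studentized_range(self):
        """Hand-sized one-way design: the adjusted p equals the textbook
        studentized-range computation q = |diff| / sqrt(MSE/n)."""
        df = pd.DataFrame({
            "fish_id": [f"f{i}" for i in range(12)],
            "treatment": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
            "sex": ["female"] * 12,
            "value": [5.1, 4.9, 5.3, 4.7, 7.2, 6.8, 7.0, 7.4, 9.1, 8.7, 9.3, 8.9],
        })
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        fit = smf.ols("value ~ C(treatment, Sum)", data=df).fit()
        mse = anova_lm(fit, typ=2).loc["Residual", "sum_sq"] / fit.df_resid
        from aquamet.stats import StatResult

        res = StatResult(model="m", anova_type="II", terms=[], _fit=fit,
                         _df_den=float(fit.df_resid))
        out = tukey_contrasts(res, "treatment", data=df)
        means = df.groupby("treatment")["value"].mean()
        for _, row in out.contrasts.iterrows():
            a, b = row.contrast.split(" - ")
            q = abs(means[a] - means[b]) / np.sqrt(mse / 4)
            p_ref = sps.studentized_range.sf(q, 3, fit.df_resid)
            assert row.p_tukey == pytest.approx(p_ref, rel=1e-6)
        # letters: a/b/c all differ here
        assert len(set(out.letters.values())) == 3

    def test_letter_display_consistency(self):
        """No letter is shared across a significant pair; every
        non-significant pair shares at least one letter (on random
        significance patterns that admit a consistent display)."""
        levels = ["a", "b", "c", "d"]
        rng = np.random.default_rng(8)
        for _ in range(20):
            sig = np.zeros((4, 4), bool)
            for i, j in itertools.combinations(range(4), 2):
                sig[i, j] = sig[j, i] = rng.random() < 0.4
            letters = letter_display(levels, sig)
            for i, j in itertools.combinations(range(4), 2):
                shared = set(letters[levels[i]]) & set(letters[levels[j]])
                if sig[i, j]:
                    assert not shared
                else:
                    assert shared


class TestGroupSummary:
    def test_two_point_sem(self):
        df = pd.DataFrame({"treatment": ["a", "a"], "value": [2.0, 4.0]})
        out = group_summary(df)
        assert out.loc[0, "mean"] == pytest.approx(3.0)
        assert out.loc[0, "sem"] == pytest.approx(1.0)

    def test_single_observation_flagged(self):
        df = pd.DataFrame({"treatment": ["a"], "value": [2.0]})
        out = group_summary(df)
        assert np.isnan(out.loc[0, "sem"])
        assert "sem undefined" in out.loc[0, "flag"]
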