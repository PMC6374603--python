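"""Mixed-effects factorial models, subgroup splits, linear SART model,
clinical correlations — including an independent lme4 oracle check."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from mindtrack import boldsim as bs, inference as inf
from mindtrack.exceptions import (DataError, DesignError,
                                  InsufficientDataError)


@pytest.fixture(scope="module")
def analysis_table():
    blocks = bs.simulate_block_table(n_subjects=40, seed=11)
    return inf.standardize_predictors(blocks, blocks.attrs["clinical"])


class TestStandardize:
    def test_unit_sd_columns(self, analysis_table):
        for col in ("mr", "sa", "av"):
            assert analysis_table[col].std(ddof=0) == pytest.approx(1.0)

    def test_error_blocks_dropped(self):
        blocks = bs.simulate_block_table(n_subjects=10, seed=3)
        tab = inf.standardize_predictors(blocks, blocks.attrs["clinical"])
        assert len(tab) == int((~blocks["error"]).sum())

    def test_toy_row_count(self):
        blocks = pd.DataFrame({
            "subject_id": ["s1"] * 3 + ["s2"] * 3,
            "block": [1, 2, 3] * 2,
            "mr": np.arange(6, dtype=float),
            "sa": np.arange(6, dtype=float)[::-1],
            "probe_deceased": [True, False] * 3,
            "error": [False, True, False, False, False, True],
        })
        clin = pd.DataFrame({"subject_id": ["s1", "s2"],
                             "avoidance": [1.0, 2.0]})
        tab = inf.standardize_predictors(blocks, clin)
        assert len(tab) == 4

    def test_missing_avoidance_rejected(self):
        blocks = bs.simulate_block_table(n_subjects=5, seed=1)
        clin = blocks.attrs["clinical"].drop(columns=["avoidance"])
        with pytest.raises(DataError):
            inf.standardize_predictors(blocks, clin)


class TestMixedLogit:
    def test_matches_lme4_glmer(self, analysis_table, tmp_path):
        """Coefficients, SEs and random-intercept s.d. agree with glmer."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        res = inf.fit_three_way_mixed_logit(analysis_table)
        path = tmp_path / "tab.tsv"
        analysis_table.to_csv(path, sep="\t", index=False)
        r_code = f'''
        suppressMessages(library(lme4))
        d <- read.delim("{path}")
        m <- glmer(y ~ mr*sa*av + (1|subject_id), data=d, family=binomial,
                   control=glmerControl(optimizer="bobyqa"))
        co <- summary(m)$coefficients
        cat(paste(rownames(co), co[,1], co[,2], sep=","), sep="\n")
        cat("ri_sd,", attr(VarCorr(m)$subject_id, "stddev"), "\n")
        '''
        out = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                             text=True, check=True).stdout
        r_terms = {}
        for line in out.strip().splitlines():
            parts = line.split(",")
            r_terms[parts[0]] = [float(v) for v in parts[1:] if v.strip()]
        mapping = {"(Intercept)": "intercept", "mr": "mr", "sa": "sa",
                   "av": "av", "mr:sa": "mr:sa", "mr:av": "mr:av",
                   "sa:av": "sa:av", "mr:sa:av": "mr:sa:av"}
        for rname, name in mapping.items():
            e = res[name]
            assert e.b == pytest.approx(r_terms[rname][0], abs=0.02)
            assert e.se == pytest.approx(r_terms[rname][1], abs=0.02)
        assert np.sqrt(res.random_intercept_var) == \
            pytest.approx(r_terms["ri_sd"][0], abs=0.05)

    def test_degenerate_random_intercept_matches_plain_logistic(self, rng):
        """With no subject-level heterogeneity the mixed fit reduces to
        ordinary logistic regression."""
        import statsmodels.api as sm
        n = 1200
        tab = pd.DataFrame({
            "subject_id": np.repeat([f"s{i}" for i in range(30)], 40),
            "mr": rng.standard_normal(n), "sa": rng.standard_normal(n),
        })
        tab["av"] = np.repeat(rng.standard_normal(30), 40)
        eta = -0.5 + 0.8 * tab.mr - 1.0 * tab.mr * tab.sa * tab.av
        tab["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        res = inf.fit_three_way_mixed_logit(tab)
        X = inf._design_from_terms(tab, inf._FACTORIAL_TERMS)
        plain = sm.GLM(tab["y"].to_numpy(), X,
                       family=sm.families.Binomial()).fit()
        for i, name in enumerate(["intercept"] + inf._FACTORIAL_TERMS):
            assert res[name].b == pytest.approx(plain.params[i], abs=0.05)

    def test_constant_outcome_rejected(self, analysis_table):
        tab = analysis_table.copy()
        tab["y"] = 1
        with pytest.raises(DataError):
            inf.fit_three_way_mixed_logit(tab)

    def test_or_equals_exp_b_machine_precision(self, analysis_table):
        res = inf.fit_three_way_mixed_logit(analysis_table)
        for e in res.effects:
            assert e.or_value == np.exp(e.b)
            assert e.ci_low <= e.ci_high

    def test_parameter_recovery_unbiased_with_ci_coverage(self):
        """At 200 subjects the seven factorial coefficients are recovered
        without systematic bias and with near-nominal CI coverage."""
        truth = bs.DEFAULT_COEFFS
        keys = ["b_mr", "b_sa", "b_av", "b_mrsa", "b_mrav", "b_saav",
                "b_three"]
        order = ["mr", "sa", "av", "mr:sa", "mr:av", "sa:av", "mr:sa:av"]
        reps = 25
        bias = {k: [] for k in keys}
        cover = {k: [] for k in keys}
        for rep in range(reps):
            blocks = bs.simulate_block_table(n_subjects=200, seed=5000 + rep)
            tab = inf.standardize_predictors(blocks, blocks.attrs["clinical"])
            res = inf.fit_three_way_mixed_logit(tab)
            for k, term in zip(keys, order):
                e = res[term]
                bias[k].append(e.b - truth[k])
                cover[k].append(e.ci_low <= truth[k] <= e.ci_high)
        mean_cover = np.mean([np.mean(cover[k]) for k in keys])
        assert mean_cover >= 0.9
        for k in keys:
            assert abs(np.mean(bias[k])) < 0.1
            assert np.mean(cover[k]) >= 0.8


class TestAdjustedModel:
    def test_independent_covariates_barely_shift_estimate(self):
        blocks = bs.simulate_block_table(n_subjects=60, seed=21)
        tab = inf.standardize_predictors(blocks, blocks.attrs["clinical"])
        base = inf.fit_three_way_mixed_logit(tab)
        adj = inf.fit_adjusted_model(tab)
        e0, e1 = base["mr:sa:av"], adj["mr:sa:av"]
        assert abs(e1.b - e0.b) < 0.2 * e0.se * np.sqrt(len(tab)) / 10
        assert abs(e1.b - e0.b) < 0.2

    def test_duplicated_covariate_rejected(self, analysis_table):
        with pytest.raises(DesignError):
            inf.fit_adjusted_model(analysis_table, covariates=("age", "age"))

    def test_outcome_driver_covariate_attenuates(self, rng):
        """Adding the generative driver itself as a covariate attenuates
        the three-way term toward zero."""
        n_sub, n_blk = 80, 16
        rows = []
        for i in range(n_sub):
            av = rng.standard_normal()
            mr = rng.standard_normal(n_blk)
            sa = rng.standard_normal(n_blk)
            driver = mr * sa * av + 0.3 * rng.standard_normal(n_blk)
            eta = -0.8 - 2.0 * driver
            y = rng.random(n_blk) < 1 / (1 + np.exp(-eta))
            for b in range(n_blk):
                rows.append({"subject_id": f"s{i}", "block": b + 1,
                             "mr": mr[b], "sa": sa[b], "av": av, "y": int(y[b]),
                             "driver": driver[b]})
        tab = pd.DataFrame(rows)
        base = inf.fit_three_way_mixed_logit(tab)
        adj = inf.fit_adjusted_model(tab, covariates=("driver",))
        assert abs(adj["mr:sa:av"].b) < abs(base["mr:sa:av"].b)


class TestMedianSplit:
    def test_group_sizes_sum_to_n(self, analysis_table):
        high, low = inf.median_split_models(analysis_table)
        assert high.n_subjects + low.n_subjects == \
            analysis_table["subject_id"].nunique()

    def test_all_equal_avoidance_degenerate(self, analysis_table):
        tab = analysis_table.copy()
        tab["avoidance_raw"] = 1.0
        with pytest.raises(DesignError):
            inf.median_split_models(tab)

    def test_sign_pattern_under_dominant_moderation(self):
        """With only the three-way generative term active (b_three < 0),
        the high-avoidance group shows a negative and the low-avoidance
        group a positive d-MR x d-SA interaction in most replicates."""
        coeffs = dict(bs.DEFAULT_COEFFS)
        coeffs.update(b_mrsa=0.0, b_mrav=0.0, b_saav=0.0)
        wins = 0
        reps = 10
        for rep in range(reps):
            blocks = bs.simulate_block_table(n_subjects=60, seed=900 + rep,
                                             coeffs=coeffs)
            tab = inf.standardize_predictors(blocks, blocks.attrs["clinical"])
            high, low = inf.median_split_models(tab)
            wins += (high["mr:sa"].b < 0) and (low["mr:sa"].b > 0)
        assert wins > reps / 2


class TestCoefToOr:
    @pytest.mark.parametrize("b,expected", [(-2.37, 0.09), (0.0, 1.0),
                                            (0.76, 2.14), (-1.04, 0.35)])
    def test_printed_rows(self, b, expected):
        assert round(inf.coef_to_or(b), 2) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(DataError):
            inf.coef_to_or(np.nan)


class TestSartLinear:
    def test_pure_mr_outcome(self, rng):
        tab = pd.DataFrame({"mr": rng.standard_normal(400),
                            "sa": rng.standard_normal(400),
                            "avoidance": rng.standard_normal(400)})
        tab["report"] = 2.0 - 1.5 * tab["mr"]
        res = inf.fit_sart_linear(tab)
        res = res.set_index("term")
        assert res.loc["mr", "semipartial_r2"] == pytest.approx(1.0, abs=0.05)
        assert res.loc["sa", "semipartial_r2"] == pytest.approx(0.0, abs=0.05)

    def test_toy_six_rows_match_hand_ols(self, rng):
        tab = pd.DataFrame({"mr": rng.standard_normal(6),
                            "sa": rng.standard_normal(6),
                            "avoidance": rng.standard_normal(6)})
        tab["report"] = 1 + tab.mr - 0.5 * tab.sa + 0.3 * rng.standard_normal(6)
        res = inf.fit_sart_linear(tab).set_index("term")
        X = np.column_stack([np.ones(6), tab[["mr", "sa", "avoidance"]]])
        beta = np.linalg.lstsq(X, tab["report"], rcond=None)[0]
        for i, term in enumerate(["mr", "sa", "avoidance"], start=1):
            assert res.loc[term, "B"] == pytest.approx(beta[i])

    def test_semipartial_in_unit_interval(self, rng):
        tab = pd.DataFrame({"mr": rng.standard_normal(25),
                            "sa": rng.standard_normal(25),
                            "avoidance": rng.standard_normal(25),
                            "report": rng.standard_normal(25)})
        res = inf.fit_sart_linear(tab)
        assert res["semipartial_r2"].between(0, 1).all()

    def test_minimum_subjects(self):
        tab = pd.DataFrame({"mr": [1.0] * 4, "sa": [1.0] * 4,
                            "avoidance": [1.0] * 4, "report": [1.0] * 4})
        with pytest.raises(InsufficientDataError):
            inf.fit_sart_linear(tab)


class TestClinicalCorrelations:
    def test_perfect_correlation(self):
        blocks = bs.simulate_block_table(n_subjects=12, seed=5)
        clin = blocks.attrs["clinical"].reset_index(drop=True)
        rate = inf.loss_thought_rate(blocks)
        clin["age"] = rate.loc[clin["subject_id"]].to_numpy() * 10 + 20
        out = inf.clinical_correlations(clin, blocks).set_index("variable")
        assert out.loc["age", "r"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        blocks = bs.simulate_block_table(n_subjects=200, seed=6)
        clin = blocks.attrs["clinical"].reset_index(drop=True)
        out = inf.clinical_correlations(clin, blocks).set_index("variable")
        # age is generatively independent of the probe model
        assert abs(out.loc["age", "r"]) < 0.2

    def test_zero_variance_column_warns(self):
        blocks = bs.simulate_block_table(n_subjects=8, seed=7)
        clin = blocks.attrs["clinical"].reset_index(drop=True)
        clin["education_years"] = 16.0
        with pytest.warns(UserWarning, match="education_years"):
            out = inf.clinical_correlations(clin, blocks)
        out = out.set_index("variable")
        assert np.isnan(out.loc["education_years", "r"])
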