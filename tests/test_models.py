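"""Weighted regression and mixed-model fits against independent oracles."""

import subprocess
import sys
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize

from softwin.datasets import PhenotypeDataset
from softwin.errors import MissingGroupError, SingularDesignError
from softwin.models import (
    backward_eliminate,
    build_design,
    effective_control_count,
    weighted_fixed_fit,
    weighted_mixed_fit,
    wls_fit,
)
from softwin.synthetic import CohortSimConfig, inject_genotype_effect, simulate_cohort
from softwin.windows import hard_window


def random_problem(rng, n=25, p=3):
    X = pd.DataFrame(
        np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))]),
        columns=["Intercept"] + [f"x{j}" for j in range(1, p)],
    )
    beta = rng.normal(size=p)
    y = X.to_numpy() @ beta + rng.normal(size=n)
    w = rng.uniform(0.05, 1.0, size=n)
    return X, y, w


class TestWLS:
    def test_unit_weights_reproduce_ols(self, rng):
        X, y, _ = random_problem(rng)
        ours = wls_fit(X, y, np.ones(len(y))).coefficients
        ols = sm.OLS(y, X).fit().params
        assert np.allclose(ours, ols, atol=1e-10)

    def test_scale_invariance(self, rng):
        X, y, w = random_problem(rng)
        a = wls_fit(X, y, w).coefficients
        b = wls_fit(X, y, 7.3 * w).coefficients
        assert np.allclose(a, b, atol=1e-10)

    def test_matches_numeric_minimizer_of_weighted_rss(self, rng):
        for _ in range(10):
            X, y, w = random_problem(rng)
            Xm = X.to_numpy()
            fun = lambda b: np.sum(w * (y - Xm @ b) ** 2)
            num = minimize(fun, np.zeros(X.shape[1]), method="BFGS", tol=1e-12).x
            assert np.allclose(wls_fit(X, y, w).coefficients, num, atol=1e-6)

    def test_indicator_weights_equal_subset_fit(self, rng):
        X, y, _ = random_problem(rng, n=40)
        keep = rng.random(40) < 0.6
        windowed = wls_fit(X, y, keep.astype(float)).coefficients
        subset = sm.OLS(y[keep], X[keep]).fit().params
        assert np.allclose(windowed, subset, atol=1e-8)

    def test_rank_deficient_names_collinear_terms(self, rng):
        X, y, w = random_problem(rng)
        X["dup"] = X["x1"] * 2.0
        with pytest.raises(SingularDesignError) as err:
            wls_fit(X, y, w)
        assert "dup" in err.value.collinear

    def test_residuals_complement_fitted(self, rng):
        X, y, w = random_problem(rng)
        fit = wls_fit(X, y, w)
        assert np.allclose(fit.residuals + fit.fitted, y)


class TestDesign:
    def test_full_terms_present(self, small_cohort):
        X, term_of, _ = build_design(small_cohort)
        assert set(term_of.values()) == {"genotype", "sex", "genotype:sex", "body_weight"}
        assert "Intercept" in X.columns

    def test_single_sex_mutants_drop_interaction(self, small_cohort):
        df = small_cohort.data.copy()
        df.loc[df["group"] == "mutant", "sex"] = "F"
        X, term_of, notes = build_design(PhenotypeDataset(df))
        assert "genotype:sex" not in term_of.values()
        assert any("single-sex" in n for n in notes)

    def test_mostly_missing_body_weight_dropped(self, small_cohort):
        df = small_cohort.data.copy()
        df.loc[df.index[: int(0.8 * len(df))], "body_weight"] = np.nan
        _, term_of, notes = build_design(PhenotypeDataset(df))
        assert "body_weight" not in term_of.values()
        assert any("missing" in n for n in notes)


class TestWeightedMixed:
    def test_matches_statsmodels_at_unit_weights(self, small_cohort):
        fit = weighted_mixed_fit(small_cohort, np.ones(small_cohort.n))
        X, _, _ = build_design(small_cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(
                small_cohort.response,
                X,
                groups=pd.Series(small_cohort.batch).astype(str).to_numpy(),
            ).fit(reml=True)
        assert np.allclose(fit.coefficients, ref.fe_params, atol=1e-4)
        assert np.allclose(fit.stderr, ref.bse_fe, rtol=0.02)

    def test_matches_lme4_with_weights(self, small_cohort, tmp_path):
        """lme4's precision-weighted REML is the independent oracle."""
        t = small_cohort.times
        w = np.clip(np.exp(-np.abs(t - t.mean()) / 50.0), 1e-12, 1.0)
        fit = weighted_mixed_fit(small_cohort, w)
        df = small_cohort.data.copy()
        df["geno"] = (df["group"] == "mutant").astype(int)
        df["sexM"] = (df["sex"] == "M").astype(int)
        df["bw"] = df["body_weight"] - df["body_weight"].mean()
        df["w"] = w
        csv = tmp_path / "cohort.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "d <- d[d$w > 1e-7 * max(d$w), ]\n"
            "m <- lmer(response ~ geno + sexM + geno:sexM + bw + (1|batch),"
            " data=d, weights=w, REML=TRUE)\n"
            "cat(fixef(m)['geno'], sqrt(diag(vcov(m)))[2], sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        coef_r, se_r = (float(v) for v in out.stdout.strip().splitlines()[-2:])
        assert fit.coefficients["genotype[mutant]"] == pytest.approx(coef_r, rel=1e-4)
        assert fit.stderr["genotype[mutant]"] == pytest.approx(se_r, rel=1e-3)

    def test_zero_batch_variance_matches_wls(self):
        data = simulate_cohort(
            CohortSimConfig(n_controls=250, n_mutants=12, span_days=150, batch_sd=0.0, seed=3)
        )
        w = np.ones(data.n)
        mixed = weighted_mixed_fit(data, w)
        fixed = weighted_fixed_fit(data, w)
        assert np.allclose(mixed.coefficients, fixed.coefficients, atol=1e-4)

    def test_single_batch_falls_back_to_wls(self, small_cohort):
        df = small_cohort.data.copy()
        df["batch"] = "d0"
        fit = weighted_mixed_fit(PhenotypeDataset(df), np.ones(len(df)))
        assert fit.model_kind == "wls"
        assert any("single batch" in n for n in fit.notes)

    def test_missing_group_raises(self, small_cohort):
        controls = small_cohort.controls_only()
        with pytest.raises(MissingGroupError):
            weighted_mixed_fit(controls, np.ones(controls.n))

    def test_batch_relabeling_invariance(self, small_cohort):
        fit = weighted_mixed_fit(small_cohort, np.ones(small_cohort.n))
        df = small_cohort.data.copy()
        codes = {b: f"relabeled_{i}" for i, b in enumerate(pd.unique(df["batch"]))}
        df["batch"] = df["batch"].map(codes)
        fit2 = weighted_mixed_fit(PhenotypeDataset(df), np.ones(len(df)))
        assert fit.genotype_p == pytest.approx(fit2.genotype_p, rel=1e-8)

    def test_power_for_three_sd_shift(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            data = simulate_cohort(
                CohortSimConfig(n_controls=300, n_mutants=14, span_days=200, seed=seed)
            )
            shifted = inject_genotype_effect(data, 3.0)
            fit = weighted_mixed_fit(shifted, np.ones(shifted.n))
            hits += fit.genotype_p < 1e-4
        assert hits >= 0.95 * reps

    def test_permutation_null_rejection_rate(self, rng):
        """Genotype p-values are uniform under label permutation.

        Permutations are spread over many simulated cohorts: the Wald
        rejection rate of a single finite cohort wobbles around the nominal
        level by a percent or so, which the aggregation averages out.
        """
        rej, reps = 0, 0
        for cohort_seed in range(50):
            data = simulate_cohort(
                CohortSimConfig(n_controls=300, n_mutants=14, span_days=200, seed=cohort_seed)
            )
            df = data.data
            labels = df["group"].to_numpy()
            for _ in range(20):
                perm = df.copy()
                perm["group"] = rng.permutation(labels)
                fit = weighted_mixed_fit(PhenotypeDataset(perm), np.ones(len(perm)))
                rej += fit.genotype_p < 0.05
                reps += 1
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < half_width


class TestBackwardElimination:
    def test_pure_noise_sex_usually_removed(self):
        removed = 0
        reps = 15
        for seed in range(reps):
            data = simulate_cohort(
                CohortSimConfig(
                    n_controls=300, n_mutants=14, span_days=200,
                    sex_effect=0.0, weight_effect=0.0, seed=seed,
                )
            )
            fit = weighted_mixed_fit(data, np.ones(data.n))
            final = backward_eliminate(fit, alpha=0.05)
            removed += "sex" not in final.terms
        assert removed >= reps // 2 + 1

    def test_genotype_never_removed(self, small_cohort):
        fit = weighted_mixed_fit(small_cohort, np.ones(small_cohort.n))
        final = backward_eliminate(fit, alpha=0.99999)
        assert "genotype" in final.terms
        assert "genotype" in final.term_pvalues

    def test_all_significant_terms_unchanged(self):
        data = simulate_cohort(
            CohortSimConfig(
                n_controls=400, n_mutants=14, span_days=200,
                sex_effect=3.0, weight_effect=1.0, seed=5,
            )
        )
        data = inject_genotype_effect(data, 4.0)
        fit = weighted_mixed_fit(data, np.ones(data.n))
        sig = {t for t, p in fit.term_pvalues.items() if p <= 0.05}
        final = backward_eliminate(fit, alpha=0.05)
        assert sig <= set(final.terms)

    def test_interaction_removed_before_sex(self, small_cohort):
        fit = weighted_mixed_fit(small_cohort, np.ones(small_cohort.n))
        final = backward_eliminate(fit, alpha=0.05)
        if "genotype:sex" in final.terms:
            assert "sex" in final.terms  # hierarchy respected


class TestEffectiveControlCount:
    def test_unit_weights_count_all_controls(self, small_cohort):
        groups = small_cohort.data["group"].to_numpy()
        n_controls = int(small_cohort.is_control.sum())
        assert effective_control_count(np.ones(small_cohort.n), groups) == n_controls

    def test_hard_weights_match_hard_count(self, small_cohort):
        t = small_cohort.times
        ind = hard_window(t, [120], 30).astype(float)
        groups = small_cohort.data["group"].to_numpy()
        expected = int(((ind == 1) & (groups == "control")).sum())
        assert effective_control_count(ind, groups) == expected

    def test_cutoff_one_counts_nothing(self, small_cohort):
        groups = small_cohort.data["group"].to_numpy()
        assert effective_control_count(np.ones(small_cohort.n), groups, cutoff=1.0) == 0
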