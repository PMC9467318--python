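"""Profiled-REML mixed models against closed-form, grid and statsmodels oracles."""

import numpy as np
import pandas as pd
import pytest

from tmtgaze import ModelSpec, ScoreSimConfig, fit_lmm, simulate_scores, wald_pvalues
from tmtgaze.lmm import RankError, _Profiler, _build_design

SPEC_FULL = ModelSpec(response="trial_duration")


def cell_mean_table(means, n_subjects=6):
    """Noise-free table with the four cell means (A-acc, A-spd, B-acc, B-spd)."""
    cells = [("A", "accuracy"), ("A", "speed"), ("B", "accuracy"), ("B", "speed")]
    rows = [
        (f"s{i}", tt, ins, m)
        for i in range(n_subjects)
        for (tt, ins), m in zip(cells, means)
    ]
    return pd.DataFrame(rows, columns=["subject", "test_type", "instruction",
                                       "trial_duration"])


def test_noise_free_cell_means_recovered_exactly():
    fit = fit_lmm(cell_mean_table([10.0, 12.0, 14.0, 16.0]), SPEC_FULL)
    assert np.allclose(fit.betas, [10.0, 4.0, 2.0, 0.0], atol=1e-8)
    assert fit.sd_resid == pytest.approx(0.0, abs=1e-6)


def test_zero_subject_variance_matches_ols_oracle():
    # sd_subject = 0: the profiled variance ratio collapses to the boundary
    # and the GLS solution must coincide with plain least squares
    df = simulate_scores(ScoreSimConfig(sd_subject=0.0, sd_resid=5.0, n_subjects=20),
                         seed=2)
    fit = fit_lmm(df, SPEC_FULL)
    assert fit.sd_intercept == 0.0
    # OLS oracle by normal equations
    X = _build_design(df, SPEC_FULL)
    y = df["trial_duration"].to_numpy()
    beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta_ols
    s2 = resid @ resid / (len(y) - X.shape[1])
    se_ols = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * s2)
    assert np.allclose(fit.betas, beta_ols, atol=1e-8)
    assert np.allclose(fit.ses, se_ols, rtol=1e-6)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_profiled_lambda_matches_dense_grid_search(seed):
    """On <= 8-subject instances the optimizer agrees with a 1e-4 log-lambda grid."""
    df = simulate_scores(ScoreSimConfig(n_subjects=8), seed=seed)
    fit = fit_lmm(df, SPEC_FULL)
    y = df["trial_duration"].to_numpy()
    X = _build_design(df, SPEC_FULL)
    prof = _Profiler(y, X, df["subject"].to_numpy(), reml=True)
    lam_hat = fit.sd_intercept**2 / fit.sd_resid**2
    # dense grid (step 1e-4 on log lambda) bracketing the plausible range
    grid = np.arange(np.log(lam_hat) - 2.0, np.log(lam_hat) + 2.0, 1e-4)
    devs = np.array([prof.deviance(np.exp(u)) for u in grid])
    lam_grid = np.exp(grid[devs.argmin()])
    assert abs(np.log(lam_hat) - np.log(lam_grid)) <= 1e-4


def test_balanced_design_instruction_effect_closed_form():
    df = simulate_scores(ScoreSimConfig(n_subjects=30), seed=9)
    fit = fit_lmm(df, SPEC_FULL)
    wide = df.pivot_table(index="subject", columns=["test_type", "instruction"],
                          values="trial_duration")
    diff = (wide[("A", "speed")] - wide[("A", "accuracy")]).mean()
    assert fit.betas[2] == pytest.approx(diff, abs=1e-8)


def test_matches_statsmodels_mixedlm():
    statsmodels = pytest.importorskip("statsmodels.formula.api")
    df = simulate_scores(ScoreSimConfig(n_subjects=25), seed=17)
    fit = fit_lmm(df, SPEC_FULL)
    m = statsmodels.mixedlm(
        'trial_duration ~ C(test_type) * C(instruction, Treatment("accuracy"))',
        df, groups=df["subject"],
    ).fit(reml=True)
    assert np.allclose(fit.betas, m.fe_params.values, rtol=1e-5)
    assert fit.sd_intercept == pytest.approx(np.sqrt(m.cov_re.values[0, 0]), rel=1e-3)
    assert fit.sd_resid == pytest.approx(np.sqrt(m.scale), rel=1e-3)


def test_parameter_recovery_at_study_scale():
    """200 draws at the trial-duration design recover beta and the intercept SD."""
    cfg = ScoreSimConfig()  # 58 subjects, sd_subject 17.22, sd_resid 20.9
    rng = np.random.SeedSequence(2024).spawn(200)
    betas, sd_int, sd_res2 = [], [], []
    for s in rng:
        fit = fit_lmm(simulate_scores(cfg, seed=np.random.default_rng(s)), SPEC_FULL)
        betas.append(fit.betas)
        sd_int.append(fit.sd_intercept)
        sd_res2.append(fit.sd_resid**2)
    mean_b = np.mean(betas, axis=0)
    # Monte-Carlo CI: se of the mean across replicates
    se_b = np.std(betas, axis=0, ddof=1) / np.sqrt(len(betas))
    assert np.all(np.abs(mean_b - np.array(cfg.betas)) < 4 * se_b + 1e-9)
    assert np.mean(sd_int) == pytest.approx(17.22, rel=0.05)
    assert np.mean(sd_res2) == pytest.approx(20.9**2, rel=0.02)


def test_log_transform_equals_manual_log():
    df = simulate_scores(ScoreSimConfig(betas=(5.5, 0.25, -0.33, 0.30),
                                        sd_subject=0.26, sd_resid=0.2,
                                        n_subjects=20, response="n_fixations"),
                         seed=5)
    df["n_fixations"] = np.exp(df["n_fixations"])
    fit_flag = fit_lmm(df, ModelSpec(response="n_fixations", log_transform=True))
    manual = df.copy()
    manual["n_fixations"] = np.log(manual["n_fixations"])
    fit_manual = fit_lmm(manual, ModelSpec(response="n_fixations"))
    assert np.allclose(fit_flag.betas, fit_manual.betas)
    assert fit_flag.sd_intercept == pytest.approx(fit_manual.sd_intercept)


def test_missing_rows_dropped_and_counted():
    df = simulate_scores(ScoreSimConfig(n_subjects=10), seed=2)
    df.loc[df.index[:5], "trial_duration"] = np.nan
    fit = fit_lmm(df, SPEC_FULL)
    assert fit.n_obs == 35
    assert fit.n_groups == 9  # one subject lost all four observations


def test_empty_cell_raises_rank_error():
    df = simulate_scores(ScoreSimConfig(n_subjects=10), seed=2)
    df = df[~((df["test_type"] == "B") & (df["instruction"] == "speed"))]
    with pytest.raises(RankError):
        fit_lmm(df, SPEC_FULL)


# ------------------------------------------------------------------- p-values
def test_wald_pvalue_limits():
    df = simulate_scores(ScoreSimConfig(n_subjects=40), seed=31)
    fit = fit_lmm(df, SPEC_FULL)
    # synthetic t values via a copied fit
    fit.betas = np.array([0.0, 1.96 * fit.ses[1], 5.921 * fit.ses[2], fit.betas[3]])
    p = wald_pvalues(fit, "residual")
    assert p["p"][0] == pytest.approx(1.0)
    assert p["p"][1] == pytest.approx(0.05, abs=0.005)  # normal limit at large df
    assert p["p"][2] < 0.001


def test_satterthwaite_df_are_sensible():
    df = simulate_scores(ScoreSimConfig(n_subjects=20), seed=13)
    fit = fit_lmm(df, SPEC_FULL)
    p = wald_pvalues(fit, "satterthwaite", table=df)
    assert (p["df"] >= 1).all() and (p["df"] <= fit.n_obs).all()
    # within-subject contrasts should keep close to the residual df scale
    assert p["df"][2] > 20
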