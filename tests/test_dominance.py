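"""JZS Bayes factors, dominance quotient, Nakagawa R^2 and the cluster bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from tmtgaze import (
    BfPriorSpec,
    LmmFit,
    ModelSpec,
    bootstrap_r2_ci,
    dominance_analysis,
    dominance_quotient,
    jzs_bf,
    r2_nakagawa,
)


from oracles import brute_force_bf, half_table


# ------------------------------------------------------------------ JZS BF
@pytest.mark.parametrize("model,r,n", [("fixed", 0.5, 6), ("random", 1.0, 6),
                                       ("fixed", 0.5, 8), ("random", 1.0, 8)])
def test_bf_matches_brute_force_integration(model, r, n):
    rng = np.random.default_rng(5 + n)
    table = half_table(rng, beta=1.0, n=n)  # <= 16 rows
    mine = jzs_bf(table, model, response="y")
    oracle = brute_force_bf(table, model, r)
    assert mine == pytest.approx(oracle, rel=0.01)


def test_bf_respects_custom_prior_scale():
    rng = np.random.default_rng(3)
    table = half_table(rng, beta=1.5, n=8)
    wide = jzs_bf(table, "fixed", BfPriorSpec(rscale_fixed=1.0), response="y")
    narrow = jzs_bf(table, "fixed", BfPriorSpec(rscale_fixed=0.2), response="y")
    oracle_wide = brute_force_bf(table, "fixed", 1.0)
    assert wide == pytest.approx(oracle_wide, rel=0.01)
    assert wide != pytest.approx(narrow, rel=0.05)


def test_null_data_favors_simpler_model():
    """Under beta = 0 the fixed-effects BF should typically fall below 1."""
    rng = np.random.default_rng(0)
    bfs = [
        jzs_bf(half_table(rng, beta=0.0, sd_u=0.0, sd_e=1.0, n=58), "fixed",
               response="y")
        for _ in range(200)
    ]
    assert np.median(bfs) < 1.0


@settings(derandomize=True, max_examples=20)
@given(scale=st.floats(0.01, 100.0), shift=st.floats(-50, 50))
def test_bf_location_scale_invariance(scale, shift):
    rng = np.random.default_rng(8)
    table = half_table(rng, beta=0.8, n=10)
    base_f = jzs_bf(table, "fixed", response="y")
    base_r = jzs_bf(table, "random", response="y")
    moved = table.assign(y=table["y"] * scale + shift)
    assert jzs_bf(moved, "fixed", response="y") == pytest.approx(base_f, rel=1e-6)
    assert jzs_bf(moved, "random", response="y") == pytest.approx(base_r, rel=1e-6)


def test_intercept_only_against_itself_is_one():
    rng = np.random.default_rng(2)
    assert jzs_bf(half_table(rng, n=6), "intercept", response="y") == 1.0


def test_degenerate_response_raises():
    rng = np.random.default_rng(1)
    table = half_table(rng, n=6).assign(y=1.0)
    with pytest.raises(ValueError):
        jzs_bf(table, "fixed", response="y")


# ----------------------------------------------------------------- quotient
def test_quotient_and_verdict():
    q, verdict = dominance_quotient(4.0, 2.0)
    assert q == 2.0 and verdict == "fixed-dominated"
    q, verdict = dominance_quotient(0.5, 0.5)
    assert q == 1.0 and verdict == "random-dominated"  # boundary goes to random
    with pytest.raises(ValueError):
        dominance_quotient(0.0, 1.0)


def test_quotient_direction_follows_data_structure():
    rng = np.random.default_rng(7)
    strong_fixed = half_table(rng, beta=-28.18, sd_u=5.0, sd_e=10.0, n=58)
    strong_random = half_table(rng, beta=0.0, sd_u=25.0, sd_e=8.0, n=58)
    qf, _ = dominance_quotient(
        jzs_bf(strong_fixed, "fixed", response="y"),
        jzs_bf(strong_fixed, "random", response="y"),
    )
    qr, _ = dominance_quotient(
        jzs_bf(strong_random, "fixed", response="y"),
        jzs_bf(strong_random, "random", response="y"),
    )
    assert qf > 1.0 > qr


# ----------------------------------------------------------------------- R^2
def _fit_with(var_f, sd_u, sd_e, n=100):
    rng = np.random.default_rng(0)
    fitted = rng.normal(0, 1, n)
    fitted = (fitted - fitted.mean()) / fitted.std() * np.sqrt(var_f)
    return LmmFit(
        spec=ModelSpec(response="y"), terms=["(Intercept)"],
        betas=np.zeros(1), ses=np.ones(1), sd_intercept=sd_u, sd_resid=sd_e,
        loglik=0.0, n_groups=10, n_obs=n, fitted_fixed=fitted,
    )


def test_r2_arithmetic():
    r2m, r2c = r2_nakagawa(_fit_with(var_f=1.0, sd_u=1.0, sd_e=np.sqrt(2.0)))
    assert r2m == pytest.approx(0.25)
    assert r2c == pytest.approx(0.50)


def test_r2_limits():
    r2m, r2c = r2_nakagawa(_fit_with(var_f=0.0, sd_u=1.0, sd_e=1.0))
    assert r2m == 0.0
    r2m, r2c = r2_nakagawa(_fit_with(var_f=2.0, sd_u=0.0, sd_e=0.0))
    assert r2m == 1.0 and r2c == 1.0
    with pytest.raises(ValueError):
        r2_nakagawa(_fit_with(var_f=0.0, sd_u=0.0, sd_e=0.0))


@settings(derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_r2_ordering_invariant(seed):
    rng = np.random.default_rng(seed)
    from tmtgaze import fit_lmm

    table = half_table(rng, beta=rng.normal(0, 2), sd_u=abs(rng.normal(0, 2)),
                       sd_e=0.5 + abs(rng.normal(0, 1)), n=8)
    fit = fit_lmm(table, ModelSpec(response="y", fixed=("instruction",)))
    r2m, r2c = r2_nakagawa(fit)
    assert 0.0 <= r2m <= r2c <= 1.0


# ------------------------------------------------------------------ bootstrap
def test_single_replicate_interval_is_a_point():
    rng = np.random.default_rng(2)
    table = half_table(rng, beta=1.0, n=10)
    out = bootstrap_r2_ci(table, ModelSpec(response="y", fixed=("instruction",)),
                          B=1, seed=0)
    assert out["ci_r2m"][0] == out["ci_r2m"][1]
    assert out["n_kept"] == 1


def test_identical_noise_free_subjects_give_zero_width():
    subj = np.repeat([f"s{i}" for i in range(8)], 2)
    instr = np.tile(["accuracy", "speed"], 8)
    y = np.where(instr == "speed", 1.0, 3.0)
    table = pd.DataFrame({"subject": subj, "test_type": "A",
                          "instruction": instr, "y": y})
    out = bootstrap_r2_ci(table, ModelSpec(response="y", fixed=("instruction",)),
                          B=25, seed=0)
    assert out["ci_r2m"][0] == pytest.approx(out["ci_r2m"][1], abs=1e-9)
    assert out["ci_r2m"][0] == pytest.approx(1.0)


def test_bootstrap_is_reproducible():
    rng = np.random.default_rng(4)
    table = half_table(rng, beta=1.0, n=10)
    spec = ModelSpec(response="y", fixed=("instruction",))
    a = bootstrap_r2_ci(table, spec, B=50, seed=123)
    b = bootstrap_r2_ci(table, spec, B=50, seed=123)
    assert a == b


# ------------------------------------------------------------- full procedure
def test_dominance_analysis_end_to_end():
    rng = np.random.default_rng(6)
    table = half_table(rng, beta=-28.0, sd_u=17.0, sd_e=20.0, n=30)
    res = dominance_analysis(table, "y", "A", B=50, seed=0)
    assert res.quotient == pytest.approx(res.bf_fixed / res.bf_random)
    assert 0 <= res.r2_marginal <= res.r2_conditional <= 1
    assert res.ci_r2m[0] <= res.r2_marginal <= res.ci_r2m[1]
    assert res.verdict in ("fixed-dominated", "random-dominated")
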