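"""Random-intercept linear mixed models by profiled (RE)ML.

The model is y = X beta + Z u + eps with one random intercept per
subject, u_j ~ N(0, sigma_u^2), eps ~ N(0, sigma_e^2). Writing
lambda = sigma_u^2 / sigma_e^2, both beta and sigma_e^2 have closed-form
GLS/profile solutions given lambda, so estimation reduces to a 1-D
bounded optimization of the profiled (restricted) deviance over
log(lambda). For grouped data with group sizes n_j the required
V^{-1} = (I + lambda Z Z')^{-1} quantities reduce to per-group sums
(Sherman-Morrison), making each deviance evaluation O(J p^2).

Fixed effects follow dummy coding with reference levels test half A and
accuracy instruction; responses may be natural-log transformed first.
Wald statistics use z = 1.96 intervals; p-values come from a t
distribution with residual or Satterthwaite degrees of freedom (the
Satterthwaite variant uses the numerically-differentiated REML
information of the variance components).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import design_matrix

__all__ = ["ModelSpec", "LmmFit", "fit_lmm", "wald_pvalues", "LOG_TRANSFORMED_DVS"]

#: Measures modelled on the natural-log scale.
LOG_TRANSFORMED_DVS = frozenset(
    {"n_fixations", "n_searching", "mean_eye_hand_span", "scanpath_length"}
)


class RankError(np.linalg.LinAlgError):
    """Design matrix is rank-deficient (a coefficient is inestimable)."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response column, fixed-effect terms, transform, criterion."""

    response: str
    fixed: tuple[str, ...] = ("test_type", "instruction", "interaction")
    grouping: str = "subject"
    log_transform: bool = False
    reml: bool = True

    def __post_init__(self) -> None:
        allowed = {"test_type", "instruction", "interaction"}
        if not set(self.fixed) <= allowed:
            raise ValueError(f"fixed terms must be a subset of {allowed}")
        if "interaction" in self.fixed and not {"test_type", "instruction"} <= set(self.fixed):
            raise ValueError("interaction requires both main effects")

    @property
    def term_names(self) -> list[str]:
        names = ["(Intercept)"]
        if "test_type" in self.fixed:
            names.append("test_type")
        if "instruction" in self.fixed:
            names.append("instruction")
        if "interaction" in self.fixed:
            names.append("test_type:instruction")
        return names


@dataclass
class LmmFit:
    """Fitted random-intercept model (one row per fixed-effect term)."""

    spec: ModelSpec
    terms: list[str]
    betas: np.ndarray
    ses: np.ndarray
    sd_intercept: float
    sd_resid: float
    loglik: float
    n_groups: int
    n_obs: int
    fitted_fixed: np.ndarray = field(repr=False)
    cov_beta: np.ndarray = field(repr=False, default=None)

    @property
    def t(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.ses > 0, self.betas / self.ses, np.nan)

    @property
    def ci95(self) -> np.ndarray:
        """Wald 95% intervals, b +/- 1.96 SE; shape (p, 2)."""
        half = 1.96 * self.ses
        return np.column_stack([self.betas - half, self.betas + half])

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.betas,
                "se": self.ses,
                "t": self.t,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            }
        )


def _build_design(df: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    full = design_matrix(df["test_type"].to_numpy(), df["instruction"].to_numpy())
    cols = [0]
    if "test_type" in spec.fixed:
        cols.append(1)
    if "instruction" in spec.fixed:
        cols.append(2)
    if "interaction" in spec.fixed:
        cols.append(3)
    return full[:, cols]


class _Profiler:
    """Profiled (RE)ML deviance of the variance ratio lambda.

    Precomputes per-group cross-products once; each evaluation of the
    deviance at a new lambda costs O(J p^2).
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray, reml: bool):
        self.reml = reml
        self.n, self.p = X.shape
        _, idx, counts = np.unique(groups, return_inverse=True, return_counts=True)
        self.J = len(counts)
        self.nj = counts.astype(float)
        self.xtx = X.T @ X
        self.xty = X.T @ y
        self.yty = float(y @ y)
        # per-group sums of columns of X and of y
        self.S = np.zeros((self.J, self.p))
        np.add.at(self.S, idx, X)
        self.ty = np.bincount(idx, weights=y, minlength=self.J)
        if np.linalg.matrix_rank(self.xtx) < self.p:
            raise RankError("fixed-effect design is rank deficient (empty cell?)")

    def _gls(self, lam: float):
        c = lam / (1.0 + lam * self.nj)  # per-group shrinkage weight
        A = self.xtx - (self.S * c[:, None]).T @ self.S
        b = self.xty - self.S.T @ (c * self.ty)
        yvy = self.yty - float(c @ self.ty**2)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise RankError(str(err)) from err
        rss = yvy - float(beta @ b)  # r' V^-1 r at the GLS solution
        return beta, A, max(rss, 1e-300)

    def deviance(self, lam: float) -> float:
        beta, A, rss = self._gls(lam)
        logdet_v = float(np.sum(np.log1p(lam * self.nj)))
        if self.reml:
            dof = self.n - self.p
            sign, logdet_a = np.linalg.slogdet(A)
            if sign <= 0:
                raise RankError("X' V^-1 X not positive definite")
            return dof * np.log(rss / dof) + logdet_v + logdet_a + dof
        return self.n * np.log(rss / self.n) + logdet_v + self.n

    def solve(self, lam: float):
        """Full solution at a given lambda: beta, cov(beta), sigma_e^2, loglik."""
        beta, A, rss = self._gls(lam)
        dof = self.n - self.p if self.reml else self.n
        sigma2 = rss / dof
        cov = np.linalg.inv(A) * sigma2
        dev = self.deviance(lam)
        const = dof * np.log(2.0 * np.pi)
        loglik = -0.5 * (dev + const)
        return beta, cov, sigma2, loglik


def fit_lmm_arrays(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, reml: bool = True
) -> dict:
    """Numpy-level profiled (RE)ML fit (no table handling).

    Returns a dict with betas, cov_beta, sd_intercept, sd_resid, loglik
    and fitted fixed-effect predictions. ``fit_lmm`` wraps this with
    design construction, transforms and bookkeeping.
    """
    prof = _Profiler(np.asarray(y, float), np.asarray(X, float), groups, reml)
    res = optimize.minimize_scalar(
        lambda u: prof.deviance(np.exp(u)),
        bounds=(np.log(1e-10), np.log(1e8)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"profiled deviance optimization failed: {res.message}")
    lam = float(np.exp(res.x))
    if prof.deviance(0.0) <= res.fun:
        lam = 0.0
    beta, cov, sigma2, loglik = prof.solve(lam)
    return {
        "betas": beta,
        "cov_beta": cov,
        "sd_intercept": float(np.sqrt(lam * sigma2)),
        "sd_resid": float(np.sqrt(sigma2)),
        "loglik": float(loglik),
        "fitted_fixed": X @ beta,
        "n_groups": prof.J,
        "n_obs": prof.n,
    }


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> LmmFit:
    """Fit the random-intercept model by profiled (RE)ML.

    Rows with a missing response are dropped (complete-case per
    response); n_obs and n_groups report what was actually fitted. The
    variance ratio lambda is optimized on the log scale over
    [1e-10, 1e8] by bounded scalar minimization of the profiled
    deviance; the lambda -> 0 boundary (no subject variance) is checked
    explicitly so OLS-like data converge to sd_intercept = 0.
    """
    df = table.dropna(subset=[spec.response])
    y = df[spec.response].to_numpy(dtype=float)
    if spec.log_transform:
        if (y <= 0).any():
            raise ValueError("log transform requires a strictly positive response")
        y = np.log(y)
    X = _build_design(df, spec)
    groups = df[spec.grouping].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 subjects")
    raw = fit_lmm_arrays(y, X, groups, spec.reml)
    return LmmFit(
        spec=spec,
        terms=spec.term_names,
        betas=raw["betas"],
        ses=np.sqrt(np.diag(raw["cov_beta"])),
        sd_intercept=raw["sd_intercept"],
        sd_resid=raw["sd_resid"],
        loglik=raw["loglik"],
        n_groups=raw["n_groups"],
        n_obs=raw["n_obs"],
        fitted_fixed=raw["fitted_fixed"],
        cov_beta=raw["cov_beta"],
    )


def _satterthwaite_df(table: pd.DataFrame, spec: ModelSpec, fit: LmmFit) -> np.ndarray:
    """Satterthwaite df per coefficient from the REML variance-component
    information, with derivatives taken numerically."""
    df = table.dropna(subset=[spec.response])
    y = df[spec.response].to_numpy(dtype=float)
    if spec.log_transform:
        y = np.log(y)
    X = _build_design(df, spec)
    groups = df[spec.grouping].to_numpy()
    prof = _Profiler(y, X, groups, reml=True)

    s2u, s2e = fit.sd_intercept**2, fit.sd_resid**2
    theta0 = np.array([s2u, s2e])

    def var_beta(theta):
        lam = theta[0] / theta[1]
        _, A, _ = prof._gls(lam)
        return np.diag(np.linalg.inv(A)) * theta[1]

    def m2ll(theta):
        lam = theta[0] / theta[1]
        _, A, rss = prof._gls(lam)
        dof = prof.n - prof.p
        _, logdet_a = np.linalg.slogdet(A)
        return (
            dof * np.log(theta[1])
            + float(np.sum(np.log1p(lam * prof.nj)))
            + logdet_a
            + rss / theta[1]
        )

    h = np.maximum(1e-4 * np.abs(theta0), 1e-8)
    grad = np.zeros((2, prof.p))
    H = np.zeros((2, 2))
    for i in range(2):
        ei = np.zeros(2); ei[i] = h[i]
        tp, tm = np.clip(theta0 + ei, 1e-12, None), np.clip(theta0 - ei, 1e-12, None)
        grad[i] = (var_beta(tp) - var_beta(tm)) / (tp[i] - tm[i])
        for j in range(2):
            ej = np.zeros(2); ej[j] = h[j]
            H[i, j] = (
                m2ll(np.clip(theta0 + ei + ej, 1e-12, None))
                - m2ll(np.clip(theta0 + ei - ej, 1e-12, None))
                - m2ll(np.clip(theta0 - ei + ej, 1e-12, None))
                + m2ll(np.clip(theta0 - ei - ej, 1e-12, None))
            ) / (4.0 * h[i] * h[j])
    info = 0.5 * H  # information of -2 log L_R
    try:
        vcov_theta = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.full(prof.p, float(prof.n - prof.p))
    out = np.empty(prof.p)
    vb = var_beta(theta0)
    for k in range(prof.p):
        g = grad[:, k]
        denom = float(g @ vcov_theta @ g)
        out[k] = 2.0 * vb[k] ** 2 / denom if denom > 0 else float(prof.n - prof.p)
    return np.clip(out, 1.0, None)


def wald_pvalues(
    fit: LmmFit,
    df_method: str = "residual",
    table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Two-sided p-values from t = b/SE.

    df_method="residual" uses n_obs - p; "satterthwaite" approximates
    per-coefficient df from the REML information (requires the fitted
    table). The method used is recorded in the output.
    """
    if df_method == "residual":
        dfs = np.full(len(fit.betas), float(fit.n_obs - len(fit.betas)))
    elif df_method == "satterthwaite":
        if table is None:
            raise ValueError("satterthwaite df needs the original table")
        dfs = _satterthwaite_df(table, fit.spec, fit)
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    t = fit.t
    p = 2.0 * stats.t.sf(np.abs(t), dfs)
    return pd.DataFrame(
        {"term": fit.terms, "t": t, "df": dfs, "p": p, "df_method": df_method}
    )
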