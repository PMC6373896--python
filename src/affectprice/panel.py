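"""Within-between random panel models for latent affect outcomes.

The central estimator is a random-intercept linear mixed model on a design
in which every time-varying (level-1) covariate is split into a
within-cluster component ``x - x_bar`` and a between-cluster component
``x_bar`` (the cluster mean over available waves):

    theta_it = alpha + sum_k beta_w_k (x_ikt - xbar_ik) + sum_k beta_b_k xbar_ik
               + sum_j beta_c_j c_ij + v_i + eps_it

with ``v_i ~ N(0, sigma_v^2)`` a cluster intercept and
``eps_it ~ N(0, sigma_eps^2)`` the occasion-level error. Because the within
coefficients are identified from within-cluster variation only, they equal
the fixed-effects (cluster-demeaned least squares) estimates exactly in the
linear case, while the model still admits time-invariant covariates and a
test of whether the between effect differs from the within effect — the
property that makes the estimator robust to cluster-level heterogeneity
correlated with the covariates.

Estimation is maximum likelihood. The marginal per-cluster covariance
``sigma_eps^2 I + sigma_v^2 11'`` is rank-one, so the likelihood is profiled
analytically over the coefficients and sigma_eps^2 and maximized over the
single variance ratio ``lambda = sigma_v^2 / sigma_eps^2`` (on the log
scale, with the lambda = 0 boundary checked explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

__all__ = [
    "DesignSpec",
    "ModelFit",
    "WaldResult",
    "SpecificationError",
    "RankError",
    "decompose_within_between",
    "fit_wb_random",
    "fit_correlated_re",
    "fit_random_effects",
    "fit_fixed_effects",
    "fit_pooled_ols",
    "wald_equal_effects",
]

_LOG2PI = np.log(2.0 * np.pi)


class SpecificationError(ValueError):
    """A variable is placed at the wrong level of the design."""


class RankError(np.linalg.LinAlgError):
    """The design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; suspect columns: {self.columns}")


@dataclass(frozen=True)
class DesignSpec:
    """Roles of the variables in one affect equation.

    level1 variables vary within clusters (alcohol grams/day, log income);
    level2 variables are constant within every cluster (demographics).
    """

    outcome: str
    level1: tuple[str, ...]
    level2: tuple[str, ...] = ()
    cluster: str = "participant_id"
    intercept: bool = True

    def __post_init__(self):
        object.__setattr__(self, "level1", tuple(self.level1))
        object.__setattr__(self, "level2", tuple(self.level2))


@dataclass
class WaldResult:
    statistic: float
    df: int
    p_value: float
    variables: tuple[str, ...]


@dataclass
class ModelFit:
    """Fitted coefficients, variance components and their joint covariance."""

    model_kind: str
    params: pd.Series
    cov: pd.DataFrame
    sigma_v2: float
    sigma_eps2: float
    loglik: float
    n_obs: int
    n_clusters: int
    spec: DesignSpec
    converged: bool = True
    boundary: bool = False

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    @property
    def zstats(self) -> pd.Series:
        return self.params / self.se

    @property
    def alpha(self) -> float:
        return float(self.params.get("const", np.nan))

    def _select(self, suffix: str) -> pd.Series:
        keep = [n for n in self.params.index if n.endswith(suffix)]
        out = self.params.loc[keep].copy()
        out.index = [n[: -len(suffix)] for n in keep]
        return out

    @property
    def beta_within(self) -> pd.Series:
        return self._select(":within")

    @property
    def beta_between(self) -> pd.Series:
        return self._select(":between")

    @property
    def beta_invariant(self) -> pd.Series:
        keep = [
            n
            for n in self.params.index
            if not (n == "const" or n.endswith(":within") or n.endswith(":between"))
        ]
        return self.params.loc[keep]

    def coef_pair(self, var_a: str, var_b: str, component: str = "between"):
        """Coefficients and 2x2 covariance for two variables of one component.

        Used to hand (beta_AC, beta_lnY) with their joint covariance to the
        shadow-pricing stage.
        """
        names = [f"{v}:{component}" for v in (var_a, var_b)]
        for n in names:
            if n not in self.params.index:
                raise KeyError(f"{n} not in fit")
        b = self.params.loc[names].to_numpy()
        V = self.cov.loc[names, names].to_numpy()
        return b, V


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def _check_levels(df: pd.DataFrame, spec: DesignSpec) -> None:
    g = df.groupby(spec.cluster, sort=False)
    for v in spec.level1:
        within_var = g[v].transform("mean")
        if float(np.max(np.abs(df[v].to_numpy() - within_var.to_numpy()))) <= 1e-12:
            raise SpecificationError(
                f"level-1 variable {v!r} has no within-cluster variation in any cluster"
            )
    for v in spec.level2:
        if (g[v].nunique() > 1).any():
            raise SpecificationError(f"level-2 variable {v!r} varies within a cluster")


def decompose_within_between(df: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    """Augment the panel with demeaned and cluster-mean columns.

    For each level-1 variable ``x`` adds ``x:within`` = x - xbar (sums to
    zero within every cluster) and ``x:between`` = xbar, the cluster mean
    over the cluster's available waves.
    """
    _check_levels(df, spec)
    out = df.copy()
    g = out.groupby(spec.cluster, sort=False)
    for v in spec.level1:
        xbar = g[v].transform("mean")
        out[f"{v}:between"] = xbar
        out[f"{v}:within"] = out[v] - xbar
    return out


def _build_design(df: pd.DataFrame, columns: Sequence[str], intercept: bool):
    names = (["const"] if intercept else []) + list(columns)
    X = np.empty((len(df), len(names)))
    j = 0
    if intercept:
        X[:, 0] = 1.0
        j = 1
    for k, c in enumerate(columns):
        X[:, j + k] = df[c].to_numpy(dtype=float)
    return X, names


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    # QR with pivoting localizes the collinear columns
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps
    bad = piv[d < tol] if np.any(d < tol) else []
    if len(bad):
        raise RankError([names[i] for i in bad])


# ---------------------------------------------------------------------------
# Profiled ML for the random-intercept model
# ---------------------------------------------------------------------------


def _cluster_index(df: pd.DataFrame, cluster: str) -> np.ndarray:
    codes, _ = pd.factorize(df[cluster], sort=False)
    return codes


def _fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    cluster_idx: np.ndarray,
    names: Sequence[str],
    *,
    log_lambda_bounds: tuple[float, float] = (-12.0, 8.0),
    xatol: float = 1e-10,
):
    """ML fit of y = X beta + v_cluster + eps via the profiled likelihood."""
    N, p = X.shape
    _check_rank(X, names)
    G = int(cluster_idx.max()) + 1
    n_i = np.bincount(cluster_idx, minlength=G).astype(float)

    XtX = X.T @ X
    Xty = X.T @ y
    Sx = np.empty((G, p))
    for j in range(p):
        Sx[:, j] = np.bincount(cluster_idx, weights=X[:, j], minlength=G)
    Sy = np.bincount(cluster_idx, weights=y, minlength=G)

    def profile(lam: float):
        c = lam / (1.0 + n_i * lam)  # Woodbury factor per cluster
        A = XtX - (Sx * c[:, None]).T @ Sx  # X' W^-1 X
        b = Xty - Sx.T @ (c * Sy)  # X' W^-1 y
        beta = np.linalg.solve(A, b)
        r = y - X @ beta
        Sr = np.bincount(cluster_idx, weights=r, minlength=G)
        rss = float(r @ r - c @ (Sr**2))  # r' W^-1 r
        sigma2 = rss / N
        neg2ll = N * np.log(sigma2) + float(np.sum(np.log1p(n_i * lam))) + N * (1.0 + _LOG2PI)
        return neg2ll, beta, A, sigma2

    lo, hi = log_lambda_bounds
    res = optimize.minimize_scalar(
        lambda t: profile(np.exp(t))[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    lam_hat = float(np.exp(res.x))
    neg2ll_hat = float(res.fun)
    neg2ll_zero = profile(0.0)[0]
    boundary = False
    if neg2ll_zero <= neg2ll_hat or lam_hat <= np.exp(lo) * 1.01:
        lam_hat = 0.0
        boundary = True

    neg2ll, beta, A, sigma2 = profile(lam_hat)
    cov_beta = sigma2 * np.linalg.inv(A)
    return {
        "beta": beta,
        "cov": cov_beta,
        "sigma_eps2": sigma2,
        "sigma_v2": lam_hat * sigma2,
        "loglik": -0.5 * neg2ll,
        "boundary": boundary,
        "converged": bool(res.success),
        "n_clusters": G,
        "names": list(names),
    }


def _to_fit(raw: dict, df_len: int, spec: DesignSpec, kind: str) -> ModelFit:
    idx = pd.Index(raw["names"])
    return ModelFit(
        model_kind=kind,
        params=pd.Series(raw["beta"], index=idx),
        cov=pd.DataFrame(raw["cov"], index=idx, columns=idx),
        sigma_v2=float(raw["sigma_v2"]),
        sigma_eps2=float(raw["sigma_eps2"]),
        loglik=float(raw["loglik"]),
        n_obs=df_len,
        n_clusters=int(raw["n_clusters"]),
        spec=spec,
        converged=raw["converged"],
        boundary=raw["boundary"],
    )


def fit_wb_random(df: pd.DataFrame, spec: DesignSpec) -> ModelFit:
    """Maximum-likelihood within-between random model.

    Coefficients carry ``:within`` / ``:between`` suffixes for the
    decomposed level-1 variables; level-2 coefficients keep their own names.
    """
    aug = decompose_within_between(df, spec)
    cols = (
        [f"{v}:within" for v in spec.level1]
        + [f"{v}:between" for v in spec.level1]
        + list(spec.level2)
    )
    X, names = _build_design(aug, cols, spec.intercept)
    y = aug[spec.outcome].to_numpy(dtype=float)
    raw = _fit_random_intercept(y, X, _cluster_index(aug, spec.cluster), names)
    return _to_fit(raw, len(df), spec, "wb_random")


def fit_correlated_re(df: pd.DataFrame, spec: DesignSpec) -> ModelFit:
    """Correlated random-effects (Mundlak) parameterization.

    Same column space as the within-between model: raw level-1 variables
    plus their cluster means. The coefficient on the raw variable is the
    within effect; the between effect is (coefficient on the cluster mean)
    plus the within effect.
    """
    aug = decompose_within_between(df, spec)
    cols = list(spec.level1) + [f"{v}:between" for v in spec.level1] + list(spec.level2)
    X, names = _build_design(aug, cols, spec.intercept)
    y = aug[spec.outcome].to_numpy(dtype=float)
    raw = _fit_random_intercept(y, X, _cluster_index(aug, spec.cluster), names)
    return _to_fit(raw, len(df), spec, "correlated_re")


def fit_random_effects(df: pd.DataFrame, spec: DesignSpec) -> ModelFit:
    """Naive random-intercept model on the undecomposed covariates."""
    _check_levels(df, spec)
    cols = list(spec.level1) + list(spec.level2)
    X, names = _build_design(df, cols, spec.intercept)
    y = df[spec.outcome].to_numpy(dtype=float)
    raw = _fit_random_intercept(y, X, _cluster_index(df, spec.cluster), names)
    return _to_fit(raw, len(df), spec, "random")


def fit_fixed_effects(df: pd.DataFrame, spec: DesignSpec) -> ModelFit:
    """Within (fixed-effects) estimator: least squares on demeaned data.

    Only level-1 variables are admissible — a variable constant within
    clusters is eliminated by the within transformation.
    """
    if spec.level2:
        raise SpecificationError(
            f"fixed-effects estimator cannot include cluster-invariant variables {spec.level2}"
        )
    _check_levels(df, spec)
    g = df.groupby(spec.cluster, sort=False)
    yd = (df[spec.outcome] - g[spec.outcome].transform("mean")).to_numpy(dtype=float)
    names = [f"{v}:within" for v in spec.level1]
    X = np.column_stack(
        [(df[v] - g[v].transform("mean")).to_numpy(dtype=float) for v in spec.level1]
    )
    _check_rank(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, yd, rcond=None)
    r = yd - X @ beta
    G = df[spec.cluster].nunique()
    dof = len(df) - G - X.shape[1]
    sigma2 = float(r @ r) / max(dof, 1)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    idx = pd.Index(names)
    return ModelFit(
        model_kind="fixed",
        params=pd.Series(beta, index=idx),
        cov=pd.DataFrame(cov, index=idx, columns=idx),
        sigma_v2=float("nan"),
        sigma_eps2=sigma2,
        loglik=float("nan"),
        n_obs=len(df),
        n_clusters=G,
        spec=spec,
    )


def fit_pooled_ols(df: pd.DataFrame, spec: DesignSpec) -> ModelFit:
    """Least squares for singleton-cluster (cross-sectional) designs.

    With one observation per cluster the within-between model degenerates:
    only between effects are identified, so level-1 exposures are reported
    with a ``:between`` suffix.
    """
    cols = list(spec.level1) + list(spec.level2)
    X, names = _build_design(df, cols, spec.intercept)
    names = [
        f"{n}:between" if n in spec.level1 else n for n in names
    ]
    _check_rank(X, names)
    y = df[spec.outcome].to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    dof = max(len(df) - X.shape[1], 1)
    sigma2 = float(r @ r) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    # gaussian log-likelihood at the ML variance
    s2_ml = float(r @ r) / len(df)
    ll = -0.5 * len(df) * (np.log(s2_ml) + 1.0 + _LOG2PI)
    idx = pd.Index(names)
    return ModelFit(
        model_kind="pooled_ols",
        params=pd.Series(beta, index=idx),
        cov=pd.DataFrame(cov, index=idx, columns=idx),
        sigma_v2=0.0,
        sigma_eps2=sigma2,
        loglik=ll,
        n_obs=len(df),
        n_clusters=len(df),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Wald test of equal between and within effects
# ---------------------------------------------------------------------------


def wald_equal_effects(fit: ModelFit, variables: Sequence[str]) -> WaldResult:
    """Quadratic-form Wald test of H0: beta_between = beta_within.

    Works for any subset of decomposed level-1 variables, including a single
    one; the reference distribution is chi-square with one degree of freedom
    per variable tested.
    """
    variables = tuple(variables)
    if not variables:
        raise ValueError("no variables to test")
    names_w = [f"{v}:within" for v in variables]
    names_b = [f"{v}:between" for v in variables]
    for n in names_w + names_b:
        if n not in fit.params.index:
            raise KeyError(f"variable {n!r} absent from fit")
    d = fit.params.loc[names_b].to_numpy() - fit.params.loc[names_w].to_numpy()
    Vbb = fit.cov.loc[names_b, names_b].to_numpy()
    Vww = fit.cov.loc[names_w, names_w].to_numpy()
    Vbw = fit.cov.loc[names_b, names_w].to_numpy()
    V = Vbb + Vww - Vbw - Vbw.T
    stat = float(d @ np.linalg.solve(V, d))
    df = len(variables)
    return WaldResult(
        statistic=stat, df=df, p_value=float(chi2.sf(stat, df)), variables=variables
    )
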