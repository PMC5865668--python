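"""Longitudinal tumor-volume modelling by generalized least squares.

Mean model: volume ~ group + day + group:day.  Residuals are block
diagonal per mouse with one of three correlation structures —
independence, compound symmetry, or AR(1) on consecutive measurement
occasions — fit by maximum likelihood with the correlation parameter
profiled out by bounded 1-D search.  Structures are compared by AIC and
group contrasts at an evaluation day use Tukey's honest significant
difference via the studentized-range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import studentized_range

STRUCTURES = ("independence", "compound_symmetry", "ar1")


@dataclass
class GrowthData:
    """Long-format tumor volumes: one row per (mouse, day)."""

    records: pd.DataFrame

    REQUIRED = ("mouse", "group", "day", "volume")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"growth records missing columns: {missing}")
        if self.records.duplicated(["mouse", "day"]).any():
            raise ValueError("one record per (mouse, day) required")
        groups_per_mouse = self.records.groupby("mouse")["group"].nunique()
        if (groups_per_mouse > 1).any():
            bad = groups_per_mouse[groups_per_mouse > 1].index.tolist()
            raise ValueError(f"mice assigned to multiple groups: {bad}")
        if (self.records["volume"] < 0).any():
            raise ValueError("volumes must be >= 0")

    @property
    def groups(self) -> list[str]:
        return sorted(self.records["group"].unique())


@dataclass
class GlsFit:
    structure: str
    coefficients: pd.Series
    sigma2: float
    rho: float | None
    log_likelihood: float
    aic: float
    n_obs: int
    n_mean_params: int
    n_cov_params: int
    cov_unscaled: np.ndarray  # (X' R^-1 X)^-1; multiply by sigma2 for Cov(beta)
    groups: list[str] = field(default_factory=list)
    reference: str = ""

    def predict_group_mean(self, group: str, day: float) -> float:
        c = self.coefficients
        mu = c["intercept"] + c["day"] * day
        if group != self.reference:
            mu += c[f"group[{group}]"] + c[f"group[{group}]:day"] * day
        return float(mu)


@dataclass
class TukeyContrast:
    group_a: str
    group_b: str
    estimate: float
    std_error: float
    p_adjusted: float


def _design(data: GrowthData, reference: str | None = None):
    rec = data.records
    groups = data.groups
    if reference is None:
        reference = "vehicle" if "vehicle" in groups else groups[0]
    others = [g for g in groups if g != reference]
    day = rec["day"].to_numpy(float)
    cols = {"intercept": np.ones(len(rec))}
    for g in others:
        cols[f"group[{g}]"] = (rec["group"] == g).to_numpy(float)
    cols["day"] = day
    for g in others:
        cols[f"group[{g}]:day"] = cols[f"group[{g}]"] * day
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys()), rec["volume"].to_numpy(float), reference, groups


def _corr_matrix(structure: str, rho: float, k: int) -> np.ndarray:
    if structure == "independence":
        return np.eye(k)
    if structure == "compound_symmetry":
        r = np.full((k, k), rho)
        np.fill_diagonal(r, 1.0)
        return r
    if structure == "ar1":
        idx = np.arange(k)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    raise ValueError(f"unknown correlation structure: {structure!r}")


def _profile_loglik(structure, rho, X, y, blocks):
    """ML log-likelihood with beta and sigma2 profiled out, at fixed rho."""
    n, p = X.shape
    xtwx = np.zeros((p, p))
    xtwy = np.zeros(p)
    ytwy = 0.0
    logdet = 0.0
    chol_cache: dict[int, np.ndarray] = {}
    for idx in blocks:
        k = len(idx)
        if k not in chol_cache:
            r = _corr_matrix(structure, rho, k)
            chol_cache[k] = np.linalg.cholesky(r)
        L = chol_cache[k]
        logdet += 2.0 * np.log(np.diag(L)).sum()
        xb = np.linalg.solve(L, X[idx])
        yb = np.linalg.solve(L, y[idx])
        xtwx += xb.T @ xb
        xtwy += xb.T @ yb
        ytwy += yb @ yb
    beta = np.linalg.solve(xtwx, xtwy)
    rss_w = ytwy - beta @ xtwy
    sigma2 = max(rss_w / n, 1e-300)
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, beta, sigma2, xtwx


def fit_gls(
    data: GrowthData,
    structure: str = "independence",
    reference: str | None = None,
    log_volume: bool = False,
) -> GlsFit:
    """Maximum-likelihood GLS fit of volume ~ group + day + group:day.

    For compound symmetry and AR(1) the correlation parameter is profiled
    by bounded search on (-0.99, 0.99).  With independence the estimates
    coincide with ordinary least squares.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"structure must be one of {STRUCTURES}")
    rec = data.records
    mice_per_group = rec.groupby("group")["mouse"].nunique()
    if (mice_per_group < 2).any():
        raise ValueError("need at least 2 mice per group")
    if rec["day"].nunique() < 2:
        raise ValueError("need at least 2 distinct days")

    X, names, y, reference, groups = _design(data, reference)
    if log_volume:
        y = np.log(y + 1.0)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (a group observed on a single day?)")
    # block index per mouse, rows ordered by day within mouse
    blocks = [
        grp.sort_values("day").index.to_numpy()
        for _, grp in rec.reset_index(drop=True).groupby("mouse", sort=True)
    ]

    if structure == "independence":
        rho = None
        ll, beta, sigma2, xtwx = _profile_loglik(structure, 0.0, X, y, blocks)
        n_cov = 1
    else:
        kmax = max(len(b) for b in blocks)
        lo = -0.99
        if structure == "compound_symmetry" and kmax > 1:
            # CS correlation is positive definite only for rho > -1/(k-1)
            lo = max(lo, -1.0 / (kmax - 1) + 1e-6)
        res = minimize_scalar(
            lambda r: -_profile_loglik(structure, r, X, y, blocks)[0],
            bounds=(lo, 0.99),
            method="bounded",
            options={"xatol": 1e-8},
        )
        rho = float(res.x)
        ll, beta, sigma2, xtwx = _profile_loglik(structure, rho, X, y, blocks)
        n_cov = 2
    n, p = X.shape
    aic = -2.0 * ll + 2.0 * (p + n_cov)
    return GlsFit(
        structure=structure,
        coefficients=pd.Series(beta, index=names),
        sigma2=float(sigma2),
        rho=rho,
        log_likelihood=float(ll),
        aic=float(aic),
        n_obs=n,
        n_mean_params=p,
        n_cov_params=n_cov,
        cov_unscaled=np.linalg.inv(xtwx),
        groups=groups,
        reference=reference,
    )


def select_structure(
    data: GrowthData, reference: str | None = None, log_volume: bool = False
) -> GlsFit:
    """Fit all three correlation structures and keep the minimum-AIC one.

    Near-ties (dAIC < 1e-9) are broken toward fewer covariance parameters.
    """
    fits = [
        fit_gls(data, s, reference=reference, log_volume=log_volume)
        for s in STRUCTURES
    ]
    fits.sort(key=lambda f: (f.aic, f.n_cov_params))
    best = fits[0]
    for f in fits[1:]:
        if abs(f.aic - best.aic) < 1e-9 and f.n_cov_params < best.n_cov_params:
            best = f
    return best


def tukey_hsd(
    fit: GlsFit, data: GrowthData, evaluation_day: float
) -> list[TukeyContrast]:
    """All pairwise group contrasts of model-predicted means at one day.

    Standard errors come from the GLS coefficient covariance (with the
    unbiased residual-variance rescaling); adjusted p-values use the
    studentized-range distribution with k = number of groups and
    df = n_obs - n_mean_params.
    """
    days = data.records["day"]
    if not days.min() <= evaluation_day <= days.max():
        raise ValueError(
            f"evaluation day {evaluation_day} outside observed range "
            f"[{days.min()}, {days.max()}]"
        )
    groups = fit.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for pairwise contrasts")
    names = list(fit.coefficients.index)
    df_resid = fit.n_obs - fit.n_mean_params
    sigma2_unbiased = fit.sigma2 * fit.n_obs / df_resid
    cov_beta = sigma2_unbiased * fit.cov_unscaled

    def contrast_vector(group: str) -> np.ndarray:
        c = np.zeros(len(names))
        c[names.index("intercept")] = 1.0
        c[names.index("day")] = evaluation_day
        if group != fit.reference:
            c[names.index(f"group[{group}]")] = 1.0
            c[names.index(f"group[{group}]:day")] = evaluation_day
        return c

    out = []
    k = len(groups)
    for ga, gb in combinations(groups, 2):
        c = contrast_vector(ga) - contrast_vector(gb)
        est = float(c @ fit.coefficients.to_numpy())
        se = float(np.sqrt(c @ cov_beta @ c))
        if se == 0.0:
            p_adj = 1.0 if est == 0.0 else 0.0
        else:
            q = abs(est) / se * np.sqrt(2.0)
            p_adj = float(studentized_range.sf(q, k, df_resid))
        out.append(
            TukeyContrast(
                group_a=ga,
                group_b=gb,
                estimate=est,
                std_error=se,
                p_adjusted=min(max(p_adj, 0.0), 1.0),
            )
        )
    return out
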