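"""Two-group differential expression with beta-uniform-mixture FDR control.

Pipeline: pooled-variance t-test per protein, signed fold-change display
convention (fold = 2**delta for delta >= 0, else -2**(-delta)), maximum
likelihood fit of the p-value distribution as

    f(p) = lambda + (1 - lambda) * a * p**(a - 1),    0 < a < 1,

an upper bound on the null proportion pi0 <= lambda + (1 - lambda) * a,
and the rejection threshold where the model-estimated FDR reaches the
nominal level.  Also hosts top-hit selection and the correlation-distance
hierarchical clustering used for the expression heatmap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.optimize import minimize
from scipy.spatial.distance import squareform
from scipy.special import expit, logit
from scipy.stats import t as t_dist

from .normalization import NON_SCC, SCC, ExpressionMatrix

logger = logging.getLogger(__name__)

_P_NUDGE = 1e-12


@dataclass
class GroupComparisonResult:
    protein: str
    delta_log2: float
    fold_change_signed: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


@dataclass
class BumFit:
    """Beta-uniform mixture of p-values: lambda*U(0,1) + (1-lambda)*Beta(a, 1)."""

    lambda_mix: float
    a_shape: float
    log_likelihood: float

    @property
    def pi0_upper(self) -> float:
        return self.lambda_mix + (1.0 - self.lambda_mix) * self.a_shape

    def density(self, p: np.ndarray | float) -> np.ndarray:
        p = np.asarray(p, float)
        return self.lambda_mix + (1.0 - self.lambda_mix) * self.a_shape * p ** (
            self.a_shape - 1.0
        )

    def cdf(self, p: np.ndarray | float) -> np.ndarray:
        p = np.asarray(p, float)
        return self.lambda_mix * p + (1.0 - self.lambda_mix) * p**self.a_shape

    def estimated_fdr(self, tau: np.ndarray | float) -> np.ndarray:
        """Model-estimated FDR of rejecting all p <= tau."""
        tau = np.asarray(tau, float)
        return self.pi0_upper * tau / self.cdf(tau)


@dataclass
class FdrDecision:
    nominal_q: float
    tau_cutoff: float
    n_significant: int
    significant: list[str] = field(default_factory=list)


def signed_fold(delta_log2: float) -> float:
    """Display convention: fold >= 1 with sign giving the direction.

    delta = +1 -> +2.0 (2-fold higher); delta = -1.770 -> -3.41
    (3.41-fold lower); delta = 0 -> +1.
    """
    if delta_log2 >= 0:
        return float(2.0**delta_log2)
    return float(-(2.0**-delta_log2))


def pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pooled-variance two-sample t statistic, df, and two-sided p."""
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    delta = x.mean() - y.mean()
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        if delta == 0.0:
            return 0.0, float(df), 1.0
        return float(np.sign(delta) * np.inf), float(df), 0.0
    t = delta / se
    return float(t), float(df), float(2.0 * t_dist.sf(abs(t), df))


def two_group_test(
    matrix: ExpressionMatrix,
    group_a: str = SCC,
    group_b: str = NON_SCC,
    equal_var: bool = True,
) -> list[GroupComparisonResult]:
    """Per-protein two-sample t-test of group_a vs group_b.

    delta_log2 = mean(group_a) - mean(group_b).  Proteins with fewer than
    2 usable samples in either group are omitted (logged, not raised).
    Set ``equal_var=False`` for a Welch test.
    """
    cols_a = [s for s in matrix.samples if matrix.histology.get(s) == group_a]
    cols_b = [s for s in matrix.samples if matrix.histology.get(s) == group_b]
    results: list[GroupComparisonResult] = []
    for protein in matrix.proteins:
        row = matrix.values.loc[protein]
        x = row[cols_a].dropna().to_numpy(float)
        y = row[cols_b].dropna().to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            logger.warning(
                "protein %s skipped: %d vs %d usable samples", protein, len(x), len(y)
            )
            continue
        if equal_var:
            t, df, p = pooled_t(x, y)
        else:
            from scipy.stats import ttest_ind

            res = ttest_ind(x, y, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
            df = float(res.df)
        delta = float(x.mean() - y.mean())
        results.append(
            GroupComparisonResult(
                protein=protein,
                delta_log2=delta,
                fold_change_signed=signed_fold(delta),
                t_statistic=t,
                degrees_of_freedom=df,
                p_value=p,
            )
        )
    return results


def _bum_negloglik(u: np.ndarray, p: np.ndarray) -> float:
    lam, a = expit(u[0]), expit(u[1])
    dens = lam + (1.0 - lam) * a * p ** (a - 1.0)
    return -float(np.log(dens).sum())


def fit_bum(p_values: np.ndarray | list[float], n_starts: int = 5) -> BumFit:
    """Maximum-likelihood fit of the beta-uniform mixture.

    Optimizes on logit-transformed (lambda, a) from an ``n_starts`` x
    ``n_starts`` grid of starting points; p-values equal to 1 are nudged
    just below 1 before taking logs.
    """
    p = np.asarray(p_values, float)
    if len(p) < 10:
        raise ValueError("need at least 10 p-values to fit the mixture")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    p = np.minimum(p, 1.0 - _P_NUDGE)

    grid = logit(np.linspace(0.1, 0.9, n_starts))
    best = None
    for u_l in grid:
        for u_a in grid:
            res = minimize(
                _bum_negloglik,
                np.array([u_l, u_a]),
                args=(p,),
                method="L-BFGS-B",
                options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
    lam, a = float(expit(best.x[0])), float(expit(best.x[1]))
    return BumFit(lambda_mix=lam, a_shape=a, log_likelihood=-float(best.fun))


def fdr_cutoff(
    fit: BumFit,
    nominal_q: float,
    results: list[GroupComparisonResult] | None = None,
    p_values: np.ndarray | None = None,
) -> FdrDecision:
    """Largest rejection threshold whose model-estimated FDR stays <= q.

    Estimated FDR(tau) = pi0_upper * tau / (lambda*tau + (1-lambda)*tau^a)
    is non-decreasing in tau for a < 1, so the threshold is found by
    bisection; if even tiny tau exceeds q the cutoff collapses to 0.
    """
    if not 0.0 < nominal_q < 1.0:
        raise ValueError("nominal_q must be in (0, 1)")
    if fit.pi0_upper <= 0.0:
        raise ValueError("degenerate mixture fit: pi0_upper must be > 0")

    lo, hi = 1e-300, 1.0
    if fit.estimated_fdr(hi) <= nominal_q:
        tau = 1.0
    elif fit.estimated_fdr(lo) > nominal_q:
        tau = 0.0
    else:
        for _ in range(200):
            mid = np.sqrt(lo * hi)  # bisect in log space: tau spans decades
            if fit.estimated_fdr(mid) <= nominal_q:
                lo = mid
            else:
                hi = mid
        tau = lo

    significant: list[str] = []
    if results is not None:
        significant = sorted(
            (r.protein for r in results if r.p_value <= tau),
        )
        n_sig = len(significant)
    elif p_values is not None:
        n_sig = int((np.asarray(p_values, float) <= tau).sum())
    else:
        n_sig = 0
    return FdrDecision(
        nominal_q=nominal_q, tau_cutoff=float(tau), n_significant=n_sig,
        significant=significant,
    )


def select_top(
    results: list[GroupComparisonResult], p_threshold: float = 0.05
) -> list[str]:
    """Proteins with p < threshold, ascending p, ties by name."""
    if not results:
        raise ValueError("no comparison results to select from")
    hits = [r for r in results if r.p_value < p_threshold]
    hits.sort(key=lambda r: (r.p_value, r.protein))
    return [r.protein for r in hits]


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    row_newick: str
    col_newick: str
    degenerate_rows: list[str] = field(default_factory=list)


def correlation_distance_matrix(data: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Pairwise 1 - Pearson distances between rows.

    Zero-variance rows have undefined correlation; their distance to every
    other row is set to the maximum (2.0).  Returns the square matrix and
    the indices of degenerate rows.
    """
    sd = data.std(axis=1)
    degenerate = np.flatnonzero(sd == 0.0).tolist()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    dist = 1.0 - corr
    for i in degenerate:
        dist[i, :] = 2.0
        dist[:, i] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return dist, degenerate


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    tree = to_tree(z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

    return walk(tree) + ";"


def hierarchical_cluster(values: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering of rows and columns at 1 - Pearson distance.

    Missing entries are imputed with the row median first.  Leaf orders are
    deterministic (scipy's convention: earliest original index first on
    tied merges).
    """
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("clustering requires at least 2 rows and 2 columns")
    data = values.to_numpy(float).copy()
    for i in range(data.shape[0]):
        row = data[i]
        if np.isnan(row).any():
            med = np.nanmedian(row)
            row[np.isnan(row)] = med

    row_dist, bad_rows = correlation_distance_matrix(data)
    col_dist, _ = correlation_distance_matrix(data.T)
    for i in bad_rows:
        logger.warning("zero-variance row %r: distance set to maximum", values.index[i])

    row_z = linkage(squareform(row_dist, checks=False), method="average")
    col_z = linkage(squareform(col_dist, checks=False), method="average")
    row_labels = [str(x) for x in values.index]
    col_labels = [str(x) for x in values.columns]
    row_order = [row_labels[i] for i in to_tree(row_z).pre_order()]
    col_order = [col_labels[i] for i in to_tree(col_z).pre_order()]
    return ClusterResult(
        row_linkage=row_z,
        col_linkage=col_z,
        row_order=row_order,
        col_order=col_order,
        row_newick=_linkage_to_newick(row_z, row_labels),
        col_newick=_linkage_to_newick(col_z, col_labels),
        degenerate_rows=[values.index[i] for i in bad_rows],
    )
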