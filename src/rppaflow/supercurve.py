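"""Joint logistic-curve quantification of dilution series.

All spots of one antibody slide are pooled into a single sigmoid response
curve; each sample's relative log2 concentration is the horizontal offset
that best places its dilution series on that curve.

Model for a spot of sample ``s`` at dilution step ``j``::

    intensity = alpha + beta * logistic(gamma * (x_s - j - x0)) + noise

``alpha`` is background, ``beta`` the dynamic range (> 0), ``gamma`` the
slope per log2 dilution unit (> 0), and ``x0`` a curve location offset.
Because a common shift of all ``x_s`` can be traded against ``x0``, the
``x_s`` are identified by the constraint mean(x) = 0; ``x0`` absorbs the
overall concentration level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import expit

from .normalization import ExpressionMatrix

_X_BOUND = 15.0  # search window for per-sample offsets after re-centering


@dataclass
class SlideMeasurements:
    """Raw spot intensities for one antibody slide.

    ``records`` columns: sample_id, dilution_step, replicate, intensity.
    """

    antibody: str
    records: pd.DataFrame
    truth: dict[str, float] | None = None

    REQUIRED = ("sample_id", "dilution_step", "replicate", "intensity")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"slide records missing columns: {missing}")
        inten = self.records["intensity"].to_numpy(float)
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")
        if (inten < 0).any():
            raise ValueError("intensities must be non-negative")
        steps_per_sample = self.records.groupby("sample_id")["dilution_step"].nunique()
        if (steps_per_sample < 3).any():
            bad = steps_per_sample[steps_per_sample < 3].index.tolist()
            raise ValueError(f"samples with < 3 distinct dilution steps: {bad}")

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())


@dataclass
class SuperCurveFit:
    """Fitted slide curve and per-sample relative log2 concentrations."""

    antibody: str
    alpha: float
    beta: float
    gamma: float
    x0: float
    x: dict[str, float]
    rss: float
    r_squared: float
    converged: bool
    iterations: int
    rss_history: list[float] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)

    def predict(self, x_value: float, step: np.ndarray | float) -> np.ndarray:
        return self.alpha + self.beta * expit(self.gamma * (x_value - np.asarray(step) - self.x0))


def _model(alpha, beta, gamma, x0, x_per_spot, steps):
    return alpha + beta * expit(gamma * (x_per_spot - steps - x0))


def _rss(alpha, beta, gamma, x0, x_per_spot, steps, intensity):
    r = intensity - _model(alpha, beta, gamma, x0, x_per_spot, steps)
    return float(r @ r)


def fit_supercurve(
    slide: SlideMeasurements, tol: float = 1e-8, max_iter: int = 200
) -> SuperCurveFit:
    """Fit the pooled logistic curve by block-coordinate descent.

    Alternates (1) nonlinear least squares on the curve parameters with the
    sample offsets held fixed, (2) a bounded 1-D refinement of each sample's
    offset on the current curve, and (3) re-centering of the offsets to
    mean 0 with the location parameter compensating.  The objective never
    increases; iteration stops when the relative RSS improvement drops
    below ``tol``.
    """
    rec = slide.records
    samples = slide.samples
    if len(samples) < 2:
        raise ValueError("supercurve fitting requires at least 2 samples")

    sample_idx = {s: i for i, s in enumerate(samples)}
    spot_sample = rec["sample_id"].map(sample_idx).to_numpy()
    steps = rec["dilution_step"].to_numpy(float)
    intensity = rec["intensity"].to_numpy(float)
    n = len(samples)

    # init: background = min, range = spread, unit slope, curve centered on steps
    alpha = float(intensity.min())
    beta = max(float(intensity.max() - intensity.min()), 1e-6)
    gamma = 1.0
    x0 = -float(steps.mean())

    sample_mean = np.zeros(n)
    for s, i in sample_idx.items():
        sample_mean[i] = intensity[spot_sample == i].mean()
    sd = sample_mean.std()
    x = (sample_mean - sample_mean.mean()) / sd if sd > 0 else np.zeros(n)

    def total_rss(a, b, g, x0_, xv):
        return _rss(a, b, g, x0_, xv[spot_sample], steps, intensity)

    rss = total_rss(alpha, beta, gamma, x0, x)
    history = [rss]
    converged = False
    iterations = 0

    for iterations in range(1, max_iter + 1):
        # (1) curve parameters given x; beta, gamma positive via log parameters
        theta0 = np.array([alpha, np.log(beta), np.log(gamma), x0])

        def curve_resid(theta):
            a, lb, lg, x0_ = theta
            b = np.exp(np.clip(lb, -50.0, 50.0))
            g = np.exp(np.clip(lg, -50.0, 50.0))
            return intensity - _model(a, b, g, x0_, x[spot_sample], steps)

        sol = least_squares(curve_resid, theta0, method="lm", max_nfev=200)
        cand = (sol.x[0], float(np.exp(sol.x[1])), float(np.exp(sol.x[2])), sol.x[3])
        if total_rss(*cand, x) <= rss:
            alpha, beta, gamma, x0 = cand

        # (2) per-sample 1-D refinement (objective unimodal on a monotone curve)
        for s, i in sample_idx.items():
            mask = spot_sample == i
            st, y = steps[mask], intensity[mask]

            def obj(xi):
                r = y - _model(alpha, beta, gamma, x0, xi, st)
                return float(r @ r)

            res = minimize_scalar(
                obj, bounds=(-_X_BOUND, _X_BOUND), method="bounded",
                options={"xatol": 1e-12},
            )
            if res.fun <= obj(x[i]):
                x[i] = float(res.x)

        # (3) identifiability: mean(x) = 0, absorbed by the location offset
        shift = x.mean()
        x -= shift
        x0 -= shift

        new_rss = total_rss(alpha, beta, gamma, x0, x)
        history.append(new_rss)
        if new_rss == 0.0:
            converged = True
            rss = new_rss
            break
        if rss > 0 and (rss - new_rss) / rss < tol:
            # tiny float jitter from the re-centering step still counts as
            # converged; a genuine RSS increase does not
            converged = new_rss <= rss * (1.0 + 100.0 * tol)
            rss = min(new_rss, rss)
            break
        rss = new_rss

    diagnostics = []
    for s, i in sample_idx.items():
        y = intensity[spot_sample == i]
        if y.std() < 1e-9 and alpha + 0.05 * beta < y.mean() < alpha + 0.95 * beta:
            diagnostics.append(f"flat dilution series at interior signal level: {s}")

    tss = float(((intensity - intensity.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return SuperCurveFit(
        antibody=slide.antibody,
        alpha=float(alpha),
        beta=float(beta),
        gamma=float(gamma),
        x0=float(x0),
        x={s: float(x[i]) for s, i in sample_idx.items()},
        rss=float(rss),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        converged=bool(converged),
        iterations=iterations,
        rss_history=history,
        diagnostics=diagnostics,
    )


def quantify_slides(
    slides: list[SlideMeasurements], tol: float = 1e-8, max_iter: int = 200
) -> tuple[ExpressionMatrix, list[SuperCurveFit]]:
    """Fit every slide and assemble the antibody x sample matrix.

    Samples absent from a slide yield missing entries.  Returns the matrix
    together with the per-slide fits for diagnostics.
    """
    if not slides:
        raise ValueError("no slides to quantify")
    fits = [fit_supercurve(s, tol=tol, max_iter=max_iter) for s in slides]
    all_samples: list[str] = []
    for s in slides:
        for smp in s.samples:
            if smp not in all_samples:
                all_samples.append(smp)
    data = pd.DataFrame(
        np.nan, index=[f.antibody for f in fits], columns=all_samples, dtype=float
    )
    for f in fits:
        for smp, val in f.x.items():
            data.loc[f.antibody, smp] = val
    return ExpressionMatrix(values=data), fits
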