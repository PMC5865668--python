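"""Median-effect dose-response fitting and drug-interaction scoring.

The median-effect law fa/(1-fa) = (D/Dm)^m is fit by ordinary least
squares on the log-log linearization; the interaction index of a
fixed-ratio combination is the two-term Loewe score

    IAI = (Dc*r1)/D1(fa) + (Dc*r2)/D2(fa)

evaluated at a stated effect level fa (default the half-effect).  Indices
within 0.05 of 1 are labelled additive, below synergism, above antagonism.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

ADDITIVE_BAND = 0.05


@dataclass
class DoseResponse:
    """Viability (fraction of untreated control) at each dose of one agent
    or fixed-ratio combination."""

    label: str
    doses: np.ndarray
    viability: np.ndarray
    ratio: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, float)
        self.viability = np.asarray(self.viability, float)
        if self.doses.shape != self.viability.shape:
            raise ValueError("doses and viability must have equal length")
        if (self.doses <= 0).any():
            raise ValueError("doses must be strictly positive")
        if not np.all(np.diff(self.doses) > 0):
            raise ValueError("doses must be sorted strictly ascending")
        if not np.all(np.isfinite(self.viability)):
            raise ValueError("viability must be finite")


@dataclass
class MedianEffectFit:
    label: str
    m: float
    dm: float
    r_squared: float
    n_points_used: int
    monotone: bool = True

    @property
    def ic50(self) -> float:
        return self.dm

    @property
    def log10_ic50(self) -> float:
        return math.log10(self.dm)

    def required_dose(self, fa: float) -> float:
        """Dose producing affected fraction fa: D = Dm*(fa/(1-fa))^(1/m)."""
        if not 0.0 < fa < 1.0:
            raise ValueError("fa must be in (0, 1)")
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


@dataclass
class CombinationResult:
    iai: float
    fa: float
    label: str


def normalize_viability(
    doses: np.ndarray | list[float],
    signals: np.ndarray | list[float],
    control_signals: np.ndarray | list[float],
    label: str = "drug",
) -> DoseResponse:
    """Scale raw well signals by the mean of the control wells."""
    control = np.asarray(control_signals, float)
    if control.size == 0:
        raise ValueError("at least one control well is required")
    ref = control.mean()
    if ref <= 0:
        raise ValueError("control mean must be positive")
    doses = np.asarray(doses, float)
    order = np.argsort(doses)
    signals = np.asarray(signals, float)
    return DoseResponse(
        label=label, doses=doses[order], viability=signals[order] / ref
    )


def fit_median_effect(dr: DoseResponse, fa_clip: float = 0.005) -> MedianEffectFit:
    """OLS fit of log10(fa/(1-fa)) on log10(dose).

    fa = 1 - viability; points with fa outside (fa_clip, 1 - fa_clip) are
    excluded (the linearization is undefined at the extremes).  A
    non-positive slope is returned with a warning rather than raised.
    """
    fa = 1.0 - dr.viability
    usable = (fa > fa_clip) & (fa < 1.0 - fa_clip)
    if usable.sum() < 2:
        raise ValueError(
            f"{dr.label}: need >= 2 doses with affected fraction inside "
            f"({fa_clip}, {1 - fa_clip}); have {int(usable.sum())}"
        )
    x = np.log10(dr.doses[usable])
    y = np.log10(fa[usable] / (1.0 - fa[usable]))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
    monotone = slope > 0
    if not monotone:
        warnings.warn(
            f"{dr.label}: non-monotone dose-response (m = {slope:.3g} <= 0)",
            stacklevel=2,
        )
        dm = float("nan")
    else:
        dm = 10.0 ** (-intercept / slope)
    return MedianEffectFit(
        label=dr.label,
        m=float(slope),
        dm=float(dm),
        r_squared=float(r2),
        n_points_used=int(usable.sum()),
        monotone=monotone,
    )


def interaction_label(iai: float, band: float = ADDITIVE_BAND) -> str:
    """Partition of (0, inf): additive within the band around 1 (inclusive),
    synergism below, antagonism above."""
    if iai <= 0:
        raise ValueError("interaction index must be > 0")
    if abs(iai - 1.0) <= band + 1e-12:  # band edges are labelled additive
        return "additive"
    return "synergism" if iai < 1.0 else "antagonism"


def interaction_index(
    fit_drug1: MedianEffectFit,
    fit_drug2: MedianEffectFit,
    fit_combo: MedianEffectFit,
    ratio: tuple[float, float] = (0.5, 0.5),
    fa: float = 0.5,
    band: float = ADDITIVE_BAND,
) -> CombinationResult:
    """Two-term Loewe interaction index of a fixed-ratio combination.

    ``ratio`` gives the dose fractions (r1, r2) of the two agents in the
    combination's total dose; r1 + r2 must be 1.
    """
    r1, r2 = ratio
    if not math.isclose(r1 + r2, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("ratio fractions must sum to 1")
    if r1 < 0 or r2 < 0:
        raise ValueError("ratio fractions must be non-negative")
    if not 0.0 < fa < 1.0:
        raise ValueError("fa must be strictly inside (0, 1)")
    for f in (fit_drug1, fit_drug2, fit_combo):
        if not (f.monotone and f.m > 0 and np.isfinite(f.dm) and f.dm > 0):
            raise ValueError(f"{f.label}: invalid median-effect fit for interaction scoring")
    dc = fit_combo.required_dose(fa)
    iai = dc * r1 / fit_drug1.required_dose(fa) + dc * r2 / fit_drug2.required_dose(fa)
    return CombinationResult(iai=float(iai), fa=fa, label=interaction_label(iai, band))


def relative_ic50_percentiles(ic50s: dict[str, float]) -> dict[str, float]:
    """Percentile (0-100) of each cell line's IC50 across all lines tested.

    Ranks ascending log10 IC50 with mean ranks on ties; percentile =
    100*(rank - 1)/(n - 1).
    """
    if len(ic50s) < 2:
        raise ValueError("need at least 2 cell lines")
    names = list(ic50s)
    values = np.log10(np.array([ic50s[k] for k in names], float))
    ranks = rankdata(values, method="average")
    pct = 100.0 * (ranks - 1.0) / (len(names) - 1.0)
    return dict(zip(names, pct.tolist()))


def compare_groups_wilcoxon(
    values: np.ndarray | list[float],
    labels: np.ndarray | list[str],
    alternative: str = "two-sided",
    exact_max_n: int = 10,
) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two labelled groups.

    Returns (rank-sum statistic of the first group, p-value).  The p-value
    is exact by full enumeration when total n <= ``exact_max_n`` and there
    are no ties, otherwise a normal approximation with tie correction.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"exactly 2 groups required, got {uniq}")
    mask1 = labels == uniq[0]
    n1, n2 = int(mask1.sum()), int((~mask1).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    ranks = rankdata(values, method="average")
    w = float(ranks[mask1].sum())
    has_ties = len(np.unique(values)) < n

    if n <= exact_max_n and not has_ties:
        sums = [sum(c) for c in combinations(range(1, n + 1), n1)]
        total = len(sums)
        p_le = sum(s <= w + 1e-12 for s in sums) / total
        p_ge = sum(s >= w - 1e-12 for s in sums) / total
    else:
        mean = n1 * (n + 1) / 2.0
        _, counts = np.unique(values, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return w, 1.0
        sd = math.sqrt(var)
        # continuity-corrected normal tails
        p_le = float(norm.cdf((w - mean + 0.5) / sd))
        p_ge = float(norm.sf((w - mean - 0.5) / sd))

    if alternative == "less":
        p = p_le
    elif alternative == "greater":
        p = p_ge
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return w, float(p)
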