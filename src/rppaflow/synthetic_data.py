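"""Synthetic-data generators with known ground truth for every pipeline stage.

Every generator draws from a single ``numpy.random.Generator`` seeded from
the configuration, so identical configurations give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .combination import DoseResponse
from .growth import GrowthData
from .normalization import NON_SCC, SCC, ExpressionMatrix
from .supercurve import SlideMeasurements

#: Signed fold-changes planted by default in the cohort generator:
#: positive = higher in SCC, negative = lower in SCC; magnitudes are on the
#: linear (2**log2) scale and must be >= 1.
DEFAULT_EFFECTS: list[tuple[str, float]] = [
    ("Keap1", 1.64),
    ("Nrf2", 1.10),
    ("CHK2", 1.41),
    ("pCHK2", 1.28),
    ("Rb", 1.34),
    ("MSH2", 1.28),
    ("PARP", 1.37),
    ("IGF1R", 1.23),
    ("TrkB", 1.56),
    ("Src3", 1.12),
    ("TTF-1", -3.41),
    ("pEGFR", -1.11),
    ("Met", -1.17),
    ("pMet", -1.08),
    ("Axl", -1.13),
    ("FGFR", -1.14),
    ("pMek", -1.14),
    ("Rab25", -1.28),
    ("p70S6K", -1.15),
    ("PKCa", -1.26),
    ("JNK2", -1.12),
    ("p90RSK", -1.09),
    ("mTOR", -1.08),
]


@dataclass
class GrowthParams:
    """Mean structure and residual covariance of the growth generator."""

    v0: float = 200.0
    slopes: dict[str, float] = field(
        default_factory=lambda: {
            "vehicle": 40.0,
            "drugA": 30.0,
            "drugB": 28.0,
            "combination": 10.0,
        }
    )
    structure: str = "ar1"  # independence | compound_symmetry | ar1
    rho: float = 0.6
    sigma: float = 20.0
    n_per_group: int = 5
    days: tuple[int, ...] = (0, 3, 7, 10, 14, 17, 21)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_scc: int = 34
    n_nonscc: int = 106
    effect_table: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_EFFECTS)
    )
    n_null_proteins: int = 104  # padded to the 127-antibody panel size
    protein_noise_sd: float = 0.5
    slide_params: tuple[float, float, float, float] = (100.0, 1000.0, 1.0, 10.0)
    dilution_steps: int = 5
    duplicate_fraction: float = 0.10
    dose_grid: tuple[float, ...] = tuple(0.0625 * 2.0**k for k in range(8))
    growth_params: GrowthParams = field(default_factory=GrowthParams)

    def __post_init__(self) -> None:
        if self.n_scc < 2 or self.n_nonscc < 2:
            raise ValueError("cohort sizes must be >= 2")
        alpha, beta, gamma, noise_sd = self.slide_params
        if beta <= 0 or gamma <= 0:
            raise ValueError("slide beta and gamma must be > 0")
        if noise_sd < 0 or self.protein_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.dilution_steps < 3:
            raise ValueError("need at least 3 dilution steps")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1]")
        if self.n_null_proteins < 0:
            raise ValueError("n_null_proteins must be >= 0")


def generate_slide(
    config: SimulationConfig,
    truth: dict[str, float],
    antibody: str = "Ab1",
    replicates: int = 1,
) -> SlideMeasurements:
    """Simulate one antibody slide from true log2 concentrations.

    Dilution steps j = 0..k-1 are log2 offsets (undiluted anchor at j=0);
    spot intensity is alpha + beta * logistic(gamma * (x - j)) plus
    Gaussian noise on the intensity scale.
    """
    values = np.asarray(list(truth.values()), float)
    if not np.all(np.isfinite(values)):
        raise ValueError("true concentrations must be finite")
    alpha, beta, gamma, noise_sd = config.slide_params
    rng = np.random.default_rng(config.seed)
    rows = []
    for sample, x in truth.items():
        for step in range(config.dilution_steps):
            mean = alpha + beta * expit(gamma * (x - step))
            for rep in range(1, replicates + 1):
                val = mean + rng.normal(0.0, noise_sd) if noise_sd > 0 else mean
                rows.append((sample, step, rep, max(val, 0.0)))
    records = pd.DataFrame(
        rows, columns=["sample_id", "dilution_step", "replicate", "intensity"]
    )
    return SlideMeasurements(antibody=antibody, records=records, truth=dict(truth))


def _signed_fold_to_log2(fold: float) -> float:
    if abs(fold) < 1.0 or fold == 0.0:
        raise ValueError(
            f"signed fold-change must have magnitude >= 1, got {fold}"
        )
    return np.log2(fold) if fold > 0 else -np.log2(-fold)


def generate_cohort_matrix(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a two-cohort log2 matrix with planted SCC vs non-SCC shifts.

    Returns the matrix (with histology annotations and duplicate samples)
    and a truth table of planted per-protein log2 differences.
    """
    rng = np.random.default_rng(config.seed)
    effects = [(name, _signed_fold_to_log2(f)) for name, f in config.effect_table]
    effects += [(f"null{i:03d}", 0.0) for i in range(config.n_null_proteins)]
    proteins = [name for name, _ in effects]
    deltas = np.array([d for _, d in effects])

    n = config.n_scc + config.n_nonscc
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    labels = [SCC] * config.n_scc + [NON_SCC] * config.n_nonscc

    baseline = rng.normal(0.0, 1.0, size=len(proteins))
    n_dup = int(round(config.duplicate_fraction * n))
    dup_choice = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)
    dup_set = set(dup_choice.tolist())

    cols: dict[str, np.ndarray] = {}
    histology: dict[str, str] = {}
    base_sample: dict[str, str] = {}
    for i, (sid, lab) in enumerate(zip(sample_ids, labels)):
        shift = deltas if lab == SCC else 0.0
        mean = baseline + shift
        cols[sid] = mean + rng.normal(0.0, config.protein_noise_sd, size=len(proteins))
        histology[sid] = lab
        base_sample[sid] = sid
        if i in dup_set:
            dup_id = f"{sid}-d2"
            cols[dup_id] = mean + rng.normal(
                0.0, config.protein_noise_sd, size=len(proteins)
            )
            histology[dup_id] = lab
            base_sample[dup_id] = sid

    matrix = ExpressionMatrix(
        values=pd.DataFrame(cols, index=proteins),
        histology=histology,
        base_sample=base_sample,
    )
    truth = pd.DataFrame(
        {"protein": proteins, "true_delta_log2": deltas}
    ).set_index("protein")
    return matrix, truth


def generate_dose_response(
    m: float,
    dm: float,
    doses: np.ndarray | list[float] | tuple[float, ...],
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "drug",
) -> DoseResponse:
    """Simulate viability under median-effect kinetics.

    Affected fraction fa(D) = 1 / (1 + (Dm/D)^m); viability = 1 - fa plus
    Gaussian noise, clipped to [0, 1.2].
    """
    doses = np.asarray(doses, float)
    if m <= 0 or dm <= 0:
        raise ValueError("m and Dm must be > 0")
    if (doses <= 0).any():
        raise ValueError("doses must be > 0")
    rng = np.random.default_rng(seed)
    fa = 1.0 / (1.0 + (dm / doses) ** m)
    viability = 1.0 - fa
    if noise_sd > 0:
        viability = viability + rng.normal(0.0, noise_sd, size=doses.shape)
    viability = np.clip(viability, 0.0, 1.2)
    order = np.argsort(doses)
    return DoseResponse(label=label, doses=doses[order], viability=viability[order])


def _residual_cov(structure: str, rho: float, k: int, sigma: float) -> np.ndarray:
    if structure == "independence":
        corr = np.eye(k)
    elif structure == "compound_symmetry":
        corr = np.full((k, k), rho)
        np.fill_diagonal(corr, 1.0)
    elif structure == "ar1":
        idx = np.arange(k)
        corr = rho ** np.abs(idx[:, None] - idx[None, :])
    else:
        raise ValueError(f"unknown correlation structure: {structure!r}")
    return sigma**2 * corr


def generate_growth_curves(config: SimulationConfig) -> GrowthData:
    """Simulate longitudinal tumor volumes per mouse.

    Mean volume is linear in day with a per-group slope; within-mouse
    residuals follow the configured correlation structure (on measurement
    occasions) with standard deviation sigma.  Volumes are floored at 0.
    """
    gp = config.growth_params
    days = np.asarray(gp.days, float)
    if not np.all(np.diff(days) > 0):
        raise ValueError("days must be sorted strictly ascending")
    if gp.n_per_group < 2:
        raise ValueError("need at least 2 mice per group")
    if gp.structure != "independence" and abs(gp.rho) >= 1:
        raise ValueError("|rho| must be < 1")

    rng = np.random.default_rng(config.seed)
    cov = _residual_cov(gp.structure, gp.rho, len(days), gp.sigma)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(days))) if gp.sigma > 0 else None

    rows = []
    mouse_no = 0
    for group, slope in gp.slopes.items():
        mean = gp.v0 + slope * days
        for _ in range(gp.n_per_group):
            mouse_no += 1
            resid = chol @ rng.standard_normal(len(days)) if chol is not None else 0.0
            vols = np.maximum(mean + resid, 0.0)
            for d, v in zip(days, vols):
                rows.append((f"m{mouse_no:03d}", group, int(d), float(v)))
    return GrowthData(
        records=pd.DataFrame(rows, columns=["mouse", "group", "day", "volume"])
    )
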