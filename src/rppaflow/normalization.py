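"""Loading adjustment, median centering, and duplicate averaging for
log2 expression matrices.

The normalization contract is: per-sample loading adjustment against the
median over the whole antibody set, then per-protein median centering,
then averaging of duplicate samples.  All three operations tolerate
missing values (NaN) and never introduce new ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCC = "SCC"
NON_SCC = "non-SCC"


@dataclass
class ExpressionMatrix:
    """Protein x sample matrix of log2 relative concentrations.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by protein name, columns by sample identifier.
        Missing entries are NaN.
    histology : dict
        Optional map sample -> histology label (``"SCC"`` / ``"non-SCC"``).
    base_sample : dict
        Optional map sample -> base-sample identifier.  Duplicate samples
        share a base identifier; samples absent from the map are their own
        base.
    """

    values: pd.DataFrame
    histology: dict[str, str] = field(default_factory=dict)
    base_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein names: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def base_of(self, sample: str) -> str:
        return self.base_sample.get(sample, sample)

    def copy_with(self, values: pd.DataFrame) -> "ExpressionMatrix":
        keep = set(values.columns)
        return ExpressionMatrix(
            values=values,
            histology={s: h for s, h in self.histology.items() if s in keep},
            base_sample={s: b for s, b in self.base_sample.items() if s in keep},
        )


def loading_adjust(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each sample's median over all non-missing proteins.

    Removes per-sample total-protein loading differences using the whole
    antibody set as the reference.  Output columns have median 0.
    """
    vals = matrix.values
    all_missing = vals.isna().all(axis=0)
    if all_missing.any():
        bad = vals.columns[all_missing].tolist()
        raise ValueError(f"samples with no measurements cannot be loading-adjusted: {bad}")
    if vals.shape[0] < 2:
        warnings.warn(
            "loading adjustment with a single protein is degenerate "
            "(every value becomes 0)",
            stacklevel=2,
        )
    medians = vals.median(axis=0, skipna=True)
    return matrix.copy_with(vals.sub(medians, axis=1))


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center each protein row at its across-sample median."""
    vals = matrix.values
    all_missing = vals.isna().all(axis=1)
    if all_missing.any():
        bad = vals.index[all_missing].tolist()
        raise ValueError(f"proteins with no measurements cannot be centered: {bad}")
    medians = vals.median(axis=1, skipna=True)
    return matrix.copy_with(vals.sub(medians, axis=0))


def average_duplicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse duplicate samples (shared base identifier) to their mean.

    Missing values are skipped in the per-protein mean; the base identifier
    becomes the sample identifier of the merged column.  Duplicates whose
    histology labels disagree are rejected.
    """
    vals = matrix.values
    bases = [matrix.base_of(s) for s in vals.columns]
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for sample, base in zip(vals.columns, bases):
        if base not in groups:
            groups[base] = []
            order.append(base)
        groups[base].append(sample)

    histology: dict[str, str] = {}
    cols = {}
    for base in order:
        members = groups[base]
        labels = {matrix.histology[s] for s in members if s in matrix.histology}
        if len(labels) > 1:
            raise ValueError(
                f"duplicate set {base!r} has conflicting histology labels: {sorted(labels)}"
            )
        if labels:
            histology[base] = labels.pop()
        cols[base] = vals[members].mean(axis=1, skipna=True)
    merged = pd.DataFrame(cols, index=vals.index)
    merged = merged[order]
    return ExpressionMatrix(
        values=merged,
        histology=histology,
        base_sample={b: b for b in order},
    )


def normalize(matrix: ExpressionMatrix, skip_loading: bool = False) -> ExpressionMatrix:
    """Full normalization chain: loading adjust, median center, average duplicates."""
    out = matrix if skip_loading else loading_adjust(matrix)
    out = median_center(out)
    return average_duplicates(out)
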