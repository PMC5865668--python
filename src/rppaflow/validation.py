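"""Cross-cohort concordance classification and probe quality scoring."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .differential import GroupComparisonResult


class Category(str, Enum):
    SAME_DIRECTION_SIGNIFICANT = "same_direction_significant"
    SAME_DIRECTION_NOT_SIGNIFICANT = "same_direction_not_significant"
    NO_TREND = "no_trend"
    OPPOSITE = "opposite"


@dataclass
class ConcordanceCall:
    protein: str
    discovery_direction: int
    validation_direction: int
    validation_p: float
    category: Category


def classify_directions(
    discovery_direction: int, validation_direction: int, validation_p: float
) -> Category:
    """Concordance rule between a discovery hit and its validation test.

    Applied in order: validation p > 0.20 -> no_trend; same direction with
    p < 0.05 -> same_direction_significant; same direction with
    0.05 <= p <= 0.20 -> same_direction_not_significant (0.20 inclusive);
    opposite direction with p < 0.05 -> opposite; opposite direction with
    0.05 <= p <= 0.20 -> no_trend.  A zero direction on either side counts
    as matching neither direction.
    """
    if not 0.0 < validation_p <= 1.0:
        raise ValueError("validation p-value must be in (0, 1]")
    if validation_p > 0.20:
        return Category.NO_TREND
    same = (
        discovery_direction != 0
        and validation_direction != 0
        and discovery_direction == validation_direction
    )
    if same:
        if validation_p < 0.05:
            return Category.SAME_DIRECTION_SIGNIFICANT
        return Category.SAME_DIRECTION_NOT_SIGNIFICANT
    if validation_p < 0.05 and discovery_direction != 0 and validation_direction != 0:
        return Category.OPPOSITE
    return Category.NO_TREND


def concordance_classify(
    discovery: GroupComparisonResult, validation: GroupComparisonResult
) -> ConcordanceCall:
    """Classify whether a validation cohort reproduces a discovery hit."""
    if discovery.protein != validation.protein:
        raise ValueError(
            f"protein mismatch: {discovery.protein!r} vs {validation.protein!r}"
        )
    d_dir = int(np.sign(discovery.delta_log2))
    v_dir = int(np.sign(validation.delta_log2))
    category = classify_directions(d_dir, v_dir, validation.p_value)
    return ConcordanceCall(
        protein=discovery.protein,
        discovery_direction=d_dir,
        validation_direction=v_dir,
        validation_p=validation.p_value,
        category=category,
    )


def concordance_counts(calls: list[ConcordanceCall]) -> dict[str, int]:
    counts = {c.value: 0 for c in Category}
    for call in calls:
        counts[call.category.value] += 1
    return counts


@dataclass
class ProbeScore:
    probe_id: str
    near_3prime: bool
    in_spliced_region: bool
    conserved_homologs: bool
    conserved_other_animals: bool

    @property
    def score(self) -> int:
        return sum(
            (
                self.near_3prime,
                self.in_spliced_region,
                self.conserved_homologs,
                self.conserved_other_animals,
            )
        )


def score_probes(probes: list[ProbeScore]) -> list[ProbeScore]:
    """Rank probes by criterion count, descending; ties by probe id."""
    return sorted(probes, key=lambda p: (-p.score, p.probe_id))


def cohort_percentage(count: int, total: int) -> int:
    """Integer percentage of a subgroup count, rounded half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return int(np.floor(100.0 * count / total + 0.5))
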