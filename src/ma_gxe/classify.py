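"""Resource-dependence classification of growth-performance loss.

A genotype at a temperature is scored against a loss cutoff log10(f) for a
fraction f in (0, 1) — e.g. f = 0.95 marks a 5% yield loss. Counting the
carbon substrates on which its relative score falls strictly below the
cutoff gives:

* resource-independent deleterious — below the cutoff on *all* E substrates,
* resource-dependent deleterious — below on at least one but not all
  (the operational signature of conditional neutrality),
* non-deleterious — below on none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import MissingDataError, ValidationError
from .scoring import ScoreTable

RESOURCE_INDEPENDENT = "resource_independent_deleterious"
RESOURCE_DEPENDENT = "resource_dependent_deleterious"
NON_DELETERIOUS = "non_deleterious"
CATEGORIES = (RESOURCE_INDEPENDENT, RESOURCE_DEPENDENT, NON_DELETERIOUS)


@dataclass(frozen=True)
class LossThreshold:
    """A loss criterion: relative growth performance < log10(fraction)."""

    label: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValidationError(f"loss fraction must be in (0,1), got {self.fraction}")

    @property
    def cutoff(self) -> float:
        return math.log10(self.fraction)


#: The three standard criteria: 1%, 5% and 10% yield loss.
DEFAULT_THRESHOLDS = (
    LossThreshold("0.99", 0.99),
    LossThreshold("0.95", 0.95),
    LossThreshold("0.90", 0.90),
)


@dataclass(frozen=True)
class ClassificationResult:
    genotype: str
    temperature_c: float
    threshold_label: str
    n_substrates_below: int
    category: str


def classify_genotype(
    scores_across_carbons: Sequence[float],
    threshold: LossThreshold,
    *,
    genotype: str = "",
    temperature_c: float = float("nan"),
) -> ClassificationResult:
    """Classify one genotype from its complete E-vector of scores.

    The comparison is strictly ``<`` the cutoff: a score exactly at the
    cutoff is not counted as a loss.
    """
    scores = np.asarray(list(scores_across_carbons), dtype=float)
    if scores.size == 0 or not np.isfinite(scores).all():
        raise MissingDataError(
            f"incomplete score vector for {genotype!r} at {temperature_c:g} C"
        )
    n_below = int((scores < threshold.cutoff).sum())
    if n_below == scores.size:
        category = RESOURCE_INDEPENDENT
    elif n_below >= 1:
        category = RESOURCE_DEPENDENT
    else:
        category = NON_DELETERIOUS
    return ClassificationResult(
        genotype=genotype,
        temperature_c=temperature_c,
        threshold_label=threshold.label,
        n_substrates_below=n_below,
        category=category,
    )


def classify_table(
    scores: ScoreTable,
    thresholds: Sequence[LossThreshold] = DEFAULT_THRESHOLDS,
) -> list[ClassificationResult]:
    """Classify every genotype at every temperature under every threshold."""
    from .gxe import build_matrix

    results = []
    for t in scores.design.temperatures:
        m = build_matrix(scores, t)
        for threshold in thresholds:
            for i, g in enumerate(m.row_labels):
                results.append(
                    classify_genotype(
                        m.values[i],
                        threshold,
                        genotype=g,
                        temperature_c=t,
                    )
                )
    return results


def proportions(
    results: Iterable[ClassificationResult], n_genotypes: int
) -> tuple[dict[str, float], dict[str, int]]:
    """Category fractions (denominator: all G genotypes) and raw counts for
    one temperature x threshold slice."""
    results = list(results)
    if not results:
        raise MissingDataError("no classification results to tabulate")
    seen: set[str] = set()
    counts = {c: 0 for c in CATEGORIES}
    for r in results:
        if r.genotype in seen:
            raise ValidationError(f"duplicate genotype {r.genotype!r} in proportions input")
        seen.add(r.genotype)
        counts[r.category] += 1
    if len(results) != n_genotypes:
        raise ValidationError(
            f"expected one result per genotype ({n_genotypes}), got {len(results)}"
        )
    fractions = {c: counts[c] / n_genotypes for c in CATEGORIES}
    return fractions, counts


def classification_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Long table: genotype,temperature_c,threshold,n_substrates_below,category."""
    return pd.DataFrame(
        [
            {
                "genotype": r.genotype,
                "temperature_c": r.temperature_c,
                "threshold": r.threshold_label,
                "n_substrates_below": r.n_substrates_below,
                "category": r.category,
            }
            for r in results
        ]
    )


def proportion_series(
    results: Sequence[ClassificationResult],
    threshold_label: str,
    category: str,
    n_genotypes: int,
) -> pd.DataFrame:
    """Per-temperature count and fraction of one category under one threshold."""
    rows = []
    frame = classification_frame(results)
    sub = frame[frame["threshold"] == threshold_label]
    for t, grp in sub.groupby("temperature_c", sort=True):
        fracs, counts = proportions(
            [r for r in results if r.threshold_label == threshold_label and r.temperature_c == t],
            n_genotypes,
        )
        rows.append(
            {
                "temperature_c": t,
                "count": counts[category],
                "n_genotypes": n_genotypes,
                "fraction": fracs[category],
            }
        )
    return pd.DataFrame(rows)
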