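"""Rank-curve tables and plots for visualizing G x E structure.

Two modes are supported. In ``per_genotype_rank`` each genotype's substrates
are sorted by its own decreasing score, so every curve is non-increasing and
the substrate at a given rank may differ between genotypes (line separation
reflects genetic variance, steepness environmental variance). In
``fixed_reference_order`` all genotypes share one substrate order — that of
the genotype with the highest mean score — so unequal slopes show
responsiveness and crossing lines show inconsistency.

Ties are broken by design order throughout, keeping outputs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gxe import GxEMatrix

PER_GENOTYPE = "per_genotype_rank"
FIXED_REFERENCE = "fixed_reference_order"


@dataclass(frozen=True)
class RankCurveSet:
    """Rank-ordered score curves for all genotypes at one temperature.

    ``curves`` maps genotype -> list of (rank, carbon, score), rank 1-based.
    """

    temperature_c: float
    mode: str
    curves: dict[str, list[tuple[int, str, float]]]
    reference_genotype: str | None = None
    carbon_order: tuple[str, ...] | None = None


def _ordered_indices(row: np.ndarray) -> np.ndarray:
    # descending score, ties broken by design (column) order
    return np.lexsort((np.arange(row.size), -row))


def per_genotype_ranks(m: GxEMatrix) -> RankCurveSet:
    """Each genotype's substrates ranked by its own decreasing score."""
    curves = {}
    for i, g in enumerate(m.row_labels):
        order = _ordered_indices(m.values[i])
        curves[g] = [
            (rank + 1, m.col_labels[j], float(m.values[i, j]))
            for rank, j in enumerate(order)
        ]
    return RankCurveSet(temperature_c=m.temperature_c, mode=PER_GENOTYPE, curves=curves)


def fixed_reference_ranks(m: GxEMatrix) -> RankCurveSet:
    """All genotypes on the substrate order of the best-performing genotype.

    The reference is the row with the greatest mean score (ties by design
    genotype order); its curve is non-increasing by construction.
    """
    means = m.values.mean(axis=1)
    ref = int(np.lexsort((np.arange(means.size), -means))[0])
    order = _ordered_indices(m.values[ref])
    carbon_order = tuple(m.col_labels[j] for j in order)
    curves = {}
    for i, g in enumerate(m.row_labels):
        curves[g] = [
            (rank + 1, m.col_labels[j], float(m.values[i, j]))
            for rank, j in enumerate(order)
        ]
    return RankCurveSet(
        temperature_c=m.temperature_c,
        mode=FIXED_REFERENCE,
        curves=curves,
        reference_genotype=m.row_labels[ref],
        carbon_order=carbon_order,
    )


def curves_frame(sets: Sequence[RankCurveSet]) -> pd.DataFrame:
    """Long table: temperature_c,mode,genotype,rank,carbon,score."""
    rows = []
    for cs in sets:
        for g, curve in cs.curves.items():
            for rank, carbon, score in curve:
                rows.append(
                    {
                        "temperature_c": cs.temperature_c,
                        "mode": cs.mode,
                        "genotype": g,
                        "rank": rank,
                        "carbon": carbon,
                        "score": score,
                    }
                )
    return pd.DataFrame(rows)


def plot_rank_curves(sets: Sequence[RankCurveSet], path: str | None = None):
    """One panel per temperature, one line per genotype; returns the Figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(sets)
    ncols = min(5, max(1, n))
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.0 * ncols, 2.6 * nrows), squeeze=False, sharey=True
    )
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    for ax, cs in zip(axes.flat, sets):
        for g, curve in cs.curves.items():
            ranks = [r for r, _, _ in curve]
            scores = [s for _, _, s in curve]
            ax.plot(ranks, scores, marker="o", markersize=2, linewidth=0.8, label=g)
        ax.axhline(0.0, color="grey", linewidth=0.5, linestyle=":")
        ax.set_title(f"{cs.temperature_c:g} \N{DEGREE SIGN}C", fontsize=9)
        ax.set_xlabel("substrate rank", fontsize=8)
        ax.set_ylabel("relative growth score", fontsize=8)
    fig.suptitle(sets[0].mode.replace("_", " ") if sets else "", fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
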