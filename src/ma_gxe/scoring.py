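"""Relative growth-performance scores from raw mOD readings.

The score for an MA genotype in one assay environment (carbon substrate x
temperature) is

    s = log10((mOD_MA + 1) / (mOD_ancestor + 1)),

where both mOD values are technical-replicate means after blank subtraction
and the +1 offset keeps the ratio defined when a culture reads zero. A
positive score means the MA genotype out-yielded the ancestor in that
environment; a negative score means a growth-yield loss.

Also houses the carbon-concentration bookkeeping: all substrates are supplied
at the same mass concentration (0.4 g/L by default), which corresponds to
slightly different molar concentrations of carbon atoms per substrate.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ExperimentDesign,
    MeasurementRecord,
    MissingDataError,
    ValidationError,
)

#: Conventional atomic weights for media chemistry (g/mol).
ATOMIC_WEIGHTS: dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
    "P": 30.974,
    "S": 32.06,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """An empirical formula contains an element with no tabulated weight."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an empirical formula like ``C6H12O6`` into an element-count map."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula) or not counts:
        raise FormulaError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class CarbonSource:
    """A carbon substrate supplied to the minimal medium."""

    name: str
    empirical_formula: Mapping[str, int]
    mass_concentration: float = 0.4  # g/L

    def __post_init__(self) -> None:
        if isinstance(self.empirical_formula, str):
            object.__setattr__(self, "empirical_formula", parse_formula(self.empirical_formula))
        if self.empirical_formula.get("C", 0) < 1:
            raise FormulaError(f"{self.name}: formula has no carbon")
        if self.mass_concentration <= 0:
            raise ValueError(f"{self.name}: mass concentration must be positive")

    @property
    def molar_mass(self) -> float:
        mass = 0.0
        for element, count in self.empirical_formula.items():
            if element not in ATOMIC_WEIGHTS:
                raise FormulaError(f"unknown element symbol {element!r} in {self.name}")
            mass += ATOMIC_WEIGHTS[element] * count
        return mass


#: The six substrates of the assay medium (Davis minimal + one carbon source).
STANDARD_CARBON_SOURCES: dict[str, CarbonSource] = {
    s.name: s
    for s in (
        CarbonSource("fructose", "C6H12O6"),
        CarbonSource("galactose", "C6H12O6"),
        CarbonSource("glucose", "C6H12O6"),
        CarbonSource("glycerol", "C3H8O3"),
        CarbonSource("maltose", "C12H22O11"),
        CarbonSource("trehalose", "C12H22O11"),
    )
}


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (display convention)."""
    if x == 0:
        return 0.0
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def carbon_molarity(source: CarbonSource, *, rounded: bool = False) -> float:
    """Millimolar concentration of carbon atoms delivered by ``source``.

    1000 * mass_concentration / molar_mass * n_carbons. Display values are
    rounded to 3 significant figures; computation uses full precision.
    """
    n_carbons = source.empirical_formula["C"]
    mm = 1000.0 * source.mass_concentration / source.molar_mass * n_carbons
    return round_sig(mm, 3) if rounded else mm


# ---------------------------------------------------------------------------
# scores


def subtract_blank(raw_mOD: float, blank_mOD: float) -> float:
    """Net mOD after background subtraction, clamped at zero."""
    if raw_mOD < 0 or blank_mOD < 0:
        raise ValidationError("mOD values must be non-negative")
    return max(raw_mOD - blank_mOD, 0.0)


def average_replicates(values: Sequence[float], cell: object = None) -> float:
    """Arithmetic mean of technical-replicate net mOD values."""
    values = list(values)
    if not values:
        raise MissingDataError(f"no replicate values for cell {cell!r}")
    return float(np.mean(values))


def relative_growth_score(mOD_MA_net: float, mOD_anc_net: float) -> float:
    """log10 ratio of offset net yields; 0 iff the two nets are equal."""
    if mOD_MA_net < 0 or mOD_anc_net < 0:
        raise ValidationError("net mOD values must be non-negative")
    return math.log10((mOD_MA_net + 1.0) / (mOD_anc_net + 1.0))


@dataclass
class ScoreTable:
    """Relative growth-performance scores, one row per MA genotype x carbon x
    temperature, alongside the net replicate-mean mOD values they were formed
    from. ``missing`` lists design cells for which no score could be formed.
    """

    frame: pd.DataFrame
    design: ExperimentDesign
    missing: tuple[tuple[str, str, float], ...] = ()

    COLUMNS = ["genotype", "carbon", "temperature_c", "score", "mOD_ma_net", "mOD_anc_net"]

    def __post_init__(self) -> None:
        absent = [c for c in ("genotype", "carbon", "temperature_c", "score") if c not in self.frame.columns]
        if absent:
            raise ValidationError(f"score table missing columns {absent}")

    def __len__(self) -> int:
        return len(self.frame)

    def score(self, genotype: str, carbon: str, temperature_c: float) -> float:
        sel = self.frame[
            (self.frame["genotype"] == genotype)
            & (self.frame["carbon"] == carbon)
            & (np.isclose(self.frame["temperature_c"], temperature_c))
        ]
        if sel.empty:
            raise MissingDataError(f"no score for ({genotype}, {carbon}, {temperature_c:g})")
        return float(sel["score"].iloc[0])

    def is_complete(self) -> bool:
        return not self.missing

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, design: ExperimentDesign) -> "ScoreTable":
        have = {
            (r.genotype, r.carbon, design.match_temperature(r.temperature_c))
            for r in frame.itertuples(index=False)
        }
        missing = tuple(
            (g, c, t)
            for g in design.genotypes
            for c in design.carbons
            for t in design.temperatures
            if (g, c, t) not in have
        )
        return cls(frame=frame.reset_index(drop=True), design=design, missing=missing)


def build_score_table(
    records: Iterable[MeasurementRecord] | pd.DataFrame,
    design: ExperimentDesign,
    *,
    clamp_negative: bool = True,
    score_then_average: bool = False,
) -> ScoreTable:
    """Blank-subtract, replicate-average and score a validated record set.

    For each assay environment the blank is the mean of that environment's
    blank wells. By default replicates are averaged on net mOD and the score
    is formed once from the two means; ``score_then_average`` instead scores
    each MA replicate against the ancestor replicate mean and averages the
    scores (a sensitivity switch — the two agree when replicates are equal).

    ``clamp_negative=False`` disables the clamp-at-zero of blank subtraction
    (negative nets are then carried into the +1 offset as-is).
    """
    if isinstance(records, pd.DataFrame):
        from .io import frame_to_records

        records = frame_to_records(records)
    records = list(records)

    blanks: dict[tuple[str, float], list[float]] = {}
    cells: dict[tuple[str, str, float], list[float]] = {}
    for rec in records:
        t = design.match_temperature(rec.temperature_c)
        if t is None:
            raise ValidationError(f"temperature {rec.temperature_c:g} not in design")
        if rec.is_blank:
            blanks.setdefault((rec.carbon, t), []).append(rec.mOD)
        else:
            cells.setdefault((rec.genotype, rec.carbon, t), []).append(rec.mOD)

    def net_values(genotype: str, carbon: str, t: float) -> list[float] | None:
        raws = cells.get((genotype, carbon, t))
        if raws is None:
            return None
        blank = float(np.mean(blanks.get((carbon, t), [0.0])))
        if clamp_negative:
            nets = [subtract_blank(v, blank) for v in raws]
        else:
            nets = [v - blank for v in raws]
        return nets

    rows = []
    missing: list[tuple[str, str, float]] = []
    for t in design.temperatures:
        for carbon in design.carbons:
            anc_nets = net_values(design.ancestor_label, carbon, t)
            env_has_data = any(
                (g, carbon, t) in cells for g in design.genotypes
            )
            if anc_nets is None:
                if env_has_data:
                    raise ValidationError(
                        f"ancestor missing in environment ({carbon}, {t:g} C): no score can be formed"
                    )
                missing.extend((g, carbon, t) for g in design.genotypes)
                continue
            anc_mean = average_replicates(anc_nets, (design.ancestor_label, carbon, t))
            for genotype in design.genotypes:
                ma_nets = net_values(genotype, carbon, t)
                if ma_nets is None:
                    missing.append((genotype, carbon, t))
                    continue
                ma_mean = average_replicates(ma_nets, (genotype, carbon, t))
                if score_then_average:
                    score = float(
                        np.mean([relative_growth_score(v, anc_mean) for v in ma_nets])
                    )
                else:
                    score = relative_growth_score(ma_mean, anc_mean)
                rows.append(
                    {
                        "genotype": genotype,
                        "carbon": carbon,
                        "temperature_c": t,
                        "score": score,
                        "mOD_ma_net": ma_mean,
                        "mOD_anc_net": anc_mean,
                    }
                )

    frame = pd.DataFrame(rows, columns=ScoreTable.COLUMNS)
    if not frame.empty and not np.isfinite(frame["score"]).all():
        raise ValidationError("non-finite score produced; check raw data")
    return ScoreTable(frame=frame, design=design, missing=tuple(missing))
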