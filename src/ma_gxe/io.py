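"""Tabular input/output and experimental-design validation.

The raw-data dialect is a single long ("tidy") CSV with columns
``genotype,carbon,temperature_c,replicate,mOD,is_blank``: one row per well
reading. Blank (medium-only) wells carry ``is_blank=true`` and an empty
genotype. All validation of the experimental design happens here, before any
science code runs: downstream modules may assume records are well formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

RAW_COLUMNS = ["genotype", "carbon", "temperature_c", "replicate", "mOD", "is_blank"]

#: Absolute tolerance for matching a file temperature against the design list.
TEMPERATURE_ATOL = 1e-9


class SchemaError(ValueError):
    """A row or header violates the documented CSV schema."""


class ValidationError(ValueError):
    """Records parse but violate an experimental-design invariant."""


class MissingDataError(ValueError):
    """A required cell (genotype x carbon x temperature) has no data."""


@dataclass(frozen=True)
class MeasurementRecord:
    """One raw plate-reader reading.

    ``genotype`` is ``None`` for blank wells (medium only); ``mOD`` is the
    milli-optical-density at 600 nm as reported by the reader, before blank
    subtraction.
    """

    genotype: str | None
    carbon: str
    temperature_c: float
    replicate: int
    mOD: float
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.mOD < 0:
            raise ValidationError(
                f"negative mOD {self.mOD!r} for {self.genotype!r}/"
                f"{self.carbon}/{self.temperature_c}"
            )
        if self.is_blank and self.genotype is not None:
            raise ValidationError("blank records must carry a null genotype")
        if not self.is_blank and not self.genotype:
            raise ValidationError("non-blank records require a genotype label")
        if self.replicate < 1:
            raise ValidationError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class ExperimentDesign:
    """The assay layout: which genotypes, carbons, temperatures, replicates.

    ``genotypes`` lists the mutation-accumulation (MA) lines only; the
    ancestor has its own reserved label and appears in every assay
    environment but never receives a score row.
    """

    genotypes: tuple[str, ...]
    ancestor_label: str
    carbons: tuple[str, ...]
    temperatures: tuple[float, ...]
    replicates: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        object.__setattr__(self, "carbons", tuple(self.carbons))
        object.__setattr__(self, "temperatures", tuple(float(t) for t in self.temperatures))
        if len(self.genotypes) < 2:
            raise ValidationError("need at least 2 MA genotypes (variance undefined below)")
        if len(self.carbons) < 2:
            raise ValidationError("need at least 2 carbon substrates")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValidationError("duplicate genotype labels")
        if len(set(self.carbons)) != len(self.carbons):
            raise ValidationError("duplicate carbon labels")
        if self.ancestor_label in self.genotypes:
            raise ValidationError("ancestor label must not appear among MA genotypes")
        if any(b <= a for a, b in zip(self.temperatures, self.temperatures[1:])):
            raise ValidationError("temperatures must be strictly increasing")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")

    @property
    def n_genotypes(self) -> int:
        """Number of MA genotypes G (ancestor excluded)."""
        return len(self.genotypes)

    @property
    def n_carbons(self) -> int:
        """Number of assay environments E at a fixed temperature."""
        return len(self.carbons)

    @property
    def all_strains(self) -> tuple[str, ...]:
        return (self.ancestor_label,) + self.genotypes

    def match_temperature(self, value: float) -> float | None:
        """Return the design temperature matching ``value``, or None."""
        for t in self.temperatures:
            if math.isclose(t, value, rel_tol=0.0, abs_tol=TEMPERATURE_ATOL):
                return t
        return None


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    """Long-format DataFrame with the canonical raw columns."""
    rows = [
        {
            "genotype": r.genotype if r.genotype is not None else "",
            "carbon": r.carbon,
            "temperature_c": r.temperature_c,
            "replicate": r.replicate,
            "mOD": r.mOD,
            "is_blank": r.is_blank,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RAW_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[MeasurementRecord]:
    missing = [c for c in RAW_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing raw-data columns: {missing}")
    records = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        is_blank = _parse_bool(row.is_blank, idx)
        genotype = row.genotype
        if genotype is None or (isinstance(genotype, float) and math.isnan(genotype)):
            genotype = ""
        genotype = str(genotype).strip()
        try:
            records.append(
                MeasurementRecord(
                    genotype=None if is_blank else genotype or None,
                    carbon=str(row.carbon).strip(),
                    temperature_c=float(row.temperature_c),
                    replicate=int(row.replicate),
                    mOD=float(row.mOD),
                    is_blank=is_blank,
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"row {idx + 2}: {exc}") from exc  # +2: header + 1-based
    return records


def _parse_bool(value: object, idx: int) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no", ""}:
        return False
    raise SchemaError(f"row {idx + 2}: cannot parse is_blank value {value!r}")


def validate_records(
    records: Sequence[MeasurementRecord], design: ExperimentDesign
) -> None:
    """Check every record against the design; raise on the first violation class.

    Unknown labels raise :class:`SchemaError` naming the offending row;
    missing blanks and a missing ancestor raise :class:`ValidationError`
    listing the affected assay environments.
    """
    known = set(design.all_strains)
    known_carbons = set(design.carbons)
    for i, rec in enumerate(records):
        if rec.carbon not in known_carbons:
            raise SchemaError(f"row {i + 2}: unknown carbon label {rec.carbon!r}")
        if design.match_temperature(rec.temperature_c) is None:
            raise SchemaError(
                f"row {i + 2}: temperature {rec.temperature_c:g} not in design "
                f"{[f'{t:g}' for t in design.temperatures]}"
            )
        if not rec.is_blank and rec.genotype not in known:
            raise SchemaError(f"row {i + 2}: unknown genotype label {rec.genotype!r}")

    envs_with_data = set()
    envs_with_blank = set()
    envs_with_ancestor = set()
    for rec in records:
        env = (rec.carbon, design.match_temperature(rec.temperature_c))
        if rec.is_blank:
            envs_with_blank.add(env)
        else:
            envs_with_data.add(env)
            if rec.genotype == design.ancestor_label:
                envs_with_ancestor.add(env)

    no_blank = sorted(envs_with_data - envs_with_blank)
    if no_blank:
        raise ValidationError(
            "assay environments without a blank well: "
            + ", ".join(f"({c}, {t:g} C)" for c, t in no_blank)
        )
    no_ancestor = sorted(envs_with_data - envs_with_ancestor)
    if no_ancestor:
        raise ValidationError(
            "assay environments without ancestor readings: "
            + ", ".join(f"({c}, {t:g} C)" for c, t in no_ancestor)
        )


def read_measurements(
    path: str | Path, design: ExperimentDesign
) -> list[MeasurementRecord]:
    """Read and validate a long-format raw measurements CSV.

    Parsing is locale independent (dot decimal separator, comma delimiter).
    """
    frame = pd.read_csv(path, dtype={"genotype": "string"}, keep_default_na=True)
    records = frame_to_records(frame)
    validate_records(records, design)
    return records


def write_table(table: pd.DataFrame | Iterable[MeasurementRecord], path: str | Path) -> None:
    """Write a tabular result as CSV with stable column order.

    Floats are serialized with ``repr`` precision (17 significant digits), so
    a write→read round trip is lossless at analysis precision.
    """
    if not isinstance(table, pd.DataFrame):
        table = records_to_frame(table)
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
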