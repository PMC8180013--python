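"""Per-temperature variance partitioning with the responsiveness–inconsistency
decomposition of genotype-by-environment interaction.

At each assay temperature the scores form a G x E cell-mean matrix (rows =
MA genotypes, columns = carbon substrates). Its variance is partitioned by
method of moments into

* sigma2_G — sample variance (over G-1) of genotype (row) means,
* sigma2_E — sample variance (over E-1) of environment (column) means,
* sigma2_GE — interaction: SS_int / ((G-1)(E-1)) with
  SS_int = sum_ge (x_ge - rowmean_g - colmean_e + grandmean)^2.

The interaction is further decomposed over ordered genotype pairs (i != j):

    R = sum (sigma_Ei - sigma_Ej)^2 / (2 G (G-1))        (responsiveness)
    I = sum sigma_Ei sigma_Ej (1 - rho_EiEj) / (G (G-1)) (inconsistency)

where sigma_Ei is genotype i's environmental standard deviation (over E-1)
and rho_EiEj the Pearson correlation of the two genotypes' score profiles
across environments. Under these denominator conventions the identity
sigma2_GE = R + I holds analytically; :func:`partition` asserts it.
Responsiveness captures genotypes differing in the *magnitude* of their
environmental response; inconsistency captures rank changes / crossing of
reaction norms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MissingDataError, ValidationError
from .scoring import ScoreTable

#: Relative tolerance for the R + I = sigma2_GE identity check.
IDENTITY_RTOL = 1e-9


@dataclass(frozen=True)
class GxEMatrix:
    """Complete G x E score matrix at one temperature, in design order."""

    temperature_c: float
    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError("G x E matrix must be two-dimensional")
        g, e = values.shape
        if g < 2 or e < 2:
            raise ValidationError(f"need G >= 2 and E >= 2, got {g} x {e}")
        if (len(self.row_labels), len(self.col_labels)) != (g, e):
            raise ValidationError("label lengths do not match matrix shape")
        if not np.isfinite(values).all():
            raise MissingDataError("G x E matrix contains non-finite entries")

    @property
    def n_genotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_environments(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GenotypeEnvStats:
    """Per-genotype environmental SDs and pairwise Pearson correlations.

    ``rho`` entries involving a zero-variance genotype are undefined and
    stored as NaN (flagged null); they contribute nothing to inconsistency
    because the corresponding SD product is zero.
    """

    sigma_E: np.ndarray
    rho: np.ndarray
    labels: tuple[str, ...]

    @property
    def n_genotypes(self) -> int:
        return self.sigma_E.shape[0]


@dataclass(frozen=True)
class VarianceComponents:
    """The five-way summary of score variation at one temperature."""

    temperature_c: float
    total: float
    sigma2_G: float
    sigma2_E: float
    sigma2_GE: float
    responsiveness_R: float
    inconsistency_I: float

    def as_dict(self) -> dict[str, float]:
        return {
            "temperature_c": self.temperature_c,
            "total": self.total,
            "sigma2_G": self.sigma2_G,
            "sigma2_E": self.sigma2_E,
            "sigma2_GE": self.sigma2_GE,
            "responsiveness_R": self.responsiveness_R,
            "inconsistency_I": self.inconsistency_I,
        }


def build_matrix(scores: ScoreTable, temperature_c: float) -> GxEMatrix:
    """Assemble the complete G x E matrix at one temperature, design order."""
    design = scores.design
    t = design.match_temperature(temperature_c)
    if t is None:
        raise ValidationError(f"temperature {temperature_c:g} not in design")
    sub = scores.frame[np.isclose(scores.frame["temperature_c"], t)]
    lookup = {
        (r.genotype, r.carbon): r.score for r in sub.itertuples(index=False)
    }
    values = np.empty((design.n_genotypes, design.n_carbons))
    for i, g in enumerate(design.genotypes):
        for j, c in enumerate(design.carbons):
            try:
                values[i, j] = lookup[(g, c)]
            except KeyError:
                raise MissingDataError(
                    f"missing score cell ({g}, {c}) at {t:g} C"
                ) from None
    return GxEMatrix(
        temperature_c=t,
        values=values,
        row_labels=design.genotypes,
        col_labels=design.carbons,
    )


def env_stats(m: GxEMatrix) -> GenotypeEnvStats:
    """Environmental SD per genotype and Pearson correlations between all
    genotype profiles across the E environments."""
    x = m.values
    centered = x - x.mean(axis=1, keepdims=True)
    e = m.n_environments
    cov = centered @ centered.T / (e - 1)
    sd = np.sqrt(np.diag(cov))
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    finite = rho[np.isfinite(rho)]
    np.clip(finite, -1.0, 1.0, out=finite)
    rho[np.isfinite(rho)] = finite
    if (sd == 0).any():
        flat = [m.row_labels[i] for i in np.flatnonzero(sd == 0)]
        warnings.warn(
            f"zero environmental variance for genotype(s) {flat} at "
            f"{m.temperature_c:g} C; their correlations are undefined "
            "(flagged null) and contribute 0 to inconsistency",
            stacklevel=2,
        )
    return GenotypeEnvStats(sigma_E=sd, rho=rho, labels=m.row_labels)


def responsiveness(stats: GenotypeEnvStats) -> float:
    """R — interaction variance from unequal environmental SDs.

    Sum over ordered pairs i != j of (sigma_Ei - sigma_Ej)^2 / (2 G (G-1)).
    """
    g = stats.n_genotypes
    if g < 2:
        raise ValidationError("responsiveness needs G >= 2")
    diff = np.subtract.outer(stats.sigma_E, stats.sigma_E)
    return float((diff**2).sum() / (2.0 * g * (g - 1)))


def inconsistency(stats: GenotypeEnvStats) -> float:
    """I — interaction variance from imperfect profile correlations.

    Sum over ordered pairs i != j of sigma_Ei sigma_Ej (1 - rho_ij) /
    (G (G-1)). Pairs with a flagged-null rho contribute 0 (their SD product
    is zero by construction).
    """
    g = stats.n_genotypes
    if g < 2:
        raise ValidationError("inconsistency needs G >= 2")
    prod = np.outer(stats.sigma_E, stats.sigma_E)
    with np.errstate(invalid="ignore"):
        term = prod * (1.0 - stats.rho)
    term = np.where(prod > 0, term, 0.0)
    np.fill_diagonal(term, 0.0)
    return float(term.sum() / (g * (g - 1)))


def partition(m: GxEMatrix) -> VarianceComponents:
    """Method-of-moments partition of a complete G x E cell-mean matrix.

    Total is defined as the sum of the three components, so the partition is
    additive by construction. The analytic identity sigma2_GE = R + I is
    verified to :data:`IDENTITY_RTOL` and a failure raises, since it can only
    indicate an implementation or conditioning problem.
    """
    x = m.values
    g, e = x.shape
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    grand = x.mean()
    sigma2_G = float(np.var(row_means, ddof=1))
    sigma2_E = float(np.var(col_means, ddof=1))
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_int = float((resid**2).sum())
    sigma2_GE = ss_int / ((g - 1) * (e - 1))

    stats = env_stats(m)
    r = responsiveness(stats)
    i = inconsistency(stats)

    scale = max(abs(sigma2_GE), abs(r + i), 1e-300)
    if abs(sigma2_GE - (r + i)) > IDENTITY_RTOL * scale + 1e-15 * max(1.0, abs(grand)):
        raise ArithmeticError(
            f"decomposition identity violated at {m.temperature_c:g} C: "
            f"sigma2_GE={sigma2_GE!r} vs R+I={(r + i)!r}"
        )

    total = sigma2_G + sigma2_E + sigma2_GE
    return VarianceComponents(
        temperature_c=m.temperature_c,
        total=total,
        sigma2_G=sigma2_G,
        sigma2_E=sigma2_E,
        sigma2_GE=sigma2_GE,
        responsiveness_R=r,
        inconsistency_I=i,
    )


def pairwise_oracle(m: GxEMatrix) -> tuple[float, float, float]:
    """Independent slow path: R and I by explicit double loops straight from
    their defining sums, and sigma2_GE by the explicit residual sum.

    Used in tests to cross-check :func:`partition`; not called by the
    pipeline.
    """
    from scipy import stats as sps

    x = m.values
    g, e = x.shape
    sds = [float(np.std(x[i], ddof=1)) for i in range(g)]
    r_sum = 0.0
    i_sum = 0.0
    for i in range(g):
        for j in range(g):
            if i == j:
                continue
            r_sum += (sds[i] - sds[j]) ** 2
            if sds[i] > 0 and sds[j] > 0:
                rho = float(sps.pearsonr(x[i], x[j])[0])
                i_sum += sds[i] * sds[j] * (1.0 - rho)
    r = r_sum / (2.0 * g * (g - 1))
    ii = i_sum / (g * (g - 1))
    ss = 0.0
    grand = float(x.mean())
    for a in range(g):
        for b in range(e):
            ss += (x[a, b] - x[a].mean() - x[:, b].mean() + grand) ** 2
    return r, ii, ss / ((g - 1) * (e - 1))


def partition_all(scores: ScoreTable) -> list[VarianceComponents]:
    """Partition at every design temperature, in design order."""
    return [partition(build_matrix(scores, t)) for t in scores.design.temperatures]


def components_frame(components: Sequence[VarianceComponents]) -> pd.DataFrame:
    """One row per temperature: temperature_c,total,sigma2_G,sigma2_E,
    sigma2_GE,responsiveness_R,inconsistency_I."""
    return pd.DataFrame([c.as_dict() for c in components])
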