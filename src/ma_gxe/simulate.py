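"""Synthetic plate-reader datasets with exact ground truth.

The generator emulates a mutation-accumulation growth-yield assay: one
ancestor plus G MA genotypes grown on E carbon substrates at each of a
ladder of temperatures, three technical replicates per culture, with blank
(medium-only) wells per assay environment. Effects are defined directly on
the score (log10) scale and inverted through the score formula to mOD, so
the noiseless score surface — and the variance components computed from it —
are exact ground truth rather than an approximation.

The noiseless score of MA genotype g on carbon c at temperature T is

    s_gc(T) = -delta_g * lambda(T) + eta_g * x_c * psi(T) + eps_gc * omega(T)

* delta_g >= 0 is the genotype's deleterious magnitude (half-normal draw);
  lambda(T) = d0 + d2 (T - T_mid)^2 makes deficits smallest at intermediate
  temperatures, so mean relative performance peaks near T_mid.
* eta_g ~ Normal(0, sigma_eta) is the genotype's sensitivity to a fixed,
  centered, unit-variance carbon axis x_c; the ramp psi(T) = psi0 +
  psi1 (T - T_min) makes responsiveness grow with temperature.
* eps_gc ~ Normal(0, 1) are idiosyncratic genotype-by-carbon effects scaled
  by omega(T) = omega0 + omega1 (T - T_min), driving inconsistency upward
  with temperature.

The ancestor's absolute yield follows a unimodal (Gaussian) thermal
performance curve per carbon; MA yields are obtained by inverting the score
formula, and technical replicates add truncated-Normal mOD noise. The blank
offset of each assay environment is drawn once and reported exactly in the
blank rows, so blank subtraction is lossless (reader noise on blanks is
second order for scores because it shifts MA and ancestor wells alike).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import gxe
from .io import ExperimentDesign, MeasurementRecord
from .scoring import ScoreTable, build_score_table


def default_design() -> ExperimentDesign:
    """The assay layout emulated by default: 10 MA genotypes + ancestor,
    6 carbon substrates, 23-41 C in 2 C steps, 3 technical replicates."""
    return ExperimentDesign(
        genotypes=tuple(f"MA{i:02d}" for i in range(1, 11)),
        ancestor_label="ANC",
        carbons=("fructose", "galactose", "glucose", "glycerol", "maltose", "trehalose"),
        temperatures=tuple(float(t) for t in range(23, 42, 2)),
        replicates=3,
    )


@dataclass(frozen=True)
class ThermalPerformance:
    """Gaussian thermal performance curve of ancestral net yield (mOD)."""

    a_max: float  # peak net mOD
    t_opt: float  # optimum temperature, C
    breadth: float  # Gaussian width, C

    def yield_at(self, temperature_c: float) -> float:
        z = (temperature_c - self.t_opt) / self.breadth
        return self.a_max * float(np.exp(-0.5 * z * z))


def default_thermal() -> dict[str, ThermalPerformance]:
    # Broad curves peaking in the upper-middle of the assay range keep
    # ancestral yields comfortably measurable at every temperature.
    return {
        "fructose": ThermalPerformance(1400.0, 37.0, 11.0),
        "galactose": ThermalPerformance(1100.0, 36.0, 12.0),
        "glucose": ThermalPerformance(1500.0, 37.5, 11.5),
        "glycerol": ThermalPerformance(900.0, 35.5, 12.5),
        "maltose": ThermalPerformance(1200.0, 38.0, 11.0),
        "trehalose": ThermalPerformance(1000.0, 36.5, 13.0),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults encode the assay design emulated.

    All scale parameters are on the score (log10) scale except mOD-unit
    noise (sigma_rep, blank_mean, blank_sd).
    """

    design: ExperimentDesign = field(default_factory=default_design)
    thermal: Mapping[str, ThermalPerformance] = field(default_factory=default_thermal)
    # deleterious magnitudes and their temperature profile
    sigma_delta: float = 0.1
    d0: float = 1.0
    d2: float = 0.001  # per C^2
    t_mid: float = 31.0
    # responsiveness knob: sensitivity spread and its temperature ramp
    sigma_eta: float = 0.06
    psi0: float = 0.2
    psi1: float = 0.05  # per C
    # inconsistency knob: idiosyncratic G x C scale and ramp
    omega0: float = 0.005
    omega1: float = 0.001  # per C
    # measurement layer
    sigma_rep: float = 5.0  # mOD
    blank_mean: float = 40.0  # mOD
    blank_sd: float = 3.0  # mOD
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_delta", "sigma_eta", "sigma_rep", "blank_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        missing = [c for c in self.design.carbons if c not in self.thermal]
        if missing:
            raise ValueError(f"no thermal performance curve for carbons {missing}")
        for t in self.design.temperatures:
            if self.lam(t) < 0 or self.psi(t) < 0 or self.omega(t) < 0:
                raise ValueError(f"lambda/psi/omega must be >= 0 at {t:g} C")
            for c in self.design.carbons:
                if self.thermal[c].yield_at(t) <= 0:
                    raise ValueError(f"ancestral yield must be positive at ({c}, {t:g} C)")

    @property
    def t_min(self) -> float:
        return self.design.temperatures[0]

    def lam(self, temperature_c: float) -> float:
        """Deficit multiplier; minimal (= d0) at t_mid."""
        return self.d0 + self.d2 * (temperature_c - self.t_mid) ** 2

    def psi(self, temperature_c: float) -> float:
        """Sensitivity ramp driving responsiveness."""
        return self.psi0 + self.psi1 * (temperature_c - self.t_min)

    def omega(self, temperature_c: float) -> float:
        """Idiosyncratic-effect ramp driving inconsistency."""
        return self.omega0 + self.omega1 * (temperature_c - self.t_min)


@dataclass(frozen=True)
class EffectDraws:
    """Per-genotype effect draws; the ancestor implicitly has all zeros."""

    delta: np.ndarray  # (G,) deleterious magnitudes, >= 0
    eta: np.ndarray  # (G,) carbon-axis sensitivities
    eps: np.ndarray  # (G, E) idiosyncratic effects, unit scale


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless score surfaces and their exact variance components."""

    surfaces: dict[float, np.ndarray]  # temperature -> (G, E) scores
    components: tuple[gxe.VarianceComponents, ...]
    effects: EffectDraws


def carbon_axis(n_carbons: int) -> np.ndarray:
    """Fixed, centered carbon axis with unit sample variance (ddof=1)."""
    x = np.linspace(-1.0, 1.0, n_carbons)
    return x / x.std(ddof=1)


def draw_effects(config: SimulationConfig, rng: np.random.Generator | None = None) -> EffectDraws:
    """Reproducible effect draws; uses ``config.seed`` unless given a rng."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = config.design.n_genotypes
    e = config.design.n_carbons
    delta = np.abs(rng.normal(0.0, config.sigma_delta, size=g)) if config.sigma_delta > 0 else np.zeros(g)
    eta = rng.normal(0.0, config.sigma_eta, size=g) if config.sigma_eta > 0 else np.zeros(g)
    eps = rng.normal(0.0, 1.0, size=(g, e))
    return EffectDraws(delta=delta, eta=eta, eps=eps)


def score_surface(effects: EffectDraws, config: SimulationConfig) -> dict[float, np.ndarray]:
    """Noiseless score matrices s_gc(T) for every design temperature."""
    x_c = carbon_axis(config.design.n_carbons)
    surfaces = {}
    for t in config.design.temperatures:
        surfaces[t] = (
            -np.outer(effects.delta, np.ones_like(x_c)) * config.lam(t)
            + np.outer(effects.eta, x_c) * config.psi(t)
            + effects.eps * config.omega(t)
        )
    return surfaces


def ground_truth_components(effects: EffectDraws, config: SimulationConfig) -> GroundTruth:
    """Run the variance partition on the noiseless surfaces (recovery target)."""
    surfaces = score_surface(effects, config)
    components = tuple(
        gxe.partition(
            gxe.GxEMatrix(
                temperature_c=t,
                values=s,
                row_labels=config.design.genotypes,
                col_labels=config.design.carbons,
            )
        )
        for t, s in surfaces.items()
    )
    return GroundTruth(surfaces=surfaces, components=components, effects=effects)


def emit_measurements(
    effects: EffectDraws,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[MeasurementRecord]:
    """Raw well readings (with blank rows) for the whole design.

    Ancestor net mean is the thermal performance curve A_c(T); each MA net
    mean is inverted from the score surface as (A_c(T)+1) 10^s - 1.
    Replicates add Normal(0, sigma_rep) truncated at zero net mOD, and the
    per-environment blank offset is added to every culture well and emitted
    as a blank row. A warning reports the rate of truncation clamps.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    design = config.design
    surfaces = score_surface(effects, config)
    records: list[MeasurementRecord] = []
    clamped = 0
    total_wells = 0
    for t in design.temperatures:
        s = surfaces[t]
        for j, carbon in enumerate(design.carbons):
            blank = max(float(rng.normal(config.blank_mean, config.blank_sd)), 0.0) if config.blank_sd > 0 else config.blank_mean
            records.append(
                MeasurementRecord(
                    genotype=None,
                    carbon=carbon,
                    temperature_c=t,
                    replicate=1,
                    mOD=blank,
                    is_blank=True,
                )
            )
            a = config.thermal[carbon].yield_at(t)
            net_means = [a] + [
                (a + 1.0) * 10.0 ** float(s[i, j]) - 1.0 for i in range(design.n_genotypes)
            ]
            for strain, net_mean in zip(design.all_strains, net_means):
                for rep in range(1, design.replicates + 1):
                    noise = float(rng.normal(0.0, config.sigma_rep)) if config.sigma_rep > 0 else 0.0
                    net = net_mean + noise
                    total_wells += 1
                    if net < 0:
                        clamped += 1
                        net = 0.0
                    records.append(
                        MeasurementRecord(
                            genotype=strain,
                            carbon=carbon,
                            temperature_c=t,
                            replicate=rep,
                            mOD=net + blank,
                            is_blank=False,
                        )
                    )
    if clamped:
        warnings.warn(
            f"{clamped}/{total_wells} wells ({clamped / total_wells:.2%}) clamped at zero net mOD",
            stacklevel=2,
        )
    return records


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[list[MeasurementRecord], GroundTruth]:
    """Draw effects, compute ground truth and emit noisy raw measurements.

    ``seed`` overrides ``config.seed``; one generator stream drives both the
    effect draws and the measurement noise, so a (config, seed) pair fully
    determines the dataset byte for byte.
    """
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    effects = draw_effects(config, rng)
    truth = ground_truth_components(effects, config)
    records = emit_measurements(effects, config, rng)
    return records, truth


def simulate_scores(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[ScoreTable, GroundTruth]:
    """Convenience: simulate and push the raw records through scoring."""
    if config is None:
        config = SimulationConfig()
    records, truth = simulate_dataset(config, seed)
    return build_score_table(records, config.design), truth


def truth_frame(truth: GroundTruth) -> pd.DataFrame:
    """Ground-truth components, one row per temperature."""
    return gxe.components_frame(truth.components)


def effects_frame(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Per-genotype effect draws (delta, eta, and the eps row)."""
    rows = []
    for i, g in enumerate(config.design.genotypes):
        row = {
            "genotype": g,
            "delta": truth.effects.delta[i],
            "eta": truth.effects.eta[i],
        }
        for j, c in enumerate(config.design.carbons):
            row[f"eps_{c}"] = truth.effects.eps[i, j]
        rows.append(row)
    return pd.DataFrame(rows)
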