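"""Flat YAML configuration for the pipeline and the simulator.

The document is versioned (``config_version: 1``) and maps directly onto the
dataclasses of the other modules: the experimental design, the loss
thresholds, analysis switches, and the simulator parameters. Every key has a
default, so an empty or absent config runs the standard assay layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import yaml

from .classify import DEFAULT_THRESHOLDS, LossThreshold
from .io import ExperimentDesign, ValidationError
from .simulate import SimulationConfig, ThermalPerformance, default_design, default_thermal

CONFIG_VERSION = 1


@dataclass
class AnalysisConfig:
    design: ExperimentDesign = field(default_factory=default_design)
    thresholds: tuple[LossThreshold, ...] = DEFAULT_THRESHOLDS
    alpha: float = 0.05
    clamp_negative_net: bool = True
    score_then_average: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


def _threshold_from_fraction(fraction: float) -> LossThreshold:
    return LossThreshold(label=f"{fraction:g}", fraction=float(fraction))


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load a YAML config; ``None`` returns the defaults."""
    if path is None:
        return AnalysisConfig()
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    version = doc.get("config_version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise ValidationError(f"unsupported config_version {version!r} (expected {CONFIG_VERSION})")

    if "design" in doc:
        d = doc["design"]
        design = ExperimentDesign(
            genotypes=tuple(d["genotypes"]),
            ancestor_label=d.get("ancestor", "ANC"),
            carbons=tuple(d["carbons"]),
            temperatures=tuple(float(t) for t in d["temperatures"]),
            replicates=int(d.get("replicates", 3)),
        )
    else:
        design = default_design()

    thresholds = tuple(
        _threshold_from_fraction(f) for f in doc.get("thresholds", (0.99, 0.95, 0.90))
    )

    sim_doc = doc.get("simulation", {})
    thermal = dict(default_thermal())
    for name, tp in sim_doc.get("thermal", {}).items():
        thermal[name] = ThermalPerformance(
            a_max=float(tp["a_max"]), t_opt=float(tp["t_opt"]), breadth=float(tp["breadth"])
        )
    thermal = {c: thermal[c] for c in design.carbons if c in thermal}
    sim_defaults = SimulationConfig()
    sim_kwargs = {
        key: type(getattr(sim_defaults, key))(sim_doc[key])
        for key in (
            "sigma_delta", "d0", "d2", "t_mid", "sigma_eta", "psi0", "psi1",
            "omega0", "omega1", "sigma_rep", "blank_mean", "blank_sd", "seed",
        )
        if key in sim_doc
    }
    simulation = SimulationConfig(design=design, thermal=thermal or default_thermal(), **sim_kwargs)

    return AnalysisConfig(
        design=design,
        thresholds=thresholds,
        alpha=float(doc.get("alpha", 0.05)),
        clamp_negative_net=bool(doc.get("clamp_negative_net", True)),
        score_then_average=bool(doc.get("score_then_average", False)),
        simulation=simulation,
    )


def dump_config(cfg: AnalysisConfig, path: str | Path) -> None:
    """Serialize a config back to versioned YAML."""
    doc = {
        "config_version": CONFIG_VERSION,
        "design": {
            "genotypes": list(cfg.design.genotypes),
            "ancestor": cfg.design.ancestor_label,
            "carbons": list(cfg.design.carbons),
            "temperatures": [float(t) for t in cfg.design.temperatures],
            "replicates": cfg.design.replicates,
        },
        "thresholds": [t.fraction for t in cfg.thresholds],
        "alpha": cfg.alpha,
        "clamp_negative_net": cfg.clamp_negative_net,
        "score_then_average": cfg.score_then_average,
        "simulation": {
            "sigma_delta": cfg.simulation.sigma_delta,
            "d0": cfg.simulation.d0,
            "d2": cfg.simulation.d2,
            "t_mid": cfg.simulation.t_mid,
            "sigma_eta": cfg.simulation.sigma_eta,
            "psi0": cfg.simulation.psi0,
            "psi1": cfg.simulation.psi1,
            "omega0": cfg.simulation.omega0,
            "omega1": cfg.simulation.omega1,
            "sigma_rep": cfg.simulation.sigma_rep,
            "blank_mean": cfg.simulation.blank_mean,
            "blank_sd": cfg.simulation.blank_sd,
            "seed": cfg.simulation.seed,
            "thermal": {
                name: {"a_max": tp.a_max, "t_opt": tp.t_opt, "breadth": tp.breadth}
                for name, tp in cfg.simulation.thermal.items()
            },
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
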