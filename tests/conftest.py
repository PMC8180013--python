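import numpy as np
import pytest

from ma_gxe import simulate
from ma_gxe.io import ExperimentDesign, MeasurementRecord


@pytest.fixture(scope="session")
def design() -> ExperimentDesign:
    """The standard assay layout: 10 MA genotypes + ancestor, 6 carbons,
    23-41 C in 2 C steps, 3 technical replicates."""
    return simulate.default_design()


@pytest.fixture(scope="session")
def toy_design() -> ExperimentDesign:
    """Minimal 2-genotype x 2-carbon x 1-temperature design for hand fixtures."""
    return ExperimentDesign(
        genotypes=("g1", "g2"),
        ancestor_label="anc",
        carbons=("a", "b"),
        temperatures=(37.0,),
        replicates=3,
    )


def toy_records(toy_design: ExperimentDesign) -> list[MeasurementRecord]:
    """Hand-written raw readings for the toy design (blanks 40 and 50 mOD)."""
    rows = [
        # carbon a: blank 40; anc raws 240/250/260; g1 140/150/160; g2 40/40/40
        (None, "a", 1, 40.0, True),
        ("anc", "a", 1, 240.0, False),
        ("anc", "a", 2, 250.0, False),
        ("anc", "a", 3, 260.0, False),
        ("g1", "a", 1, 140.0, False),
        ("g1", "a", 2, 150.0, False),
        ("g1", "a", 3, 160.0, False),
        ("g2", "a", 1, 40.0, False),
        ("g2", "a", 2, 40.0, False),
        ("g2", "a", 3, 40.0, False),
        # carbon b: blank 50; anc 150 x3; g1 250 x3; g2 50 x3
        (None, "b", 1, 50.0, True),
        ("anc", "b", 1, 150.0, False),
        ("anc", "b", 2, 150.0, False),
        ("anc", "b", 3, 150.0, False),
        ("g1", "b", 1, 250.0, False),
        ("g1", "b", 2, 250.0, False),
        ("g1", "b", 3, 250.0, False),
        ("g2", "b", 1, 50.0, False),
        ("g2", "b", 2, 50.0, False),
        ("g2", "b", 3, 50.0, False),
    ]
    return [
        MeasurementRecord(genotype=g, carbon=c, temperature_c=37.0, replicate=r, mOD=v, is_blank=b)
        for g, c, r, v, b in rows
    ]


@pytest.fixture()
def toy_measurements(toy_design):
    return toy_records(toy_design)


@pytest.fixture(scope="session")
def default_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig()


@pytest.fixture(scope="session")
def sim_scores(default_config):
    """One simulated dataset pushed through scoring (seed 42), with truth."""
    return simulate.simulate_scores(default_config, seed=42)


def random_matrix(rng: np.random.Generator, g: int | None = None, e: int | None = None):
    """A random complete G x E score matrix for property tests."""
    from ma_gxe.gxe import GxEMatrix

    g = int(rng.integers(2, 13)) if g is None else g
    e = int(rng.integers(2, 9)) if e is None else e
    values = rng.normal(0.0, 0.2, size=(g, e))
    return GxEMatrix(
        temperature_c=30.0,
        values=values,
        row_labels=tuple(f"g{i}" for i in range(g)),
        col_labels=tuple(f"c{j}" for j in range(e)),
    )
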