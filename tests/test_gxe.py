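import numpy as np
import pytest

from conftest import random_matrix
from ma_gxe import gxe
from ma_gxe.gxe import (
    GxEMatrix,
    build_matrix,
    env_stats,
    inconsistency,
    partition,
    pairwise_oracle,
    responsiveness,
)
from ma_gxe.io import MissingDataError


def matrix(values, t=30.0):
    values = np.asarray(values, dtype=float)
    return GxEMatrix(
        temperature_c=t,
        values=values,
        row_labels=tuple(f"g{i}" for i in range(values.shape[0])),
        col_labels=tuple(f"c{j}" for j in range(values.shape[1])),
    )


class TestBuildMatrix:
    def test_full_table_gives_design_shaped_matrix(self, sim_scores):
        table, _ = sim_scores
        m = build_matrix(table, 37.0)
        assert m.values.shape == (10, 6)
        assert m.row_labels == table.design.genotypes
        assert m.col_labels == table.design.carbons

    def test_missing_cell_is_named(self, sim_scores):
        table, _ = sim_scores
        frame = table.frame
        drop = ~((frame["genotype"] == "MA03") & (frame["carbon"] == "maltose")
                 & (frame["temperature_c"] == 29.0))
        pruned = type(table)(frame=frame[drop], design=table.design)
        with pytest.raises(MissingDataError, match=r"MA03.*maltose"):
            build_matrix(pruned, 29.0)

    def test_deterministic(self, sim_scores):
        table, _ = sim_scores
        a = build_matrix(table, 33.0)
        b = build_matrix(table, 33.0)
        assert np.array_equal(a.values, b.values)


class TestEnvStats:
    def test_hand_sd(self):
        stats = env_stats(matrix([[0.1, -0.1], [0.0, 0.0]]))
        assert stats.sigma_E[0] == pytest.approx(np.sqrt(0.02), abs=1e-7)

    def test_proportional_profiles_correlate_perfectly(self):
        stats = env_stats(matrix([[0.1, -0.1], [0.2, -0.2]]))
        assert stats.rho[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_mirrored_profiles_anticorrelate(self):
        stats = env_stats(matrix([[0.1, -0.1], [-0.1, 0.1]]))
        assert stats.rho[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_row_flagged_null(self):
        with pytest.warns(UserWarning, match="zero environmental variance"):
            stats = env_stats(matrix([[0.1, -0.1], [0.3, 0.3]]))
        assert np.isnan(stats.rho[0, 1])
        assert stats.sigma_E[1] == 0.0


class TestResponsivenessInconsistency:
    def test_equal_sds_give_zero_R(self):
        stats = env_stats(matrix([[0.1, -0.1], [-0.1, 0.1]]))
        assert responsiveness(stats) == pytest.approx(0.0, abs=1e-15)

    def test_hand_R(self):
        stats = env_stats(matrix([[0.1, -0.1], [0.2, -0.2]]))
        assert responsiveness(stats) == pytest.approx(0.01, abs=1e-12)

    def test_perfect_correlation_gives_zero_I(self):
        stats = env_stats(matrix([[0.1, -0.1], [0.2, -0.2]]))
        assert inconsistency(stats) == pytest.approx(0.0, abs=1e-15)

    def test_hand_I(self):
        stats = env_stats(matrix([[0.1, -0.1], [-0.1, 0.1]]))
        assert inconsistency(stats) == pytest.approx(0.04, abs=1e-12)

    def test_zero_variance_pairs_contribute_nothing(self):
        with pytest.warns(UserWarning):
            stats = env_stats(matrix([[0.1, -0.1], [0.2, 0.2], [0.3, -0.3]]))
        assert np.isfinite(inconsistency(stats))


class TestPartition:
    def test_additive_matrix_has_no_interaction(self):
        a = np.array([0.0, -0.1, 0.2])
        b = np.array([0.05, -0.05, 0.1, 0.0])
        vc = partition(matrix(a[:, None] + b[None, :]))
        assert vc.sigma2_GE == pytest.approx(0.0, abs=1e-15)
        assert vc.responsiveness_R == pytest.approx(0.0, abs=1e-15)
        assert vc.inconsistency_I == pytest.approx(0.0, abs=1e-15)

    def test_worked_2x2_pure_inconsistency(self):
        vc = partition(matrix([[0.1, -0.1], [-0.1, 0.1]]))
        assert vc.sigma2_G == pytest.approx(0.0, abs=1e-15)
        assert vc.sigma2_E == pytest.approx(0.0, abs=1e-15)
        assert vc.sigma2_GE == pytest.approx(0.04, abs=1e-12)
        assert vc.responsiveness_R == pytest.approx(0.0, abs=1e-12)
        assert vc.inconsistency_I == pytest.approx(0.04, abs=1e-12)

    def test_constant_matrix_all_zero(self):
        with pytest.warns(UserWarning):
            vc = partition(matrix(np.full((3, 4), 0.7)))
        for value in (vc.total, vc.sigma2_G, vc.sigma2_E, vc.sigma2_GE,
                      vc.responsiveness_R, vc.inconsistency_I):
            assert value == pytest.approx(0.0, abs=1e-15)

    def test_total_is_sum_of_components(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vc = partition(random_matrix(rng))
            assert vc.total == pytest.approx(
                vc.sigma2_G + vc.sigma2_E + vc.sigma2_GE, rel=1e-12
            )
            assert min(vc.sigma2_G, vc.sigma2_E, vc.sigma2_GE,
                       vc.responsiveness_R, vc.inconsistency_I) >= -1e-12


class TestPairwiseOracle:
    def test_agrees_with_partition_on_random_matrices(self):
        rng = np.random.default_rng(202)
        for _ in range(30):
            m = random_matrix(rng)
            vc = partition(m)
            r, i, ge = pairwise_oracle(m)
            assert vc.responsiveness_R == pytest.approx(r, abs=1e-10)
            assert vc.inconsistency_I == pytest.approx(i, abs=1e-10)
            assert vc.sigma2_GE == pytest.approx(ge, abs=1e-10)

    def test_identity_on_simulated_matrix(self, sim_scores):
        table, _ = sim_scores
        m = build_matrix(table, 41.0)
        r, i, ge = pairwise_oracle(m)
        assert r + i == pytest.approx(ge, rel=1e-10)

    def test_worked_2x2(self):
        r, i, ge = pairwise_oracle(matrix([[0.1, -0.1], [-0.1, 0.1]]))
        assert (r, i, ge) == pytest.approx((0.0, 0.04, 0.04), abs=1e-12)


class TestInvariances:
    def test_constant_shift_changes_nothing(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, 6, 5)
        vc0 = partition(m)
        vc1 = partition(matrix(m.values + 0.37))
        for attr in ("sigma2_G", "sigma2_E", "sigma2_GE", "responsiveness_R", "inconsistency_I"):
            assert getattr(vc1, attr) == pytest.approx(getattr(vc0, attr), abs=1e-12)

    def test_genotype_shift_touches_only_genetic(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 6, 5)
        vc0 = partition(m)
        shift = rng.normal(size=(6, 1))
        vc1 = partition(matrix(m.values + shift))
        assert vc1.sigma2_E == pytest.approx(vc0.sigma2_E, abs=1e-12)
        assert vc1.sigma2_GE == pytest.approx(vc0.sigma2_GE, abs=1e-12)
        assert vc1.responsiveness_R == pytest.approx(vc0.responsiveness_R, abs=1e-12)
        assert vc1.inconsistency_I == pytest.approx(vc0.inconsistency_I, abs=1e-12)
        assert vc1.sigma2_G != pytest.approx(vc0.sigma2_G, abs=1e-6)

    def test_carbon_shift_touches_only_environmental(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, 6, 5)
        vc0 = partition(m)
        shift = rng.normal(size=(1, 5))
        vc1 = partition(matrix(m.values + shift))
        assert vc1.sigma2_G == pytest.approx(vc0.sigma2_G, abs=1e-12)
        assert vc1.sigma2_GE == pytest.approx(vc0.sigma2_GE, abs=1e-12)
        assert vc1.sigma2_E != pytest.approx(vc0.sigma2_E, abs=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        m = random_matrix(rng, 7, 6)
        vc0 = partition(m)
        rows = rng.permutation(7)
        cols = rng.permutation(6)
        vc1 = partition(matrix(m.values[np.ix_(rows, cols)]))
        for attr in ("total", "sigma2_G", "sigma2_E", "sigma2_GE",
                     "responsiveness_R", "inconsistency_I"):
            assert getattr(vc1, attr) == pytest.approx(getattr(vc0, attr), rel=1e-9, abs=1e-14)

    def test_rescaled_profiles_with_equal_sd_have_zero_R(self):
        # rows are +/- one profile: all sigma_E equal, so R must vanish
        base = np.array([0.3, -0.1, 0.2, -0.4])
        m = matrix(np.vstack([base, -base, base]))
        vc = partition(m)
        assert vc.responsiveness_R == pytest.approx(0.0, abs=1e-14)
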