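import numpy as np
import pytest

from batchsw.covariance import (
    ParameterError,
    cluster_period_cov,
    from_icc_cac,
)
from batchsw.designs import UNOBSERVED, TreatmentSchematic, build_standard_sw, make_batched
from batchsw.lmm_power import (
    InestimableDesignError,
    clusters_for_power,
    combine_batches,
    gls_oracle,
    power_from_variance,
    var_batched,
    var_single_batch,
)


class TestCombineBatches:
    @pytest.mark.parametrize(
        "variances, expected",
        [([0.1, 0.1], 0.05), ([0.2, 0.3], 0.12), ([0.4], 0.4)],
    )
    def test_precision_sum(self, variances, expected):
        assert combine_batches(variances).var_combined == pytest.approx(expected)

    def test_identical_batches_expose_var0(self):
        res = combine_batches([0.3, 0.3, 0.3])
        assert res.var0 == pytest.approx(0.3)
        assert res.var_combined == pytest.approx(0.1)

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            combine_batches([])

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ParameterError):
            combine_batches([0.1, 0.0])


class TestVarSingleBatch:
    def test_clusters_scale_information_additively(self, staircase6, hh_model):
        v = cluster_period_cov(6, 10, hh_model)
        var1 = var_single_batch(staircase6, v, clusters_per_sequence=1)
        var4 = var_single_batch(staircase6, v, clusters_per_sequence=4)
        assert var4 == pytest.approx(var1 / 4, rel=1e-12)

    def test_inestimable_all_intervention(self, hh_model):
        sch = TreatmentSchematic(np.ones((3, 4), dtype=int))
        v = cluster_period_cov(4, 10, hh_model)
        with pytest.raises(InestimableDesignError):
            var_single_batch(sch, v)

    def test_ols_oracle_no_clustering(self):
        """With no cluster effects and m=1, GLS collapses to OLS.

        Independent route: materialize the period-dummy + treatment
        design matrix and read the theta entry of sigma^2 (W'W)^-1.
        """
        model = from_icc_cac("hussey_hughes", 0.0)
        sch = build_standard_sw(4)
        v = cluster_period_cov(4, 1, model)
        got = var_single_batch(sch, v)

        k, t = sch.cells.shape
        z = np.tile(np.eye(t), (k, 1))
        x = sch.cells.reshape(-1, 1).astype(float)
        w = np.hstack([z, x])
        cov = model.sigma_eps2 * np.linalg.inv(w.T @ w)
        assert got == pytest.approx(cov[-1, -1], rel=1e-12)


class TestVarBatched:
    def test_single_batch_passthrough(self, staircase6, hh_model):
        bd = make_batched(staircase6, n_batches=1)
        v = cluster_period_cov(6, 10, hh_model)
        res = var_batched(bd, hh_model, 10)
        assert res.var_combined == pytest.approx(var_single_batch(staircase6, v))

    def test_batches_equivalent_to_extra_clusters(self, staircase6, hh_model):
        """B batches with C clusters/sequence = one component with B*C."""
        batched = var_batched(
            make_batched(staircase6, n_batches=3, clusters_per_sequence=2),
            hh_model,
            m=10,
        ).var_combined
        single = var_batched(
            make_batched(staircase6, n_batches=1, clusters_per_sequence=6),
            hh_model,
            m=10,
        ).var_combined
        assert batched == pytest.approx(single, rel=1e-10)

    @pytest.mark.parametrize("overlap", range(7))
    def test_overlap_invariance(self, staircase6, hh_model, overlap):
        """Calendar overlap between batches never moves the variance."""
        base = var_batched(
            make_batched(staircase6, n_batches=3, overlap=0), hh_model, 10
        ).var_combined
        shifted = var_batched(
            make_batched(staircase6, n_batches=3, overlap=overlap), hh_model, 10
        ).var_combined
        assert shifted == pytest.approx(base, rel=1e-12)


def _incomplete_staircase():
    cells = build_standard_sw(4).cells.copy()
    cells[0, 3] = UNOBSERVED  # drop one post-rollout cell
    cells[2, 0] = UNOBSERVED  # and one pre-rollout cell
    return TreatmentSchematic(cells)


class TestGlsOracle:
    """Full individual-level GLS agrees with the reduced computation."""

    @pytest.mark.parametrize(
        "structure, cac", [("hussey_hughes", 1.0), ("discrete_decay", 0.9)]
    )
    def test_two_batches_small(self, structure, cac):
        model = from_icc_cac(structure, 0.05, cac)
        bd = make_batched(build_standard_sw(3), n_batches=2, clusters_per_sequence=1)
        reduced = var_batched(bd, model, m=2).var_combined
        full = gls_oracle(bd, model, m=2)
        assert full == pytest.approx(reduced, rel=1e-8)

    def test_heterogeneous_batches_with_missing_cells(self):
        model = from_icc_cac("nested_exchangeable", 0.1, 0.8)
        bd = make_batched(
            [_incomplete_staircase(), build_standard_sw(3)],
            overlap=0,
            clusters_per_sequence=[1, 2],
        )
        reduced = var_batched(bd, model, m=3).var_combined
        full = gls_oracle(bd, model, m=3)
        assert full == pytest.approx(reduced, rel=1e-8)

    def test_shared_calendar_periods_irrelevant_when_disjoint(self, hh_model):
        """Without overlap, calendar-period effects saturate to batch ones."""
        bd = make_batched(build_standard_sw(3), n_batches=2, overlap=0)
        with_interaction = gls_oracle(bd, hh_model, m=2, include_batch_period_interaction=True)
        without = gls_oracle(bd, hh_model, m=2, include_batch_period_interaction=False)
        assert without == pytest.approx(with_interaction, rel=1e-10)

    def test_overlapping_shared_period_effects_differ(self, hh_model):
        """With shared calendar period effects, overlap does change variance."""
        bd0 = make_batched(build_standard_sw(3), n_batches=2, overlap=0)
        bd2 = make_batched(build_standard_sw(3), n_batches=2, overlap=2)
        v0 = gls_oracle(bd0, hh_model, m=2, include_batch_period_interaction=False)
        v2 = gls_oracle(bd2, hh_model, m=2, include_batch_period_interaction=False)
        assert v0 != pytest.approx(v2, rel=1e-6)

    def test_no_contrast_is_inestimable(self, hh_model):
        sch = TreatmentSchematic(np.array([[0, 0, 0], [0, 0, 0]]))
        bd = make_batched(sch, n_batches=1)
        with pytest.raises(InestimableDesignError):
            gls_oracle(bd, hh_model, m=1)


class TestPowerFromVariance:
    def test_null_effect_gives_one_tail(self):
        assert power_from_variance(1.0, 0.0) == pytest.approx(0.025)

    def test_vanishing_variance_gives_full_power(self):
        assert power_from_variance(1e-12, 0.1) == pytest.approx(1.0)

    def test_monotone_in_effect_and_variance(self):
        assert power_from_variance(0.01, 0.3) > power_from_variance(0.01, 0.2)
        assert power_from_variance(0.005, 0.2) > power_from_variance(0.01, 0.2)

    def test_monotone_in_clusters_per_sequence(self, staircase6, hh_model):
        powers = [
            power_from_variance(
                var_batched(
                    make_batched(staircase6, n_batches=2, clusters_per_sequence=c),
                    hh_model,
                    10,
                ).var_combined,
                0.15,
            )
            for c in (1, 2, 4, 8)
        ]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    @pytest.mark.parametrize("bad", [{"var": 0.0}, {"alpha": 0.0}, {"alpha": 1.0}])
    def test_parameter_validation(self, bad):
        kwargs = {"var": 0.01, "theta": 0.1, "alpha": 0.05, **bad}
        with pytest.raises(ParameterError):
            power_from_variance(**kwargs)


class TestClustersForPower:
    def test_returns_minimal_count(self, staircase6, hh_model):
        c = clusters_for_power(staircase6, hh_model, m=10, theta=0.15)
        v = cluster_period_cov(6, 10, hh_model)

        def power_at(cc):
            return power_from_variance(var_single_batch(staircase6, v, cc), 0.15)

        assert power_at(c) >= 0.8
        assert c == 1 or power_at(c - 1) < 0.8

    def test_unreachable_target_raises(self, staircase6, hh_model):
        with pytest.raises(ParameterError):
            clusters_for_power(
                staircase6, hh_model, m=1, theta=1e-6, max_clusters=10
            )
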