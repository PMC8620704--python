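"""Inverse transform sampling, perturbation transforms, and cell simulation."""

import numpy as np
import pytest
from scipy import stats as sps

from cellcom import (
    DomainError,
    EmpiricalSampler,
    PerturbationSpec,
    shift_transform,
    simulate_cells,
    spread_transform,
)
from cellcom.simulate import run_simulation_study


class TestEmpiricalSampler:
    def test_linear_interpolation_midpoint(self):
        assert EmpiricalSampler([0.0, 1.0]).quantile(0.5) == 0.5

    def test_boundaries_hit_min_and_max(self):
        s = EmpiricalSampler([3.0, -1.0, 7.0])
        assert s.quantile(0.0) == -1.0
        assert s.quantile(1.0) == 7.0

    def test_draws_stay_within_source_range(self):
        rng = np.random.default_rng(0)
        src = rng.normal(0, 1, 50)
        draws = EmpiricalSampler(src).sample(2000, rng)
        assert draws.min() >= src.min() and draws.max() <= src.max()

    def test_ks_convergence_to_source(self):
        rng = np.random.default_rng(12)
        src = rng.normal(0, 1, 2000)
        draws = EmpiricalSampler(src).sample(10_000, rng)
        ks = sps.ks_2samp(src, draws).statistic
        assert ks < 0.05

    def test_fewer_than_two_values_errors(self):
        with pytest.raises(DomainError):
            EmpiricalSampler([1.0])


class TestShiftTransform:
    def test_identity_at_n_zero(self):
        np.testing.assert_array_equal(shift_transform([1, 2, 3], 0.0), [1, 2, 3])

    def test_forced_arithmetic(self):
        np.testing.assert_allclose(shift_transform([1, 2, 3], 1.0), [3, 4, 5])

    def test_mean_closed_form(self):
        rng = np.random.default_rng(1)
        v = rng.gamma(2, 3, 500)
        for n in (0.2, 1.0, 2.0):
            assert shift_transform(v, n).mean() == pytest.approx(
                v.mean() * (1 + n), rel=1e-12
            )


class TestSpreadTransform:
    def test_identity_at_n_zero(self):
        v = np.array([1.0, 5.0, 2.0])
        np.testing.assert_array_equal(spread_transform(v, 0.0, 3), v)

    def test_elementwise_bound(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(10, 30, 400)
        n = 1.5
        out = spread_transform(v, n, 4)
        assert np.all(np.abs(out - v) <= n * abs(v.mean()) + 1e-9)

    def test_mean_preserved_and_variance_increases(self):
        rng = np.random.default_rng(9)
        v = rng.normal(100, 10, 10_000)
        out = spread_transform(v, 1.0, 10)
        # E[x_rnd - mean] ~ 0, so the mean moves only by Monte-Carlo error
        assert out.mean() == pytest.approx(v.mean(), rel=0.01)
        assert out.var() > v.var()

    def test_degenerate_input_errors(self):
        with pytest.raises(DomainError):
            spread_transform([5.0, 5.0, 5.0], 1.0, 0)

    def test_deterministic_given_seed(self):
        v = np.linspace(0, 10, 100)
        np.testing.assert_array_equal(
            spread_transform(v, 0.7, 123), spread_transform(v, 0.7, 123)
        )


class TestSimulateCells:
    def test_deterministic_given_seed(self, small_group):
        spec = PerturbationSpec(mode="shift", n=0.5)
        a = simulate_cells(small_group, spec, 6, seed=77)
        b = simulate_cells(small_group, spec, 6, seed=77)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.positions(), cb.positions())
            np.testing.assert_array_equal(ca.intensities(), cb.intensities())
            np.testing.assert_array_equal(ca.reference_point, cb.reference_point)

    def test_counts_resampled_from_source(self, small_group):
        sim = simulate_cells(small_group, PerturbationSpec(), 20, seed=5)
        source_counts = {c.n_objects for c in small_group}
        assert all(c.n_objects in source_counts for c in sim)

    def test_shift_moves_pooled_mean_by_closed_form(self, small_group):
        n = 2.0
        sim = simulate_cells(
            small_group, PerturbationSpec(mode="shift", n=n), 40, seed=21
        )
        src_x = np.concatenate([c.positions()[:, 0] for c in small_group])
        sim_x = np.concatenate([c.positions()[:, 0] for c in sim])
        assert sim_x.mean() == pytest.approx(src_x.mean() * (1 + n), rel=0.02)

    def test_reference_points_not_perturbed(self, small_group):
        sim = simulate_cells(
            small_group, PerturbationSpec(mode="shift", n=2.0), 40, seed=22
        )
        src_refs = np.array([c.reference_point for c in small_group])
        sim_refs = np.array([c.reference_point for c in sim])
        for ax in range(3):
            assert sim_refs[:, ax].min() >= src_refs[:, ax].min() - 1e-9
            assert sim_refs[:, ax].max() <= src_refs[:, ax].max() + 1e-9

    def test_volume_intensity_untouched_by_default_spatial_flags(self, small_group):
        sim = simulate_cells(
            small_group, PerturbationSpec(mode="shift", n=2.0), 40, seed=23
        )
        src_v = np.concatenate([c.volumes() for c in small_group])
        sim_v = np.concatenate([c.volumes() for c in sim])
        assert sim_v.max() <= src_v.max() and sim_v.min() >= src_v.min()

    def test_unperturbed_simulation_is_faithful(self, small_group):
        from cellcom import compare_samples

        sim = simulate_cells(small_group, PerturbationSpec(), 60, seed=31)
        src_x = np.concatenate([c.positions()[:, 0] for c in small_group])
        sim_x = np.concatenate([c.positions()[:, 0] for c in sim])
        rep = compare_samples(src_x, sim_x)
        assert rep.histogram_overlap > 0.8
        assert rep.hellinger < 0.3

    def test_empty_source_errors(self):
        from cellcom import StudyGroup

        with pytest.raises(DomainError):
            simulate_cells(StudyGroup("empty"), PerturbationSpec(), 3, seed=0)


class TestSimulationStudy:
    def test_rejection_rate_monotone_in_n(self, small_group):
        """Power grows with perturbation magnitude for the matched metric."""
        res = run_simulation_study(
            small_group, n_values=(0.0, 1.0, 2.0), modes=("shift",),
            reps=5, seed=3, n_split_reps=2,
        )
        ref = res.table[res.table["metric"] == "reference"].sort_values("n")
        rates = ref["reject_fraction"].to_numpy()
        assert np.all(np.diff(rates) >= 0)

    def test_study_table_layout(self, small_group):
        res = run_simulation_study(
            small_group, n_values=(0.0, 1.0), modes=("spread",), reps=3,
            seed=4, n_split_reps=3,
        )
        assert set(res.table["metric"]) == {"reference", "spread"}
        assert len(res.table) == 4
        assert res.random_split["p_value"].between(0, 1).all()
        assert (res.table["stars"].isin(["-", "*", "**", "***", "****"])).all()
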