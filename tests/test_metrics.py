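"""Center-of-mass metric correctness: oracles and invariances."""

from dataclasses import replace
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellcom import (
    CellRecord,
    DomainError,
    ReceptorObject,
    center_of_mass,
    reference_metric,
    spread_metric,
    virtual_mass,
)
from conftest import random_cell


def com_bruteforce(objects):
    """Exact rational-arithmetic center of mass (independent oracle)."""
    out = []
    for axis in ("x", "y", "z"):
        num = Fraction(0)
        den = Fraction(0)
        for o in objects:
            w = Fraction(o.mean_intensity) * o.n_voxels
            num += w * Fraction(getattr(o, axis))
            den += w
        out.append(float(num / den))
    return np.array(out)


class TestVirtualMass:
    def test_identity_normalization(self):
        obj = ReceptorObject(x=0, y=0, z=0, n_voxels=5, mean_intensity=10.0)
        assert virtual_mass(obj, 10.0) == 5.0

    def test_formula(self):
        obj = ReceptorObject(x=0, y=0, z=0, n_voxels=3, mean_intensity=20.0)
        assert virtual_mass(obj, 10.0) == 6.0

    def test_inverse_scaling_in_global_intensity(self):
        obj = ReceptorObject(x=1, y=2, z=3, n_voxels=7, mean_intensity=13.5)
        for c in (0.5, 2.0, 11.0):
            assert virtual_mass(obj, c * 4.0) == pytest.approx(
                virtual_mass(obj, 4.0) / c
            )

    def test_nonpositive_global_intensity_errors(self):
        obj = ReceptorObject(x=0, y=0, z=0, n_voxels=1, mean_intensity=1.0)
        with pytest.raises(DomainError):
            virtual_mass(obj, 0.0)


class TestCenterOfMass:
    def test_single_object_is_its_own_com(self):
        obj = ReceptorObject(x=3, y=4, z=5, n_voxels=2, mean_intensity=7.0)
        np.testing.assert_allclose(center_of_mass([obj]), [3, 4, 5])

    def test_two_equal_masses_symmetric(self):
        objs = [
            ReceptorObject(x=0, y=0, z=0, n_voxels=4, mean_intensity=5.0),
            ReceptorObject(x=2, y=0, z=0, n_voxels=4, mean_intensity=5.0),
        ]
        np.testing.assert_allclose(center_of_mass(objs), [1, 0, 0])

    def test_matches_bruteforce_on_random_cells(self):
        rng = np.random.default_rng(202)
        for _ in range(25):
            cell = random_cell(rng, n_objects=50)
            np.testing.assert_allclose(
                center_of_mass(cell.objects),
                com_bruteforce(cell.objects),
                rtol=1e-9, atol=1e-9,
            )

    def test_empty_list_errors(self):
        with pytest.raises(DomainError):
            center_of_mass([])

    def test_all_zero_weights_error(self):
        objs = [ReceptorObject(x=1, y=1, z=1, n_voxels=1, mean_intensity=0.0)]
        with pytest.raises(DomainError):
            center_of_mass(objs)

    @given(factor=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_global_intensity_normalization_cancels(self, factor):
        rng = np.random.default_rng(7)
        cell = random_cell(rng, n_objects=12)
        scaled = [replace(o, mean_intensity=o.mean_intensity * factor)
                  for o in cell.objects]
        np.testing.assert_allclose(
            center_of_mass(cell.objects), center_of_mass(scaled), rtol=1e-9
        )


class TestReferenceMetric:
    def test_zero_when_com_equals_reference(self):
        obj = ReceptorObject(x=3, y=4, z=5, n_voxels=1, mean_intensity=1.0)
        cell = CellRecord(cell_id="c", objects=[obj], reference_point=[3, 4, 5])
        assert reference_metric(cell).value_um == 0.0

    def test_3_4_5_triangle_times_voxel_size(self):
        s = 0.2
        obj = ReceptorObject(x=3, y=4, z=0, n_voxels=1, mean_intensity=1.0)
        cell = CellRecord(cell_id="c", objects=[obj], reference_point=[0, 0, 0],
                          voxel_size_um=(s, s, s))
        assert reference_metric(cell).value_um == pytest.approx(5 * s)

    def test_missing_reference_errors(self):
        obj = ReceptorObject(x=0, y=0, z=0, n_voxels=1, mean_intensity=1.0)
        with pytest.raises(DomainError):
            reference_metric(CellRecord(cell_id="c", objects=[obj]))

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(5)
        cell = random_cell(rng, n_objects=40)
        com = com_bruteforce(cell.objects)
        expected = float(np.linalg.norm(
            (com - cell.reference_point) * np.array(cell.voxel_size_um)
        ))
        assert reference_metric(cell).value_um == pytest.approx(expected, rel=1e-9)

    def test_anisotropic_voxels_change_the_value(self):
        obj = ReceptorObject(x=1, y=0, z=0, n_voxels=1, mean_intensity=1.0)
        iso = CellRecord(cell_id="c", objects=[obj], reference_point=[0, 0, 0],
                         voxel_size_um=(0.1, 0.1, 0.1))
        aniso = CellRecord(cell_id="c", objects=[obj], reference_point=[0, 0, 0],
                           voxel_size_um=(0.3, 0.1, 0.1))
        assert aniso.reference_point is not None
        assert reference_metric(aniso).value_um == pytest.approx(
            3 * reference_metric(iso).value_um
        )


class TestSpreadMetric:
    def test_single_object_spreads_zero(self):
        obj = ReceptorObject(x=9, y=9, z=9, n_voxels=3, mean_intensity=2.0)
        cell = CellRecord(cell_id="c", objects=[obj])
        assert spread_metric(cell).value_um == 0.0

    def test_two_equal_masses_mean_half_separation(self):
        s = 0.15
        objs = [
            ReceptorObject(x=0, y=0, z=0, n_voxels=1, mean_intensity=1.0),
            ReceptorObject(x=2, y=0, z=0, n_voxels=1, mean_intensity=1.0),
        ]
        cell = CellRecord(cell_id="c", objects=objs, voxel_size_um=(s, s, s))
        assert spread_metric(cell).value_um == pytest.approx(s)

    def test_matches_bruteforce_mean_distance(self):
        rng = np.random.default_rng(17)
        cell = random_cell(rng, n_objects=30)
        com = com_bruteforce(cell.objects)
        vs = np.array(cell.voxel_size_um)
        dists = [
            float(np.linalg.norm((o.position - com) * vs)) for o in cell.objects
        ]
        assert spread_metric(cell).value_um == pytest.approx(
            float(np.mean(dists)), rel=1e-9
        )

    def test_weighted_variant_uses_virtual_masses(self):
        objs = [
            ReceptorObject(x=0, y=0, z=0, n_voxels=9, mean_intensity=1.0),
            ReceptorObject(x=10, y=0, z=0, n_voxels=1, mean_intensity=1.0),
        ]
        cell = CellRecord(cell_id="c", objects=objs, voxel_size_um=(1, 1, 1))
        # COM at x=1; distances 1 and 9; weighted mean = (9*1 + 1*9)/10
        assert spread_metric(cell, weighted=True).value_um == pytest.approx(1.8)
        assert spread_metric(cell).value_um == pytest.approx(5.0)


class TestTranslationEquivariance:
    @given(
        t=st.tuples(*[st.floats(min_value=-50, max_value=50) for _ in range(3)])
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_both_metrics_translation_invariant(self, t):
        rng = np.random.default_rng(23)
        cell = random_cell(rng, n_objects=15)
        moved = cell.translated(t)
        assert reference_metric(moved).value_um == pytest.approx(
            reference_metric(cell).value_um, abs=1e-8
        )
        assert spread_metric(moved).value_um == pytest.approx(
            spread_metric(cell).value_um, abs=1e-8
        )
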