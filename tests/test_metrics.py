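import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from agree3d.errors import DegenerateResolutionError
from agree3d.geometry import shared_grid, voxelize
from agree3d.metrics import (
    AgreementRecord,
    PairwiseEvaluator,
    dc,
    deviation_map,
    dsc,
    mssd,
    um95,
)
from agree3d.primitives import ellipsoid, icosphere
from agree3d.synthetic import ObserverModel, perturb_contour


class TestDC:
    def test_identical_is_zero(self, sphere10):
        assert dc(sphere10, sphere10) == 0.0

    def test_sphere_pair_offset(self):
        a = icosphere(8.0, 2)
        b = icosphere(8.0, 2, center=(0, 0, 5.0))
        assert dc(a, b) == pytest.approx(5.0, abs=1e-9)

    def test_translated_uterus(self, uterus):
        assert dc(uterus, uterus.translated([3, 4, 0])) == pytest.approx(5.0, abs=1e-6)

    def test_symmetric(self, uterus, sphere10):
        assert dc(uterus, sphere10) == dc(sphere10, uterus)


class TestDSC:
    def test_identical_is_one(self, sphere10):
        assert dsc(sphere10, sphere10, spacing=1.0) == 1.0

    def test_disjoint_is_zero(self):
        a = icosphere(5.0, 2)
        b = icosphere(5.0, 2, center=(30, 0, 0))
        assert dsc(a, b, spacing=1.0) == 0.0

    def test_concentric_spheres_analytic(self, sphere10, sphere20):
        # volumes r^3 : (2r)^3 -> 2*1/(1+8)
        assert dsc(sphere10, sphere20, spacing=0.5) == pytest.approx(2 / 9, rel=0.01)

    def test_offset_cubes_analytic(self, unit_cube):
        b = unit_cube.translated([0.5, 0, 0])
        assert dsc(unit_cube, b, spacing=0.1) == pytest.approx(0.5, abs=0.02)

    def test_symmetric_exact(self, sphere10, uterus):
        assert dsc(sphere10, uterus, 1.0) == dsc(uterus, sphere10, 1.0)

    def test_monotone_decrease_under_translation(self, sphere10):
        vals = [dsc(sphere10, sphere10.translated([d, 0, 0]), 1.0)
                for d in (0, 4, 8, 12, 16, 25)]
        assert all(x > y or (x == y == 0) for x, y in zip(vals, vals[1:]))
        assert vals[0] == 1.0 and vals[-1] == 0.0

    def test_fine_grid_drift_small(self, uterus):
        other = perturb_contour(uterus, ObserverModel(sigma_obs=2.0, seed=3))
        coarse = dsc(uterus, other, spacing=1.0)
        fine = dsc(uterus, other, spacing=0.5)
        assert coarse == pytest.approx(fine, abs=0.01)


class TestMSSD:
    def test_identical_is_zero(self, sphere10):
        assert mssd(sphere10, sphere10) == 0.0

    def test_concentric_icospheres_radial(self, sphere10, sphere20):
        assert mssd(sphere10, sphere20) == pytest.approx(10.0, abs=1e-9)
        assert mssd(sphere20, sphere10) == pytest.approx(10.0, abs=1e-9)

    def test_brute_force_oracle_exact(self):
        a = icosphere(9.0, 1)   # 42 vertices
        b = icosphere(12.0, 2)  # 162 vertices
        d = cdist(a.vertices, b.vertices).min(axis=1).mean()
        assert mssd(a, b) == pytest.approx(d, abs=0)  # bit-exact

    def test_directedness(self):
        inner = icosphere(5.0, 2)
        outer = ellipsoid((20.0, 10.0, 8.0), 2)
        assert mssd(inner, outer) != pytest.approx(mssd(outer, inner), abs=0.1)

    def test_point_to_surface_not_larger(self, sphere10, sphere20):
        p2s = mssd(sphere10, sphere20, point_to_surface=True)
        assert p2s <= mssd(sphere10, sphere20) + 1e-12
        assert p2s == pytest.approx(10.0, abs=0.2)


class TestUM95:
    def test_contained_is_zero(self, sphere10, sphere20):
        assert um95(sphere20, sphere10, spacing=1.0) == 0.0

    def test_concentric_analytic(self, sphere10, sphere20):
        expect = 10 * (2 * 0.95 ** (1 / 3) - 1)
        got = um95(sphere10, sphere20, spacing=1.0, pad=12.0)
        assert got == pytest.approx(expect, abs=1.0)

    def test_coverage_domain(self, sphere10, sphere20):
        with pytest.raises(ValueError):
            um95(sphere10, sphere20, coverage=0.0)
        with pytest.raises(ValueError):
            um95(sphere10, sphere20, coverage=1.2)

    def test_full_coverage_requested(self, sphere10, sphere20):
        m = um95(sphere10, sphere20, coverage=1.0, spacing=1.0, pad=12.0)
        assert m == pytest.approx(10.0, abs=1.5)

    def test_dilation_sweep_oracle(self):
        # blob pair on a coarse (<= 48^3) grid; independent oracle uses
        # brute-force nearest-occupied distances and a 0.05 mm margin sweep
        from agree3d.synthetic import UterusShapeParams, generate_true_shape

        small = generate_true_shape(
            UterusShapeParams(body_length=60, fundal_width=32,
                              cervix_length=20, cervix_radius=9, seed=2)
        )
        a = perturb_contour(small, ObserverModel(sigma_obs=3.0, seed=1))
        b = perturb_contour(small, ObserverModel(sigma_obs=3.0, seed=2))
        spacing = 2.5
        origin, shape = shared_grid([a, b], spacing, pad=6.0)
        assert max(shape) <= 48
        ma = voxelize(a, spacing, origin=origin, shape=shape)
        mb = voxelize(b, spacing, origin=origin, shape=shape)
        ia = np.argwhere(ma.occupancy) * spacing
        ib = np.argwhere(mb.occupancy) * spacing
        nn = cdist(ib, ia).min(axis=1)
        step = 0.05
        margins = np.arange(0.0, nn.max() + step, step)
        cov = [(nn <= m + 1e-9).mean() for m in margins]
        oracle = margins[int(np.argmax(np.asarray(cov) >= 0.95))]
        got = um95(a, b, spacing=spacing, pad=6.0)
        assert got == pytest.approx(oracle, abs=step + 1e-9)

    def test_coverage_certificate(self, uterus):
        from agree3d.geometry import expand_uniform

        a = perturb_contour(uterus, ObserverModel(sigma_obs=4.0, seed=5))
        b = perturb_contour(uterus, ObserverModel(sigma_obs=4.0, seed=6))
        spacing = 1.5
        origin, shape = shared_grid([a, b], spacing, pad=10.0)
        ma = voxelize(a, spacing, origin=origin, shape=shape)
        mb = voxelize(b, spacing, origin=origin, shape=shape)
        m = um95(a, b, spacing=spacing, pad=10.0)
        nb = mb.occupancy.sum()
        cov = (expand_uniform(ma, m).occupancy & mb.occupancy).sum() / nb
        assert cov >= 0.95
        if m > 2 * spacing:
            cov_lo = (expand_uniform(ma, m - 2 * spacing).occupancy
                      & mb.occupancy).sum() / nb
            assert cov_lo < 0.95

    def test_empty_target(self, sphere10):
        from agree3d.metrics import mask_um
        from agree3d.geometry import VoxelMask

        ma = voxelize(sphere10, 1.0)
        empty = VoxelMask(ma.origin, ma.spacing, np.zeros(ma.shape, bool))
        with pytest.raises(DegenerateResolutionError):
            mask_um(ma, empty)


class TestRigidMotion:
    def test_all_metrics_invariant(self, uterus):
        a = perturb_contour(uterus, ObserverModel(sigma_obs=2.0, seed=7))
        b = perturb_contour(uterus, ObserverModel(sigma_obs=2.0, seed=8))
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        t = np.array([12.0, -8.0, 20.0])
        a2, b2 = a.transformed(R, t), b.transformed(R, t)
        sp = 1.2
        assert dc(a2, b2) == pytest.approx(dc(a, b), abs=1e-8)
        assert mssd(a2, b2) == pytest.approx(mssd(a, b), abs=1e-8)
        assert dsc(a2, b2, sp) == pytest.approx(dsc(a, b, sp), abs=0.02)
        assert um95(a2, b2, spacing=sp) == pytest.approx(
            um95(a, b, spacing=sp), abs=sp
        )


class TestDeviationMap:
    def test_copy_gives_zeros(self, sphere10):
        assert np.all(deviation_map(sphere10, [sphere10]) == 0)

    def test_rigid_shift_bound(self, uterus):
        d = deviation_map(uterus, [uterus.translated([2, 0, 0])])
        assert np.all(d <= 2.0 + 1e-9)
        assert d.max() == pytest.approx(2.0, abs=0.3)

    def test_max_of_singles(self, uterus):
        o1 = uterus.translated([1.5, 0, 0])
        o2 = uterus.translated([0, 0, -2.5])
        combined = deviation_map(uterus, [o1, o2])
        singles = np.maximum(deviation_map(uterus, [o1]), deviation_map(uterus, [o2]))
        assert combined == pytest.approx(singles, abs=0)

    def test_empty_others(self, sphere10):
        with pytest.raises(ValueError):
            deviation_map(sphere10, [])


class TestAgreementRecord:
    def test_validation(self):
        kw = dict(image_id="i", source_label="a", target_label="b",
                  comparison_kind="manual_vs_manual", spacing_mm=1.0)
        AgreementRecord(dc_mm=1, dsc=0.5, mssd_mm=1, um95_mm=1, **kw)
        with pytest.raises(ValueError):
            AgreementRecord(dc_mm=1, dsc=1.5, mssd_mm=1, um95_mm=1, **kw)
        with pytest.raises(ValueError):
            AgreementRecord(dc_mm=-1, dsc=0.5, mssd_mm=1, um95_mm=1, **kw)
        with pytest.raises(ValueError):
            AgreementRecord(dc_mm=np.nan, dsc=0.5, mssd_mm=1, um95_mm=1, **kw)

    def test_evaluator_swap_symmetry(self, uterus):
        a = perturb_contour(uterus, ObserverModel(sigma_obs=2.0, seed=1))
        b = perturb_contour(uterus, ObserverModel(sigma_obs=2.0, seed=2))
        ev = PairwiseEvaluator({"a": a, "b": b}, spacing=1.5)
        r1 = ev.record("a", "b", "manual_vs_manual")
        r2 = ev.record("b", "a", "manual_vs_manual")
        assert r1.dc_mm == r2.dc_mm
        assert r1.dsc == r2.dsc  # symmetric under swap
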