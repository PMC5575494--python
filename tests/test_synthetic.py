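import numpy as np
import pytest

from agree3d.errors import ValidationError
from agree3d.geometry import enclosed_volume
from agree3d.metrics import dsc, mssd, um95
from agree3d.pipeline import evaluate_cohort, failure_report
from agree3d.synthetic import (
    AGSErrorModel,
    CohortConfig,
    ObserverModel,
    UterusShapeParams,
    build_cohort,
    calibrate_sigma,
    generate_true_shape,
    perturb_contour,
    random_shape_params,
    simulate_ags,
)


class TestTrueShape:
    def test_deterministic(self):
        p = UterusShapeParams(seed=9)
        a = generate_true_shape(p)
        b = generate_true_shape(p)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_anteversion_preserves_volume(self):
        v0 = enclosed_volume(generate_true_shape(UterusShapeParams(anteversion_deg=0)))
        v45 = enclosed_volume(generate_true_shape(UterusShapeParams(anteversion_deg=45)))
        assert v45 == pytest.approx(v0, rel=0.01)

    def test_volume_in_organ_range(self):
        rng = np.random.default_rng(123)
        for k in range(60):
            p = random_shape_params(rng, seed=k)
            vol = enclosed_volume(generate_true_shape(p)) / 1000.0  # cm^3
            assert 30.0 <= vol <= 300.0

    def test_watertight(self, uterus):
        uterus.validate()

    def test_bad_params(self):
        with pytest.raises(ValidationError):
            generate_true_shape(UterusShapeParams(body_length=-1))


class TestPerturbation:
    def test_zero_sigma_identity(self, uterus):
        out = perturb_contour(uterus, ObserverModel(sigma_obs=0.0))
        assert np.array_equal(out.vertices, uterus.vertices)
        assert mssd(uterus, out) == 0.0

    def test_deterministic_given_seed(self, uterus):
        m = ObserverModel(sigma_obs=2.0, seed=4)
        a = perturb_contour(uterus, m)
        b = perturb_contour(uterus, m)
        assert np.array_equal(a.vertices, b.vertices)

    def test_output_watertight(self, uterus):
        out = perturb_contour(uterus, ObserverModel(sigma_obs=3.0, seed=2))
        out._checked = False
        out.validate()

    def test_mssd_monotone_in_sigma(self, uterus):
        means = []
        for sigma in (1.0, 3.0, 6.0):
            model = ObserverModel(sigma_obs=sigma)
            vals = [
                mssd(
                    perturb_contour(uterus, model, rng=np.random.default_rng(2 * k)),
                    perturb_contour(uterus, model, rng=np.random.default_rng(2 * k + 1)),
                )
                for k in range(8)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_cohort_metric_monotonicity(self):
        """Median DSC falls and MSSD/UM95 rise strictly with sigma."""
        meds = []
        for sigma in (1.0, 3.0, 6.0):
            cfg = CohortConfig(
                rating_counts={2: 3}, n_excluded=0,
                observer=ObserverModel(sigma_obs=sigma),
                ags=AGSErrorModel(failure_prob={1: 1.0, 2: 1.0, 3: 0.0},
                                  corruption_mm={1: 0, 2: 0, 3: 0},
                                  extrusion_rate={1: 0, 2: 0, 3: 0}),
            )
            # rating-3 absent so every ags attempt fails fast (manual only)
            df = evaluate_cohort(build_cohort(cfg, master_seed=21), spacing=2.0)
            meds.append(df[["dsc", "mssd_mm", "um95_mm"]].median())
        assert meds[0].dsc > meds[1].dsc > meds[2].dsc
        assert meds[0].mssd_mm < meds[1].mssd_mm < meds[2].mssd_mm
        assert meds[0].um95_mm < meds[1].um95_mm < meds[2].um95_mm


class TestSimulateAGS:
    def test_always_fails(self, uterus):
        model = AGSErrorModel(failure_prob={1: 1.0, 2: 1.0, 3: 0.0})
        for s in range(10):
            assert simulate_ags(uterus, 1, model,
                                rng=np.random.default_rng(s)) is None

    def test_rating3_never_fails_by_default(self, uterus):
        model = AGSErrorModel()
        for s in range(20):
            out = simulate_ags(uterus, 3, model, rng=np.random.default_rng(s))
            assert out is not None
            assert out.method == "ags"

    def test_rating3_nonzero_failure_rejected(self):
        with pytest.raises(ValidationError):
            AGSErrorModel(failure_prob={1: 0.5, 2: 0.2, 3: 0.1}).validate()

    def test_invalid_rating(self, uterus):
        with pytest.raises(ValidationError):
            simulate_ags(uterus, 0, AGSErrorModel())

    def test_expected_failure_rate_near_19pct(self):
        cfg = CohortConfig()
        expected = sum(
            cnt * cfg.ags.failure_prob[r] for r, cnt in cfg.rating_counts.items()
        ) / cfg.n_images
        assert expected * 100 == pytest.approx(19.3, abs=1.5)


class TestCohort:
    def test_default_study_counts(self):
        cfg = CohortConfig()
        assert cfg.n_images == 35
        assert cfg.rating_counts == {1: 6, 2: 18, 3: 11}

    def test_mini_structure(self, mini_cohort):
        assert len(mini_cohort.images) == 5
        assert len(mini_cohort.excluded) == 1
        for img in mini_cohort.images:
            assert len(img.manual) == 4
            assert len(img.ags) == 4
            assert img.final_rating in (1, 2, 3)
            s1, s2 = img.session_ratings
            assert 0 not in (s1, s2)
            assert int(np.floor((s1 + s2) / 2 + 0.5)) == img.final_rating
        for _, sessions in mini_cohort.excluded:
            assert 0 in sessions

    def test_single_image_two_observers(self):
        cfg = CohortConfig(rating_counts={3: 1}, n_excluded=0, n_observers=2)
        co = build_cohort(cfg, master_seed=1)
        img = co.images[0]
        assert len(img.manual) == 2
        from agree3d.pipeline import enumerate_ags_pairs, enumerate_manual_pairs

        assert len(enumerate_manual_pairs(img.manual)) == 2
        ok = [o for o, c in img.ags.items() if c is not None]
        assert len(enumerate_ags_pairs(ok, img.manual)) <= 4

    def test_reproducible(self):
        cfg = CohortConfig(rating_counts={2: 2}, n_excluded=1)
        a = build_cohort(cfg, master_seed=77)
        b = build_cohort(cfg, master_seed=77)
        assert a.excluded == b.excluded
        for ia, ib in zip(a.images, b.images):
            assert ia.image_id == ib.image_id
            assert ia.session_ratings == ib.session_ratings
            assert np.array_equal(ia.true_shape.vertices, ib.true_shape.vertices)
            for obs in ia.manual:
                assert np.array_equal(ia.manual[obs].vertices,
                                      ib.manual[obs].vertices)

    def test_failure_ledger_integration(self, mini_cohort):
        led = failure_report(mini_cohort)
        assert led.n_attempts == 20


class TestCalibration:
    def test_monotone_curve(self):
        s1 = calibrate_sigma(1.5, seed=3)
        s2 = calibrate_sigma(4.0, seed=3)
        assert 0 < s1 < s2

    def test_target_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_sigma(-1.0)

    def test_recovery_single_level(self):
        target = 3.2
        sigma = calibrate_sigma(target, seed=0)
        model = ObserverModel(sigma_obs=sigma)
        rng_base = 900
        vals = []
        for s in range(12):
            true = generate_true_shape(
                random_shape_params(np.random.default_rng(s), seed=s)
            )
            a = perturb_contour(true, model, rng=np.random.default_rng(rng_base + 2 * s))
            b = perturb_contour(true, model, rng=np.random.default_rng(rng_base + 2 * s + 1))
            vals.append(mssd(a, b))
        assert np.median(vals) == pytest.approx(target, rel=0.25)
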