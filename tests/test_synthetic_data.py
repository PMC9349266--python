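"""Generator ground truth and parameter recovery."""

import numpy as np
import pytest

from captrans.capsule_quant import capsule_thickness, coherency
from captrans.itt_analysis import auc_bg, compute_metrics, max_drop
from captrans.synthetic_data import (
    BGGeneratorParams,
    FiberFieldParams,
    effect_from_release,
    gen_bg_curves,
    gen_capsule_mask,
    gen_fiber_image,
    gen_point_mask,
    gen_thickness_efficacy_pairs,
    k_insulin_for_drop,
    parametric_effect,
)


class TestBGCurves:
    def test_no_insulin_effect_flat_at_baseline(self):
        p = BGGeneratorParams(k_insulin=0.0, noise_sd=0.0, animal_sigma=0.0,
                              n_animals=2, seed=0)
        cohort = gen_bg_curves(p)
        for s in cohort.series:
            assert np.allclose(s.glucose, p.baseline_mgdl)
            assert max_drop(s) == 0.0

    def test_seed_determinism(self):
        p = BGGeneratorParams(seed=42)
        a, b = gen_bg_curves(p), gen_bg_curves(p)
        for sa, sb in zip(a.series, b.series):
            assert np.array_equal(sa.glucose, sb.glucose)
        assert a.meta["seed"] == 42

    def test_programmed_steady_drop_recovered(self):
        # constant effect sized for a 40% steady drop; fast recovery rate so
        # the ODE settles well inside the 120 min window
        k_r = 0.1
        k_i = k_insulin_for_drop(0.4, effect_level=1.0, k_recovery=k_r)
        p = BGGeneratorParams(
            k_insulin=k_i, k_recovery=k_r,
            effect=lambda t: np.ones_like(np.asarray(t, float)),
            noise_sd=0.0, animal_sigma=0.0, n_animals=1, seed=0,
        )
        cohort = gen_bg_curves(p)
        assert max_drop(cohort.series[0]) == pytest.approx(40.0, abs=0.4)

    def test_lag_delays_response(self):
        base = dict(noise_sd=0.0, animal_sigma=0.0, n_animals=1, seed=0)
        fast = gen_bg_curves(BGGeneratorParams(effect=parametric_effect(1.0, 0.0), **base))
        slow = gen_bg_curves(BGGeneratorParams(effect=parametric_effect(1.0, 45.0), **base))
        m_fast = compute_metrics(fast.series[0])
        m_slow = compute_metrics(slow.series[0])
        assert m_slow.time_to_drop > m_fast.time_to_drop
        assert m_slow.auc > m_fast.auc


class TestFiberImages:
    def test_parallel_fibers_highly_coherent(self):
        fi = gen_fiber_image(FiberFieldParams(kappa=100.0, seed=7))
        assert coherency(fi.image).coherency >= 0.8

    def test_isotropic_fibers_low_coherency(self):
        fi = gen_fiber_image(FiberFieldParams(kappa=0.0, n_fibers=200, seed=7))
        assert coherency(fi.image).coherency <= 0.2

    def test_coherency_monotone_in_kappa(self):
        vals = [
            coherency(gen_fiber_image(FiberFieldParams(kappa=k, seed=7)).image).coherency
            for k in (0.0, 1.0, 3.0, 10.0, 100.0)
        ]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_seed_determinism(self):
        a = gen_fiber_image(FiberFieldParams(seed=9))
        b = gen_fiber_image(FiberFieldParams(seed=9))
        assert np.array_equal(a.image, b.image)


class TestCapsuleMasks:
    def test_constant_profile_recovered(self):
        cm = gen_capsule_mask(100.0, pixel_size=2.0)
        res = capsule_thickness(cm.mask, 2.0)
        assert res.mean_um == pytest.approx(100.0, abs=2.0)

    def test_linear_profile_correlates(self):
        prof = np.linspace(50, 200, 512)
        cm = gen_capsule_mask(prof, pixel_size=2.0, image_size=(256, 512))
        res = capsule_thickness(cm.mask, 2.0)
        cols = res.midline[:, 1]
        r = np.corrcoef(prof[cols], res.per_location_um)[0, 1]
        assert r > 0.95

    def test_waviness_preserves_mean_thickness(self):
        flat = gen_capsule_mask(100.0, 2.0, waviness=0.0, seed=3)
        wavy = gen_capsule_mask(100.0, 2.0, waviness=20.0, seed=3)
        t_flat = capsule_thickness(flat.mask, 2.0).mean_um
        t_wavy = capsule_thickness(wavy.mask, 2.0).mean_um
        assert abs(t_wavy - t_flat) / t_flat <= 0.02

    def test_band_must_fit(self):
        with pytest.raises(ValueError):
            gen_capsule_mask(10000.0, 2.0, image_size=(64, 128))


class TestPointMasks:
    def test_empty_and_full(self):
        assert not gen_point_mask(0.0, 64).mask.any()
        assert gen_point_mask(1.0, 64).mask.all()

    def test_target_fraction_hit(self):
        pm = gen_point_mask(0.25, image_size=512, seed=5)
        assert 0.245 <= pm.true_fraction_actual <= 0.255
        assert pm.mask.mean() == pytest.approx(pm.true_fraction_actual)

    def test_seed_determinism(self):
        a = gen_point_mask(0.3, 128, seed=2)
        b = gen_point_mask(0.3, 128, seed=2)
        assert np.array_equal(a.mask, b.mask)


class TestThicknessEfficacyPairs:
    def test_programmed_correlation(self):
        th, dr, meta = gen_thickness_efficacy_pairs(r=-0.9, n=200, seed=11)
        assert np.corrcoef(th, dr)[0, 1] == pytest.approx(-0.9, abs=0.05)
        assert meta["n"] == 200


class TestEndToEndOrderings:
    def test_thick_capsule_blunts_and_delays_response(self, desk_passive):
        """Thicker capsule -> smaller max drop, later time to effect, larger AUC."""
        ref = desk_passive[50].outside_fc_amount[-1]
        metrics = {}
        for th in (50, 200):
            eff = effect_from_release(desk_passive[th], scale=1.0, reference_amount=ref)
            cohort = gen_bg_curves(
                BGGeneratorParams(effect=eff, noise_sd=0.0, animal_sigma=0.0,
                                  n_animals=1, seed=1)
            )
            metrics[th] = compute_metrics(cohort.series[0])
        assert metrics[200].max_drop_pct < metrics[50].max_drop_pct
        assert metrics[200].time_to_drop > metrics[50].time_to_drop
        assert metrics[200].auc > metrics[50].auc
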