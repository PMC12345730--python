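"""Phantom generator: Z-spectrum synthesis, calibration, DWI decay, studies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cestdwi import cest
from cestdwi.phantom import (
    AcquisitionGeometry,
    CESTPool,
    InvalidPoolConfigurationError,
    PhantomSpec,
    SaturationSchedule,
    build_study,
    calibrate_pool_amplitude,
    default_cells,
    mt_pool,
    sample_compartment_pixels,
    synthesize_dwi,
    synthesize_zspectrum,
    water_pool,
)


class TestZSpectrumSynthesis:
    def test_symmetric_pools_give_symmetric_spectrum(self, schedule):
        z = synthesize_zspectrum([CESTPool(0.0, 0.9, 1.4)], schedule)
        assert np.max(np.abs(z - z[::-1])) == 0.0

    def test_single_solute_pool_hand_values(self, schedule):
        amp = 0.0601381
        z = synthesize_zspectrum([CESTPool(1.8, amp, 1.0)], schedule)
        i_pos = np.argmin(np.abs(schedule.offsets_ppm - 1.8))
        i_neg = np.argmin(np.abs(schedule.offsets_ppm + 1.8))
        assert z[i_pos] == pytest.approx(1 - amp, abs=1e-12)
        assert z[i_neg] == pytest.approx(1 - amp * 0.25 / 13.21, abs=1e-9)

    def test_b0_shift_is_a_translation(self, schedule):
        pools = [water_pool(), CESTPool(1.8, 0.05, 1.0)]
        shifted = synthesize_zspectrum(pools, schedule, b0_shift_ppm=0.3)
        moved = SaturationSchedule(offsets_ppm=schedule.offsets_ppm)  # same grid
        ref = synthesize_zspectrum(pools, moved, b0_shift_ppm=0.0)
        # grid step is exactly 0.3, so a +0.3 shift is an index shift
        assert shifted[1:] == pytest.approx(ref[:-1], abs=1e-12)

    def test_negative_z_raises_naming_offset(self, schedule):
        with pytest.raises(InvalidPoolConfigurationError, match="ppm"):
            synthesize_zspectrum(
                [CESTPool(0.0, 0.9, 1.4), CESTPool(0.0, 0.5, 2.0)], schedule)

    def test_values_within_unit_interval(self, schedule):
        z = synthesize_zspectrum(
            [water_pool(), mt_pool(), CESTPool(1.8, 0.06, 1.0)], schedule)
        assert np.all((z >= 0) & (z <= 1))


class TestCalibration:
    @pytest.mark.parametrize("target,delta,fwhm,expected", [
        (5.9, 1.8, 1.0, 0.0601381),
        (4.3, 1.8, 1.0, 0.0438295),
    ])
    def test_closed_form_amplitudes(self, target, delta, fwhm, expected):
        assert calibrate_pool_amplitude(target, delta, fwhm) == pytest.approx(
            expected, abs=5e-7)

    def test_narrow_line_limit_is_target(self):
        assert calibrate_pool_amplitude(5.0, 1.8, 1e-9) == pytest.approx(
            0.05, rel=1e-9)

    def test_zero_offset_rejected(self):
        with pytest.raises(ValueError):
            calibrate_pool_amplitude(5.0, 0.0, 1.0)

    @given(target=st.floats(0.5, 20.0), delta=st.floats(0.5, 4.5),
           fwhm=st.floats(0.2, 3.0))
    @settings(max_examples=40, derandomize=True)
    def test_round_trip_through_asymmetry(self, target, delta, fwhm):
        """calibrate -> synthesize -> asymmetry returns the target exactly."""
        amp = calibrate_pool_amplitude(target, delta, fwhm)
        offsets = np.round(np.linspace(-2 * delta, 2 * delta, 41), 12)
        offsets[20] = 0.0
        sched = SaturationSchedule(offsets_ppm=offsets)
        z = synthesize_zspectrum([CESTPool(delta, amp, fwhm)], sched)
        got = cest.mtr_asym((offsets, z), delta)
        assert got == pytest.approx(target, abs=1e-10)


class TestDWISynthesis:
    def test_noiseless_decay_hand_values(self):
        s = synthesize_dwi(0.7e-3, 1.0, (0, 1000, 2000))
        assert s == pytest.approx([1.0, 0.496585, 0.246597], abs=1e-6)

    def test_vanishing_adc_gives_constant(self):
        s = synthesize_dwi(1e-12, 2.5, (0, 1000, 2000))
        assert s == pytest.approx([2.5, 2.5, 2.5], rel=1e-8)

    def test_seeded_noise_is_reproducible(self):
        a = synthesize_dwi(0.7e-3, 1.0, (0, 1000, 2000), noise_sd=0.05, rng=3)
        b = synthesize_dwi(0.7e-3, 1.0, (0, 1000, 2000), noise_sd=0.05, rng=3)
        assert np.array_equal(a, b)

    def test_b_table_must_start_at_zero(self):
        with pytest.raises(ValueError):
            synthesize_dwi(0.7e-3, 1.0, (500, 1000))


class TestCompartmentSampling:
    def test_negative_coupling_yields_negative_sample_correlation(self, rng):
        adc, mtr = sample_compartment_pixels(
            500, 0.7e-3, 5.0, 0.1e-3, 2.0, rho=-0.8, rng=rng)
        r = np.corrcoef(adc, mtr)[0, 1]
        assert r < -0.6

    def test_marginals_near_requested(self, rng):
        adc, mtr = sample_compartment_pixels(
            4000, 0.7e-3, 5.0, 0.05e-3, 1.0, rho=0.0, rng=rng)
        assert adc.mean() == pytest.approx(0.7e-3, rel=0.01)
        assert mtr.std(ddof=1) == pytest.approx(1.0, rel=0.1)


class TestGeometryTypes:
    def test_grid_divisibility_enforced(self):
        with pytest.raises(ValueError):
            AcquisitionGeometry(t2_matrix=250, cest_dwi_matrix=128)

    def test_schedule_must_be_symmetric(self):
        with pytest.raises(ValueError):
            SaturationSchedule(offsets_ppm=np.array([-1.0, 0.0, 2.0]))

    def test_default_schedule_shape(self, schedule):
        off = schedule.offsets_ppm
        assert off.size == 33
        assert off[0] == pytest.approx(-4.8)
        assert off[-1] == pytest.approx(4.8)
        assert np.allclose(np.diff(off), 0.3)

    def test_control_volumes_must_increase(self):
        cells = default_cells()
        bad = cells[("control", 17)]
        cells[("control", 17)] = type(bad)(**{
            **bad.__dict__, "volume_mm3": 10.0})
        with pytest.raises(ValueError, match="increase"):
            PhantomSpec(cells=cells).validate()


@pytest.fixture(scope="module")
def tiny_study(tmp_path_factory):
    spec = PhantomSpec(
        n_animals_per_group=1, groups=("control",), days=(10,),
        cest_noise_sd=0.0, dwi_noise_sd=0.0, t2_noise_sd=0.0,
        b0_range_ppm=0.0, seed=11,
    )
    out = tmp_path_factory.mktemp("tiny")
    return spec, build_study(spec, out), out


class TestBuildStudy:
    def test_noiseless_adc_recovery_matches_truth(self, tiny_study):
        from cestdwi.dwi import DWISeries, adc_map
        from cestdwi.ioutils import load_nifti, read_json

        spec, truth, out = tiny_study
        rec = truth.manifest.iloc[0]
        t = truth.records[(rec.group, rec.day, rec.animal)]
        sig = load_nifti(rec.dwi)[:, :, 0, :]
        bv = np.asarray(read_json(rec.dwi_sidecar)["bvalues_s_per_mm2"])
        tumor = t.label_map >= 2
        amap = adc_map(DWISeries(b_values=bv, signals=sig), tumor)
        assert amap.adc[tumor] == pytest.approx(t.adc_map[tumor], rel=1e-9)

    def test_same_seed_rebuild_is_identical(self, tiny_study, tmp_path):
        spec, truth, _ = tiny_study
        truth2 = build_study(spec, tmp_path / "again")
        k = next(iter(truth.records))
        assert np.array_equal(truth.records[k].adc_map,
                              truth2.records[k].adc_map, equal_nan=True)
        assert np.array_equal(truth.records[k].mtr_map,
                              truth2.records[k].mtr_map, equal_nan=True)

    def test_changing_seed_preserves_compartment_means(self, tmp_path):
        """Ground-truth tumor means move by < 3 standard errors across seeds."""
        base = dict(n_animals_per_group=1, groups=("control",), days=(10,),
                    b0_range_ppm=0.0)
        cells = default_cells()
        mu = cells[("control", 10)].adc_mean
        sd = cells[("control", 10)].adc_sd_pixel
        sd_an = cells[("control", 10)].adc_sd_animal
        for seed in (1, 2):
            truth = build_study(PhantomSpec(seed=seed, **base),
                                tmp_path / f"s{seed}")
            t = next(iter(truth.records.values()))
            tumor = t.label_map >= 2
            vals = t.adc_map[tumor]
            se = np.sqrt(sd_an**2 + sd**2 / vals.size)
            assert abs(vals.mean() - mu) < 3 * se

    def test_ground_truth_volume_consistent_with_mask(self, tiny_study):
        from cestdwi.ioutils import load_nifti

        spec, truth, _ = tiny_study
        rec = truth.manifest.iloc[0]
        mask = load_nifti(rec.mask_t2)
        g = spec.geometry
        expected = mask.sum() * g.t2_pixel_mm**2 * g.slice_thickness_mm
        assert rec.true_volume_mm3 == pytest.approx(expected, abs=1e-9)

    def test_negative_coupling_visible_in_truth_table(self, tmp_path):
        spec = PhantomSpec(n_animals_per_group=1, groups=("control",),
                           days=(10,), seed=5)
        truth = build_study(spec, tmp_path / "corr")
        t = next(iter(truth.records.values()))
        tumor = t.label_map >= 2
        r = np.corrcoef(t.adc_map[tumor], t.mtr_map[tumor])[0, 1]
        assert r < -0.4
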