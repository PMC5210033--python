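"""Phantom generator: signal model, noise model, seeds, rosters, reader tables."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import adrenadc as ad
from adrenadc.cohort import CLINICAL_FLAGS


class TestPhantomSignal:
    def test_gland_signal_follows_closed_form_decay(self, noiseless_phantom):
        spec, series, truth = noiseless_phantom
        mask = truth.true_masks["right"].mask
        for i, b in enumerate(series.b_values):
            expected = spec.gland_s0 * np.exp(-b * spec.gland_true_adc["right"])
            np.testing.assert_allclose(series.signal[..., i][mask], expected, rtol=1e-12)
        # spot value: S0=1000, ADC=1.44e-3, b=1000 -> 1000 * e^-1.44
        assert series.signal[..., 3][mask][0] == pytest.approx(1000 * np.exp(-1.44), rel=1e-12)

    def test_b0_signal_is_s0_everywhere(self, noiseless_phantom):
        spec, series, truth = noiseless_phantom
        assert np.all(series.signal[..., 0][truth.true_masks["left"].mask] == spec.gland_s0)

    def test_log_signal_linear_in_b_for_every_voxel_and_pair(self, noiseless_phantom):
        _, series, truth = noiseless_phantom
        adc = truth.true_adc_map.adc
        ls = np.log(series.signal)
        b = series.b_values
        for i in range(len(b)):
            for j in range(i + 1, len(b)):
                np.testing.assert_allclose(ls[..., i] - ls[..., j], adc * (b[j] - b[i]), atol=1e-10)

    def test_same_seed_gives_bit_identical_volumes(self):
        spec = ad.PhantomSpec(rician_sigma=25.0, rng_seed=42)
        s1, _ = ad.generate_phantom(spec)
        s2, _ = ad.generate_phantom(spec)
        assert np.array_equal(s1.signal, s2.signal)

    def test_rician_noise_biases_mean_signal_upward(self):
        """Magnitude noise is non-negative in expectation: the sample mean
        over many identically distributed voxels exceeds the clean value."""
        sigma = 30.0
        clean_s, _ = ad.generate_phantom(ad.PhantomSpec(rician_sigma=0.0))
        noisy_s, noisy_t = ad.generate_phantom(ad.PhantomSpec(rician_sigma=sigma, rng_seed=3))
        structures = noisy_t.true_masks["right"].mask | noisy_t.true_masks["left"].mask
        fat = ~structures & (clean_s.signal[..., 3] == clean_s.signal[..., 3].min())
        assert fat.sum() > 10_000
        assert noisy_s.signal[..., 3][fat].mean() > clean_s.signal[..., 3][fat].mean()

    def test_gland_spans_multiple_slices_and_is_hyperintense_at_b500(self, noiseless_phantom):
        spec, series, truth = noiseless_phantom
        vol = series.volume_at(500.0)
        for side, rm in truth.true_masks.items():
            slices = np.unique(np.argwhere(rm.mask)[:, spec.slice_axis])
            assert len(slices) >= 2
            background = ~(truth.true_masks["right"].mask | truth.true_masks["left"].mask)
            assert vol[rm.mask].min() > np.median(vol[background])

    def test_seeds_lie_inside_truth_and_cover_every_gland_slice(self, noiseless_phantom):
        spec, _, truth = noiseless_phantom
        for side, seeds in truth.seeds.items():
            mask = truth.true_masks[side].mask
            gland_slices = set(np.unique(np.argwhere(mask)[:, spec.slice_axis]).tolist())
            assert {s.slice_index for s in seeds} == gland_slices
            for s in seeds:
                assert mask[s.interior_ref]
                assert not mask[s.exterior_ref]

    def test_true_adc_map_equals_configured_adc_on_masks(self, noiseless_phantom):
        spec, _, truth = noiseless_phantom
        for side, rm in truth.true_masks.items():
            assert np.all(truth.true_adc_map.adc[rm.mask] == spec.gland_true_adc[side])

    @pytest.mark.parametrize(
        "field,value",
        [
            ("grid_dims", (4, 64, 16)),
            ("b_values", (20.0, 500.0)),
            ("b_values", (0.0, 500.0, 500.0)),
            ("rician_sigma", -1.0),
            ("gland_true_adc", {"right": -1e-3}),
        ],
    )
    def test_invalid_spec_raises_naming_the_field(self, field, value):
        with pytest.raises(ad.ValidationError) as err:
            ad.PhantomSpec(**{field: value})
        assert field.split("_")[0] in str(err.value)


class TestCohortRoster:
    def test_printed_counts_roster_has_exact_flag_totals(self):
        roster = ad.generate_cohort_roster(ad.RosterSpec())
        assert len(roster) == 1330
        assert sum(r.abnormal_imaging for r in roster) == 1273
        assert sum(r.hormonal_disturbance for r in roster) == 5
        assert sum(r.neoplasia_history for r in roster) == 5
        assert sum(r.ibd_suspicion for r in roster) == 3
        assert sum(r.storage_disease_suspicion for r in roster) == 4
        assert sum(r.high_bmi_for_age for r in roster) == 7
        assert sum(r.missing_radiologic_data for r in roster) == 1
        assert sum(not r.has_any_flag for r in roster) == 32

    def test_no_exclusions_gives_unflagged_roster(self):
        rspec = ad.RosterSpec(
            n_total=10, n_abnormal_imaging=0,
            clinical_exclusion_counts={}, n_missing_radiologic=0,
            n_prepubertal=4,
        )
        roster = ad.generate_cohort_roster(rspec)
        assert len(roster) == 10
        assert all(not r.has_any_flag for r in roster)

    def test_counts_exceeding_total_rejected(self):
        with pytest.raises(ad.ValidationError):
            ad.RosterSpec(n_total=10, n_abnormal_imaging=8,
                          clinical_exclusion_counts={"hormonal_disturbance": 3},
                          n_missing_radiologic=0, n_prepubertal=0)

    @given(
        n_img=st.integers(0, 20),
        clin=st.lists(st.integers(0, 5), min_size=5, max_size=5),
        n_miss=st.integers(0, 3),
        extra=st.integers(0, 30),
        seed=st.integers(0, 2**16),
    )
    def test_flag_totals_always_match_spec_exactly(self, n_img, clin, n_miss, extra, seed):
        counts = dict(zip(CLINICAL_FLAGS, clin))
        n_total = n_img + sum(clin) + n_miss + extra
        if n_total == 0:
            return
        rspec = ad.RosterSpec(
            n_total=n_total, n_abnormal_imaging=n_img,
            clinical_exclusion_counts=counts, n_missing_radiologic=n_miss,
            n_prepubertal=min(2, extra), rng_seed=seed,
        )
        roster = ad.generate_cohort_roster(rspec)
        assert len(roster) == n_total
        assert sum(r.abnormal_imaging for r in roster) == n_img
        for flag, c in counts.items():
            assert sum(getattr(r, flag) for r in roster) == c
        assert sum(r.missing_radiologic_data for r in roster) == n_miss

    def test_survivor_groups_match_spec_split(self):
        roster = ad.generate_cohort_roster(ad.RosterSpec(rng_seed=5))
        eligible, _ = ad.apply_exclusion_cascade(roster)
        groups = [ad.assign_group(r) for r in eligible]
        assert groups.count("PreP") == 12
        assert groups.count("PostP") == 20


class TestReaderMeasurements:
    def test_zero_noise_zero_bias_reproduces_truth(self):
        truth = {"a": 1.4e-3, "b": 1.2e-3}
        ms = ad.generate_reader_measurements(truth, [0.0, 0.0], 0.0, n_readers=2)
        for m in ms:
            assert m.mean_adc == truth[m.subject_id]

    def test_constant_reader_bias_shifts_every_measurement(self):
        truth = [1.4e-3, 1.2e-3, 1.6e-3]
        ms = ad.generate_reader_measurements(truth, [0.0, 1e-4], 0.0, n_readers=2)
        r1 = {m.subject_id: m.mean_adc for m in ms if m.reader_id == "reader1"}
        r2 = {m.subject_id: m.mean_adc for m in ms if m.reader_id == "reader2"}
        for sid in r1:
            assert r2[sid] - r1[sid] == pytest.approx(1e-4, abs=1e-18)

    def test_fixed_seed_reproducible(self):
        kw = dict(true_values=[1.4, 1.5], reader_bias=[0.0], noise_sd=0.1, seed=9)
        a = ad.generate_reader_measurements(**kw)
        b = ad.generate_reader_measurements(**kw)
        assert [m.mean_adc for m in a] == [m.mean_adc for m in b]

    def test_empty_truth_rejected(self):
        with pytest.raises(ad.ValidationError):
            ad.generate_reader_measurements([], [0.0], 0.1)
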