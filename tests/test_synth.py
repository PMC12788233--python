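"""Synthetic 12-lead generator: beat model, lead identities, ground truth."""

import numpy as np
import pytest

import leadrecon as lr
from leadrecon.synth import (BeatMorphology, ParameterError, SubjectParams,
                             Wave, estimate_qrs_axis, stratified_param_sampler)
from leadrecon.preprocess import discretize_metadata


def gaussian_sum_oracle(morph, fs):
    """Closed-form evaluation of the five-bump beat on the same grid."""
    waves = morph.waves()
    lo = min(w.center_ms - 3 * w.width_ms for w in waves.values())
    hi = max(w.center_ms + 3 * w.width_ms for w in waves.values())
    t = np.arange(np.floor(lo * fs / 1000), np.ceil(hi * fs / 1000) + 1) * 1000 / fs
    return sum(w.amp_mv * np.exp(-0.5 * ((t - w.center_ms) / w.width_ms) ** 2)
               for w in waves.values())


class TestGenerateBeat:
    def test_zero_amplitudes_give_zero_waveform(self):
        morph = BeatMorphology(p=Wave(-180, 0, 22), q=Wave(-20, 0, 10),
                               r=Wave(0, 1e-30, 10), s=Wave(20, 0, 10),
                               t=Wave(320, 0, 55))
        beat = lr.generate_beat(morph, fs=500)
        assert np.allclose(beat, 0.0, atol=1e-29)

    def test_single_r_bump_peaks_at_center(self):
        morph = BeatMorphology(p=Wave(-180, 0, 22), q=Wave(-20, 0, 10),
                               r=Wave(0, 1.0, 10), s=Wave(20, 0, 10),
                               t=Wave(320, 0, 55))
        beat = lr.generate_beat(morph, fs=500)
        assert beat.max() == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_gaussian_sum(self):
        morph = BeatMorphology()
        beat = lr.generate_beat(morph, fs=500)
        assert np.allclose(beat, gaussian_sum_oracle(morph, 500), atol=1e-12)

    def test_negative_s_wave_sets_the_minimum(self):
        # S placed far enough from R that the R tail is negligible there
        morph = BeatMorphology(p=Wave(-180, 0, 22), q=Wave(-90, 0, 8),
                               r=Wave(0, 1.0, 8), s=Wave(60, -0.3, 8),
                               t=Wave(320, 0, 55))
        fs = 500
        beat = lr.generate_beat(morph, fs)
        oracle = gaussian_sum_oracle(morph, fs)
        assert beat.min() == pytest.approx(oracle.min(), abs=1e-12)
        assert beat.min() == pytest.approx(-0.3, abs=2e-3)
        # minimum within one sample of the S center
        t0 = np.floor((morph.p.center_ms - 3 * morph.p.width_ms) * fs / 1000)
        s_idx = morph.s.center_ms * fs / 1000 - t0
        assert abs(int(beat.argmin()) - s_idx) <= 1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            BeatMorphology(r=Wave(0, 1.0, -1.0))
        with pytest.raises(ParameterError):
            lr.generate_beat(BeatMorphology(), fs=0)


class TestFrontalProjection:
    def test_dipole_along_zero_degrees_maximizes_lead_i(self):
        t = np.linspace(0, 1, 100)
        m = np.sin(2 * np.pi * t)
        leads = lr.project_frontal_leads(np.stack([m, np.zeros_like(m)]))
        amps = {k: np.abs(v).max() for k, v in leads.items()}
        assert amps["I"] == max(amps.values())
        # aVF = II - I/2 exactly
        assert np.allclose(leads["aVF"], leads["II"] - leads["I"] / 2)

    def test_zero_dipole_gives_zero_leads(self):
        leads = lr.project_frontal_leads(np.zeros((2, 50)))
        for v in leads.values():
            assert np.all(v == 0)

    def test_einthoven_identity_holds_for_any_dipole(self):
        rng = np.random.default_rng(0)
        leads = lr.project_frontal_leads(rng.normal(size=(2, 200)))
        assert np.allclose(leads["III"] + leads["I"] - leads["II"], 0, atol=1e-12)

    def test_nonfinite_dipole_rejected(self):
        bad = np.zeros((2, 10))
        bad[0, 3] = np.nan
        with pytest.raises(ParameterError):
            lr.project_frontal_leads(bad)


class TestGenerateRecord:
    def test_72_bpm_10_s_yields_12_beats(self):
        params = SubjectParams(heart_rate_bpm=72, rr_jitter=0.0, noise_mv=0.0)
        rec = lr.generate_record(params, seed=3)
        assert rec.metadata.qrs_count == 12
        assert rec.metadata.ventricular_rate == 72.0

    def test_same_seed_gives_bit_identical_records(self):
        params = SubjectParams()
        a = lr.generate_record(params, seed=7)
        b = lr.generate_record(params, seed=7)
        for name in a.leads:
            assert np.array_equal(a.leads[name], b.leads[name])

    def test_seed_is_mandatory(self):
        with pytest.raises(ParameterError):
            lr.generate_record(SubjectParams())

    def test_normal_axis_discretizes_to_normal(self):
        rec = lr.generate_record(SubjectParams(theta_r=45.0), seed=1)
        cats = discretize_metadata(rec.metadata)
        assert cats.r_axis_cat == "Normal"

    @pytest.mark.parametrize("theta", [-150.0, -60.0, 0.0, 45.0, 90.0, 150.0])
    def test_qrs_axis_recovered_within_5_degrees(self, theta):
        params = SubjectParams(theta_r=theta, rr_jitter=0.0, noise_mv=0.0)
        rec = lr.generate_record(params, seed=11)
        est = estimate_qrs_axis(rec)
        dev = (est - theta + 180) % 360 - 180
        assert abs(dev) <= 5.0

    def test_r_peak_count_matches_ground_truth_on_clean_lead_ii(self):
        params = SubjectParams(heart_rate_bpm=66, rr_jitter=0.0, noise_mv=0.0)
        rec = lr.generate_record(params, seed=5)
        peaks = lr.detect_r_peaks(rec.leads["II"][::5], fs=100)
        assert len(peaks) == rec.metadata.qrs_count

    def test_lead_identities_hold_on_noisy_records(self):
        # noise enters at the dipole, so the derived-lead identities survive
        rng = np.random.default_rng(42)
        for k in range(20):
            params = SubjectParams(theta_r=float(rng.uniform(-170, 170)),
                                   noise_mv=0.05)
            rec = lr.generate_record(params, seed=int(rng.integers(2**31)))
            lead = rec.leads
            assert np.max(np.abs(lead["III"] - (lead["II"] - lead["I"]))) <= 1e-9
            assert np.max(np.abs(lead["aVR"] + (lead["I"] + lead["II"]) / 2)) <= 1e-9
            assert np.max(np.abs(lead["aVL"] - (lead["I"] - lead["II"] / 2))) <= 1e-9
            assert np.max(np.abs(lead["aVF"] - (lead["II"] - lead["I"] / 2))) <= 1e-9


class TestGenerateDataset:
    def test_split_proportions_at_n_100(self):
        _, split = lr.generate_dataset(100, seed=2)
        counts = {s: sum(1 for v in split.values() if v == s)
                  for s in ("train", "val", "test")}
        assert counts == {"train": 70, "val": 15, "test": 15}

    def test_same_master_seed_reproduces_dataset_and_split(self):
        recs_a, split_a = lr.generate_dataset(12, seed=9)
        recs_b, split_b = lr.generate_dataset(12, seed=9)
        assert split_a == split_b
        for a, b in zip(recs_a, recs_b):
            assert np.array_equal(a.leads["V3"], b.leads["V3"])

    def test_stratified_sampler_covers_every_category(self):
        records, _ = lr.generate_dataset(48, seed=4, stratified=True)
        seen = {f: set() for f in ("RAxis", "TAxis", "QRSDuration",
                                   "VentricularRate", "QRSCount")}
        for rec in records:
            cats = discretize_metadata(rec.metadata).as_dict()
            for f, c in cats.items():
                seen[f].add(c)
        assert len(seen["RAxis"]) == 4
        assert len(seen["TAxis"]) == 4
        assert len(seen["QRSDuration"]) == 2
        assert len(seen["VentricularRate"]) == 3
        assert len(seen["QRSCount"]) == 3

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ParameterError):
            lr.generate_dataset(5, seed=1)

    def test_out_of_range_angles_rejected(self):
        def bad_sampler(rng):
            return SubjectParams(theta_r=270.0)

        with pytest.raises(ParameterError):
            lr.generate_dataset(10, seed=1, param_sampler=bad_sampler)
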