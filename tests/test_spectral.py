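"""Welch spectra, relative power normalisation, and band power extraction."""

import numpy as np
import pytest

import alphaslow as al
from alphaslow.cohort import Recording
from alphaslow.spectral import BandDefinition, PowerSpectrum, fit_aperiodic_exponent


def _mono_recording(signal, fs):
    return Recording(
        subject_id="x", group="control", modality="EEG", fs=fs,
        data=np.atleast_2d(signal), region_labels=["r0"], hemisphere=["left"],
    )


def _toy_spectrum(power_rows, df=0.5, normalized=False, norm_band=None):
    power = np.atleast_2d(np.asarray(power_rows, dtype=float))
    freqs = np.arange(power.shape[1]) * df
    return PowerSpectrum(freqs=freqs, power=power, normalized=normalized,
                         norm_band=norm_band)


class TestWelch:
    def test_dc_signal_concentrates_at_zero(self):
        ps = al.welch_psd(_mono_recording(np.full(2500, 3.0), 250.0))
        assert np.argmax(ps.power[0]) == 0
        assert ps.power[0, 5:].max() < 1e-12 * ps.power[0, 0]

    def test_sinusoid_peaks_at_exact_bin(self, sine_recording):
        ps = al.welch_psd(sine_recording)
        assert ps.freqs[1] - ps.freqs[0] == pytest.approx(0.5)
        assert ps.freqs[np.argmax(ps.power[0])] == pytest.approx(10.0)

    def test_white_noise_spectrum_is_flat_on_average(self):
        rng = np.random.default_rng(123)
        fs = 250.0
        acc = None
        for _ in range(100):
            ps = al.welch_psd(_mono_recording(rng.standard_normal(int(fs * 10)), fs))
            acc = ps.power[0] if acc is None else acc + ps.power[0]
        mask = (ps.freqs >= 1.0) & (ps.freqs <= 40.0)
        mean_bins = acc[mask]
        assert mean_bins.max() / mean_bins.min() < 1.5

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            al.welch_psd(_mono_recording(np.zeros(600), 250.0))

    def test_parseval_total_power_near_variance(self, small_cohort):
        # band-limit first: a 2-s window cannot represent the sub-0.5 Hz
        # mass of the raw 1/f background
        rec = al.bandpass(small_cohort[0][0], 1.0, 47.5)
        ps = al.welch_psd(rec)
        df = ps.freqs[1] - ps.freqs[0]
        total = ps.power.sum(axis=1) * df
        variance = rec.data.var(axis=1)
        assert np.all(np.abs(total - variance) / variance < 0.10)


class TestRelativePower:
    def test_sums_to_one_per_region(self, small_cohort):
        ps = al.relative_power(al.welch_psd(small_cohort[0][0]))
        mask = ps.band_mask(1.0, 47.5)
        np.testing.assert_allclose(ps.power[:, mask].sum(axis=1), 1.0, atol=1e-9)

    def test_scale_invariance(self, small_cohort):
        raw = al.welch_psd(small_cohort[0][0])
        scaled = PowerSpectrum(freqs=raw.freqs, power=1000.0 * raw.power)
        np.testing.assert_allclose(
            al.relative_power(raw).power, al.relative_power(scaled).power
        )

    def test_two_bin_arithmetic(self):
        ps = _toy_spectrum([[0.0, 0.0, 0.3, 0.1]])
        rel = al.relative_power(ps, norm_band=(1.0, 1.5))
        np.testing.assert_allclose(rel.power[0], [0.0, 0.0, 0.75, 0.25])

    def test_double_normalisation_rejected(self, small_cohort):
        rel = al.relative_power(al.welch_psd(small_cohort[0][0]))
        with pytest.raises(ValueError, match="already normalized"):
            al.relative_power(rel)

    def test_all_zero_region_rejected(self):
        ps = _toy_spectrum([[0.0, 0.0, 0.0, 0.0], [0.0, 1.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="region"):
            al.relative_power(ps, norm_band=(0.5, 1.5))


class TestBandPower:
    def test_partition_of_unity(self, small_cohort):
        rel = al.relative_power(al.welch_psd(small_cohort[0][0]))
        # contiguous bands splitting (1, 47.5) at bin boundaries, no shared bins
        parts = [
            BandDefinition("a", 1.0, 9.5),
            BandDefinition("b", 10.0, 29.5),
            BandDefinition("c", 30.0, 47.5),
        ]
        total = sum(al.band_power(rel, b) for b in parts)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_fast_band_covers_three_bins(self):
        ps = _toy_spectrum([np.ones(96)], normalized=True, norm_band=(1.0, 47.5))
        bp = al.band_power(ps, al.FAST_ALPHA)
        assert bp[0] == pytest.approx(3.0)  # bins 10.0, 10.5, 11.0
        bp_slow = al.band_power(ps, al.SLOW_ALPHA)
        assert bp_slow[0] == pytest.approx(7.0)  # bins 6.0 .. 9.0

    def test_additivity_over_disjoint_bands(self, small_cohort):
        rel = al.relative_power(al.welch_psd(small_cohort[0][0]))
        a = BandDefinition("a", 6.0, 9.0)
        b = BandDefinition("b", 10.0, 11.0)
        union_sum = al.band_power(rel, a) + al.band_power(rel, b)
        manual = rel.power[:, rel.band_mask(6.0, 9.0) | rel.band_mask(10.0, 11.0)].sum(axis=1)
        np.testing.assert_allclose(union_sum, manual, atol=1e-12)

    def test_slow_peak_subject_has_more_slow_than_fast(self):
        spec = al.CohortSpec(duration=30.0, alpha_peak_sd=0.0,
                             alpha_peak_mean_patient=8.0)
        rec = al.simulate_subject(spec, "left_TLE", np.random.default_rng(9))
        rel = al.relative_power(al.welch_psd(rec))
        occ = int(np.argmax(spec.topography()))
        assert al.band_power(rel, al.SLOW_ALPHA)[occ] > al.band_power(rel, al.FAST_ALPHA)[occ]

    def test_unnormalized_spectrum_rejected(self, small_cohort):
        ps = al.welch_psd(small_cohort[0][0])
        with pytest.raises(ValueError, match="normalized"):
            al.band_power(ps, al.SLOW_ALPHA)

    def test_band_outside_norm_band_rejected(self, small_cohort):
        rel = al.relative_power(al.welch_psd(small_cohort[0][0]))
        with pytest.raises(ValueError, match="outside"):
            al.band_power(rel, BandDefinition("hf", 40.0, 60.0))


class TestGlobalBandPower:
    def test_single_uniform_subject_has_zero_ci(self):
        row = np.linspace(1.0, 2.0, 41)
        ps = PowerSpectrum(freqs=np.arange(41) * 0.5,
                           power=np.tile(row, (68, 1)),
                           normalized=True, norm_band=(0.0, 20.0))
        curve = al.global_band_power([ps], f_range=(1.0, 20.0))
        mask = (ps.freqs >= 1.0) & (ps.freqs <= 20.0)
        np.testing.assert_allclose(curve["mean"], row[mask])
        np.testing.assert_allclose(curve["ci_hi"] - curve["ci_lo"], 0.0)

    def test_two_subjects_average(self):
        freqs = np.arange(41) * 0.5
        p = np.tile(np.linspace(1, 2, 41), (3, 1))
        q = np.tile(np.linspace(2, 1, 41), (3, 1))
        psa = PowerSpectrum(freqs=freqs, power=p, normalized=True, norm_band=(0, 20))
        psb = PowerSpectrum(freqs=freqs, power=q, normalized=True, norm_band=(0, 20))
        curve = al.global_band_power([psa, psb], f_range=(0.0, 20.0))
        np.testing.assert_allclose(curve["mean"], (p[0] + q[0]) / 2)

    def test_mismatched_grids_rejected(self):
        a = PowerSpectrum(freqs=np.arange(10) * 0.5, power=np.ones((1, 10)))
        b = PowerSpectrum(freqs=np.arange(10) * 0.25, power=np.ones((1, 10)))
        with pytest.raises(ValueError, match="grid"):
            al.global_band_power([a, b])


def test_aperiodic_exponent_recovered():
    """Log-log Welch slope recovers the generative 1/f exponent within 0.15."""
    from alphaslow.experiments import exponent_recovery

    df = exponent_recovery(n_seeds=20, base_seed=303)
    err = np.abs(df["estimated_exponent"] - df["true_exponent"])
    assert (err <= 0.15).mean() >= 0.9


def test_cohort_spectra_show_alpha_slowing_shift(small_cohort):
    """Patient cohort's mean-spectrum alpha argmax sits below controls'."""
    recordings, _ = small_cohort
    spectra = [al.relative_power(al.welch_psd(r)) for r in recordings]
    ctl = [s for s, r in zip(spectra, recordings) if r.group == "control"]
    pat = [s for s, r in zip(spectra, recordings) if r.group != "control"]
    c_curve = al.global_band_power(ctl, f_range=(6.0, 13.0))
    p_curve = al.global_band_power(pat, f_range=(6.0, 13.0))
    f_ctl = c_curve["freqs"][np.argmax(c_curve["mean"])]
    f_pat = p_curve["freqs"][np.argmax(p_curve["mean"])]
    assert f_pat < f_ctl


def test_fit_aperiodic_exponent_needs_enough_bins():
    ps = PowerSpectrum(freqs=np.arange(4) * 0.5, power=np.ones((1, 4)))
    with pytest.raises(ValueError):
        fit_aperiodic_exponent(ps, f_range=(0.4, 0.6))
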