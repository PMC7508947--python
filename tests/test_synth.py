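"""Generator-level tests: determinism, variance accounting, rate convergence,
ground-truth consistency, and parameter validation."""

import numpy as np
import pandas as pd
import pytest

from optoplaque import synth
from optoplaque.exceptions import ParameterError, PlacementError
from optoplaque.plaques import GENOTYPE_CONTROL, GENOTYPE_TREATED, normalize_densities


class TestGenerateEEG:
    def test_same_seed_identical_traces(self):
        p = synth.SynthEEGParams(
            duration_pre_s=5, duration_stim_s=5, duration_post_s=5,
            gamma_amplitude_rel=1.0, seed=7,
        )
        a = synth.generate_eeg(p)
        b = synth.generate_eeg(p)
        assert np.array_equal(a.trace, b.trace)
        assert a.periods == b.periods

    def test_trace_length_and_periods(self):
        p = synth.SynthEEGParams(
            duration_pre_s=10, duration_stim_s=20, duration_post_s=5, seed=0
        )
        rec = synth.generate_eeg(p)
        assert len(rec.trace) == 35 * 1000
        assert rec.period_labels() == ("Pre", "Stim", "Post")
        assert len(rec.period_slice("Stim")) == 20_000

    def test_background_independent_of_injection(self):
        base = dict(duration_pre_s=20, duration_stim_s=20, duration_post_s=20, seed=3)
        rec0 = synth.generate_eeg(synth.SynthEEGParams(gamma_amplitude_rel=0.0, **base))
        rec1 = synth.generate_eeg(synth.SynthEEGParams(gamma_amplitude_rel=1.0, **base))
        assert np.array_equal(rec0.period_slice("Pre"), rec1.period_slice("Pre"))
        assert np.array_equal(rec0.period_slice("Post"), rec1.period_slice("Post"))
        assert not np.array_equal(rec0.period_slice("Stim"), rec1.period_slice("Stim"))

    def test_stim_variance_is_background_plus_injected(self):
        """Total Stim-segment variance = background + injected variance (2%)."""
        base = dict(duration_pre_s=2, duration_stim_s=300, duration_post_s=2, seed=5)
        rec0 = synth.generate_eeg(synth.SynthEEGParams(gamma_amplitude_rel=0.0, **base))
        rec1 = synth.generate_eeg(synth.SynthEEGParams(gamma_amplitude_rel=1.0, **base))
        bg = rec0.period_slice("Stim")
        total = rec1.period_slice("Stim")
        injected = total - bg
        assert total.var() == pytest.approx(bg.var() + injected.var(), rel=0.02)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(duration_pre_s=0),
            dict(duration_stim_s=-1),
            dict(fs=100.0),
            dict(gamma_amplitude_rel=-0.5),
            dict(delta_attenuation_stim=0.0),
            dict(delta_attenuation_stim=1.5),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            synth.SynthEEGParams(**kwargs)

    def test_delta_attenuation_reduces_delta_power(self):
        from optoplaque import eeg

        base = dict(duration_pre_s=120, duration_stim_s=120, duration_post_s=2, seed=9)
        rec_full = synth.generate_eeg(synth.SynthEEGParams(**base))
        rec_att = synth.generate_eeg(
            synth.SynthEEGParams(delta_attenuation_stim=0.5, **base)
        )
        def delta(rec):
            f, psd = eeg.welch_psd(rec, "Stim")
            return eeg.band_power(f, psd)["delta"]

        ratio = delta(rec_att) / delta(rec_full)
        assert 0.35 < ratio < 0.65


class TestGenerateSpikes:
    def test_deterministic(self):
        p = synth.SynthSpikeParams(n_units=3, n_pulses=50, seed=1)
        (ua, _), (ub, _) = synth.generate_spike_data(p), synth.generate_spike_data(p)
        for a, b in zip(ua, ub):
            assert np.array_equal(a.spike_times_s, b.spike_times_s)

    def test_rates_converge_inside_and_outside_pulses(self):
        """Empirical rates match specified rates at 1% with >= 1e5 expected spikes."""
        p = synth.SynthSpikeParams(
            n_units=1, baseline_rate_hz=100.0, rate_ratio=2.0, n_pulses=4000, seed=2
        )
        (unit,), protocol = synth.generate_spike_data(p)
        t = unit.spike_times_s
        on = protocol.pulse_onsets_s
        inside = (
            np.searchsorted(t, on + protocol.pulse_duration_s) - np.searchsorted(t, on)
        ).sum()
        total_on = protocol.n_pulses * protocol.pulse_duration_s
        total_s = p.pad_s * 2 + p.n_pulses * 0.5
        outside = len(t) - inside
        assert inside / total_on == pytest.approx(200.0, rel=0.01)
        assert outside / (total_s - total_on) == pytest.approx(100.0, rel=0.01)

    def test_metadata_propagated(self):
        p = synth.SynthSpikeParams(
            n_units=2,
            trough_to_peak_ms=[0.3, 0.8],
            isolation_distance=[15.0, 45.0],
            region=["BF", "mPFC"],
            n_pulses=5,
            seed=0,
        )
        units, _ = synth.generate_spike_data(p)
        assert [u.trough_to_peak_ms for u in units] == [0.3, 0.8]
        assert [u.isolation_distance for u in units] == [15.0, 45.0]
        assert [u.region for u in units] == ["BF", "mPFC"]

    def test_modulation_classes_derived_from_ratio(self):
        p = synth.SynthSpikeParams(n_units=3, rate_ratio=[2.0, 0.5, 1.0], n_pulses=5)
        assert p.modulation_classes() == ["activated", "suppressed", "unmodulated"]

    def test_zero_pulses_rejected(self):
        with pytest.raises(ParameterError):
            synth.SynthSpikeParams(n_units=1, n_pulses=0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(baseline_rate_hz=-1.0),
            dict(rate_ratio=0.0),
            dict(pulse_on_ms=0.0),
            dict(n_units=0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            synth.SynthSpikeParams(**kwargs)


class TestGenerateMicrograph:
    def test_deterministic(self):
        p = synth.SynthImageParams(seed=4)
        (a, ta), (b, tb) = synth.generate_micrograph(p), synth.generate_micrograph(p)
        assert np.array_equal(a.image, b.image)
        pd.testing.assert_frame_equal(ta, tb)

    def test_zero_plaques_pure_noise(self):
        roi, truth = synth.generate_micrograph(
            synth.SynthImageParams(n_plaques=0, seed=1)
        )
        assert truth.empty
        # pure Gaussian background around the mean
        assert roi.image.mean() == pytest.approx(1000.0, rel=0.01)

    def test_ground_truth_count_and_separation(self, default_micrograph):
        _, truth = default_micrograph
        assert len(truth) == 25
        xy = truth[["x_px", "y_px"]].to_numpy()
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 40.0

    def test_areas_match_support_mask(self, default_micrograph):
        """Sum of ground-truth areas equals the union blob-support mask area."""
        _, truth = default_micrograph
        mask = synth.blob_support_mask(synth.SynthImageParams(seed=42), truth)
        assert int(mask.sum()) == int(truth["area_px"].sum())

    def test_placement_error_when_infeasible(self):
        with pytest.raises(PlacementError):
            synth.generate_micrograph(
                synth.SynthImageParams(
                    height_px=64, width_px=64, n_plaques=30,
                    min_center_separation_px=40.0, plaque_radius_px=(3.0, 5.0),
                    seed=0,
                )
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_plaques=-1),
            dict(plaque_radius_px=(0.0, 5.0)),
            dict(plaque_radius_px=(600.0, 700.0)),
            dict(plaque_peak_intensity=(500.0, 600.0)),  # below background mean
            dict(noise="salt"),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            synth.SynthImageParams(**kwargs)


class TestGenerateGroupTable:
    def test_noise_free_limit_recovers_multipliers(self):
        """With zero noise, normalized treated means equal the multipliers."""
        p = synth.SynthGroupParams(
            regions=("ACA", "mPFC", "S1", "ENT", "DG", "SUB", "SEP", "TH"),
            effect_multiplier={"mPFC": 2.0, "SEP": 2.0},
            animal_cv=0.0, section_cv=0.0, seed=0,
        )
        norm = normalize_densities(synth.generate_group_table(p))
        treated = norm[norm["genotype"] == GENOTYPE_TREATED]
        means = treated.groupby("region")["normalized"].mean()
        for region in p.regions:
            expected = 2.0 if region in ("mPFC", "SEP") else 1.0
            assert means[region] == pytest.approx(expected, abs=1e-12)

    def test_table_shape_and_keys(self):
        p = synth.SynthGroupParams(n_animals_per_group=3, sections_per_region=4, seed=1)
        table = synth.generate_group_table(p)
        assert len(table) == 2 * 3 * len(p.regions) * 4
        assert not table.duplicated(["animal_id", "region", "section"]).any()
        assert set(table["genotype"]) == {GENOTYPE_CONTROL, GENOTYPE_TREATED}

    def test_expected_effect_in_noisy_tables(self):
        """Treated/control mean ratio converges to the multiplier."""
        p = synth.SynthGroupParams(
            regions=("mPFC",), effect_multiplier=3.0,
            n_animals_per_group=20, sections_per_region=20,
            animal_cv=0.1, section_cv=0.1, seed=3,
        )
        table = synth.generate_group_table(p)
        ratio = (
            table[table["genotype"] == GENOTYPE_TREATED]["density"].mean()
            / table[table["genotype"] == GENOTYPE_CONTROL]["density"].mean()
        )
        assert ratio == pytest.approx(3.0, rel=0.1)

    def test_parameter_recovery_slope(self):
        """Estimated normalized means regress on true multipliers with slope 1."""
        mult = {
            "ACA": 1.0, "mPFC": 2.0, "S1": 1.25, "ENT": 1.5, "DG": 0.75,
            "SUB": 1.1, "SEP": 2.5, "TH": 0.9, "CA1": 1.0, "CA3": 1.75,
        }
        est, truth = [], []
        for seed in range(100):
            p = synth.SynthGroupParams(
                effect_multiplier=mult, animal_cv=0.0, section_cv=0.1, seed=seed
            )
            norm = normalize_densities(synth.generate_group_table(p))
            treated = norm[norm["genotype"] == GENOTYPE_TREATED]
            means = treated.groupby("region")["normalized"].mean()
            for region, m in mult.items():
                est.append(means[region])
                truth.append(m)
        slope = np.polyfit(truth, est, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_animals_per_group=1),
            dict(effect_multiplier=0.0),
            dict(animal_cv=-0.1),
            dict(sections_per_region=0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            synth.SynthGroupParams(**kwargs)
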