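"""Anchor detection, band construction, ratios and risk groups."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alphaband.banding import (
    AnchorFrequencies,
    PipelineError,
    band_powers,
    classify_risk,
    compute_ratios,
    define_bands,
    detect_iaf,
    detect_tf,
    relative_band_power,
    subject_pipeline,
)
from alphaband.config import PipelineConfig
from alphaband.spectral import CollapsedSpectrum
from alphaband.synthetic import (
    SubjectSpec,
    analytic_markers,
    generate_eeg,
    subject_preset,
)

GRID = np.arange(0.0, 125.5, 0.5)


def spectrum(power):
    return CollapsedSpectrum(freqs=GRID, power=np.asarray(power, float),
                             channel_set=["x"])


def bump_spectrum(centers_amps, background=lambda f: 10.0 / np.maximum(f, 0.5)):
    p = background(GRID).copy()
    for c, a in centers_amps:
        p = p + a * np.exp(-0.5 * ((GRID - c) / 0.5) ** 2)
    return spectrum(p)


class TestDetectIaf:
    def test_bump_on_pink_background(self):
        iaf, flags = detect_iaf(bump_spectrum([(10.0, 50.0)]))
        assert iaf == 10.0
        assert not flags

    def test_monotone_spectrum_flags_no_peak(self):
        iaf, flags = detect_iaf(spectrum(100.0 / np.maximum(GRID, 0.5)))
        assert iaf == 5.0
        assert "no-alpha-peak" in flags

    def test_equal_twin_peaks_resolve_upward_with_flag(self):
        cs = bump_spectrum([(9.0, 50.0), (11.0, 50.0)],
                           background=lambda f: np.ones_like(f))
        iaf, flags = detect_iaf(cs)
        assert iaf == 11.0
        assert "double-peak" in flags

    def test_search_range_outside_grid_rejected(self):
        cs = spectrum(np.ones(GRID.size))
        with pytest.raises(ValueError, match="outside"):
            detect_iaf(cs, (5.0, 200.0))


class TestDetectTf:
    def test_trough_between_theta_and_alpha(self):
        cs = bump_spectrum([(6.0, 30.0), (10.0, 50.0)])
        tf, flags = detect_tf(cs, iaf=10.0)
        assert tf == 8.0
        assert not flags

    def test_flat_window_ties_to_lower_bound_with_flag(self):
        cs = spectrum(np.ones(GRID.size))
        tf, flags = detect_tf(cs, iaf=10.0)
        assert tf == 4.0
        assert "tf-at-boundary" in flags

    def test_empty_window_rejected(self):
        cs = spectrum(np.ones(GRID.size))
        with pytest.raises(ValueError, match="window"):
            detect_tf(cs, iaf=10.0, search_low=9.8)


class TestDefineBands:
    def test_cohort_mean_anchors_reproduce_printed_ranges(self):
        scheme = define_bands(AnchorFrequencies(tf=6.9, iaf=10.9))
        assert scheme["delta"] == pytest.approx((2.9, 4.9))
        assert scheme["theta"] == pytest.approx((4.9, 6.9))
        assert scheme["alpha1"] == pytest.approx((6.9, 8.9))
        assert scheme["alpha2"] == pytest.approx((8.9, 10.9))
        assert scheme["alpha3"] == pytest.approx((10.9, 12.9))

    def test_on_grid_midpoint_rounds_half_up(self):
        # exact midpoint 8.25 falls between bins; snaps up to 8.5
        scheme = define_bands(AnchorFrequencies(tf=6.5, iaf=10.0))
        assert scheme["alpha1"][1] == 8.5
        # exact on-grid midpoint is kept
        scheme = define_bands(AnchorFrequencies(tf=7.0, iaf=10.0))
        assert scheme["alpha1"][1] == 8.5

    @pytest.mark.parametrize("tf,iaf,err", [
        (3.5, 10.0, "delta"),
        (8.0, 8.0, None),       # iaf <= tf rejected by AnchorFrequencies
    ])
    def test_invalid_anchors_rejected(self, tf, iaf, err):
        if err is None:
            with pytest.raises(ValueError):
                AnchorFrequencies(tf=tf, iaf=iaf)
        else:
            with pytest.raises(ValueError, match=err):
                define_bands(AnchorFrequencies(tf=tf, iaf=iaf))

    def test_contiguity_over_anchor_sweep(self):
        for tf in np.arange(4.0, 8.5, 0.5):
            for iaf in np.arange(tf + 1.0, 13.5, 0.5):
                scheme = define_bands(AnchorFrequencies(tf=float(tf), iaf=float(iaf)))
                names = ["delta", "theta", "alpha1", "alpha2", "alpha3"]
                for a, b in zip(names, names[1:]):
                    assert scheme[a][1] == scheme[b][0]
                edges = [e for n in names for e in scheme[n]]
                assert all(x < y for x, y in zip(edges[::2], edges[1::2]))
                # every individual edge on the 0.5 Hz grid
                for e in edges:
                    assert abs(e * 2 - round(e * 2)) < 1e-9


class TestRelativePower:
    def test_flat_spectrum_gives_bin_count_fraction(self):
        cs = spectrum(np.ones(GRID.size))
        rp = relative_band_power(cs, (8.9, 10.9), (2.0, 45.0))
        n_band = ((GRID >= 8.9 - 1e-9) & (GRID < 10.9 - 1e-9)).sum()
        n_tot = ((GRID >= 2.0) & (GRID < 45.0 - 1e-9)).sum()
        assert rp == pytest.approx(n_band / n_tot)

    def test_band_equal_to_total_is_one(self):
        cs = spectrum(np.ones(GRID.size))
        assert relative_band_power(cs, (2.0, 45.0)) == pytest.approx(1.0)

    def test_single_line_spectrum(self):
        p = np.zeros(GRID.size)
        p[GRID == 10.0] = 7.0
        assert relative_band_power(spectrum(p), (8.0, 12.0)) == 1.0

    def test_zero_total_power_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            relative_band_power(spectrum(np.zeros(GRID.size)), (8.0, 12.0))

    def test_band_outside_total_rejected_unless_clipped(self):
        cs = spectrum(np.ones(GRID.size))
        with pytest.raises(ValueError, match="not within"):
            relative_band_power(cs, (0.5, 2.5))
        assert relative_band_power(cs, (0.5, 2.5), clip=True) > 0

    def test_five_band_additivity(self):
        cs = bump_spectrum([(6.0, 10.0), (10.0, 30.0)])
        scheme = define_bands(AnchorFrequencies(tf=6.5, iaf=10.0))
        powers = band_powers(cs, scheme)
        direct = relative_band_power(cs, (6.5 - 4.0, 10.0 + 2.0))
        total5 = sum(powers[b] for b in ("delta", "theta", "alpha1",
                                         "alpha2", "alpha3"))
        assert total5 == pytest.approx(direct, abs=1e-12)


class TestRatios:
    def test_equal_bands_give_unity(self):
        r, _ = compute_ratios({"alpha2": 0.2, "alpha3": 0.2,
                               "theta": 0.1, "gamma": 0.1})
        assert r == 1.0

    def test_printed_high_cutoff_construction(self):
        r, _ = compute_ratios({"alpha2": 0.2, "alpha3": 0.2 * 1.17,
                               "theta": 0.1, "gamma": 0.1})
        assert r == pytest.approx(1.17)
        assert classify_risk(r) == "high"

    def test_absolute_and_relative_powers_agree(self):
        cs = bump_spectrum([(6.0, 10.0), (10.0, 30.0)])
        scheme = define_bands(AnchorFrequencies(tf=6.5, iaf=10.0))
        rel = band_powers(cs, scheme)
        df = 0.5
        absolute = {
            name: cs.power[(GRID >= lo - 1e-9) & (GRID < hi - 1e-9)].sum() * df
            for name, (lo, hi) in scheme
        }
        r_rel, t_rel = compute_ratios(rel)
        r_abs, t_abs = compute_ratios(absolute)
        assert abs(r_rel - r_abs) < 1e-12
        assert abs(t_rel - t_abs) < 1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(scale=st.floats(min_value=1e-6, max_value=1e6,
                           allow_nan=False, allow_infinity=False))
    def test_ratio_invariant_under_spectrum_rescaling(self, scale):
        cs = bump_spectrum([(6.0, 10.0), (10.0, 30.0)])
        scaled = spectrum(cs.power * scale)
        scheme = define_bands(AnchorFrequencies(tf=6.5, iaf=10.0))
        r1, _ = compute_ratios(band_powers(cs, scheme))
        r2, _ = compute_ratios(band_powers(scaled, scheme))
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="alpha2"):
            compute_ratios({"alpha2": 0.0, "alpha3": 0.1,
                            "theta": 0.1, "gamma": 0.1})


class TestClassifyRisk:
    @pytest.mark.parametrize("ratio,group", [
        (1.29, "high"), (0.9, "low"), (1.165, "middle"),
        (1.0, "middle"), (1.17, "high"), (0.999, "low"),
    ])
    def test_fixed_cutoffs(self, ratio, group):
        assert classify_risk(ratio) == group

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(ratio=st.floats(min_value=1e-9, max_value=100.0,
                           allow_nan=False, allow_infinity=False))
    def test_fixed_rule_partitions_positive_reals(self, ratio):
        group = classify_risk(ratio)
        expected = "low" if ratio < 1.0 else ("high" if ratio >= 1.17 else "middle")
        assert group == expected

    def test_cohort_tertiles_balanced(self):
        cohort = [0.8, 0.9, 1.0, 1.1, 1.2, 1.3]
        labels = [classify_risk(r, "cohort-tertile", cohort) for r in cohort]
        assert labels == ["low", "low", "middle", "middle", "high", "high"]

    def test_tertile_needs_cohort(self):
        with pytest.raises(ValueError, match="cohort"):
            classify_risk(1.0, "cohort-tertile")


class TestSubjectPipeline:
    def test_deterministic(self):
        rec = generate_eeg(subject_preset("low-risk", seed=3), duration=20.0)
        r1 = subject_pipeline(rec)
        r2 = subject_pipeline(rec)
        assert r1.markers.a3_a2_ratio == r2.markers.a3_a2_ratio
        np.testing.assert_array_equal(r1.spectrum.power, r2.spectrum.power)

    def test_ratio_matches_analytic_oracle(self):
        """Recovered a3/a2 within 0.05 of the expected-spectrum oracle."""
        for seed in range(10):
            spec = subject_preset("high-risk", seed)
            oracle, _ = analytic_markers(spec)
            res = subject_pipeline(generate_eeg(spec, duration=300.0))
            assert res.markers.a3_a2_ratio == pytest.approx(
                oracle.a3_a2_ratio, abs=0.05
            )

    def test_all_epochs_rejected_names_the_stage(self):
        rec = generate_eeg(SubjectSpec(seed=0), duration=8.0)
        cfg = PipelineConfig(amp_threshold_uv=1e-6, grad_threshold_uv=1e-6)
        with pytest.raises(PipelineError, match="artifact-rejection"):
            subject_pipeline(rec, cfg)

    def test_silent_alpha_flags_no_peak(self):
        """No oscillators at all: the detection stage must flag the
        absence of an alpha peak (the degenerate anchors then stop the
        full pipeline at band construction)."""
        from alphaband.preprocess import rereference_common_average, segment_epochs
        from alphaband.spectral import collapse_spectrum, welch_psd

        spec = SubjectSpec(amp_theta=0.0, amp_alpha_low=0.0,
                           amp_alpha_high=0.0, seed=1)
        rec = generate_eeg(spec, duration=300.0)
        cs = collapse_spectrum(
            welch_psd(segment_epochs(rereference_common_average(rec), 2.0))
        )
        _, flags = detect_iaf(cs)
        assert "no-alpha-peak" in flags
        with pytest.raises(PipelineError):
            subject_pipeline(rec)
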