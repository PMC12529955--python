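"""GIXD reduction: Q-space conversion, peak fitting, lattice indexing, tilt."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from monolayer import synthetic as syn
from monolayer.gixd import (
    BraggPeak,
    FitError,
    analyze_map,
    coherence_length,
    extract_profiles,
    fit_bragg_peaks,
    fit_rod,
    index_lattice,
    q_from_angles,
    tilt_angle,
)


class TestQFromAngles:
    def test_zero_angles(self):
        assert q_from_angles(0.0, 0.0) == (0.0, 0.0)

    def test_inverse_evaluation(self):
        lam = 1.55
        two_theta = 2 * math.degrees(math.asin(1.458 * lam / (4 * math.pi)))
        qxy, _ = q_from_angles(two_theta, 0.0, lam)
        assert qxy == pytest.approx(1.458, abs=1e-12)

    def test_grazing_exit_maximum(self):
        _, qz = q_from_angles(0.0, 90.0, 1.55)
        assert qz == pytest.approx(2 * math.pi / 1.55, abs=1e-9)
        assert qz == pytest.approx(4.0537, abs=1e-3)


class TestExtractProfiles:
    def test_zero_map(self):
        gm = syn.gen_map(syn.MapParams(peaks=[], background=0.0))
        (qxy, prof), (qz, rod) = extract_profiles(
            gm, (0.0, 0.9), (float(gm.qxy[0]), float(gm.qxy[-1]))
        )
        assert np.all(prof == 0) and np.all(rod == 0)

    def test_single_peak_location(self):
        gm = syn.gen_map(syn.MapParams(peaks=[(1.45, 0.0, 0.01, 0.3, 100.0)], background=0.0))
        (qxy, prof), _ = extract_profiles(gm, (0.0, 0.9), (1.1, 1.7))
        assert abs(qxy[np.argmax(prof)] - 1.45) <= float(np.diff(gm.qxy).max())

    def test_two_peak_map_has_two_maxima(self):
        from scipy.signal import find_peaks

        gm = syn.gen_map(syn.MapParams())
        (qxy, prof), _ = extract_profiles(gm, (0.0, 0.9), (1.1, 1.7))
        idx, _ = find_peaks(prof, prominence=0.1 * prof.max())
        assert idx.size == 2

    def test_empty_band_rejected(self):
        gm = syn.gen_map(syn.MapParams())
        with pytest.raises(ValueError):
            extract_profiles(gm, (5.0, 6.0), (1.1, 1.7))


def lorentzian(x, center, fwhm, amp):
    return amp * (fwhm / 2) ** 2 / ((x - center) ** 2 + (fwhm / 2) ** 2)


class TestFitBraggPeaks:
    def test_noiseless_lorentzian_recovery(self):
        x = np.arange(1.4, 1.6, 0.001)
        y = lorentzian(x, 1.489, 0.01, 500.0)
        (pk,) = fit_bragg_peaks(x, y, 1)
        assert pk.qxy == pytest.approx(1.489, abs=1e-4)
        assert pk.fwhm_qxy == pytest.approx(0.01, abs=1e-4)

    def test_two_overlapping_lorentzians(self):
        x = np.arange(1.25, 1.60, 0.001)
        y = lorentzian(x, 1.344, 0.024, 200.0) + lorentzian(x, 1.458, 0.010, 500.0) + 5.0
        p1, p2 = fit_bragg_peaks(x, y, 2)
        assert p1.qxy == pytest.approx(1.344, abs=0.002)
        assert p2.qxy == pytest.approx(1.458, abs=0.002)

    def test_flat_profile_errors(self):
        x = np.arange(1.2, 1.6, 0.002)
        with pytest.raises(FitError):
            fit_bragg_peaks(x, np.full_like(x, 7.0), 1)


class TestFitRod:
    def test_tilted_rod_center(self):
        qz = np.arange(0.0, 1.2, 0.01)
        sig = 0.3 / (2 * math.sqrt(2 * math.log(2)))
        rod = 100 * np.exp(-0.5 * ((qz - 0.693) / sig) ** 2) + 2
        center, fwhm = fit_rod(qz, rod)
        assert center == pytest.approx(0.693, abs=0.005)
        assert fwhm == pytest.approx(0.3, abs=0.01)

    def test_horizon_rod_center_zero(self):
        qz = np.arange(0.0, 0.9, 0.01)
        sig = 0.12
        rod = 50 * np.exp(-0.5 * (qz / sig) ** 2)
        center, _ = fit_rod(qz, rod)
        assert center == pytest.approx(0.0, abs=0.01)

    def test_all_zero_rod_errors(self):
        qz = np.arange(0.0, 0.9, 0.01)
        with pytest.raises(FitError):
            fit_rod(qz, np.zeros_like(qz))


class TestIndexLattice:
    def test_hexagonal_from_single_peak(self):
        # Qxy = 1.489 ⇒ d = 4.22 Å, a = 4.87 Å, γ = 120°
        lat = index_lattice([BraggPeak(qxy=1.489, qz=0.0)])
        assert lat.lattice_class == "hexagonal"
        assert lat.d_spacings[(1, 0)] == pytest.approx(4.22, abs=0.005)
        assert lat.a == pytest.approx(4.87, abs=0.005)
        assert lat.gamma == 120.0
        assert lat.a == pytest.approx(2 * (2 * math.pi / 1.489) / math.sqrt(3), rel=1e-12)

    def test_centered_rectangular_from_two_peaks(self):
        # drug-mixture condensed phase: a = 5.55, b = 8.62 Å, A_uc = 47.86 Å²
        peaks = [BraggPeak(qxy=1.458, qz=0.0), BraggPeak(qxy=1.346, qz=0.681)]
        lat = index_lattice(peaks)
        assert lat.lattice_class == "centered-rectangular"
        assert lat.a == pytest.approx(5.55, abs=0.005)
        assert lat.b == pytest.approx(8.62, abs=0.005)
        assert lat.area_per_cell == pytest.approx(47.86, abs=0.01)
        assert lat.d_spacings[(0, 2)] == pytest.approx(4.31, abs=0.005)

    def test_unit_qxy(self):
        lat = index_lattice([BraggPeak(qxy=2 * math.pi, qz=0.0)])
        assert lat.d_spacings[(1, 0)] == pytest.approx(1.0, rel=1e-12)

    def test_more_than_two_peaks_rejected(self):
        with pytest.raises(FitError):
            index_lattice([BraggPeak(qxy=q, qz=0.0) for q in (1.3, 1.4, 1.5)])

    def test_ambiguous_rod_pattern_rejected(self):
        with pytest.raises(FitError, match="horizon"):
            index_lattice([BraggPeak(qxy=1.458, qz=0.0), BraggPeak(qxy=1.346, qz=0.0)])

    @given(
        a=st.floats(4.0, 7.0),
        b_over_a=st.floats(1.2, 2.2),
    )
    @settings(derandomize=True, max_examples=50)
    def test_rectangular_round_trip(self, a, b_over_a):
        b = a * b_over_a
        q02 = 2 * math.pi / (b / 2)
        d11 = (1 / a**2 + 1 / b**2) ** -0.5
        q11 = 2 * math.pi / d11
        lat = index_lattice([BraggPeak(qxy=q02, qz=0.0), BraggPeak(qxy=q11, qz=0.4)])
        assert lat.a == pytest.approx(a, rel=1e-6)
        assert lat.b == pytest.approx(b, rel=1e-6)
        assert lat.area_per_cell == pytest.approx(a * b, rel=1e-6)


class TestTiltAngle:
    def test_printed_peak_positions(self):
        peaks = [BraggPeak(qxy=1.458, qz=0.0), BraggPeak(qxy=1.346, qz=0.681)]
        lat = index_lattice(peaks)
        assert tilt_angle(lat, peaks) == pytest.approx(31.0, abs=0.15)

    def test_untilted_hexagonal(self):
        peaks = [BraggPeak(qxy=1.489, qz=0.0)]
        lat = index_lattice(peaks)
        assert tilt_angle(lat, peaks) == 0.0

    def test_water_subphase_peak_positions(self):
        # nearest-neighbour azimuth gives 31.5° from the rounded maxima
        peaks = [BraggPeak(qxy=1.458, qz=0.0), BraggPeak(qxy=1.344, qz=0.693)]
        lat = index_lattice(peaks)
        assert tilt_angle(lat, peaks) == pytest.approx(31.5, abs=0.15)

    def test_model_violation_rejected(self):
        peaks = [BraggPeak(qxy=1.458, qz=0.2), BraggPeak(qxy=1.346, qz=0.681)]
        with pytest.raises(FitError):
            index_lattice(peaks)


class TestCoherenceLength:
    def test_direct_ratio(self):
        length, limited = coherence_length(0.01)
        assert length == pytest.approx(200.0)
        assert not limited

    def test_printed_length_inversion(self):
        length, _ = coherence_length(2 / 382.0)
        assert length == pytest.approx(382.0, rel=1e-12)

    def test_resolution_limited_flagged(self):
        _, limited = coherence_length(0.005)
        assert limited

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            coherence_length(0.0)


class TestPipelineRecovery:
    @pytest.mark.parametrize("preset,n_peaks", [("dppc_ptx_epi", 2), ("dmps_water", 1)])
    def test_noisy_map_parameter_recovery(self, preset, n_peaks):
        truth = syn.MAP_PRESETS[preset]
        for seed in range(5):
            gm = syn.gen_map(syn.MapParams(peaks=truth, poisson=True, seed=seed))
            lat = analyze_map(gm, n_peaks=n_peaks)
            if n_peaks == 2:
                assert lat.lattice_class == "centered-rectangular"
                assert lat.tilt == pytest.approx(31.04, abs=0.5)
            else:
                assert lat.lattice_class == "hexagonal"
                assert lat.tilt == 0.0
                assert lat.a == pytest.approx(4.87, abs=0.01)
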