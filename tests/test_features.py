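import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import semgrasp as sg
from semgrasp.features import SpectrumEstimate, max_peen

FS = 500.0

finite_signals = arrays(
    np.float64, st.integers(4, 200),
    elements=st.floats(-100, 100, allow_nan=False, allow_infinity=False),
)


class TestMav:
    def test_hand_computed_example(self):
        assert sg.mav(np.array([1.0, -1.0, 2.0, -2.0])) == pytest.approx(1.5)

    def test_constant_signal(self):
        assert sg.mav(np.full(17, -3.2)) == pytest.approx(3.2)

    @given(sig=finite_signals, scale=st.floats(-10, 10, allow_nan=False))
    def test_homogeneous_degree_one(self, sig, scale):
        assert sg.mav(scale * sig) == pytest.approx(abs(scale) * sg.mav(sig), abs=1e-9)

    def test_empty_signal_raises(self):
        with pytest.raises(ValueError):
            sg.mav(np.array([]))


class TestSpectrum:
    def test_pure_tone_concentrates_in_one_bin(self):
        t = np.arange(2000) / FS
        spec = sg.estimate_spectrum(np.sin(2 * np.pi * 50 * t), FS)
        non_dc = spec.powers[1:]
        peak = spec.freqs[1 + int(np.argmax(non_dc))]
        assert peak == pytest.approx(50.0)
        assert non_dc.max() / non_dc.sum() > 0.99

    def test_parseval_total_power_matches_mean_square(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4096)
        spec = sg.estimate_spectrum(x, FS)
        assert spec.total_power == pytest.approx(np.mean(x**2), rel=0.05)

    def test_zero_signal_gives_zero_power(self):
        spec = sg.estimate_spectrum(np.zeros(64), FS)
        assert spec.total_power == 0.0


def brute_force_mdf(freqs, powers):
    """Oracle: scan the cumulative sum for the first bin reaching half."""
    half = powers.sum() / 2.0
    acc = 0.0
    for f, p in zip(freqs, powers):
        acc += p
        if acc >= half:
            return f
    raise AssertionError("unreachable for positive total power")


def brute_force_mnf(freqs, powers):
    return sum(f * p for f, p in zip(freqs, powers)) / powers.sum()


class TestMdfMnf:
    def test_all_power_in_one_bin(self):
        spec = SpectrumEstimate(freqs=np.array([10.0, 50.0, 90.0]),
                                powers=np.array([0.0, 4.0, 0.0]))
        assert sg.mdf(spec) == 50.0
        assert sg.mnf(spec) == 50.0

    def test_mdf_tie_takes_first_bin_reaching_half(self):
        spec = SpectrumEstimate(freqs=np.array([10.0, 90.0]),
                                powers=np.array([1.0, 1.0]))
        assert sg.mdf(spec) == 10.0

    def test_mnf_equal_power_two_bins_is_midpoint(self):
        spec = SpectrumEstimate(freqs=np.array([10.0, 90.0]),
                                powers=np.array([1.0, 1.0]))
        assert sg.mnf(spec) == pytest.approx(50.0)

    def test_flat_spectrum_median_is_50th_bin(self):
        freqs = np.arange(1.0, 101.0)
        spec = SpectrumEstimate(freqs=freqs, powers=np.ones(100))
        assert sg.mdf(spec) == freqs[49] == brute_force_mdf(freqs, np.ones(100))

    @given(
        powers=arrays(np.float64, st.integers(2, 60),
                      elements=st.floats(0, 10, allow_nan=False)),
    )
    def test_matches_direct_summation_oracles(self, powers):
        if powers.sum() <= 0:
            return
        freqs = np.arange(1.0, powers.size + 1.0) * 2.5
        spec = SpectrumEstimate(freqs=freqs, powers=powers)
        assert sg.mdf(spec) == pytest.approx(brute_force_mdf(freqs, powers), abs=1e-12)
        assert sg.mnf(spec) == pytest.approx(brute_force_mnf(freqs, powers), abs=1e-12)
        assert freqs[0] <= sg.mnf(spec) <= freqs[-1]
        assert freqs[0] <= sg.mdf(spec) <= freqs[-1]

    def test_zero_power_raises(self):
        spec = SpectrumEstimate(freqs=np.array([1.0, 2.0]), powers=np.zeros(2))
        with pytest.raises(ValueError):
            sg.mdf(spec)
        with pytest.raises(ValueError):
            sg.mnf(spec)


def exhaustive_peen(signal, m, delay):
    """Oracle: count ordinal patterns with explicit tuples."""
    n = len(signal) - (m - 1) * delay
    counts = {}
    for i in range(n):
        vec = [signal[i + j * delay] for j in range(m)]
        pattern = tuple(sorted(range(m), key=lambda j: (vec[j], j)))
        counts[pattern] = counts.get(pattern, 0) + 1
    return -sum((c / n) * math.log(c / n) for c in counts.values())


class TestPeen:
    def test_monotone_series_has_zero_entropy(self):
        assert sg.peen(np.arange(50.0), m=3) == 0.0

    def test_uniform_patterns_reach_log_m_factorial(self):
        # This 14-point sequence visits each of the 6 ordinal patterns of
        # m=3 exactly twice (verified by the exhaustive oracle below), so
        # the entropy attains its maximum ln(3!) exactly.
        sig = np.array([3, 2, 0, 5, 4, 7, 13, 10, 11, 6, 9, 12, 8, 1], dtype=float)
        assert exhaustive_peen(sig, 3, 1) == pytest.approx(math.log(6), abs=1e-12)
        assert sg.peen(sig, m=3) == pytest.approx(math.log(6), abs=1e-12)
        # m=2: an alternating series has equal up/down counts, entropy ln 2.
        alt = np.array([0.0, 1.0] * 10 + [0.0])
        assert sg.peen(alt, m=2) == pytest.approx(math.log(2), abs=1e-12)

    def test_iid_noise_approaches_ln6(self):
        rng = np.random.default_rng(7)
        sig = rng.normal(size=2000)
        assert abs(sg.peen(sig, m=3) - math.log(6)) < 0.05

    @given(sig=finite_signals)
    def test_matches_exhaustive_oracle(self, sig):
        assert sg.peen(sig, m=3, delay=1) == pytest.approx(
            exhaustive_peen(sig, 3, 1), abs=1e-12
        )

    @given(sig=finite_signals)
    def test_invariant_under_monotone_transform(self, sig):
        # Scaling by a power of two is exactly order-preserving in floats.
        assert sg.peen(4.0 * sig, m=3) == sg.peen(sig, m=3)

    def test_invariant_under_nonlinear_monotone_transform(self):
        rng = np.random.default_rng(9)
        sig = rng.permutation(500) / 500.0
        assert sg.peen(np.exp(sig), m=3) == sg.peen(sig, m=3)
        assert sg.peen(sig**3, m=3) == sg.peen(sig, m=3)

    def test_bounded_by_ln_m_factorial(self):
        rng = np.random.default_rng(1)
        for m in (2, 3, 4):
            val = sg.peen(rng.normal(size=500), m=m)
            assert 0 <= val <= max_peen(m) + 1e-12

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            sg.peen(np.array([1.0, 2.0]), m=3, delay=2)

    def test_pattern_probabilities_sum_to_one_and_give_entropy(self):
        from semgrasp.features import ordinal_pattern_probabilities
        rng = np.random.default_rng(2)
        sig = rng.normal(size=300)
        p = ordinal_pattern_probabilities(sig, m=3)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p > 0) and p.size <= 6
        assert sg.peen(sig, m=3) == pytest.approx(float(-(p * np.log(p)).sum()))


@pytest.fixture(scope="module")
def mode_sets(two_tone):
    _, sig = two_tone
    win = sg.Window(
        samples=np.column_stack([sig, sig]),
        class_label="CY", subject_id="s1", source_trial=0, start_index=0,
        sample_rate_hz=FS,
    )
    return sg.decompose_window(win, sg.VmdConfig(K=10))


class TestExtractFeatures:

    def test_two_channels_k10_gives_88_features(self, mode_sets):
        fv = sg.extract_features(mode_sets, class_label="CY")
        assert fv.values.size == 88
        assert len(fv.names) == 88 == len(set(fv.names))
        assert np.all(np.isfinite(fv.values))

    def test_one_channel_k4_gives_20_features(self, two_tone):
        _, sig = two_tone
        ms = sg.vmd_decompose(sig, FS, sg.VmdConfig(K=4))
        fv = sg.extract_features([ms])
        assert fv.values.size == 20  # 1 x (4 + 1) x 4

    def test_identical_channels_give_identical_blocks(self, mode_sets):
        fv = sg.extract_features(mode_sets)
        assert np.array_equal(fv.values[:44], fv.values[44:])

    def test_name_ordering_channel_major(self):
        names = sg.feature_names(2, 2)
        assert names[0] == "ch1/VMF01/MAV"
        assert names[4] == "ch1/VMF02/MAV"
        assert names[8] == "ch1/RES/MAV"
        assert names[12] == "ch2/VMF01/MAV"
        assert names[-1] == "ch2/RES/PeEn"

    def test_scale_invariance_of_frequency_and_entropy_features(self, two_tone):
        """MDF/MNF/PeEn unchanged, MAV scaled, under amplitude scaling."""
        _, sig = two_tone
        ms1 = sg.vmd_decompose(sig, FS, sg.VmdConfig(K=3))
        ms2 = sg.vmd_decompose(5.0 * sig, FS, sg.VmdConfig(K=3))
        fv1 = sg.extract_features([ms1])
        fv2 = sg.extract_features([ms2])
        for i, name in enumerate(fv1.names):
            kind = name.rsplit("/", 1)[1]
            if kind == "MAV":
                assert fv2.values[i] == pytest.approx(5.0 * fv1.values[i], rel=1e-6)
            else:
                assert fv2.values[i] == pytest.approx(fv1.values[i], rel=1e-6, abs=1e-9)
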