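import numpy as np
import pytest

from pcg_chd.emd import (
    ImfDecomposition,
    ShallowDecompositionError,
    decompose,
    denoise,
    denoise_signal,
    find_extrema,
    sift_once,
)
from pcg_chd.synthetic_pcg import SynthParams, synth_recording

from .oracles import reference_emd


def _corr(a, b):
    return np.corrcoef(a, b)[0, 1]


class TestFindExtrema:
    def test_single_peak(self):
        mx, mn = find_extrema([1, 3, 1])
        assert mx.tolist() == [1] and mn.tolist() == []

    def test_monotone_has_no_extrema(self):
        mx, mn = find_extrema([1, 2, 3, 4])
        assert mx.size == 0 and mn.size == 0

    def test_sine_extrema_match_brute_force_scan(self):
        t = np.arange(1000) / 1000.0
        x = np.sin(2 * np.pi * 5 * t)
        mx, mn = find_extrema(x)
        assert mx.size == 5 and mn.size == 5
        # alternation and agreement with a direct first-difference scan
        brute_mx = [i for i in range(1, 999) if x[i] > x[i - 1] and x[i] > x[i + 1]]
        brute_mn = [i for i in range(1, 999) if x[i] < x[i - 1] and x[i] < x[i + 1]]
        assert mx.tolist() == brute_mx and mn.tolist() == brute_mn
        merged = sorted([(i, "M") for i in mx] + [(i, "m") for i in mn])
        kinds = "".join(k for _, k in merged)
        assert "MM" not in kinds and "mm" not in kinds

    def test_plateau_contributes_midpoint(self):
        mx, mn = find_extrema([0, 1, 2, 2, 2, 1, 0])
        assert mx.tolist() == [3] and mn.tolist() == []

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            find_extrema([1, 2])


class TestSiftOnce:
    def test_pure_sine_is_nearly_fixed_point(self):
        t = np.arange(2000) / 2000.0
        x = np.sin(2 * np.pi * 10 * t)
        y = sift_once(x)
        interior = slice(200, -200)
        assert np.max(np.abs(y[interior] - x[interior])) < 1e-3

    def test_constant_offset_absorbed_into_envelope_mean(self):
        t = np.arange(2000) / 2000.0
        x = np.sin(2 * np.pi * 10 * t)
        y = sift_once(x + 3.0)
        interior = slice(200, -200)
        assert np.max(np.abs(y[interior] - x[interior])) < 1e-2

    def test_too_few_extrema_raises(self):
        with pytest.raises(ValueError, match="maxima"):
            sift_once(np.linspace(0, 1, 64))


class TestDecompose:
    def test_constant_signal_yields_no_imfs(self):
        dec = decompose(np.ones(64))
        assert dec.n_imfs == 0
        np.testing.assert_array_equal(dec.residual, np.ones(64))

    def test_completeness_on_random_signals(self, rng):
        for _ in range(20):
            x = rng.standard_normal(256)
            dec = decompose(x)
            err = np.linalg.norm(dec.reconstruct() - x) / np.linalg.norm(x)
            assert err <= 1e-8

    def test_imf_extrema_zero_crossing_balance(self, rng, two_tone):
        """IMFs oscillate about zero: extrema and zero-crossing counts agree.

        The Cauchy sift stop (SD < 0.2) yields *approximately* symmetric
        modes, so broadband-noise IMFs are allowed a small relative slack;
        the smooth two-tone IMFs must satisfy the balance within 1.
        """
        mixed, _, _ = two_tone
        for k, h in enumerate(decompose(mixed).imfs[:2]):
            mx, mn = find_extrema(h)
            zc = np.sum(np.diff(np.signbit(h[np.abs(h) > 1e-12])) != 0)
            assert abs((mx.size + mn.size) - zc) <= 1
        x = rng.standard_normal(512)
        dec = decompose(x)
        assert dec.n_imfs >= 2
        for h in dec.imfs[:-1]:  # last IMF can be boundary-dominated
            mx, mn = find_extrema(h)
            zc = np.sum(np.diff(np.signbit(h[np.abs(h) > 1e-12])) != 0)
            n_ext = mx.size + mn.size
            assert abs(n_ext - zc) <= max(2, 0.05 * n_ext)

    def test_two_tone_separation(self, two_tone):
        mixed, slow, fast = two_tone
        dec = decompose(mixed)
        assert dec.n_imfs >= 2
        assert _corr(dec.imfs[0], fast) > 0.9
        assert _corr(dec.imfs[1], slow) > 0.9

    def test_agrees_with_independent_reference_emd(self, two_tone):
        mixed, _, _ = two_tone
        ours = decompose(mixed)
        ref_imfs, _ = reference_emd(mixed)
        assert len(ref_imfs) >= 2
        for k in range(2):
            assert _corr(ours.imfs[k], ref_imfs[k]) > 0.95

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError):
            decompose(np.zeros(8))


class TestDenoise:
    def _fake(self, n_imfs, length=32):
        imfs = [np.full(length, float(k + 1)) for k in range(n_imfs)]
        return ImfDecomposition(imfs=imfs, residual=np.zeros(length))

    @pytest.mark.parametrize(
        "n,expected_sum",
        [(4, 2.0), (5, 2.0 + 3.0), (6, 2.0 + 3.0 + 4.0)],
    )
    def test_keeps_modes_two_through_n_minus_two(self, n, expected_sum):
        out = denoise(self._fake(n))
        np.testing.assert_allclose(out, expected_sum)

    def test_shallow_decomposition_errors_or_passes_through(self):
        dec = self._fake(3)
        with pytest.raises(ShallowDecompositionError):
            denoise(dec)
        np.testing.assert_allclose(denoise(dec, on_shallow="passthrough"), 1.0 + 2.0 + 3.0)

    def test_denoising_recovers_clean_pcg_better_than_raw(self):
        """At 10 dB SNR the denoised signal should track the clean recording
        more closely than the noisy input does, in most random trials."""
        wins = 0
        trials = 10
        for trial in range(trials):
            params = SynthParams(fs=2000.0, duration_s=3.0, snr_db=10.0, seed=900 + trial)
            clean = synth_recording("normal", SynthParams(**{**params.__dict__, "snr_db": 200.0}))
            noisy = synth_recording("normal", params)
            den = denoise_signal(noisy.samples)
            if _corr(den, clean.samples) > _corr(noisy.samples, clean.samples):
                wins += 1
        assert wins >= 9
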