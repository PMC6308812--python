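"""Feature extractors vs. independent oracles: PSD, Yule-Walker AR, SampEn/MSE."""

import math

import numpy as np
import pytest
from statsmodels.regression.linear_model import yule_walker
from statsmodels.tsa.arima_process import arma_acovf

from drowsyeeg.bands import BANDS_11, Band
from drowsyeeg.features import (
    ARCoefficients,
    MultiscaleEntropy,
    PSDBandPower,
    ar_from_autocov,
    coarse_grain,
    compute_ar_coeffs,
    compute_mse,
    compute_psd_bands,
    sample_entropy,
)

FS = 512


# ---------------------------------------------------------------------------
# PSD band power
# ---------------------------------------------------------------------------

class TestPSDBands:
    def test_interior_tone_concentrates_in_its_band(self):
        """A tone away from band edges leaves >=95% of 1-100 Hz power in
        its band: the Blackman mainlobe (+/-3 bins at 0.1 Hz resolution)
        stays interior to 10-12 Hz for an 11 Hz tone."""
        t = np.arange(10 * FS) / FS
        x = np.sin(2 * np.pi * 11.0 * t)
        powers = compute_psd_bands(x, FS)
        total = sum(powers.values())
        assert powers["band_10_12"] / total >= 0.95

    def test_half_open_convention_assigns_edge_tone_upward(self):
        """A tone at exactly 10 Hz belongs to [10, 12) under the half-open
        rule: that band receives the single largest share."""
        t = np.arange(10 * FS) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        powers = compute_psd_bands(x, FS)
        assert max(powers, key=powers.get) == "band_10_12"

    def test_white_noise_power_proportional_to_bandwidth(self, rng):
        """Flat-spectrum oracle: averaged over many draws, per-Hz power
        density is equal across bands within 10%."""
        acc = {b.name: 0.0 for b in BANDS_11}
        n_draws = 400
        for _ in range(n_draws):
            powers = compute_psd_bands(rng.standard_normal(2 * FS), FS)
            for k, v in powers.items():
                acc[k] += v
        densities = {
            b.name: acc[b.name] / n_draws / (b.high - b.low) for b in BANDS_11
        }
        vals = np.array(list(densities.values()))
        assert vals.max() / vals.min() < 1.10

    def test_zero_signal_zero_power(self):
        powers = compute_psd_bands(np.zeros(2 * FS), FS)
        assert all(v == 0 for v in powers.values())

    def test_scale_covariance(self, rng):
        """Multiplying the signal by c multiplies every band power by c^2."""
        x = rng.standard_normal(4 * FS)
        p1 = compute_psd_bands(x, FS)
        p2 = compute_psd_bands(3.0 * x, FS)
        for k in p1:
            assert p2[k] == pytest.approx(9.0 * p1[k], rel=1e-9)

    def test_notch_gap_band_set_respected(self):
        names = [b.name for b in BANDS_11]
        assert "band_40_49" in names and "band_51_65" in names
        assert not any(b.contains(50.0) for b in BANDS_11)

    def test_transformer_matches_function(self, rng):
        X = rng.standard_normal((3, 2 * FS))
        tr = PSDBandPower(fs=FS)
        out = tr.fit_transform(X)
        row = compute_psd_bands(X[1], FS)
        np.testing.assert_allclose(out[1], [row[b.name] for b in BANDS_11])
        assert list(tr.get_feature_names_out()) == [b.name for b in BANDS_11]


# ---------------------------------------------------------------------------
# Yule-Walker AR coefficients
# ---------------------------------------------------------------------------

class TestARCoefficients:
    def test_matches_statsmodels_yule_walker(self, rng):
        x = rng.standard_normal(4096)
        ours = compute_ar_coeffs(x, order=5)
        theirs, _ = yule_walker(x, order=5, method="mle")
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_recovers_ar1_coefficient(self):
        """a1 = 0.5 +/- 0.05 from long AR(1) realizations (20 seeds)."""
        ests = []
        for s in range(20):
            rng = np.random.default_rng(s)
            e = rng.standard_normal(30720)
            x = np.empty_like(e)
            x[0] = e[0]
            for t in range(1, len(e)):
                x[t] = 0.5 * x[t - 1] + e[t]
            ests.append(compute_ar_coeffs(x, order=5))
        mean = np.mean(ests, axis=0)
        assert mean[0] == pytest.approx(0.5, abs=0.05)
        assert np.all(np.abs(mean[1:]) < 0.05)

    def test_white_noise_coefficients_near_zero(self):
        coeffs = [
            compute_ar_coeffs(np.random.default_rng(s).standard_normal(8192))
            for s in range(10)
        ]
        assert np.all(np.abs(np.mean(coeffs, axis=0)) < 0.05)

    def test_exact_recovery_from_exact_autocovariances(self):
        """Feeding the theoretical autocovariance sequence of a stable AR(5)
        to the solver returns the generating coefficients exactly."""
        a = np.array([0.4, -0.2, 0.1, 0.05, -0.08])
        acov = arma_acovf(np.r_[1, -a], np.array([1.0]), nobs=6)
        np.testing.assert_allclose(ar_from_autocov(acov, 5), a, atol=1e-10)

    def test_constant_signal_raises_singularity_error(self):
        with pytest.raises(ValueError, match="singular"):
            compute_ar_coeffs(np.full(100, 2.0))

    def test_transformer_shape_and_names(self, rng):
        out = ARCoefficients().fit_transform(rng.standard_normal((4, 1000)))
        assert out.shape == (4, 5)


# ---------------------------------------------------------------------------
# Sample entropy / multiscale entropy
# ---------------------------------------------------------------------------

def sampen_bruteforce(x, m=2, r=None):
    """O(n^2) exhaustive template-pair oracle for sample entropy."""
    x = np.asarray(x, float)
    n = len(x)
    if r is None:
        r = 0.15 * x.std()
    b = a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if b == 0 or a == 0:
        return float("nan")
    return -math.log(a / b)


def _pink_noise(rng, n):
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    x = np.fft.irfft(spec / np.sqrt(f), n)
    return x / x.std()


class TestCoarseGrain:
    def test_scale_one_is_identity(self, rng):
        x = rng.standard_normal(50)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_block_means(self):
        np.testing.assert_allclose(coarse_grain([1, 2, 3, 4], 2), [1.5, 3.5])

    def test_floor_division_length(self):
        assert coarse_grain(np.arange(5120.0), 20).size == 256

    def test_tail_dropped(self):
        np.testing.assert_allclose(coarse_grain([1, 2, 3, 4, 5], 2), [1.5, 3.5])


class TestSampleEntropy:
    def test_alternating_series_has_zero_entropy(self):
        """Every m-match of a strict period-2 series extends to m+1: A = B."""
        x = np.tile([1.0, -1.0], 50)
        assert sample_entropy(x) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 201))
        x = rng.standard_normal(n)
        ours = sample_entropy(x)
        ref = sampen_bruteforce(x)
        if math.isnan(ref):
            assert math.isnan(ours)
        else:
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_shuffling_does_not_decrease_entropy(self):
        """Destroying temporal structure of an AR(1) series raises SampEn
        on average (complexity ordering, 50 seeds)."""
        diffs = []
        for s in range(50):
            rng = np.random.default_rng(s)
            e = rng.standard_normal(400)
            x = np.empty_like(e)
            x[0] = e[0]
            for t in range(1, len(e)):
                x[t] = 0.9 * x[t - 1] + e[t]
            shuffled = rng.permutation(x)
            diffs.append(sample_entropy(shuffled) - sample_entropy(x))
        assert np.mean(diffs) > 0

    def test_zero_variance_flagged_undefined(self):
        assert math.isnan(sample_entropy(np.ones(100)))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            sample_entropy(np.array([1.0, 2.0]))


class TestMultiscaleEntropy:
    def test_white_decreases_pink_flatter(self):
        """Canonical MSE signature: white-noise entropy falls with scale;
        1/f noise keeps a flatter profile (mean over 30 seeds)."""
        drops_white, drops_pink = [], []
        for s in range(30):
            rng = np.random.default_rng(s)
            w = compute_mse(rng.standard_normal(2000), n_scales=8)
            p = compute_mse(_pink_noise(rng, 2000), n_scales=8)
            drops_white.append(w[0] - w[-1])
            drops_pink.append(p[0] - p[-1])
        assert np.mean(drops_white) > 0
        assert np.mean(drops_white) > np.mean(drops_pink)

    def test_single_scale_equals_raw_sample_entropy(self, rng):
        x = rng.standard_normal(500)
        mse = compute_mse(x, n_scales=1)
        assert mse[0] == pytest.approx(sample_entropy(x), abs=1e-12)

    def test_constant_signal_all_scales_undefined(self):
        mse = compute_mse(np.full(1000, 5.0), n_scales=5)
        assert np.all(np.isnan(mse))

    def test_precondition_on_coarsest_scale_length(self):
        with pytest.raises(ValueError, match="scale"):
            compute_mse(np.random.default_rng(0).standard_normal(200), n_scales=20)

    def test_transformer_names(self, rng):
        tr = MultiscaleEntropy(n_scales=4)
        out = tr.fit_transform(rng.standard_normal((2, 500)))
        assert out.shape == (2, 4)
        assert list(tr.get_feature_names_out()) == [
            "mse_scale_1", "mse_scale_2", "mse_scale_3", "mse_scale_4",
        ]


def test_band_validation_rejects_overlap():
    with pytest.raises(ValueError, match="overlap"):
        compute_psd_bands(np.zeros(1024), FS, [Band("a", 1, 5), Band("b", 4, 8)])
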