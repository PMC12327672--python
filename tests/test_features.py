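"""Feature extraction: closed-form and brute-force oracles for moments,
Hjorth, fractal dimensions, entropies, DFA, spectra, wavelets, CSP and
connectivity measures."""

import numpy as np
import pytest
from scipy import linalg

from eegflow.features import (EEG_BANDS, approx_entropy, band_power, coherence,
                              csp_fit, csp_transform, dfa, dwt_features,
                              extract, higuchi_fd, hjorth, katz_fd,
                              phase_slope_index, relative_band_power,
                              sample_entropy, shannon_entropy, stft_features,
                              tdf_moments, welch_psd, xcorr)
from eegflow.signal_model import EpochSet

FS = 250.0


class TestMoments:
    def test_constant_signal_flagged(self):
        m = tdf_moments(np.full(100, 2.0))
        assert m["variance"] == 0.0
        assert np.isnan(m["skewness"]) and np.isnan(m["kurtosis"])

    def test_symmetric_signal_zero_skew(self):
        x = np.sin(np.linspace(0, 8 * np.pi, 4000))
        assert abs(tdf_moments(x)["skewness"]) < 1e-9

    def test_gaussian_excess_kurtosis_near_zero(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        assert abs(tdf_moments(x)["kurtosis"]) < 0.05

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            tdf_moments(np.array([1.0, 2.0]))


class TestHjorth:
    def test_sine_mobility_closed_form(self):
        # first difference of a sampled sinusoid scales by 2 sin(pi f / fs)
        t = np.arange(0, 40, 1 / FS)
        x = np.sin(2 * np.pi * 10.0 * t)
        h = hjorth(x)
        assert h["mobility"] == pytest.approx(2 * np.sin(np.pi * 10 / FS),
                                              rel=1e-3)

    def test_sine_complexity_is_one(self):
        t = np.arange(0, 40, 1 / FS)
        h = hjorth(np.sin(2 * np.pi * 10.0 * t))
        assert h["complexity"] == pytest.approx(1.0, rel=1e-3)

    def test_scaling_homogeneity(self):
        x = np.random.default_rng(1).standard_normal(5000)
        h1, h3 = hjorth(x), hjorth(3.0 * x)
        assert h3["activity"] == pytest.approx(9 * h1["activity"], rel=1e-9)
        assert h3["mobility"] == pytest.approx(h1["mobility"], rel=1e-9)
        assert h3["complexity"] == pytest.approx(h1["complexity"], rel=1e-9)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            hjorth(np.ones(100))


class TestFractalDimensions:
    def test_katz_line_is_one(self):
        assert katz_fd(np.linspace(0, 5, 500)) == pytest.approx(1.0, abs=1e-9)

    def test_higuchi_smooth_sine_near_one(self):
        t = np.linspace(0, 8 * np.pi, 1000)
        assert higuchi_fd(np.sin(t)) == pytest.approx(1.0, abs=0.1)

    def test_higuchi_white_noise_near_two(self):
        x = np.random.default_rng(2).standard_normal(5000)
        assert higuchi_fd(x) == pytest.approx(2.0, abs=0.15)

    def test_higuchi_monotone_in_noise_mixing(self):
        """FD grows monotonically from sine (≈1) to white noise (≈2)."""
        t = np.linspace(0, 8 * np.pi, 2000)
        sine = np.sin(t)
        levels = [0.0, 0.05, 0.2, 0.6, 3.0]
        fds = []
        for seed in range(10):
            noise = np.random.default_rng(seed).standard_normal(2000)
            fds.append([higuchi_fd(sine + a * noise) for a in levels])
        mean_fd = np.mean(fds, axis=0)
        assert np.all(np.diff(mean_fd) > 0)

    def test_higuchi_input_length(self):
        with pytest.raises(ValueError):
            higuchi_fd(np.ones(10), k_max=10)


def sampen_bruteforce(x, m, r):
    """O(n²) template counting, self-matches excluded (independent oracle)."""
    n = len(x)
    b = a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return -np.log(a / b)


def apen_bruteforce(x, m, r):
    """Direct Φ_m − Φ_{m+1} with self-matches (independent oracle)."""
    def phi(mm):
        n = len(x) - mm + 1
        total = 0.0
        for i in range(n):
            c = 0
            for j in range(n):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
            total += np.log(c / n)
        return total / n
    return phi(m) - phi(m + 1)


class TestEntropies:
    def test_constant_signal_sampen_zero(self):
        assert sample_entropy(np.ones(50)) == 0.0

    def test_uniform_histogram_shannon(self):
        # 16 bins each holding the same count -> exactly 4 bits
        x = np.repeat(np.arange(16) + 0.5, 10)
        assert shannon_entropy(x, n_bins=16) == pytest.approx(4.0, abs=1e-12)

    def test_sampen_matches_bruteforce(self):
        x = np.random.default_rng(3).standard_normal(200)
        r = 0.2 * x.std()
        assert sample_entropy(x, 2, r) == pytest.approx(
            sampen_bruteforce(x, 2, r), abs=1e-12)

    def test_apen_matches_bruteforce(self):
        x = np.random.default_rng(4).standard_normal(120)
        r = 0.2 * x.std()
        assert approx_entropy(x, 2, r) == pytest.approx(
            apen_bruteforce(x, 2, r), abs=1e-12)

    def test_sampen_undefined_flagged(self):
        x = np.arange(20.0)  # no matches at tiny radius
        with pytest.warns(UserWarning, match="no template"):
            v = sample_entropy(x, 2, 1e-12)
        assert np.isnan(v)


class TestDFA:
    def test_white_noise_alpha_half(self):
        x = np.random.default_rng(5).standard_normal(4096)
        assert dfa(x) == pytest.approx(0.5, abs=0.1)

    def test_brownian_alpha_three_halves(self):
        x = np.cumsum(np.random.default_rng(6).standard_normal(4096))
        assert dfa(x) == pytest.approx(1.5, abs=0.15)

    def test_amplitude_invariance(self):
        x = np.random.default_rng(7).standard_normal(2048)
        assert dfa(5.0 * x) == pytest.approx(dfa(x), abs=1e-9)

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            dfa(np.ones(10))


class TestSpectral:
    def test_relative_powers_form_simplex(self):
        x = np.random.default_rng(8).standard_normal(5000)
        f, psd = welch_psd(x, FS, 512)
        rel = relative_band_power(f, psd)
        assert sum(rel.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in rel.values())

    def test_alpha_sine_dominates(self):
        t = np.arange(0, 20, 1 / FS)
        x = 10 * np.sin(2 * np.pi * 10 * t) + \
            0.5 * np.random.default_rng(9).standard_normal(len(t))
        f, psd = welch_psd(x, FS, 1024)
        rel = relative_band_power(f, psd)
        assert rel["alpha"] > 0.8

    def test_parseval_white_noise(self):
        x = np.random.default_rng(10).standard_normal(50_000)
        f, psd = welch_psd(x, FS, 1024)
        total = band_power(f, psd, (0.0, FS / 2))
        assert total == pytest.approx(1.0, rel=0.1)

    def test_band_outside_range(self):
        f, psd = welch_psd(np.random.default_rng(0).standard_normal(1000),
                           FS, 256)
        with pytest.raises(ValueError):
            band_power(f, psd, (100.0, 200.0))


class TestTimeFrequency:
    def test_chirp_ridge_monotone(self):
        from scipy.signal import chirp
        t = np.arange(0, 8, 1 / FS)
        x = chirp(t, f0=5, f1=20, t1=8)
        f, frames, mag = stft_features(x, FS, nperseg=256)
        ridge = f[np.argmax(mag, axis=0)]
        inner = ridge[2:-2]
        assert np.all(np.diff(inner) >= 0)
        assert inner[-1] > inner[0]

    def test_dwt_energy_conservation(self):
        x = np.random.default_rng(11).standard_normal(1024)
        energies = dwt_features(x, "db4", level=5)
        assert sum(energies.values()) == pytest.approx(np.sum(x ** 2),
                                                       rel=1e-6)

    def test_zero_signal_zero_features(self):
        energies = dwt_features(np.zeros(256), "db4", level=3)
        assert all(v == 0 for v in energies.values())

    def test_too_deep_level(self):
        with pytest.raises(ValueError, match="too deep"):
            dwt_features(np.ones(32), "db4", level=10)


class TestCSP:
    def test_filters_match_direct_eigendecomposition(self, two_class_epochs):
        """CSP filters equal the brute-force generalized eigenvectors of the
        independently computed class covariances (|cosine| > 0.999)."""
        ep = two_class_epochs
        model = csp_fit(ep, n_components=4, shrinkage=0.05)
        # oracle: recompute class covariances from scratch
        covs = {"A": [], "B": []}
        for x, l in zip(ep.data, ep.labels):
            xc = x - x.mean(axis=1, keepdims=True)
            c = xc @ xc.T / (x.shape[1] - 1)
            covs[l].append(c / np.trace(c))
        ca = np.mean(covs["A"], axis=0)
        cb = np.mean(covs["B"], axis=0)
        d = ca.shape[0]
        g = 0.05
        ca = (1 - g) * ca + g * np.trace(ca) / d * np.eye(d)
        cb = (1 - g) * cb + g * np.trace(cb) / d * np.eye(d)
        evals, evecs = linalg.eigh(ca, ca + cb)
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        oracle = evecs[:, [0, 1, d - 2, d - 1]].T
        for w_fit, w_oracle in zip(model.filters, oracle):
            cos = abs(w_fit @ w_oracle) / (
                np.linalg.norm(w_fit) * np.linalg.norm(w_oracle))
            assert cos > 0.999

    def test_variance_ratio_dominance(self, two_class_epochs):
        """No random unit filter beats the first CSP filter's class-A
        variance ratio (oracle dominance, 1000 trials)."""
        ep = two_class_epochs
        model = csp_fit(ep, n_components=4)
        # independently recomputed class covariances (same normalization)
        cls_cov = {}
        for lbl in ("A", "B"):
            cs = []
            for x, l in zip(ep.data, ep.labels):
                if l != lbl:
                    continue
                xc = x - x.mean(axis=1, keepdims=True)
                c = xc @ xc.T / (x.shape[1] - 1)
                cs.append(c / np.trace(c))
            c = np.mean(cs, axis=0)
            d = c.shape[0]
            cls_cov[lbl] = 0.95 * c + 0.05 * np.trace(c) / d * np.eye(d)

        def ratio(w):
            va = w @ cls_cov["A"] @ w
            vb = w @ cls_cov["B"] @ w
            return va / (va + vb)

        best = ratio(model.filters[0])
        rng = np.random.default_rng(12)
        for _ in range(1000):
            w = rng.standard_normal(ep.n_channels)
            assert ratio(w / np.linalg.norm(w)) <= best + 1e-9

    def test_label_swap_keeps_filter_set(self, two_class_epochs):
        ep = two_class_epochs
        swapped = EpochSet(ep.data,
                           ["B" if l == "A" else "A" for l in ep.labels],
                           ep.fs, ep.window, ep.channel_names)
        m1 = csp_fit(ep)
        m2 = csp_fit(swapped)
        np.testing.assert_allclose(np.sort(m1.eigenvalues),
                                   np.sort(1 - m2.eigenvalues), atol=1e-9)
        # selected filter subspaces coincide (up to order and sign)
        f1 = m1.filters / np.linalg.norm(m1.filters, axis=1, keepdims=True)
        f2 = m2.filters / np.linalg.norm(m2.filters, axis=1, keepdims=True)
        gram = np.abs(f1 @ f2.T)
        assert np.allclose(np.sort(gram.max(axis=1)), 1.0, atol=1e-6)

    def test_top_filter_separates_classes(self, two_class_epochs):
        ep = two_class_epochs
        model = csp_fit(ep)
        feats = csp_transform(model, ep)
        y = np.array([l == "A" for l in ep.labels])
        from sklearn.metrics import roc_auc_score
        auc = roc_auc_score(y, feats[:, 0])
        assert max(auc, 1 - auc) > 0.95

    def test_multiclass_rejected(self):
        rng = np.random.default_rng(13)
        ep = EpochSet(rng.standard_normal((6, 2, 100)),
                      ["A", "B", "C"] * 2, FS, (0, 0.4), ["x", "y"])
        with pytest.raises(ValueError, match="one-vs-rest"):
            csp_fit(ep)


class TestConnectivity:
    def test_xcorr_zero_lag_autocorrelation(self):
        x = np.random.default_rng(14).standard_normal(1000)
        lags, r = xcorr(x, x, max_lag=10)
        assert r[lags == 0][0] == pytest.approx(1.0, abs=1e-12)

    def test_coherence_with_self_is_one(self):
        x = np.random.default_rng(15).standard_normal(4000)
        f, c = coherence(x, x, FS)
        np.testing.assert_allclose(c, 1.0, atol=1e-6)

    def test_psi_antisymmetry(self):
        rng = np.random.default_rng(16)
        a = rng.standard_normal(8000)
        b = rng.standard_normal(8000)
        p1 = phase_slope_index(a, b, FS, (4, 40))
        p2 = phase_slope_index(b, a, FS, (4, 40))
        assert p1 == pytest.approx(-p2, abs=1e-12)

    def test_psi_positive_when_first_leads(self):
        """b lags a by 20 ms -> a leads -> PSI(a, b) > 0."""
        rng = np.random.default_rng(17)
        lag = round(0.02 * FS)  # 5 samples
        base = rng.standard_normal(12_000)
        a = base[lag:]
        b = base[:-lag]  # b is a delayed copy of a
        assert phase_slope_index(a, b, FS, (4, 40)) > 0

    def test_narrow_band_rejected(self):
        a = np.random.default_rng(18).standard_normal(1000)
        with pytest.raises(ValueError, match="band"):
            phase_slope_index(a, a, FS, (10.0, 10.2))


class TestExtract:
    def make_epochs(self):
        rng = np.random.default_rng(19)
        return EpochSet(rng.standard_normal((4, 3, 250)), list("abab"), FS,
                        (0, 1), ["C3", "Cz", "C4"])

    def test_column_naming(self):
        df = extract(self.make_epochs(), ["variance"])
        assert list(df.columns) == ["label", "variance.ch0", "variance.ch1",
                                    "variance.ch2"]

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            extract(self.make_epochs(), [])

    def test_unknown_feature_lists_registry(self):
        with pytest.raises(KeyError, match="registry"):
            extract(self.make_epochs(), ["nope"])

    def test_column_order_independent_of_epoch_order(self):
        ep = self.make_epochs()
        rev = EpochSet(ep.data[::-1], ep.labels[::-1], ep.fs, ep.window,
                       ep.channel_names)
        df1 = extract(ep, ["variance", "hjorth_mobility"])
        df2 = extract(rev, ["variance", "hjorth_mobility"])
        assert list(df1.columns) == list(df2.columns)
        np.testing.assert_allclose(df1.iloc[0, 1:].to_numpy(dtype=float),
                                   df2.iloc[-1, 1:].to_numpy(dtype=float))
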