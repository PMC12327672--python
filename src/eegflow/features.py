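"""EEG feature extraction.

Time-domain (moments, Hjorth, fractal dimensions, entropies, DFA),
frequency-domain (Welch PSD, band powers), time-frequency (STFT, DWT),
spatial (CSP) and connectivity (cross-correlation, coherence, phase slope
index) measures, assembled into labeled feature vectors.

Conventions: kurtosis is excess kurtosis (Gaussian → 0); entropy tolerance
radius defaults to r = 0.2·SD with embedding dimension m = 2; Higuchi uses
k_max = 10; Welch uses Hann windows with 50 % overlap; DWT defaults to the
orthogonal db4 wavelet; canonical EEG bands are delta 1–4, theta 4–8, alpha
8–13, beta 13–30, gamma 30–45 Hz.  PSI sign convention: positive means the
first argument leads the second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import linalg, signal, stats

from .signal_model import EpochSet

__all__ = [
    "tdf_moments", "hjorth", "higuchi_fd", "katz_fd",
    "shannon_entropy", "approx_entropy", "sample_entropy", "dfa",
    "welch_psd", "band_power", "relative_band_power",
    "stft_features", "dwt_features",
    "CSPModel", "csp_fit", "csp_transform",
    "xcorr", "coherence", "phase_slope_index",
    "extract", "FEATURE_REGISTRY", "EEG_BANDS",
]

EEG_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


# ---------------------------------------------------------------- time domain

def tdf_moments(x: np.ndarray) -> dict[str, float]:
    """Sample mean, variance, skewness and excess kurtosis."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for moments")
    var = float(np.var(x))
    if var == 0:
        return {"mean": float(np.mean(x)), "variance": 0.0,
                "skewness": np.nan, "kurtosis": np.nan}
    return {
        "mean": float(np.mean(x)),
        "variance": var,
        "skewness": float(stats.skew(x)),
        "kurtosis": float(stats.kurtosis(x)),  # excess: Gaussian -> 0
    }


def hjorth(x: np.ndarray) -> dict[str, float]:
    """Hjorth activity, mobility and complexity.

    activity = var(x); mobility = sqrt(var(Δx)/var(x));
    complexity = mobility(Δx)/mobility(x), Δ the first difference.
    """
    x = np.asarray(x, dtype=float)
    v0 = np.var(x)
    if v0 == 0:
        raise ValueError("Hjorth parameters undefined for a constant signal")
    d1 = np.diff(x)
    d2 = np.diff(d1)
    v1, v2 = np.var(d1), np.var(d2)
    mobility = np.sqrt(v1 / v0)
    complexity = np.sqrt(v2 / v1) / mobility if v1 > 0 else np.nan
    return {"activity": float(v0), "mobility": float(mobility),
            "complexity": float(complexity)}


def higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension.

    Mean normalized curve length L(k) over decimated subseries; the FD is
    minus the slope of log L(k) against log k (≈ 1 for a smooth curve,
    → 2 for white noise).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * k_max:
        raise ValueError(f"need at least {2 * k_max} samples for k_max={k_max}")
    lk = np.empty(k_max)
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    k_arr = np.arange(1, k_max + 1)
    slope = np.polyfit(np.log(k_arr), np.log(lk), 1)[0]
    return float(-slope)


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension: log10(n) / (log10(n) + log10(d/L)).

    L is the total path length, d the maximum distance from the first point,
    n the number of steps.  A straight line gives exactly 1.
    """
    x = np.asarray(x, dtype=float)
    dists = np.abs(np.diff(x))
    L = dists.sum()
    if L == 0:
        return 1.0
    d = np.abs(x - x[0]).max()
    n = x.size - 1
    return float(np.log10(n) / (np.log10(n) + np.log10(d / L)))


# ----------------------------------------------------------------- entropies

def shannon_entropy(x: np.ndarray, n_bins: int = 16) -> float:
    """Shannon entropy (bits) of an equal-width amplitude histogram."""
    counts, _ = np.histogram(np.asarray(x, dtype=float), bins=n_bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _phi_apen(x: np.ndarray, m: int, r: float) -> float:
    # mean log fraction of templates within Chebyshev distance r (self-matches in)
    n = x.size
    templ = np.lib.stride_tricks.sliding_window_view(x, m)
    d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=2)
    c = (d <= r).mean(axis=1)
    return float(np.mean(np.log(c)))


def approx_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) = Φ_m − Φ_{m+1}, self-matches included."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x)
    return _phi_apen(x, m, r) - _phi_apen(x, m + 1, r)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy −ln(A/B), self-matches excluded.

    B counts template pairs of length m within tolerance r, A the subset
    that stays within tolerance at length m+1.  Returns NaN (flagged with a
    warning) when no length-m matches exist; a constant signal gives 0.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x)
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[: x.size - m]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    dm = np.max(np.abs(tm[:, None, :] - tm[None, :, :]), axis=2)
    dm1 = np.max(np.abs(tm1[:, None, :] - tm1[None, :, :]), axis=2)
    iu = np.triu_indices(len(tm), k=1)
    b = int((dm[iu] <= r).sum())
    iu1 = np.triu_indices(len(tm1), k=1)
    a = int((dm1[iu1] <= r).sum())
    if b == 0:
        warnings.warn("sample_entropy: no template matches (B = 0), undefined",
                      stacklevel=2)
        return float("nan")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


def dfa(x: np.ndarray, scales: np.ndarray | None = None) -> float:
    """Detrended fluctuation analysis scaling exponent α.

    Integrates the mean-centered signal, linearly detrends it in
    non-overlapping windows of each scale, and fits the slope of
    log RMS-fluctuation against log scale.  White noise gives α ≈ 0.5,
    Brownian motion α ≈ 1.5.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 16:
        raise ValueError("need at least 16 samples for DFA")
    if scales is None:
        scales = np.unique(np.geomspace(4, n // 4, 10).astype(int))
    y = np.cumsum(x - x.mean())
    f = np.empty(len(scales))
    for i, s in enumerate(scales):
        n_win = n // s
        segs = y[: n_win * s].reshape(n_win, s)
        t = np.arange(s)
        # per-window least-squares line
        coef = np.polynomial.polynomial.polyfit(t, segs.T, 1)
        trend = coef[0][:, None] + coef[1][:, None] * t[None, :]
        f[i] = np.sqrt(np.mean((segs - trend) ** 2))
    alpha = np.polyfit(np.log(scales), np.log(f), 1)[0]
    return float(alpha)


# ------------------------------------------------------------ frequency domain

def welch_psd(x: np.ndarray, fs: float, nperseg: int = 256,
              overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with Hann windows; returns (freqs, psd in µV²/Hz)."""
    x = np.asarray(x, dtype=float)
    nperseg = min(nperseg, x.size)
    return signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                        noverlap=int(nperseg * overlap))


def band_power(freqs: np.ndarray, psd: np.ndarray,
               band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over [f_lo, f_hi), in µV²."""
    lo, hi = band
    if lo < 0 or hi > freqs[-1] + 1e-9 or lo >= hi:
        raise ValueError(f"band {band} outside resolvable range "
                         f"[0, {freqs[-1]}] Hz")
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band} narrower than the frequency resolution")
    return float(np.trapezoid(psd[mask], freqs[mask]))


def relative_band_power(freqs: np.ndarray, psd: np.ndarray,
                        bands: dict[str, tuple[float, float]] | None = None
                        ) -> dict[str, float]:
    """Band powers normalized to sum to 1 over the band partition."""
    bands = bands or EEG_BANDS
    raw = {name: band_power(freqs, psd, b) for name, b in bands.items()}
    total = sum(raw.values())
    if total == 0:
        return {name: 0.0 for name in raw}
    return {name: v / total for name, v in raw.items()}


# ------------------------------------------------------------- time-frequency

def stft_features(x: np.ndarray, fs: float, nperseg: int = 128,
                  hop: int | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Fourier magnitude grid; returns (freqs, frame_times, |S|)."""
    x = np.asarray(x, dtype=float)
    hop = hop or nperseg // 2
    win = signal.windows.hann(nperseg, sym=False)
    sft = signal.ShortTimeFFT(win, hop=hop, fs=fs)
    S = sft.stft(x)
    return sft.f, sft.t(x.size), np.abs(S)


def dwt_features(x: np.ndarray, wavelet: str = "db4",
                 level: int | None = None) -> dict[str, float]:
    """Per-level energies Σ coeff² of a discrete wavelet decomposition.

    With an orthogonal wavelet in periodization mode the level energies sum
    to the signal energy.
    """
    x = np.asarray(x, dtype=float)
    max_level = pywt.dwt_max_level(x.size, wavelet)
    if level is None:
        level = max_level
    if level > max_level:
        raise ValueError(f"level {level} too deep for {x.size} samples "
                         f"(max {max_level})")
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="periodization")
    out = {f"A{level}": float(np.sum(coeffs[0] ** 2))}
    for i, c in enumerate(coeffs[1:]):
        out[f"D{level - i}"] = float(np.sum(c ** 2))
    return out


# ------------------------------------------------------------------- spatial

@dataclass
class CSPModel:
    """Common-spatial-pattern filters.

    ``filters`` rows are spatial filters w (applied as w·X); ``patterns``
    columns are the corresponding source-distribution patterns
    (inverse-transpose of the full filter matrix); ``eigenvalues`` are the
    class-A variance fractions λ ∈ (0, 1) of the selected filters.
    """

    filters: np.ndarray      # [n_components, n_channels]
    patterns: np.ndarray     # [n_channels, n_components]
    eigenvalues: np.ndarray  # per selected filter
    n_components: int
    classes: tuple[str, str]


def _class_mean_cov(data: np.ndarray, shrinkage: float) -> np.ndarray:
    """Average of trace-normalized per-epoch covariances with shrinkage."""
    covs = []
    for ep in data:
        xc = ep - ep.mean(axis=1, keepdims=True)
        c = xc @ xc.T / (ep.shape[1] - 1)
        tr = np.trace(c)
        if tr > 0:
            c = c / tr
        covs.append(c)
    c = np.mean(covs, axis=0)
    d = c.shape[0]
    return (1 - shrinkage) * c + shrinkage * (np.trace(c) / d) * np.eye(d)


def csp_fit(epochs: EpochSet, n_components: int = 4,
            shrinkage: float = 0.05) -> CSPModel:
    """Fit CSP spatial filters on a two-class epoch set.

    Solves the generalized eigenproblem C_A w = λ (C_A + C_B) w on
    shrinkage-regularized class-mean covariances and keeps
    ``n_components/2`` filters from each spectral extreme (the filters that
    maximize the variance of one class relative to the pooled variance).
    """
    classes = sorted(set(epochs.labels))
    if len(classes) != 2:
        raise ValueError(
            f"CSP requires exactly 2 classes, got {len(classes)}; "
            "use a one-vs-rest wrapper for multi-class")
    la, lb = classes
    mask_a = np.array([l == la for l in epochs.labels])
    for lbl, m in ((la, mask_a), (lb, ~mask_a)):
        if m.sum() < 2:
            raise ValueError(f"class {lbl!r} has fewer than 2 epochs")
    ca = _class_mean_cov(epochs.data[mask_a], shrinkage)
    cb = _class_mean_cov(epochs.data[~mask_a], shrinkage)
    evals, evecs = linalg.eigh(ca, ca + cb)
    order = np.argsort(evals)[::-1]  # descending lambda = class-A fraction
    evals, evecs = evals[order], evecs[:, order]
    W_full = evecs.T
    # patterns satisfy X ≈ A @ (W X): column j of inv(W) is source pattern j
    A_full = linalg.inv(W_full)

    half = n_components // 2
    sel = list(range(half)) + list(range(len(evals) - (n_components - half),
                                         len(evals)))
    return CSPModel(
        filters=W_full[sel],
        patterns=A_full[:, sel],
        eigenvalues=evals[sel],
        n_components=n_components,
        classes=(la, lb),
    )


def csp_transform(model: CSPModel, epochs: EpochSet) -> np.ndarray:
    """Log-variance of the spatially filtered epochs, shape (n_epochs, n_comp)."""
    out = np.empty((epochs.n_epochs, model.filters.shape[0]))
    for i, ep in enumerate(epochs.data):
        s = model.filters @ (ep - ep.mean(axis=1, keepdims=True))
        out[i] = np.log(np.maximum(s.var(axis=1), 1e-12))
    return out


# --------------------------------------------------------------- connectivity

def xcorr(a: np.ndarray, b: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation; returns (lags, r).

    Normalization by sqrt(energy_a · energy_b) makes the zero-lag
    autocorrelation equal 1.  Positive lag means ``a`` is shifted forward.
    """
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    full = signal.correlate(a, b, mode="full")
    lags = signal.correlation_lags(a.size, b.size, mode="full")
    norm = np.sqrt(np.sum(a ** 2) * np.sum(b ** 2))
    keep = np.abs(lags) <= max_lag
    return lags[keep], full[keep] / (norm if norm > 0 else 1.0)


def coherence(a: np.ndarray, b: np.ndarray, fs: float,
              nperseg: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence from Welch cross/auto spectra, C ∈ [0, 1]."""
    nperseg = min(nperseg, len(a))
    return signal.coherence(a, b, fs=fs, window="hann", nperseg=nperseg,
                            noverlap=nperseg // 2)


def phase_slope_index(a: np.ndarray, b: np.ndarray, fs: float,
                      band: tuple[float, float], nperseg: int = 256) -> float:
    """Phase slope index over ``band``; positive ⇒ ``a`` leads ``b``.

    PSI = Im Σ_f conj(C(f))·C(f+δf) with complex coherency
    C = S_ab / sqrt(S_aa·S_bb), where S_ab carries the phase of A(f)·conj(B(f)).
    """
    nperseg = min(nperseg, len(a))
    f, sab = signal.csd(a, b, fs=fs, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2)
    _, saa = signal.welch(a, fs=fs, window="hann", nperseg=nperseg,
                          noverlap=nperseg // 2)
    _, sbb = signal.welch(b, fs=fs, window="hann", nperseg=nperseg,
                          noverlap=nperseg // 2)
    # scipy csd returns conj(A)·B; conjugate for the a-leads-positive convention
    c = np.conj(sab) / np.sqrt(saa * sbb)
    mask = (f >= band[0]) & (f <= band[1])
    if mask.sum() < 2:
        raise ValueError(f"band {band} narrower than 2 frequency bins "
                         f"(resolution {f[1] - f[0]:.3g} Hz)")
    ci = c[mask]
    return float(np.imag(np.sum(np.conj(ci[:-1]) * ci[1:])))


# ------------------------------------------------------------------ assembly

def _per_channel(fn):
    def wrapped(ep: np.ndarray, fs: float, params: dict) -> dict[str, float]:
        return {f"ch{c}": fn(ep[c], fs, params) for c in range(ep.shape[0])}
    return wrapped


FEATURE_REGISTRY: dict = {
    "mean": _per_channel(lambda x, fs, p: tdf_moments(x)["mean"]),
    "variance": _per_channel(lambda x, fs, p: tdf_moments(x)["variance"]),
    "skewness": _per_channel(lambda x, fs, p: tdf_moments(x)["skewness"]),
    "kurtosis": _per_channel(lambda x, fs, p: tdf_moments(x)["kurtosis"]),
    "hjorth_activity": _per_channel(lambda x, fs, p: hjorth(x)["activity"]),
    "hjorth_mobility": _per_channel(lambda x, fs, p: hjorth(x)["mobility"]),
    "hjorth_complexity": _per_channel(lambda x, fs, p: hjorth(x)["complexity"]),
    "higuchi_fd": _per_channel(
        lambda x, fs, p: higuchi_fd(x, p.get("k_max", 10))),
    "katz_fd": _per_channel(lambda x, fs, p: katz_fd(x)),
    "shannon_entropy": _per_channel(
        lambda x, fs, p: shannon_entropy(x, p.get("n_bins", 16))),
    "sample_entropy": _per_channel(
        lambda x, fs, p: sample_entropy(x, p.get("m", 2), p.get("r"))),
    "approx_entropy": _per_channel(
        lambda x, fs, p: approx_entropy(x, p.get("m", 2), p.get("r"))),
    "dfa": _per_channel(lambda x, fs, p: dfa(x)),
    "band_power": _per_channel(
        lambda x, fs, p: band_power(*welch_psd(x, fs), p.get("band", (8, 13)))),
}


def extract(epochs: EpochSet, feature_spec: list[dict | str]):
    """Apply a configured feature list per channel; returns a DataFrame.

    Each spec entry is a registry name or ``{"name": ..., **params}``.
    Columns are named ``feature.chN``; column order is determined by the
    spec, not by the data.  Unknown names fail fast listing the registry.
    """
    import pandas as pd

    if not feature_spec:
        raise ValueError("empty feature spec")
    norm = []
    for item in feature_spec:
        if isinstance(item, str):
            norm.append({"name": item})
        else:
            norm.append(dict(item))
    for item in norm:
        if item["name"] not in FEATURE_REGISTRY:
            raise KeyError(
                f"unknown feature {item['name']!r}; registry: "
                f"{sorted(FEATURE_REGISTRY)}")
    rows = []
    for ep in epochs.data:
        row = {}
        for item in norm:
            name = item["name"]
            params = {k: v for k, v in item.items() if k != "name"}
            vals = FEATURE_REGISTRY[name](ep, epochs.fs, params)
            for ch, v in vals.items():
                row[f"{name}.{ch}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    df.insert(0, "label", epochs.labels)
    return df
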