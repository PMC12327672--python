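"""Channel selection: score channels by class-relevance, keep the top n.

Four filter criteria are provided, all operating on a per-epoch per-channel
scalar (the log of the epoch sample variance — the same second-order
quantity CSP exploits, which keeps the criteria comparable):

* correlation — |Pearson R| between the channel scalar and integer-coded
  class labels, R = cov(x, Y) / sqrt(var(x)·var(Y));
* mutual information — I(X, Y) = H(Y) − H(Y|X) in bits, with the channel
  scalar discretized into equal-frequency bins;
* chi-squared — X² = Σ (O_i − E_i)² / E_i on the binned-scalar × class
  contingency table;
* CSP patterns — peak absolute weight of the channel across the most
  discriminative spatial patterns (source-distribution vectors).

Selection is done offline on labeled calibration epochs; the resulting
channel list is then applied online via ``signal_model.channel_subset``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import csp_fit
from .signal_model import EpochSet

__all__ = [
    "ChannelScores",
    "channel_feature",
    "score_correlation",
    "score_mutual_information",
    "score_chi_squared",
    "score_csp",
    "select_top_n",
    "score_channels",
]

_VAR_FLOOR = 1e-12


@dataclass
class ChannelScores:
    method: str
    scores: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.channel_names):
            raise ValueError("scores / channel_names length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


def channel_feature(epochs: EpochSet) -> np.ndarray:
    """Per-epoch per-channel scalar: log sample variance, shape (epochs, channels).

    Constant channels are floored at 1e-12 before the log and flagged.
    """
    var = epochs.data.var(axis=2)
    if np.any(var < _VAR_FLOOR):
        warnings.warn("channel_feature: constant channel(s), variance floored",
                      stacklevel=2)
        var = np.maximum(var, _VAR_FLOOR)
    return np.log(var)


def _encode_labels(labels: list[str]) -> np.ndarray:
    classes = sorted(set(labels))
    code = {c: i for i, c in enumerate(classes)}
    return np.array([code[l] for l in labels], dtype=float)


def _equal_freq_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-based discretization into codes 0..n_bins-1 (monotone-invariant)."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def score_correlation(epochs: EpochSet, labels: list[str] | None = None
                      ) -> ChannelScores:
    """|Pearson R| between each channel's log-variance and integer class codes."""
    labels = labels if labels is not None else epochs.labels
    if len(set(labels)) < 2:
        raise ValueError("correlation undefined with a single class")
    if epochs.n_epochs < 2:
        raise ValueError("need at least 2 epochs")
    x = channel_feature(epochs)
    y = _encode_labels(labels)
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    cov = (xc * yc[:, None]).mean(axis=0)
    denom = np.sqrt(xc.var(axis=0) * yc.var())
    r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return ChannelScores("correlation", np.abs(r), epochs.channel_names)


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def score_mutual_information(epochs: EpochSet, labels: list[str] | None = None,
                             n_bins: int = 4) -> ChannelScores:
    """Plug-in mutual information I = H(Y) − H(Y|X) in bits per channel."""
    labels = labels if labels is not None else epochs.labels
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if epochs.n_epochs < n_bins:
        raise ValueError(
            f"need at least n_bins={n_bins} epochs, got {epochs.n_epochs}")
    x = channel_feature(epochs)
    y = _encode_labels(labels).astype(int)
    hy = _entropy_bits(np.bincount(y))
    scores = np.empty(epochs.n_channels)
    n = len(y)
    for c in range(epochs.n_channels):
        xb = _equal_freq_bins(x[:, c], n_bins)
        hcond = 0.0
        for b in np.unique(xb):
            mask = xb == b
            hcond += mask.sum() / n * _entropy_bits(np.bincount(y[mask]))
        scores[c] = hy - hcond
    return ChannelScores("mutual_information", np.maximum(scores, 0.0),
                         epochs.channel_names)


def chi_squared_statistic(table: np.ndarray) -> float:
    """X² = Σ (O_i − E_i)²/E_i with E from row/column marginals.

    Rows or columns whose marginal is zero are dropped (equivalent to
    merging empty bins) with a warning.
    """
    O = np.asarray(table, dtype=float)
    keep_r = O.sum(axis=1) > 0
    keep_c = O.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("chi_squared: empty bins merged (zero expected counts)",
                      stacklevel=2)
        O = O[keep_r][:, keep_c]
    if O.size == 0:
        return 0.0
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / O.sum()
    return float(((O - E) ** 2 / E).sum())


def score_chi_squared(epochs: EpochSet, labels: list[str] | None = None,
                      n_bins: int = 4) -> ChannelScores:
    """Chi-squared statistic of binned channel scalar vs class contingency."""
    labels = labels if labels is not None else epochs.labels
    x = channel_feature(epochs)
    y = _encode_labels(labels).astype(int)
    k = y.max() + 1
    scores = np.empty(epochs.n_channels)
    for c in range(epochs.n_channels):
        xb = _equal_freq_bins(x[:, c], n_bins)
        table = np.zeros((n_bins, k))
        np.add.at(table, (xb, y), 1)
        scores[c] = chi_squared_statistic(table)
    return ChannelScores("chi_squared", scores, epochs.channel_names)


def score_csp(epochs: EpochSet, labels: list[str] | None = None,
              n_patterns: int = 4) -> ChannelScores:
    """Score channels by their peak weight across discriminative CSP patterns.

    Each of the ``n_patterns`` most discriminative source-distribution
    patterns is normalized to unit max-abs and weighted by its
    discriminability 2|λ − 0.5| (λ the CSP eigenvalue: the share of class-A
    variance captured by the filter); a channel's score is its maximum
    weighted absolute pattern entry.  The weighting keeps patterns with
    λ ≈ 0.5 — which carry no class contrast, only noise — from handing
    their peak channel a spuriously high score.  Multi-class labels are
    handled one-vs-rest, taking the per-channel maximum over the wrappings.
    """
    labels = list(labels) if labels is not None else epochs.labels
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("CSP scoring needs at least 2 classes")
    if len(classes) > 2:
        per = []
        for c in classes:
            ovr = [l if l == c else "__rest__" for l in labels]
            ep = EpochSet(epochs.data, ovr, epochs.fs, epochs.window,
                          epochs.channel_names)
            per.append(score_csp(ep, n_patterns=n_patterns).scores)
        return ChannelScores("csp", np.max(per, axis=0), epochs.channel_names)

    ep = epochs if labels is epochs.labels else EpochSet(
        epochs.data, labels, epochs.fs, epochs.window, epochs.channel_names)
    model = csp_fit(ep, n_components=min(n_patterns, epochs.n_channels))
    A = model.patterns  # [channels x selected patterns]
    A = A / np.max(np.abs(A), axis=0, keepdims=True)
    w = 2.0 * np.abs(model.eigenvalues - 0.5)
    return ChannelScores("csp", np.max(np.abs(A) * w[None, :], axis=1),
                         epochs.channel_names)


def select_top_n(scores: ChannelScores, n: int) -> list[str]:
    """Names of the n highest-scoring channels, descending; ties by lower index."""
    if n > len(scores.scores):
        raise ValueError(
            f"requested {n} channels but only {len(scores.scores)} scored")
    order = sorted(range(len(scores.scores)),
                   key=lambda i: (-scores.scores[i], i))
    return [scores.channel_names[i] for i in order[:n]]


_METHODS = {
    "correlation": score_correlation,
    "corr": score_correlation,
    "mutual_information": score_mutual_information,
    "mi": score_mutual_information,
    "chi_squared": score_chi_squared,
    "chi2": score_chi_squared,
    "csp": score_csp,
}


def score_channels(epochs: EpochSet, method: str, **kwargs) -> ChannelScores:
    """Dispatch to a scoring criterion by name."""
    if method not in _METHODS:
        raise KeyError(f"unknown method {method!r}; choose from "
                       f"{sorted(set(_METHODS))}")
    return _METHODS[method](epochs, **kwargs)
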