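"""Preprocessing and artifact removal.

Butterworth filtering (zero-phase for offline analysis, causal for
streaming), Kaiser windowing, common-average re-referencing,
amplitude-threshold epoch rejection, EOG regression cleaning from
calibration data, and ICA decomposition / reconstruction with
reference-correlation artifact-component labeling.

The zero-phase mode applies the filter forward and backward, which squares
the magnitude response (|H| at the cutoff becomes 1/2 instead of 1/√2) and
cancels group delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .signal_model import EpochSet, Recording

__all__ = [
    "FilterSpec", "design_filter", "apply_filter",
    "apply_window", "rereference_car", "reject_amplitude",
    "RegressionCoeffs", "fit_regression", "remove_artifact_regression",
    "ICAModel", "ica_fit", "identify_artifact_ics", "ica_reconstruct",
]


@dataclass
class FilterSpec:
    """Butterworth filter description.

    kind: lowpass | highpass | bandpass | bandstop; ``cutoffs_hz`` has one
    entry for lowpass/highpass and two ordered entries otherwise; ``mode``
    selects zero-phase (forward-backward) or causal application.
    """

    kind: str
    order: int
    cutoffs_hz: tuple[float, ...]
    fs_hz: float
    mode: str = "zero_phase"

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass", "bandstop"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.mode not in ("zero_phase", "causal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        cuts = tuple(float(c) for c in np.atleast_1d(self.cutoffs_hz))
        nyq = self.fs_hz / 2
        if any(c <= 0 or c >= nyq for c in cuts):
            raise ValueError(
                f"cutoffs {cuts} must lie strictly inside (0, Nyquist="
                f"{nyq} Hz)")
        n_expected = 2 if self.kind in ("bandpass", "bandstop") else 1
        if len(cuts) != n_expected:
            raise ValueError(f"{self.kind} needs {n_expected} cutoff(s)")
        if n_expected == 2 and cuts[0] >= cuts[1]:
            raise ValueError("band cutoffs must be ordered")
        self.cutoffs_hz = cuts


def design_filter(spec: FilterSpec):
    """Design the Butterworth filter; returns (sos, response).

    ``response(freqs_hz)`` evaluates the effective magnitude response —
    squared for zero-phase mode.  The causal magnitude at each cutoff is
    1/√2 by the Butterworth definition.
    """
    wn = spec.cutoffs_hz if len(spec.cutoffs_hz) > 1 else spec.cutoffs_hz[0]
    sos = signal.butter(spec.order, wn, btype=spec.kind,
                        fs=spec.fs_hz, output="sos")

    def response(freqs_hz):
        w, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs_hz),
                               fs=spec.fs_hz)
        mag = np.abs(h)
        return mag ** 2 if spec.mode == "zero_phase" else mag

    return sos, response


def _filter_array(data: np.ndarray, spec: FilterSpec, sos) -> np.ndarray:
    if spec.mode == "zero_phase":
        # sosfiltfilt needs padding room; 3x the effective filter length
        ntaps = 2 * spec.order + 1
        if data.shape[-1] < 3 * ntaps:
            raise ValueError(
                f"signal of {data.shape[-1]} samples too short for "
                f"zero-phase order-{spec.order} filtering")
        return signal.sosfiltfilt(sos, data, axis=-1)
    return signal.sosfilt(sos, data, axis=-1)


def apply_filter(x: Recording | EpochSet, spec: FilterSpec):
    """Filter every channel (and epoch) along time; returns the same type."""
    sos, _ = design_filter(spec)
    if isinstance(x, Recording):
        return Recording(_filter_array(x.data, spec, sos), x.fs,
                         list(x.channel_names), x.t0)
    if isinstance(x, EpochSet):
        return EpochSet(_filter_array(x.data, spec, sos), list(x.labels),
                        x.fs, x.window, list(x.channel_names))
    raise TypeError(type(x).__name__)


def apply_window(epochs: EpochSet, kind: str = "kaiser",
                 length: int | None = None, beta: float = 8.6) -> EpochSet:
    """Multiply each epoch sample-wise by a taper window.

    Kaiser with beta = 8.6 approximates Blackman sidelobe behavior;
    beta = 0 degenerates to rectangular (identity).  ``length`` must match
    the epoch sample count.
    """
    if kind != "kaiser":
        raise ValueError(f"unsupported window kind {kind!r}")
    length = epochs.n_samples if length is None else length
    if length != epochs.n_samples:
        raise ValueError(
            f"window length {length} != epoch samples {epochs.n_samples}")
    w = np.kaiser(length, beta)
    return EpochSet(epochs.data * w[None, None, :], list(epochs.labels),
                    epochs.fs, epochs.window, list(epochs.channel_names))


def rereference_car(x: Recording | EpochSet):
    """Common-average reference: subtract the cross-channel mean per sample."""
    if isinstance(x, Recording):
        if x.n_channels < 2:
            raise ValueError("CAR undefined for a single channel")
        return Recording(x.data - x.data.mean(axis=0, keepdims=True), x.fs,
                         list(x.channel_names), x.t0)
    if isinstance(x, EpochSet):
        if x.n_channels < 2:
            raise ValueError("CAR undefined for a single channel")
        return EpochSet(x.data - x.data.mean(axis=1, keepdims=True),
                        list(x.labels), x.fs, x.window, list(x.channel_names))
    raise TypeError(type(x).__name__)


def reject_amplitude(epochs: EpochSet, threshold_uv: float
                     ) -> tuple[EpochSet, np.ndarray, dict]:
    """Drop epochs whose peak |amplitude| over channels/samples exceeds the threshold.

    Returns (kept epochs, keep mask, report dict).  High-amplitude
    transients such as EOG blinks typically stand far above background EEG,
    so a fixed µV threshold separates flawed epochs cheaply.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    peaks = np.abs(epochs.data).max(axis=(1, 2))
    keep = peaks <= threshold_uv
    kept = EpochSet(epochs.data[keep],
                    [l for l, k in zip(epochs.labels, keep) if k],
                    epochs.fs, epochs.window, list(epochs.channel_names))
    report = {
        "threshold_uv": float(threshold_uv),
        "n_total": int(epochs.n_epochs),
        "n_kept": int(keep.sum()),
        "n_rejected": int((~keep).sum()),
        "peak_uv": peaks.tolist(),
    }
    return kept, keep, report


# ----------------------------------------------------------- EOG regression

@dataclass
class RegressionCoeffs:
    """Per-channel OLS slopes of EEG on the EOG reference."""

    b: np.ndarray
    reference_name: str

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        if not np.all(np.isfinite(self.b)):
            raise ValueError("coefficients must be finite")


def fit_regression(calib_eeg: Recording, eog_ref: Recording) -> RegressionCoeffs:
    """OLS slope of each (mean-centered) EEG channel on the EOG reference.

    Fitted on calibration data recorded before the main experiment, during
    which the subject blinks on cue so the reference dominates the mixture.
    """
    if eog_ref.n_channels != 1:
        raise ValueError("eog_ref must be a single channel")
    if calib_eeg.fs != eog_ref.fs or calib_eeg.n_samples != eog_ref.n_samples:
        raise ValueError("calibration EEG and EOG must share fs and length")
    ref = eog_ref.data[0] - eog_ref.data[0].mean()
    denom = (ref ** 2).sum()
    if denom == 0:
        raise ValueError("zero-variance EOG reference")
    x = calib_eeg.data - calib_eeg.data.mean(axis=1, keepdims=True)
    b = x @ ref / denom
    return RegressionCoeffs(b, eog_ref.channel_names[0])


def remove_artifact_regression(x: Recording, coeffs: RegressionCoeffs,
                               eog_ref: Recording) -> Recording:
    """Subtract b_c · reference from each channel (channels with b = 0 untouched).

    The reference enters uncentered: the contamination model is additive
    ``b·ref``, so subtracting the raw reference removes the artifact without
    introducing a DC shift when the reference has a non-zero mean (blink
    bumps are one-sided).
    """
    if eog_ref.n_samples != x.n_samples:
        raise ValueError("recording and EOG reference length mismatch")
    if len(coeffs.b) != x.n_channels:
        raise ValueError("coefficient count != channel count")
    return Recording(x.data - coeffs.b[:, None] * eog_ref.data[0][None, :],
                     x.fs, list(x.channel_names), x.t0)


# --------------------------------------------------------------------- ICA

@dataclass
class ICAModel:
    """Fitted ICA: x ≈ mixing @ sources + mean, sources = unmixing @ (x − mean).

    Components are ordered by explained variance (descending).
    """

    unmixing: np.ndarray      # [n_components, n_channels]
    mixing: np.ndarray        # [n_channels, n_components]
    sources: np.ndarray       # [n_components, n_samples]
    mean: np.ndarray          # per-channel mean
    fs: float
    channel_names: list[str]
    seed: int


def ica_fit(x: Recording, n_components: int | None = None,
            seed: int = 0, max_iter: int = 500, tol: float = 1e-4,
            n_restarts: int = 3) -> ICAModel:
    """Whiten + fixed-point (FastICA) decomposition with seeded init.

    Fixed-point ICA is sensitive to its random initialization, so up to
    ``n_restarts`` deterministic re-initializations (seeds derived from
    ``seed``) are attempted before raising on non-convergence; the
    diagnostics report the settings tried.  Components are sorted by the
    variance they explain in the sensor signal.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    n_components = n_components or x.n_channels
    if x.n_samples < 3 * x.n_channels:
        raise ValueError("need many more samples than channels for ICA")
    tried = []
    ica = sources = None
    for attempt in range(n_restarts):
        init_seed = seed + 7919 * attempt
        ica = FastICA(n_components=n_components, whiten="unit-variance",
                      max_iter=max_iter, random_state=init_seed, tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(x.data.T).T
                break
            except ConvergenceWarning:
                tried.append(init_seed)
                sources = None
    if sources is None:
        raise RuntimeError(
            f"ICA did not converge in {max_iter} iterations for any of "
            f"{n_restarts} seeded inits (n_components={n_components}, "
            f"tol={tol}, seeds tried: {tried})")
    mixing = ica.mixing_                # [channels x components]
    unmixing = ica.components_          # [components x channels]
    # order by explained sensor-space variance
    expl = (mixing ** 2).sum(axis=0) * sources.var(axis=1)
    order = np.argsort(expl)[::-1]
    return ICAModel(unmixing[order], mixing[:, order], sources[order],
                    ica.mean_, x.fs, list(x.channel_names), seed)


def identify_artifact_ics(model: ICAModel, eog_ref: Recording | None = None,
                          r_threshold: float = 0.8,
                          kurtosis_threshold: float = 5.0) -> list[int]:
    """Flag components whose activation tracks the EOG reference.

    A component is flagged when |Pearson r| with the reference is at least
    ``r_threshold``.  Without a reference the fallback flags components with
    excess kurtosis above ``kurtosis_threshold`` (blink activations are
    strongly super-Gaussian), with a warning.
    """
    if eog_ref is None:
        warnings.warn("identify_artifact_ics: no EOG reference, falling back "
                      "to kurtosis flagging", stacklevel=2)
        kurt = stats.kurtosis(model.sources, axis=1)
        return [int(i) for i in np.where(kurt > kurtosis_threshold)[0]]
    ref = eog_ref.data[0]
    if ref.size != model.sources.shape[1]:
        raise ValueError("reference length != activation length")
    flagged = []
    refc = ref - ref.mean()
    for i, s in enumerate(model.sources):
        sc = s - s.mean()
        denom = np.sqrt((sc ** 2).sum() * (refc ** 2).sum())
        r = (sc @ refc) / denom if denom > 0 else 0.0
        if abs(r) >= r_threshold:
            flagged.append(i)
    return flagged


def ica_reconstruct(model: ICAModel, drop: list[int] | None = None) -> Recording:
    """Invert the ICA with the listed components zeroed.

    The channel mean is attributed to components through the unmixing
    matrix (c = W·mean), so a dropped artifact component takes its DC
    contribution with it — a one-sided artifact such as a blink train would
    otherwise leave a constant offset behind.  Dropping nothing reproduces
    the input (to numerical tolerance); dropping everything gives zero.
    """
    drop = list(drop or [])
    k = model.sources.shape[0]
    bad = [i for i in drop if not 0 <= i < k]
    if bad:
        raise IndexError(f"component indices out of range: {bad} (have {k})")
    keep = [i for i in range(k) if i not in drop]
    src_mean = model.unmixing @ model.mean  # per-component DC
    uncentered = model.sources[keep] + src_mean[keep, None]
    data = model.mixing[:, keep] @ uncentered
    return Recording(data, model.fs, list(model.channel_names))
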