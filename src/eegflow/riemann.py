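"""Covariance-manifold operations and classification.

Epoch covariance matrices are symmetric positive-definite (SPD) and live on
a Riemannian manifold; the affine-invariant Riemannian metric (AIRM)

    d(A, B) = || log(B^{-1/2} A B^{-1/2}) ||_F = sqrt(Σ_i log² λ_i)

(λ_i generalized eigenvalues of (A, B)) respects that geometry.  On top of
it this module provides the Fréchet (geometric) mean by fixed-point
iteration, the minimum-distance-to-mean classifier (RMDM: assign a
covariance to the class whose Fréchet mean is nearest), tangent-space
projection so covariances can feed ordinary vector classifiers, a plug-in
registry of standard classifiers (decision tree, random forest, SVM, naive
Bayes), and a stratified cross-validation harness reporting accuracy and
the Matthews correlation coefficient.

A log-Euclidean metric (d = ||log A − log B||_F) is available as a cheaper
configuration alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .signal_model import EpochSet

__all__ = [
    "epoch_covariance", "airm_distance", "logeuclid_distance",
    "frechet_mean", "RMDMModel", "rmdm_fit", "rmdm_predict",
    "tangent_project", "register_classifier", "registry_fit_predict",
    "make_classifier", "CLASSIFIER_REGISTRY",
    "EvalReport", "crossvalidate", "matthews_corrcoef",
]


def _check_spd(m: np.ndarray, name: str = "matrix", tol: float = 1e-9) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T, atol=tol * max(1.0, np.abs(m).max())):
        raise ValueError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(m)
    if w.min() <= 0:
        raise ValueError(f"{name} is not positive definite "
                         f"(min eigenvalue {w.min():.3g})")
    return 0.5 * (m + m.T)


def epoch_covariance(epochs: EpochSet, shrinkage: float = 0.05) -> np.ndarray:
    """Shrunk sample covariance per epoch, shape (n_epochs, d, d), in µV².

    C = (1−γ)·XXᵀ/(n−1) + γ·(trace/d)·I on the mean-centered epoch; the
    identity-target shrinkage guarantees positive definiteness even when an
    epoch has fewer samples than channels (γ > 0 required in that case).
    """
    n, d = epochs.n_samples, epochs.n_channels
    if n <= d and shrinkage == 0:
        raise ValueError("samples <= channels needs shrinkage > 0")
    out = np.empty((epochs.n_epochs, d, d))
    for i, ep in enumerate(epochs.data):
        xc = ep - ep.mean(axis=1, keepdims=True)
        c = xc @ xc.T / (n - 1)
        out[i] = (1 - shrinkage) * c + shrinkage * (np.trace(c) / d) * np.eye(d)
    return out


def airm_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant Riemannian distance sqrt(Σ log² λ_i(A, B))."""
    A = _check_spd(A, "A")
    B = _check_spd(B, "B")
    lam = linalg.eigvalsh(A, B)
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def _logm_spd(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    return (v * np.log(w)) @ v.T


def _expm_sym(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    return (v * np.exp(w)) @ v.T


def _sqrtm_spd(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, v = np.linalg.eigh(m)
    s = np.sqrt(w)
    return (v * s) @ v.T, (v / s) @ v.T  # (M^1/2, M^-1/2)


def logeuclid_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Log-Euclidean distance ||log A − log B||_F."""
    return float(np.linalg.norm(_logm_spd(_check_spd(A, "A"))
                                - _logm_spd(_check_spd(B, "B")), "fro"))


def frechet_mean(covs: np.ndarray, tol: float = 1e-8,
                 max_iter: int = 50) -> np.ndarray:
    """Fréchet (Karcher) mean of SPD matrices under the AIRM.

    Fixed-point iteration: average the matrix logarithms in the tangent
    space at the current base point and exponentiate back, until the update
    norm drops below ``tol``.  For commuting inputs this converges to the
    elementwise geometric mean.
    """
    covs = np.asarray(covs, dtype=float)
    if covs.ndim != 3 or len(covs) == 0:
        raise ValueError("need a non-empty stack of SPD matrices")
    if len(covs) == 1:
        return _check_spd(covs[0])
    g = covs.mean(axis=0)
    trace = [np.inf]
    for _ in range(max_iter):
        g_half, g_ihalf = _sqrtm_spd(g)
        t = np.mean([_logm_spd(g_ihalf @ c @ g_ihalf) for c in covs], axis=0)
        t = 0.5 * (t + t.T)
        step = float(np.linalg.norm(t, "fro"))
        trace.append(step)
        g = g_half @ _expm_sym(t) @ g_half
        g = 0.5 * (g + g.T)
        if step < tol:
            return g
    raise RuntimeError(
        f"Fréchet mean did not converge in {max_iter} iterations; "
        f"update norms: {[f'{s:.2e}' for s in trace[1:6]]}...{trace[-1]:.2e}")


@dataclass
class RMDMModel:
    """Per-class Fréchet means for minimum-distance-to-mean classification."""

    class_means: dict[str, np.ndarray]
    metric: str = "airm"


def rmdm_fit(covs: np.ndarray, labels: list[str],
             metric: str = "airm") -> RMDMModel:
    """Fit: one Fréchet mean (AIRM) or log-Euclidean mean per class."""
    covs = np.asarray(covs, dtype=float)
    if len(covs) != len(labels):
        raise ValueError("covs and labels length mismatch")
    if len(covs) == 0:
        raise ValueError("no training covariances")
    means = {}
    for c in sorted(set(labels)):
        sel = covs[[i for i, l in enumerate(labels) if l == c]]
        if len(sel) == 0:
            raise ValueError(f"class {c!r} has no training covariance")
        if metric == "airm":
            means[c] = frechet_mean(sel)
        elif metric == "logeuclid":
            means[c] = _expm_sym(np.mean([_logm_spd(s) for s in sel], axis=0))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return RMDMModel(means, metric)


def rmdm_predict(model: RMDMModel, covs: np.ndarray) -> list[str]:
    """Assign each covariance to the nearest class mean (ties → smaller label)."""
    dist = (airm_distance if model.metric == "airm" else logeuclid_distance)
    labels = sorted(model.class_means)  # lexicographic tie-break via ordering
    out = []
    for c in np.asarray(covs, dtype=float):
        d = [dist(c, model.class_means[l]) for l in labels]
        out.append(labels[int(np.argmin(d))])
    return out


def tangent_project(covs: np.ndarray,
                    base: np.ndarray | None = None) -> np.ndarray:
    """Project covariances onto the tangent space at ``base``.

    Vectorizes S = log(base^{-1/2} C base^{-1/2}) keeping the diagonal and
    the √2-scaled upper off-diagonals, so the Euclidean norm of the vector
    equals the AIRM distance of C to the base point.  Output dimension is
    d(d+1)/2.  ``base`` defaults to the Fréchet mean of the inputs.
    """
    covs = np.asarray(covs, dtype=float)
    if base is None:
        base = frechet_mean(covs)
    base = _check_spd(base, "base")
    _, b_ihalf = _sqrtm_spd(base)
    d = base.shape[0]
    iu = np.triu_indices(d, k=1)
    out = np.empty((len(covs), d * (d + 1) // 2))
    for i, c in enumerate(covs):
        s = _logm_spd(_check_spd(b_ihalf @ c @ b_ihalf, f"projected cov {i}",
                                 tol=1e-6))
        out[i] = np.concatenate([np.diag(s), np.sqrt(2.0) * s[iu]])
    return out


# -------------------------------------------------------- classifier registry

CLASSIFIER_REGISTRY: dict = {}


def register_classifier(name: str, factory) -> None:
    """Register ``factory(seed) -> sklearn-style estimator`` under ``name``."""
    if name in CLASSIFIER_REGISTRY:
        raise ValueError(f"classifier {name!r} already registered")
    CLASSIFIER_REGISTRY[name] = factory


def _default_registry() -> None:
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    register_classifier("dt", lambda seed: DecisionTreeClassifier(
        random_state=seed))
    register_classifier("rf", lambda seed: RandomForestClassifier(
        n_estimators=100, random_state=seed))
    register_classifier("svm", lambda seed: SVC(kernel="rbf", C=1.0,
                                                random_state=seed))
    register_classifier("nb", lambda seed: GaussianNB())


_default_registry()


def make_classifier(name: str, seed: int = 0):
    if name not in CLASSIFIER_REGISTRY:
        raise KeyError(f"unknown classifier {name!r}; registry: "
                       f"{sorted(CLASSIFIER_REGISTRY)}")
    return CLASSIFIER_REGISTRY[name](seed)


def registry_fit_predict(name: str, train_x: np.ndarray, train_y: list[str],
                         test_x: np.ndarray, seed: int = 0) -> list[str]:
    """Uniform train/predict call for any registered classifier."""
    clf = make_classifier(name, seed)
    clf.fit(np.asarray(train_x), np.asarray(train_y))
    return list(clf.predict(np.asarray(test_x)))


# ------------------------------------------------------------------ evaluation

def matthews_corrcoef(confusion: np.ndarray) -> float:
    """Multi-class MCC (Gorodkin) from a confusion matrix C[true, pred]."""
    C = np.asarray(confusion, dtype=float)
    t = C.sum(axis=1)   # per-true-class totals
    p = C.sum(axis=0)   # per-predicted totals
    n = C.sum()
    cov_yy = n * np.trace(C) - t @ p
    cov_tt = n ** 2 - t @ t
    cov_pp = n ** 2 - p @ p
    denom = np.sqrt(cov_tt * cov_pp)
    return float(cov_yy / denom) if denom > 0 else 0.0


@dataclass
class EvalReport:
    """Cross-validation summary: per-fold and mean accuracy (%) and MCC."""

    fold_accuracy: list[float]
    fold_mcc: list[float]
    confusion: np.ndarray
    classes: list[str]
    seed: int
    fold_assignment: np.ndarray
    mean_accuracy: float = field(init=False)
    mean_mcc: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_accuracy = float(np.mean(self.fold_accuracy))
        self.mean_mcc = float(np.mean(self.fold_mcc))


def crossvalidate(inputs: np.ndarray, labels: list[str], model_spec: dict,
                  k: int = 5, seed: int = 0) -> EvalReport:
    """Stratified k-fold evaluation with accuracy (%) and MCC per fold.

    ``model_spec`` is either ``{"model": "rmdm"}`` (inputs are SPD
    covariance stacks) or ``{"model": <registry name>, ...}`` (inputs are
    feature vectors).  The confusion matrix is pooled over folds.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = [str(l) for l in labels]
    classes = sorted(set(labels))
    y = np.array(labels)
    counts = {c: labels.count(c) for c in classes}
    if min(counts.values()) < k:
        raise ValueError(
            f"smallest class has {min(counts.values())} members; "
            f"cannot stratify into {k} folds")
    name = model_spec["model"]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    idx_class = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc, fold_mcc = [], []
    assignment = np.empty(len(labels), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), y)):
        assignment[te] = fold
        if name == "rmdm":
            model = rmdm_fit(inputs[tr], [labels[i] for i in tr],
                             metric=model_spec.get("metric", "airm"))
            pred = rmdm_predict(model, inputs[te])
        else:
            pred = registry_fit_predict(
                name, inputs[tr], [labels[i] for i in tr], inputs[te],
                seed=seed)
        fc = np.zeros_like(conf)
        for i, p in zip(te, pred):
            fc[idx_class[labels[i]], idx_class[p]] += 1
        conf += fc
        fold_acc.append(100.0 * np.trace(fc) / fc.sum())
        fold_mcc.append(matthews_corrcoef(fc))
    return EvalReport(fold_acc, fold_mcc, conf, classes, seed, assignment)
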