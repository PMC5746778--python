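"""Fall detection from micro-motion signatures with a one-class SVM.

Signatures over a sliding detection window (default 4 s, 1 s stride) are
vectorized into: the window-mean Doppler profile, movement-amplitude
statistics (max, mean, variance), the range excursion, and the post-peak
immobility fraction (falls end with the subject motionless, so stillness
right after a large amplitude peak is discriminative).  An RBF-kernel
one-class SVM is trained either on fall windows (supervised protocol: train
on one cohort's falls, test on another's) or on ADL-only windows
(unsupervised protocol: falls are flagged as anomalies, so no fall data is
needed for training — the realistic deployment setting).  Scores are
oriented so that larger means more fall-like in both modes; consecutive
positive windows merge into one event.  ROC analysis sweeps the score
threshold, reports the trapezoidal AUC and the Youden-optimal operating
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import OneClassSVM

from .micromotion import MicroMotionSignature

__all__ = [
    "FeatureSpec",
    "FeatureWindow",
    "DetectorModel",
    "DetectionMetrics",
    "AccuracyReport",
    "FallDetectError",
    "build_features",
    "train",
    "detect",
    "merge_events",
    "roc_analysis",
    "accuracy_mre",
]


class FallDetectError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSpec:
    """Detection windowing and feature composition."""

    window_s: float = 4.0
    stride_s: float = 1.0
    immobility_fraction: float = 0.05  # amplitude below this fraction of the
    # window peak counts as immobile


@dataclass
class FeatureWindow:
    """One detection window's feature vector and its start time."""

    features: np.ndarray
    start: float


def _window_features(sigs: list[MicroMotionSignature], spec: FeatureSpec) -> np.ndarray:
    profiles = np.stack([s.profile for s in sigs])
    amps = np.array([s.amplitude for s in sigs])
    dists = np.array([s.distance for s in sigs])
    dists = dists[np.isfinite(dists)]
    range_drop = float(dists.max() - dists.min()) if dists.size else 0.0
    peak_idx = int(np.argmax(amps))
    peak = amps[peak_idx]
    if peak > 0 and peak_idx < amps.size - 1:
        after = amps[peak_idx + 1 :]
        immobility = float(np.mean(after < spec.immobility_fraction * peak))
    else:
        immobility = 0.0
    # energy-derived quantities span orders of magnitude between quiet
    # sitting and a fall impact; log compression keeps distances informative
    # where an RBF kernel would otherwise saturate for every far outlier
    return np.concatenate(
        [
            np.log1p(profiles.mean(axis=0)),
            np.log1p([amps.max(), amps.mean(), amps.var()]),
            [range_drop, immobility],
        ]
    )


def build_features(
    signatures: list[MicroMotionSignature], spec: FeatureSpec | None = None
) -> list[FeatureWindow]:
    """Sliding-window feature vectors from a signature sequence.

    Windows without enough signature history are skipped; the feature
    dimensionality is constant (n_dtft profile bins + 5 statistics).
    """
    spec = spec or FeatureSpec()
    if not signatures:
        return []
    times = np.array([s.window_start for s in signatures])
    t0, t_end = times[0], times[-1]
    out: list[FeatureWindow] = []
    start = t0
    while start + spec.window_s <= t_end + 1e-9:
        mask = (times >= start) & (times < start + spec.window_s)
        if mask.sum() >= 2:
            sigs = [signatures[i] for i in np.nonzero(mask)[0]]
            out.append(FeatureWindow(_window_features(sigs, spec), float(start)))
        start += spec.stride_s
    return out


@dataclass
class DetectorModel:
    """Fitted one-class boundary plus the scaling fitted on training data.

    ``mode`` is "supervised" (trained on fall windows; fall-likeness grows
    with the decision function) or "unsupervised" (trained on ADL windows;
    falls are anomalies, so fall-likeness is the negated decision function).
    """

    mode: str
    nu: float
    gamma: float | str
    threshold: float = 0.0
    scaler: StandardScaler = field(default_factory=StandardScaler)
    svm: OneClassSVM | None = None
    training_minutes: float = 0.0
    seed: int | None = None

    def score(self, features: np.ndarray) -> np.ndarray:
        """Fall-likeness score per window (monotone in the signed distance
        from the learned boundary)."""
        if self.svm is None:
            raise FallDetectError("model is not trained")
        x = self.scaler.transform(np.atleast_2d(features))
        raw = self.svm.decision_function(x)
        return raw if self.mode == "supervised" else -raw


def train(
    features: list[FeatureWindow] | np.ndarray,
    mode: str = "unsupervised",
    nu: float = 0.05,
    gamma: float | str = "scale",
    threshold: float = 0.0,
    training_minutes: float = 0.0,
    seed: int | None = None,
) -> DetectorModel:
    """Fit the one-class SVM on the given training windows.

    Supervised mode expects fall windows; unsupervised mode expects
    ADL-only windows.  Fitting is deterministic for fixed inputs.
    """
    if mode not in ("supervised", "unsupervised"):
        raise FallDetectError(f"unknown mode {mode!r}")
    x = _as_matrix(features)
    if x.shape[0] == 0:
        raise FallDetectError("empty training set")
    if not 0 < nu <= 1:
        raise FallDetectError("nu must lie in (0, 1]")
    model = DetectorModel(
        mode=mode, nu=nu, gamma=gamma, threshold=threshold,
        training_minutes=training_minutes, seed=seed,
    )
    xs = model.scaler.fit_transform(x)
    model.svm = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma).fit(xs)
    return model


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.atleast_2d(features)
    return (
        np.stack([f.features for f in features])
        if features
        else np.empty((0, 0))
    )


def detect(
    model: DetectorModel, features: list[FeatureWindow] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window fall labels and scores; label = score above the model
    threshold."""
    x = _as_matrix(features)
    if x.shape[0] == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    scores = model.score(x)
    return scores > model.threshold, scores


def merge_events(labels: np.ndarray, starts: np.ndarray | None = None) -> list[tuple[int, int]]:
    """Merge runs of consecutive positive windows into (first, last) events."""
    labels = np.asarray(labels, dtype=bool)
    events: list[tuple[int, int]] = []
    i = 0
    while i < labels.size:
        if labels[i]:
            j = i
            while j + 1 < labels.size and labels[j + 1]:
                j += 1
            events.append((i, j))
            i = j + 1
        else:
            i += 1
    return events


@dataclass
class DetectionMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    auc: float
    best_threshold: float

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def fpr(self) -> float:
        return 1.0 - self.tnr


def roc_analysis(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[DetectionMetrics, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Threshold sweep: trapezoidal AUC, Youden-optimal operating point, and
    the (fpr, tpr, thresholds) curve."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise FallDetectError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise FallDetectError("need both positive and negative examples")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    youden = tpr - fpr
    best = int(np.argmax(youden))
    best_threshold = float(thresholds[best])
    pred = scores >= best_threshold
    metrics = DetectionMetrics(
        tp=int(np.sum(pred & labels)),
        tn=int(np.sum(~pred & ~labels)),
        fp=int(np.sum(pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
        auc=auc,
        best_threshold=best_threshold,
    )
    return metrics, (fpr, tpr, thresholds)


@dataclass
class AccuracyReport:
    """Vital-sign accuracy versus a reference series: accuracy = 1 - MRE."""

    mre: float

    @property
    def accuracy(self) -> float:
        return 1.0 - self.mre


def accuracy_mre(measured: np.ndarray, reference: np.ndarray) -> AccuracyReport:
    """Mean relative error MRE = mean(|measured - reference| / reference)."""
    measured = np.asarray(measured, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if measured.shape != reference.shape:
        raise FallDetectError("series must have equal length")
    if np.any(reference <= 0):
        raise FallDetectError("reference values must be positive")
    return AccuracyReport(mre=float(np.mean(np.abs(measured - reference) / reference)))
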