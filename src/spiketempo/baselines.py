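"""Bin-count features and the bin-based classifier roster.

The conventional route to decoding spike trains is to discretize time:
count the spikes of each channel in fixed bins over the analysis
window, concatenate the per-channel count vectors channel-major, and
feed the result to a vector classifier.  Binning necessarily discards
within-bin spike timing — the property the spiking decoders in
:mod:`spiketempo.tempotron` are designed to exploit.

The roster follows common practice in this literature: decision tree,
k-nearest neighbors, linear discriminant analysis, linear and RBF
support-vector machines (all delegated to scikit-learn), plus a
diagonal-Gaussian maximum-likelihood classifier implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import Trial

__all__ = [
    "BinFeatures",
    "bin_features",
    "feature_matrix",
    "GaussianMLE",
    "make_classifier",
    "BinDecoder",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("dt", "knn", "lda", "mle", "svm-l", "svm-r")


@dataclass(frozen=True)
class BinFeatures:
    """Per-channel spike-count vectors and their concatenation."""

    per_neuron: np.ndarray  # (n_channels, M) counts
    bin_size: float
    period: float

    @property
    def M(self) -> int:
        return int(self.per_neuron.shape[1])

    @property
    def concatenated(self) -> np.ndarray:
        return self.per_neuron.reshape(-1)


def bin_features(trial: Trial, bin_size: float, period: float) -> BinFeatures:
    """Spike counts per channel in half-open bins [b*h, (b+1)*h).

    ``period`` must be an integer multiple of ``bin_size``; M =
    period / bin_size bins per channel.  Counts sum to the number of
    spikes in [0, period).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if period <= 0 or period > trial.duration:
        raise ValueError(
            f"period must lie in (0, duration={trial.duration}], got {period}"
        )
    ratio = period / bin_size
    M = round(ratio)
    if M < 1 or abs(ratio - M) > 1e-9 * max(1.0, ratio):
        raise ValueError(
            f"period {period} is not an integer multiple of bin_size {bin_size}"
        )
    edges = np.linspace(0.0, period, M + 1)
    counts = np.empty((trial.n_channels, M), dtype=int)
    for c, times in enumerate(trial.spike_times()):
        # histogram's closed last edge is harmless: spike times < duration
        # and spikes at t >= period are excluded first
        counts[c] = np.histogram(times[times < period], bins=edges)[0]
    return BinFeatures(per_neuron=counts, bin_size=bin_size, period=period)


def feature_matrix(
    trials: Sequence[Trial], bin_size: float, period: float
) -> np.ndarray:
    """Stacked concatenated bin features, one row per trial."""
    return np.stack(
        [bin_features(t, bin_size, period).concatenated for t in trials]
    ).astype(float)


class GaussianMLE:
    """Diagonal-Gaussian maximum-likelihood classifier.

    Fits an independent Gaussian per feature per class and classifies by
    the largest summed log-likelihood.  Variances are floored at
    ``var_floor`` so constant features cannot produce degenerate
    densities.  A full covariance would be singular at the sample sizes
    typical here (tens of trials against dozens of features), hence the
    diagonal model.
    """

    def __init__(self, var_floor: float = 1e-6):
        self.var_floor = var_floor
        self.classes_: Optional[np.ndarray] = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("GaussianMLE needs >= 2 classes")
        means, variances = [], []
        for c in self.classes_:
            Xc = X[y == c]
            if Xc.shape[0] < 2:
                raise ValueError(
                    f"class {c!r} has {Xc.shape[0]} sample(s); need >= 2"
                )
            means.append(Xc.mean(axis=0))
            variances.append(np.maximum(Xc.var(axis=0), self.var_floor))
        self.means_ = np.stack(means)
        self.vars_ = np.stack(variances)
        return self

    def _log_likelihood(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        diff = X[:, None, :] - self.means_[None, :, :]
        return -0.5 * np.sum(
            diff**2 / self.vars_ + np.log(2.0 * np.pi * self.vars_), axis=2
        )

    def predict(self, X):
        if self.classes_ is None:
            raise RuntimeError("classifier is not fitted")
        return self.classes_[np.argmax(self._log_likelihood(X), axis=1)]


def make_classifier(name: str, random_state: int = 0, **params):
    """Fresh classifier by roster name: dt, knn, lda, mle, svm-l, svm-r."""
    if name == "dt":
        return DecisionTreeClassifier(random_state=random_state, **params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    if name == "lda":
        return LinearDiscriminantAnalysis(**params)
    if name == "mle":
        return GaussianMLE(**params)
    if name == "svm-l":
        return SVC(kernel="linear", random_state=random_state, **params)
    if name == "svm-r":
        return SVC(kernel="rbf", random_state=random_state, **params)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


class BinDecoder:
    """Decoder-protocol adapter: bin features + a roster classifier."""

    def __init__(
        self,
        clf_name: str = "mle",
        bin_size: float = 0.5,
        period: Optional[float] = None,
        random_state: int = 0,
        **clf_params,
    ):
        self.clf_name = clf_name
        self.bin_size = bin_size
        self.period = period
        self.random_state = random_state
        self.clf_params = clf_params
        self._clf = None

    def fit(self, trials: Sequence[Trial], classes: Sequence[str]):
        period = self.period if self.period is not None else trials[0].duration
        self._period = period
        X = feature_matrix(trials, self.bin_size, period)
        y = np.asarray([t.label for t in trials])
        self._clf = make_classifier(
            self.clf_name, random_state=self.random_state, **self.clf_params
        )
        self._clf.fit(X, y)
        return self

    def predict(self, trial: Trial) -> str:
        if self._clf is None:
            raise RuntimeError("decoder is not fitted")
        x = bin_features(trial, self.bin_size, self._period).concatenated
        return str(self._clf.predict(x.reshape(1, -1))[0])
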