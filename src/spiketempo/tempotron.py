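"""Tempotron learning and its voltage-regulated variant.

The decoder is a two-layer spiking network: input channels project with
plastic weights onto ``C`` groups of ``G`` LIF output neurons, one group
per class.  Each output neuron fires at most one spike per trial; a
trial's class is read out by majority vote over firing neurons per group.

**Classic Tempotron** is error-driven: when the target neuron stays
silent its weights grow, when a non-target neuron fires its weights
shrink, and correctly behaving neurons are untouched.  The update for
channel i is the kernel-weighted credit of its spikes at the time of
the voltage maximum,

    dw_i = lam * sum_{ti < tmax} K(tmax - ti).

**Voltage regulation (VR)** replaces the error gate with a graded
factor derived from the softplus-transformed voltage maxima across
groups.  With f(V) = ln(e^V + 1) and S = sum_m f(V_m), the factor for a
neuron in the target group is f'(V)*(1/f(V) - 1/S) > 0 and for other
groups f'(V)*(-1/S) < 0; every neuron is updated by dw_i * F' on every
presentation.  Target-group maxima are continually pushed up and the
rest down, which regularizes voltage margins and helps generalization
when training sets are small.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, field
from typing import Optional, Sequence, Union

import numpy as np

from .data import Dataset, Trial
from .lif import LIFParams, evaluation_grid, psp_kernel, psp_matrix

__all__ = [
    "TrainConfig",
    "NetworkModel",
    "tempotron_delta",
    "vr_factor",
    "vr_delta",
    "train",
    "train_epoch",
    "predict",
    "save_model",
    "load_model",
    "TempotronDecoder",
]


@dataclass(frozen=True)
class TrainConfig:
    """Learning hyperparameters.

    lam        : learning rate; caps the per-spike weight change
    max_epochs : hard limit on passes over the training set
    group_size : output neurons per class group (G)
    use_vr     : voltage-regulated updates instead of error-gated ones
    shuffle_seed : master seed for weight init and epoch shuffling
    init_scale : std of the Gaussian weight initialization
    early_stop_patience : classic mode only — epochs without
                 training-accuracy improvement tolerated before stopping.
                 The regulated mode always runs the full epoch budget:
                 it is built to keep widening voltage margins after
                 training accuracy saturates, so a plateau is not a
                 stopping signal for it.
    """

    lam: float = 5e-3
    max_epochs: int = 200
    group_size: int = 5
    use_vr: bool = False
    shuffle_seed: int = 0
    init_scale: float = 0.01
    early_stop_patience: int = 60

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if self.init_scale < 0:
            raise ValueError("init_scale must be >= 0")


@dataclass
class NetworkModel:
    """Trained readout: weights (C groups x G neurons x N channels)."""

    weights: np.ndarray
    params: LIFParams
    class_labels: tuple[str, ...]
    group_size: int
    rng_seed: int = 0
    history: list = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def n_channels(self) -> int:
        return int(self.weights.shape[-1])


def tempotron_delta(
    trial: Trial, t_max: float, params: LIFParams, lam: float
) -> np.ndarray:
    """Per-channel unsigned weight update at the voltage maximum.

    dw_i = lam * sum over spikes ti < t_max of K(t_max - ti).  The sign
    (potentiation for a silent target neuron, depression for an
    erroneously firing one) is applied by the caller.
    """
    out = np.zeros(trial.n_channels)
    for c, times in enumerate(trial.spike_times()):
        past = times[times < t_max]
        if past.size:
            out[c] = float(np.sum(psp_kernel(t_max - past, params)))
    return lam * out


def _softplus(v: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, v)


def _sigmoid(v: np.ndarray) -> np.ndarray:
    out = np.empty_like(v, dtype=float)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out


def vr_factor(v_max_by_group: Sequence[float], target_group: int) -> np.ndarray:
    """Voltage-regulation factors F' for one within-group neuron index.

    Given the voltage maxima of the n-th neuron of each of the C groups
    and the index of the trial's target group, returns the C factors:
    positive for the target group, negative for every other group.
    Softplus keeps every transformed voltage positive, so no division
    by zero can occur for finite inputs.
    """
    v = np.asarray(v_max_by_group, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need voltage maxima for C >= 2 groups")
    if not 0 <= target_group < v.size:
        raise ValueError(f"target_group {target_group} out of range")
    f = _softplus(v)
    fp = _sigmoid(v)
    total = float(f.sum())
    out = fp * (-1.0 / total)
    out[target_group] = fp[target_group] * (1.0 / f[target_group] - 1.0 / total)
    return out


def vr_delta(
    trial: Trial,
    t_max: float,
    params: LIFParams,
    lam: float,
    f_prime: float,
) -> np.ndarray:
    """Regulated update: the Tempotron credit scaled by the factor F'.

    F' carries the sign — positive drives the target group toward
    firing, negative suppresses the others.
    """
    return tempotron_delta(trial, t_max, params, lam) * f_prime


# ---------------------------------------------------------------------------
# training internals: trials are compiled once into PSP matrices so every
# epoch (and every output neuron) reuses the same kernel sums


class _CompiledTrial:
    __slots__ = ("grid", "psp", "label_idx")

    def __init__(self, trial: Trial, params: LIFParams, label_idx: Optional[int]):
        self.grid = evaluation_grid(trial, params)
        self.psp = psp_matrix(trial, self.grid, params)
        self.label_idx = label_idx


def _compile(trials, params, class_labels):
    index = {lab: i for i, lab in enumerate(class_labels)}
    return [
        _CompiledTrial(t, params, index.get(t.label) if t.label else None)
        for t in trials
    ]


def _neuron_maxima(ct: _CompiledTrial, W: np.ndarray, v_rest: float):
    """Voltage maxima and their grid rows for all neurons on one trial.

    W is (n_neurons, n_channels); returns (v_max, argmax_row) arrays.
    np.argmax returns the first maximum, i.e. the earliest tied time.
    """
    V = ct.psp @ W.T + v_rest
    rows = np.argmax(V, axis=0)
    return V[rows, np.arange(W.shape[0])], rows


def _vote(v_max: np.ndarray, theta: float, C: int, G: int) -> int:
    """Majority vote over firing neurons; ties by summed v_max, then index."""
    fired = (v_max > theta).reshape(C, G)
    counts = fired.sum(axis=1)
    vsum = v_max.reshape(C, G).sum(axis=1)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if tied.size == 1:
        return int(tied[0])
    return int(tied[np.argmax(vsum[tied])])


def train_epoch(
    compiled: Sequence[_CompiledTrial],
    W: np.ndarray,
    params: LIFParams,
    config: TrainConfig,
    order: Sequence[int],
) -> int:
    """One online pass over the training trials; mutates W in place.

    Returns the number of neuron-level output errors encountered (a
    zero-error classic-mode epoch provably leaves W unchanged, since
    every classic update is gated on an error).
    """
    C = W.shape[0] // config.group_size
    G = config.group_size
    groups = np.repeat(np.arange(C), G)
    n_errors = 0
    for k in order:
        ct = compiled[k]
        target = ct.label_idx
        v_max, rows = _neuron_maxima(ct, W, params.v_rest)
        fired = v_max > params.theta
        is_target = groups == target
        wrong = np.where(is_target, ~fired, fired)
        n_errors += int(wrong.sum())
        delta_rows = ct.psp[rows]  # (n_neurons, n_channels) kernel sums at tmax
        if config.use_vr:
            # factors computed per within-group neuron index across groups
            scale = np.empty(W.shape[0])
            vm = v_max.reshape(C, G)
            for n in range(G):
                scale[n::G] = vr_factor(vm[:, n], target)
            W += config.lam * scale[:, None] * delta_rows
        else:
            sign = np.where(is_target & ~fired, 1.0, 0.0)
            sign = np.where(~is_target & fired, -1.0, sign)
            W += config.lam * sign[:, None] * delta_rows
    return n_errors


def _training_accuracy(compiled, W, params, C, G) -> float:
    correct = 0
    for ct in compiled:
        v_max, _ = _neuron_maxima(ct, W, params.v_rest)
        correct += _vote(v_max, params.theta, C, G) == ct.label_idx
    return correct / len(compiled)


def train(
    dataset: Union[Dataset, Sequence[Trial]],
    config: TrainConfig,
    params: Optional[LIFParams] = None,
    class_labels: Optional[Sequence[str]] = None,
) -> NetworkModel:
    """Fit a grouped-output spiking readout to labeled trials.

    Weights start from a seeded Gaussian(0, init_scale^2); each epoch
    visits the trials in a freshly shuffled seeded order and applies
    either error-gated classic updates or voltage-regulated updates to
    every neuron (``config.use_vr``).  Classic training stops at
    ``max_epochs``, at a zero-error epoch (after which the gated rule
    can change nothing), or once training accuracy has not improved for
    ``early_stop_patience`` consecutive epochs; regulated training runs
    the full ``max_epochs`` because its margin growth deliberately
    continues past the training-accuracy plateau.  The final-epoch
    weights are returned.  Identical data, config and seeds reproduce
    the identical model.
    """
    params = params or LIFParams()
    if isinstance(dataset, Dataset):
        trials = list(dataset.trials)
        labels = class_labels or dataset.classes
    else:
        trials = list(dataset)
        labels = class_labels or tuple(
            sorted({t.label for t in trials if t.label is not None})
        )
    labels = tuple(labels)
    trials = [t for t in trials if t.label is not None]
    if not trials:
        raise ValueError("training requires labeled trials")
    present = {t.label for t in trials}
    if len(present) < 2:
        raise ValueError(f"need >= 2 classes to train, got {sorted(present)}")
    C, G = len(labels), config.group_size
    n_channels = trials[0].n_channels

    ss = np.random.SeedSequence(config.shuffle_seed)
    init_ss, shuffle_ss = ss.spawn(2)
    # independent stream per output neuron, so G or C changes do not
    # reshuffle the init of unrelated neurons
    neuron_streams = init_ss.spawn(C * G)
    W = np.stack(
        [
            np.random.default_rng(s).normal(0.0, config.init_scale, size=n_channels)
            for s in neuron_streams
        ]
    )
    shuffle_rng = np.random.default_rng(shuffle_ss)

    compiled = _compile(trials, params, labels)
    history: list[dict] = []
    best_acc, best_epoch = -1.0, 0
    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(len(compiled))
        n_err = train_epoch(compiled, W, params, config, order)
        acc = _training_accuracy(compiled, W, params, C, G)
        history.append({"epoch": epoch, "train_accuracy": acc, "neuron_errors": n_err})
        if acc > best_acc:
            best_acc, best_epoch = acc, epoch
        if not config.use_vr:
            if n_err == 0:
                break  # error-gated updates are frozen from here on
            if epoch - best_epoch >= config.early_stop_patience:
                break

    # final weights, not a best-epoch snapshot: the regulated rule keeps
    # widening voltage margins after training accuracy saturates, which
    # is where its small-sample benefit comes from
    return NetworkModel(
        weights=W.reshape(C, G, n_channels),
        params=params,
        class_labels=labels,
        group_size=G,
        rng_seed=config.shuffle_seed,
        history=history,
    )


def predict(model: NetworkModel, trial: Trial) -> str:
    """Class label by majority vote over firing neurons per group.

    All-silent trials and tied counts fall back to the largest summed
    voltage maximum over the tied groups' neurons, then the lowest
    class index.
    """
    if trial.n_channels != model.n_channels:
        raise ValueError(
            f"trial has {trial.n_channels} channels, model expects "
            f"{model.n_channels}"
        )
    C, G = model.n_classes, model.group_size
    W = model.weights.reshape(C * G, model.n_channels)
    ct = _CompiledTrial(trial, model.params, None)
    v_max, _ = _neuron_maxima(ct, W, model.params.v_rest)
    return model.class_labels[_vote(v_max, model.params.theta, C, G)]


def predict_dataset(model: NetworkModel, trials) -> list[str]:
    return [predict(model, t) for t in trials]


def save_model(model: NetworkModel, path: Union[str, os.PathLike]) -> None:
    bundle = {
        "class_labels": list(model.class_labels),
        "group_size": model.group_size,
        "rng_seed": model.rng_seed,
        "lif": {
            "tau": model.params.tau,
            "tau_s": model.params.tau_s,
            "theta": model.params.theta,
            "v_rest": model.params.v_rest,
            "grid_dt": model.params.grid_dt,
        },
        "weights": model.weights.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh)


def load_model(path: Union[str, os.PathLike]) -> NetworkModel:
    with open(path) as fh:
        bundle = json.load(fh)
    return NetworkModel(
        weights=np.asarray(bundle["weights"], dtype=float),
        params=LIFParams(**bundle["lif"]),
        class_labels=tuple(bundle["class_labels"]),
        group_size=int(bundle["group_size"]),
        rng_seed=int(bundle.get("rng_seed", 0)),
    )


class TempotronDecoder:
    """Decoder-protocol adapter: ``fit(trials, classes)`` / ``predict(trial)``."""

    def __init__(
        self,
        params: Optional[LIFParams] = None,
        config: Optional[TrainConfig] = None,
        **overrides,
    ):
        self.params = params or LIFParams()
        cfg = config or TrainConfig()
        if overrides:
            cfg = TrainConfig(**{**asdict(cfg), **overrides})
        self.config = cfg
        self.model: Optional[NetworkModel] = None

    def fit(self, trials: Sequence[Trial], classes: Sequence[str]):
        self.model = train(trials, self.config, self.params, class_labels=classes)
        return self

    def predict(self, trial: Trial) -> str:
        if self.model is None:
            raise RuntimeError("decoder is not fitted")
        return predict(self.model, trial)
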