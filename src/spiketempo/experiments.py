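"""Evaluation protocols for trial-based spike-train decoders.

The reference protocol is the *random test*: many repetitions of a
seeded stratified split (a fixed number of training samples per class,
the rest held out), a decoder trained fresh per repetition, and the
mean held-out accuracy reported.  Hyperparameters are chosen inside
each repetition by a 20% stratified validation holdout of the training
set.  Sweeps rerun the protocol along one axis: feature bin size,
number of training sample groups (one sample of each class per group),
or the post-onset time window both train and test trials are truncated
to (quick recognition).

Splits depend only on the master seed, never on the decoder, so
different decoders evaluated with the same seed see identical splits
and are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .baselines import CLASSIFIER_NAMES, BinDecoder
from .data import Dataset, Trial, truncate_dataset
from .lif import LIFParams
from .tempotron import TempotronDecoder, TrainConfig

__all__ = [
    "DecoderSpec",
    "make_decoder_spec",
    "ExperimentResult",
    "random_test_protocol",
    "cv_select",
    "sweep",
    "results_to_frame",
    "DECODER_NAMES",
]

DECODER_NAMES = ("tempotron", "tempotron-vr") + CLASSIFIER_NAMES

_LIF_KEYS = {"tau", "tau_s", "theta", "v_rest", "grid_dt"}


@dataclass(frozen=True)
class DecoderSpec:
    """A named decoder factory plus an optional hyperparameter grid.

    ``factory(random_state, **params)`` must return an unfitted decoder
    exposing ``fit(trials, classes)`` and ``predict(trial)``.
    """

    name: str
    factory: Callable
    param_grid: tuple = ()

    def build(self, random_state: int, **params):
        return self.factory(random_state=random_state, **params)


def make_decoder_spec(
    name: str,
    lif: Optional[LIFParams] = None,
    train_config: Optional[TrainConfig] = None,
    bin_size: float = 0.5,
    period: Optional[float] = None,
    param_grid: Sequence[dict] = (),
    **fixed,
) -> DecoderSpec:
    """Decoder spec by roster name.

    ``tempotron`` / ``tempotron-vr`` build spiking decoders (grid keys
    may address LIF fields like ``tau``/``tau_s`` or training fields
    like ``lam``); the remaining names build bin-feature decoders
    (grid keys like ``bin_size``, ``n_neighbors``, ``C``, ``gamma``).
    """
    if name in ("tempotron", "tempotron-vr"):
        base_lif = lif or LIFParams()
        base_cfg = train_config or TrainConfig()
        use_vr = name == "tempotron-vr"

        def factory(random_state: int = 0, **params):
            p = {**fixed, **params}
            lif_over = {k: v for k, v in p.items() if k in _LIF_KEYS}
            cfg_over = {k: v for k, v in p.items() if k not in _LIF_KEYS}
            lif_kwargs = {
                "tau": base_lif.tau, "tau_s": base_lif.tau_s,
                "theta": base_lif.theta, "v_rest": base_lif.v_rest,
                "grid_dt": base_lif.grid_dt, **lif_over,
            }
            cfg_kwargs = {
                **{k: v for k, v in asdict(base_cfg).items()},
                "use_vr": use_vr, "shuffle_seed": random_state, **cfg_over,
            }
            return TempotronDecoder(LIFParams(**lif_kwargs), TrainConfig(**cfg_kwargs))

        return DecoderSpec(name=name, factory=factory, param_grid=tuple(param_grid))

    if name in CLASSIFIER_NAMES:

        def factory(random_state: int = 0, **params):
            p = {"bin_size": bin_size, "period": period, **fixed, **params}
            return BinDecoder(clf_name=name, random_state=random_state, **p)

        return DecoderSpec(name=name, factory=factory, param_grid=tuple(param_grid))

    raise ValueError(f"unknown decoder {name!r}; choose from {DECODER_NAMES}")


@dataclass
class ExperimentResult:
    """Per-repetition held-out accuracies plus their summary."""

    per_repetition_accuracy: np.ndarray
    config_snapshot: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_repetition_accuracy))

    @property
    def std(self) -> float:
        return float(np.std(self.per_repetition_accuracy))

    @property
    def n_reps(self) -> int:
        return int(len(self.per_repetition_accuracy))


def _labeled_by_class(dataset: Dataset) -> dict[str, list[int]]:
    by_class: dict[str, list[int]] = {c: [] for c in dataset.classes}
    for i, t in enumerate(dataset.trials):
        if t.label is not None:
            by_class[t.label].append(i)
    return {c: idx for c, idx in by_class.items() if idx}


def _stratified_split(by_class, k_train: int, rng) -> tuple[list[int], list[int]]:
    train_idx, test_idx = [], []
    for c in by_class:
        perm = rng.permutation(by_class[c])
        train_idx.extend(int(i) for i in perm[:k_train])
        test_idx.extend(int(i) for i in perm[k_train:])
    return train_idx, test_idx


def cv_select(
    train_trials: Sequence[Trial],
    classes: Sequence[str],
    spec: DecoderSpec,
    param_grid: Sequence[dict],
    seed: int,
    holdout_frac: float = 0.2,
):
    """Grid selection on a stratified validation holdout.

    Holds out ``holdout_frac`` of the training set (at least one sample
    per class), scores every grid point fitted on the remainder, picks
    the argmax (ties resolved toward the earlier grid entry), and
    refits the winner on the full training set.  Returns
    ``(best_params, fitted_decoder)``.
    """
    grid = list(param_grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if len(grid) == 1:
        best = grid[0]
        return best, spec.build(int(rng.integers(2**31)), **best).fit(
            train_trials, classes
        )

    by_class: dict[str, list[int]] = {}
    for i, t in enumerate(train_trials):
        by_class.setdefault(t.label, []).append(i)
    fit_idx, val_idx = [], []
    for c in sorted(by_class):
        perm = rng.permutation(by_class[c])
        n_val = max(1, round(holdout_frac * len(perm)))
        val_idx.extend(int(i) for i in perm[:n_val])
        fit_idx.extend(int(i) for i in perm[n_val:])
    fit_trials = [train_trials[i] for i in fit_idx]
    val_trials = [train_trials[i] for i in val_idx]

    build_seed = int(rng.integers(2**31))
    scores = []
    for params in grid:
        dec = spec.build(build_seed, **params).fit(fit_trials, classes)
        hits = sum(dec.predict(t) == t.label for t in val_trials)
        scores.append(hits / len(val_trials))
    best = grid[int(np.argmax(scores))]
    fitted = spec.build(build_seed, **best).fit(train_trials, classes)
    return best, fitted


def random_test_protocol(
    dataset: Dataset,
    spec: DecoderSpec,
    n_reps: int = 100,
    train_per_class: int = 16,
    seed: int = 0,
    use_cv: bool = False,
) -> ExperimentResult:
    """Repeated seeded stratified splits, fresh decoder per repetition.

    Each repetition draws ``train_per_class`` training samples per
    class, tests on the remainder, and records correct/tested.  With
    ``use_cv`` and a nonempty ``spec.param_grid``, hyperparameters are
    selected inside each repetition via :func:`cv_select`.
    """
    by_class = _labeled_by_class(dataset)
    if len(by_class) < 2:
        raise ValueError("protocol needs >= 2 represented classes")
    for c, idx in by_class.items():
        if len(idx) < train_per_class + 1:
            raise ValueError(
                f"class {c!r} has {len(idx)} samples; need > {train_per_class}"
            )
    classes = tuple(c for c in dataset.classes if c in by_class)

    rep_streams = np.random.SeedSequence(seed).spawn(n_reps)
    accs = np.empty(n_reps)
    for r, stream in enumerate(rep_streams):
        rng = np.random.default_rng(stream)
        train_idx, test_idx = _stratified_split(by_class, train_per_class, rng)
        train_trials = [dataset.trials[i] for i in train_idx]
        test_trials = [dataset.trials[i] for i in test_idx]
        dec_seed = int(rng.integers(2**31))
        if use_cv and spec.param_grid:
            _, decoder = cv_select(
                train_trials, classes, spec, spec.param_grid, dec_seed
            )
        else:
            decoder = spec.build(dec_seed).fit(train_trials, classes)
        hits = sum(decoder.predict(t) == t.label for t in test_trials)
        accs[r] = hits / len(test_trials)

    return ExperimentResult(
        per_repetition_accuracy=accs,
        config_snapshot={
            "decoder": spec.name,
            "n_reps": n_reps,
            "train_per_class": train_per_class,
            "use_cv": use_cv,
        },
        seed=seed,
    )


def sweep(
    dataset: Dataset,
    spec: DecoderSpec,
    axis: str,
    values: Sequence,
    n_reps: int = 100,
    seed: int = 0,
    train_per_class: int = 16,
    use_cv: bool = False,
) -> dict:
    """Rerun the random-test protocol along one experimental axis.

    axis = ``bin_size``: feature bin width (bin decoders only; each
    value must divide the analysis period evenly); ``train_groups``:
    number of training sample groups, one sample per class each, the
    rest tested; ``time_period``: both training and test trials are
    truncated to the given post-onset window.  Returns
    ``{value: ExperimentResult}``.
    """
    results: dict = {}
    if axis == "bin_size":
        for v in values:
            ratio = dataset.duration / v
            if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
                raise ValueError(
                    f"bin_size {v} does not divide the period {dataset.duration}"
                )
        for v in values:
            sub = DecoderSpec(
                name=spec.name,
                factory=lambda random_state, _v=v, **p: spec.factory(
                    random_state=random_state, bin_size=_v, **p
                ),
                param_grid=spec.param_grid,
            )
            results[v] = random_test_protocol(
                dataset, sub, n_reps, train_per_class, seed, use_cv
            )
    elif axis == "train_groups":
        n_min = min(len(ix) for ix in _labeled_by_class(dataset).values())
        for v in values:
            if not 1 <= v <= n_min - 1:
                raise ValueError(
                    f"train_groups {v} out of range 1..{n_min - 1}"
                )
        for v in values:
            results[v] = random_test_protocol(
                dataset, spec, n_reps, int(v), seed, use_cv
            )
    elif axis == "time_period":
        for v in values:
            if not 0 < v <= dataset.duration:
                raise ValueError(
                    f"time_period {v} outside (0, {dataset.duration}]"
                )
        for v in values:
            results[v] = random_test_protocol(
                truncate_dataset(dataset, float(v)), spec, n_reps,
                train_per_class, seed, use_cv,
            )
    else:
        raise ValueError(
            f"unknown axis {axis!r}; choose bin_size, train_groups or time_period"
        )
    for v, res in results.items():
        res.config_snapshot.update({"axis": axis, "axis_value": v})
    return results


def results_to_frame(results: dict) -> pd.DataFrame:
    """Long-format table: one row per (axis_value, repetition)."""
    rows = []
    for v, res in results.items():
        for r, acc in enumerate(res.per_repetition_accuracy):
            rows.append({"axis_value": v, "repetition": r, "accuracy": acc})
    return pd.DataFrame(rows)
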