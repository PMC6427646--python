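"""Core containers for multi-channel spike-train trials.

A recording session yields *trials*: one stimulus presentation each, with
the spike times of every recorded unit (channel) expressed in seconds
relative to stimulus onset (t = 0).  A :class:`Dataset` is a collection of
trials sharing channel count and duration, with an ordered label set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["SpikeTrain", "Trial", "Dataset", "truncate"]


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one channel within one trial.

    Times are strictly increasing, nonnegative offsets (seconds) from
    stimulus onset and must stay below the trial duration.
    """

    channel_id: int
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D sequence")
        if t.size and t[0] < 0:
            raise ValueError(f"channel {self.channel_id}: negative spike time {t[0]}")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(
                f"channel {self.channel_id}: spike times not strictly increasing"
            )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation: a spike train per channel plus a label.

    ``trains`` holds exactly one train per channel with channel ids
    0..N-1 in order; ``label`` is None for unlabeled trials.
    """

    trains: tuple[SpikeTrain, ...]
    duration: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "trains", tuple(self.trains))
        if self.duration <= 0:
            raise ValueError("trial duration must be positive")
        ids = [tr.channel_id for tr in self.trains]
        if ids != list(range(len(ids))):
            raise ValueError(f"channel ids must be 0..N-1 in order, got {ids}")
        for tr in self.trains:
            if tr.times.size and tr.times[-1] >= self.duration:
                raise ValueError(
                    f"channel {tr.channel_id}: spike at {tr.times[-1]} s "
                    f">= duration {self.duration} s"
                )

    @property
    def n_channels(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return sum(len(tr) for tr in self.trains)

    def spike_times(self) -> list[np.ndarray]:
        """Per-channel spike-time arrays, in channel order."""
        return [tr.times for tr in self.trains]


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of trials sharing shape and duration."""

    trials: tuple[Trial, ...]
    n_channels: int
    classes: tuple[str, ...] = field(default_factory=tuple)
    duration: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        object.__setattr__(self, "classes", tuple(self.classes))
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class labels")
        dur = self.duration
        for k, t in enumerate(self.trials):
            if t.n_channels != self.n_channels:
                raise ValueError(
                    f"trial {k}: {t.n_channels} channels, expected {self.n_channels}"
                )
            if dur == 0.0:
                dur = t.duration
            elif t.duration != dur:
                raise ValueError(
                    f"trial {k}: duration {t.duration} differs from {dur}"
                )
            if t.label is not None and t.label not in self.classes:
                raise ValueError(f"trial {k}: label {t.label!r} not in classes")
        object.__setattr__(self, "duration", dur)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def labels(self) -> list[Optional[str]]:
        return [t.label for t in self.trials]

    def class_index(self, label: str) -> int:
        return self.classes.index(label)

    def subset(self, indices: Sequence[int]) -> "Dataset":
        """New dataset holding the trials at ``indices`` (order kept)."""
        return Dataset(
            trials=tuple(self.trials[i] for i in indices),
            n_channels=self.n_channels,
            classes=self.classes,
            duration=self.duration,
        )


def truncate(trial: Trial, period: float) -> Trial:
    """Restrict a trial to its first ``period`` seconds.

    Keeps spikes with t < period and sets the trial duration to the
    period; the label is preserved.  Used by the quick-recognition sweep
    that evaluates decoders on short post-onset windows.
    """
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    if period > trial.duration:
        raise ValueError(
            f"period {period} s exceeds trial duration {trial.duration} s"
        )
    trains = tuple(
        SpikeTrain(tr.channel_id, tr.times[tr.times < period]) for tr in trial.trains
    )
    return Trial(trains=trains, duration=period, label=trial.label)


def truncate_dataset(dataset: Dataset, period: float) -> Dataset:
    return Dataset(
        trials=tuple(truncate(t, period) for t in dataset.trials),
        n_channels=dataset.n_channels,
        classes=dataset.classes,
        duration=period,
    )
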