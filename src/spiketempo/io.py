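"""Plain-text spike-event format.

A dataset file is CSV-like with hash-prefixed header lines followed by
one row per spike event::

    #channels=11
    #duration=5.0
    #classes=odor-1,odor-2,odor-3,odor-4
    #trial=0,odor-1
    #trial=1,odor-2
    trial_id,channel_id,spike_time_s,label
    0,0,0.102345678,odor-1
    ...

The ``#trial=`` lines declare every trial with its label (empty label =
unlabeled), which lets trials without any spikes round-trip; files
lacking them are accepted, with trials inferred from event rows.  Times
are written with 17 significant digits so floats round-trip exactly.
"""

from __future__ import annotations

import os
from typing import Optional, Union

import numpy as np

from .data import Dataset, SpikeTrain, Trial

__all__ = ["write_dataset", "read_dataset"]

_COLUMNS = "trial_id,channel_id,spike_time_s,label"


class FormatError(ValueError):
    """Malformed spike-event file; message carries the offending line."""


def write_dataset(dataset: Dataset, path: Union[str, os.PathLike]) -> None:
    """Write a dataset to the spike-event text format."""
    with open(path, "w") as fh:
        fh.write(f"#channels={dataset.n_channels}\n")
        fh.write(f"#duration={dataset.duration!r}\n")
        fh.write(f"#classes={','.join(dataset.classes)}\n")
        for tid, trial in enumerate(dataset.trials):
            fh.write(f"#trial={tid},{trial.label or ''}\n")
        fh.write(_COLUMNS + "\n")
        for tid, trial in enumerate(dataset.trials):
            label = trial.label or ""
            for train in trial.trains:
                for t in train.times:
                    fh.write(f"{tid},{train.channel_id},{t:.17g},{label}\n")


def read_dataset(path: Union[str, os.PathLike]) -> Dataset:
    """Read a spike-event file, validating structure row by row.

    Raises :class:`FormatError` (a ``ValueError``) naming the line
    number for unsorted or negative times, out-of-range channels,
    unknown labels, or inconsistent per-trial labels.
    """
    n_channels: Optional[int] = None
    duration: Optional[float] = None
    classes: tuple[str, ...] = ()
    declared: dict[int, Optional[str]] = {}
    events: dict[int, dict[int, list[float]]] = {}
    labels: dict[int, Optional[str]] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key == "channels":
                    n_channels = int(val)
                elif key == "duration":
                    duration = float(val)
                elif key == "classes":
                    classes = tuple(c for c in val.split(",") if c)
                elif key == "trial":
                    tid_s, _, lab = val.partition(",")
                    tid = int(tid_s)
                    declared[tid] = lab or None
                    if lab and lab not in classes:
                        raise FormatError(
                            f"line {lineno}: label {lab!r} not in header classes"
                        )
                continue
            if line == _COLUMNS:
                continue
            if n_channels is None or duration is None:
                raise FormatError(
                    f"line {lineno}: event row before #channels/#duration headers"
                )
            parts = line.split(",")
            if len(parts) != 4:
                raise FormatError(f"line {lineno}: expected 4 fields, got {len(parts)}")
            try:
                tid, cid, t = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as e:
                raise FormatError(f"line {lineno}: {e}") from None
            lab = parts[3] or None
            if not 0 <= cid < n_channels:
                raise FormatError(
                    f"line {lineno}: channel {cid} out of range 0..{n_channels - 1}"
                )
            if t < 0:
                raise FormatError(f"line {lineno}: negative spike time {t}")
            if t >= duration:
                raise FormatError(
                    f"line {lineno}: spike time {t} >= duration {duration}"
                )
            if lab is not None and lab not in classes:
                raise FormatError(
                    f"line {lineno}: label {lab!r} not in header classes"
                )
            if tid in labels and labels[tid] != lab:
                raise FormatError(
                    f"line {lineno}: trial {tid} label {lab!r} conflicts with "
                    f"{labels[tid]!r}"
                )
            labels[tid] = lab
            chan = events.setdefault(tid, {}).setdefault(cid, [])
            if chan and t <= chan[-1]:
                raise FormatError(
                    f"line {lineno}: trial {tid} channel {cid} times not "
                    f"strictly increasing ({t} after {chan[-1]})"
                )
            chan.append(t)

    if n_channels is None or duration is None:
        raise FormatError("missing #channels or #duration header")

    trial_ids = sorted(declared) if declared else sorted(events)
    for tid in events:
        if declared and tid not in declared:
            raise FormatError(f"trial {tid} has events but no #trial declaration")
    trials = []
    for tid in trial_ids:
        lab = declared.get(tid, labels.get(tid))
        if tid in labels and declared.get(tid, labels[tid]) != labels[tid]:
            raise FormatError(
                f"trial {tid}: row labels disagree with #trial declaration"
            )
        per_chan = events.get(tid, {})
        trains = tuple(
            SpikeTrain(c, np.asarray(per_chan.get(c, []), dtype=float))
            for c in range(n_channels)
        )
        trials.append(Trial(trains=trains, duration=duration, label=lab))

    return Dataset(
        trials=tuple(trials),
        n_channels=n_channels,
        classes=classes,
        duration=duration,
    )
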