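"""Core data containers and their plain-text serializations.

Two record types flow through the whole pipeline:

* :class:`ChannelTimeSeries` — a channels × samples matrix of hemodynamic
  concentration time courses with a sampling rate (10 Hz for the target
  instrument) and ordered channel labels.
* :class:`TrialLog` — the ordered per-trial behavioral record of the 36-trial
  guessing game: whether the guess was correct, what the child reported, and
  whether the report was a lie (reporting "correct" after an incorrect guess).

On disk a subject is a directory with ``timeseries.tsv`` (tab-delimited,
header row of channel ids, one row per sample) and ``trials.csv``; a cohort
adds a top-level ``subjects.csv`` (subject_id, age_years, is_liar, flt_trial).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "ChannelTimeSeries",
    "Trial",
    "TrialLog",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_trials_csv",
    "write_trials_csv",
]


@dataclass
class ChannelTimeSeries:
    """A multichannel time series: ``data`` is channels × samples."""

    data: np.ndarray
    sampling_rate: float
    channel_ids: Sequence[str] = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidParameterError("data must be a 2-D channels × samples matrix")
        if self.data.shape[0] < 2:
            raise InvalidParameterError("need at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("time series contains non-finite values")
        if not self.sampling_rate > 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        else:
            self.channel_ids = list(self.channel_ids)
        if len(self.channel_ids) != self.data.shape[0]:
            raise InvalidParameterError("channel_ids length must equal number of channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.sampling_rate

    def slice_samples(self, start: int, stop: int) -> "ChannelTimeSeries":
        return ChannelTimeSeries(
            self.data[:, start:stop], self.sampling_rate, self.channel_ids
        )


@dataclass(frozen=True)
class Trial:
    """One trial of the guessing game (``trial_index`` is 1-based)."""

    trial_index: int
    onset_sample: int
    guess_correct: bool
    reported_correct: bool
    is_lie: bool

    def __post_init__(self):
        # A lie is, by task design, falsely reporting success after an
        # incorrect guess; truthful reports mirror the guess outcome.
        if self.is_lie and self.guess_correct:
            raise InvalidParameterError("a lie requires an incorrect guess")
        if self.is_lie and not self.reported_correct:
            raise InvalidParameterError("a lie is a false 'correct' report")


@dataclass
class TrialLog:
    """Ordered list of trials for one subject."""

    trials: list[Trial]

    def __post_init__(self):
        if not self.trials:
            raise InvalidParameterError("trial log is empty")
        idx = [t.trial_index for t in self.trials]
        if idx != list(range(1, len(idx) + 1)):
            raise InvalidParameterError("trial_index must run 1..n_trials in order")
        onsets = [t.onset_sample for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])) or onsets[0] < 0:
            raise InvalidParameterError("onset_sample must be non-negative and increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def lie_count(self) -> int:
        return sum(t.is_lie for t in self.trials)

    @property
    def first_lie_trial(self) -> int | None:
        """1-based index of the first lie (FLT), or None if the subject never lied."""
        for t in self.trials:
            if t.is_lie:
                return t.trial_index
        return None

    @property
    def is_liar(self) -> bool:
        return self.first_lie_trial is not None

    def onset_of_trial(self, trial_index: int) -> int:
        return self.trials[trial_index - 1].onset_sample


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------

def write_timeseries_tsv(ts: ChannelTimeSeries, path: str | Path) -> None:
    """Write one row per sample, one column per channel, channel-id header."""
    df = pd.DataFrame(ts.data.T, columns=ts.channel_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_timeseries_tsv(path: str | Path, sampling_rate: float = 10.0) -> ChannelTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return ChannelTimeSeries(df.to_numpy().T, sampling_rate, list(df.columns))


_TRIAL_COLS = ["trial_index", "onset_sample", "guess_correct", "reported_correct", "is_lie"]


def write_trials_csv(log: TrialLog, path: str | Path) -> None:
    rows = [
        (t.trial_index, t.onset_sample, int(t.guess_correct), int(t.reported_correct), int(t.is_lie))
        for t in log.trials
    ]
    pd.DataFrame(rows, columns=_TRIAL_COLS).to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> TrialLog:
    df = pd.read_csv(path)
    missing = set(_TRIAL_COLS) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"trials file missing columns: {sorted(missing)}")
    trials = [
        Trial(int(r.trial_index), int(r.onset_sample), bool(r.guess_correct),
              bool(r.reported_correct), bool(r.is_lie))
        for r in df.itertuples()
    ]
    return TrialLog(trials)
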