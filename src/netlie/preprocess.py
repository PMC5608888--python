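"""Band-pass filtering and state splitting of channel time courses.

The slow hemodynamic band of interest is 0.008–0.09 Hz: below it live drifts,
above it respiratory/cardiac and instrument noise. Filtering is applied once
to the full series (a 4th-order Butterworth run forward and backward for zero
phase), and the two analysis segments are then exact sample slices of the
filtered series, so the split point cannot introduce differential edge
artifacts between states.

Liars are split at the onset of their first-lie trial (honest state before,
dishonest state after); lie-free subjects are split at a fixed fraction of the
series, by default 11.5/36 — the cohort-mean first-lie trial over the 36-trial
session — so that the two groups' segment pairs are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data import ChannelTimeSeries, TrialLog
from .errors import InvalidParameterError, TooShortSegmentError, WrongSubjectTypeError

__all__ = [
    "StateSegments",
    "bandpass_filter",
    "split_at_first_lie",
    "split_at_fraction",
    "DEFAULT_BAND",
    "DEFAULT_SPLIT_FRACTION",
    "DEFAULT_MIN_SEGMENT_SECONDS",
]

DEFAULT_BAND = (0.008, 0.09)
DEFAULT_SPLIT_FRACTION = 11.5 / 36.0
#: correlation over the 0.008 Hz band needs several slow cycles; segments
#: shorter than this abort rather than return meaningless estimates
DEFAULT_MIN_SEGMENT_SECONDS = 60.0


@dataclass
class StateSegments:
    """A series split into two contiguous, exhaustive segments."""

    first: ChannelTimeSeries
    second: ChannelTimeSeries
    split_sample: int
    split_kind: str  # "first_lie" | "fixed_fraction" | "none"

    def __post_init__(self):
        if self.split_kind not in ("first_lie", "fixed_fraction", "none"):
            raise InvalidParameterError(f"unknown split_kind {self.split_kind!r}")
        if self.first.n_samples != self.split_sample:
            raise InvalidParameterError("split_sample inconsistent with first segment")


def bandpass_filter(
    ts: ChannelTimeSeries,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    order: int = 4,
) -> ChannelTimeSeries:
    """Zero-phase Butterworth band-pass, per channel.

    Forward-backward application (``sosfiltfilt``) doubles the effective
    order and cancels phase distortion, preserving event alignment relative
    to the trial onsets.
    """
    nyq = ts.sampling_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise InvalidParameterError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < Nyquist ({nyq})"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=ts.sampling_rate, output="sos")
    # sosfiltfilt needs warm-up padding; a shorter series cannot be filtered
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    if ts.n_samples <= padlen:
        raise TooShortSegmentError(
            f"series of {ts.n_samples} samples is shorter than the filter "
            f"warm-up length ({padlen} samples)"
        )
    filtered = signal.sosfiltfilt(sos, ts.data, axis=1)
    return ChannelTimeSeries(filtered, ts.sampling_rate, ts.channel_ids)


def _check_segments(
    ts: ChannelTimeSeries, split: int, kind: str, min_seconds: float
) -> StateSegments:
    min_samples = int(np.ceil(min_seconds * ts.sampling_rate))
    first_n, second_n = split, ts.n_samples - split
    if first_n < min_samples or second_n < min_samples:
        raise TooShortSegmentError(
            f"split at sample {split} leaves segments of {first_n} and {second_n} "
            f"samples; both must be >= {min_samples} ({min_seconds} s)"
        )
    return StateSegments(
        first=ts.slice_samples(0, split),
        second=ts.slice_samples(split, ts.n_samples),
        split_sample=split,
        split_kind=kind,
    )


def split_at_first_lie(
    ts: ChannelTimeSeries,
    trial_log: TrialLog,
    min_seconds: float = DEFAULT_MIN_SEGMENT_SECONDS,
) -> StateSegments:
    """Honest state = samples before the first-lie trial onset; dishonest after."""
    flt = trial_log.first_lie_trial
    if flt is None:
        raise WrongSubjectTypeError("subject never lied; use split_at_fraction")
    split = trial_log.onset_of_trial(flt)
    return _check_segments(ts, split, "first_lie", min_seconds)


def split_at_fraction(
    ts: ChannelTimeSeries,
    fraction: float = DEFAULT_SPLIT_FRACTION,
    min_seconds: float = DEFAULT_MIN_SEGMENT_SECONDS,
) -> StateSegments:
    """Split at round(fraction * n_samples); rounding is round-half-even."""
    if not 0 < fraction < 1:
        raise InvalidParameterError("fraction must be in (0, 1)")
    split = int(round(fraction * ts.n_samples))
    return _check_segments(ts, split, "fixed_fraction", min_seconds)
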