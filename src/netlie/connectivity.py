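"""Inter-channel Pearson correlation matrices.

One estimator, applied to different time-series segments, yields all the
matrix pairs the analysis needs: a liar's honest/dishonest state matrices,
a non-liar's first/second period matrices, and everyone's overall matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ChannelTimeSeries
from .errors import InvalidParameterError, ZeroVarianceError

__all__ = [
    "ConnectivityMatrix",
    "correlation_matrix",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric correlation matrix with unit diagonal."""

    values: np.ndarray
    channel_ids: list[str] = field(default=None)
    n_samples_used: int = 0
    segment_label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidParameterError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InvalidParameterError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise InvalidParameterError("correlation matrix must have unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise InvalidParameterError("correlations must lie in [-1, 1]")
        # enforce the invariants exactly
        v = np.clip((v + v.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:02d}" for i in range(v.shape[0])]
        else:
            self.channel_ids = list(self.channel_ids)
        if len(self.channel_ids) != v.shape[0]:
            raise InvalidParameterError("channel_ids length must match matrix size")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n_channels, k=1)
        return self.values[iu]


def correlation_matrix(ts: ChannelTimeSeries, segment_label: str = "") -> ConnectivityMatrix:
    """Pearson r for every unordered channel pair of a time-series segment."""
    if ts.n_samples < 3:
        raise InvalidParameterError("need at least 3 samples for a correlation matrix")
    sd = ts.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.channel_ids[i] for i in dead[:5])
        raise ZeroVarianceError(f"zero-variance channel(s): {names}")
    r = np.corrcoef(ts.data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        r,
        channel_ids=list(ts.channel_ids),
        n_samples_used=ts.n_samples,
        segment_label=segment_label,
    )


def write_matrix_tsv(C: ConnectivityMatrix, path: str | Path) -> None:
    """Square TSV with channel ids as both header and index."""
    df = pd.DataFrame(C.values, index=C.channel_ids, columns=C.channel_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path: str | Path, segment_label: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise InvalidParameterError("matrix TSV must have matching row/column ids")
    return ConnectivityMatrix(
        df.to_numpy(), channel_ids=list(df.columns), segment_label=segment_label
    )
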