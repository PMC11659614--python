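"""Core data containers and plain-text I/O.

All tabular data travels as TSV; a multichannel recording is a TSV matrix
(rows = samples, columns = channels) with a small YAML sidecar carrying the
sampling rate, channel names and optional per-sample state labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "read_connectome_matrix",
    "write_connectome_matrix",
]


@dataclass
class Recording:
    """A multichannel time series with a sampling rate.

    Parameters
    ----------
    data:
        Array of shape ``(n_samples, n_channels)``.
    fs:
        Sampling rate in Hz.
    channel_names:
        Optional channel labels; defaults to ``ch000, ch001, ...``.
    labels:
        Optional per-sample behavioral-state labels (length ``n_samples``).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (samples x channels)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i:03d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match data columns")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.n_samples:
                raise ValueError("labels length does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as TSV plus a ``<path>.yaml`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data, columns=rec.channel_names)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta: dict = {"fs": float(rec.fs), "channel_names": list(rec.channel_names)}
    if rec.labels is not None:
        meta["labels"] = [str(v) for v in rec.labels]
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    with open(path.with_suffix(path.suffix + ".yaml")) as fh:
        meta = yaml.safe_load(fh)
    labels = np.asarray(meta["labels"]) if "labels" in meta else None
    return Recording(
        data=df.to_numpy(),
        fs=float(meta["fs"]),
        channel_names=list(meta.get("channel_names", df.columns)),
        labels=labels,
    )


def write_connectome_matrix(W: np.ndarray, path: str | Path) -> None:
    """Write a square coupling matrix as headerless CSV."""
    np.savetxt(path, np.asarray(W, dtype=float), delimiter=",", fmt="%.12g")


def read_connectome_matrix(path: str | Path) -> np.ndarray:
    W = np.loadtxt(path, delimiter=",")
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {W.shape}")
    return W
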