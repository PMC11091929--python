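"""In-memory containers shared across the pipeline.

``SensorRecording`` is the universal signal container: a channels x samples
matrix with a sampling rate, a band tag, and per-channel metadata held in a
:class:`pandas.DataFrame` with columns ``name``, ``kind`` and ``pair``.

Channel kinds follow MEG convention:

- ``MAG``  — magnetometer (field in fT),
- ``GRAD`` — planar gradiometer (one loop of a figure-of-eight pair;
  ``pair`` groups the two loops),
- ``COMB`` — combined gradiometer amplitude (root-sum-of-squares of a
  GRAD pair; nonnegative).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CHANNEL_KINDS = ("MAG", "GRAD", "COMB")

_META_COLUMNS = ("name", "kind", "pair")


def make_channel_meta(
    names: list[str], kinds: list[str], pairs: list[str | None] | None = None
) -> pd.DataFrame:
    """Assemble a channel-metadata table from parallel lists."""
    if pairs is None:
        pairs = [None] * len(names)
    meta = pd.DataFrame({"name": names, "kind": kinds, "pair": pairs})
    bad = set(meta["kind"]) - set(CHANNEL_KINDS)
    if bad:
        raise ValueError(f"unknown channel kinds {sorted(bad)}; allowed: {CHANNEL_KINDS}")
    if meta["name"].duplicated().any():
        dupes = meta.loc[meta["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate channel names: {dupes}")
    return meta


def default_meg_meta(n_mag: int = 102, n_comb: int = 102) -> pd.DataFrame:
    """Channel table for the canonical 204-channel MAG+COMB layout."""
    names = [f"MAG{i:03d}" for i in range(n_mag)] + [f"COMB{i:03d}" for i in range(n_comb)]
    kinds = ["MAG"] * n_mag + ["COMB"] * n_comb
    return make_channel_meta(names, kinds)


@dataclass
class SensorRecording:
    """A multichannel sensor time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Sensor signals; rows follow ``channels``.
    fs : float
        Sampling rate in Hz.
    band : str
        Band tag (one of the names in :data:`oscistate.bands.BAND_TABLE`,
        or ``"broadband-raw"`` before band decomposition).
    channels : DataFrame
        Per-channel metadata with columns ``name``, ``kind``, ``pair``.
    """

    data: np.ndarray
    fs: float
    band: str = "broadband-raw"
    channels: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.channels is None:
            self.channels = make_channel_meta(
                [f"CH{i:03d}" for i in range(self.data.shape[0])],
                ["MAG"] * self.data.shape[0],
            )
        if list(self.channels.columns[:3]) != list(_META_COLUMNS):
            self.channels = self.channels[list(_META_COLUMNS)]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"channel metadata length {len(self.channels)} does not match "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_indices(self, kind: str) -> np.ndarray:
        """Row indices of channels of the given kind."""
        return np.flatnonzero((self.channels["kind"] == kind).to_numpy())

    def with_data(self, data: np.ndarray, **changes) -> "SensorRecording":
        """Copy of this recording with new data (and optional field changes)."""
        return replace(self, data=np.asarray(data, float), **changes)

    def copy(self) -> "SensorRecording":
        return SensorRecording(
            self.data.copy(), self.fs, self.band, self.channels.copy()
        )
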