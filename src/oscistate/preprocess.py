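"""Band decomposition, resampling and planar-channel combination.

These steps turn a raw sensor matrix into the 204-channel band-limited
input the microstate clustering consumes: zero-phase Butterworth band
filtering (a high-pass pass followed by a low-pass pass, each applied
forward and backward), polyphase resampling to 250 Hz, root-sum-of-squares
combination of planar-gradiometer pairs, and concatenation of the
magnetometer and combined-gradiometer blocks with optional unit
harmonization.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BandSpec
from .containers import SensorRecording, make_channel_meta

__all__ = [
    "butter_bandpass_array",
    "bandpass",
    "resample_250",
    "combine_planar",
    "concatenate_and_scale",
]

TARGET_FS = 250.0


def butter_bandpass_array(
    data: np.ndarray, fs: float, high_pass: float, low_pass: float, order: int = 4
) -> np.ndarray:
    """Two-pass Butterworth band filter on a channels x samples array.

    A high-pass filter is applied first, then a low-pass filter, each with
    zero phase shift (forward-backward via ``sosfiltfilt``).  The passband
    is therefore [high_pass, low_pass] with an effective attenuation of
    twice the nominal filter order on each edge.
    """
    if not 0 < high_pass < low_pass:
        raise ValueError("need 0 < high_pass < low_pass")
    if low_pass >= fs / 2:
        raise ValueError(
            f"low_pass={low_pass} Hz at or above Nyquist ({fs / 2} Hz)"
        )
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    sos_hp = signal.butter(order, high_pass, btype="highpass", fs=fs, output="sos")
    sos_lp = signal.butter(order, low_pass, btype="lowpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos_hp, data, axis=-1)
    out = signal.sosfiltfilt(sos_lp, out, axis=-1)
    return out


def bandpass(recording: SensorRecording, band: BandSpec, order: int = 4) -> SensorRecording:
    """Restrict a recording to one frequency band (zero-phase, two-pass)."""
    filtered = butter_bandpass_array(
        recording.data, recording.fs, band.high_pass, band.low_pass, order=order
    )
    return recording.with_data(filtered, band=band.name)


def resample_250(recording: SensorRecording) -> SensorRecording:
    """Resample to 250 Hz with polyphase anti-alias filtering.

    Upsampling is refused: the pipeline only ever decimates recordings
    acquired at 250 Hz or above.  At exactly 250 Hz the data pass through
    unchanged.
    """
    fs_in = recording.fs
    if fs_in < TARGET_FS:
        raise ValueError(
            f"refusing to upsample: input fs {fs_in} Hz below target {TARGET_FS} Hz"
        )
    if fs_in == TARGET_FS:
        return recording.copy()
    ratio = Fraction(TARGET_FS / fs_in).limit_denominator(10_000)
    out = signal.resample_poly(
        recording.data, ratio.numerator, ratio.denominator, axis=-1
    )
    n_target = int(round(recording.n_samples * TARGET_FS / fs_in))
    out = out[:, :n_target]
    return recording.with_data(out, fs=TARGET_FS)


def combine_planar(recording: SensorRecording, rule: str = "rss") -> SensorRecording:
    """Merge planar-gradiometer pairs into nonnegative combined channels.

    Each GRAD pair (g1, g2) becomes one COMB channel with amplitude
    ``sqrt(g1**2 + g2**2)`` per sample (``rule="rss"``) or that value
    divided by sqrt(2) (``rule="rms"``; differs only by a global
    constant).  Magnetometer channels pass through unchanged, ahead of
    the COMB block.

    Raises
    ------
    ValueError
        If any GRAD channel lacks a pair partner (the channel is named in
        the message).
    """
    if rule not in ("rss", "rms"):
        raise ValueError(f"unknown combination rule {rule!r}")
    meta = recording.channels
    grad_rows = meta.index[meta["kind"] == "GRAD"]
    mag_rows = meta.index[meta["kind"] == "MAG"]
    comb_rows = meta.index[meta["kind"] == "COMB"]
    if len(comb_rows):
        raise ValueError("recording already contains COMB channels")

    pairs: dict[str, list[int]] = {}
    for i in grad_rows:
        pair = meta.at[i, "pair"]
        if pair is None or (isinstance(pair, float) and np.isnan(pair)):
            raise ValueError(f"GRAD channel {meta.at[i, 'name']!r} has no pair id")
        pairs.setdefault(str(pair), []).append(i)
    for pair, members in pairs.items():
        if len(members) != 2:
            names = [meta.at[i, "name"] for i in members]
            raise ValueError(
                f"planar pair {pair!r} has {len(members)} member(s) {names}; "
                "expected exactly 2"
            )

    mag_data = recording.data[mag_rows.to_numpy(), :] if len(mag_rows) else np.empty(
        (0, recording.n_samples)
    )
    comb_data = []
    comb_names = []
    for pair in sorted(pairs):
        i, j = pairs[pair]
        amp = np.sqrt(recording.data[i] ** 2 + recording.data[j] ** 2)
        if rule == "rms":
            amp = amp / np.sqrt(2.0)
        comb_data.append(amp)
        comb_names.append(f"COMB_{pair}")
    comb_block = np.stack(comb_data) if comb_data else np.empty((0, recording.n_samples))

    names = [meta.at[i, "name"] for i in mag_rows] + comb_names
    kinds = ["MAG"] * len(mag_rows) + ["COMB"] * len(comb_names)
    out_meta = make_channel_meta(names, kinds)
    return SensorRecording(
        np.vstack([mag_data, comb_block]), recording.fs, recording.band, out_meta
    )


def concatenate_and_scale(
    mag_part: SensorRecording,
    comb_part: SensorRecording,
    scaling: str = "per-type-z",
) -> SensorRecording:
    """Row-concatenate the MAG and COMB blocks with unit harmonization.

    Scaling modes:

    - ``"none"``: stack unmodified (magnetometer fT and combined-gradient
      amplitudes keep their native scales);
    - ``"per-type-z"``: divide each sensor-type block by its pooled
      standard deviation, so neither type dominates the global field
      power purely through units;
    - ``"per-channel-z"``: z-score every channel individually
      (zero-variance channels are an error).
    """
    if mag_part.fs != comb_part.fs:
        raise ValueError(
            f"sampling-rate mismatch: {mag_part.fs} Hz vs {comb_part.fs} Hz"
        )
    if mag_part.n_samples != comb_part.n_samples:
        raise ValueError("sample-count mismatch between MAG and COMB parts")

    blocks = []
    for part in (mag_part, comb_part):
        block = part.data.astype(float).copy()
        if scaling == "none":
            pass
        elif scaling == "per-type-z":
            pooled = block.std()
            if pooled == 0:
                raise ValueError("zero pooled variance in a sensor-type block")
            block /= pooled
        elif scaling == "per-channel-z":
            sd = block.std(axis=1, keepdims=True)
            if np.any(sd == 0):
                flat = part.channels["name"].iloc[
                    np.flatnonzero(sd[:, 0] == 0)
                ].tolist()
                raise ValueError(f"zero-variance channel(s): {flat}")
            block = (block - block.mean(axis=1, keepdims=True)) / sd
        else:
            raise ValueError(f"unknown scaling mode {scaling!r}")
        blocks.append(block)

    meta = pd.concat(
        [mag_part.channels, comb_part.channels], ignore_index=True
    )
    return SensorRecording(
        np.vstack(blocks), mag_part.fs, mag_part.band, meta
    )
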