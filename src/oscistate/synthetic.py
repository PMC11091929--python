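"""Synthetic multichannel recordings with planted microstate structure.

The generative model mirrors the discrete-state view of resting-state
topographic dynamics: a hidden state sequence switches between K fixed
sensor topographies, each state holding for a random duration before
jumping to a different state.  The active topography is carried by a
band-limited oscillatory amplitude (filtered Gaussian noise restricted to
the requested frequency band), and i.i.d. Gaussian sensor noise is added
per channel.  Because the planted maps, segments and labels are returned
alongside the signals, every downstream stage (clustering, backfitting,
temporal parameters, cohort statistics) can be tested for recovery without
any external data.

A demographics fixture with the cohort's printed per-group counts is also
provided for the statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import SensorRecording, default_meg_meta
from .bands import get_band
from .preprocess import butter_bandpass_array

__all__ = [
    "SyntheticTruth",
    "make_topographies",
    "simulate_state_sequence",
    "simulate_recording",
    "make_truth",
    "labels_from_segments",
    "table1_fixture",
    "write_truth_csv",
    "write_demographics_csv",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic recording.

    Parameters
    ----------
    topographies : ndarray, shape (K, n_channels)
        Unit-norm state maps.
    segments : list of (int, float)
        Ordered (state index, duration in seconds) pairs tiling the
        recording; adjacent segments always differ in state.
    band : str
        Frequency band carried by the oscillatory amplitude.
    snr : float
        Amplitude ratio of signal to sensor noise (per sample vector:
        RMS carrier amplitude over expected noise-vector norm).
    seed : int
        Seed the truth was generated from.
    """

    topographies: np.ndarray
    segments: list[tuple[int, float]]
    band: str
    snr: float
    seed: int

    def __post_init__(self) -> None:
        self.topographies = np.asarray(self.topographies, dtype=float)
        K = self.topographies.shape[0]
        norms = np.linalg.norm(self.topographies, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("topography rows must be unit-norm")
        for s, d in self.segments:
            if not 0 <= s < K:
                raise ValueError(f"state index {s} outside [0, {K})")
            if d <= 0:
                raise ValueError("segment durations must be strictly positive")

    @property
    def n_states(self) -> int:
        return self.topographies.shape[0]

    @property
    def total_s(self) -> float:
        return float(sum(d for _, d in self.segments))


def make_topographies(
    n_channels: int, K: int, max_abs_corr: float = 0.3, seed: int = 0
) -> np.ndarray:
    """Draw K unit-norm sensor topographies with bounded pairwise similarity.

    Rows are zero-mean across channels (so Pearson correlation and cosine
    similarity coincide) and pairwise |correlation| is at most
    ``max_abs_corr``.  With ``max_abs_corr=0`` the rows are made exactly
    orthogonal.  In the degenerate case ``K == n_channels`` a zero-mean
    orthogonal set does not exist, so a plain random orthonormal basis is
    returned (mutually orthogonal raw inner products).

    Raises
    ------
    ValueError
        If ``K > n_channels`` or the correlation bound cannot be met.
    """
    if K > n_channels:
        raise ValueError(f"cannot place K={K} maps in {n_channels} channels")
    if not 0 <= max_abs_corr < 1:
        raise ValueError("max_abs_corr must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    if K == n_channels:
        return stats.ortho_group.rvs(n_channels, random_state=rng)

    if max_abs_corr == 0.0:
        # zero-mean Gram-Schmidt: orthonormal AND decorrelated rows
        raw = rng.standard_normal((K, n_channels))
        raw -= raw.mean(axis=1, keepdims=True)
        q, _ = np.linalg.qr(raw.T)
        topo = q[:, :K].T
    else:
        rows: list[np.ndarray] = []
        attempts = 0
        while len(rows) < K:
            v = rng.standard_normal(n_channels)
            v -= v.mean()
            v /= np.linalg.norm(v)
            if all(abs(v @ r) <= max_abs_corr for r in rows):
                rows.append(v)
            attempts += 1
            if attempts > 500 * K:
                raise ValueError(
                    f"could not draw {K} maps with |corr| <= {max_abs_corr} "
                    f"in {n_channels} channels; relax the bound"
                )
        topo = np.stack(rows)
    # sign convention: strongest channel positive
    for row in topo:
        row *= np.sign(row[np.argmax(np.abs(row))]) or 1.0
    return topo


def _truncated_gamma_scale(mean_dur_s: float, min_dur_s: float, shape: float) -> float:
    """Scale theta such that E[X | X > min_dur_s] = mean_dur_s for Gamma(shape, theta)."""

    def trunc_mean(theta: float) -> float:
        c = min_dur_s / theta
        q = special.gammaincc(shape, c)
        if q == 0.0:  # theta so small the whole mass is truncated away
            return min_dur_s
        # E[X | X > c*theta] = shape*theta * Q(shape+1, c) / Q(shape, c)
        return shape * theta * special.gammaincc(shape + 1, c) / q

    f = lambda th: trunc_mean(th) - mean_dur_s
    lo = mean_dur_s * 1e-4
    hi = mean_dur_s * 10.0
    # trunc_mean(lo) ~ min_dur_s < mean_dur_s; trunc_mean(hi) > mean
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


#: Gamma shape for state dwell times; k=2 gives the positive, right-skewed,
#: non-exponential durations seen in empirical microstate histograms.
DWELL_GAMMA_SHAPE = 2.0


def simulate_state_sequence(
    total_s: float,
    K: int,
    mean_dur_s: float = 0.08,
    min_dur_s: float = 0.02,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Simulate a hidden microstate segment sequence.

    Dwell times follow a gamma distribution (shape 2) truncated below at
    ``min_dur_s``, with the scale calibrated so the truncated mean equals
    ``mean_dur_s``.  Successive states always differ; transitions are
    uniform over the remaining states, so long-run coverage is symmetric
    (1/K per state).  The final segment is clipped so durations sum
    exactly to ``total_s``.
    """
    if total_s < min_dur_s:
        raise ValueError(f"total_s={total_s} shorter than min_dur_s={min_dur_s}")
    if not 0 < min_dur_s < mean_dur_s:
        raise ValueError("need 0 < min_dur_s < mean_dur_s")
    if K < 2:
        raise ValueError("need K >= 2 states for alternating segments")

    rng = np.random.default_rng(seed)
    theta = _truncated_gamma_scale(mean_dur_s, min_dur_s, DWELL_GAMMA_SHAPE)
    dist = stats.gamma(DWELL_GAMMA_SHAPE, scale=theta)
    f_min = dist.cdf(min_dur_s)

    segments: list[tuple[int, float]] = []
    t = 0.0
    state = int(rng.integers(K))
    while t < total_s:
        u = f_min + (1.0 - f_min) * rng.random()
        dur = float(dist.ppf(u))
        if t + dur > total_s:
            dur = total_s - t
        segments.append((state, dur))
        t += dur
        nxt = int(rng.integers(K - 1))
        state = nxt if nxt < state else nxt + 1
    return segments


def labels_from_segments(
    segments: list[tuple[int, float]], fs: float, n_samples: int | None = None
) -> np.ndarray:
    """Per-sample planted state labels; sample t covers time [t/fs, (t+1)/fs)."""
    bounds = np.cumsum([d for _, d in segments])
    states = np.array([s for s, _ in segments])
    if n_samples is None:
        n_samples = int(round(bounds[-1] * fs))
    times = (np.arange(n_samples) + 0.5) / fs
    idx = np.minimum(np.searchsorted(bounds, times, side="right"), len(states) - 1)
    return states[idx]


def simulate_recording(
    truth: SyntheticTruth,
    fs: float = 250.0,
    noise_sigma: float = 0.1,
    seed: int = 0,
    channels: pd.DataFrame | None = None,
    noise_scale_by_kind: dict[str, float] | None = None,
) -> tuple[SensorRecording, np.ndarray]:
    """Render a planted state sequence into a noisy sensor recording.

    The sample at time t is ``a(t) * m[s(t)] + sigma_c * eps(t)`` where
    ``a(t)`` is band-limited filtered white noise (restricted to
    ``truth.band``) scaled so the per-sample signal-to-noise amplitude
    ratio equals ``truth.snr``, ``m`` are the planted topographies, and
    ``eps`` is i.i.d. unit Gaussian per channel.  ``noise_scale_by_kind``
    optionally scales the noise per channel kind (e.g. noisier
    magnetometers than combined gradiometers).

    Returns the recording together with the planted per-sample labels.
    """
    band = get_band(truth.band)
    if fs < 2.0 * band.low_pass:
        raise ValueError(
            f"fs={fs} below Nyquist for band {truth.band} (upper edge {band.low_pass} Hz)"
        )
    K, n_channels = truth.topographies.shape
    n_samples = int(round(truth.total_s * fs))
    if channels is None:
        n_mag = n_channels - n_channels // 2
        channels = default_meg_meta(n_mag, n_channels - n_mag)
    if len(channels) != n_channels:
        raise ValueError("channel table length does not match topographies")

    ss = np.random.SeedSequence(seed)
    rng_carrier, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    # steeper filter than the analysis passes (order 8 per direction) so the
    # carrier's power is genuinely confined to the nominal band
    carrier = butter_bandpass_array(
        rng_carrier.standard_normal(n_samples)[None, :],
        fs,
        band.high_pass,
        band.low_pass,
        order=8,
    )[0]
    carrier /= np.sqrt(np.mean(carrier**2))
    # per-sample vector SNR: ||a m||_rms = |a|_rms vs E||noise|| = sigma*sqrt(n)
    amp = truth.snr * noise_sigma * np.sqrt(n_channels) if noise_sigma > 0 else 1.0
    carrier *= amp

    labels = labels_from_segments(truth.segments, fs, n_samples)
    data = carrier[None, :] * truth.topographies[labels].T

    if noise_sigma > 0:
        scale = np.full(n_channels, noise_sigma)
        if noise_scale_by_kind:
            kinds = channels["kind"].to_numpy()
            for kind, s in noise_scale_by_kind.items():
                scale[kinds == kind] *= s
        data = data + scale[:, None] * rng_noise.standard_normal((n_channels, n_samples))

    rec = SensorRecording(data, fs=fs, band=truth.band, channels=channels.copy())
    return rec, labels


def make_truth(
    n_channels: int = 204,
    K: int = 4,
    band: str = "alpha",
    snr: float = 3.0,
    total_s: float = 60.0,
    mean_dur_s: float = 0.08,
    min_dur_s: float = 0.02,
    max_abs_corr: float = 0.3,
    seed: int = 0,
) -> SyntheticTruth:
    """Convenience constructor drawing both maps and segments from one seed."""
    ss = np.random.SeedSequence(seed)
    s_topo, s_seg = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    topo = make_topographies(n_channels, K, max_abs_corr, seed=s_topo)
    segs = simulate_state_sequence(total_s, K, mean_dur_s, min_dur_s, seed=s_seg)
    return SyntheticTruth(topo, segs, band=band, snr=snr, seed=seed)


# -- demographics fixture ----------------------------------------------------

_TABLE1_ROWS = [
    # group, n, female, male, right, left, ambidextrous
    ("YA", 67, 38, 29, 61, 6, 0),
    ("EMA", 141, 68, 73, 126, 14, 1),
    ("LMA", 150, 73, 77, 139, 11, 0),
    ("YS", 150, 75, 75, 135, 14, 1),
    ("EA", 116, 56, 60, 111, 5, 0),
]


def table1_fixture() -> pd.DataFrame:
    """Per-group cohort demographics (counts of sex and handedness).

    Columns: ``group, n, female, male, right, left, ambidextrous``.
    Sex counts sum to n; handedness counts (right + left + ambidextrous)
    also sum to n.  Ambidextrous participants are kept as a third
    handedness category and excluded from right/left comparisons.
    """
    df = pd.DataFrame(
        _TABLE1_ROWS,
        columns=["group", "n", "female", "male", "right", "left", "ambidextrous"],
    )
    assert ((df["female"] + df["male"]) == df["n"]).all()
    assert ((df["right"] + df["left"] + df["ambidextrous"]) == df["n"]).all()
    return df


def write_truth_csv(truth: SyntheticTruth, path) -> None:
    """Write the planted segment table (state, duration_s, onset_s) to CSV."""
    onsets = np.concatenate([[0.0], np.cumsum([d for _, d in truth.segments])[:-1]])
    pd.DataFrame(
        {
            "state": [s for s, _ in truth.segments],
            "duration_s": [d for _, d in truth.segments],
            "onset_s": onsets,
        }
    ).to_csv(path, index=False)


def write_demographics_csv(path) -> None:
    table1_fixture().to_csv(path, index=False)
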