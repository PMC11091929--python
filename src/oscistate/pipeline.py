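"""Group templates, backfitting and temporal microstate parameters.

Subject-level models are pooled per age group and band into a second,
"global" clustering pass; the resulting group templates are re-ordered
against a reference template set (the young-adult broadband maps) so that
MS1..MS4 mean the same thing in every cell of the group x band grid.
Group maps are then backfitted to each member subject's recording to
obtain a per-sample label sequence, from which the three temporal
parameters are computed per state:

- duration: mean length (s) of the maximal runs in which the state stays
  dominant;
- occurrence: number of such runs per second;
- coverage: fraction of samples assigned to the state.

By construction coverage = duration x occurrence for every state with at
least one run, and coverages sum to one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SensorRecording
from .microstate import MicrostateModel, _demean_normalize, gev as _gev, modified_kmeans

__all__ = [
    "GroupTemplates",
    "LabelSequence",
    "two_level_global_maps",
    "reorder_to_template",
    "apply_reorder",
    "backfit",
    "smooth_labels",
    "microstate_parameters",
    "gev_by_sensor_type",
]


@dataclass
class GroupTemplates:
    """Ordered group-level maps with their re-ordering provenance."""

    group: str
    band: str
    maps: np.ndarray
    reorder_perm: np.ndarray
    reorder_corrs: np.ndarray
    gev: float


@dataclass
class LabelSequence:
    """Per-sample state assignments from backfitting."""

    labels: np.ndarray
    fs: float
    subject: str = ""
    band: str = ""

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def total_s(self) -> float:
        return self.n_samples / self.fs


def two_level_global_maps(
    subject_models: list[MicrostateModel],
    K: int = 4,
    n_restarts: int = 20,
    seed: int = 0,
) -> MicrostateModel:
    """Cluster the pooled subject maps into K group-level maps.

    Level 1 is each subject's own clustering; level 2 pools all subjects'
    maps and re-runs the polarity-invariant k-means on that map set.
    """
    if not subject_models:
        raise ValueError("no subject models to pool")
    n_ch = subject_models[0].n_channels
    for m in subject_models:
        if m.n_channels != n_ch:
            raise ValueError(
                f"channel-set mismatch: {m.n_channels} vs {n_ch} channels"
            )
    pooled = np.vstack([m.maps for m in subject_models])
    return modified_kmeans(pooled, K=K, n_restarts=n_restarts, seed=seed)


def _abs_corr_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    an, a_norms = _demean_normalize(np.asarray(a, float))
    bn, b_norms = _demean_normalize(np.asarray(b, float))
    if np.any(a_norms == 0) or np.any(b_norms == 0):
        raise ValueError("constant map encountered in correlation")
    r = an @ bn.T
    return np.abs(r), np.sign(r)


def reorder_to_template(
    group_maps: np.ndarray, reference_maps: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match group maps to a reference template set.

    Evaluates all K! permutations and selects the one maximizing the sum
    of |Pearson r| between group map pi(j) and reference map j (polarity
    ignored).  Returns ``(perm, abs_corrs, signs)`` where ``perm[j]`` is
    the group-map index assigned to reference slot j, ``abs_corrs[j]``
    the achieved |r| and ``signs[j]`` the polarity aligning that map to
    the reference.
    """
    G = np.asarray(group_maps, float)
    R = np.asarray(reference_maps, float)
    if G.shape != R.shape:
        raise ValueError(f"shape mismatch: group {G.shape} vs reference {R.shape}")
    K = G.shape[0]
    absr, signs = _abs_corr_matrix(G, R)
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(K)):
        score = sum(absr[perm[j], j] for j in range(K))
        if score > best_score:
            best_score, best_perm = score, perm
    perm = np.asarray(best_perm)
    corrs = absr[perm, np.arange(K)]
    sg = signs[perm, np.arange(K)]
    return perm, corrs, sg


def apply_reorder(
    maps: np.ndarray, perm: np.ndarray, signs: np.ndarray | None = None
) -> np.ndarray:
    """Reorder (and optionally polarity-align) maps; content is unchanged."""
    out = np.asarray(maps, float)[np.asarray(perm)]
    if signs is not None:
        out = out * np.asarray(signs, float)[:, None]
    return out


def _label_samples(data: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Argmax of squared spatial correlation per sample; zero-variance
    samples inherit the previous label (ties go to the lowest index)."""
    dn, d_norms = _demean_normalize(data)
    mn, m_norms = _demean_normalize(maps)
    if np.any(m_norms == 0):
        raise ValueError("constant template map")
    labels = np.argmax(np.abs(dn @ mn.T), axis=1)
    flat = d_norms == 0
    if np.any(flat):
        ok = np.flatnonzero(~flat)
        if ok.size == 0:
            raise ValueError("recording is constant at every sample")
        # forward-fill; leading flat samples take the first valid label
        idx = np.maximum.accumulate(np.where(~flat, np.arange(len(labels)), -1))
        idx[idx < 0] = ok[0]
        labels = labels[idx]
    return labels


def backfit(
    group_maps: np.ndarray,
    recording: SensorRecording,
    mode: str = "continuous",
    subject: str = "",
) -> LabelSequence:
    """Label every sample of a recording with its best-matching template.

    ``mode="continuous"`` labels each sample independently by squared
    spatial correlation (polarity ignored).  ``mode="peak-interp"``
    labels only the GFP peaks — the samples with the best topographic
    signal-to-noise — and assigns every other sample the label of its
    nearest peak, which avoids spurious switches at the zero crossings of
    an oscillatory carrier.
    """
    from .microstate import find_gfp_peaks, global_field_power

    maps = np.asarray(group_maps, float)
    data = recording.data.T  # samples x channels
    if maps.shape[1] != recording.n_channels:
        raise ValueError(
            f"channel mismatch: maps have {maps.shape[1]}, recording has "
            f"{recording.n_channels}"
        )
    if mode == "continuous":
        labels = _label_samples(data, maps)
    elif mode == "peak-interp":
        peaks = find_gfp_peaks(global_field_power(recording))
        if peaks.size == 0:
            raise ValueError("no GFP peaks to label")
        peak_labels = _label_samples(data[peaks], maps)
        t = np.arange(recording.n_samples)
        pos = np.searchsorted(peaks, t)
        left = np.clip(pos - 1, 0, peaks.size - 1)
        right = np.clip(pos, 0, peaks.size - 1)
        # ties (equidistant) go to the earlier peak
        nearest = np.where(
            np.abs(t - peaks[left]) <= np.abs(peaks[right] - t), left, right
        )
        labels = peak_labels[nearest]
    else:
        raise ValueError(f"unknown backfit mode {mode!r}")
    return LabelSequence(labels=labels, fs=recording.fs, subject=subject, band=recording.band)


def smooth_labels(seq: LabelSequence, min_dur_s: float) -> LabelSequence:
    """Minimum-duration smoother: runs shorter than ``min_dur_s`` are merged
    into the preceding run (off by default in the pipeline)."""
    min_len = max(int(round(min_dur_s * seq.fs)), 1)
    labels = seq.labels.copy()
    changed = True
    while changed:
        changed = False
        starts, lengths, values = _runs(labels)
        for i in range(1, len(starts)):
            if lengths[i] < min_len:
                labels[starts[i] : starts[i] + lengths[i]] = values[i - 1]
                changed = True
                break
    return LabelSequence(labels, seq.fs, seq.subject, seq.band)


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal constant runs: (start indices, lengths, values)."""
    n = labels.shape[0]
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    return starts, ends - starts, labels[starts]


def microstate_parameters(seq: LabelSequence, K: int = 4) -> pd.DataFrame:
    """Duration, occurrence and coverage per state from a label sequence.

    Returns a DataFrame with one row per state (0..K-1) and columns
    ``state, duration_s, occurrence_hz, coverage``.  States that never
    appear get zeros for all three parameters.
    """
    labels = np.asarray(seq.labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    total_s = labels.size / seq.fs
    _, lengths, values = _runs(labels)
    rows = []
    for k in range(K):
        run_lengths = lengths[values == k]
        n_runs = run_lengths.size
        if n_runs:
            duration = float(run_lengths.mean()) / seq.fs
            occurrence = n_runs / total_s
            coverage = float(run_lengths.sum()) / labels.size
        else:
            duration = occurrence = coverage = 0.0
        rows.append(
            {
                "state": k,
                "duration_s": duration,
                "occurrence_hz": occurrence,
                "coverage": coverage,
            }
        )
    return pd.DataFrame(rows)


def gev_by_sensor_type(
    recording: SensorRecording,
    group_maps: np.ndarray,
    kind: str,
    mode: str = "continuous",
) -> float:
    """GEV of the template fit restricted to one sensor type (MAG or COMB).

    Maps and data are restricted to the subset's channels, the maps are
    re-normalized, the subset is backfitted and its GEV returned.
    """
    idx = recording.channel_indices(kind)
    if idx.size == 0:
        raise ValueError(f"no channels of kind {kind!r}")
    sub = SensorRecording(
        recording.data[idx],
        recording.fs,
        recording.band,
        recording.channels.iloc[idx].reset_index(drop=True),
    )
    maps = np.asarray(group_maps, float)[:, idx]
    norms = np.linalg.norm(maps, axis=1)
    if np.any(norms == 0):
        raise ValueError("template maps vanish on the requested channel subset")
    maps = maps / norms[:, None]
    seq = backfit(maps, sub, mode=mode)
    return _gev(maps, sub.data.T, seq.labels)
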