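"""Condition-level ERP statistics for the error-related negativity.

The ERN is measured at a fronto-central electrode (FCz) as the mean
amplitude in a fixed post-response window and as the most negative peak
(amplitude and latency). Differences between conditions (error vs
correct, short- vs long-duration errors) are assessed with paired
t-tests on per-participant measures and with nonparametric cluster-based
permutation tests over time (optionally time x electrode), which control
the family-wise error rate without picking a window a priori.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import EpochSet

__all__ = [
    "ErnMeasures",
    "mean_amplitude",
    "negative_peak",
    "ern_measures",
    "has_visible_ern",
    "cluster_permutation_test",
]


@dataclass(frozen=True)
class ErnMeasures:
    """ERN summary for one condition at one channel."""

    channel: str
    window: tuple[float, float]
    mean_amplitude: float
    peak_amplitude: float
    peak_time: float
    peak_on_edge: bool
    condition: str = ""


def _condition_average(epochs: EpochSet) -> np.ndarray:
    if epochs.n_trials == 0:
        raise ValueError("no trials in condition")
    return epochs.data.mean(axis=0)


def _erp_and_times(data, times, channel, channels):
    erp = np.asarray(data, dtype=float)
    if erp.ndim != 2:
        raise ValueError("expected a (channels x time) array")
    try:
        ci = list(channels).index(channel)
    except ValueError:
        raise KeyError(f"channel {channel!r} not present") from None
    return erp[ci], np.asarray(times, dtype=float)


def mean_amplitude(epochs, channel: str, window: tuple[float, float]) -> float:
    """Time-average (µV) of the condition-average waveform in ``window`` (ms).

    ``epochs`` may be an EpochSet (averaged across trials first) or a
    (channels x time) ERP with matching ``.times``/``.channels`` —
    pass an EpochSet in normal use.
    """
    if isinstance(epochs, EpochSet):
        erp, times = _erp_and_times(
            _condition_average(epochs), epochs.times, channel, epochs.channels
        )
    else:
        raise TypeError("pass an EpochSet")
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError("window outside the epoch")
    return float(erp[mask].mean())


def negative_peak(
    epochs: EpochSet, channel: str, window: tuple[float, float]
) -> tuple[float, float, bool]:
    """Most negative sample in the window: (amplitude µV, latency ms, edge flag).

    Ties go to the earlier sample. The edge flag is set when the minimum
    sits on a window boundary, i.e. there is no true local peak inside.
    """
    erp, times = _erp_and_times(
        _condition_average(epochs), epochs.times, channel, epochs.channels
    )
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError("window outside the epoch")
    seg = erp[mask]
    tseg = times[mask]
    k = int(np.argmin(seg))  # argmin takes the first of equal minima
    on_edge = k == 0 or k == seg.size - 1
    return float(seg[k]), float(tseg[k]), bool(on_edge)


def ern_measures(
    epochs: EpochSet,
    channel: str = "FCz",
    window: tuple[float, float] = (32.0, 82.0),
    condition: str = "",
) -> ErnMeasures:
    """Mean amplitude plus negative-peak measures in the ERN window."""
    amp, lat, edge = negative_peak(epochs, channel, window)
    return ErnMeasures(
        channel=channel,
        window=window,
        mean_amplitude=mean_amplitude(epochs, channel, window),
        peak_amplitude=amp,
        peak_time=lat,
        peak_on_edge=edge,
        condition=condition,
    )


def has_visible_ern(
    epochs: EpochSet, channel: str = "FCz", window: tuple[float, float] = (0.0, 150.0)
) -> bool:
    """Whether a participant shows a negative local minimum in the window.

    Participants without a visible ERN are conventionally excluded from
    peak-latency statistics (peaks of a flat waveform are meaningless).
    """
    erp, times = _erp_and_times(
        _condition_average(epochs), epochs.times, channel, epochs.channels
    )
    mask = (times >= window[0]) & (times <= window[1])
    seg = erp[mask]
    k = int(np.argmin(seg))
    if seg[k] >= 0 or k == 0 or k == seg.size - 1:
        return False
    return True


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------

def _point_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t statistic per (channel, time) point from difference maps."""
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
    return t


def _find_clusters(tmap: np.ndarray, thr: float, adjacency) -> list[tuple[np.ndarray, float]]:
    """Suprathreshold clusters of one sign family at a time.

    tmap is (channels x time). Temporal neighbors are adjacent samples
    within a channel; spatial neighbors are supplied as an adjacency
    list (channel index -> neighbor indices) and connect simultaneous
    samples. Returns (mask, signed mass) pairs.
    """
    clusters = []
    for sign in (1.0, -1.0):
        supra = (sign * tmap) > thr
        if not supra.any():
            continue
        labels = np.full(tmap.shape, -1, dtype=int)
        next_label = 0
        nch, nt = tmap.shape
        for c in range(nch):
            for t in np.flatnonzero(supra[c]):
                if labels[c, t] >= 0:
                    continue
                # BFS over the suprathreshold graph
                stack = [(c, t)]
                labels[c, t] = next_label
                while stack:
                    cc, tt = stack.pop()
                    for nc, ntt in _neighbors(cc, tt, nch, nt, adjacency):
                        if supra[nc, ntt] and labels[nc, ntt] < 0:
                            labels[nc, ntt] = next_label
                            stack.append((nc, ntt))
                next_label += 1
        for lbl in range(next_label):
            mask = labels == lbl
            clusters.append((mask, float(tmap[mask].sum())))
    return clusters


def _neighbors(c, t, nch, nt, adjacency):
    if t > 0:
        yield c, t - 1
    if t < nt - 1:
        yield c, t + 1
    if adjacency is not None:
        for nc in adjacency.get(c, ()):
            yield nc, t


def _max_cluster_mass_1d(tvec: np.ndarray, thr: float) -> float:
    """Largest |sum of t| over suprathreshold runs of a single channel."""
    best = 0.0
    for sign in (1.0, -1.0):
        supra = (sign * tvec) > thr
        if not supra.any():
            continue
        edges = np.diff(np.concatenate(([0], supra.view(np.int8), [0])))
        starts = np.flatnonzero(edges == 1)
        stops = np.flatnonzero(edges == -1)
        for a, b in zip(starts, stops):
            best = max(best, abs(float(tvec[a:b].sum())))
    return best


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    times: np.ndarray,
    channel_adjacency: dict[int, list[int]] | None = None,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[dict]:
    """Paired cluster-based permutation test over time (x electrode).

    ``cond_a``/``cond_b`` are per-participant condition means of shape
    (participants, channels, times); the test operates on their paired
    differences. Points with |t| above the two-sided ``cluster_alpha``
    critical value are clustered by temporal adjacency (and electrode
    adjacency, if supplied as an index-based neighbor dict); cluster
    mass is the sum of t inside a cluster. The null distribution of the
    maximum |mass| is built by randomly sign-flipping participants'
    difference maps, which is exact under exchangeability of the two
    condition labels within participant.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("conditions must be (participants, channels, times) alike")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    diffs = a - b
    thr = float(stats.t.ppf(1 - cluster_alpha / 2, n - 1))
    tmap = _point_t(diffs)
    observed = _find_clusters(tmap, thr, channel_adjacency)
    if not observed:
        return []

    rng = np.random.default_rng(seed)
    nch = a.shape[1]
    flat = diffs.reshape(n, -1)
    ss = (flat ** 2).sum(axis=0)  # invariant under sign flips
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = flips @ flat / n
    var = np.maximum(ss - n * means ** 2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tperm = np.where(var > 0, means / np.sqrt(var / n), 0.0)
    tperm = tperm.reshape(n_perm, nch, -1)

    null_max = np.empty(n_perm)
    for p in range(n_perm):
        if nch == 1 and channel_adjacency is None:
            null_max[p] = _max_cluster_mass_1d(tperm[p, 0], thr)
        else:
            cl = _find_clusters(tperm[p], thr, channel_adjacency)
            null_max[p] = max((abs(m) for _, m in cl), default=0.0)

    out = []
    for mask, mass in observed:
        pval = (1 + int(np.sum(null_max >= abs(mass)))) / (n_perm + 1)
        tsel = times[mask.any(axis=0)]
        out.append(
            {
                "mask": mask,
                "mass": mass,
                "p": pval,
                "sign": 1 if mass > 0 else -1,
                "time_range": (float(tsel.min()), float(tsel.max())),
            }
        )
    out.sort(key=lambda d: d["p"])
    return out
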