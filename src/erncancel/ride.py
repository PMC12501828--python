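"""Residue-iteration decomposition (RIDE) into response-locked clusters.

Single-trial EEG around an erroneous keypress superimposes activity
locked to different events: the onset of the response, its offset (key
release), and intermediate processing. Because response duration jitters
from trial to trial, these contributions can be separated: RIDE
iteratively estimates one component waveform per cluster by, for each
cluster in turn, subtracting the current estimates of all *other*
clusters from every trial (shifted to that trial's event latencies),
re-aligning the residuals to the cluster's own event, and taking a
median-based average.

The decomposition is deliberately conservative about shared variance:
the response-onset cluster is updated first in every iteration and is
initialized to the full onset-locked average, so any variance that both
the onset and offset clusters could explain is attributed to onset. A
genuine offset-locked signature surviving this scheme is therefore
strong evidence for offset-locked brain activity.

Clusters with ``latency_source='estimated'`` (the intermediate cluster)
have their single-trial latencies refined each iteration by maximizing
the cross-correlation between the trial residual and the current
component template inside a search window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet
from . import erpstats

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSpec",
    "RideConfig",
    "RideResult",
    "ride_decompose",
    "reconstruct",
    "cluster_condition_contrast",
    "three_cluster_config",
    "two_cluster_config",
]

LATENCY_SOURCES = ("response_onset", "response_offset", "estimated")


@dataclass(frozen=True)
class ClusterSpec:
    """One RIDE cluster: its latency stream and component window (ms)."""

    name: str
    latency_source: str
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.latency_source not in LATENCY_SOURCES:
            raise ValueError(f"unknown latency_source {self.latency_source!r}")
        if self.window[0] >= self.window[1]:
            raise ValueError("window must be ordered")


@dataclass
class RideConfig:
    """Cluster layout and iteration controls.

    tol is the maximum absolute change of any component waveform (µV)
    under which the iteration is declared converged.
    """

    clusters: list[ClusterSpec] = field(
        default_factory=lambda: three_cluster_config()
    )
    max_iter: int = 20
    tol: float = 0.01
    search_ms: float = 100.0
    taper_frac: float = 0.1
    average: str = "median"

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.average not in ("median", "mean"):
            raise ValueError("average must be 'median' or 'mean'")
        names = [c.name for c in self.clusters]
        if len(set(names)) != len(names):
            raise ValueError("cluster names must be unique")


def three_cluster_config() -> list[ClusterSpec]:
    """R-Onset, R-Intermediate, R-Offset (the default decomposition)."""
    return [
        ClusterSpec("r_onset", "response_onset", (-150.0, 300.0)),
        ClusterSpec("r_intermediate", "estimated", (-100.0, 300.0)),
        ClusterSpec("r_offset", "response_offset", (-100.0, 400.0)),
    ]


def two_cluster_config() -> list[ClusterSpec]:
    """R-Onset and R-Offset only (no intermediate cluster)."""
    return [
        ClusterSpec("r_onset", "response_onset", (-150.0, 300.0)),
        ClusterSpec("r_offset", "response_offset", (-100.0, 400.0)),
    ]


@dataclass
class RideResult:
    """Decomposition output.

    components maps cluster name to a (channels x window-samples) array;
    component_times maps it to the matching ms axis relative to the
    cluster's own lock event. latencies holds the per-trial event
    latencies (ms, relative to the epoch lock) actually used, including
    refined estimates for 'estimated' clusters.
    """

    components: dict[str, np.ndarray]
    component_times: dict[str, np.ndarray]
    latencies: dict[str, np.ndarray]
    residual: np.ndarray
    iterations: int
    convergence: list[float]
    converged: bool
    channels: list[str]
    sfreq: float
    epoch_times: np.ndarray


# ---------------------------------------------------------------------------
# shifting helpers (integer-sample, zero-padded)
# ---------------------------------------------------------------------------

def _window_samples(window: tuple[float, float], sfreq: float) -> np.ndarray:
    dt = 1000.0 / sfreq
    return np.arange(int(round(window[0] / dt)), int(round(window[1] / dt)))


def _taper(n: int, frac: float) -> np.ndarray:
    """Cosine ramp to zero over ``frac`` of the length at each edge."""
    w = np.ones(n)
    k = max(int(round(frac * n)), 1)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
    w[:k] *= ramp
    w[-k:] *= ramp[::-1]
    return w


def _extract(data_trial: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Samples of a (channels x time) trial at epoch indices idx; NaN outside."""
    n = data_trial.shape[1]
    out = np.full((data_trial.shape[0], idx.size), np.nan)
    valid = (idx >= 0) & (idx < n)
    out[:, valid] = data_trial[:, idx[valid]]
    return out


def _place(component: np.ndarray, idx: np.ndarray, n_times: int) -> np.ndarray:
    """Put a (channels x wlen) component at epoch indices idx, zero elsewhere."""
    out = np.zeros((component.shape[0], n_times))
    valid = (idx >= 0) & (idx < n_times)
    out[:, idx[valid]] = component[:, valid]
    return out


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def ride_decompose(
    epochs: EpochSet,
    onset_latencies,
    offset_latencies,
    cfg: RideConfig | None = None,
) -> RideResult:
    """Decompose epochs into response-locked cluster components.

    ``onset_latencies`` / ``offset_latencies`` are per-trial event times
    in ms relative to the epoch lock (for response-onset-locked epochs
    the onset latencies are typically all zero). Offsets must follow
    onsets and must jitter across trials (positive CV of the response
    duration) — without that jitter the clusters are not identifiable.
    """
    if cfg is None:
        cfg = RideConfig()
    data = epochs.data
    n_trials, n_channels, n_times = data.shape
    if n_trials < 2:
        raise ValueError("RIDE needs at least 2 trials")
    onset = np.asarray(onset_latencies, dtype=float)
    offset = np.asarray(offset_latencies, dtype=float)
    if onset.size != n_trials or offset.size != n_trials:
        raise ValueError("latency streams must have one entry per trial")
    if not (np.all(np.isfinite(onset)) and np.all(np.isfinite(offset))):
        raise ValueError("latencies must be finite")
    if np.any(offset <= onset):
        raise ValueError("offset latencies must exceed onset latencies")
    rd = offset - onset
    if np.std(rd, ddof=1) == 0 and len(cfg.clusters) > 1:
        raise ValueError(
            "response durations have zero variance; clusters are not identifiable"
        )

    dt = 1000.0 / epochs.sfreq
    idx0 = int(round(-epochs.times[0] / dt))  # epoch sample of time 0

    latencies: dict[str, np.ndarray] = {}
    for cl in cfg.clusters:
        if cl.latency_source == "response_onset":
            latencies[cl.name] = onset.copy()
        elif cl.latency_source == "response_offset":
            latencies[cl.name] = offset.copy()
        else:
            latencies[cl.name] = 0.5 * (onset + offset)

    wsamps = {cl.name: _window_samples(cl.window, epochs.sfreq) for cl in cfg.clusters}
    tapers = {name: _taper(w.size, cfg.taper_frac) for name, w in wsamps.items()}
    lat_samp = {
        name: np.round(lat / dt).astype(int) for name, lat in latencies.items()
    }

    def trial_indices(name: str, i: int) -> np.ndarray:
        return idx0 + lat_samp[name][i] + wsamps[name]

    reducer = np.nanmedian if cfg.average == "median" else np.nanmean

    def aligned_average(name: str, source: np.ndarray) -> np.ndarray:
        segs = np.stack([_extract(source[i], trial_indices(name, i))
                         for i in range(n_trials)])
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            comp = reducer(segs, axis=0)
        comp[~np.isfinite(comp)] = 0.0
        return comp * tapers[name]

    # conservative initialization: R-Onset (first cluster) absorbs the
    # full aligned average; all later clusters start at zero
    first = cfg.clusters[0].name
    components = {cl.name: np.zeros((n_channels, wsamps[cl.name].size))
                  for cl in cfg.clusters}
    components[first] = aligned_average(first, data)

    search_samp = max(int(round(cfg.search_ms / dt)), 1)
    convergence: list[float] = []
    converged = False
    iterations = 0

    for it in range(cfg.max_iter):
        iterations = it + 1
        max_change = 0.0
        for cl in cfg.clusters:
            others = [c for c in cfg.clusters if c.name != cl.name]
            # residual with all other clusters removed
            resid = np.empty_like(data)
            for i in range(n_trials):
                r = data[i].copy()
                for oc in others:
                    r -= _place(components[oc.name],
                                trial_indices(oc.name, i), n_times)
                resid[i] = r
            if cl.latency_source == "estimated" and np.any(
                np.abs(components[cl.name]) > 0
            ):
                _refine_latencies(
                    resid, components[cl.name], lat_samp[cl.name],
                    wsamps[cl.name], idx0, search_samp,
                )
                latencies[cl.name] = lat_samp[cl.name] * dt
            new = aligned_average(cl.name, resid)
            max_change = max(max_change, float(np.max(np.abs(new - components[cl.name]))))
            components[cl.name] = new
        convergence.append(max_change)
        if max_change < cfg.tol:
            converged = True
            break
    if not converged:
        logger.warning("RIDE did not converge in %d iterations (last change %.4g µV)",
                       cfg.max_iter, convergence[-1])

    recon = _reconstruction(components, lat_samp, wsamps, idx0, n_times, n_trials)
    residual = data - recon
    return RideResult(
        components=components,
        component_times={name: w * dt for name, w in wsamps.items()},
        latencies={name: lat_samp[name] * dt for name in lat_samp},
        residual=residual,
        iterations=iterations,
        convergence=convergence,
        converged=converged,
        channels=list(epochs.channels),
        sfreq=epochs.sfreq,
        epoch_times=epochs.times.copy(),
    )


def _refine_latencies(resid, component, lat_samp, wsamp, idx0, search_samp) -> None:
    """Shift each trial's latency to maximize residual/template correlation."""
    n_trials, _, n_times = resid.shape
    shifts = np.arange(-search_samp, search_samp + 1)
    for i in range(n_trials):
        best, best_score = 0, -np.inf
        for s in shifts:
            idx = idx0 + lat_samp[i] + s + wsamp
            seg = _extract(resid[i], idx)
            m = np.isfinite(seg[0])
            if m.sum() < wsamp.size // 2:
                continue
            score = float(np.nansum(seg[:, m] * component[:, m]))
            if score > best_score:
                best_score, best = score, s
        lat_samp[i] += best


def _reconstruction(components, lat_samp, wsamps, idx0, n_times, n_trials):
    recon = np.zeros((n_trials,) + (next(iter(components.values())).shape[0], n_times))
    for i in range(n_trials):
        for name, comp in components.items():
            recon[i] += _place(comp, idx0 + lat_samp[name][i] + wsamps[name], n_times)
    return recon


def reconstruct(result: RideResult, latencies: dict[str, np.ndarray] | None = None):
    """Sum of latency-shifted components per trial (trials x channels x time).

    ``latencies`` (ms per cluster per trial) defaults to the ones stored
    in the result; adding the stored residual recovers the input epochs.
    """
    if latencies is None:
        latencies = result.latencies
    dt = 1000.0 / result.sfreq
    idx0 = int(round(-result.epoch_times[0] / dt))
    n_times = result.epoch_times.size
    n_trials = len(next(iter(latencies.values())))
    for name, lat in latencies.items():
        lat = np.asarray(lat, dtype=float)
        if np.any(lat < result.epoch_times[0]) or np.any(lat > result.epoch_times[-1]):
            raise ValueError(f"latency outside epoch for cluster {name!r}")
    lat_samp = {n: np.round(np.asarray(l, float) / dt).astype(int)
                for n, l in latencies.items()}
    wsamps = {n: np.round(result.component_times[n] / dt).astype(int)
              for n in result.components}
    return _reconstruction(result.components, lat_samp, wsamps, idx0,
                           n_times, n_trials)


# ---------------------------------------------------------------------------
# condition contrasts on cluster components
# ---------------------------------------------------------------------------

def cluster_condition_contrast(
    results_a: list[RideResult],
    results_b: list[RideResult],
    cluster: str,
    channel: str,
    window: tuple[float, float],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Paired contrast of a cluster component between two conditions.

    One RideResult per participant (or simulated dataset) and condition.
    Returns the per-condition mean amplitude in ``window`` (ms relative
    to the cluster's lock), their difference, a sign-flip permutation p
    for the mean-amplitude difference, and the cluster-based permutation
    test over the full component time course.
    """
    if len(results_a) != len(results_b):
        raise ValueError("paired design needs equal numbers of results")
    if not results_a:
        raise ValueError("no results given")

    def waveforms(results):
        rows = []
        for r in results:
            if r.channels != results_a[0].channels:
                raise ValueError("mismatched channels across results")
            ci = r.channels.index(channel)
            rows.append(r.components[cluster][ci])
        return np.vstack(rows)

    times = results_a[0].component_times[cluster]
    wa, wb = waveforms(results_a), waveforms(results_b)
    mask = (times >= window[0]) & (times <= window[1])
    amp_a = wa[:, mask].mean(axis=1)
    amp_b = wb[:, mask].mean(axis=1)
    diff = amp_a - amp_b
    rng = np.random.default_rng(seed)
    obs = abs(diff.mean())
    flips = rng.choice([-1.0, 1.0], size=(n_perm, diff.size))
    null = np.abs((flips * diff).mean(axis=1))
    p_amp = (1 + int(np.sum(null >= obs))) / (n_perm + 1)
    clusters = erpstats.cluster_permutation_test(
        wa[:, None, :], wb[:, None, :], times=times, n_perm=n_perm, seed=seed
    )
    return {
        "mean_a": float(amp_a.mean()),
        "mean_b": float(amp_b.mean()),
        "difference": float(diff.mean()),
        "p_amplitude": p_amp,
        "clusters": clusters,
        "times": times,
    }
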