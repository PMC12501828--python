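"""EEG preprocessing: epoching, filtering, artifact screening, cleaning.

Turns continuous multichannel recordings into clean, balanced epoch
sets: cut 1200-ms epochs around stimulus onset, response onset, or
response offset; baseline-correct with a lock-specific window; remove
line noise with a band-stop filter; screen epochs for jump and muscle
artifacts with a Hilbert-envelope z-score; equalize trial counts across
response-duration bins; remove ocular components by correlation with
the EOG channels; re-reference to linked mastoids; and apply the final
band-limiting filters. All filters are 4th-order Butterworth IIR applied
forward and backward (zero phase).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import FastICA

from .containers import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocConfig",
    "epoch",
    "baseline_correct",
    "filter_data",
    "artifact_screen",
    "remove_eog_components",
    "rereference_linked_mastoids",
    "balance_trial_counts",
    "preprocess_epochs",
    "read_brainvision",
]

#: baseline windows (ms) per lock type
DEFAULT_BASELINES = {
    "stimulus": (-100.0, 0.0),
    "response_onset": (-150.0, -50.0),
    "response_offset": (-300.0, -200.0),
}


@dataclass
class PreprocConfig:
    """Filter edges, artifact cutoffs and reference choice."""

    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    bandstop: tuple[float, float] = (47.5, 52.5)
    highpass: float = 0.1
    lowpass: float = 20.0
    filter_order: int = 4
    jump_cutoff: float = 20.0
    muscle_cutoff: float = 8.0
    muscle_band: tuple[float, float] = (110.0, 140.0)
    eog_r_threshold: float = 0.40
    mastoids: tuple[str, str] = ("M1", "M2")
    eog_channels: tuple[str, ...] = ("VEOG", "HEOG")

    def __post_init__(self) -> None:
        for lo, hi in (self.bandstop, self.muscle_band):
            if not 0 < lo < hi:
                raise ValueError("band edges must be positive and ordered")
        if self.jump_cutoff <= 0 or self.muscle_cutoff <= 0:
            raise ValueError("artifact cutoffs must be positive")


# ---------------------------------------------------------------------------
# epoching and baseline
# ---------------------------------------------------------------------------

def epoch(
    continuous: np.ndarray,
    events: np.ndarray,
    sfreq: float,
    channels: list[str],
    lock: str,
    window: tuple[float, float] = (-600.0, 600.0),
    metadata: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut epochs from a (channels x samples) recording around event samples.

    The window is half-open [start, end) in ms relative to the event.
    Events whose epoch would leave the recording are dropped with a
    warning (their metadata rows are dropped too).
    """
    events = np.asarray(events, dtype=int)
    if events.size == 0:
        raise ValueError("no events to epoch around")
    n_samples = continuous.shape[1]
    lo = int(round(window[0] * sfreq / 1000.0))
    hi = int(round(window[1] * sfreq / 1000.0))
    keep = (events + lo >= 0) & (events + hi <= n_samples)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} event(s) outside recording bounds",
            stacklevel=2,
        )
    events = events[keep]
    if events.size == 0:
        raise ValueError("all events fall outside the recording")
    data = np.stack([continuous[:, e + lo : e + hi] for e in events])
    times = (np.arange(lo, hi) / sfreq) * 1000.0
    if metadata is not None:
        metadata = metadata.loc[keep].reset_index(drop=True)
    else:
        metadata = pd.DataFrame(index=range(events.size))
    return EpochSet(
        data=data, times=times, channels=list(channels), sfreq=sfreq,
        lock=lock, metadata=metadata,
    )


def baseline_correct(
    epochs: EpochSet, window: tuple[float, float] | None = None
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    if window is None:
        window = DEFAULT_BASELINES[epochs.lock]
    mask = epochs.time_mask(window)
    if not mask.any():
        raise ValueError("baseline window outside the epoch")
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _butter_sos(kind: str, edges, order: int, sfreq: float):
    nyq = sfreq / 2.0
    arr = np.atleast_1d(np.asarray(edges, dtype=float))
    if np.any(arr >= nyq) or np.any(arr <= 0):
        raise ValueError(f"filter edges {arr} outside (0, Nyquist={nyq})")
    if kind not in ("bandstop", "bandpass", "highpass", "lowpass"):
        raise ValueError(f"unknown filter kind {kind!r}")
    wn = arr / nyq if kind in ("bandstop", "bandpass") else float(arr[0]) / nyq
    return signal.butter(order, wn, btype=kind, output="sos")


def filter_data(
    data: np.ndarray | EpochSet,
    kind: str,
    edges,
    sfreq: float | None = None,
    order: int = 4,
    zero_phase: bool = True,
    pad_ms: float = 100.0,
):
    """Butterworth IIR filter along the last (time) axis.

    Zero-phase filtering runs the filter forward and backward (squared
    magnitude response). Epoched data is reflection-padded by ``pad_ms``
    before filtering to suppress edge transients.
    """
    if isinstance(data, EpochSet):
        out = data.copy()
        out.data = filter_data(
            out.data, kind, edges, out.sfreq, order, zero_phase, pad_ms
        )
        return out
    if sfreq is None:
        raise ValueError("sfreq required for array input")
    sos = _butter_sos(kind, edges, order, sfreq)
    x = np.asarray(data, dtype=float)
    npad = int(round(pad_ms * sfreq / 1000.0))
    npad = min(npad, x.shape[-1] - 1)
    if npad > 0:
        pad = [(0, 0)] * (x.ndim - 1) + [(npad, npad)]
        x = np.pad(x, pad, mode="reflect")
    y = signal.sosfiltfilt(sos, x, axis=-1) if zero_phase else signal.sosfilt(sos, x, axis=-1)
    if npad > 0:
        y = y[..., npad:-npad]
    return y


# ---------------------------------------------------------------------------
# artifact screening
# ---------------------------------------------------------------------------

def artifact_screen(
    epochs: EpochSet,
    kind: str = "jump",
    cutoff: float | None = None,
    cfg: PreprocConfig | None = None,
    exclude_channels: tuple[str, ...] = (),
) -> np.ndarray:
    """Keep mask from the Hilbert-envelope z-score screen.

    Per channel, the magnitude of the analytic signal of each epoch is
    z-scored against that channel's envelope distribution over the whole
    session, then averaged across (EEG) channels; an epoch is rejected
    when any sample of the averaged z trace exceeds the cutoff. The
    muscle variant band-pass filters the data first.
    """
    cfg = cfg or PreprocConfig()
    if kind not in ("jump", "muscle"):
        raise ValueError("kind must be 'jump' or 'muscle'")
    if cutoff is None:
        cutoff = cfg.jump_cutoff if kind == "jump" else cfg.muscle_cutoff
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    use = [c for c in epochs.channels if c not in exclude_channels]
    if len(use) < 2:
        raise ValueError("artifact screen needs at least 2 channels")
    idx = [epochs.channel_index(c) for c in use]
    data = epochs.data[:, idx, :]
    if kind == "muscle":
        data = filter_data(data, "bandpass", cfg.muscle_band, epochs.sfreq,
                           cfg.filter_order)
    env = np.abs(signal.hilbert(data, axis=-1))
    # session-level moments per channel
    mu = env.mean(axis=(0, 2), keepdims=True)
    sd = env.std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    z = ((env - mu) / sd).mean(axis=1)  # trials x time, averaged over channels
    keep = (z <= cutoff).all(axis=1)
    frac = 1.0 - keep.mean()
    logger.info("%s screen rejected %.2f%% of epochs", kind, 100 * frac)
    return keep


# ---------------------------------------------------------------------------
# ocular component removal and re-referencing
# ---------------------------------------------------------------------------

def remove_eog_components(
    epochs: EpochSet,
    eog_channels: tuple[str, ...] = ("VEOG", "HEOG"),
    r_threshold: float = 0.40,
    seed: int = 0,
) -> tuple[EpochSet, int]:
    """Zero independent components correlated with the EOG and recompose.

    A FastICA decomposition of the concatenated EEG epochs is computed;
    components whose time course correlates with any EOG channel at
    |r| >= threshold are removed. Returns the cleaned epochs and the
    number of removed components. The EOG channels themselves are passed
    through unchanged.
    """
    missing = [c for c in eog_channels if c not in epochs.channels]
    if missing:
        raise ValueError(f"missing EOG channel(s): {missing}")
    eeg_idx = [i for i, c in enumerate(epochs.channels) if c not in eog_channels]
    eog_idx = [epochs.channel_index(c) for c in eog_channels]
    n_tr, _, n_t = epochs.data.shape
    # channels x (trials * time), channels as features
    X = epochs.data[:, eeg_idx, :].transpose(1, 0, 2).reshape(len(eeg_idx), -1).T
    eog = epochs.data[:, eog_idx, :].transpose(1, 0, 2).reshape(len(eog_idx), -1)

    ica = FastICA(whiten="unit-variance", random_state=seed, max_iter=2000, tol=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # FastICA convergence chatter
        sources = ica.fit_transform(X)  # samples x components
    remove = []
    for k in range(sources.shape[1]):
        for e in range(eog.shape[0]):
            r = np.corrcoef(sources[:, k], eog[e])[0, 1]
            if np.isfinite(r) and abs(r) >= r_threshold:
                remove.append(k)
                break
    kept_sources = sources.copy()
    kept_sources[:, remove] = 0.0
    cleaned = kept_sources @ ica.mixing_.T + ica.mean_
    out = epochs.copy()
    out.data[:, eeg_idx, :] = cleaned.T.reshape(len(eeg_idx), n_tr, n_t).transpose(1, 0, 2)
    logger.info("removed %d EOG-correlated component(s)", len(remove))
    return out, len(remove)


def rereference_linked_mastoids(
    epochs: EpochSet, mastoids: tuple[str, str] = ("M1", "M2")
) -> EpochSet:
    """Subtract the mean of the two mastoid channels from every channel."""
    try:
        m = [epochs.channel_index(c) for c in mastoids]
    except KeyError as err:
        raise ValueError(f"mastoid channel missing: {err}") from None
    out = epochs.copy()
    ref = out.data[:, m, :].mean(axis=1, keepdims=True)
    out.data -= ref
    return out


# ---------------------------------------------------------------------------
# trial-count balancing
# ---------------------------------------------------------------------------

def balance_trial_counts(
    short_idx, long_idx, rds
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize bin sizes by trimming the larger bin near its median RD.

    Repeatedly removes, from the larger bin, the trial whose RD lies
    closest to that bin's current median (ties broken toward the earlier
    trial index), until both bins are equally large.
    """
    short_idx = list(np.asarray(short_idx, dtype=int))
    long_idx = list(np.asarray(long_idx, dtype=int))
    rds = np.asarray(rds, dtype=float)
    if not short_idx or not long_idx:
        raise ValueError("both bins must be non-empty")
    while len(short_idx) != len(long_idx):
        big = short_idx if len(short_idx) > len(long_idx) else long_idx
        med = float(np.median(rds[big]))
        dist = np.abs(rds[big] - med)
        # ties: np.argmin picks the first, and bins are kept in trial order
        big.pop(int(np.argmin(dist)))
    return np.array(short_idx), np.array(long_idx)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def preprocess_epochs(
    epochs: EpochSet,
    cfg: PreprocConfig | None = None,
    balance_by: str | None = None,
    seed: int = 0,
) -> tuple[EpochSet, dict]:
    """Run the standard cleaning chain on an epoch set.

    Order: baseline -> band-stop -> jump/muscle screen -> (optional
    RD-bin balancing via the metadata column ``balance_by``) -> ocular
    component removal -> linked-mastoid re-reference -> baseline again
    -> final high-pass and low-pass. Returns the cleaned epochs and a
    per-stage count report.
    """
    cfg = cfg or PreprocConfig()
    report = {"n_in": epochs.n_trials}
    aux = set(cfg.eog_channels) | set(cfg.mastoids)

    out = baseline_correct(epochs)
    out = filter_data(out, "bandstop", cfg.bandstop, order=cfg.filter_order)

    keep = artifact_screen(out, "jump", cfg.jump_cutoff, cfg, tuple(aux))
    keep &= artifact_screen(out, "muscle", cfg.muscle_cutoff, cfg, tuple(aux))
    report["n_artifact_rejected"] = int((~keep).sum())
    out = out.select_trials(np.flatnonzero(keep))
    if out.n_trials == 0:
        raise ValueError("all epochs rejected by the artifact screen")

    if balance_by is not None:
        bins = out.metadata[balance_by].to_numpy()
        rds = out.metadata["rd"].to_numpy(dtype=float)
        short = np.flatnonzero(bins == "short")
        long_ = np.flatnonzero(bins == "long")
        s, l = balance_trial_counts(short, long_, rds)
        sel = np.sort(np.concatenate([s, l]))
        report["n_balance_removed"] = out.n_trials - sel.size
        out = out.select_trials(sel)

    out, n_removed = remove_eog_components(out, cfg.eog_channels,
                                           cfg.eog_r_threshold, seed)
    report["n_eog_components_removed"] = n_removed
    out = rereference_linked_mastoids(out, cfg.mastoids)
    out = baseline_correct(out)
    out = filter_data(out, "highpass", cfg.highpass, order=cfg.filter_order)
    out = filter_data(out, "lowpass", cfg.lowpass, order=cfg.filter_order)
    report["n_out"] = out.n_trials
    return out, report


# ---------------------------------------------------------------------------
# BrainVision input
# ---------------------------------------------------------------------------

def read_brainvision(vhdr_path) -> dict:
    """Read a BrainVision recording (.vhdr/.vmrk/.eeg) via MNE.

    Returns data in µV (channels x samples), the sampling rate, channel
    labels, and the marker list as (sample, description) pairs.
    """
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6
    # MNE exposes markers as "Type/Description"; keep the description
    markers = [
        (int(round(onset * raw.info["sfreq"])), desc.split("/")[-1])
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
        if "New Segment" not in desc
    ]
    return {
        "data": data,
        "sfreq": raw.info["sfreq"],
        "channels": raw.ch_names,
        "markers": markers,
    }
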