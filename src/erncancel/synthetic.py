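"""Synthetic cohorts with the statistical structure of peri-error data.

Generates behavioral trial logs and matching EEG epoch sets in which
every effect the analysis pipeline is meant to detect is planted with a
known magnitude, so each stage can be validated by parameter recovery:

* ~10% commission errors embedded in correct-trial sequences;
* response times with pre-error speeding and post-error slowing;
* response durations shortened on errors (the cancellation effect);
* an onset-locked fronto-central negativity on errors whose amplitude
  and peak latency depend on the response-duration bin, an intermediate
  positivity, and an offset-locked negativity that rides at
  onset + RD on every trial;
* colored noise (white + AR(1)) and blink artifacts mirrored into the
  EOG channels.

Component templates are Hann-windowed biphasic pulses — convenient
ground truth for recovery tests, not a claim about real ERN morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet

__all__ = ["GenConfig", "gen_behavior", "gen_epochs", "gen_continuous",
           "gen_component_epochs", "write_brainvision"]


@dataclass
class GenConfig:
    """Cohort sizes, planted effect magnitudes, and EEG layout.

    Effect defaults follow the magnitudes typical of speeded
    choice-response studies of error cancellation: 22 ms RD shortening
    on errors, 8 ms pre-error speeding, 18 ms post-error slowing, an
    ERN amplitude split of -4.18 vs -1.16 µV between short- and long-RD
    errors peaking at 52 vs 75 ms.
    """

    n_participants: int = 30
    n_blocks: int = 19
    trials_per_block: int = 64
    error_rate: float = 0.10
    omission_rate: float = 0.0864
    misc_rate: float = 0.0034

    # RT model (lognormal base, ms)
    rt_mean: float = 443.0
    rt_cv: float = 0.18
    rt_participant_sd: float = 20.0
    pre_error_speeding: float = 8.0
    post_error_slowing: float = 18.0
    error_rt_offset: float = -20.0
    effect_between_sd: float = 4.0

    # RD model (normal, truncated at rd_floor, ms)
    rd_correct: float = 142.0
    rd_cancellation: float = 22.0
    rd_sd: float = 30.0
    rd_participant_sd: float = 8.0
    rd_floor: float = 20.0

    # EEG
    sfreq: float = 1000.0
    channels: tuple[str, ...] = (
        "Fz", "FCz", "Cz", "Pz", "Oz", "M1", "M2", "VEOG", "HEOG"
    )
    epoch_window: tuple[float, float] = (-600.0, 600.0)
    noise_white_sd: float = 2.0
    noise_ar_sd: float = 4.0
    noise_ar_rho: float = 0.95
    ern_amp_short: float = -4.18
    ern_amp_long: float = -1.16
    ern_peak_short: float = 52.0
    ern_peak_long: float = 75.0
    onset_amp_correct: float = 2.0
    pe_amp: float = 3.0
    pe_center: float = 125.0
    offset_amp_error: float = -1.5
    offset_amp_correct: float = 0.2
    component_half_width: float = 60.0
    blink_prob: float = 0.12
    blink_amp: float = 120.0
    seed: int = 0

    #: scalp projection of the planted cortical components
    topography: dict = field(default_factory=lambda: {
        "Fz": 0.8, "FCz": 1.0, "Cz": 0.8, "Pz": 0.3, "Oz": 0.1,
        "M1": 0.0, "M2": 0.0, "VEOG": 0.0, "HEOG": 0.0,
    })
    #: frontal projection of the blink source (VEOG carries it at 1.0)
    blink_topography: dict = field(default_factory=lambda: {
        "Fz": 0.35, "FCz": 0.25, "Cz": 0.15, "Pz": 0.06, "Oz": 0.02,
        "M1": 0.0, "M2": 0.0, "VEOG": 1.0, "HEOG": 0.1,
    })

    def __post_init__(self) -> None:
        for p in (self.error_rate, self.omission_rate, self.misc_rate,
                  self.blink_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rd_correct <= 0 or self.rd_floor <= 0:
            raise ValueError("response durations must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def gen_behavior(cfg: GenConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Trial log with planted peri-error RT/RD structure.

    Outcomes are drawn independently per trial; RT offsets are applied
    relative to each commission error (speeding on E-1, slowing on E+1)
    so that the peri-error statistics recover the planted magnitudes.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sigma = np.sqrt(np.log(1 + cfg.rt_cv ** 2))
    frames = []
    nb = cfg.trials_per_block
    for pid in range(cfg.n_participants):
        rt_base = cfg.rt_mean + rng.normal(0, cfg.rt_participant_sd)
        mu = np.log(rt_base) - sigma ** 2 / 2
        speeding = cfg.pre_error_speeding + rng.normal(0, cfg.effect_between_sd)
        slowing = cfg.post_error_slowing + rng.normal(0, cfg.effect_between_sd)
        rd_corr = cfg.rd_correct + rng.normal(0, cfg.rd_participant_sd)
        rd_err = rd_corr - (cfg.rd_cancellation + rng.normal(0, cfg.effect_between_sd))
        for block in range(cfg.n_blocks):
            u = rng.random(nb)
            outcome = np.full(nb, "correct", dtype=object)
            outcome[u < cfg.error_rate] = "commission_error"
            m = (u >= cfg.error_rate) & (u < cfg.error_rate + cfg.omission_rate)
            outcome[m] = "omission"
            m = (u >= cfg.error_rate + cfg.omission_rate) & (
                u < cfg.error_rate + cfg.omission_rate + cfg.misc_rate
            )
            outcome[m] = "miscellaneous"
            rt = rng.lognormal(mu, sigma, nb)
            is_err = outcome == "commission_error"
            rt[is_err] += cfg.error_rt_offset
            rt[:-1][is_err[1:]] -= speeding   # trial before an error
            rt[1:][is_err[:-1]] += slowing    # trial after an error
            rd = np.where(
                is_err,
                rng.normal(rd_err, cfg.rd_sd, nb),
                rng.normal(rd_corr, cfg.rd_sd, nb),
            )
            rd = np.maximum(rd, cfg.rd_floor)
            stim = rng.choice(["left", "right"], nb)
            responded = outcome != "omission"
            resp = np.where(is_err,
                            np.where(stim == "left", "right", "left"), stim)
            frames.append(pd.DataFrame({
                "participant": pid,
                "block": block,
                "trial": np.arange(nb),
                "stimulus": stim,
                "response": np.where(responded, resp, ""),
                "outcome": outcome,
                "rt": np.where(responded, np.round(rt, 1), np.nan),
                "rd": np.where(responded, np.round(rd, 1), np.nan),
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# EEG templates and epochs
# ---------------------------------------------------------------------------

def _biphasic(times: np.ndarray, center: float, half_width: float,
              amp: float) -> np.ndarray:
    """Hann-windowed pulse with a 40% opposite-sign rebound."""
    out = np.zeros_like(times, dtype=float)
    for c, a in ((center, amp), (center + 1.3 * half_width, -0.4 * amp)):
        x = (times - c) / half_width
        m = np.abs(x) < 1
        out[m] += a * 0.5 * (1 + np.cos(np.pi * x[m]))
    return out


def _ar1_noise(rng, rho, sd, shape):
    white = rng.normal(0, 1, shape)
    out = np.empty(shape)
    out[..., 0] = white[..., 0]
    for t in range(1, shape[-1]):
        out[..., t] = rho * out[..., t - 1] + white[..., t]
    out *= sd * np.sqrt(1 - rho ** 2)
    return out


def gen_epochs(
    behavior: pd.DataFrame,
    cfg: GenConfig,
    rng: np.random.Generator | None = None,
    participant: int | None = None,
) -> tuple[EpochSet, dict]:
    """Response-onset-locked epochs for all responded trials.

    Each epoch is colored noise plus three planted components: an
    onset-locked deflection at time 0 (negative for errors, amplitude
    and latency set by the trial's RD relative to the error-RD mean), an
    intermediate positivity, and an offset-locked deflection placed at
    the trial's RD. Blink events are drawn per epoch and mirrored into
    the EOG channels. Returns the epochs and a ground-truth dictionary
    (templates, per-trial amplitudes and latencies, blink source).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    df = behavior
    if participant is not None:
        df = df[df["participant"] == participant]
    df = df[df["outcome"].isin(["correct", "commission_error"])].reset_index(drop=True)
    n = len(df)
    if n == 0:
        raise ValueError("no responded trials to build epochs from")
    dt = 1000.0 / cfg.sfreq
    times = np.arange(*cfg.epoch_window, dt)
    if times.max() < df["rd"].max() + cfg.component_half_width:
        raise ValueError("offset template extends beyond the epoch window")
    nch, nt = len(cfg.channels), times.size
    topo = np.array([cfg.topography[c] for c in cfg.channels])
    btopo = np.array([cfg.blink_topography[c] for c in cfg.channels])

    is_err = (df["outcome"] == "commission_error").to_numpy()
    rd = df["rd"].to_numpy(dtype=float)
    err_rd_mean = rd[is_err].mean() if is_err.any() else cfg.rd_correct
    short = rd < err_rd_mean

    data = np.empty((n, nch, nt))
    data[:] = rng.normal(0, cfg.noise_white_sd, (n, nch, nt))
    data += _ar1_noise(rng, cfg.noise_ar_rho, cfg.noise_ar_sd, (n, nch, nt))

    onset_amp = np.where(
        is_err,
        np.where(short, cfg.ern_amp_short, cfg.ern_amp_long),
        cfg.onset_amp_correct,
    )
    onset_peak = np.where(
        is_err, np.where(short, cfg.ern_peak_short, cfg.ern_peak_long), 40.0
    )
    offset_amp = np.where(is_err, cfg.offset_amp_error, cfg.offset_amp_correct)

    blink_trials = rng.random(n) < cfg.blink_prob
    blink_source = np.zeros((n, nt))
    hw = cfg.component_half_width
    for i in range(n):
        sig = (
            _biphasic(times, onset_peak[i], hw, onset_amp[i])
            + _biphasic(times, cfg.pe_center, hw, cfg.pe_amp)
            + _biphasic(times, rd[i] + 50.0, hw, offset_amp[i])
        )
        data[i] += topo[:, None] * sig[None, :]
        if blink_trials[i]:
            c = rng.uniform(times[0] + 150, times[-1] - 150)
            blink_source[i] = _biphasic(times, c, 120.0, cfg.blink_amp)
            data[i] += btopo[:, None] * blink_source[i][None, :]

    meta = df[["participant", "block", "trial", "outcome", "rt", "rd"]].copy()
    meta["onset_latency"] = 0.0
    meta["offset_latency"] = rd
    epochs = EpochSet(
        data=data, times=times, channels=list(cfg.channels), sfreq=cfg.sfreq,
        lock="response_onset", metadata=meta.reset_index(drop=True),
    )
    truth = {
        "times": times,
        "onset_amp": onset_amp,
        "onset_peak": onset_peak,
        "offset_amp": offset_amp,
        "offset_latency": rd + 50.0,
        "topography": topo,
        "blink_source": blink_source,
        "blink_trials": blink_trials,
        "onset_template_error_short": _biphasic(times, cfg.ern_peak_short, hw,
                                                cfg.ern_amp_short),
        "half_width": hw,
    }
    return epochs, truth


def gen_component_epochs(
    n_trials: int = 200,
    sfreq: float = 500.0,
    rd_mean: float = 140.0,
    rd_jitter_sd: float = 30.0,
    onset_amp: float = -4.0,
    offset_amp: float = -2.0,
    noise_sd: float = 1.0,
    onset_peak: float = 50.0,
    offset_lag: float = 50.0,
    half_width: float = 60.0,
    seed: int = 0,
) -> tuple[EpochSet, np.ndarray, np.ndarray, dict]:
    """Minimal planted-component epochs for decomposition recovery tests.

    Single channel; an onset-locked pulse at time ``onset_peak`` plus an
    offset-locked pulse riding ``offset_lag`` ms after the per-trial
    response offset (RD ~ N(rd_mean, rd_jitter_sd), floored at 60 ms),
    in white noise. Returns the epochs, the onset/offset latency streams
    and the ground-truth template parameters.
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sfreq
    times = np.arange(-300.0, 600.0, dt)
    rd = np.maximum(rng.normal(rd_mean, rd_jitter_sd, n_trials), 60.0)
    data = rng.normal(0, noise_sd, (n_trials, 1, times.size))
    for i in range(n_trials):
        data[i, 0] += _biphasic(times, onset_peak, half_width, onset_amp)
        data[i, 0] += _biphasic(times, rd[i] + offset_lag, half_width, offset_amp)
    meta = pd.DataFrame({"rd": rd})
    ep = EpochSet(data, times, ["FCz"], sfreq, "response_onset", meta)
    truth = {
        "onset_peak": onset_peak,
        "offset_lag": offset_lag,
        "half_width": half_width,
        "onset_amp": onset_amp,
        "offset_amp": offset_amp,
    }
    return ep, np.zeros(n_trials), rd, truth


# ---------------------------------------------------------------------------
# continuous recording and BrainVision export
# ---------------------------------------------------------------------------

def gen_continuous(
    epochs: EpochSet, cfg: GenConfig, gap_ms: float = 400.0
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Concatenate epochs into a continuous recording with event markers.

    Returns (channels x samples) data and (sample, description) markers:
    ``R`` at each response onset and ``O`` at each response offset.
    """
    dt = 1000.0 / cfg.sfreq
    nt = epochs.n_times
    gap = int(round(gap_ms / dt))
    total = epochs.n_trials * (nt + gap)
    data = np.zeros((epochs.n_channels, total))
    markers = []
    zero_off = int(round(-epochs.times[0] / dt))
    for i in range(epochs.n_trials):
        start = i * (nt + gap)
        data[:, start:start + nt] = epochs.data[i]
        onset_sample = start + zero_off
        markers.append((onset_sample, "R"))
        rd = float(epochs.metadata["rd"].iloc[i])
        markers.append((onset_sample + int(round(rd / dt)), "O"))
    return data, markers


def write_brainvision(basename, data, sfreq, channels, markers) -> None:
    """Minimal BrainVision writer (IEEE float32 multiplexed, µV).

    Writes ``<basename>.vhdr``, ``.vmrk`` and ``.eeg`` readable by
    standard EEG software.
    """
    import os

    base = os.fspath(basename)
    stem = os.path.basename(base)
    nch = len(channels)
    with open(base + ".vhdr", "w") as f:
        f.write("BrainVision Data Exchange Header File Version 1.0\n\n")
        f.write("[Common Infos]\n")
        f.write(f"DataFile={stem}.eeg\nMarkerFile={stem}.vmrk\n")
        f.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        f.write(f"NumberOfChannels={nch}\n")
        f.write(f"SamplingInterval={1e6 / sfreq:.0f}\n\n")
        f.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n\n")
        f.write("[Channel Infos]\n")
        for i, ch in enumerate(channels, 1):
            f.write(f"Ch{i}={ch},,1,µV\n")
    with open(base + ".vmrk", "w") as f:
        f.write("BrainVision Data Exchange Marker File, Version 1.0\n\n")
        f.write("[Common Infos]\n")
        f.write(f"DataFile={stem}.eeg\n\n")
        f.write("[Marker Infos]\n")
        f.write("Mk1=New Segment,,1,1,0\n")
        for k, (sample, desc) in enumerate(markers, 2):
            f.write(f"Mk{k}=Stimulus,{desc},{sample + 1},1,0\n")
    np.asarray(data, dtype="<f4").T.tofile(base + ".eeg")
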