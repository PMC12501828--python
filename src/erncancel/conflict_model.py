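"""Conflict-monitoring network simulation with response-offset registration.

A three-layer recurrent network performs a noisy letter-classification
task: an input layer with two center units (targets mapped to the left /
right response) and two surround units (irrelevant flankers), a response
layer with one unit per hand, and an attention layer that allocates gain
to center versus surround. Response conflict is the Hopfield energy of
the response layer, bounded below at 0:

    energy = max(0, -2 * a_L * a_R * w_inh_response)

Conflict accumulated within a trial feeds back as external input to the
center attention unit on the next cycle (conflict adaptation), so the
network attends more to the target after high-conflict episodes and
attention drifts back to the surround when conflict is low.

A response onset is registered when a response unit first exceeds a
fixed threshold, and its offset when that unit falls back below the
threshold — giving simulated response times *and* response durations.
Because an erroneous response is suppressed by lateral inhibition from
the concurrently active correct unit, the model predicts shorter
response durations for errors, the signature of error auto-cancellation.

Gaussian noise is added to every unit's net input on each cycle
(``noise_targets='all_units'``, the classic rule); ``'surround_only'``
restricts it to the two surround input units. At the default noise level
only the all-units rule produces commission errors at a realistic rate —
fast guesses in which a noise-driven response unit crosses threshold
before stimulus evidence settles the race.

Sending activations are rectified at zero by default
(``transmission='rectified'``, the interactive-activation convention):
a unit below its resting level transmits nothing. This makes the resting
state a true fixed point of the noise-free dynamics; the ``'linear'``
option transmits raw (possibly negative) activations as in the printed
net-input formula, at the price of a self-exciting resting state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "NetworkState",
    "SimTrial",
    "UNITS",
    "build_weight_matrix",
    "step_cycle",
    "compute_conflict",
    "update_attention",
    "run_trial",
    "run_dataset",
    "run_experiment",
    "trials_to_dataframe",
    "dataset_summary",
    "response_locked_conflict",
    "write_sim_h5",
]

#: unit order used throughout: input layer (2 center, 2 surround),
#: response layer, attention layer (center, one per surround unit)
UNITS = ("C_L", "C_R", "S_1", "S_2", "L", "R", "A_C", "A_S1", "A_S2")
IDX = {u: i for i, u in enumerate(UNITS)}
INPUT_UNITS = (0, 1, 2, 3)
SURROUND_UNITS = (2, 3)
RESPONSE_UNITS = (4, 5)
ATTENTION_UNITS = (6, 7, 8)


@dataclass
class SimConfig:
    """All network and schedule parameters of the simulation."""

    extscale: float = 0.4
    ext_prep: float = 0.03
    ext_stim: float = 0.15
    w_ff: float = 1.5
    w_att: float = 2.0
    w_inh_input: float = -2.0
    w_inh_response: float = -3.0
    w_inh_attention: float = -1.0
    intscale_exc: float = 0.08
    intscale_inh: float = 0.12
    noise_sd: float = 0.035
    decay: float = 0.1
    a_min: float = -0.2
    a_max: float = 1.0
    a_rest: float = -0.1
    threshold: float = 0.18
    cycles_per_trial: int = 50
    prep_cycles: int = 3
    ms_per_cycle: float = 16.0
    lam: float = 0.5
    alpha: float = 4.41
    beta: float = 1.08
    extC_bounds: tuple[float, float] = (1.0, 3.0)
    stop_mu: float = 6.0
    stop_sd: float = 0.5
    stop_min: float = 5.0
    n_trials: int = 1248
    n_datasets: int = 34
    seed: int = 0
    activation_rule: str = "grossberg_standard"
    noise_targets: str = "all_units"
    transmission: str = "rectified"
    deadline_cycles: int | None = None

    def __post_init__(self) -> None:
        if not self.a_min < self.a_rest < self.a_max:
            raise ValueError("need a_min < a_rest < a_max")
        if self.threshold <= self.a_rest:
            raise ValueError("threshold must exceed a_rest")
        if self.threshold >= self.a_max:
            # legal but unreachable: every trial becomes an omission
            warnings.warn("threshold >= a_max: no response can ever be registered",
                          stacklevel=2)
        if self.extC_bounds[0] > self.extC_bounds[1]:
            raise ValueError("extC_bounds must be ordered")
        if self.activation_rule not in ("grossberg_standard", "paper_literal"):
            raise ValueError(f"unknown activation_rule {self.activation_rule!r}")
        if self.noise_targets not in ("surround_only", "all_units"):
            raise ValueError(f"unknown noise_targets {self.noise_targets!r}")
        if self.transmission not in ("rectified", "linear"):
            raise ValueError(f"unknown transmission {self.transmission!r}")


@dataclass
class NetworkState:
    """Activations of the nine units plus attention drive and trial energy."""

    activations: np.ndarray
    ext_C: float
    energy_total: float = 0.0
    cycle: int = 0

    @classmethod
    def initial(cls, cfg: SimConfig) -> "NetworkState":
        # ext_C starts at its lower bound; the conflict-free fixed point
        # beta / (1 - lam) is reached within a few trials either way
        return cls(
            activations=np.full(len(UNITS), cfg.a_rest, dtype=float),
            ext_C=cfg.extC_bounds[0],
        )

    def reset_for_trial(self, cfg: SimConfig) -> None:
        """Activations back to rest and trial energy to 0; ext_C carries over."""
        self.activations[:] = cfg.a_rest
        self.energy_total = 0.0
        self.cycle = 0


@dataclass
class SimTrial:
    """One simulated trial: conflict trace, response events, accuracy."""

    stimulus: str
    conflict_trace: np.ndarray
    onset_cycle: int | None
    offset_cycle: int | None
    responded_unit: str
    accuracy: str
    rt_ms: float | None
    rd_ms: float | None


def build_weight_matrix(cfg: SimConfig) -> np.ndarray:
    """Effective connection matrix M with M[i, j] = w_ij * intscale.

    Feedforward input->response (center and surround each drive their
    mapped response), bidirectional input<->attention (one attention unit
    per surround input unit, one for both center units), and pairwise
    within-layer inhibition among all units of a layer.
    """
    w = np.zeros((9, 9))
    # feedforward: C_L -> L, C_R -> R, S_1 -> L, S_2 -> R
    for src, dst in ((IDX["C_L"], IDX["L"]), (IDX["C_R"], IDX["R"]),
                     (IDX["S_1"], IDX["L"]), (IDX["S_2"], IDX["R"])):
        w[dst, src] = cfg.w_ff
    # bidirectional attention wiring
    for a, targets in ((IDX["A_C"], (IDX["C_L"], IDX["C_R"])),
                       (IDX["A_S1"], (IDX["S_1"],)),
                       (IDX["A_S2"], (IDX["S_2"],))):
        for t in targets:
            w[a, t] = cfg.w_att
            w[t, a] = cfg.w_att
    # pairwise within-layer inhibition
    for units, wi in ((INPUT_UNITS, cfg.w_inh_input),
                      (RESPONSE_UNITS, cfg.w_inh_response),
                      (ATTENTION_UNITS, cfg.w_inh_attention)):
        for i in units:
            for j in units:
                if i != j:
                    w[i, j] = wi
    scale = np.where(w > 0, cfg.intscale_exc, cfg.intscale_inh)
    return w * scale


def step_cycle(
    state: NetworkState,
    ext_inputs: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None,
    matrix: np.ndarray | None = None,
) -> NetworkState:
    """Advance the network by one Euler cycle (in place, returns state).

    net input_i = ext_i * extscale + sum_j a_j * w_ij * intscale_j + noise;
    da = input * (a_max - a) - decay * (a - a_rest)        for input > 0
    da = input * (a - a_min) - decay * (a - a_rest)        otherwise
    (the shunting form; ``paper_literal`` flips the second driving term to
    input * (a_min - a)). Activations are clamped to [a_min, a_max].
    """
    if matrix is None:
        matrix = build_weight_matrix(cfg)
    a = state.activations
    src = np.maximum(a, 0.0) if cfg.transmission == "rectified" else a
    inp = ext_inputs * cfg.extscale + matrix @ src
    if rng is not None and cfg.noise_sd > 0:
        if cfg.noise_targets == "surround_only":
            inp[SURROUND_UNITS[0]:SURROUND_UNITS[1] + 1] += rng.normal(
                0.0, cfg.noise_sd, size=2
            )
        else:
            inp += rng.normal(0.0, cfg.noise_sd, size=inp.size)
    pos = inp > 0
    da = np.empty_like(a)
    da[pos] = inp[pos] * (cfg.a_max - a[pos])
    if cfg.activation_rule == "grossberg_standard":
        da[~pos] = inp[~pos] * (a[~pos] - cfg.a_min)
    else:
        da[~pos] = inp[~pos] * (cfg.a_min - a[~pos])
    da -= cfg.decay * (a - cfg.a_rest)
    a += da
    if not np.all(np.isfinite(a)):
        raise FloatingPointError(f"non-finite activation; state = {state}")
    np.clip(a, cfg.a_min, cfg.a_max, out=a)
    state.cycle += 1
    return state


def compute_conflict(state: NetworkState, cfg: SimConfig) -> float:
    """Hopfield energy of the response layer, bounded below at 0.

    Computed on the transmitted (rectified) activations under the
    default transmission rule, so conflict is nonzero only when both
    response units are genuinely co-active; a doubly sub-resting pair
    produces no conflict.
    """
    a_l, a_r = state.activations[RESPONSE_UNITS[0]], state.activations[RESPONSE_UNITS[1]]
    if cfg.transmission == "rectified":
        a_l, a_r = max(a_l, 0.0), max(a_r, 0.0)
    return max(0.0, -2.0 * a_l * a_r * cfg.w_inh_response)


def update_attention(state: NetworkState, cfg: SimConfig) -> tuple[float, float]:
    """Leaky update of the attention drive from accumulated trial conflict.

    ext_C <- lam * ext_C + (1 - lam) * (alpha * E + beta), clamped to
    extC_bounds; both surround attention units receive
    ext_S = 0.5 * (3 - ext_C). Updates state.ext_C in place.
    """
    ext_c = cfg.lam * state.ext_C + (1 - cfg.lam) * (
        cfg.alpha * state.energy_total + cfg.beta
    )
    ext_c = float(np.clip(ext_c, *cfg.extC_bounds))
    state.ext_C = ext_c
    return ext_c, 0.5 * (3.0 - ext_c)


def run_trial(
    state: NetworkState,
    stimulus: str,
    cfg: SimConfig,
    rng: np.random.Generator | None,
    matrix: np.ndarray | None = None,
) -> SimTrial:
    """Simulate one trial of ``cycles_per_trial`` cycles.

    Both response units receive ``ext_prep`` during the preparatory
    cycles; from the next cycle the stimulus center unit receives
    ``ext_stim``. Response onset is the first cycle a response unit
    exceeds the threshold, offset the first later cycle it is back at or
    below it. A random delay after onset (N(stop_mu, stop_sd) cycles,
    bounded below at stop_min) the net input to all units is cut and the
    network decays freely toward rest — this is what terminates the
    response and produces its offset.
    """
    if stimulus not in ("left", "right"):
        raise ValueError("stimulus must be 'left' or 'right'")
    if matrix is None:
        matrix = build_weight_matrix(cfg)
    state.reset_for_trial(cfg)
    stim_unit = IDX["C_L"] if stimulus == "left" else IDX["C_R"]
    correct_unit = "L" if stimulus == "left" else "R"

    trace = np.zeros(cfg.cycles_per_trial)
    onset = offset = None
    responded = None
    stop_cycle: float = np.inf
    ext = np.zeros(9)
    ext_s = 0.5 * (3.0 - state.ext_C)
    thr = cfg.threshold
    il, ir = RESPONSE_UNITS

    for t in range(1, cfg.cycles_per_trial + 1):
        if t >= stop_cycle:
            # input stopped: all units decay freely toward rest
            a = state.activations
            a -= cfg.decay * (a - cfg.a_rest)
            np.clip(a, cfg.a_min, cfg.a_max, out=a)
            state.cycle += 1
        else:
            ext[:] = 0.0
            if t <= cfg.prep_cycles:
                ext[il] = ext[ir] = cfg.ext_prep
            else:
                ext[stim_unit] = cfg.ext_stim
            ext[IDX["A_C"]] = state.ext_C
            ext[IDX["A_S1"]] = ext[IDX["A_S2"]] = ext_s
            step_cycle(state, ext, cfg, rng, matrix)
        e = compute_conflict(state, cfg)
        state.energy_total += e
        trace[t - 1] = e
        _, ext_s = update_attention(state, cfg)
        a_l, a_r = state.activations[il], state.activations[ir]
        if onset is None:
            if a_l > thr or a_r > thr:
                if cfg.deadline_cycles is not None and (
                    t - cfg.prep_cycles > cfg.deadline_cycles
                ):
                    continue  # too late to register a response
                onset = t
                responded = "L" if a_l >= a_r else "R"
                delay = cfg.stop_mu if rng is None else rng.normal(cfg.stop_mu, cfg.stop_sd)
                stop_cycle = onset + round(max(cfg.stop_min, delay))
        elif offset is None:
            unit = il if responded == "L" else ir
            if state.activations[unit] <= thr:
                offset = t

    if onset is None:
        accuracy = "omission"
        responded_unit = "none"
    else:
        responded_unit = responded
        accuracy = "correct" if responded == correct_unit else "commission_error"
    return SimTrial(
        stimulus=stimulus,
        conflict_trace=trace,
        onset_cycle=onset,
        offset_cycle=offset,
        responded_unit=responded_unit,
        accuracy=accuracy,
        rt_ms=None if onset is None else (onset - cfg.prep_cycles) * cfg.ms_per_cycle,
        rd_ms=None if (onset is None or offset is None)
        else (offset - onset) * cfg.ms_per_cycle,
    )


def run_dataset(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[SimTrial]:
    """Simulate one dataset of ``cfg.n_trials`` trials.

    The attention drive ext_C carries over from trial to trial; trial
    energy and activations reset at each trial start. Stimuli are drawn
    left/right with equal probability.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    matrix = build_weight_matrix(cfg)
    state = NetworkState.initial(cfg)
    stimuli = np.where(rng.random(cfg.n_trials) < 0.5, "left", "right")
    return [run_trial(state, s, cfg, rng, matrix) for s in stimuli]


def run_experiment(cfg: SimConfig) -> list[list[SimTrial]]:
    """Simulate ``cfg.n_datasets`` datasets with per-dataset derived seeds."""
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_datasets)
    datasets = []
    for i, ss in enumerate(streams):
        trials = run_dataset(cfg, np.random.default_rng(ss))
        summ = dataset_summary(trials)
        logger.info(
            "dataset %d: error rate %.3f, RT %.0f ms, RD(corr) %.0f ms, RD(err) %.0f ms",
            i, summ["error_rate"], summ["mean_rt_correct"],
            summ["mean_rd_correct"], summ["mean_rd_error"],
        )
        datasets.append(trials)
    return datasets


def trials_to_dataframe(trials: list[SimTrial], dataset: int = 0) -> pd.DataFrame:
    """Flat trial table (dataset, trial, stimulus, response, accuracy, rt, rd)."""
    return pd.DataFrame(
        {
            "dataset": dataset,
            "trial": np.arange(len(trials)),
            "stimulus": [t.stimulus for t in trials],
            "response": [t.responded_unit for t in trials],
            "accuracy": [t.accuracy for t in trials],
            "rt_ms": [t.rt_ms for t in trials],
            "rd_ms": [t.rd_ms for t in trials],
        }
    )


def dataset_summary(trials: list[SimTrial]) -> dict:
    """Error rate and mean RT/RD by accuracy class for one dataset."""
    df = trials_to_dataframe(trials)
    responded = df[df["accuracy"] != "omission"]
    err = df[df["accuracy"] == "commission_error"]
    corr = df[df["accuracy"] == "correct"]
    return {
        "n_trials": len(df),
        "error_rate": len(err) / max(len(responded), 1),
        "omission_rate": 1 - len(responded) / len(df),
        "mean_rt_correct": corr["rt_ms"].mean(),
        "mean_rt_error": err["rt_ms"].mean(),
        "mean_rd_correct": corr["rd_ms"].mean(),
        "mean_rd_error": err["rd_ms"].mean(),
    }


def response_locked_conflict(
    trials: list[SimTrial],
    lock: str = "onset",
    window: tuple[int, int] = (-10, 15),
) -> dict:
    """Mean conflict trace per accuracy class, aligned at response events.

    ``window`` is in cycles relative to the lock (closed on both ends);
    cycles outside a trial contribute nothing (NaN-averaged). Returns the
    per-class means, the error-correct difference, the cycle axis, and a
    list of classes with no lockable trials.
    """
    if lock not in ("onset", "offset"):
        raise ValueError("lock must be 'onset' or 'offset'")
    lo, hi = window
    axis = np.arange(lo, hi + 1)
    aligned: dict[str, list[np.ndarray]] = {"correct": [], "commission_error": []}
    for tr in trials:
        ref = tr.onset_cycle if lock == "onset" else tr.offset_cycle
        if ref is None or tr.accuracy not in aligned:
            continue
        seg = np.full(axis.size, np.nan)
        for k, c in enumerate(axis + ref):
            if 1 <= c <= tr.conflict_trace.size:
                seg[k] = tr.conflict_trace[c - 1]
        aligned[tr.accuracy].append(seg)
    out: dict = {"cycles": axis, "lock": lock, "missing": []}
    for cls, segs in aligned.items():
        if not segs:
            out["missing"].append(cls)
            continue
        with np.errstate(invalid="ignore"):
            out[cls] = np.nanmean(np.vstack(segs), axis=0)
    if "correct" in out and "commission_error" in out:
        out["difference"] = out["commission_error"] - out["correct"]
    return out


def write_sim_h5(path, datasets: list[list[SimTrial]], cfg: SimConfig) -> None:
    """HDF5 container: per-dataset conflict traces plus flat trial metadata."""
    with h5py.File(path, "w") as f:
        for k, v in asdict(cfg).items():
            if v is not None:
                f.attrs[k] = v if not isinstance(v, tuple) else list(v)
        for i, trials in enumerate(datasets):
            g = f.create_group(f"dataset_{i:03d}")
            g.create_dataset(
                "conflict", data=np.vstack([t.conflict_trace for t in trials])
            )
            df = trials_to_dataframe(trials, i)
            for col in df.columns:
                vals = df[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype(str).astype(h5py.string_dtype())
                else:
                    vals = vals.astype(float)
                g.create_dataset(col, data=vals)
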