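"""End-to-end analyses: orchestration, recovery experiments, reporting.

High-level entry points tying the modules together:

* :func:`simulator_properties` — the network-model study (34 datasets of
  1248 trials): response-duration shortening on errors, the ERN-like
  onset-locked conflict signature, and the RIDE attribution of conflict
  to the response-onset versus response-offset cluster.
* :func:`behavior_recovery` — generate a synthetic cohort and recover
  the planted peri-error effects with confidence intervals.
* :func:`ride_recovery` — planted-component recovery metrics for the
  decomposition.
* :func:`ern_recovery` — full EEG pipeline on synthetic epochs: median
  split, trial balancing, ERN measures.
* :func:`fwer_calibration` — family-wise error of the cluster
  permutation test under a pure-noise null.
* :func:`run_pipeline` — config-driven demo pipeline with a manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import behavior as beh
from . import conflict_model as cm
from . import erpstats, preprocess, ride, synthetic
from .containers import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "RunManifest",
    "simulator_properties",
    "behavior_recovery",
    "ride_recovery",
    "ern_recovery",
    "fwer_calibration",
    "run_pipeline",
    "acceptance_suite",
]


@dataclass
class RunManifest:
    """Bookkeeping for one pipeline run."""

    config: dict
    seed: int
    outputs: list[str] = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# simulator study
# ---------------------------------------------------------------------------

def _conflict_epochs(trials, accuracy, max_n, rng):
    """EpochSet of conflict traces for one accuracy class with latencies."""
    sel = [t for t in trials
           if t.accuracy == accuracy and t.onset_cycle and t.offset_cycle]
    if len(sel) > max_n:
        idx = rng.choice(len(sel), max_n, replace=False)
        sel = [sel[i] for i in idx]
    if len(sel) < 2:
        raise ValueError(f"not enough {accuracy} trials with offsets")
    cfg_ms = 16.0
    data = np.stack([t.conflict_trace for t in sel])[:, None, :]
    times = np.arange(data.shape[2]) * cfg_ms
    onset = np.array([(t.onset_cycle - 1) * cfg_ms for t in sel])
    offset = np.array([(t.offset_cycle - 1) * cfg_ms for t in sel])
    ep = EpochSet(data, times, ["conflict"], 1000.0 / cfg_ms, "stimulus",
                  pd.DataFrame({"rd": offset - onset}))
    return ep, onset, offset


def simulator_properties(
    sim_cfg: cm.SimConfig | None = None,
    n_perm: int = 1000,
    seed: int = 1,
) -> dict:
    """Run the simulation study and measure its three key properties.

    1. In how many datasets mean RD(error) < RD(correct);
    2. the onset-locked error-correct conflict difference (peak and its
       cycle within 10 cycles post-onset);
    3. RIDE of the conflict traces per dataset and condition (matched
       trial counts, mean averaging) with cluster-permutation contrasts
       on the R-Onset and R-Offset components.
    """
    if sim_cfg is None:
        sim_cfg = cm.SimConfig(seed=seed)
    datasets = cm.run_experiment(sim_cfg)

    rd_ok = 0
    peaks = []
    res_err, res_cor = [], []
    rcfg = ride.RideConfig(clusters=ride.three_cluster_config(),
                           max_iter=10, average="mean")
    for i, trials in enumerate(datasets):
        s = cm.dataset_summary(trials)
        if s["mean_rd_error"] < s["mean_rd_correct"]:
            rd_ok += 1
        rlc = cm.response_locked_conflict(trials, "onset")
        ax, d = rlc["cycles"], rlc["difference"]
        post = d[(ax >= 0) & (ax <= 10)]
        peaks.append((float(post.max()),
                      int(ax[(ax >= 0) & (ax <= 10)][int(np.argmax(post))])))
        rng = np.random.default_rng(10_000 + i)
        n_err = sum(1 for t in trials
                    if t.accuracy == "commission_error" and t.onset_cycle
                    and t.offset_cycle)
        epe, one, offe = _conflict_epochs(trials, "commission_error", n_err, rng)
        epc, onc, offc = _conflict_epochs(trials, "correct", n_err, rng)
        res_err.append(ride.ride_decompose(epe, one, offe, rcfg))
        res_cor.append(ride.ride_decompose(epc, onc, offc, rcfg))

    onset_c = ride.cluster_condition_contrast(
        res_err, res_cor, "r_onset", "conflict", (0.0, 160.0), n_perm, seed)
    offset_c = ride.cluster_condition_contrast(
        res_err, res_cor, "r_offset", "conflict", (50.0, 100.0), n_perm, seed)
    return {
        "n_datasets": sim_cfg.n_datasets,
        "rd_error_lt_correct": rd_ok,
        "conflict_peaks": peaks,
        "min_peak": min(p for p, _ in peaks),
        "onset_contrast": onset_c,
        "offset_contrast": offset_c,
        "onset_sig_positive": any(
            d["p"] < 0.05 and d["sign"] > 0 for d in onset_c["clusters"]),
        "offset_any_sig": any(d["p"] < 0.05 for d in offset_c["clusters"]),
    }


# ---------------------------------------------------------------------------
# recovery experiments
# ---------------------------------------------------------------------------

def behavior_recovery(gen_cfg: synthetic.GenConfig | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Generate a cohort and estimate the planted peri-error effects."""
    if gen_cfg is None:
        gen_cfg = synthetic.GenConfig(seed=seed)
    trials = synthetic.gen_behavior(gen_cfg)
    chunks = beh.extract_error_chunks(trials)
    chunks, _ = beh.remove_rd_outliers(chunks)
    tab = beh.chunk_stats_table(chunks)
    return beh.group_effects(tab)


def ride_recovery(jitter_sd: float = 30.0, n_trials: int = 200,
                  seed: int = 0) -> dict:
    """Planted onset+offset component recovery by the decomposition."""
    cfg = ride.RideConfig(clusters=ride.two_cluster_config())
    ep, on, off, truth = synthetic.gen_component_epochs(
        n_trials=n_trials, rd_jitter_sd=jitter_sd, seed=seed)
    res = ride.ride_decompose(ep, on, off, cfg)

    def planted(name, lag):
        t = res.component_times[name]
        return synthetic._biphasic(t, lag, truth["half_width"],
                                   truth[f"{name.split('_')[1]}_amp"])

    w_on = planted("r_onset", truth["onset_peak"])
    w_off = planted("r_offset", truth["offset_lag"])
    c_on = float(np.corrcoef(res.components["r_onset"][0], w_on)[0, 1])
    c_off = float(np.corrcoef(res.components["r_offset"][0], w_off)[0, 1])

    # onset-only control: the offset component should stay near zero
    ep0, on0, off0, truth0 = synthetic.gen_component_epochs(
        n_trials=n_trials, rd_jitter_sd=jitter_sd, offset_amp=0.0, seed=seed + 1)
    res0 = ride.ride_decompose(ep0, on0, off0, cfg)
    leak = float(np.abs(res0.components["r_offset"][0]).max()
                 / np.abs(res0.components["r_onset"][0]).max())

    recon = ride.reconstruct(res)
    conserve = float(np.max(np.abs(recon + res.residual - ep.data)))
    return {
        "corr_onset": c_on,
        "corr_offset": c_off,
        "onset_only_leak_ratio": leak,
        "conservation_error": conserve,
        "iterations": res.iterations,
        "converged": res.converged,
    }


def ern_recovery(gen_cfg: synthetic.GenConfig | None = None,
                 n_participants: int | None = None,
                 seed: int = 0) -> dict:
    """EEG pipeline on synthetic epochs: split errors by RD, measure ERN.

    For each participant: generate epochs, median-split the error trials
    by RD, balance trial counts, and measure mean ERN amplitude at FCz
    in [32, 82] ms for the short- and long-RD bins. Returns group means,
    the short-long difference with its 95% CI, and peak latencies.
    """
    if gen_cfg is None:
        gen_cfg = synthetic.GenConfig(seed=seed)
    if n_participants is None:
        n_participants = gen_cfg.n_participants
    trials = synthetic.gen_behavior(gen_cfg)
    rows = []
    for pid in range(n_participants):
        rng = np.random.default_rng((seed << 8) + pid)
        ep, _ = synthetic.gen_epochs(trials, gen_cfg, rng, participant=pid)
        err = ep.select_trials(
            np.flatnonzero(ep.metadata["outcome"] == "commission_error"))
        rd = err.metadata["rd"].to_numpy(dtype=float)
        med = np.median(rd)
        labels = np.where(rd < med, "short", "long")
        short = np.flatnonzero(labels == "short")
        long_ = np.flatnonzero(labels == "long")
        if short.size < 2 or long_.size < 2:
            continue
        s_idx, l_idx = preprocess.balance_trial_counts(short, long_, rd)
        m = {}
        for name, idx in (("short", s_idx), ("long", l_idx)):
            cond = err.select_trials(idx)
            meas = erpstats.ern_measures(cond, "FCz", (32.0, 82.0), name)
            m[f"amp_{name}"] = meas.mean_amplitude
            m[f"peak_{name}"] = meas.peak_time
        rows.append(m)
    df = pd.DataFrame(rows)
    diff = df["amp_short"] - df["amp_long"]
    n = len(diff)
    from scipy import stats as st
    se = diff.std(ddof=1) / np.sqrt(n)
    tcrit = st.t.ppf(0.975, n - 1)
    return {
        "n_participants": n,
        "amp_short": float(df["amp_short"].mean()),
        "amp_long": float(df["amp_long"].mean()),
        "amp_diff": float(diff.mean()),
        "amp_diff_ci": (float(diff.mean() - tcrit * se),
                        float(diff.mean() + tcrit * se)),
        "peak_short": float(df["peak_short"].mean()),
        "peak_long": float(df["peak_long"].mean()),
    }


def fwer_calibration(
    n_reps: int = 200,
    n_perm: int = 500,
    n_participants: int = 20,
    n_times: int = 40,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise error of the cluster test under a pure-noise null.

    Each replication draws per-participant condition-difference maps of
    white noise and asks whether any cluster reaches p < alpha.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(n_times, dtype=float)
    false_pos = 0
    for r in range(n_reps):
        a = rng.normal(size=(n_participants, 1, n_times))
        b = rng.normal(size=(n_participants, 1, n_times))
        clusters = erpstats.cluster_permutation_test(
            a, b, times, n_perm=n_perm, cluster_alpha=alpha,
            seed=int(rng.integers(2**31 - 1)))
        if any(c["p"] < alpha for c in clusters):
            false_pos += 1
    return {"n_reps": n_reps, "fwer": false_pos / n_reps, "alpha": alpha}


# ---------------------------------------------------------------------------
# config-driven pipeline
# ---------------------------------------------------------------------------

KNOWN_STAGES = {"gendata", "behavior", "ern", "simulate"}


def run_pipeline(config: dict, out_dir=None) -> tuple[RunManifest, dict]:
    """Run the stages requested in a config dict (YAML-loadable).

    Config layout: a top-level ``seed`` plus one section per stage
    (``gendata``, ``behavior``, ``ern``, ``simulate``); unknown keys are
    rejected by name. Returns the manifest and a JSON-serializable
    report.
    """
    unknown = set(config) - KNOWN_STAGES - {"seed"}
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config, seed=seed)
    report: dict = {"seed": seed}

    gen_cfg = None
    trials = None
    if "gendata" in config:
        t0 = time.time()
        gen_cfg = synthetic.GenConfig(seed=seed, **(config["gendata"] or {}))
        trials = synthetic.gen_behavior(gen_cfg)
        manifest.stage_counts["gendata"] = {"n_trials": len(trials)}
        manifest.stage_seconds["gendata"] = round(time.time() - t0, 2)
        report["gendata"] = {
            "n_trials": len(trials),
            "error_rate": float((trials.outcome == "commission_error").mean()),
        }
        if out_dir is not None:
            path = f"{out_dir}/trials.csv"
            trials.to_csv(path, index=False)
            manifest.outputs.append(path)

    if "behavior" in config:
        if trials is None:
            raise ValueError("behavior stage requires gendata (or input data)")
        t0 = time.time()
        mode = (config["behavior"] or {}).get("mode", "pm2")
        chunks = beh.extract_error_chunks(trials)
        kept, frac = beh.remove_rd_outliers(chunks)
        tab = beh.chunk_stats_table(kept, cancellation_mode=mode)
        eff = beh.group_effects(tab)
        manifest.stage_counts["behavior"] = {
            "n_chunks": len(chunks), "n_after_outliers": len(kept),
            "removed_fraction": round(frac, 4),
        }
        manifest.stage_seconds["behavior"] = round(time.time() - t0, 2)
        report["behavior"] = {
            k: {kk: float(vv) for kk, vv in v.items()}
            for k, v in eff.to_dict("index").items()
        }

    if "ern" in config:
        t0 = time.time()
        opts = config["ern"] or {}
        rec = ern_recovery(gen_cfg, n_participants=opts.get("n_participants"),
                           seed=seed)
        manifest.stage_counts["ern"] = {"n_participants": rec["n_participants"]}
        manifest.stage_seconds["ern"] = round(time.time() - t0, 2)
        report["ern"] = rec

    if "simulate" in config:
        t0 = time.time()
        opts = dict(config["simulate"] or {})
        sim_cfg = cm.SimConfig(seed=seed, **opts)
        datasets = cm.run_experiment(sim_cfg)
        summaries = [cm.dataset_summary(d) for d in datasets]
        manifest.stage_counts["simulate"] = {
            "n_datasets": len(datasets), "n_trials": sim_cfg.n_trials}
        manifest.stage_seconds["simulate"] = round(time.time() - t0, 2)
        report["simulate"] = {
            "mean_error_rate": float(np.mean([s["error_rate"] for s in summaries])),
            "mean_rd_correct": float(np.mean([s["mean_rd_correct"] for s in summaries])),
            "mean_rd_error": float(np.mean([s["mean_rd_error"] for s in summaries])),
        }
    return manifest, report


def demo_config() -> dict:
    """A small configuration exercising the behavioral stages."""
    return {
        "seed": 0,
        "gendata": {"n_participants": 6, "n_blocks": 6},
        "behavior": {"mode": "pm2"},
    }


# ---------------------------------------------------------------------------
# acceptance suite
# ---------------------------------------------------------------------------

def acceptance_suite(seed: int = 1, fast: bool = False) -> dict:
    """Recompute the headline quantities of the study from scratch.

    Covers the power analysis, the simulator properties, decomposition
    and behavioral recovery, and the permutation-test calibration.
    ``fast`` scales the stochastic blocks down for a quick look.
    """
    out: dict = {}
    spec = beh.PowerSpec(d_z=0.50, alpha=0.05, power=0.80)
    out["power_n"] = beh.paired_power(spec, "solve_n")
    out["power_n34_d134"] = beh.paired_power(
        beh.PowerSpec(d_z=1.34, n=34), "solve_power")
    out["power_n30_d134"] = beh.paired_power(
        beh.PowerSpec(d_z=1.34, n=30), "solve_power")

    sim_cfg = cm.SimConfig(seed=seed, n_datasets=6 if fast else 34)
    out["simulator"] = simulator_properties(sim_cfg, n_perm=500, seed=seed)

    out["ride"] = ride_recovery(seed=seed)
    out["behavior"] = behavior_recovery(
        synthetic.GenConfig(seed=seed,
                            n_participants=10 if fast else 30)).to_dict("index")
    out["fwer"] = fwer_calibration(
        n_reps=50 if fast else 200, n_perm=500, seed=seed)
    return out
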