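"""Peri-error behavioral statistics.

Commission errors in a speeded choice task are surrounded by a
characteristic response-time (RT) pattern — speeding on the trial before
the error and slowing on the trial after — while the erroneous keypress
itself is *shorter* than correct keypresses (response duration, RD),
the behavioral signature of immediate error cancellation.

This module extracts peri-error chunks (an error E with its two correct
neighbors on each side), screens them for RD outliers, and computes:

* pre-error speeding  = (RT[E-2] + RT[E+2]) / 2 - RT[E-1]
* post-error slowing  =  RT[E+1] - (RT[E-2] + RT[E+2]) / 2
* error cancellation  =  mean RD of the correct neighbors - RD[E]

plus condition median splits of RD, coefficients of variation, and the
paired-design power calculations used for sample-size planning.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorChunk",
    "PowerSpec",
    "read_trial_log",
    "extract_error_chunks",
    "remove_rd_outliers",
    "peri_error_stats",
    "chunk_stats_table",
    "participant_means",
    "median_split_rd",
    "coefficient_of_variation",
    "compare_cv_rd_rt",
    "paired_power",
    "fisher_mean_correlation",
]

#: outcome labels in a trial log
OUTCOMES = ("correct", "commission_error", "omission", "miscellaneous")

#: required columns of a trial log
TRIAL_COLUMNS = ["participant", "block", "trial", "outcome", "rt", "rd"]


@dataclass(frozen=True)
class ErrorChunk:
    """A commission error E with its two correct neighbors on each side.

    ``trials`` holds the rows E-2, E-1, E, E+1, E+2 in order.
    """

    participant: object
    block: object
    error_trial: int
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.trials) != 5:
            raise ValueError("chunk must hold exactly 5 trials")
        out = self.trials["outcome"].to_numpy()
        if out[2] != "commission_error":
            raise ValueError("center trial must be a commission error")
        if not np.all(out[[0, 1, 3, 4]] == "correct"):
            raise ValueError("all four neighbors must be correct")
        idx = self.trials["trial"].to_numpy()
        if not np.all(np.diff(idx) == 1):
            raise ValueError("trial indices must be consecutive")

    @property
    def rts(self) -> np.ndarray:
        return self.trials["rt"].to_numpy(dtype=float)

    @property
    def rds(self) -> np.ndarray:
        return self.trials["rd"].to_numpy(dtype=float)


@dataclass(frozen=True)
class PowerSpec:
    """Specification of an a priori paired t-test power analysis."""

    d_z: float
    alpha: float = 0.05
    power: float = 0.80
    n: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.d_z <= 0:
            raise ValueError("d_z must be positive")


def read_trial_log(path, sep=None) -> pd.DataFrame:
    """Read a CSV/TSV trial log with the documented column schema.

    Required columns: participant, block, trial, outcome, rt, rd
    (rt/rd in ms; empty for omissions). Optional: stimulus, response.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log missing columns: {missing}")
    bad = set(df["outcome"].unique()) - set(OUTCOMES)
    if bad:
        raise ValueError(f"unknown outcome labels: {sorted(bad)}")
    return df.sort_values(["participant", "block", "trial"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# chunk extraction and screening
# ---------------------------------------------------------------------------

def extract_error_chunks(
    trials: pd.DataFrame,
    n_pre: int = 2,
    n_post: int = 2,
    allow_overlap: bool = True,
) -> list[ErrorChunk]:
    """Select commission errors flanked by ``n_pre``/``n_post`` correct trials.

    Chunks never span block boundaries. With ``allow_overlap=False`` an
    error within ``n_pre + n_post`` trials of another error is dropped even
    if its own neighbors are correct.
    """
    chunks: list[ErrorChunk] = []
    for (pid, block), grp in trials.groupby(["participant", "block"], sort=False):
        grp = grp.sort_values("trial").reset_index(drop=True)
        out = grp["outcome"].to_numpy()
        idx = grp["trial"].to_numpy()
        err_pos = np.flatnonzero(out == "commission_error")
        for p in err_pos:
            lo, hi = p - n_pre, p + n_post
            if lo < 0 or hi >= len(grp):
                continue
            window = np.arange(lo, hi + 1)
            if not np.all(np.diff(idx[window]) == 1):
                continue
            neighbors = np.concatenate([window[:n_pre], window[n_pre + 1 :]])
            if not np.all(out[neighbors] == "correct"):
                continue
            if not allow_overlap and np.any(
                (err_pos != p) & (np.abs(err_pos - p) <= n_pre + n_post)
            ):
                continue
            chunks.append(
                ErrorChunk(
                    participant=pid,
                    block=block,
                    error_trial=int(idx[p]),
                    trials=grp.iloc[window].reset_index(drop=True),
                )
            )
    n_overlap = _count_overlaps(chunks)
    if n_overlap:
        logger.info("%d chunk pairs share trials (overlap permitted)", n_overlap)
    return chunks


def _count_overlaps(chunks: list[ErrorChunk]) -> int:
    n = 0
    by_key: dict[tuple, list[int]] = {}
    for ch in chunks:
        by_key.setdefault((ch.participant, ch.block), []).append(ch.error_trial)
    for errs in by_key.values():
        errs = sorted(errs)
        n += sum(1 for a, b in zip(errs, errs[1:]) if b - a <= 4)
    return n


def remove_rd_outliers(
    chunks: list[ErrorChunk], k: float = 2.5
) -> tuple[list[ErrorChunk], float]:
    """Drop chunks containing any RD outlier (|RD - cell mean| > k * cell SD).

    Cells are participant x correctness; means/SDs use the sample SD
    (n-1 denominator) over all chunk-member trials of the cell. Returns
    the survivors and the removed fraction.
    """
    if not chunks:
        return [], 0.0
    rows = []
    for i, ch in enumerate(chunks):
        for j in range(5):
            rows.append(
                (
                    i,
                    ch.participant,
                    "commission_error" if j == 2 else "correct",
                    ch.rds[j],
                )
            )
    tab = pd.DataFrame(rows, columns=["chunk", "participant", "cell", "rd"])
    bad_chunks: set[int] = set()
    for (pid, cell), grp in tab.groupby(["participant", "cell"]):
        if len(grp) < 2:
            warnings.warn(
                f"cell ({pid}, {cell}) has < 2 trials; SD undefined, no outliers flagged",
                stacklevel=2,
            )
            continue
        sd = grp["rd"].std(ddof=1)
        if sd == 0:
            continue
        z = (grp["rd"] - grp["rd"].mean()).abs() / sd
        bad_chunks.update(grp.loc[z > k, "chunk"])
    kept = [ch for i, ch in enumerate(chunks) if i not in bad_chunks]
    frac = len(bad_chunks) / len(chunks)
    logger.info("outlier screen removed %.2f%% of chunks", 100 * frac)
    return kept, frac


# ---------------------------------------------------------------------------
# peri-error statistics
# ---------------------------------------------------------------------------

def peri_error_stats(chunk: ErrorChunk, cancellation_mode: str = "pm2") -> dict:
    """Speeding, slowing and cancellation for one chunk (all in ms).

    ``cancellation_mode='pm2'`` uses all four correct neighbors as the
    correct-RD reference; ``'pm1'`` uses only E-1 and E+1.
    """
    rt = chunk.rts
    rd = chunk.rds
    baseline = (rt[0] + rt[4]) / 2.0
    if cancellation_mode == "pm2":
        rd_correct = float(np.mean(rd[[0, 1, 3, 4]]))
    elif cancellation_mode == "pm1":
        rd_correct = float(np.mean(rd[[1, 3]]))
    else:
        raise ValueError("cancellation_mode must be 'pm2' or 'pm1'")
    return {
        "pre_error_speeding": baseline - rt[1],
        "post_error_slowing": rt[3] - baseline,
        "error_cancellation": rd_correct - rd[2],
        "rd_error": float(rd[2]),
        "rd_correct": rd_correct,
    }


def chunk_stats_table(
    chunks: list[ErrorChunk], cancellation_mode: str = "pm2"
) -> pd.DataFrame:
    """Per-chunk peri-error statistics as a flat table."""
    rows = []
    for ch in chunks:
        row = peri_error_stats(ch, cancellation_mode)
        row["participant"] = ch.participant
        rows.append(row)
    return pd.DataFrame(rows)


def participant_means(stats_table: pd.DataFrame) -> pd.DataFrame:
    """Mean of chunk-level statistics per participant (the unit of analysis)."""
    return stats_table.groupby("participant", sort=True).mean(numeric_only=True)


def group_effects(stats_table: pd.DataFrame, ci: float = 0.95) -> pd.DataFrame:
    """Across-participant t-tests on the three peri-error effects.

    Returns mean, CI bounds, t, df, p and d_z per effect, computed on the
    per-participant means (paired design against zero).
    """
    per = participant_means(stats_table)
    out = []
    for effect in ("pre_error_speeding", "post_error_slowing", "error_cancellation"):
        x = per[effect].to_numpy(dtype=float)
        n = x.size
        m = x.mean()
        if n < 2:
            sd = se = tcrit = t = p = np.nan
        else:
            sd = x.std(ddof=1)
            se = sd / math.sqrt(n)
            tcrit = stats.t.ppf(0.5 + ci / 2, n - 1)
            t, p = stats.ttest_1samp(x, 0.0)
        out.append(
            {
                "effect": effect,
                "mean": m,
                "ci_low": m - tcrit * se,
                "ci_high": m + tcrit * se,
                "t": t,
                "df": n - 1,
                "p": p,
                "d_z": m / sd if sd > 0 else np.nan,
            }
        )
    return pd.DataFrame(out).set_index("effect")


# ---------------------------------------------------------------------------
# median split / CV
# ---------------------------------------------------------------------------

def median_split_rd(trials: pd.DataFrame) -> pd.Series:
    """Label each responded trial 'short' or 'long' by its cell median RD.

    Cells are participant x correctness; RDs equal to the median go to the
    long (slower) bin.
    """
    labels = pd.Series(index=trials.index, dtype=object)
    responded = trials["outcome"].isin(["correct", "commission_error"])
    for _, grp in trials[responded].groupby(["participant", "outcome"]):
        if len(grp) < 2:
            raise ValueError("median split needs >= 2 trials per cell")
        med = grp["rd"].median()
        labels.loc[grp.index] = np.where(grp["rd"] < med, "short", "long")
    return labels


def coefficient_of_variation(values) -> float:
    """CV = sample SD / mean; mean must be positive."""
    x = np.asarray(values, dtype=float)
    m = x.mean()
    if m <= 0:
        raise ValueError("CV requires a positive mean")
    return float(x.std(ddof=1) / m)


def compare_cv_rd_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Paired comparison of CV(RD) vs CV(RT) across participants.

    Computed separately for correct and erroneous responses; returns t,
    df, p and d_z per correctness cell. A CV(RD) clearly above CV(RT)
    certifies that RD jitter is meaningful relative to RT jitter.
    """
    rows = []
    responded = trials[trials["outcome"].isin(["correct", "commission_error"])]
    for outcome, grp in responded.groupby("outcome"):
        cvs = grp.groupby("participant").agg(
            cv_rt=("rt", coefficient_of_variation),
            cv_rd=("rd", coefficient_of_variation),
        )
        d = cvs["cv_rd"] - cvs["cv_rt"]
        n = len(d)
        if n < 2:
            t = p = np.nan
        else:
            t, p = stats.ttest_rel(cvs["cv_rd"], cvs["cv_rt"])
        rows.append(
            {
                "outcome": outcome,
                "mean_cv_rt": cvs["cv_rt"].mean(),
                "mean_cv_rd": cvs["cv_rd"].mean(),
                "t": t,
                "df": n - 1,
                "p": p,
                "d_z": d.mean() / d.std(ddof=1) if d.std(ddof=1) > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("outcome")


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

def _paired_power_at_n(d_z: float, n: int, alpha: float) -> float:
    """Two-sided paired t-test power via the noncentral t distribution."""
    df = n - 1
    nc = d_z * math.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def paired_power(spec: PowerSpec, mode: str = "solve_n", n_max: int = 100000):
    """Solve the paired t-test power equation.

    ``mode='solve_n'`` returns the smallest n whose power reaches
    ``spec.power``; ``mode='solve_power'`` returns the power at ``spec.n``.
    """
    if mode == "solve_power":
        if spec.n is None or spec.n < 2:
            raise ValueError("solve_power requires n >= 2")
        return _paired_power_at_n(spec.d_z, spec.n, spec.alpha)
    if mode != "solve_n":
        raise ValueError("mode must be 'solve_n' or 'solve_power'")
    for n in range(2, n_max + 1):
        if _paired_power_at_n(spec.d_z, n, spec.alpha) >= spec.power:
            return n
    raise RuntimeError("no n below n_max reaches the target power")


def fisher_mean_correlation(r_values) -> float:
    """Average correlations via Fisher z, back-transformed to r."""
    r = np.asarray(r_values, dtype=float)
    return float(np.tanh(np.mean(np.arctanh(r))))
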