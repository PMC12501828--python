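"""Residue-iteration decomposition: recovery, conservation, order effects."""

import numpy as np
import pandas as pd
import pytest

from erncancel import ride
from erncancel.containers import EpochSet
from erncancel.synthetic import _biphasic, gen_component_epochs


def planted_waveform(times, lag, half_width, amp):
    return _biphasic(times, lag, half_width, amp)


def corr(a, b):
    return float(np.corrcoef(a, b)[0, 1])


@pytest.fixture(scope="module")
def two_component_result():
    ep, on, off, truth = gen_component_epochs(n_trials=200, rd_jitter_sd=30.0,
                                              seed=0)
    cfg = ride.RideConfig(clusters=ride.two_cluster_config())
    return ep, on, off, truth, ride.ride_decompose(ep, on, off, cfg)


def test_planted_components_recovered(two_component_result):
    ep, on, off, truth, res = two_component_result
    t_on = res.component_times["r_onset"]
    t_off = res.component_times["r_offset"]
    c_on = corr(res.components["r_onset"][0],
                planted_waveform(t_on, truth["onset_peak"],
                                 truth["half_width"], truth["onset_amp"]))
    c_off = corr(res.components["r_offset"][0],
                 planted_waveform(t_off, truth["offset_lag"],
                                  truth["half_width"], truth["offset_amp"]))
    assert c_on >= 0.9 and c_off >= 0.9


def test_conservation_reconstruction_plus_residual(two_component_result):
    ep, on, off, truth, res = two_component_result
    recon = ride.reconstruct(res)
    assert np.max(np.abs(recon + res.residual - ep.data)) < 1e-6


def test_convergence_trace_nonincreasing_after_first(two_component_result):
    *_, res = two_component_result
    c = res.convergence
    assert all(c[i + 1] <= c[i] + 1e-9 for i in range(1, len(c) - 1))


def test_onset_only_input_leaves_offset_component_flat():
    ep, on, off, truth = gen_component_epochs(offset_amp=0.0, seed=1)
    res = ride.ride_decompose(ep, on, off,
                              ride.RideConfig(clusters=ride.two_cluster_config()))
    ratio = (np.abs(res.components["r_offset"][0]).max()
             / np.abs(res.components["r_onset"][0]).max())
    assert ratio < 0.10


def test_all_zero_epochs_converge_immediately():
    times = np.arange(-200.0, 400.0, 2.0)
    n = 10
    ep = EpochSet(np.zeros((n, 1, times.size)), times, ["FCz"], 500.0,
                  "response_onset", pd.DataFrame({"rd": np.linspace(100, 180, n)}))
    res = ride.ride_decompose(ep, np.zeros(n), np.linspace(100, 180, n),
                              ride.RideConfig(clusters=ride.two_cluster_config()))
    assert res.iterations == 1 and res.converged
    for comp in res.components.values():
        np.testing.assert_allclose(comp, 0.0)
    np.testing.assert_allclose(res.residual, 0.0)


def test_recovery_degrades_monotonically_with_less_jitter():
    cfg = ride.RideConfig(clusters=ride.two_cluster_config())
    cors = []
    for sd in (2.0, 10.0, 30.0):
        ep, on, off, truth = gen_component_epochs(rd_jitter_sd=sd, seed=2)
        res = ride.ride_decompose(ep, on, off, cfg)
        t_off = res.component_times["r_offset"]
        cors.append(corr(res.components["r_offset"][0],
                         planted_waveform(t_off, truth["offset_lag"],
                                          truth["half_width"],
                                          truth["offset_amp"])))
    assert cors[0] < cors[1] < cors[2]


def test_zero_jitter_is_rejected():
    times = np.arange(-200.0, 400.0, 2.0)
    ep = EpochSet(np.zeros((5, 1, times.size)), times, ["FCz"], 500.0,
                  "response_onset", pd.DataFrame({"rd": [140.0] * 5}))
    with pytest.raises(ValueError, match="zero variance"):
        ride.ride_decompose(ep, np.zeros(5), np.full(5, 140.0))


def test_update_order_moves_shared_variance():
    """Offset-first updating grabs more shared variance than onset-first."""
    ep, on, off, truth = gen_component_epochs(rd_jitter_sd=8.0, seed=3)
    fwd = ride.RideConfig(clusters=ride.two_cluster_config())
    rev = ride.RideConfig(clusters=list(reversed(ride.two_cluster_config())))
    res_f = ride.ride_decompose(ep, on, off, fwd)
    res_r = ride.ride_decompose(ep, on, off, rev)
    energy_off_f = float(np.sum(res_f.components["r_offset"] ** 2))
    energy_off_r = float(np.sum(res_r.components["r_offset"] ** 2))
    assert energy_off_r > energy_off_f


def test_two_cluster_solution_absorbs_intermediate_into_offset():
    """A mid-latency positivity that rides between onset and offset loads
    on the offset cluster in a 2-cluster fit and migrates to the
    intermediate cluster when one is available."""
    rng = np.random.default_rng(4)
    n, sfreq = 150, 500.0
    times = np.arange(-300.0, 600.0, 1000.0 / sfreq)
    rd = np.maximum(rng.normal(140, 30, n), 60)
    data = rng.normal(0, 0.5, (n, 1, times.size))
    for i in range(n):
        data[i, 0] += _biphasic(times, rd[i] * 0.75, 60.0, 3.0)
    ep = EpochSet(data, times, ["FCz"], sfreq, "response_onset",
                  pd.DataFrame({"rd": rd}))
    res2 = ride.ride_decompose(ep, np.zeros(n), rd,
                               ride.RideConfig(clusters=ride.two_cluster_config()))
    res3 = ride.ride_decompose(ep, np.zeros(n), rd,
                               ride.RideConfig(clusters=ride.three_cluster_config()))
    on2 = float(np.abs(res2.components["r_onset"]).max())
    off2 = float(np.abs(res2.components["r_offset"]).max())
    assert off2 > 1.5 and off2 > on2  # positivity lands in the offset cluster
    inter3 = float(np.abs(res3.components["r_intermediate"]).max())
    off3 = float(np.abs(res3.components["r_offset"]).max())
    assert inter3 > off3  # ... and moves to the intermediate cluster
    assert off3 < off2


def test_reconstruct_rejects_latency_outside_epoch(two_component_result):
    ep, on, off, truth, res = two_component_result
    bad = {k: v.copy() for k, v in res.latencies.items()}
    bad["r_offset"] = bad["r_offset"] + 10_000.0
    with pytest.raises(ValueError, match="outside epoch"):
        ride.reconstruct(res, bad)


def test_fewer_than_two_trials_rejected():
    times = np.arange(-100.0, 100.0, 2.0)
    ep = EpochSet(np.zeros((1, 1, times.size)), times, ["FCz"], 500.0,
                  "response_onset", pd.DataFrame({"rd": [100.0]}))
    with pytest.raises(ValueError, match="2 trials"):
        ride.ride_decompose(ep, [0.0], [100.0])


# ---------------------------------------------------------------------------
# condition contrasts
# ---------------------------------------------------------------------------

def _results_for(amp, n_results=8, seed=0):
    out = []
    cfg = ride.RideConfig(clusters=ride.two_cluster_config())
    for k in range(n_results):
        ep, on, off, _ = gen_component_epochs(
            n_trials=60, offset_amp=amp, noise_sd=0.8, seed=seed + 100 * k)
        out.append(ride.ride_decompose(ep, on, off, cfg))
    return out


def test_identical_conditions_give_zero_difference():
    res = _results_for(-2.0, n_results=4)
    c = ride.cluster_condition_contrast(res, res, "r_offset", "FCz",
                                        (0.0, 100.0), n_perm=200)
    assert c["difference"] == 0.0
    assert all(d["p"] >= 0.05 for d in c["clusters"])


def test_planted_offset_negativity_detected():
    res_a = _results_for(-2.5, seed=1)
    res_b = _results_for(0.0, seed=2)
    c = ride.cluster_condition_contrast(res_a, res_b, "r_offset", "FCz",
                                        (0.0, 100.0), n_perm=500)
    assert c["difference"] < 0
    assert any(d["p"] < 0.05 and d["sign"] < 0 for d in c["clusters"])


def test_window_sample_arithmetic():
    # [50, 100] ms at 1000 Hz covers 51 samples
    times = np.arange(-100.0, 200.0)
    mask = (times >= 50) & (times <= 100)
    assert mask.sum() == 51
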