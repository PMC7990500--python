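import numpy as np
import pandas as pd
import pytest

from optodetect import ephys as ep
from optodetect.simulate import UnitConfig
from optodetect.simulate.spikes import simulate_unit, suppression_factor


def events_frame(trials, led=100.0, stim=110.0, tlen=350.0, intensity=0.0,
                 unit="u0", area="V1"):
    return pd.DataFrame({
        "unit_id": unit, "intensity": intensity, "trial": np.arange(trials),
        "led_on_ms": led, "stim_on_ms": stim, "trial_len_ms": tlen,
        "area_label": area,
    })


def spikes_from_times(times_by_trial, intensity=0.0, unit="u0"):
    rows = []
    for trial, times in times_by_trial.items():
        for t in times:
            rows.append((unit, intensity, trial, t))
    return pd.DataFrame(rows, columns=["unit_id", "intensity", "trial", "spike_time_ms"])


def test_window_rates_arithmetic():
    # r_base window [50, 90): 2 spikes in 40 ms -> 50 Hz
    # r_min window [125, 150): 1 spike in 25 ms -> 40 Hz
    # r_vis window [175, 225): 3 spikes in 50 ms -> 60 Hz
    spikes = spikes_from_times({0: [60.0, 70.0, 130.0, 180.0, 190.0, 200.0]})
    win = ep.window_rates(spikes, events_frame(1))
    assert win["r_base"].iloc[0] == pytest.approx(50.0)
    assert win["r_min"].iloc[0] == pytest.approx(40.0)
    assert win["r_vis"].iloc[0] == pytest.approx(60.0)


def test_window_rates_pm_shift():
    # PM visual window starts 25 ms later: [200, 250)
    spikes = spikes_from_times({0: [180.0, 210.0]})
    win = ep.window_rates(spikes, events_frame(1, area="PM"))
    assert win["r_vis"].iloc[0] == pytest.approx(20.0)  # only the 210 ms spike


def test_window_rates_window_outside_epoch_raises():
    spikes = spikes_from_times({0: [60.0]})
    with pytest.raises(ValueError):
        ep.window_rates(spikes, events_frame(1, led=30.0))  # baseline before 0


def test_classify_waveform_cutoff():
    assert ep.classify_waveform(0.30) == "narrow"
    assert ep.classify_waveform(0.45) == "wide"
    assert ep.classify_waveform(0.60) == "wide"


def test_select_units_criteria():
    windows = pd.DataFrame({
        "unit_id": ["a", "b", "c", "d"],
        "intensity": 0.0,
        "r_base": [10.0, 10.0, 10.0, 10.0],
        "r_min": [2.0, 2.0, 2.0, 2.0],
        "r_vis": [15.0, 15.0, 15.0, 10.5],  # d is not responsive (ratio 1.05)
        "area_label": "V1",
        "n_trials": 50,
    })
    qc = pd.DataFrame({
        "unit_id": ["a", "b", "c", "d"],
        "snr": [3.0, 2.0, 3.0, 3.0],  # b fails SNR
        "trough_to_peak_ms": [0.6, 0.6, 0.3, 0.6],  # c is narrow
        "is_single_unit": [True, True, True, True],
    })
    assert ep.select_units(windows, qc) == ["a"]


def test_normalized_response_identities():
    windows = pd.DataFrame({
        "unit_id": "u0",
        "intensity": [0.0, 0.2, 0.8],
        "r_base": 10.0,
        "r_min": [5.0, 5.0, 5.0],
        "r_vis": [25.0, 10.0, 5.0],  # spans 20, 5, 0 above r_min
        "area_label": "V1",
        "n_trials": 50,
    })
    norm = ep.normalized_response(windows)
    by_i = norm.set_index("intensity")["norm_response"]
    assert by_i[0.0] == 1.0  # exactly 1 at zero intensity
    assert by_i[0.2] == pytest.approx(0.25)  # 5 / 20
    assert by_i[0.8] == 0.0  # full suppression


def test_normalized_response_drops_nonresponsive_unit():
    windows = pd.DataFrame({
        "unit_id": "bad",
        "intensity": [0.0, 0.2],
        "r_base": 10.0,
        "r_min": [8.0, 8.0],
        "r_vis": [8.0, 6.0],  # zero response at zero intensity
        "area_label": "V1",
        "n_trials": 50,
    })
    with pytest.warns(UserWarning):
        out = ep.normalized_response(windows)
    assert len(out) == 0


def test_normalized_response_scale_invariant():
    base = pd.DataFrame({
        "unit_id": "u0",
        "intensity": [0.0, 0.2, 0.4],
        "r_base": 10.0,
        "r_min": [5.0, 4.0, 3.0],
        "r_vis": [25.0, 12.0, 6.0],
        "area_label": "V1",
        "n_trials": 50,
    })
    scaled = base.copy()
    for col in ("r_base", "r_min", "r_vis"):
        scaled[col] = scaled[col] * 3.7
    a = ep.normalized_response(base)["norm_response"].to_numpy()
    b = ep.normalized_response(scaled)["norm_response"].to_numpy()
    assert np.allclose(a, b)


def test_fit_suppression_noiseless_fwhm():
    sigma = 0.73 / (2.0 * ep.SQRT_2LN2)
    x = np.linspace(0.0, 1.2, 13)
    y = np.exp(-(x**2) / (2.0 * sigma**2))
    fit = ep.fit_suppression(np.column_stack([x, y]), domain="distance", n_boot=0)
    assert fit.fwhm == pytest.approx(0.73, rel=1e-4)
    assert fit.predict(fit.i50) == pytest.approx(0.5, rel=1e-6)


def test_fit_suppression_monotone_and_domain_scaling():
    x = np.array([0.0, 0.1, 0.2, 0.4, 0.8])
    y = np.exp(-(x**2) / (2.0 * 0.17**2))
    fit = ep.fit_suppression(np.column_stack([x, y]), domain="intensity", n_boot=0)
    grid = np.linspace(0, 1, 50)
    assert np.all(np.diff(fit.predict(grid)) <= 0)
    assert fit.fwhm == pytest.approx(2.0 * fit.i50)
    assert fit.i50 == pytest.approx(0.17 * ep.SQRT_2LN2, rel=1e-4)


def test_fit_suppression_needs_three_x():
    with pytest.raises(ValueError):
        ep.fit_suppression([(0.0, 1.0), (0.1, 0.8), (0.1, 0.7)])


def test_suppression_factor_limits():
    cfg = UnitConfig()
    assert suppression_factor(cfg, 0.0) == pytest.approx(1.0)
    assert suppression_factor(cfg, 100.0, distance_mm=0.0) == pytest.approx(0.0, abs=1e-6)
    # at I50 and zero distance the rate is halved
    i50 = cfg.sigma_i * ep.SQRT_2LN2
    assert suppression_factor(cfg, i50) == pytest.approx(0.5, rel=1e-6)


def test_latency_logistic_midpoint_and_shift():
    t = np.arange(0.0, 200.0, 2.0)
    r = 5.0 + 20.0 / (1.0 + np.exp(-(t - 65.0) / 4.0))
    assert ep.latency_half_max(t, r) == pytest.approx(65.0, abs=0.1)
    assert ep.latency_half_max(t + 25.0, r) == pytest.approx(90.0, abs=0.1)


def test_latency_rejects_flat_psth():
    t = np.arange(0.0, 200.0, 2.0)
    with pytest.raises(ValueError):
        ep.latency_half_max(t, np.full_like(t, 7.0))


def test_simulated_unit_pipeline_recovers_i50():
    rng = np.random.default_rng(23)
    intensities = [0.0, 0.05, 0.1, 0.2, 0.4, 0.8]
    sp_all, ev_all = [], []
    for u in range(4):
        sp, ev = simulate_unit(UnitConfig(), intensities, 100, rng, unit_id=f"u{u}")
        sp_all.append(sp)
        ev_all.append(ev)
    win = ep.window_rates(pd.concat(sp_all), pd.concat(ev_all))
    norm = ep.normalized_response(win)
    fit = ep.fit_suppression(
        norm[["intensity", "norm_response"]].to_numpy(), domain="intensity",
        groups=norm["unit_id"].to_numpy(), n_boot=200,
        rng=np.random.default_rng(1),
    )
    assert fit.i50 == pytest.approx(0.2, rel=0.15)
    assert fit.ci95[0] < fit.i50 < fit.ci95[1]


def test_direct_suppression_exceeds_downstream():
    # a unit under the light loses more of its response than one 0.5 mm away
    cfg = UnitConfig()
    assert suppression_factor(cfg, 0.4, 0.0) < suppression_factor(cfg, 0.4, 0.5)
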