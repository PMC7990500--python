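import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from helpers import censored_constant_hazard_trials
from optodetect import sdt
from optodetect.simulate import ObserverParams, SessionConfig, simulate_session


def trials_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "trial_type", "outcome", "release_ms", "trial_len_ms",
            "actual_onset_ms", "pulse_phase_ms",
        ],
    )


def test_binned_hazard_worked_example():
    # 1 false alarm in a 1 ms bin among 500 trials at risk -> 2.0 per second
    rows = [("OFF", "false_alarm", 0.5, 0.5, 2000.0, 0.0)]
    rows += [("OFF", "miss", np.nan, 2100.0, 2000.0, 0.0)] * 499
    curve = sdt.hazard_binned(trials_frame(rows), bin_ms=1.0, max_ms=10.0)
    assert curve.hazard_per_s[0] == pytest.approx(2.0)
    assert curve.survivors[0] == 500


def test_binned_hazard_no_events_is_zero():
    rows = [("ON", "miss", np.nan, 1500.0, 1400.0, 0.0)] * 50
    curve = sdt.hazard_binned(trials_frame(rows), bin_ms=50.0)
    ok = curve.survivors > 0
    assert np.all(curve.hazard_per_s[ok] == 0.0)


def test_binned_hazard_nan_when_no_survivors():
    rows = [("ON", "miss", np.nan, 600.0, 500.0, 0.0)] * 10
    curve = sdt.hazard_binned(trials_frame(rows), bin_ms=100.0, max_ms=1000.0)
    assert np.isnan(curve.hazard_per_s[-1])


def test_binned_hazard_drops_events_beyond_horizon():
    # an event past max_ms must not be folded into the last bin
    rows = [
        ("ON", "false_alarm", 950.0, 950.0, 2000.0, 0.0),
        ("ON", "miss", np.nan, 2100.0, 2000.0, 0.0),
    ]
    curve = sdt.hazard_binned(trials_frame(rows), bin_ms=100.0, max_ms=500.0)
    assert curve.events.sum() == 0.0


def test_binned_hazard_censors_at_onset_plus_cutoff():
    rows = [("ON", "miss", np.nan, 1000.0, 850.0, 0.0)] * 10
    curve = sdt.hazard_binned(trials_frame(rows), bin_ms=100.0, max_ms=1200.0)
    # at risk through onset + 100 = 950 ms, gone afterwards
    assert curve.survivors[9] == 10  # bin starting 900
    assert curve.survivors[10] == 0  # bin starting 1000


def test_hazard_estimated_worked_example():
    # 100 trials, 20 false alarms, mean trial length 2 s -> 0.1 per second
    rows = [("OFF", "false_alarm", 2000.0, 2000.0, 3000.0, 0.0)] * 20
    rows += [("OFF", "miss", np.nan, 2000.0, 1900.0, 0.0)] * 80
    assert sdt.hazard_estimated(trials_frame(rows), "OFF") == pytest.approx(0.1)


def test_hazard_estimated_zero_when_no_fa():
    rows = [("ON", "miss", np.nan, 2000.0, 1900.0, 0.0)] * 30
    assert sdt.hazard_estimated(trials_frame(rows), "ON") == 0.0


def test_hazard_estimated_requires_trials():
    rows = [("ON", "miss", np.nan, 2000.0, 1900.0, 0.0)]
    with pytest.raises(ValueError):
        sdt.hazard_estimated(trials_frame(rows), "OFF")


def test_hazard_mle_unbiased_on_censored_process():
    df = censored_constant_hazard_trials(seed=77, n_trials=4000, hazard_per_s=0.1)
    for t in ("ON", "OFF"):
        assert sdt.hazard_mle(df, t) == pytest.approx(0.1, rel=0.12)


def test_hazard_estimated_underestimates_on_full_sessions():
    # On observer sessions the trial continues past the false-alarm window
    # (reaction time bookkeeping), so the length-based estimator reads low;
    # the exposure-based MLE does not.
    cfg = SessionConfig(n_trials=3000)
    rng = np.random.default_rng(13)
    df = simulate_session(cfg, ObserverParams(fa_hazard=0.1), rng).to_frame()
    est = sdt.hazard_estimated(df, "OFF")
    mle = sdt.hazard_mle(df, "OFF")
    assert mle == pytest.approx(0.1, rel=0.12)
    assert est < 0.9 * mle


def test_pulse_aligned_hazard_flat_for_constant_process():
    df = censored_constant_hazard_trials(seed=5, n_trials=3000, hazard_per_s=0.1)
    curve = sdt.hazard_binned(df, bin_ms=100.0, align="pulse_onset")
    # total folded exposure equals total at-risk time
    t, _ = sdt._risk_times(df, 100.0)
    assert curve.survivors.sum() == pytest.approx(t.sum(), rel=1e-6)
    w = curve.survivors
    mean_h = np.average(curve.hazard_per_s, weights=w)
    assert mean_h == pytest.approx(0.1, rel=0.15)
    # no folded bin deviates wildly from the constant rate
    assert np.nanmax(curve.hazard_per_s) < 0.3


def test_rate_correct_clamps_extremes():
    assert sdt.rate_correct(0, 50) == pytest.approx(0.01)
    assert sdt.rate_correct(50, 50) == pytest.approx(0.99)
    assert sdt.rate_correct(25, 50) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        sdt.rate_correct(1, 0)


def test_criteria_worked_example():
    # (z(0.9) + z(0.2)) / 2 = (1.28155 - 0.84162) / 2
    c_abs, c_rel = sdt.criteria(0.9, 0.2)
    assert c_abs == pytest.approx((norm.ppf(0.9) + norm.ppf(0.2)) / 2.0, abs=1e-12)
    assert c_abs == pytest.approx(0.219965, abs=1e-5)
    assert c_rel == pytest.approx(c_abs / (norm.ppf(0.9) - norm.ppf(0.2)))


def test_criteria_zero_when_fa_mirrors_hit():
    c_abs, _ = sdt.criteria(0.73, 0.27)
    assert c_abs == pytest.approx(0.0, abs=1e-12)


def test_criteria_relative_undefined_at_zero_dprime():
    c_abs, c_rel = sdt.criteria(0.5, 0.5)
    assert c_abs == 0.0
    assert np.isnan(c_rel)


def test_criteria_conventional_sign_flip():
    paper, _ = sdt.criteria(0.9, 0.2, convention="paper")
    conv, _ = sdt.criteria(0.9, 0.2, convention="conventional")
    assert conv == pytest.approx(-paper)
    with pytest.raises(ValueError):
        sdt.criteria(0.9, 0.2, convention="other")


def test_criteria_rejects_boundary_rates():
    with pytest.raises(ValueError):
        sdt.criteria(1.0, 0.2)


def test_dprime_by_contrast_on_session():
    cfg = SessionConfig(n_trials=3000)
    rng = np.random.default_rng(19)
    session = simulate_session(cfg, ObserverParams(fa_hazard=0.1), rng)
    tab = sdt.dprime_by_contrast(session, hazard_fn=sdt.hazard_mle)
    assert set(tab["trial_type"]) == {"ON", "OFF"}
    # monotone in contrast on average (noise permitting at the top end)
    off = tab[tab["trial_type"] == "OFF"].sort_values("contrast")
    assert off["dprime"].iloc[-1] > off["dprime"].iloc[0] + 1.0
    # FA = hazard * reaction window
    fa = tab["FA"].iloc[0]
    assert fa == pytest.approx(tab["fa_hazard_est"].iloc[0] * 0.55, rel=1e-9)


def test_dprime_zero_when_hit_equals_fa():
    # construct a frame with one contrast whose hit rate equals the FA rate
    rows = []
    # 11 hits, 39 misses at contrast 4 -> H = 0.22
    rows += [("OFF", "hit", 2300.0, 2300.0, 2000.0, 0.0)] * 11
    rows += [("OFF", "miss", np.nan, 2550.0, 2000.0, 0.0)] * 39
    df = trials_frame(rows)
    df["contrast"] = 4.0
    tab = sdt.dprime_by_contrast(df, hazard_fn=lambda *a, **k: 0.4)
    assert tab["dprime"].iloc[0] == pytest.approx(0.0, abs=1e-9)  # FA = 0.22
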