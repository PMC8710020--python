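"""KM, log-rank, maximally selected cutpoints and Cox, against oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from mihcquant import (
    ConvergenceError, NoCutpointError, SingularError, UntestableError,
    cox_univariate, km_curve, logrank, max_sel_cutpoint, survival_screen,
)


def _sim(rng, n=80, beta=0.0, cens=0.01):
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.02 * np.exp(beta * x)))
    c = rng.exponential(1.0 / cens, n)
    return np.minimum(t, c), (t <= c).astype(int), x


# --- Kaplan-Meier ----------------------------------------------------------

def test_km_hand_computed_product_limit():
    # times (2, 4+, 6): S = 1 on [0,2), 2/3 on [2,6), 0 at 6; median 6
    curve = km_curve([2.0, 4.0, 6.0], [1, 0, 1])
    assert curve.evaluate(1.9) == pytest.approx(1.0)
    assert curve.evaluate(2.0) == pytest.approx(2 / 3)
    assert curve.evaluate(5.9) == pytest.approx(2 / 3)
    assert curve.evaluate(6.0) == pytest.approx(0.0)
    assert curve.median == pytest.approx(6.0)


def test_km_no_censoring_equals_empirical(rng):
    t = rng.exponential(10, 50)
    curve = km_curve(t, np.ones(50, int))
    grid = np.quantile(t, [0.1, 0.35, 0.6, 0.9])
    for g in grid:
        assert curve.evaluate(g) == pytest.approx((t > g).mean())


def test_km_all_censored_flat_one():
    curve = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
    assert curve.evaluate(100.0) == pytest.approx(1.0)
    assert curve.median is None


def test_km_monotone_right_continuous(rng):
    t, e, _ = _sim(rng, 120)
    curve = km_curve(t, e)
    assert curve.evaluate(0.0) == 1.0
    vals = curve.evaluate(np.sort(np.concatenate([curve.event_times,
                                                  curve.event_times + 1e-9])))
    assert (np.diff(vals) <= 1e-12).all()


def test_km_nonpositive_time_rejected():
    with pytest.raises(Exception):
        km_curve([0.0, 1.0], [1, 1])


# --- log-rank --------------------------------------------------------------

def test_logrank_hand_computed_six_subjects():
    # A: (1,e) (3,e) (5,c); B: (2,e) (4,c) (6,e)
    # t=1: n=6 n_B=3 d=1(A): U_B += -1/2,  V += (1/2)(1/2)
    # t=2: n=5 n_B=3 d=1(B): U_B += 1-3/5, V += (3/5)(2/5)
    # t=3: n=4 n_B=2 d=1(A): U_B += -1/2,  V += (1/2)(1/2)
    # t=6: n=1 n_B=1 d=1(B): U_B += 0,     V += 0
    # U = -0.6, V = 0.74, chi2 = 0.36/0.74
    t = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
    e = [1, 1, 0, 1, 0, 1]
    g = ["A", "A", "A", "B", "B", "B"]
    res = logrank(t, e, g)
    assert res.observed_minus_expected == pytest.approx(-0.6)
    assert res.variance == pytest.approx(0.74)
    assert res.chi_square == pytest.approx(0.36 / 0.74)


def test_logrank_identical_groups_zero():
    t = [1.0, 2.0, 3.0] * 2
    e = [1, 0, 1] * 2
    g = ["A"] * 3 + ["B"] * 3
    assert logrank(t, e, g).chi_square == pytest.approx(0.0, abs=1e-12)


def test_logrank_relabeling_invariance(rng):
    t, e, x = _sim(rng, 60)
    g = (x > 0).astype(int)
    a = logrank(t, e, g)
    b = logrank(t, e, 1 - g)
    assert a.chi_square == pytest.approx(b.chi_square)
    assert a.chi_square >= 0


def test_logrank_all_censored_untestable():
    with pytest.raises(UntestableError):
        logrank([1.0, 2.0], [0, 0], ["A", "B"])


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test

    t, e, x = _sim(rng, 100, beta=0.4)
    g = (x > 0).astype(int)
    ours = logrank(t, e, g)
    ll = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
    assert ours.chi_square == pytest.approx(ll.test_statistic, rel=1e-9)


# --- maximally selected cutpoint ------------------------------------------

def test_cutpoint_perfect_separation():
    t = [1.0, 1.5, 2.0, 20.0, 22.0, 25.0, 30.0, 28.0, 26.0, 24.0]
    e = [1] * 10
    x = [1.0, 1.1, 1.2, 5.0, 5.1, 5.2, 5.3, 5.4, 5.5, 5.6]
    res = max_sel_cutpoint(t, e, x, minprop=0.1)
    assert 1.2 <= res.cutpoint < 5.0


def test_cutpoint_equals_brute_force_scan(rng):
    for _ in range(10):
        t, e, x = _sim(rng, 60, beta=0.4)
        res = max_sel_cutpoint(t, e, x, minprop=0.1)
        k = math.ceil(0.1 * 60)
        best = None
        for c in np.unique(x):
            lo, hi = (x <= c).sum(), (x > c).sum()
            if lo < k or hi < k:
                continue
            lr = logrank(t, e, (x > c).astype(int))
            z = abs(lr.observed_minus_expected / np.sqrt(lr.variance))
            if best is None or z > best[1] + 1e-12:
                best = (c, z)
        assert res.cutpoint == best[0]
        assert abs(res.standardized_statistic) == pytest.approx(best[1], abs=1e-9)


def test_cutpoint_minprop_constraint(rng):
    t, e, x = _sim(rng, 50)
    res = max_sel_cutpoint(t, e, x, minprop=0.2)
    assert min(res.n_low, res.n_high) >= math.ceil(0.2 * 50)
    assert res.cutpoint in x


def test_cutpoint_constant_covariate_rejected():
    with pytest.raises(NoCutpointError):
        max_sel_cutpoint([1.0, 2.0, 3.0], [1, 1, 1], [2.0, 2.0, 2.0])


def test_cutpoint_threshold_model_recovery(rng):
    """Hazard doubles above theta; recovered cutpoints concentrate near it."""
    theta = 0.0
    cuts = []
    for _ in range(25):
        x = rng.normal(size=300)
        lam = 0.02 * np.exp(np.log(2) * (x > theta))
        t = rng.exponential(1.0 / lam)
        c = rng.exponential(100, 300)
        obs, e = np.minimum(t, c), (t <= c).astype(int)
        cuts.append(max_sel_cutpoint(obs, e, x, minprop=0.1).cutpoint)
    lo, hi = np.quantile(cuts, [0.1, 0.9])
    assert lo <= theta <= hi
    assert abs(np.median(cuts) - theta) < 0.5


# --- Cox -------------------------------------------------------------------

def test_cox_constant_covariate_error():
    with pytest.raises(SingularError):
        cox_univariate([1.0, 2.0, 3.0], [1, 1, 1], [0.0, 0.0, 0.0])


def test_cox_matches_lifelines_tie_free(rng):
    from lifelines import CoxPHFitter

    t, e, x = _sim(rng, 120, beta=0.6)
    ours = cox_univariate(t, e, x)
    df = pd.DataFrame({"T": t, "E": e, "x": x})
    cph = CoxPHFitter().fit(df, "T", "E")
    assert ours.log_hazard == pytest.approx(cph.params_["x"], abs=1e-6)
    assert ours.standard_error == pytest.approx(cph.standard_errors_["x"], abs=1e-6)


def test_cox_efron_matches_lifelines_with_ties(rng):
    from lifelines import CoxPHFitter

    t, e, x = _sim(rng, 150, beta=0.5)
    t = np.ceil(t / 10)  # force heavy ties
    ours = cox_univariate(t, e, x, ties="efron")
    df = pd.DataFrame({"T": t, "E": e, "x": x})
    cph = CoxPHFitter().fit(df, "T", "E")  # lifelines uses Efron
    assert ours.log_hazard == pytest.approx(cph.params_["x"], abs=1e-5)


def test_cox_efron_breslow_identical_without_ties(rng):
    t, e, x = _sim(rng, 100, beta=0.3)
    assert len(np.unique(t)) == len(t)
    a = cox_univariate(t, e, x, ties="efron")
    b = cox_univariate(t, e, x, ties="breslow")
    assert a.log_hazard == pytest.approx(b.log_hazard, abs=1e-6)


def test_cox_score_test_equals_logrank_binary_tie_free(rng):
    t, e, x = _sim(rng, 90, beta=0.5)
    g = (x > 0).astype(float)
    cox = cox_univariate(t, e, g)
    lr = logrank(t, e, g.astype(int))
    assert cox.score_chi_square == pytest.approx(lr.chi_square, abs=1e-6)


def test_cox_perfect_separation_reports_direction():
    t = np.concatenate([np.arange(1.0, 11), np.arange(100.0, 110)])
    e = np.ones(20, int)
    x = np.concatenate([np.ones(10), np.zeros(10)])
    with pytest.raises(ConvergenceError) as err:
        cox_univariate(t, e, x)
    assert err.value.direction == 1


def test_cox_parameter_recovery_mean_bias():
    """|mean(beta_hat) - beta| < 0.05 at n=2000 over replicates."""
    for beta in [0.0, 0.7]:
        ests = []
        for rep in range(30):
            rng = np.random.default_rng(500 + rep)
            x = rng.integers(0, 2, 2000).astype(float)
            t = rng.exponential(1.0 / (0.01 * np.exp(beta * x)))
            c = rng.exponential(200, 2000)
            obs, e = np.minimum(t, c), (t <= c).astype(int)
            ests.append(cox_univariate(obs, e, x).log_hazard)
        assert abs(np.mean(ests) - beta) < 0.05


def test_cox_ci_contains_hr_and_p_in_unit_interval(rng):
    t, e, x = _sim(rng, 80, beta=0.5)
    r = cox_univariate(t, e, x)
    assert r.ci95[0] < r.hazard_ratio < r.ci95[1]
    assert 0 < r.p_value <= 1
    assert r.hazard_ratio > 0


# --- survival screen -------------------------------------------------------

def _screen_table(rng, n=60, beta=0.0):
    x = rng.lognormal(3, 0.6, n)
    z = (x - x.mean()) / x.std()
    t = rng.exponential(1.0 / (0.01 * np.exp(beta * z)))
    c = rng.exponential(120, n)
    return pd.DataFrame({
        "NK_tumoral_density": x,
        "os_months": np.minimum(t, c), "os_event": (t <= c).astype(int),
        "pfs_months": np.minimum(t, c) * 0.8, "pfs_event": (t <= c).astype(int),
    })


def test_screen_empty_variable_list():
    table = _screen_table(np.random.default_rng(0))
    out = survival_screen(table, [], compartments=["tumoral"])
    assert len(out) == 0


def test_screen_reports_errors_and_continues(rng):
    table = _screen_table(rng)
    out = survival_screen(table, ["NK", "missing_var"], compartments=["tumoral"],
                          endpoints=["os"])
    ok = out[out["variable"] == "NK"]
    bad = out[out["variable"] == "missing_var"]
    assert ok["error"].iloc[0] == "" and np.isfinite(ok["hr"].iloc[0])
    assert "missing" in bad["error"].iloc[0]


def test_screen_directional_effect_flagged(rng):
    hits = 0
    for rep in range(10):
        table = _screen_table(np.random.default_rng(900 + rep), n=80, beta=0.8)
        out = survival_screen(table, ["NK"], compartments=["tumoral"], endpoints=["os"])
        row = out.iloc[0]
        hits += bool(row["flag"] and row["hr"] > 1)
    assert hits >= 7
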