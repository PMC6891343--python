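"""Calibration fitting, inversion with uncertainty, species comparisons."""

import itertools

import numpy as np
import pytest
import scipy.stats

from leafthz import (
    ForwardModelParams,
    adjusted_r2,
    correlation_table,
    fit_calibration,
    fit_zero_intercept,
    forward_tau,
    pearson_test,
    predict_water_mass,
    tukey_letters,
)
from leafthz.calibrate import fit_line
from leafthz.errors import (
    DegenerateDesignError,
    DomainError,
    InsufficientDataError,
    NegativePredictionWarning,
    NonInvertibleCalibrationError,
)
from .conftest import make_leaf


def _ols_normal_equations(x, y):
    """Independent oracle: closed-form normal equations for slope/intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxx = n * np.sum(x * x) - np.sum(x) ** 2
    slope = (n * np.sum(x * y) - np.sum(x) * np.sum(y)) / sxx
    intercept = (np.sum(y) - slope * np.sum(x)) / n
    yhat = intercept + slope * x
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    return slope, intercept, 1 - ss_res / ss_tot


def test_fit_exact_lines(exact_line_records):
    m = fit_calibration(exact_line_records)
    assert m.C1 == pytest.approx(0.4, abs=1e-12)
    assert m.C0 == pytest.approx(0.0, abs=1e-9)
    assert m.adj_r2 == pytest.approx(1.0, abs=1e-12)
    assert m.pearson_r == pytest.approx(1.0, abs=1e-12)

    shifted = [
        make_leaf(mw=l.water_mass, la=l.leaf_area, leaf_id=l.leaf_id,
                  tau=(0.47 * l.water_mass + 2.0) / l.leaf_area)
        for l in exact_line_records
    ]
    m2 = fit_calibration(shifted)
    assert m2.C1 == pytest.approx(0.47, abs=1e-10)
    assert m2.C0 == pytest.approx(2.0, abs=1e-8)


def test_ols_matches_normal_equations_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.1, 1.9, 3.2, 3.8])
    m = fit_line(x, y)
    slope, intercept, r2 = _ols_normal_equations(x, y)
    assert m.C1 == pytest.approx(slope, abs=1e-12)
    assert m.C0 == pytest.approx(intercept, abs=1e-12)
    assert m.r2 == pytest.approx(r2, abs=1e-12)
    assert m.adj_r2 == pytest.approx(adjusted_r2(r2, 4), abs=1e-12)


def test_ols_oracle_on_random_vectors(rng):
    for _ in range(10):
        n = int(rng.integers(4, 30))
        x = rng.uniform(0, 100, n)
        y = 0.3 * x + rng.normal(0, 5, n)
        m = fit_line(x, y)
        slope, intercept, r2 = _ols_normal_equations(x, y)
        assert m.C1 == pytest.approx(slope, rel=1e-10)
        assert m.C0 == pytest.approx(intercept, rel=1e-8, abs=1e-8)
        assert m.r2 == pytest.approx(r2, rel=1e-10)


def test_fit_errors():
    with pytest.raises(InsufficientDataError):
        fit_line([1, 2], [1, 2])
    with pytest.raises(DegenerateDesignError):
        fit_line([3, 3, 3, 3], [1, 2, 3, 4])


def test_zero_intercept():
    recs = [make_leaf(mw=m, la=1.0, leaf_id=str(m), tau=0.5 * m) for m in (10, 20, 40)]
    assert fit_zero_intercept(recs) == pytest.approx(0.5, abs=1e-12)
    # hand value: sum(xy)/sum(x^2) = (1*1 + 2*1)/(1 + 4)
    recs2 = [
        make_leaf(mw=1, la=1.0, leaf_id="a", tau=1.0),
        make_leaf(mw=2, la=1.0, leaf_id="b", tau=1.0),
        make_leaf(mw=3, la=1.0, leaf_id="c", tau=1.0),
    ]
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([1.0, 1.0, 1.0])
    assert fit_zero_intercept(recs2) == pytest.approx(np.dot(x, y) / np.dot(x, x))


@pytest.mark.parametrize(
    "r2,n,expected",
    [(1.0, 10, 1.0), (0.9, 10, 1 - 0.1 * 9 / 8), (0.0, 10, -0.125)],
)
def test_adjusted_r2(r2, n, expected):
    assert adjusted_r2(r2, n) == pytest.approx(expected, abs=1e-12)


def test_adjusted_r2_domain():
    with pytest.raises(DomainError):
        adjusted_r2(0.5, 2)
    with pytest.raises(DomainError):
        adjusted_r2(1.5, 10)


def test_pearson_exact_cases():
    x = np.arange(5.0)
    r, p = pearson_test(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r, _ = pearson_test(x, -x)
    assert r == pytest.approx(-1.0)
    r, _ = pearson_test([1, 2, 3], [1, 3, 2])
    assert r == pytest.approx(0.5)


def test_pearson_matches_direct_formula(rng):
    """Oracle equivalence with the sample-correlation formula and t transform."""
    for _ in range(10):
        n = int(rng.integers(4, 25))
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        r, p = pearson_test(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        t = r_direct * np.sqrt((n - 2) / (1 - r_direct**2))
        p_direct = 2 * scipy.stats.t.sf(abs(t), n - 2)
        assert r == pytest.approx(r_direct, abs=1e-12)
        assert p == pytest.approx(p_direct, rel=1e-8)


def test_pearson_degenerate():
    with pytest.raises(DegenerateDesignError):
        pearson_test([1, 1, 1], [1, 2, 3])


def test_predict_exact_inversion(exact_line_records):
    m = fit_calibration(exact_line_records)
    res = predict_water_mass(5.0, 10.0, m)
    assert res.M_w_hat == pytest.approx(5.0 * 10.0 / 0.4, rel=1e-10)
    # exact fit: zero residuals, zero-width interval
    assert res.se == pytest.approx(0.0, abs=1e-6)
    res0 = predict_water_mass(0.0, 25.0, m)
    assert res0.M_w_hat == pytest.approx(0.0, abs=1e-7)


def test_predict_vv_mean_leaf():
    """tau = 4.754 on an 85.35 cm^2 blade at slope 0.39 is ~1040 mg of water."""
    from leafthz import CalibrationModel

    m = CalibrationModel(
        species_code="V_V", C1=0.39, C0=0.0, se_C1=0.0, se_C0=0.0,
        cov_C1_C0=0.0, r2=1.0, adj_r2=1.0, pearson_r=1.0, pearson_p=0.0,
        n=10, residual_sd=0.0,
    )
    res = predict_water_mass(4.754, 85.35, m)
    assert res.M_w_hat == pytest.approx(1040.4, abs=0.5)
    assert res.interval[0] == res.interval[1] == res.M_w_hat


def test_predict_round_trip_through_forward_model(exact_line_records):
    m = fit_calibration(exact_line_records)
    params = ForwardModelParams(K=m.C1, C0=m.C0)
    for mw, la in [(10.0, 3.0), (500.0, 40.0), (1200.0, 90.0)]:
        tau = forward_tau(mw, la, params)
        assert predict_water_mass(tau, la, m).M_w_hat == pytest.approx(mw, rel=1e-8)


def test_predict_guards_and_warnings(exact_line_records):
    m = fit_calibration(exact_line_records)
    bad = m.__class__(**{**m.__dict__, "C1": -0.1})
    with pytest.raises(NonInvertibleCalibrationError):
        predict_water_mass(5.0, 10.0, bad)
    shifted = m.__class__(**{**m.__dict__, "C0": 10.0})
    with pytest.warns(NegativePredictionWarning):
        res = predict_water_mass(0.01, 10.0, shifted)
    assert res.M_w_hat < 0


def test_predict_interval_coverage(rng):
    """~95% of noisy-calibration predictions cover the true water mass."""
    k_true, sd = 0.45, 3.0
    hits = 0
    trials = 200
    for _ in range(trials):
        x = rng.uniform(50, 500, 12)
        y = k_true * x + rng.normal(0, sd, 12)
        recs = [
            make_leaf(mw=xi, la=1.0, leaf_id=str(i), tau=yi)
            for i, (xi, yi) in enumerate(zip(x, y))
        ]
        m = fit_calibration(recs)
        mw_new = 300.0
        tau_new = k_true * mw_new + rng.normal(0, sd)
        res = predict_water_mass(tau_new, 1.0, m, confidence=0.95)
        hits += res.interval[0] <= mw_new <= res.interval[1]
    assert 0.90 <= hits / trials <= 0.99


def _tukey_kramer_p(groups, a, b):
    """Oracle: explicit Tukey–Kramer p-value via the studentized range."""
    k = len(groups)
    df = sum(len(v) for v in groups.values()) - k
    mse = sum(np.sum((np.asarray(v) - np.mean(v)) ** 2) for v in groups.values()) / df
    na, nb = len(groups[a]), len(groups[b])
    se = np.sqrt(mse / 2 * (1 / na + 1 / nb))
    q = abs(np.mean(groups[a]) - np.mean(groups[b])) / se
    return float(scipy.stats.studentized_range.sf(q, k, df))


def test_tukey_letters_basic_cases():
    same = {"a": [1.0, 1.1, 0.9, 1.0], "b": [1.0, 0.95, 1.05, 1.0]}
    assert set(tukey_letters(same).values()) == {"a"}

    apart = {"lo": [0.0, 0.01, -0.01, 0.0, 0.005], "hi": [1000.0, 1000.01, 999.99, 1000.0, 1000.005]}
    letters = tukey_letters(apart)
    assert set(letters["lo"]) & set(letters["hi"]) == set()


def test_tukey_letters_chain():
    """Only the extreme pair differs: letters a / ab / b."""
    offsets = np.array([-1.2, -0.6, 0.0, 0.6, 1.2])
    groups = {
        "high": list(10.4 + offsets),
        "mid": list(9.2 + offsets),
        "low": list(8.0 + offsets),
    }
    # confirm the intended significance pattern with the oracle
    assert _tukey_kramer_p(groups, "high", "low") <= 0.05
    assert _tukey_kramer_p(groups, "high", "mid") > 0.05
    assert _tukey_kramer_p(groups, "mid", "low") > 0.05
    letters = tukey_letters(groups)
    assert letters["high"] == "a"
    assert letters["mid"] == "ab"
    assert letters["low"] == "b"


def test_tukey_letters_agree_with_pairwise_oracle(rng):
    """Two groups share a letter iff their Tukey–Kramer p exceeds alpha."""
    for trial in range(5):
        groups = {
            f"g{i}": list(rng.normal(loc=i * 1.2, scale=1.0, size=int(rng.integers(4, 9))))
            for i in range(4)
        }
        letters = tukey_letters(groups, alpha=0.05)
        for a, b in itertools.combinations(groups, 2):
            share = bool(set(letters[a]) & set(letters[b]))
            assert share == (_tukey_kramer_p(groups, a, b) > 0.05), (trial, a, b)


def test_tukey_letters_insufficient_data():
    with pytest.raises(InsufficientDataError):
        tukey_letters({"a": [1, 2]})
    with pytest.raises(InsufficientDataError):
        tukey_letters({"a": [1, 2], "b": [3]})


def test_correlation_table_noiseless_product_row():
    recs = []
    for i, (mw, la) in enumerate([(50, 5.0), (120, 8.0), (300, 14.0), (520, 21.0)]):
        recs.append(make_leaf(mw=mw, la=la, leaf_id=str(i), tau=0.4 * mw / la))
    table = correlation_table(recs)
    product = table[table.relation == "tauLA_vs_Mw"].iloc[0]
    assert product.adj_r2 == pytest.approx(1.0, abs=1e-9)
    assert bool(product.significant)


def test_correlation_table_constant_area_identity(rng):
    """With constant L_A the tau and tau*L_A regressions share their R^2."""
    la = 12.0
    recs = []
    for i in range(8):
        mw = rng.uniform(50, 400)
        tau = 0.4 * mw / la + rng.normal(0, 0.3)
        recs.append(make_leaf(mw=mw, la=la, leaf_id=str(i), tau=tau))
    # constant L_A breaks the tau_vs_LA fit; compare the two Mw rows directly
    mw = np.array([r.water_mass for r in recs])
    tau = np.array([r.tau for r in recs])
    m1 = fit_line(mw, tau)
    m2 = fit_line(mw, tau * la)
    assert m1.adj_r2 == pytest.approx(m2.adj_r2, abs=1e-12)


def test_correlation_table_shuffled_response_rarely_significant(rng):
    """Shuffling y kills the association ~(1-alpha) of the time."""
    n_sig = 0
    trials = 100
    for _ in range(trials):
        x = rng.uniform(0, 100, 10)
        y = rng.permutation(rng.uniform(0, 100, 10))
        _, p = pearson_test(x, y)
        n_sig += p <= 0.05
    assert n_sig <= 15  # binomial(100, 0.05) upper tail
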