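import numpy as np
import pytest

from distillsurv import (
    CensoringDistribution,
    SurvivalCurveMatrix,
    antolini_c,
    brier_score,
    build_dataset,
    default_ibs_grid,
    fit_teacher,
    harrell_c,
    integrated_brier_score,
    simulate_survival,
    uno_c,
)

from conftest import random_survival_data


# ----------------------------------------------------------- brute force


def harrell_oracle(eta, time, event):
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j or event[i] != 1:
                continue
            comparable = time[i] < time[j] or (
                time[i] == time[j] and event[j] == 0
            )
            if not comparable:
                continue
            den += 1
            if eta[i] > eta[j]:
                num += 1
            elif eta[i] == eta[j]:
                num += 0.5
    return num / den


def uno_oracle(train, test, eta, tau):
    G = CensoringDistribution(train)
    num = den = 0.0
    n = test.n
    for i in range(n):
        if test.event[i] != 1 or test.time[i] >= tau:
            continue
        g = float(G.eval_left(test.time[i]))
        if g <= 0:
            continue
        w = g ** -2
        for j in range(n):
            if test.time[i] < test.time[j]:
                den += w
                if eta[i] > eta[j]:
                    num += w
                elif eta[i] == eta[j]:
                    num += 0.5 * w
    return num / den


def brier_oracle(surv, test, G, t):
    idx = np.searchsorted(surv.times, t, side="right") - 1
    total = 0.0
    kept = 0
    for i in range(test.n):
        S = surv.S[i, idx] if idx >= 0 else 1.0
        if test.time[i] <= t and test.event[i] == 1:
            g = float(G.eval_left(test.time[i]))
            if g <= 0:
                continue
            total += S**2 / g
        elif test.time[i] > t:
            g = float(G(t))
            if g <= 0:
                continue
            total += (1 - S) ** 2 / g
        kept += 1
    return total / kept


# ----------------------------------------------------------- Harrell


def test_perfect_and_tied_concordance(rng):
    t = rng.exponential(size=30) + 0.1
    e = np.ones(30, dtype=int)
    assert harrell_c(-t, t, e) == 1.0
    assert harrell_c(np.zeros(30), t, e) == 0.5


def test_harrell_matches_brute_force():
    d = random_survival_data(5, n=100, p=1, ties=True)
    eta = np.round(np.random.default_rng(5).standard_normal(d.n), 1)
    assert harrell_c(eta, d.time, d.event) == pytest.approx(
        harrell_oracle(eta, d.time, d.event), abs=1e-12
    )


def test_harrell_matches_lifelines_on_tie_free_data():
    lifelines = pytest.importorskip("lifelines")
    d = random_survival_data(6, n=80, p=1)
    eta = np.random.default_rng(6).standard_normal(d.n)
    ours = harrell_c(eta, d.time, d.event)
    ref = lifelines.utils.concordance_index(d.time, -eta, d.event)
    assert ours == pytest.approx(ref, abs=1e-12)


def test_concordance_invariances():
    d = random_survival_data(9, n=60, p=1)
    eta = np.random.default_rng(9).standard_normal(d.n)
    base = harrell_c(eta, d.time, d.event)
    # strictly monotone transform
    assert harrell_c(np.exp(eta), d.time, d.event) == pytest.approx(base, abs=1e-12)
    # row permutation
    perm = np.random.default_rng(1).permutation(d.n)
    assert harrell_c(eta[perm], d.time[perm], d.event[perm]) == pytest.approx(
        base, abs=1e-12
    )


def test_no_comparable_pairs_raises():
    with pytest.raises(ValueError, match="comparable"):
        harrell_c([1.0], [1.0], [1])


# ----------------------------------------------------------- Uno


def test_uno_reduces_to_harrell_without_censoring():
    rng = np.random.default_rng(2)
    t = rng.exponential(size=50) + 0.1
    e = np.ones(50, dtype=int)
    d = build_dataset(t, e, np.zeros((50, 1)))
    eta = rng.standard_normal(50)
    tau = float(t.max()) + 1.0
    assert uno_c(d, d, eta, tau) == pytest.approx(
        harrell_c(eta, d.time, d.event), abs=1e-12
    )


def test_uno_matches_brute_force():
    train = random_survival_data(12, n=90, p=1)
    test = random_survival_data(13, n=80, p=1)
    eta = np.random.default_rng(13).standard_normal(test.n)
    tau = float(np.quantile(test.time, 0.8))
    assert uno_c(train, test, eta, tau) == pytest.approx(
        uno_oracle(train, test, eta, tau), abs=1e-12
    )


def test_uno_close_to_scikit_survival():
    sksurv = pytest.importorskip("sksurv.metrics")
    train = random_survival_data(20, n=150, p=1)
    test = random_survival_data(21, n=120, p=1)
    eta = np.random.default_rng(21).standard_normal(test.n)
    tau = float(np.quantile(test.time[test.event == 1], 0.8))
    ours = uno_c(train, test, eta, tau)
    y_tr = np.array([(bool(e), t) for e, t in zip(train.event, train.time)],
                    dtype=[("event", bool), ("time", float)])
    y_te = np.array([(bool(e), t) for e, t in zip(test.event, test.time)],
                    dtype=[("event", bool), ("time", float)])
    ref = sksurv.concordance_index_ipcw(y_tr, y_te, eta, tau=tau)[0]
    assert ours == pytest.approx(ref, abs=0.02)


# ----------------------------------------------------------- Antolini


def _ph_surv(eta, times, H0):
    S = np.exp(-np.outer(np.exp(eta), H0))
    return SurvivalCurveMatrix(times=times, S=S)


def test_antolini_equals_harrell_under_proportional_hazards():
    d = random_survival_data(30, n=70, p=1)
    eta = np.random.default_rng(30).standard_normal(d.n)
    times = np.unique(d.time)
    H0 = np.linspace(0.05, 2.0, times.size)
    surv = _ph_surv(eta, times, H0)
    assert antolini_c(surv, d) == pytest.approx(
        harrell_c(eta, d.time, d.event), abs=1e-12
    )


def test_antolini_all_identical_curves_is_half():
    d = random_survival_data(31, n=40, p=1)
    times = np.unique(d.time)
    surv = SurvivalCurveMatrix(times=times,
                               S=np.tile(np.linspace(1, 0.2, times.size), (d.n, 1)))
    assert antolini_c(surv, d) == 0.5


def test_antolini_crossing_curves_hand_enumerated():
    # four subjects, all events at t = 1, 2, 3, 4; curves cross deliberately
    d = build_dataset([1, 2, 3, 4], [1, 1, 1, 1], np.zeros((4, 1)))
    times = np.array([1.0, 2.0, 3.0, 4.0])
    S = np.array([
        [0.9, 0.8, 0.7, 0.6],   # subject with t=1
        [0.5, 0.4, 0.3, 0.2],   # t=2
        [0.6, 0.5, 0.4, 0.3],   # t=3
        [0.95, 0.45, 0.35, 0.1] # t=4
    ])
    surv = SurvivalCurveMatrix(times=times, S=S)
    # pairs (i earlier, j later), concordant iff S_i(t_i) < S_j(t_i):
    # (1,2): S1(1)=.9 vs S2(1)=.5  -> discordant
    # (1,3): .9 vs .6              -> discordant
    # (1,4): .9 vs .95             -> concordant
    # (2,3): S2(2)=.4 vs S3(2)=.5  -> concordant
    # (2,4): .4 vs .45             -> concordant
    # (3,4): S3(3)=.4 vs S4(3)=.35 -> discordant
    assert antolini_c(surv, d) == pytest.approx(3 / 6, abs=1e-12)


# ----------------------------------------------------------- Brier / IBS


def test_brier_perfect_and_coin_flip_predictions():
    rng = np.random.default_rng(3)
    t = rng.exponential(size=40) + 0.1
    d = build_dataset(t, np.ones(40, dtype=int), np.zeros((40, 1)))
    G = CensoringDistribution(d)  # no censoring -> G == 1
    times = np.array([0.05, 0.5, 1.0])
    ones = SurvivalCurveMatrix(times=times, S=np.ones((40, 3)))
    assert brier_score(ones, d, G, 0.04) == 0.0  # nobody failed yet
    half = SurvivalCurveMatrix(times=times, S=np.full((40, 3), 0.5))
    for t0 in (0.2, 0.7, 1.4):
        assert brier_score(half, d, G, t0) == pytest.approx(0.25, abs=1e-12)
    grid = np.linspace(0.1, 1.2, 7)
    half7 = SurvivalCurveMatrix(times=grid, S=np.full((40, 7), 0.5))
    assert integrated_brier_score(half7, d, G, grid) == pytest.approx(
        0.25, abs=1e-12
    )


def test_brier_matches_triple_loop_oracle():
    train = random_survival_data(40, n=100, p=1)
    test = random_survival_data(41, n=90, p=1)
    G = CensoringDistribution(train)
    times = np.unique(test.time)
    rng = np.random.default_rng(41)
    S = np.sort(rng.uniform(size=(test.n, times.size)))[:, ::-1]
    surv = SurvivalCurveMatrix(times=times, S=S)
    for t0 in np.quantile(test.time, [0.2, 0.5, 0.8]):
        assert brier_score(surv, test, G, t0) == pytest.approx(
            brier_oracle(surv, test, G, t0), abs=1e-12
        )
    grid = default_ibs_grid(test)
    ibs = integrated_brier_score(surv, test, G, grid)
    assert 0.0 <= ibs <= 1.0


# ----------------------------------------------------------- censoring KM


def test_censoring_km_matches_lifelines():
    lifelines = pytest.importorskip("lifelines")
    d = random_survival_data(50, n=120, p=1, ties=True)
    G = CensoringDistribution(d)
    km = lifelines.KaplanMeierFitter().fit(d.time, 1 - d.event)
    probe = np.unique(d.time)
    ref = km.survival_function_at_times(probe).to_numpy()
    assert np.allclose(np.asarray(G(probe)), ref, atol=1e-12)


def test_metrics_on_fitted_model_better_than_chance():
    data, _ = simulate_survival("cox", 250, 4, [1.0, -1.0, 0.5, 0.0], seed=77)
    test, _ = simulate_survival("cox", 200, 4, [1.0, -1.0, 0.5, 0.0], seed=78)
    fit = fit_teacher(data, "cox_breslow")
    eta = fit.predict_linear(test.X)
    assert harrell_c(eta, test.time, test.event) > 0.6
    assert uno_c(data, test, eta) > 0.6
    surv = fit.predict_survival(test.X, np.unique(test.time))
    assert antolini_c(surv, test) > 0.6
    G = CensoringDistribution(data)
    grid = default_ibs_grid(test)
    assert integrated_brier_score(surv, test, G, grid) < 0.25
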