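import json

import numpy as np
import pytest

from distillsurv import (
    CVResult,
    KDSurv,
    RegularizationPathFit,
    StudentModel,
    TeacherSpec,
    fit_kd,
    harrell_c,
    kd_cross_validate,
    select_lambda,
    simulate_survival,
)


def make_cv(mean, se=None, lambdas=None):
    mean = np.asarray(mean, dtype=float)
    L = mean.shape[0]
    se = np.zeros(L) if se is None else np.asarray(se, dtype=float)
    lambdas = np.geomspace(1, 0.01, L) if lambdas is None else lambdas
    return CVResult(lambdas=lambdas, scores=mean[None, :], mean=mean, se=se,
                    selected={}, scoring_method="vvh")


def make_path(n_nonzero, lambdas=None):
    n_nonzero = np.asarray(n_nonzero)
    L = n_nonzero.shape[0]
    lambdas = np.geomspace(1, 0.01, L) if lambdas is None else lambdas
    return RegularizationPathFit(
        lambdas=lambdas, alpha=1.0, coefs=np.zeros((L, 1)),
        intercepts=np.zeros(L), n_nonzero=n_nonzero,
    )


# ------------------------------------------------------- selection rules


def test_flat_profile_all_rules_pick_sparsest():
    cv = make_cv(np.zeros(10))
    path = make_path([0, 1, 2, 3, 4, 5, 6, 7, 8, 9])
    for rule in ("min", "1se", "pcvl"):
        assert select_lambda(cv, rule, path) == 0


def test_strictly_increasing_profile_zero_se():
    cv = make_cv(np.linspace(0, 1, 8))
    path = make_path([0, 0, 1, 2, 3, 4, 5, 6])
    assert select_lambda(cv, "min", path) == 7
    assert select_lambda(cv, "1se", path) == 7


def test_pcvl_hand_computed_five_point_example():
    # mean cvl and supports chosen so the penalized profile peaks mid-path:
    # penalty per coefficient = (mean[min] - mean[null]) / N[min]
    #   = (1.0 - 0.0) / 8 = 0.125
    # profile = mean - N * 0.125 = [0, .55-.125, .8-.375, .95-.625, 1-1]
    #         = [0, 0.425, 0.425, 0.325, 0.0]  -> argmax index 1 (tie->sparser)
    cv = make_cv([0.0, 0.55, 0.80, 0.95, 1.0])
    path = make_path([0, 1, 3, 5, 8])
    assert select_lambda(cv, "min", path) == 4
    assert select_lambda(cv, "pcvl", path) == 1


def test_pcvl_returns_null_index_when_best_model_is_empty():
    cv = make_cv([0.5, 0.4, 0.3])
    path = make_path([0, 0, 2])
    assert select_lambda(cv, "pcvl", path) == 0


def test_selection_rule_ordering_on_random_profiles():
    rng = np.random.default_rng(0)
    for _ in range(50):
        mean = rng.standard_normal(30).cumsum() / 10
        se = rng.uniform(0.01, 0.2, 30)
        nz = np.sort(rng.integers(0, 15, 30))
        nz[0] = 0
        cv = make_cv(mean, se)
        path = make_path(nz)
        i_min = select_lambda(cv, "min", path)
        i_1se = select_lambda(cv, "1se", path)
        i_pcvl = select_lambda(cv, "pcvl", path)
        assert i_1se <= i_min          # lambda(1se) >= lambda(min)
        assert i_pcvl <= i_min         # lambda(pcvl) >= lambda(min)
        assert nz[i_1se] <= nz[i_min]  # N(1se) <= N(min)


# ------------------------------------------------------- cross-validation


@pytest.fixture(scope="module")
def cox_data():
    return simulate_survival("cox", 150, 10, [1.0, -1.0, 0.5], seed=42)[0]


def test_cv_score_matrix_shape_matches_protocol(cox_data):
    cv = kd_cross_validate(cox_data, "cox_breslow", k=5, repeats=5, L=25,
                           seed=0)
    assert cv.scores.shape == (25, 25)  # k * repeats rows
    assert cv.mean.shape == (25,)
    assert (cv.se >= 0).all()
    assert set(cv.selected) == {"min", "1se", "pcvl"}
    assert all(0 <= i < 25 for i in cv.selected.values())


def test_cv_determinism_and_seed_sensitivity(cox_data):
    a = kd_cross_validate(cox_data, "cox_breslow", k=3, L=15, seed=7)
    b = kd_cross_validate(cox_data, "cox_breslow", k=3, L=15, seed=7)
    c = kd_cross_validate(cox_data, "cox_breslow", k=3, L=15, seed=8)
    assert np.array_equal(a.scores, b.scores)
    assert a.selected == b.selected
    assert not np.array_equal(a.scores, c.scores)


@pytest.mark.parametrize("scoring", ["basic", "linear_predictor"])
def test_alternative_scoring_methods_run(cox_data, scoring):
    cv = kd_cross_validate(cox_data, "cox_breslow", k=3, repeats=2, L=10,
                           scoring=scoring, seed=1)
    expected_rows = 2 if scoring == "linear_predictor" else 6
    assert cv.scores.shape == (expected_rows, 10)
    assert np.isfinite(cv.scores).all()


def test_lambda_grid_shared_across_folds(cox_data):
    cv = kd_cross_validate(cox_data, "cox_breslow", k=3, L=12, seed=3)
    assert cv.lambdas.shape == (12,)
    assert np.all(np.diff(cv.lambdas) < 0)
    assert cv.path.n_nonzero[0] == 0


# ------------------------------------------------------- full pipeline


def test_student_tracks_teacher_at_path_end():
    data, _ = simulate_survival("cox", 200, 8, [1.0, -0.8, 0.5], seed=11)
    student = fit_kd(data, "cox_breslow", rule="min", k=3, L=30, seed=2)
    teacher_eta = student.teacher.predict_linear(data.X)
    cv = student.cv
    last = cv.path.L - 1
    student_eta = cv.path.predict(data.X, last)
    r = np.corrcoef(teacher_eta, student_eta)[0, 1]
    assert r >= 0.99


def test_pcvl_student_no_denser_than_min():
    sparser = 0
    for seed in range(8):
        data, _ = simulate_survival("cox", 120, 12, [1.0, -1.0], seed=100 + seed)
        cv = kd_cross_validate(data, "cox_breslow", k=3, L=30, seed=seed)
        n_min = cv.path.n_nonzero[cv.selected["min"]]
        n_pcvl = cv.path.n_nonzero[cv.selected["pcvl"]]
        sparser += int(n_pcvl <= n_min)
    assert sparser >= 7


def test_fit_kd_returns_usable_student(cox_data):
    student = fit_kd(cox_data, "cox_breslow", rule="min", k=3, L=20, seed=5)
    assert student.beta.shape == (cox_data.p,)
    assert student.n_nonzero == np.count_nonzero(student.beta)
    eta = student.predict_linear(cox_data.X)
    assert harrell_c(eta, cox_data.time, cox_data.event) > 0.5
    S = student.predict_survival(cox_data.X[:5], np.unique(cox_data.time))
    assert (np.diff(S.S, axis=1) <= 1e-12).all()
    assert "StudentModel" in student.summary()


def test_student_json_round_trip_preserves_predictions(cox_data):
    student = fit_kd(cox_data, "cox_breslow", rule="1se", k=3, L=20, seed=5)
    blob = json.dumps(student.to_dict())
    back = StudentModel.from_dict(json.loads(blob))
    X = np.random.default_rng(0).standard_normal((20, cox_data.p))
    assert np.allclose(back.predict_linear(X), student.predict_linear(X),
                       atol=1e-12)
    t = np.unique(cox_data.time)[:10]
    assert np.allclose(back.predict_survival(X, t).S,
                       student.predict_survival(X, t).S, atol=1e-12)


def test_eh_distillation_two_students_union_support():
    data, _ = simulate_survival("eh", 150, 5, [0.6, 0.0], beta2=[0.6, 0.5],
                                seed=9)
    spec = TeacherSpec(family="eh", bandwidth=0.5, tol=1e-4)
    student = fit_kd(data, spec, rule="min", k=3, L=15, seed=3)
    assert student.beta2 is not None
    union = np.count_nonzero((student.beta != 0) | (student.beta2 != 0))
    assert student.n_nonzero == union


def test_kdsurv_model_object_from_dataframe(cox_data):
    df = cox_data.to_frame()
    model = KDSurv.from_dataframe(df, teacher="cox_breslow", k=3, L=15, seed=4)
    student = model.fit(rule="min")
    assert student.feature_names == tuple(df.columns[2:])
    direct = fit_kd(cox_data, "cox_breslow", rule="min", k=3, L=15, seed=4)
    assert np.allclose(student.beta, direct.beta, atol=1e-12)


def test_unknown_rule_and_scoring_rejected(cox_data):
    with pytest.raises(ValueError, match="rule"):
        fit_kd(cox_data, "cox_breslow", rule="best")
    with pytest.raises(ValueError, match="scoring"):
        kd_cross_validate(cox_data, "cox_breslow", scoring="magic")
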