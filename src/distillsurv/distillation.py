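"""Knowledge distillation of survival teachers into sparse linear students.

The procedure has two steps.  A teacher (Cox PH, smoothed AFT/EH, or any
object emitting linear predictors for training rows) is fitted to the
training data and asked for predictions on those same rows.  Those
predictions then become the regression targets of an elastic-net student
fitted along a 100-point regularization path, which separates model
estimation (the teacher's job) from feature selection (the penalty's job).

The regularization hyperparameter is chosen by k-fold cross-validation
stratified on the event indicator, with three selection rules:

* ``min``  — the path index maximizing the mean held-out score;
* ``1se``  — the sparsest model within one standard error of the best;
* ``pcvl`` — penalized cross-validated likelihood: the gain of each model
  over the null model is taxed per active coefficient, favouring sparser
  models.

Held-out scores are teacher-family log-likelihoods of the student's
predictions; the default ``vvh`` (Verweij-van Houwelingen) variant scores
a fold as  l(eta_all; all data) - l(eta_train; training data), the
established remedy for small-fold partial-likelihood instability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import breslow_cumulative_hazard, predict_survival, \
    transformed_scale_cumulative_hazard
from .datasets import SurvivalDataset, build_dataset
from .enet import RegularizationPathFit, fit_path, lambda_path
from .likelihoods import cox_partial_loglik, default_bandwidth, eh_loglik_at_eta
from .stepfunctions import StepFunction
from .teachers import TeacherFit, fit_teacher

__all__ = [
    "TeacherSpec",
    "CVResult",
    "StudentModel",
    "KDSurv",
    "kd_cross_validate",
    "select_lambda",
    "fit_kd",
]

RULES = ("min", "1se", "pcvl")
SCORINGS = ("vvh", "basic", "linear_predictor")


@dataclass(frozen=True)
class TeacherSpec:
    """Configuration of the teacher refitted inside every CV fold."""

    family: str = "cox_breslow"
    ties: str | None = None
    bandwidth: float | None = None
    reduction: object = None     # None, int rank, variance fraction, "default"
    ridge: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500

    def fit(self, data: SurvivalDataset) -> TeacherFit:
        return fit_teacher(
            data, self.family, ties=self.ties, bandwidth=self.bandwidth,
            reduction=self.reduction, ridge=self.ridge, tol=self.tol,
            max_iter=self.max_iter,
        )


@dataclass
class CVResult:
    """Held-out score profiles along the path with the selected indices.

    ``scores`` has one row per fold x repeat (per repeat for pooled
    ``linear_predictor`` scoring) and one column per lambda; higher is
    better.  ``selected`` maps each rule to a path index.
    """

    lambdas: np.ndarray
    scores: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    selected: dict
    scoring_method: str
    teacher: TeacherFit = field(default=None, repr=False)
    path: RegularizationPathFit = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "lambda": self.lambdas,
            "mean_score": self.mean,
            "se_score": self.se,
            "n_nonzero": self.path.n_nonzero if self.path is not None else np.nan,
        })
        df.index.name = "path_index"
        return df


@dataclass
class StudentModel:
    """Distilled sparse student, ready for survival prediction and metrics.

    Inherits family semantics (and for EH the second predictor) from its
    teacher; the baseline cumulative hazard is re-estimated from the
    student's own training-set linear predictors.
    """

    family: str
    beta: np.ndarray
    intercept: float
    beta2: np.ndarray | None = None
    intercept2: float = 0.0
    lambda_index: int = 0
    lambda_value: float = float("nan")
    rule: str = "min"
    alpha: float = 0.9
    teacher: TeacherFit | None = None
    baseline: StepFunction | None = None
    cv: CVResult | None = field(default=None, repr=False)
    feature_names: tuple = ()

    @property
    def n_nonzero(self) -> int:
        support = self.beta != 0
        if self.beta2 is not None:
            support = support | (self.beta2 != 0)
        return int(support.sum())

    def predict_linear(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.family == "eh":
            return X @ self.beta2 + self.intercept2
        return X @ self.beta + self.intercept

    def predict_linear_pair(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta1 = X @ self.beta + self.intercept
        if self.family == "eh":
            return eta1, X @ self.beta2 + self.intercept2
        return eta1, eta1

    def predict_survival(self, X, times):
        return predict_survival(self, X, times)

    def summary(self) -> str:
        names = list(self.feature_names) or [
            f"x{j+1}" for j in range(self.beta.shape[0])
        ]
        lines = [
            f"StudentModel  family={self.family}  rule={self.rule}  "
            f"alpha={self.alpha:g}",
            f"selected path index {self.lambda_index} "
            f"(lambda={self.lambda_value:.4g}); {self.n_nonzero} of "
            f"{self.beta.shape[0]} features active",
        ]
        sup = self.beta != 0
        if self.beta2 is not None:
            sup = sup | (self.beta2 != 0)
        if sup.any():
            df = pd.DataFrame(
                {"coef": self.beta[sup]}, index=[names[j] for j in np.flatnonzero(sup)]
            )
            if self.beta2 is not None:
                df["coef (hazard scale)"] = self.beta2[sup]
            lines.append(df.to_string(float_format=lambda v: f"{v: .4f}"))
        else:
            lines.append("(fully sparse: intercept-only model)")
        return "\n".join(lines)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        def sparse(vec):
            idx = np.flatnonzero(vec)
            return {"p": int(vec.shape[0]), "index": idx.tolist(),
                    "value": vec[idx].tolist()}

        return {
            "family": self.family,
            "beta": sparse(self.beta),
            "intercept": float(self.intercept),
            "beta2": None if self.beta2 is None else sparse(self.beta2),
            "intercept2": float(self.intercept2),
            "lambda_index": int(self.lambda_index),
            "lambda_value": float(self.lambda_value),
            "rule": self.rule,
            "alpha": float(self.alpha),
            "baseline": None if self.baseline is None else self.baseline.to_dict(),
            "teacher": None if self.teacher is None else self.teacher.to_dict(),
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudentModel":
        def dense(s):
            v = np.zeros(s["p"])
            v[np.asarray(s["index"], dtype=int)] = s["value"]
            return v

        return cls(
            family=d["family"],
            beta=dense(d["beta"]),
            intercept=float(d["intercept"]),
            beta2=None if d.get("beta2") is None else dense(d["beta2"]),
            intercept2=float(d.get("intercept2", 0.0)),
            lambda_index=int(d["lambda_index"]),
            lambda_value=float(d["lambda_value"]),
            rule=d["rule"],
            alpha=float(d["alpha"]),
            baseline=None if d.get("baseline") is None
            else StepFunction.from_dict(d["baseline"]),
            teacher=None if d.get("teacher") is None
            else TeacherFit.from_dict(d["teacher"]),
            feature_names=tuple(d.get("feature_names", ())),
        )


# ---------------------------------------------------------------------------
# cross-validation machinery
# ---------------------------------------------------------------------------

def _stratified_folds(event, k, rng):
    """Fold labels stratified by the event indicator."""
    n = event.shape[0]
    labels = np.empty(n, dtype=int)
    for group in (np.flatnonzero(event == 1), np.flatnonzero(event == 0)):
        perm = rng.permutation(group)
        labels[perm] = np.arange(perm.size) % k
    return labels


def _teacher_targets(teacher, X):
    """Teacher predictions on training rows, as one or two target vectors."""
    if teacher.family == "eh":
        return teacher.predict_linear_pair(X)
    return (teacher.predict_linear(X),)


def _student_eta(paths, X, idx):
    """Student linear predictor(s) at path index ``idx``."""
    return tuple(p.predict(X, idx) for p in paths)


def _family_loglik(family, ties, bandwidth, etas, dataset):
    if family in ("cox_breslow", "cox_efron"):
        return cox_partial_loglik(etas[0], dataset, ties or family.split("_")[1])
    if family == "aft":
        return eh_loglik_at_eta(etas[0], etas[0], dataset, bandwidth)
    if family == "eh":
        return eh_loglik_at_eta(etas[0], etas[1], dataset, bandwidth)
    raise ValueError(f"unknown family {family!r}")


def kd_cross_validate(
    data: SurvivalDataset,
    teacher_spec: TeacherSpec | str = "cox_breslow",
    alpha: float = 0.9,
    k: int = 5,
    repeats: int = 1,
    scoring: str = "vvh",
    seed: int = 0,
    L: int = 100,
    eps: float | None = None,
) -> CVResult:
    """Cross-validated score profile of the distilled student along a
    shared lambda grid.

    The grid is computed once on the full data (teacher fitted to all
    rows) so path indices align across folds; each fold refits the teacher
    on its k-1 training folds, distills the student on those same rows and
    scores every lambda on the held-out fold.
    """
    if isinstance(teacher_spec, str):
        teacher_spec = TeacherSpec(family=teacher_spec)
    if k < 2:
        raise ValueError("k must be >= 2")
    if scoring not in SCORINGS:
        raise ValueError(f"unknown scoring {scoring!r}; choose from {SCORINGS}")
    rng = np.random.default_rng(seed)
    family = teacher_spec.family
    bw = teacher_spec.bandwidth or default_bandwidth(data.n)

    teacher_full = teacher_spec.fit(data)
    targets_full = _teacher_targets(teacher_full, data.X)
    grids = [lambda_path(data.X, y, alpha=alpha, L=L, eps=eps) for y in targets_full]
    lambdas = max(grids, key=lambda g: g[0])
    path_full = [fit_path(data.X, y, lambdas, alpha) for y in targets_full]
    full = _merge_paths(path_full, lambdas, alpha)

    rows = []
    for _ in range(repeats):
        for _attempt in range(20):
            labels = _stratified_folds(data.event, k, rng)
            ok = all(
                data.event[labels == f].sum() >= 1
                and data.event[labels != f].sum() >= 1
                for f in range(k)
            )
            if ok:
                break
        else:
            raise ValueError("could not draw folds with events in every fold")

        fold_paths = []
        for f in range(k):
            tr, te = labels != f, labels == f
            train_ds = data.subset(np.flatnonzero(tr))
            test_ds = data.subset(np.flatnonzero(te))
            teacher_f = teacher_spec.fit(train_ds)
            targets = _teacher_targets(teacher_f, train_ds.X)
            paths = [fit_path(train_ds.X, y, lambdas, alpha) for y in targets]
            s = np.empty(lambdas.shape[0])
            for l in range(lambdas.shape[0]):
                if scoring == "vvh":
                    eta_all = _student_eta(paths, data.X, l)
                    eta_tr = _student_eta(paths, train_ds.X, l)
                    s[l] = _family_loglik(family, teacher_spec.ties, bw,
                                          eta_all, data) \
                        - _family_loglik(family, teacher_spec.ties, bw,
                                         eta_tr, train_ds)
                elif scoring == "basic":
                    eta_te = _student_eta(paths, test_ds.X, l)
                    s[l] = _family_loglik(family, teacher_spec.ties, bw,
                                          eta_te, test_ds)
            if scoring == "linear_predictor":
                fold_paths.append(paths)
            else:
                rows.append(s)
        if scoring == "linear_predictor":
            s = np.empty(lambdas.shape[0])
            for l in range(lambdas.shape[0]):
                etas = [np.empty(data.n) for _ in targets_full]
                for f, paths in enumerate(fold_paths):
                    te = labels == f
                    for m, p in enumerate(paths):
                        etas[m][te] = p.predict(data.X[te], l)
                s[l] = _family_loglik(family, teacher_spec.ties, bw,
                                      tuple(etas), data)
            rows.append(s)

    scores = np.vstack(rows)
    mean = scores.mean(axis=0)
    if scores.shape[0] > 1:
        se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
    else:
        se = np.zeros_like(mean)
    cv = CVResult(
        lambdas=lambdas, scores=scores, mean=mean, se=se, selected={},
        scoring_method=scoring, teacher=teacher_full, path=full,
    )
    cv.selected = {rule: select_lambda(cv, rule, full) for rule in RULES}
    return cv


def _merge_paths(paths, lambdas, alpha):
    """Union-support view of one (cox/aft) or two (eh) student paths."""
    if len(paths) == 1:
        return paths[0]
    sup = (paths[0].coefs != 0) | (paths[1].coefs != 0)
    return RegularizationPathFit(
        lambdas=lambdas, alpha=alpha, coefs=paths[0].coefs,
        intercepts=paths[0].intercepts,
        n_nonzero=sup.sum(axis=1),
        kkt_max_violation=max(p.kkt_max_violation for p in paths),
    )


def select_lambda(cv: CVResult, rule: str, path: RegularizationPathFit) -> int:
    """Path index selected by ``min``, ``1se`` or ``pcvl``.

    Ties in the score profile always break toward sparser models (larger
    lambda, smaller index).
    """
    mean, se = cv.mean, cv.se
    i_min = int(np.argmax(mean))  # first occurrence = largest lambda
    if rule == "min":
        return i_min
    if rule == "1se":
        thresh = mean[i_min] - se[i_min]
        return int(np.flatnonzero(mean >= thresh)[0])
    if rule == "pcvl":
        N = np.asarray(path.n_nonzero, dtype=float)
        zero = np.flatnonzero(N == 0)
        i_null = int(zero[0]) if zero.size else 0
        if N[i_min] == 0:
            return i_null
        penalty = (mean[i_min] - mean[i_null]) / N[i_min]
        profile = mean - N * penalty
        return int(np.argmax(profile))
    raise ValueError(f"unknown selection rule {rule!r}; choose from {RULES}")


def fit_kd(
    data: SurvivalDataset,
    teacher_spec: TeacherSpec | str = "cox_breslow",
    alpha: float = 0.9,
    rule: str = "min",
    k: int = 5,
    repeats: int = 1,
    scoring: str = "vvh",
    seed: int = 0,
    L: int = 100,
    eps: float | None = None,
) -> StudentModel:
    """Full distillation pipeline: cross-validate, select lambda by
    ``rule``, refit teacher and student on all rows at the selected
    penalty, and re-estimate the baseline from student predictions."""
    if isinstance(teacher_spec, str):
        teacher_spec = TeacherSpec(family=teacher_spec)
    if rule not in RULES:
        raise ValueError(f"unknown selection rule {rule!r}; choose from {RULES}")
    cv = kd_cross_validate(
        data, teacher_spec, alpha=alpha, k=k, repeats=repeats,
        scoring=scoring, seed=seed, L=L, eps=eps,
    )
    idx = cv.selected[rule]
    teacher = cv.teacher
    targets = _teacher_targets(teacher, data.X)
    paths = [fit_path(data.X, y, cv.lambdas, alpha) for y in targets]
    family = teacher.family

    beta, b0 = paths[0].coefs[idx], float(paths[0].intercepts[idx])
    beta2 = inter2 = None
    if family == "eh":
        beta2, inter2 = paths[1].coefs[idx], float(paths[1].intercepts[idx])
        eta1 = data.X @ beta + b0
        eta2 = data.X @ beta2 + inter2
        baseline = transformed_scale_cumulative_hazard(data, eta1, eta2)
    elif family == "aft":
        eta = data.X @ beta + b0
        baseline = transformed_scale_cumulative_hazard(data, eta, eta)
    else:
        eta = data.X @ beta + b0
        baseline = breslow_cumulative_hazard(data, eta, teacher.ties or "breslow")
    return StudentModel(
        family=family,
        beta=beta,
        intercept=b0,
        beta2=beta2,
        intercept2=inter2 or 0.0,
        lambda_index=idx,
        lambda_value=float(cv.lambdas[idx]),
        rule=rule,
        alpha=float(alpha),
        teacher=teacher,
        baseline=baseline,
        cv=cv,
        feature_names=data.feature_names,
    )


class KDSurv:
    """Model-object wrapper over the distillation pipeline.

    Built from a :class:`SurvivalDataset` (or a DataFrame with ``time``
    and ``event`` columns via :meth:`from_dataframe`); ``fit`` runs the
    cross-validated distillation and returns a :class:`StudentModel`.
    """

    def __init__(self, data: SurvivalDataset, teacher="cox_breslow",
                 alpha: float = 0.9, k: int = 5, repeats: int = 1,
                 scoring: str = "vvh", L: int = 100, eps: float | None = None,
                 seed: int = 0, **teacher_options):
        self.data = data
        if isinstance(teacher, str):
            teacher = TeacherSpec(family=teacher, **teacher_options)
        elif teacher_options:
            raise ValueError("pass teacher options inside the TeacherSpec")
        self.teacher_spec = teacher
        self.alpha = alpha
        self.k = k
        self.repeats = repeats
        self.scoring = scoring
        self.L = L
        self.eps = eps
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "KDSurv":
        covs = [c for c in df.columns if c not in ("time", "event")]
        data = build_dataset(
            df["time"].to_numpy(), df["event"].to_numpy(),
            df[covs].to_numpy(dtype=float), feature_names=covs,
        )
        return cls(data, **kwargs)

    def fit(self, rule: str = "min") -> StudentModel:
        return fit_kd(
            self.data, self.teacher_spec, alpha=self.alpha, rule=rule,
            k=self.k, repeats=self.repeats, scoring=self.scoring,
            seed=self.seed, L=self.L, eps=self.eps,
        )
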