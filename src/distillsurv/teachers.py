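"""Teacher models: Cox PH (Breslow/Efron), smoothed-profile AFT and EH.

The interface follows the model/results idiom: a model object is built
from a :class:`~distillsurv.datasets.SurvivalDataset`, ``fit()`` maximizes
the family log-likelihood by quasi-Newton iteration with analytic
gradients, and the returned :class:`TeacherFit` carries coefficients on
the original feature scale, the attached baseline cumulative hazard,
convergence diagnostics and a ``summary()`` table.

High-dimensional data (p >= n) require either PCA reduction or a ridge
penalty on the teacher; both are supported and exactly one may be active.
Any object exposing ``family``, ``predict_linear`` (and for EH
``predict_linear_pair``) can serve as a teacher downstream — the built-in
families are not a closed list.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .baselines import breslow_cumulative_hazard, predict_survival, \
    transformed_scale_cumulative_hazard
from .datasets import SurvivalDataset
from .likelihoods import (
    aft_profile_loglik,
    cox_partial_gradient,
    cox_partial_loglik,
    default_bandwidth,
    eh_profile_loglik,
    eh_value_and_grad,
)
from .reduction import Projection, reduce_dimensions
from .stepfunctions import StepFunction

__all__ = ["TeacherFit", "CoxPHTeacher", "AFTTeacher", "EHTeacher", "fit_teacher",
           "FAMILIES"]

FAMILIES = ("cox_breslow", "cox_efron", "aft", "eh")


@dataclass
class TeacherFit:
    """Fitted teacher: coefficients, baseline hazard and diagnostics.

    ``beta`` (and for EH ``beta2``) are on the original feature scale even
    when the model was fitted on a PCA representation; ``offset`` absorbs
    the centering constant so ``predict_linear(X) = X @ beta + offset``.
    """

    family: str
    beta: np.ndarray
    offset: float = 0.0
    beta2: np.ndarray | None = None          # EH hazard-scale coefficients
    offset2: float = 0.0
    projection: Projection | None = None
    bandwidth: float | None = None
    baseline: StepFunction | None = None
    converged: bool = True
    grad_norm: float = float("nan")
    loglik: float = float("nan")
    n_obs: int = 0
    ties: str | None = None
    feature_names: tuple = ()
    _bse: np.ndarray | None = field(default=None, repr=False)
    _model: object = field(default=None, repr=False)

    # -- prediction ---------------------------------------------------
    def predict_linear(self, X) -> np.ndarray:
        """Risk-ordering linear predictor (for EH: the hazard-scale one)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.family == "eh":
            return X @ self.beta2 + self.offset2
        return X @ self.beta + self.offset

    def predict_linear_pair(self, X):
        """(time-scale, hazard-scale) linear predictors; equal for AFT."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta1 = X @ self.beta + self.offset
        if self.family == "eh":
            return eta1, X @ self.beta2 + self.offset2
        return eta1, eta1

    def predict_survival(self, X, times):
        return predict_survival(self, X, times)

    # -- uncertainty ----------------------------------------------------
    @property
    def bse(self) -> np.ndarray:
        """Naive model-based standard errors from the inverse observed
        information (finite-difference Hessian of the analytic score), on
        the scale the model was actually fitted on (reduced space when a
        projection is present).  For the smoothed AFT/EH likelihoods these
        ignore smoothing bias and are indicative only."""
        if self._bse is None and self._model is not None:
            self._bse = self._model._standard_errors(self)
        return self._bse

    def summary(self) -> str:
        names = list(self.feature_names) or [
            f"x{j+1}" for j in range(self.beta.shape[0])
        ]
        lines = [
            f"{type(self).__name__}  family={self.family}"
            + (f"  ties={self.ties}" if self.ties else "")
            + (f"  bandwidth={self.bandwidth:.4g}" if self.bandwidth else ""),
            f"n={self.n_obs}  loglik={self.loglik:.6g}  "
            f"converged={self.converged}  |grad|_inf={self.grad_norm:.3g}",
        ]
        if self.projection is not None:
            lines.append(
                f"fitted on a rank-{self.projection.rank} PCA representation "
                f"({self.projection.explained_variance_ratio.sum():.1%} variance)"
            )
        df = pd.DataFrame({"coef": self.beta}, index=names)
        if self.beta2 is not None:
            df["coef (hazard scale)"] = self.beta2
        lines.append(df.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "beta": self.beta.tolist(),
            "offset": self.offset,
            "beta2": None if self.beta2 is None else self.beta2.tolist(),
            "offset2": self.offset2,
            "projection": None if self.projection is None else self.projection.to_dict(),
            "bandwidth": self.bandwidth,
            "baseline": None if self.baseline is None else self.baseline.to_dict(),
            "converged": bool(self.converged),
            "grad_norm": float(self.grad_norm),
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "ties": self.ties,
            "feature_names": list(self.feature_names),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TeacherFit":
        return cls(
            family=d["family"],
            beta=np.asarray(d["beta"], dtype=float),
            offset=float(d["offset"]),
            beta2=None if d.get("beta2") is None else np.asarray(d["beta2"], float),
            offset2=float(d.get("offset2", 0.0)),
            projection=None if d.get("projection") is None
            else Projection.from_dict(d["projection"]),
            bandwidth=d.get("bandwidth"),
            baseline=None if d.get("baseline") is None
            else StepFunction.from_dict(d["baseline"]),
            converged=bool(d.get("converged", True)),
            grad_norm=float(d.get("grad_norm", float("nan"))),
            loglik=float(d.get("loglik", float("nan"))),
            n_obs=int(d.get("n_obs", 0)),
            ties=d.get("ties"),
            feature_names=tuple(d.get("feature_names", ())),
        )


class _BaseTeacher:
    """Shared fitting machinery for the likelihood-based teachers."""

    family: str = ""

    def __init__(self, data: SurvivalDataset, reduction=None, ridge: float = 0.0):
        self.data = data
        self.ridge = float(ridge)
        if reduction is not None and self.ridge > 0:
            raise ValueError("enable either PCA reduction or ridge, not both")
        if reduction == "default":
            reduction = None if data.p < data.n else 0.9
        if data.p >= data.n and reduction is None and self.ridge == 0.0:
            raise ValueError(
                "p >= n: enable PCA reduction (reduction=...) or a ridge "
                "penalty (ridge=...) to fit this teacher"
            )
        if reduction is not None:
            proj, Z = reduce_dimensions(data.X, reduction)
            cap = min(data.n - 1, 64)
            if not isinstance(reduction, (int, np.integer)) and proj.rank > cap:
                proj = Projection(
                    center=proj.center, scale=proj.scale,
                    loadings=proj.loadings[:, :cap],
                    explained_variance_ratio=proj.explained_variance_ratio[:cap],
                )
                Z = Z[:, :cap]
            self.projection, self._Z = proj, Z
        else:
            self.projection, self._Z = None, data.X
        # dataset whose covariates are the working design
        self._work = dataclasses.replace(data, X=self._Z, feature_names=())

    # subclasses define _n_params, _neg_loglik_and_grad(params), _finalize(...)

    def fit(self, init=None, tol: float = 1e-7, max_iter: int = 500) -> TeacherFit:
        """Maximize the family log-likelihood by BFGS with analytic
        gradients from ``init`` (default the zero vector) until the
        gradient max-norm drops below ``tol``."""
        k = self._n_params()
        x0 = np.zeros(k) if init is None else np.asarray(init, dtype=float)
        if x0.shape != (k,):
            raise ValueError(f"init must have shape ({k},)")

        def fun(params):
            f, g = self._neg_loglik_and_grad(params)
            if not np.isfinite(f):
                return 1e30, np.zeros_like(params)
            return f, g

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy line-search chatter
            res = minimize(
                fun, x0, jac=True, method="BFGS",
                options={"gtol": tol, "maxiter": max_iter, "norm": np.inf},
            )
        _, g_final = self._neg_loglik_and_grad(res.x)
        grad_norm = float(np.max(np.abs(g_final))) if g_final.size else 0.0
        converged = grad_norm < max(tol, 1e-6) or res.success
        if not converged:
            warnings.warn(
                f"{type(self).__name__} did not converge "
                f"(|grad|_inf={grad_norm:.3g})",
                UserWarning,
                stacklevel=2,
            )
        fit = self._finalize(res.x, converged, grad_norm)
        fit._model = self
        return fit

    def _standard_errors(self, fit: TeacherFit) -> np.ndarray:
        """Finite-difference observed information on the working scale."""
        x = self._params_from_fit(fit)
        k = x.shape[0]
        H = np.zeros((k, k))
        h = 1e-5
        for j in range(k):
            e = np.zeros(k)
            e[j] = h
            _, gp = self._neg_loglik_and_grad(x + e)
            _, gm = self._neg_loglik_and_grad(x - e)
            H[:, j] = (gp - gm) / (2 * h)
        H = 0.5 * (H + H.T) * self._info_scale()
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
        return se


class CoxPHTeacher(_BaseTeacher):
    """Cox proportional hazards maximum partial likelihood, with the
    Breslow (default) or Efron correction for tied event times."""

    def __init__(self, data, ties: str = "breslow", reduction=None, ridge=0.0):
        super().__init__(data, reduction=reduction, ridge=ridge)
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown tie correction {ties!r}")
        self.ties = ties
        self.family = f"cox_{ties}"

    def _n_params(self):
        return self._Z.shape[1]

    def _neg_loglik_and_grad(self, b):
        # optimized on the 1/n scale so the gradient tolerance is
        # sample-size free (matches the normalized AFT/EH objectives)
        n = self.data.n
        eta = self._Z @ b
        ll = cox_partial_loglik(eta, self._work, self.ties) / n
        g = (self._Z.T @ cox_partial_gradient(eta, self._work, self.ties)) / n
        if self.ridge:
            ll -= 0.5 * self.ridge * float(b @ b) / n
            g = g - self.ridge * b / n
        return -ll, -g

    def _info_scale(self):
        return self.data.n

    def _params_from_fit(self, fit):
        if self.projection is not None:
            # recover reduced-space params from the stored composition
            return self.projection.loadings.T @ (fit.beta * self.projection.scale)
        return fit.beta

    def _finalize(self, b, converged, grad_norm):
        eta = self._Z @ b
        if self.projection is not None:
            beta, offset = self.projection.compose_beta(b)
        else:
            beta, offset = b.copy(), 0.0
        baseline = breslow_cumulative_hazard(self.data, eta, self.ties)
        return TeacherFit(
            family=self.family,
            beta=beta,
            offset=offset,
            projection=self.projection,
            baseline=baseline,
            converged=converged,
            grad_norm=grad_norm,
            loglik=cox_partial_loglik(eta, self._work, self.ties),
            n_obs=self.data.n,
            ties=self.ties,
            feature_names=self.data.feature_names,
        )


class _SmoothedTeacher(_BaseTeacher):
    def __init__(self, data, bandwidth: float | None = None, reduction=None,
                 ridge=0.0):
        super().__init__(data, reduction=reduction, ridge=ridge)
        self.bandwidth = (
            default_bandwidth(data.n) if bandwidth is None else float(bandwidth)
        )
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")

    def _info_scale(self):
        # smoothed likelihoods are normalized by 1/n
        return self.data.n


class AFTTeacher(_SmoothedTeacher):
    """Semiparametric accelerated failure time model via the
    kernel-smoothed profile likelihood (Gaussian kernel)."""

    family = "aft"

    def _n_params(self):
        return self._Z.shape[1]

    def _neg_loglik_and_grad(self, b):
        ll, g1, g2 = eh_value_and_grad(b, b, self._work, self.bandwidth)
        g = g1 + g2
        if self.ridge:
            ll -= 0.5 * self.ridge * float(b @ b)
            g = g - self.ridge * b
        return -ll, -g

    def _params_from_fit(self, fit):
        if self.projection is not None:
            return self.projection.loadings.T @ (fit.beta * self.projection.scale)
        return fit.beta

    def _finalize(self, b, converged, grad_norm):
        eta = self._Z @ b
        if self.projection is not None:
            beta, offset = self.projection.compose_beta(b)
        else:
            beta, offset = b.copy(), 0.0
        baseline = transformed_scale_cumulative_hazard(self.data, eta, eta)
        ll, _, _ = eh_value_and_grad(b, b, self._work, self.bandwidth)
        return TeacherFit(
            family="aft",
            beta=beta,
            offset=offset,
            bandwidth=self.bandwidth,
            projection=self.projection,
            baseline=baseline,
            converged=converged,
            grad_norm=grad_norm,
            loglik=ll,
            n_obs=self.data.n,
            feature_names=self.data.feature_names,
        )


class EHTeacher(_SmoothedTeacher):
    """Semiparametric extended hazards model via the kernel-smoothed
    profile likelihood; carries a time-scale and a hazard-scale
    coefficient vector and nests Cox (beta1 = 0) and AFT (beta1 = beta2)."""

    family = "eh"

    def _n_params(self):
        return 2 * self._Z.shape[1]

    def _split(self, params):
        r = self._Z.shape[1]
        return params[:r], params[r:]

    def _neg_loglik_and_grad(self, params):
        b1, b2 = self._split(params)
        ll, g1, g2 = eh_value_and_grad(b1, b2, self._work, self.bandwidth)
        g = np.concatenate([g1, g2])
        if self.ridge:
            ll -= 0.5 * self.ridge * float(params @ params)
            g = g - self.ridge * params
        return -ll, -g

    def _params_from_fit(self, fit):
        if self.projection is not None:
            L, s = self.projection.loadings, self.projection.scale
            return np.concatenate([L.T @ (fit.beta * s), L.T @ (fit.beta2 * s)])
        return np.concatenate([fit.beta, fit.beta2])

    def _finalize(self, params, converged, grad_norm):
        b1, b2 = self._split(params)
        eta1, eta2 = self._Z @ b1, self._Z @ b2
        if self.projection is not None:
            beta1, off1 = self.projection.compose_beta(b1)
            beta2, off2 = self.projection.compose_beta(b2)
        else:
            beta1, off1, beta2, off2 = b1.copy(), 0.0, b2.copy(), 0.0
        baseline = transformed_scale_cumulative_hazard(self.data, eta1, eta2)
        ll, _, _ = eh_value_and_grad(b1, b2, self._work, self.bandwidth)
        return TeacherFit(
            family="eh",
            beta=beta1,
            offset=off1,
            beta2=beta2,
            offset2=off2,
            bandwidth=self.bandwidth,
            projection=self.projection,
            baseline=baseline,
            converged=converged,
            grad_norm=grad_norm,
            loglik=ll,
            n_obs=self.data.n,
            feature_names=self.data.feature_names,
        )


def fit_teacher(
    data: SurvivalDataset,
    family: str = "cox_breslow",
    *,
    ties: str | None = None,
    bandwidth: float | None = None,
    reduction=None,
    ridge: float = 0.0,
    tol: float = 1e-7,
    max_iter: int = 500,
    init=None,
) -> TeacherFit:
    """Fit a teacher of the requested family and attach its baseline.

    Convenience dispatcher over :class:`CoxPHTeacher`, :class:`AFTTeacher`
    and :class:`EHTeacher`.
    """
    if family in ("cox_breslow", "cox_efron"):
        model = CoxPHTeacher(
            data, ties=ties or family.split("_")[1], reduction=reduction,
            ridge=ridge,
        )
    elif family == "aft":
        model = AFTTeacher(data, bandwidth=bandwidth, reduction=reduction,
                           ridge=ridge)
    elif family == "eh":
        model = EHTeacher(data, bandwidth=bandwidth, reduction=reduction,
                          ridge=ridge)
    else:
        raise ValueError(f"unknown teacher family {family!r}; choose from {FAMILIES}")
    return model.fit(init=init, tol=tol, max_iter=max_iter)
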