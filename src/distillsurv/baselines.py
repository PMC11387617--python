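"""Baseline cumulative-hazard and conditional survival estimation.

The Cox baseline uses the Breslow estimator (or its Efron-consistent
variant after an Efron fit).  The AFT/EH baseline is a Breslow-type
estimator on the transformed time scale ``r_i = t_i * exp(eta1_i)`` with
risk weights ``exp(eta2_j - eta1_j)``; with ``eta1 = eta2 = 0`` it reduces
to Nelson-Aalen, and with ``eta1 = 0`` to the Cox Breslow baseline.

Conditional survival:
  Cox:     S(t|x) = exp(-L0(t) * exp(eta(x)))
  AFT/EH:  S(t|x) = exp(-L0(t * exp(eta1(x))) * exp(eta2(x) - eta1(x)))
with the cumulative hazard L0 evaluated right-continuously (0 before its
first knot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import SurvivalDataset, build_dataset
from .stepfunctions import StepFunction

__all__ = [
    "breslow_cumulative_hazard",
    "transformed_scale_cumulative_hazard",
    "predict_survival",
    "SurvivalCurveMatrix",
]


@dataclass(frozen=True)
class SurvivalCurveMatrix:
    """Conditional survival probabilities on a common time grid.

    ``S[i, k]`` is the predicted survival of subject i at ``times[k]``;
    entries lie in [0, 1] and each row is non-increasing.
    """

    times: np.ndarray
    S: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))
        if self.S.ndim != 2 or self.S.shape[1] != self.times.shape[0]:
            raise ValueError("S must be (n_subjects, n_times)")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.S, columns=[f"{t:g}" for t in self.times])
        df.insert(0, "subject", np.arange(self.S.shape[0]))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SurvivalCurveMatrix":
        df = pd.read_csv(path)
        times = np.asarray([float(c) for c in df.columns[1:]])
        return cls(times=times, S=df.iloc[:, 1:].to_numpy(dtype=float))


def breslow_cumulative_hazard(data: SurvivalDataset, eta, ties: str = "breslow") -> StepFunction:
    """Baseline cumulative hazard with knots at the distinct event times.

    Breslow increment at event time t:  d_t / sum_{j in R(t)} e^{eta_j}.
    Efron increment:  sum_{l=1}^{d_t} 1 / (S_R - ((l-1)/d_t) S_D)  with
    S_R, S_D the risk-set and tied-event sums of e^{eta_j}.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (data.n,):
        raise ValueError(f"eta has shape {eta.shape}, expected ({data.n},)")
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie correction {ties!r}")
    t, delta = data.time, data.event
    shift = eta.max()
    w = np.exp(eta - shift)
    rev = np.cumsum(w[::-1])[::-1]
    ev_times = t[delta == 1]
    uniq = np.unique(ev_times)
    starts = np.searchsorted(t, uniq, side="left")
    counts = np.searchsorted(ev_times, uniq, side="right") - np.searchsorted(
        ev_times, uniq, side="left"
    )
    risk = rev[starts]
    if ties == "breslow":
        inc = counts * np.exp(-shift) / risk
    else:
        inc = np.empty(len(uniq))
        for k, (s, d, r) in enumerate(zip(starts, counts, risk)):
            tied = w[s : s + d].sum()
            l = np.arange(d)
            inc[k] = float(np.sum(np.exp(-shift) / (r - (l / d) * tied)))
    return StepFunction(knots=uniq, values=np.cumsum(inc), left_value=0.0)


def transformed_scale_cumulative_hazard(data: SurvivalDataset, eta1, eta2) -> StepFunction:
    """Breslow-type baseline on the transformed time scale (AFT/EH).

    With ``r_i = t_i * exp(eta1_i)`` and risk weights
    ``v_j = exp(eta2_j - eta1_j)``:

      L0(r) = sum_{r_i <= r, delta_i = 1}  1 / sum_{j: r_j >= r_i} v_j
    """
    eta1 = np.asarray(eta1, dtype=float)
    eta2 = np.asarray(eta2, dtype=float)
    if eta1.shape != (data.n,) or eta2.shape != (data.n,):
        raise ValueError("eta1/eta2 must be aligned to canonical order")
    r = data.time * np.exp(eta1)
    diff = eta2 - eta1
    # re-canonicalize on the transformed scale (events first at tied r)
    tdata = build_dataset(r, data.event, np.column_stack([diff]))
    diff_s = tdata.X[:, 0]
    shift = diff_s.max()
    v = np.exp(diff_s - shift)
    rev = np.cumsum(v[::-1])[::-1]
    ev_times = tdata.time[tdata.event == 1]
    uniq = np.unique(ev_times)
    starts = np.searchsorted(tdata.time, uniq, side="left")
    counts = np.searchsorted(ev_times, uniq, side="right") - np.searchsorted(
        ev_times, uniq, side="left"
    )
    inc = counts * np.exp(-shift) / rev[starts]
    return StepFunction(knots=uniq, values=np.cumsum(inc), left_value=0.0)


def predict_survival(model, X_new, times) -> SurvivalCurveMatrix:
    """Conditional survival curves for new covariate rows on a time grid.

    ``model`` is any fitted object exposing ``family``, a ``baseline``
    cumulative hazard, and ``predict_linear`` (teacher results or distilled
    students).  Survival is floored at 0 and capped at 1 after
    exponentiation.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(times <= 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be positive and strictly increasing")
    baseline = getattr(model, "baseline", None)
    if baseline is None:
        raise ValueError(
            "model carries no baseline cumulative hazard; fit or attach one "
            "before predicting survival"
        )
    family = model.family
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if family in ("cox_breslow", "cox_efron"):
        eta = model.predict_linear(X_new)
        H = baseline(times)[None, :] * np.exp(eta)[:, None]
    elif family in ("aft", "eh"):
        eta1, eta2 = model.predict_linear_pair(X_new)
        r = times[None, :] * np.exp(eta1)[:, None]
        H = baseline(r) * np.exp(eta2 - eta1)[:, None]
    else:
        raise ValueError(f"unknown family {family!r}")
    S = np.clip(np.exp(-H), 0.0, 1.0)
    return SurvivalCurveMatrix(times=times, S=S)
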