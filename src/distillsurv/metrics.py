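"""Evaluation metrics for survival predictions.

Concordance comes in three flavours: Harrell's (unweighted pairwise),
Uno's (inverse-probability-of-censoring-weighted, IPCW) and Antolini's
(time-dependent, based on the predicted survival curves).  Calibration is
measured by the IPCW Brier score and its integrated version (IBS).

Tie conventions (documented because they vary across packages): tied
predictions receive 0.5 credit; pairs with equal times and two events are
incomparable; an event tied with a censoring time counts the event first
(Harrell only — Uno's estimator uses strict time ordering).
"""

from __future__ import annotations

import warnings

import numpy as np

from .baselines import SurvivalCurveMatrix
from .datasets import SurvivalDataset
from .stepfunctions import StepFunction

__all__ = [
    "CensoringDistribution",
    "harrell_c",
    "uno_c",
    "antolini_c",
    "brier_score",
    "integrated_brier_score",
    "default_ibs_grid",
]


class CensoringDistribution:
    """Kaplan-Meier estimate G(t) of the censoring survival function.

    Fitted with the roles of events and censorings swapped: the "events"
    of this product-limit estimator are the censored records of the
    reference (training) dataset.  Exposes right-continuous evaluation and
    the left limit G(t-), which IPCW weights need.
    """

    def __init__(self, data: SurvivalDataset):
        t, cens = data.time, 1 - data.event
        uniq = np.unique(t[cens == 1])
        n_at_risk = data.n - np.searchsorted(t, uniq, side="left")
        d = np.array([int(((t == u) & (cens == 1)).sum()) for u in uniq])
        factors = 1.0 - d / n_at_risk
        self.G = StepFunction(knots=uniq, values=np.cumprod(factors),
                              left_value=1.0)

    def __call__(self, t):
        return self.G(t)

    def eval_left(self, t):
        return self.G.eval_left(t)


def _check_aligned(eta, time, event):
    eta = np.asarray(eta, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).astype(int).ravel()
    if not (eta.shape == time.shape == event.shape):
        raise ValueError("eta, time and event must be aligned 1-d vectors")
    return eta, time, event


def harrell_c(eta, time, event) -> float:
    """Harrell's concordance index of a risk score (higher eta = riskier).

    Comparable pairs: (i, j) with t_i < t_j and subject i an event, plus
    t_i == t_j with i an event and j censored.  Tied scores get 0.5.
    """
    eta, time, event = _check_aligned(eta, time, event)
    ev = event == 1
    lt = time[ev, None] < time[None, :]
    tie_ec = (time[ev, None] == time[None, :]) & (event[None, :] == 0)
    # no self-pairs arise: tie_ec needs j censored while row i is an event
    comparable = lt | tie_ec
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    gt = eta[ev, None] > eta[None, :]
    eq = eta[ev, None] == eta[None, :]
    conc = (gt & comparable).sum() + 0.5 * (eq & comparable).sum()
    return float(conc / n_pairs)


def uno_c(train_data: SurvivalDataset, test_data: SurvivalDataset, eta_test,
          tau: float | None = None) -> float:
    """Uno's IPCW concordance, weighting comparable pairs by
    G(t_i-)^{-2} with G the censoring Kaplan-Meier from the training data.

    Pairs: t_i < t_j with i an event and t_i < tau (default: the largest
    test event time).  Pairs whose weight would divide by G = 0 are
    excluded with a warning.
    """
    eta, time, event = _check_aligned(eta_test, test_data.time, test_data.event)
    G = CensoringDistribution(train_data)
    if tau is None:
        tau = float(time[event == 1].max())
    ev = event == 1
    Gi = np.asarray(G.eval_left(time[ev]))
    w = np.zeros_like(Gi)
    ok = Gi > 0
    if not ok.all():
        warnings.warn(
            "censoring survival G(t-) = 0 for some event times; those pairs "
            "are excluded",
            UserWarning,
            stacklevel=2,
        )
    w[ok] = Gi[ok] ** -2
    comparable = (time[ev, None] < time[None, :]) & (time[ev] < tau)[:, None]
    gt = eta[ev, None] > eta[None, :]
    eq = eta[ev, None] == eta[None, :]
    num = float((w[:, None] * comparable * (gt + 0.5 * eq)).sum())
    den = float((w[:, None] * comparable).sum())
    if den == 0:
        raise ValueError("no comparable pairs before tau")
    return num / den


def antolini_c(surv: SurvivalCurveMatrix, test_data: SurvivalDataset) -> float:
    """Antolini's time-dependent concordance: pair (i, j) with t_i < t_j
    and i an event is concordant when S_i(t_i) < S_j(t_i); survival-curve
    ties count 0.5.  The curves are evaluated right-continuously on their
    own grid."""
    time, event = test_data.time, test_data.event
    if surv.S.shape[0] != test_data.n:
        raise ValueError("survival matrix rows must align with test subjects")
    # S_k(t_i) for all subjects k at every event subject i's time
    idx = np.searchsorted(surv.times, time, side="right") - 1
    S_at = np.where(idx[None, :] >= 0, surv.S[:, np.clip(idx, 0, None)], 1.0)
    # S_at[k, i] = S_k(t_i)
    ev = event == 1
    comparable = time[ev, None] < time[None, :]
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    rows = np.flatnonzero(ev)
    Si = S_at[rows, rows]            # S_i(t_i) for each event subject i
    Sj = S_at[:, rows].T             # Sj[a, j] = S_j(t_{i_a})
    lt = Si[:, None] < Sj
    eq = Si[:, None] == Sj
    conc = (lt & comparable).sum() + 0.5 * (eq & comparable).sum()
    return float(conc / n_pairs)


def brier_score(surv: SurvivalCurveMatrix, test_data: SurvivalDataset,
                G: CensoringDistribution, t: float) -> float:
    """IPCW Brier score at horizon t.

    BS(t) = mean_i [ S_i(t)^2 1{t_i <= t, event} / G(t_i-)
                     + (1 - S_i(t))^2 1{t_i > t} / G(t) ]
    Subjects whose weight would divide by G = 0 are dropped from the
    average at that horizon (with a warning).
    """
    time, event = test_data.time, test_data.event
    idx = np.searchsorted(surv.times, t, side="right") - 1
    S_t = surv.S[:, idx] if idx >= 0 else np.ones(test_data.n)
    died = (time <= t) & (event == 1)
    alive = time > t
    Gi = np.asarray(G.eval_left(time))
    Gt = float(G(t))
    contrib = np.zeros(test_data.n)
    keep = np.ones(test_data.n, dtype=bool)
    bad_d = died & (Gi <= 0)
    bad_a = alive & (Gt <= 0)
    if bad_d.any() or bad_a.any():
        warnings.warn(
            "zero IPCW weight at this horizon; affected subjects dropped",
            UserWarning,
            stacklevel=2,
        )
        keep &= ~(bad_d | bad_a)
    d = died & keep
    a = alive & keep
    contrib[d] = S_t[d] ** 2 / Gi[d]
    contrib[a] = (1 - S_t[a]) ** 2 / Gt
    return float(contrib[keep].sum() / keep.sum())


def integrated_brier_score(surv: SurvivalCurveMatrix,
                           test_data: SurvivalDataset,
                           G: CensoringDistribution, t_grid) -> float:
    """Trapezoidal average of the Brier score over a time grid, normalized
    by the grid span."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.shape[0] < 2:
        raise ValueError("t_grid needs at least two points")
    bs = np.array([brier_score(surv, test_data, G, t) for t in t_grid])
    return float(np.trapezoid(bs, t_grid) / (t_grid[-1] - t_grid[0]))


def default_ibs_grid(test_data: SurvivalDataset) -> np.ndarray:
    """Distinct test event times between the 5th and 95th percentile of
    test follow-up (avoids the unstable IPCW tails)."""
    lo, hi = np.percentile(test_data.time, [5, 95])
    ts = np.unique(test_data.time[test_data.event == 1])
    grid = ts[(ts >= lo) & (ts <= hi)]
    if grid.shape[0] < 2:
        grid = np.unique(test_data.time[test_data.event == 1])
    return grid
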