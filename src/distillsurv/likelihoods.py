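"""Log-likelihoods and analytic gradients for the three teacher families.

Cox proportional hazards uses the log partial likelihood with either the
Breslow or the Efron correction for tied event times.  The semiparametric
accelerated failure time (AFT) and extended hazards (EH) models use a
kernel-smoothed profile likelihood: the baseline hazard is profiled out and
the resulting density / risk-set indicator terms are replaced by Gaussian
kernel smooths, giving a differentiable objective.

The EH model has hazard ``lambda(t|x) = lambda0(t * exp(x'b1)) * exp(x'b2)``
and nests both special cases used here:

* AFT:  b1 = b2  (covariates accelerate time),
* Cox:  b1 = 0   (covariates scale the hazard).

All functions evaluate on the canonical (time-sorted) order of a
:class:`~distillsurv.datasets.SurvivalDataset` and are overflow-safe via
max-shifting / log-sum-exp.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, logsumexp

from .datasets import SurvivalDataset

__all__ = [
    "cox_partial_loglik",
    "cox_partial_gradient",
    "aft_profile_loglik",
    "eh_profile_loglik",
    "aft_loglik_at_eta",
    "eh_loglik_at_eta",
    "smoothed_gradient",
    "eh_value_and_grad",
    "default_bandwidth",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def default_bandwidth(n: int, constant: float = 1.30) -> float:
    """Default kernel bandwidth ``constant * n**(-1/5)`` for the smoothed
    AFT/EH profile likelihoods (standard one-dimensional smoothing rate)."""
    return constant * float(n) ** (-0.2)


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def _event_blocks(data: SurvivalDataset):
    """Distinct event times with their risk-set start index and tie count.

    Returns (start_indices, tie_counts); ``start[k]`` is the first canonical
    row with ``time >= event_time_k``.  Because events precede censored rows
    at tied times, the ``d`` tied events occupy rows ``start .. start+d-1``.
    """
    t, delta = data.time, data.event
    ev_times = t[delta == 1]
    uniq = np.unique(ev_times)
    starts = np.searchsorted(t, uniq, side="left")
    counts = np.searchsorted(ev_times, uniq, side="right") - np.searchsorted(
        ev_times, uniq, side="left"
    )
    return starts, counts, uniq


def _check_eta(eta, data):
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (data.n,):
        raise ValueError(
            f"eta has shape {eta.shape}, expected ({data.n},) aligned to "
            "canonical order"
        )
    return eta


def cox_partial_loglik(eta, data: SurvivalDataset, ties: str = "breslow") -> float:
    """Log partial likelihood of the Cox model at linear predictor ``eta``.

    Breslow:  sum_{i: d_i=1} eta_i - sum_t d_t * log( sum_{j in R(t)} e^{eta_j} )
    Efron:    the l-th of d_t tied events (l = 1..d_t) uses denominator
              sum_{R(t)} e^{eta_j} - ((l-1)/d_t) * sum_{D(t)} e^{eta_j}.
    """
    eta = _check_eta(eta, data)
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie correction {ties!r}")
    delta = data.event
    shift = eta.max()
    w = np.exp(eta - shift)
    rev = np.cumsum(w[::-1])[::-1]  # rev[i] = sum_{j >= i} w_j
    starts, counts, _ = _event_blocks(data)
    ll = float(eta[delta == 1].sum())
    risk = rev[starts]  # shifted risk sums at each distinct event time
    if ties == "breslow":
        ll -= float(np.sum(counts * (np.log(risk) + shift)))
    else:
        for s, d, r in zip(starts, counts, risk):
            tied = w[s : s + d].sum()
            l = np.arange(d)
            ll -= float(np.sum(np.log(r - (l / d) * tied) + shift))
    return ll


def cox_partial_gradient(eta, data: SurvivalDataset, ties: str = "breslow"):
    """Gradient of :func:`cox_partial_loglik` with respect to ``eta``.

    The beta-gradient follows by the chain rule as ``X.T @ g``.
    """
    eta = _check_eta(eta, data)
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie correction {ties!r}")
    t, delta = data.time, data.event
    shift = eta.max()
    w = np.exp(eta - shift)
    rev = np.cumsum(w[::-1])[::-1]
    starts, counts, uniq = _event_blocks(data)
    risk = rev[starts]

    # coef[k]: weight each member of R(t_k) receives from event time k
    if ties == "breslow":
        coef = counts / risk
        extra = None
    else:
        coef = np.empty(len(starts))
        extra = np.zeros(len(starts))  # correction applied to tied events
        for k, (s, d, r) in enumerate(zip(starts, counts, risk)):
            tied = w[s : s + d].sum()
            l = np.arange(d)
            denom = r - (l / d) * tied
            coef[k] = float(np.sum(1.0 / denom))
            # tied event i gets sum_l (1 - l/d)/denom_l instead of coef
            extra[k] = float(np.sum((l / d) / denom))

    # cumulative coefficient over event times with t_event <= t_i
    cum = np.concatenate([[0.0], np.cumsum(coef)])
    k_i = np.searchsorted(uniq, t, side="right")  # how many event times <= t_i
    g = delta - w * cum[k_i]
    if extra is not None:
        for s, d, e in zip(starts, counts, extra):
            g[s : s + d] += w[s : s + d] * e
    return g


# ---------------------------------------------------------------------------
# Kernel-smoothed AFT / EH profile likelihoods
# ---------------------------------------------------------------------------

def _eh_terms(e, eta_diff, delta, a):
    """Shared log-density / log-risk terms of the smoothed EH likelihood.

    e         : residuals on the log transformed-time scale, e_i = log t_i + eta1_i
    eta_diff  : eta2 - eta1 per subject (risk weights)
    Returns (logD, logR) per subject, where
      D_i = (1/(n a)) sum_j delta_j K((e_j - e_i)/a)
      R_i = (1/n)     sum_j exp(eta_diff_j) Phi((e_j - e_i)/a)
    with K the standard Gaussian density and Phi its CDF.  The full EH
    log-likelihood is (1/n) sum_i delta_i [ (eta2_i - eta1_i) + log D_i
    - log R_i ]; with eta1 = 0 the event term reduces to the Cox partial
    likelihood's eta2_i and with eta1 = eta2 it vanishes (AFT).
    """
    n = e.shape[0]
    u = (e[:, None] - e[None, :]) / a  # u[j, i] = (e_j - e_i)/a
    log_phi = -0.5 * u * u - _LOG_SQRT_2PI
    ev = delta == 1
    logD = logsumexp(log_phi[ev, :], axis=0) - np.log(n * a)
    logR = logsumexp(log_ndtr(u) + eta_diff[:, None], axis=0) - np.log(n)
    return u, log_phi, logD, logR


def eh_loglik_at_eta(eta1, eta2, data: SurvivalDataset, bandwidth: float) -> float:
    """Smoothed EH profile log-likelihood evaluated at given linear
    predictors (used both for fitting, via ``eta = X @ beta``, and for
    scoring distilled students whose predictors need not be X @ beta)."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    eta1 = _check_eta(eta1, data)
    eta2 = _check_eta(eta2, data)
    delta = data.event
    diff = eta2 - eta1
    e = np.log(data.time) + eta1
    _, _, logD, logR = _eh_terms(e, diff, delta, bandwidth)
    ev = delta == 1
    return float(np.mean(ev * (diff + logD - logR)))


def aft_loglik_at_eta(eta, data: SurvivalDataset, bandwidth: float) -> float:
    """Smoothed AFT profile log-likelihood at a linear predictor (EH with
    equal time- and hazard-scale predictors)."""
    return eh_loglik_at_eta(eta, eta, data, bandwidth)


def aft_profile_loglik(beta, data: SurvivalDataset, bandwidth: float) -> float:
    """Kernel-smoothed AFT profile log-likelihood at coefficient vector beta.

    With residuals ``e_i = log t_i + x_i'beta``, returns

    (1/n) sum_i delta_i [ log( (1/(n a)) sum_j delta_j K((e_j - e_i)/a) )
                        - log( (1/n)     sum_j Phi((e_j - e_i)/a) ) ],

    the profile likelihood of the residual hazard with its Breslow-type
    estimator kernel-smoothed (no linear event term arises for AFT: the
    hazard- and time-scale predictors coincide and their contributions
    cancel).  The j = i kernel self-term is included in the density sum,
    which keeps the likelihood finite for any finite (beta, a > 0).
    """
    beta = np.asarray(beta, dtype=float)
    eta = data.X @ beta
    return aft_loglik_at_eta(eta, data, bandwidth)


def eh_profile_loglik(beta1, beta2, data: SurvivalDataset, bandwidth: float) -> float:
    """Kernel-smoothed EH profile log-likelihood at (beta1, beta2); beta1
    acts on the time scale, beta2 on the hazard scale.

    With residuals ``e_i = log t_i + x_i'beta1``:

    (1/n) sum_i delta_i [ x_i'(beta2 - beta1)
        + log( (1/(n a)) sum_j delta_j K((e_j - e_i)/a) )
        - log( (1/n) sum_j e^{x_j'(beta2 - beta1)} Phi((e_j - e_i)/a) ) ].

    Reduces exactly to :func:`aft_profile_loglik` when beta1 == beta2, and
    for beta1 = 0 its beta2-argmax approaches the Cox partial-likelihood
    MLE as the bandwidth shrinks.
    """
    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    return eh_loglik_at_eta(data.X @ beta1, data.X @ beta2, data, bandwidth)


def eh_value_and_grad(beta1, beta2, data: SurvivalDataset, a: float):
    """Smoothed EH log-likelihood and its analytic gradient w.r.t. (beta1,
    beta2), computed in one pass (the O(n^2) kernel matrices are shared)."""
    X, delta, n = data.X, data.event, data.n
    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    eta1, eta2 = X @ beta1, X @ beta2
    e = np.log(data.time) + eta1
    diff = eta2 - eta1
    u, log_phi, logD, logR = _eh_terms(e, diff, delta, a)
    ev = delta == 1
    ll = float(np.mean(ev * (diff + logD - logR)))

    # P[j, i]: normalized kernel-density weights (event rows j only)
    P = np.zeros_like(u)
    P[ev, :] = np.exp(log_phi[ev, :] - logD[None, :] - np.log(n * a))
    # Q[j, i]: normalized risk weights; A[j, i]: density-in-risk weights
    log_ndtr_u = log_ndtr(u)
    Q = np.exp(diff[:, None] + log_ndtr_u - logR[None, :] - np.log(n))
    A = np.exp(diff[:, None] + log_phi - logR[None, :] - np.log(n))

    s1 = np.sum(P * u, axis=0)                  # sum_j P_ji u_ji
    v1 = X.T @ (P * u)                          # (p, n): sum_j P_ji u_ji x_j
    a0 = np.sum(A, axis=0)
    vA = X.T @ A
    vQ = X.T @ Q

    dlogD_db1 = (X.T * s1 - v1) / a             # (p, n) columns per subject i
    dlogR_db1 = (vA - X.T * a0) / a - vQ
    # the event term delta_i * x_i'(b2 - b1) contributes -x_i / +x_i
    g1 = (dlogD_db1[:, ev] - dlogR_db1[:, ev] - X.T[:, ev]).sum(axis=1) / n
    g2 = (X.T[:, ev] - vQ[:, ev]).sum(axis=1) / n
    return ll, g1, g2


def smoothed_gradient(family: str, params, data: SurvivalDataset, bandwidth: float):
    """Analytic gradient of the smoothed profile log-likelihood.

    family='aft': ``params`` is beta (p,), returns a p-vector.
    family='eh' : ``params`` is (beta1, beta2), returns a pair of p-vectors.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if family == "aft":
        beta = np.asarray(params, dtype=float)
        _, g1, g2 = eh_value_and_grad(beta, beta, data, bandwidth)
        return g1 + g2
    if family == "eh":
        beta1, beta2 = params
        _, g1, g2 = eh_value_and_grad(beta1, beta2, data, bandwidth)
        return g1, g2
    raise ValueError(f"unknown smoothed family {family!r}")
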