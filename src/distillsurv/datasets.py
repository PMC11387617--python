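"""Canonical container for right-censored survival data.

Every estimator in the package consumes a :class:`SurvivalDataset`, which
stores observations in ascending follow-up-time order with events preceding
censored records at tied times.  That tie rule means risk sets include
subjects censored exactly at an event time, matching the Breslow/Efron
risk-set convention used throughout.

Left truncation, interval censoring, competing risks and time-varying
covariates are out of scope: `time` is a positive follow-up time and
`event` a 0/1 indicator, nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "build_dataset", "read_survival_csv"]


class SurvivalDataError(ValueError):
    """Raised when input data violate the right-censored data contract."""


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored survival data in canonical (time-ascending) order.

    Attributes
    ----------
    time : ndarray of shape (n,)
        Strictly positive follow-up times, ascending.
    event : ndarray of shape (n,)
        Event indicators (1 = event observed, 0 = right-censored).  At tied
        times, event rows are stored before censored rows.
    X : ndarray of shape (n, p)
        Covariate matrix, rows permuted together with ``time``/``event``.
    sort_order : ndarray of shape (n,)
        Permutation such that ``time[i] == original_time[sort_order[i]]``;
        un-permuting with ``np.argsort(sort_order)`` restores user order.
    feature_names : tuple of str
        Optional column labels for ``X``.
    """

    time: np.ndarray
    event: np.ndarray
    X: np.ndarray
    sort_order: np.ndarray
    feature_names: tuple = field(default=())

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, rows) -> "SurvivalDataset":
        """Dataset restricted to ``rows`` (indices into canonical order),
        re-canonicalized."""
        rows = np.asarray(rows)
        return build_dataset(
            self.time[rows], self.event[rows], self.X[rows],
            feature_names=self.feature_names,
        )

    def to_frame(self, original_order: bool = False) -> pd.DataFrame:
        names = self.feature_names or tuple(f"x{j+1}" for j in range(self.p))
        t, e, X = self.time, self.event, self.X
        if original_order:
            inv = np.argsort(self.sort_order)
            t, e, X = t[inv], e[inv], X[inv]
        df = pd.DataFrame({"time": t, "event": e.astype(int)})
        for j, name in enumerate(names):
            df[name] = X[:, j]
        return df


def build_dataset(time, event, X, feature_names=None) -> SurvivalDataset:
    """Validate and canonically sort right-censored survival data.

    Sorting is by ascending time; among tied times event rows precede
    censored rows.  Idempotent on already-canonical data, and the original
    row order is recoverable through ``sort_order``.

    Raises
    ------
    SurvivalDataError
        On non-positive/non-finite times (names the offending row),
        non-binary event indicators, shape mismatches, or zero events.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and time.shape[0] != 1 and X.shape[1] == time.shape[0]:
        X = X.T
    n = time.shape[0]
    if time.ndim != 1 or event.shape != (n,) or X.shape[0] != n:
        raise SurvivalDataError(
            f"shape mismatch: time {time.shape}, event {event.shape}, X {X.shape}"
        )
    bad = ~np.isfinite(time) | (time <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SurvivalDataError(
            f"time must be strictly positive and finite; offending row {row} "
            f"(value {time[row]!r})"
        )
    ev = np.asarray(event, dtype=float)
    if not np.isin(ev, (0.0, 1.0)).all():
        raise SurvivalDataError("event indicators must be 0 or 1")
    event = ev.astype(np.int64)
    if not np.isfinite(X).all():
        raise SurvivalDataError("covariate matrix X contains non-finite values")
    if event.sum() < 1:
        raise SurvivalDataError(
            "no events: at least one observed event is required"
        )
    # events (event=1) before censored at tied times -> sort on (time, -event)
    order = np.lexsort((-event, time))
    names = tuple(feature_names) if feature_names is not None else ()
    return SurvivalDataset(
        time=time[order],
        event=event[order],
        X=np.ascontiguousarray(X[order]),
        sort_order=order,
        feature_names=names,
    )


def read_survival_csv(path, delimiter: str | None = None) -> SurvivalDataset:
    """Read a survival dataset from CSV/TSV.

    Requires a header with columns ``time`` and ``event``; every remaining
    column is treated as a numeric covariate.  The delimiter is inferred
    from the extension (``.tsv``/``.tab`` -> tab) unless given explicitly.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter)
    for col in ("time", "event"):
        if col not in df.columns:
            raise SurvivalDataError(f"missing required column {col!r} in {path}")
    covs = [c for c in df.columns if c not in ("time", "event")]
    X = df[covs].to_numpy(dtype=float) if covs else np.empty((len(df), 0))
    return build_dataset(
        df["time"].to_numpy(), df["event"].to_numpy(), X, feature_names=covs
    )
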