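"""Right-continuous step functions for cumulative hazards and survival curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StepFunction"]


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous piecewise-constant function.

    ``f(t) = values[k]`` for the largest ``k`` with ``knots[k] <= t`` and
    ``f(t) = left_value`` for ``t < knots[0]``.  Cumulative hazards use
    ``left_value = 0`` with non-decreasing values; survival curves use
    ``left_value = 1`` with non-increasing values in [0, 1].
    """

    knots: np.ndarray
    values: np.ndarray
    left_value: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "knots", np.asarray(self.knots, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.knots.shape != self.values.shape or self.knots.ndim != 1:
            raise ValueError("knots and values must be 1-d of equal length")
        if self.knots.size and np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right") - 1
        out = np.where(
            idx >= 0,
            self.values[np.clip(idx, 0, None)] if self.values.size else self.left_value,
            self.left_value,
        )
        return out if out.ndim else float(out)

    def eval_left(self, t):
        """Left limit f(t-): the value just before t."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="left") - 1
        out = np.where(
            idx >= 0,
            self.values[np.clip(idx, 0, None)] if self.values.size else self.left_value,
            self.left_value,
        )
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "knots": self.knots.tolist(),
            "values": self.values.tolist(),
            "left_value": float(self.left_value),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StepFunction":
        return cls(np.asarray(d["knots"]), np.asarray(d["values"]),
                   float(d.get("left_value", 0.0)))
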