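"""Computed ABC analysis: data-driven partition of positive items into sets A, B, C.

ABC analysis divides a set of non-negative item values into a most-profitable
subset "A", an intermediate subset "B" and a trivial subset "C" using only the
shape of the cumulative yield-vs-effort curve (the Lorenz-type curve obtained
after sorting items in descending order).  Two limits are computed from the
empirical curve:

* the A/B limit is the curve point closest (Euclidean) to the ideal point
  (0, 1) — "minimum effort, maximum yield" (the Pareto point);
* the B/C limit is placed just before the first item whose marginal yield
  falls below the uniform rate 1/n (the break-even point): items beyond it
  contribute less than an average item would.

The curve is evaluated on the observed points without interpolation, which
makes the partition deterministic and checkable by exhaustive search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ABCResult", "abc_curve", "abc_partition"]


@dataclass(frozen=True)
class ABCResult:
    """Outcome of a computed ABC analysis.

    Attributes
    ----------
    order : item indices into the input vector, sorted by descending value
        (ties broken by original position).
    effort, yield_ : curve coordinates; ``effort[i] = i/n`` and ``yield_[i]``
        is the cumulative value share of the top ``i`` items, with the origin
        (0, 0) included at position 0.
    limit_ab, limit_bc : 1-based item counts; set A holds the top ``limit_ab``
        items, set B the next ``limit_bc - limit_ab``.
    a, b, c : original-vector indices of each set's members.
    """

    order: np.ndarray
    effort: np.ndarray
    yield_: np.ndarray
    limit_ab: int
    limit_bc: int
    a: np.ndarray = field(repr=False)
    b: np.ndarray = field(repr=False)
    c: np.ndarray = field(repr=False)

    def set_labels(self) -> np.ndarray:
        """Per-item labels 'A'/'B'/'C' aligned with the input vector."""
        n = len(self.order)
        labels = np.empty(n, dtype="U1")
        labels[self.a] = "A"
        labels[self.b] = "B"
        labels[self.c] = "C"
        return labels

    def to_frame(self, names=None) -> pd.DataFrame:
        """Tabulate items in descending-value order with their set label."""
        labels = self.set_labels()
        idx = self.order
        frame = pd.DataFrame(
            {
                "item": idx if names is None else np.asarray(names)[idx],
                "effort": self.effort[1:],
                "cum_yield": self.yield_[1:],
                "set": labels[idx],
            }
        )
        return frame


def _validated(values) -> np.ndarray:
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size == 0:
        raise ValueError("ABC analysis needs a one-dimensional, non-empty vector")
    if np.any(~np.isfinite(vals)) or np.any(vals < 0):
        raise ValueError("ABC analysis requires finite, non-negative values")
    if not np.any(vals > 0):
        raise ValueError("ABC analysis requires at least one positive value")
    return vals


def abc_curve(values) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative yield-vs-effort curve of a value vector.

    Returns ``(order, effort, yield)`` where items are sorted descending
    (stable), ``effort[i] = i/n`` and ``yield[i]`` is the value share of the
    top ``i`` items.  Both coordinate arrays start at the origin (0, 0).
    """
    vals = _validated(values)
    n = vals.size
    order = np.argsort(-vals, kind="stable")
    cum = np.concatenate([[0.0], np.cumsum(vals[order])]) / vals.sum()
    effort = np.arange(n + 1) / n
    return order, effort, cum


def abc_partition(values) -> ABCResult:
    """Partition non-negative item values into ABC sets from their curve."""
    order, effort, cum = abc_curve(values)
    n = order.size

    # Pareto point: observed curve point nearest to the ideal (0, 1);
    # evaluated over item counts 1..n so A is never empty.  Ties (within
    # round-off of the cumulative sums) break toward the smaller set.
    d2 = effort[1:] ** 2 + (1.0 - cum[1:]) ** 2
    limit_ab = int(np.nonzero(d2 <= d2.min() + 1e-9)[0][0]) + 1

    # Break-even: first item whose marginal yield falls below the uniform
    # rate 1/n; everything from it onward is set C.  The relative tolerance
    # keeps exactly-uniform marginals (cumsum round-off) out of C.
    marginal = np.diff(cum) * n
    below = np.nonzero(marginal < 1.0 - 1e-9)[0]
    limit_bc = int(below[0]) if below.size else n
    if limit_bc < limit_ab:  # keep the A/B/C value ordering intact
        limit_bc = limit_ab

    return ABCResult(
        order=order,
        effort=effort,
        yield_=cum,
        limit_ab=limit_ab,
        limit_bc=limit_bc,
        a=order[:limit_ab],
        b=order[limit_ab:limit_bc],
        c=order[limit_bc:],
    )
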