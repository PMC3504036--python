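"""Recover mutation positions from observed dual-channel band sizes.

The physical constraint is additivity: a cleavage at forward-strand position
``p`` of an ``L``-bp product leaves an ``p``-bp fragment in the 700 channel
and an ``L - p``-bp fragment in the 800 channel.  :func:`pair_bands` inverts
this by an exact maximum-cardinality, minimum-deviation matching of the two
channels, with a fully deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .exceptions import ValidationError

_BIG = 10**9


@dataclass
class CallResult:
    """Outcome of pairing one lane's band sizes."""

    called_positions: list[tuple[int, int, int]]  # (position_p, size_700, size_800)
    unpaired_700: list[int]
    unpaired_800: list[int]
    amplicon_length_L: int
    full_length_700: list[int] = field(default_factory=list)
    full_length_800: list[int] = field(default_factory=list)

    @property
    def positions(self) -> list[int]:
        return [p for p, _, _ in self.called_positions]


def _max_pairing_value(costs: np.ndarray) -> tuple[int, int]:
    """(cardinality, total deviation) of the optimal pairing for a cost matrix."""
    if costs.size == 0:
        return 0, 0
    n7, n8 = costs.shape
    k = min(n7, n8)
    rows, cols = linear_sum_assignment(costs)
    chosen = costs[rows, cols]
    valid = chosen < _BIG
    return int(valid.sum()), int(chosen[valid].sum())


def pair_bands(
    sizes_700: Iterable[int],
    sizes_800: Iterable[int],
    L: int,
    tol: int = 1,
) -> CallResult:
    """Pair 700- and 800-channel bands so each pair sums to ``L`` within ``tol``.

    Maximum-cardinality pairing; among those, minimal total ``|sum - L|``;
    remaining ties resolved by walking the 700 sizes in ascending order and
    giving each the least-deviating (then smallest) 800 partner compatible
    with global optimality.  Full-length bands are recognized and excluded.
    Leftovers are reported, never dropped.
    """
    if L <= 0:
        raise ValidationError("product length must be positive")
    if tol < 0:
        raise ValidationError("tolerance must be >= 0")
    s700 = sorted(int(s) for s in sizes_700)
    s800 = sorted(int(s) for s in sizes_800)
    for s in s700 + s800:
        if s < 0:
            raise ValidationError(f"negative band size {s}")
        if s > L:
            raise ValidationError(f"band size {s} exceeds product length {L}")

    full_700 = [s for s in s700 if abs(s - L) <= tol]
    full_800 = [s for s in s800 if abs(s - L) <= tol]
    s700 = [s for s in s700 if abs(s - L) > tol]
    s800 = [s for s in s800 if abs(s - L) > tol]

    costs = np.full((len(s700), len(s800)), _BIG, dtype=np.int64)
    for i, a in enumerate(s700):
        for j, b in enumerate(s800):
            dev = abs(a + b - L)
            if dev <= tol:
                costs[i, j] = dev
    best_card, best_dev = _max_pairing_value(costs)

    # Deterministic construction: smallest 700 size first, least-deviating
    # (then smallest) 800 partner, each choice checked against optimality.
    pairs: list[tuple[int, int, int]] = []
    unpaired_700: list[int] = []
    remaining = list(range(len(s800)))
    card, dev = best_card, best_dev
    for i, a in enumerate(s700):
        choice = None
        options = sorted(
            (abs(a + s800[j] - L), s800[j], j) for j in remaining
            if abs(a + s800[j] - L) <= tol
        )
        for d, b, j in options:
            rest = [x for x in remaining if x != j]
            sub = costs[np.ix_(range(i + 1, len(s700)), rest)]
            c, v = _max_pairing_value(sub)
            if c + 1 == card and v + d == dev:
                choice = (d, b, j)
                break
        if choice is None:
            # pairing this band cannot stay optimal: leave it unpaired
            sub = costs[np.ix_(range(i + 1, len(s700)), remaining)]
            c, v = _max_pairing_value(sub)
            assert c == card and v == dev, "optimal completion lost"
            unpaired_700.append(a)
        else:
            d, b, j = choice
            pairs.append((a, a, b))
            remaining.remove(j)
            card -= 1
            dev -= d
    unpaired_800 = [s800[j] for j in remaining]
    pairs.sort()
    return CallResult(
        called_positions=pairs,
        unpaired_700=unpaired_700,
        unpaired_800=sorted(unpaired_800),
        amplicon_length_L=L,
        full_length_700=full_700,
        full_length_800=full_800,
    )


def matrix_to_positions(
    presence: pd.DataFrame,
    position_labels: Sequence[int] | None = None,
) -> dict[str, set[int]]:
    """Per-sample position sets from a sample x position presence grid.

    ``presence`` is indexed by sample with one column per labelled position;
    truthy cells ("+", 1, True) mark an intense band.  ``position_labels``
    overrides the column labels and must be strictly increasing.
    """
    if position_labels is None:
        position_labels = [int(c) for c in presence.columns]
    else:
        position_labels = [int(p) for p in position_labels]
        if len(position_labels) != presence.shape[1]:
            raise ValidationError("label count disagrees with grid width")
    if any(b <= a for a, b in zip(position_labels, position_labels[1:])):
        raise ValidationError("position labels must be strictly increasing")
    grid = presence.map(lambda v: str(v).strip() in {"+", "1", "True"})
    return {
        str(sample): {p for p, flag in zip(position_labels, row) if flag}
        for sample, row in zip(presence.index, grid.to_numpy())
    }


def distinct_positions(per_sample: Mapping[str, set[int]]) -> set[int]:
    """Union of all called positions across samples."""
    out: set[int] = set()
    for s in per_sample.values():
        out |= s
    return out
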