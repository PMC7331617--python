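"""Quantitative bipartite networks and the indices computed from them.

A pollinator-by-plant interaction matrix whose cells are visit counts (or
standardized, real-valued visit weights) is the object every network metric
consumes.  Two families of indices are provided:

* ``h2prime`` -- network-level specialization H2', the deviation of the
  two-dimensional Shannon entropy of the interaction matrix from its
  maximum under fixed marginal totals, scaled by the achievable entropy
  range.  0 means interactions are distributed exactly in proportion to
  partner abundances (no specialization); 1 means every pollinator uses an
  exclusive set of plants (perfect specialization).

* ``muller_pac`` -- Muller's potential-apparent-competition index, a
  row-stochastic matrix ``d`` over pollinator taxa where ``d[i, j]``
  combines taxon *i*'s dietary reliance on each plant with taxon *j*'s
  share of the visits that plant receives; it quantifies the potential of
  *j* to influence *i* through their shared diet.  The diagonal is the
  intraspecific (conspecific) component, the off-diagonal entries feed the
  interspecific competition index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuantNetwork",
    "EntropyBounds",
    "PACMatrix",
    "shannon_H2",
    "entropy_bounds",
    "h2prime",
    "muller_pac",
    "intraspecific_index",
    "interspecific_index",
    "focal_species_filter",
]

Mode = Literal["continuous", "integer", "auto"]

_EPS = 1e-12


@dataclass(frozen=True)
class QuantNetwork:
    """Labeled pollinator x plant interaction matrix with non-negative weights."""

    matrix: pd.DataFrame  # rows = pollinators, columns = plants

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy(dtype=float)
        if vals.size and (vals < 0).any():
            raise ValueError("interaction weights must be non-negative")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        weights: np.ndarray | Sequence[Sequence[float]],
        pollinators: Sequence[str],
        plants: Sequence[str],
    ) -> "QuantNetwork":
        return cls(pd.DataFrame(np.asarray(weights, dtype=float),
                                index=list(pollinators), columns=list(plants)))

    @classmethod
    def empty(cls) -> "QuantNetwork":
        """Sentinel for a patch/day with no recorded visits."""
        return cls(pd.DataFrame(np.zeros((0, 0))))

    # -- basic views -------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.matrix.size == 0 or float(self.matrix.to_numpy().sum()) == 0.0

    @property
    def pollinators(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def plants(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def total(self) -> float:
        return float(self.matrix.to_numpy().sum())

    @property
    def is_integer(self) -> bool:
        vals = self.matrix.to_numpy(dtype=float)
        return bool(np.allclose(vals, np.round(vals), atol=1e-9))

    def drop_empty_margins(self) -> "QuantNetwork":
        """Remove all-zero rows and columns (taxa without interactions)."""
        m = self.matrix
        m = m.loc[m.sum(axis=1) > 0, m.sum(axis=0) > 0]
        return QuantNetwork(m)

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    # -- serialization -----------------------------------------------------
    def to_csv(self, path) -> None:
        self.matrix.to_csv(path, index_label="pollinator")

    @classmethod
    def read_csv(cls, path) -> "QuantNetwork":
        return cls(pd.read_csv(path, index_col="pollinator"))


@dataclass(frozen=True)
class EntropyBounds:
    """Shannon entropy of a table plus its extrema under fixed margins (nats)."""

    H2: float
    H2max: float
    H2min: float
    mode: str

    def __post_init__(self) -> None:
        if not (self.H2min - 1e-9 <= self.H2 <= self.H2max + 1e-9):
            raise ValueError(
                f"entropy bounds violated: {self.H2min} <= {self.H2} <= {self.H2max}"
            )


@dataclass(frozen=True)
class PACMatrix:
    """Row-stochastic potential-apparent-competition matrix over pollinators."""

    d: pd.DataFrame

    @property
    def taxa(self) -> list[str]:
        return list(self.d.index)


def _table_entropy(table: np.ndarray) -> float:
    """Shannon entropy (nats) of table cells as proportions; 0 ln 0 = 0."""
    total = table.sum()
    if total <= 0:
        return 0.0
    p = table[table > 0] / total
    return float(-np.sum(p * np.log(p)))


def shannon_H2(net: QuantNetwork) -> float:
    """Two-dimensional Shannon entropy of the interaction matrix, in nats.

    Returns NaN for an empty network (undefined-metric sentinel).
    """
    if net.is_empty:
        return math.nan
    return _table_entropy(net.values())


def _greedy_min_entropy_table(row_tot: np.ndarray, col_tot: np.ndarray) -> np.ndarray:
    """Pack the margins as unevenly as possible (heuristic minimum entropy).

    Repeatedly assign min(remaining row, remaining col) to the (row, col)
    pair with the largest product of remaining totals.  Ties break on the
    larger remaining row total, then larger remaining column total, then
    index order, so the result is platform-stable.
    """
    r = row_tot.astype(float).copy()
    c = col_tot.astype(float).copy()
    table = np.zeros((len(r), len(c)))
    while True:
        prod = np.outer(r, c)
        top = prod.max()
        if top <= _EPS:
            break
        ii, jj = np.nonzero(prod >= top - _EPS)
        # tie-break: larger remaining row total, larger remaining col total, index order
        keys = np.lexsort((jj, ii, -c[jj], -r[ii]))
        i, j = int(ii[keys[0]]), int(jj[keys[0]])
        amount = min(r[i], c[j])
        table[i, j] += amount
        r[i] -= amount
        c[j] -= amount
    return table


def _integer_outer_table(row_tot: np.ndarray, col_tot: np.ndarray) -> np.ndarray:
    """Integer table with the given margins, closest to the outer product.

    Largest-remainder apportionment of the continuous outer-product table,
    followed by marginal repair: rows are fixed by moving units within a
    column (leaving column sums intact), then columns by moving units
    within a row (leaving the now-correct row sums intact).
    """
    r = row_tot.astype(int)
    c = col_tot.astype(int)
    m = int(r.sum())
    expected = np.outer(r, c) / m
    table = np.floor(expected).astype(int)
    frac = expected - table
    deficit = m - int(table.sum())
    if deficit > 0:
        order = np.argsort(-frac, axis=None, kind="stable")
        for flat in order[:deficit]:
            table[np.unravel_index(flat, table.shape)] += 1

    def _repair(tab: np.ndarray, targets: np.ndarray, axis: int) -> None:
        # move units between over- and under-full lines, within the
        # perpendicular line so the other margin is untouched
        sums = tab.sum(axis=1 - axis)
        while True:
            over = np.flatnonzero(sums > targets)
            under = np.flatnonzero(sums < targets)
            if len(over) == 0:
                break
            i_over, i_under = int(over[0]), int(under[0])
            line_over = tab[i_over, :] if axis == 0 else tab[:, i_over]
            exp_over = expected[i_over, :] if axis == 0 else expected[:, i_over]
            # donate from the cell furthest above its expected value
            surplus = np.where(line_over > 0, line_over - exp_over, -np.inf)
            j = int(np.argmax(surplus))
            if axis == 0:
                tab[i_over, j] -= 1
                tab[i_under, j] += 1
            else:
                tab[j, i_over] -= 1
                tab[j, i_under] += 1
            sums[i_over] -= 1
            sums[i_under] += 1

    _repair(table, r, axis=0)
    _repair(table, c, axis=1)
    return table


def entropy_bounds(net: QuantNetwork, mode: Mode = "auto") -> EntropyBounds:
    """Entropy of the network with its max/min achievable under fixed margins.

    ``continuous`` mode treats margins as real masses: the maximum-entropy
    table is the outer product of the marginal proportions (so
    H2max = H(rows) + H(cols)) and the minimum comes from the greedy
    marginal-packing heuristic.  ``integer`` mode restricts both extrema to
    integer tables (unit-respecting greedy packing; largest-remainder
    apportionment of the outer product with marginal repair).  ``auto``
    picks integer when every weight is a whole number.
    """
    if net.is_empty:
        raise ValueError("entropy bounds undefined for an empty network")
    if mode == "auto":
        mode = "integer" if net.is_integer else "continuous"
    vals = net.values()
    if mode == "integer" and not net.is_integer:
        raise ValueError("integer mode requested for a non-integer matrix")

    H2 = _table_entropy(vals)
    # the extrema depend only on the marginal totals; sorting them descending
    # canonicalizes the heuristics so permuting rows/columns cannot change
    # the bounds through tie-breaking
    row_tot = np.sort(vals.sum(axis=1))[::-1]
    col_tot = np.sort(vals.sum(axis=0))[::-1]

    if mode == "continuous":
        H2max = _table_entropy(row_tot) + _table_entropy(col_tot)
        H2min = _table_entropy(_greedy_min_entropy_table(row_tot, col_tot))
    else:
        r = np.round(row_tot).astype(int)
        c = np.round(col_tot).astype(int)
        H2max = _table_entropy(_integer_outer_table(r, c).astype(float))
        H2min = _table_entropy(_greedy_min_entropy_table(r.astype(float), c.astype(float)))
    # numerical guard: observed entropy can exceed the heuristic max by FP noise
    H2max = max(H2max, H2)
    H2min = min(H2min, H2)
    return EntropyBounds(H2=H2, H2max=H2max, H2min=H2min, mode=mode)


def h2prime(net: QuantNetwork, mode: Mode = "auto", degenerate_eps: float = 1e-9) -> float:
    """Network-level specialization H2' = (H2max - H2) / (H2max - H2min).

    Ranges from 0 (interactions proportional to partner abundances) to 1
    (perfect reciprocal specialization).  Networks with fewer than two
    pollinators or two plants carrying interactions return NaN and are
    meant to be excluded from downstream models; networks whose entropy
    range collapses (H2max ~ H2min) return 0.
    """
    if net.is_empty:
        return math.nan
    net = net.drop_empty_margins()
    if len(net.pollinators) < 2 or len(net.plants) < 2:
        return math.nan
    b = entropy_bounds(net, mode=mode)
    span = b.H2max - b.H2min
    if span < degenerate_eps:
        return 0.0
    return (b.H2max - b.H2) / span


def muller_pac(net: QuantNetwork) -> PACMatrix:
    """Muller's potential-apparent-competition matrix.

    ``d[i, j] = sum_k (a[i, k] / A_i) * (a[j, k] / C_k)`` where ``A_i`` is
    pollinator *i*'s total visits and ``C_k`` plant *k*'s total visits:
    taxon *i*'s reliance on plant *k* times taxon *j*'s share of that
    plant's visitation.  Rows sum to one; taxa with no interactions are
    excluded.
    """
    if net.is_empty:
        raise ValueError("PAC undefined for an empty network")
    net = net.drop_empty_margins()
    a = net.values()
    reliance = a / a.sum(axis=1, keepdims=True)          # a_ik / A_i
    share = a / a.sum(axis=0, keepdims=True)             # a_jk / C_k
    d = reliance @ share.T
    return PACMatrix(pd.DataFrame(d, index=net.pollinators, columns=net.pollinators))


def intraspecific_index(pac: PACMatrix, focal: str) -> float:
    """Potential of a species to influence conspecifics via shared plants: d[f, f].

    Returns NaN when the focal taxon is absent from the network.
    """
    if focal not in pac.d.index:
        return math.nan
    return float(pac.d.loc[focal, focal])


def interspecific_index(
    pac: PACMatrix, focal: str, aggregation: str = "mean", direction: str = "on_others"
) -> float:
    """Potential of a focal species to influence other bumblebees via shared plants.

    ``direction='on_others'`` aggregates d[i, focal] over recipients i != focal
    (the focal's influence on each other taxon); ``'from_others'`` aggregates
    d[focal, i] instead.  ``aggregation`` is one of mean / sum / max.
    Returns NaN when the focal taxon is absent or is the only taxon.
    """
    if focal not in pac.d.index or len(pac.taxa) < 2:
        return math.nan
    if direction == "on_others":
        others = pac.d.loc[pac.d.index != focal, focal]
    elif direction == "from_others":
        others = pac.d.loc[focal, pac.d.columns != focal]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    agg = {"mean": np.mean, "sum": np.sum, "max": np.max}.get(aggregation)
    if agg is None:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return float(agg(others.to_numpy()))


def focal_species_filter(
    networks: dict[str, QuantNetwork], threshold: float = 0.5
) -> list[str]:
    """Pollinator taxa present in at least ``threshold`` of the patches.

    Presence means at least one interaction in that patch's network.  A
    taxon is retained when it occurs in >= ceil(threshold * n_patches)
    patches; the result is sorted by decreasing occurrence then name.
    """
    if not networks:
        raise ValueError("no networks supplied")
    n_patches = len(networks)
    counts: dict[str, int] = {}
    for net in networks.values():
        if net.is_empty:
            continue
        for taxon in net.drop_empty_margins().pollinators:
            counts[taxon] = counts.get(taxon, 0) + 1
    needed = math.ceil(threshold * n_patches)
    kept = [t for t, c in counts.items() if c >= needed]
    return sorted(kept, key=lambda t: (-counts[t], t))
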