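"""Efficiency frontiers, ICERs, CEACs, and annuity-based affordability.

The frontier algorithm removes strictly dominated strategies (costlier, no
more effective), then extendedly dominated ones (an ICER exceeding that of
a more effective alternative), and computes ICERs along what remains. It is
equivalent to net-monetary-benefit maximization over all willingness-to-pay
values, which the test suite checks against a brute-force oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "IcerRow",
    "IcerTable",
    "PerspectiveSummary",
    "CEAC",
    "build_icer_table",
    "optimal_at_wtp",
    "annuity_factor",
    "annualize_cost",
    "affordability_check",
    "compute_ceac",
    "ceac_switch_points",
]

REFERENCE = "reference"
NONDOMINATED = "nondominated"
STRICTLY_DOMINATED = "strictly_dominated"
EXTENDEDLY_DOMINATED = "extendedly_dominated"


@dataclass(frozen=True)
class IcerRow:
    strategy: str
    cost: float
    effect: float
    status: str
    incremental_cost: float | None = None
    incremental_effect: float | None = None
    icer: float | None = None


@dataclass(frozen=True)
class IcerTable:
    """Strategies sorted by cost with dominance status and frontier ICERs."""

    rows: Tuple[IcerRow, ...]

    def __iter__(self):
        return iter(self.rows)

    def row(self, strategy: str) -> IcerRow:
        for r in self.rows:
            if r.strategy == strategy:
                return r
        raise KeyError(strategy)

    @property
    def frontier(self) -> List[IcerRow]:
        """Non-dominated rows in cost order (reference first)."""
        return [r for r in self.rows if r.status in (REFERENCE, NONDOMINATED)]

    def on_frontier(self, strategy: str) -> bool:
        return self.row(strategy).status in (REFERENCE, NONDOMINATED)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": r.strategy,
                    "cost": r.cost,
                    "effect": r.effect,
                    "status": r.status,
                    "incremental_cost": r.incremental_cost,
                    "incremental_effect": r.incremental_effect,
                    "icer": r.icer,
                }
                for r in self.rows
            ]
        )


def build_icer_table(points: Sequence[Tuple[str, float, float]]) -> IcerTable:
    """Build the efficiency frontier and ICER ladder from (strategy, cost,
    effect) points.

    Sorts by cost (ties broken by effect descending), removes strict
    dominance (higher cost, no higher effect), iteratively removes extended
    dominance (non-increasing ICER along the ladder), and computes each
    remaining strategy's ICER against the previous non-dominated one. The
    cheapest strategy is the reference.
    """
    if not points:
        raise ValueError("at least one strategy required")
    names = [p[0] for p in points]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy ids")
    for s, c, e in points:
        if not (np.isfinite(c) and np.isfinite(e)):
            raise ValueError(f"non-finite cost/effect for {s!r}")

    pts = sorted(points, key=lambda p: (p[1], -p[2]))
    status: Dict[str, str] = {}

    # strict dominance: any strategy whose effect does not exceed the best
    # effect among strictly cheaper-or-equal alternatives is dominated
    best_effect = -np.inf
    for i, (s, c, e) in enumerate(pts):
        if i > 0 and e <= best_effect:
            status[s] = STRICTLY_DOMINATED
        else:
            status[s] = NONDOMINATED
            best_effect = max(best_effect, e)

    # extended dominance: drop rungs with a weakly higher ICER than the next
    ladder = [p for p in pts if status[p[0]] == NONDOMINATED]
    while True:
        if len(ladder) < 3:
            break
        icers = [
            (ladder[i][1] - ladder[i - 1][1]) / (ladder[i][2] - ladder[i - 1][2])
            for i in range(1, len(ladder))
        ]
        removed = False
        for i in range(len(icers) - 1):
            if icers[i] >= icers[i + 1]:
                status[ladder[i + 1][0]] = EXTENDEDLY_DOMINATED
                del ladder[i + 1]
                removed = True
                break
        if not removed:
            break

    status[ladder[0][0]] = REFERENCE
    rows: List[IcerRow] = []
    prev: Dict[str, Tuple[float, float]] = {}
    ladder_pos = {p[0]: i for i, p in enumerate(ladder)}
    for s, c, e in pts:
        if status[s] in (REFERENCE, NONDOMINATED) and ladder_pos[s] > 0:
            pc, pe = ladder[ladder_pos[s] - 1][1], ladder[ladder_pos[s] - 1][2]
            dc, de = c - pc, e - pe
            rows.append(IcerRow(s, c, e, status[s], dc, de, dc / de))
        else:
            rows.append(IcerRow(s, c, e, status[s]))
    return IcerTable(tuple(rows))


def optimal_at_wtp(table: IcerTable, wtp: float) -> str:
    """Frontier strategy with the largest ICER <= wtp (reference if none).

    Equivalent to maximizing net monetary benefit wtp x effect - cost over
    all strategies, with ties broken toward the cheaper strategy.
    """
    frontier = table.frontier
    best = frontier[0].strategy
    for r in frontier[1:]:
        if r.icer is not None and r.icer <= wtp:
            best = r.strategy
    return best


def annuity_factor(d: float, years: float) -> float:
    """Present-value annuity factor (1 - (1+d)^-Y)/d; Y in the d = 0 limit."""
    if years <= 0:
        raise ValueError("years must be > 0")
    if d < 0:
        raise ValueError("discount rate must be >= 0")
    if d == 0:
        return years
    # -expm1(-Y log1p(d))/d == (1 - (1+d)^-Y)/d, stable for small d
    return -math.expm1(-years * math.log1p(d)) / d


def annualize_cost(C_T: float, Y_T: float, d: float) -> float:
    """Equivalent annual cost: lump-sum present value spread over Y_T years."""
    if C_T < 0:
        raise ValueError("C_T must be >= 0")
    return C_T / annuity_factor(d, Y_T)


@dataclass(frozen=True)
class PerspectiveSummary:
    """Lifetime cost, treatment years, and the equivalent annual cost."""

    strategy: str
    perspective: str
    C_T: float  # discounted lifetime cost
    Y_T: float  # average years on treatment
    d: float  # annual discount fraction
    C_A: float = field(init=False)  # equivalent annual cost

    def __post_init__(self) -> None:
        object.__setattr__(self, "C_A", annualize_cost(self.C_T, self.Y_T, self.d))


def affordability_check(C_A: float, threshold: float) -> Tuple[bool, float]:
    """Compare an equivalent annual cost to an affordability threshold.

    Returns (affordable, ratio) with ratio = C_A / threshold; the boundary
    C_A == threshold counts as affordable.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    ratio = C_A / threshold
    return C_A <= threshold, ratio


@dataclass(frozen=True)
class CEAC:
    """Probability each strategy is NMB-optimal at each willingness-to-pay."""

    wtp_grid: np.ndarray
    strategies: Tuple[str, ...]
    probabilities: np.ndarray  # (len(grid), len(strategies)); rows sum to 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, columns=list(self.strategies))
        df.insert(0, "wtp", self.wtp_grid)
        return df

    def modal_strategy(self) -> List[str]:
        return [self.strategies[j] for j in np.argmax(self.probabilities, axis=1)]


def compute_ceac(psa_results: pd.DataFrame, wtp_grid: Sequence[float]) -> CEAC:
    """Build a CEAC from per-draw results.

    ``psa_results`` needs columns ``draw``, ``strategy``, ``cost``,
    ``effect``, with every strategy present in every draw. At each grid
    point, the NMB-maximal strategy of each draw gets one vote (ties broken
    toward the cheaper strategy); the CEAC is the vote share.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp grid must be nonempty")
    required = {"draw", "strategy", "cost", "effect"}
    if not required <= set(psa_results.columns):
        raise ValueError(f"psa_results must have columns {sorted(required)}")
    wide_c = psa_results.pivot(index="draw", columns="strategy", values="cost")
    wide_e = psa_results.pivot(index="draw", columns="strategy", values="effect")
    if wide_c.isna().any().any():
        raise ValueError("every strategy must be present in every draw")
    # stable order: cheapest-first mean cost so argmax ties favor cheaper
    order = wide_c.mean().sort_values(kind="stable").index.tolist()
    C = wide_c[order].to_numpy()  # (draws, strategies)
    E = wide_e[order].to_numpy()
    votes = np.empty((grid.size, len(order)))
    for i, lam in enumerate(grid):
        nmb = lam * E - C
        best = np.argmax(nmb, axis=1)  # first (cheapest) argmax wins ties
        votes[i] = np.bincount(best, minlength=len(order)) / C.shape[0]
    return CEAC(grid, tuple(order), votes)


def ceac_switch_points(ceac: CEAC) -> List[Tuple[float, float, str, str]]:
    """Willingness-to-pay brackets where the modal-optimal strategy changes.

    Returns (wtp_low, wtp_high, from_strategy, to_strategy) per switch.
    """
    modal = ceac.modal_strategy()
    out = []
    for i in range(1, len(modal)):
        if modal[i] != modal[i - 1]:
            out.append(
                (float(ceac.wtp_grid[i - 1]), float(ceac.wtp_grid[i]), modal[i - 1], modal[i])
            )
    return out
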