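"""Seeded individual-level Monte Carlo engine over monthly cycles.

The cohort is stepped in lockstep with numpy (one Philox counter-based
generator per run), so a full 200k-person, 1200-cycle cohort is feasible on
one CPU while remaining bit-for-bit reproducible given
(seed, n, params, strategy). ``simulate_person`` is the n = 1 special case
of the same code path.

Accounting conventions (half-cycle corrected):

* every accrual in cycle m is discounted at its midpoint, (m - 0.5)/12 years;
* death in cycle m contributes (m - 0.5)/12 years of survival, no cost/YLD
  accrual for that cycle, and years-of-life-lost (weight 1 per year) for
  cycles m..horizon;
* DALYs = YLD (state disability weights) + YLL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .disease import CARE_STATUSES, HealthState, TransitionModel, build_transition_model
from .economics import CostModel
from .params import CD4_BANDS, ParameterSet, RunConfig, StrategyDefinition

__all__ = [
    "PersonResult",
    "CohortResult",
    "CohortSummary",
    "discount",
    "accrue_daly",
    "simulate_cohort",
    "simulate_person",
]


def discount(amount, time_years, d: float):
    """Present value of ``amount`` accruing at ``time_years``: amount x (1+d)^-t."""
    if d < 0:
        raise ValueError("discount rate must be >= 0")
    return amount * (1.0 + d) ** (-np.asarray(time_years, dtype=float))


def accrue_daly(
    state: HealthState, on_art: bool, params: ParameterSet, cycle_fraction: float
) -> float:
    """Disability (YLD) increment for time lived in a state: weight x years."""
    weights = params.daly_weight_on_art if on_art else params.daly_weight_off_art
    return weights[state.cd4_band].base * cycle_fraction


@dataclass(frozen=True)
class PersonResult:
    discounted_cost_patient: float
    discounted_cost_health_sector: float
    discounted_dalys: float
    undiscounted_cost_patient: float
    undiscounted_cost_health_sector: float
    undiscounted_dalys: float
    survival_years: float
    years_on_art: float
    final_state: Optional[HealthState]  # None if dead


_FIELDS = (
    "discounted_cost_patient",
    "discounted_cost_health_sector",
    "discounted_dalys",
    "undiscounted_cost_patient",
    "undiscounted_cost_health_sector",
    "undiscounted_dalys",
    "survival_years",
    "years_on_art",
)


@dataclass(frozen=True)
class CohortResult:
    """Per-person accumulators for one simulated cohort (arrays of length n)."""

    strategy_id: str
    seed: int
    horizon_years: float
    discounted_cost_patient: np.ndarray
    discounted_cost_health_sector: np.ndarray
    discounted_dalys: np.ndarray
    undiscounted_cost_patient: np.ndarray
    undiscounted_cost_health_sector: np.ndarray
    undiscounted_dalys: np.ndarray
    survival_years: np.ndarray
    years_on_art: np.ndarray
    final_band: np.ndarray  # -1 if dead
    final_status: np.ndarray  # -1 if dead

    @property
    def n(self) -> int:
        return len(self.survival_years)

    def person(self, i: int) -> PersonResult:
        alive = self.final_band[i] >= 0
        state = (
            HealthState(CD4_BANDS[self.final_band[i]], CARE_STATUSES[self.final_status[i]])
            if alive
            else None
        )
        return PersonResult(
            *(float(getattr(self, f)[i]) for f in _FIELDS), final_state=state
        )

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({f: getattr(self, f) for f in _FIELDS})
        df.insert(0, "strategy", self.strategy_id)
        return df

    def summary(self) -> "CohortSummary":
        means = {f: float(np.mean(getattr(self, f))) for f in _FIELDS}
        ses = {
            f: float(np.std(getattr(self, f), ddof=1) / np.sqrt(self.n))
            if self.n > 1
            else float("nan")
            for f in _FIELDS
        }
        return CohortSummary(self.strategy_id, self.n, self.seed, means, ses)


@dataclass(frozen=True)
class CohortSummary:
    strategy_id: str
    n: int
    seed: int
    means: Dict[str, float]
    standard_errors: Dict[str, float]

    @property
    def mean_cost_patient(self) -> float:
        return self.means["discounted_cost_patient"]

    @property
    def mean_cost_health_sector(self) -> float:
        return self.means["discounted_cost_health_sector"]

    @property
    def mean_dalys(self) -> float:
        return self.means["discounted_dalys"]

    @property
    def mean_survival_years(self) -> float:
        return self.means["survival_years"]

    @property
    def mean_years_on_art(self) -> float:
        return self.means["years_on_art"]


def simulate_cohort(
    params: ParameterSet,
    strategy: StrategyDefinition,
    *,
    n: int,
    horizon_years: float,
    seed: int,
    model: TransitionModel | None = None,
    cost_model: CostModel | None = None,
    init: Dict[str, np.ndarray] | None = None,
) -> CohortResult:
    """Simulate ``n`` persons over monthly cycles; returns per-person results.

    ``init`` may override the sampled initial arrays (``band``, ``status``,
    ``regimen``, ``arm``) for oracle tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if horizon_years <= 0:
        raise ValueError("horizon_years must be > 0")
    tm = model if model is not None else build_transition_model(params, strategy)
    cm = cost_model if cost_model is not None else CostModel.build(params, strategy)
    d = params.discount_rate.base
    M = int(round(horizon_years * 12))

    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))

    band = rng.choice(4, size=n, p=params.cd4_init_probs()).astype(np.int64)
    on_first = rng.random(n) < params.pct_first_line.base
    status = np.where(on_first, 0, 2).astype(np.int64)  # 0=on 1st, 2=on 2nd line
    is_dtg = rng.random(n) < params.pct_dolutegravir.base
    regimen = np.where(on_first, np.where(is_dtg, 0, 1), 2).astype(np.int64)
    allocs = np.array([a.allocation for a in strategy.arms])
    arm = rng.choice(len(allocs), size=n, p=allocs).astype(np.int64)
    if init:
        for key, arr in init.items():
            target = {"band": band, "status": status, "regimen": regimen, "arm": arm}[key]
            target[:] = arr

    failed = np.zeros(n, dtype=bool)
    months_on_art = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    death_cycle = np.zeros(n, dtype=np.int64)  # 0 = survived to horizon

    pc_disc = np.zeros(n)
    hs_disc = np.zeros(n)
    yld_disc = np.zeros(n)
    pc_undisc = np.zeros(n)
    hs_undisc = np.zeros(n)
    yld_undisc = np.zeros(n)
    art_months = np.zeros(n, dtype=np.int64)

    disc = (1.0 + d) ** (-(np.arange(1, M + 1) - 0.5) / 12.0)
    w_on = params.band_base("daly_weight_on_art")
    w_off = params.band_base("daly_weight_off_art")

    for m in range(1, M + 1):
        if not alive.any():
            break
        u = rng.random((4, n))

        # 1. death
        die = alive & (u[0] < tm.p_death_by_band[band])
        death_cycle[die] = m
        alive &= ~die

        on_art = alive & ((status == 0) | (status == 2))
        forced = on_art & ((months_on_art < 3) | (band == 3))
        f_idx = forced.astype(np.int64)

        # 2. accruals for survivors of this cycle
        w = np.where(on_art, w_on[band], w_off[band]) * alive / 12.0
        pc = np.where(on_art, cm.patient_table[arm, f_idx], 0.0)
        hs = np.where(on_art, cm.hs_table[arm, f_idx, regimen], 0.0)
        dm = disc[m - 1]
        yld_undisc += w
        yld_disc += w * dm
        pc_undisc += pc
        pc_disc += pc * dm
        hs_undisc += hs
        hs_disc += hs * dm
        art_months += on_art

        # 3. LTFU / re-engagement (sequential after surviving the cycle)
        p_l = np.where(forced, tm.p_ltfu_forced, tm.p_ltfu_by_arm[arm])
        go_ltfu = on_art & (u[1] < p_l)
        off_art = alive & ~on_art
        go_re = off_art & (u[1] < tm.p_reengage)
        status = status + go_ltfu - go_re  # 0<->1, 2<->3

        # 4. line switch (first -> second, at most once) and second-line failure
        on1 = alive & (status == 0)
        switch = on1 & (u[2] < tm.p_switch_by_regimen[regimen])
        status[switch] = 2
        regimen[switch] = 2
        on2 = alive & (status == 2) & ~failed & ~switch
        failed |= on2 & (u[2] < tm.p_fail_second)

        # 5. CD4 band drift
        art_now = alive & ((status == 0) | (status == 2))
        gaining = art_now & ~((status == 2) & failed)
        p_up = np.where(gaining, tm.p_up_gain[band], 0.0)
        p_dn = np.where(
            art_now & ~gaining,
            tm.p_down_fail[band],
            np.where(alive & ~art_now, tm.p_down_offart[band], 0.0),
        )
        band = band - (u[3] < p_up) + (~(u[3] < p_up) & (u[3] < p_dn))

        months_on_art += on_art

    # survival and years of life lost
    dead = death_cycle > 0
    survival = np.where(dead, (death_cycle - 0.5) / 12.0, M / 12.0)
    yll_undisc = np.where(dead, (M - death_cycle + 1) / 12.0, 0.0)
    if d > 0:
        q = (1.0 + d) ** (-1.0 / 12.0)
        a = np.where(dead, death_cycle, M + 1)  # first lost cycle
        yll_disc = np.where(
            dead, q ** (a - 0.5) * (1.0 - q ** (M - a + 1)) / (1.0 - q) / 12.0, 0.0
        )
    else:
        yll_disc = yll_undisc.copy()

    return CohortResult(
        strategy_id=strategy.id,
        seed=seed,
        horizon_years=horizon_years,
        discounted_cost_patient=pc_disc,
        discounted_cost_health_sector=hs_disc,
        discounted_dalys=yld_disc + yll_disc,
        undiscounted_cost_patient=pc_undisc,
        undiscounted_cost_health_sector=hs_undisc,
        undiscounted_dalys=yld_undisc + yll_undisc,
        survival_years=survival,
        years_on_art=art_months / 12.0,
        final_band=np.where(dead, -1, band),
        final_status=np.where(dead, -1, status),
    )


def simulate_person(
    params: ParameterSet,
    strategy: StrategyDefinition,
    *,
    horizon_years: float,
    seed: int,
    initial_state: HealthState | None = None,
    model: TransitionModel | None = None,
) -> PersonResult:
    """Simulate a single person (deterministic given the seed)."""
    init = None
    if initial_state is not None:
        status_idx = CARE_STATUSES.index(initial_state.care_status)
        init = {
            "band": np.array([CD4_BANDS.index(initial_state.cd4_band)]),
            "status": np.array([status_idx]),
            "regimen": np.array([2 if status_idx >= 2 else 0]),
        }
    res = simulate_cohort(
        params,
        strategy,
        n=1,
        horizon_years=horizon_years,
        seed=seed,
        model=model,
        init=init,
    )
    return res.person(0)


def run_config_cohort(
    params: ParameterSet,
    strategy: StrategyDefinition,
    run: RunConfig,
    *,
    scale: float = 1.0,
    seed: int | None = None,
) -> CohortResult:
    """Simulate one strategy under a RunConfig, optionally scaled down."""
    n = max(1, int(round(run.n_individuals * scale)))
    return simulate_cohort(
        params,
        strategy,
        n=n,
        horizon_years=run.horizon_years,
        seed=run.seed if seed is None else seed,
    )
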