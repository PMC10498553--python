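"""Per-cycle costs under the patient and health-sector perspectives.

Patient costs are time and travel to refill visits: chapa (minibus) riders
pay the hourly fare over the expected round-trip transit time and value
transit + wait time at an hourly wage proxy (net national income / 2000 h);
walkers value walk + wait time. Community (mobile brigade) visits scale
travel time and fare by the brigade distance fraction. Health-sector costs
are ARV regimen + facility/community service + viral-load testing, plus
case management where the strategy includes it. Costs accrue only while
alive and, for service/ARV components, only while on ART.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet, StrategyDefinition

__all__ = [
    "expected_transit_hours",
    "expected_patient_cost_per_visit",
    "health_sector_cost_per_cycle",
    "patient_cost_per_cycle",
    "CostModel",
]

#: Midpoints (hours) of the chapa round-trip transit-time bands; the open
#: ">240 min" band is valued at 5 h.
TRANSIT_BAND_HOURS = {"lt60min": 0.5, "m60_240": 2.5, "gt240min": 5.0}

#: Hours of paid work per year used to turn annual net income into an
#: hourly time value.
WORK_HOURS_PER_YEAR = 2000.0


def _hourly_time_value(params: ParameterSet) -> float:
    return params.net_national_income_pc.base / WORK_HOURS_PER_YEAR


def expected_transit_hours(params: ParameterSet) -> float:
    """Expected chapa round-trip hours over the three-band distribution."""
    return sum(
        params.transit_time_distribution[band] * hours
        for band, hours in TRANSIT_BAND_HOURS.items()
    )


def expected_patient_cost_per_visit(params: ParameterSet, setting: str) -> float:
    """Expected out-of-pocket + time cost of one refill visit.

    Mixture over travel mode: with probability ``pct_travel_by_chapa`` the
    visit costs fare x transit + w x (transit + wait); otherwise
    w x (walk + wait). Community visits scale travel (and fare) by
    ``brigade_distance_fraction``.
    """
    if setting not in ("clinic", "community"):
        raise ValueError(f"unknown setting {setting!r}")
    w = _hourly_time_value(params)
    scale = params.brigade_distance_fraction.base if setting == "community" else 1.0
    transit = expected_transit_hours(params) * scale
    walk = params.walk_roundtrip_hours.base * scale
    wait = params.wait_time_hours.base
    fare = params.chapa_cost_per_hour.base
    p_chapa = params.pct_travel_by_chapa.base
    chapa_cost = fare * transit + w * (transit + wait)
    walk_cost = w * (walk + wait)
    return p_chapa * chapa_cost + (1.0 - p_chapa) * walk_cost


def health_sector_cost_per_cycle(
    params: ParameterSet,
    strategy: StrategyDefinition,
    *,
    regimen: str,
    on_art: bool,
    forced_1m: bool = False,
    arm: int = 0,
) -> float:
    """Monthly health-sector cost for one person-state.

    ARV cost by regimen, a facility/community service component scaled by
    visit frequency, annual viral-load testing spread monthly, and the
    case-management add-on in strategies that include it. Off-ART persons
    have no service contact and cost 0.
    """
    if regimen not in ("dtg", "efv", "second_line"):
        raise ValueError(f"unknown regimen {regimen!r}")
    if not on_art:
        return 0.0
    arv = {
        "dtg": params.arv_cost_monthly_dtg.base,
        "efv": params.arv_cost_monthly_efv.base,
        "second_line": params.arv_cost_monthly_second_line.base,
    }[regimen]
    arm_def = strategy.arms[arm]
    monthly_1m_facility = params.facility_cost_1m_annual.base / 12.0
    if forced_1m:
        facility = monthly_1m_facility
    elif arm_def.setting == "community":
        facility = params.community_cost_3m_annual.base / 12.0
    else:
        facility = monthly_1m_facility / arm_def.refill_interval_months
    vl = params.vl_test_cost_annual.base / 12.0
    case_mgmt = (
        params.case_mgmt_cost_monthly.base if strategy.tracing_enabled else 0.0
    )
    return arv + facility + vl + case_mgmt


def patient_cost_per_cycle(
    params: ParameterSet,
    strategy: StrategyDefinition,
    *,
    on_art: bool,
    forced_1m: bool = False,
    arm: int = 0,
) -> float:
    """Monthly patient cost: expected visits/month x expected per-visit cost.

    Steady state uses 1/interval visits per month; forced 1-month periods
    use one clinic visit per month. Zero while off ART (no visits).
    """
    if not on_art:
        return 0.0
    arm_def = strategy.arms[arm]
    if forced_1m:
        return expected_patient_cost_per_visit(params, "clinic")
    per_visit = expected_patient_cost_per_visit(params, arm_def.setting)
    return per_visit / arm_def.refill_interval_months


@dataclass(frozen=True)
class CostModel:
    """Per-cycle cost lookup tables for the vectorized engine.

    ``patient_table[arm, forced]`` and ``hs_table[arm, forced, regimen]``
    give the monthly cost while on ART (regimens: 0=DTG, 1=EFV, 2=second
    line); off-ART cost is 0 for both perspectives.
    """

    strategy_id: str
    patient_table: np.ndarray  # (n_arms, 2)
    hs_table: np.ndarray  # (n_arms, 2, 3)

    @staticmethod
    def build(params: ParameterSet, strategy: StrategyDefinition) -> "CostModel":
        n_arms = len(strategy.arms)
        patient = np.zeros((n_arms, 2))
        hs = np.zeros((n_arms, 2, 3))
        regimens = ("dtg", "efv", "second_line")
        for a in range(n_arms):
            for forced in (0, 1):
                patient[a, forced] = patient_cost_per_cycle(
                    params, strategy, on_art=True, forced_1m=bool(forced), arm=a
                )
                for r, reg in enumerate(regimens):
                    hs[a, forced, r] = health_sector_cost_per_cycle(
                        params,
                        strategy,
                        regimen=reg,
                        on_art=True,
                        forced_1m=bool(forced),
                        arm=a,
                    )
        if np.any(patient < 0) or np.any(hs < 0):
            raise ValueError("negative cost in cost model")
        return CostModel(strategy.id, patient, hs)

    def to_frame(self):
        """Audit CSV: monthly cost per (arm, phase, regimen, perspective)."""
        import pandas as pd

        rows = []
        regimens = ("dtg", "efv", "second_line")
        for a in range(self.patient_table.shape[0]):
            for forced, phase in ((0, "steady_state"), (1, "forced_1m")):
                rows.append(
                    {
                        "strategy": self.strategy_id,
                        "arm": a,
                        "phase": phase,
                        "perspective": "patient",
                        "regimen": "any",
                        "monthly_cost": self.patient_table[a, forced],
                    }
                )
                for r, reg in enumerate(regimens):
                    rows.append(
                        {
                            "strategy": self.strategy_id,
                            "arm": a,
                            "phase": phase,
                            "perspective": "health_sector",
                            "regimen": reg,
                            "monthly_cost": self.hs_table[a, forced, r],
                        }
                    )
        return pd.DataFrame(rows)
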