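"""State space and monthly transition probabilities.

The model has 17 states: 4 CD4 bands x 4 care statuses plus an absorbing
death state. Care statuses: on first-line ART, off ART but first-line
eligible, on second-line ART, off ART second-line only. Each month, events
resolve by sequential conditional draws in the fixed order
death -> LTFU/re-engagement -> line switch / second-line failure -> CD4 drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .params import CD4_BANDS, ParameterSet, StrategyDefinition

__all__ = [
    "CARE_STATUSES",
    "HealthState",
    "TransitionModel",
    "rate_to_monthly_prob",
    "risk_to_monthly_prob",
    "apply_odds_ratio",
    "cd4_band_transition_probs",
    "build_transition_model",
]

#: Care statuses; indices match the engine's status array.
CARE_STATUSES: Tuple[str, ...] = (
    "on_first_line",
    "off_art_first_line_eligible",
    "on_second_line",
    "off_art_second_line_only",
)

ON_FIRST, OFF_FIRST, ON_SECOND, OFF_SECOND = range(4)

#: Width (cells/uL) of each band used for expected-crossing-time conversion;
#: the open-ended gt500 band is treated as width 150.
BAND_WIDTH = {"gt500": 150.0, "c350_500": 150.0, "c200_349": 150.0, "lt200": 200.0}


@dataclass(frozen=True)
class HealthState:
    """One of the 16 living states (death is represented separately)."""

    cd4_band: str
    care_status: str
    alive: bool = True

    def __post_init__(self) -> None:
        if self.cd4_band not in CD4_BANDS:
            raise ValueError(f"unknown CD4 band {self.cd4_band!r}")
        if self.care_status not in CARE_STATUSES:
            raise ValueError(f"unknown care status {self.care_status!r}")

    @property
    def on_art(self) -> bool:
        return self.care_status in ("on_first_line", "on_second_line")


def living_states() -> List[HealthState]:
    return [HealthState(b, s) for s in CARE_STATUSES for b in CD4_BANDS]


# ---------------------------------------------------------------------------
# Elementary conversions
# ---------------------------------------------------------------------------


def rate_to_monthly_prob(rate: float) -> float:
    """Constant-hazard conversion of a per-100-person-year rate to a monthly
    probability: p = 1 - exp(-rate / 1200)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return 1.0 - math.exp(-rate / 1200.0)


def risk_to_monthly_prob(P: float, m: float) -> float:
    """Geometric de-compounding of an m-month risk to a monthly probability:
    p = 1 - (1-P)^(1/m). Compounding p back over m months recovers P."""
    if not (0.0 <= P < 1.0):
        raise ValueError("P must be in [0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - P) ** (1.0 / m)


def apply_odds_ratio(P_base: float, OR: float) -> float:
    """Apply an odds ratio to a baseline probability on the odds scale."""
    if not (0.0 < P_base < 1.0):
        raise ValueError("P_base must be in (0, 1)")
    if OR <= 0:
        raise ValueError("OR must be > 0")
    o = P_base / (1.0 - P_base)
    return (OR * o) / (1.0 + OR * o)


def cd4_band_transition_probs(annual_drift: float, band: str) -> Tuple[str, float]:
    """Monthly probability of crossing to the adjacent CD4 band.

    Expected-crossing-time model: p = min(1, |drift| / (12 * band_width)),
    in the direction of the drift's sign. The top band has no upward exit
    and the bottom band no downward exit.

    Returns
    -------
    (direction, probability) with direction one of "up", "down", "none".
    """
    if band not in CD4_BANDS:
        raise ValueError(f"unknown band {band!r}")
    if annual_drift == 0:
        return "none", 0.0
    direction = "up" if annual_drift > 0 else "down"
    i = CD4_BANDS.index(band)
    if direction == "up" and i == 0:
        return "none", 0.0
    if direction == "down" and i == len(CD4_BANDS) - 1:
        return "none", 0.0
    p = min(1.0, abs(annual_drift) / (12.0 * BAND_WIDTH[band]))
    return direction, p


# ---------------------------------------------------------------------------
# Transition model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionModel:
    """Precomputed monthly probabilities for one (parameter set, strategy).

    LTFU hazards are per arm; ``p_ltfu_forced`` applies during forced
    1-month refill periods (first 3 months on ART, or CD4 < 200) in every
    strategy.
    """

    strategy_id: str
    p_death_by_band: np.ndarray  # (4,)
    p_ltfu_forced: float
    p_ltfu_by_arm: np.ndarray  # (n_arms,)
    p_reengage: float
    p_switch_by_regimen: np.ndarray  # (3,): [dtg, efv, second(=0)]
    p_fail_second: float
    p_up_gain: np.ndarray  # (4,) on ART, CD4 rising
    p_down_fail: np.ndarray  # (4,) on failing second-line
    p_down_offart: np.ndarray  # (4,) off ART

    def validate(self) -> None:
        for name in (
            "p_death_by_band", "p_ltfu_by_arm", "p_switch_by_regimen",
            "p_up_gain", "p_down_fail", "p_down_offart",
        ):
            arr = getattr(self, name)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name}: probability outside [0, 1]")
        for name in ("p_ltfu_forced", "p_reengage", "p_fail_second"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}: probability outside [0, 1]")

    # -- audit surface ----------------------------------------------------

    def event_probs(
        self, state: HealthState, months_on_art: int = 99, arm: int = 0
    ) -> Dict[str, float]:
        """All outgoing event probabilities for a state; 'stay' is the residual
        so the outgoing mass sums to 1 by construction."""
        b = CD4_BANDS.index(state.cd4_band)
        s = CARE_STATUSES.index(state.care_status)
        probs: Dict[str, float] = {"death": float(self.p_death_by_band[b])}
        live = 1.0 - probs["death"]
        if s in (ON_FIRST, ON_SECOND):
            forced = months_on_art < 3 or state.cd4_band == "lt200"
            probs["ltfu"] = live * (
                self.p_ltfu_forced if forced else float(self.p_ltfu_by_arm[arm])
            )
            remain = live - probs["ltfu"]
            if s == ON_FIRST:
                # regimen mix is person-level; report the DTG hazard for audit
                probs["switch_to_second_line"] = remain * float(
                    self.p_switch_by_regimen[0]
                )
                remain -= probs["switch_to_second_line"]
            else:
                probs["second_line_failure"] = remain * self.p_fail_second
                remain -= probs["second_line_failure"]
            probs["cd4_band_up"] = remain * float(self.p_up_gain[b])
        else:
            probs["reengage"] = live * self.p_reengage
            remain = live - probs["reengage"]
            probs["cd4_band_down"] = remain * float(self.p_down_offart[b])
        used = sum(probs.values())
        probs["stay"] = 1.0 - used
        return probs

    def to_frame(self):
        """Per-state event probabilities as a DataFrame (audit/CSV export)."""
        import pandas as pd

        rows = []
        for st in living_states():
            for months_on_art, label in ((0, "first_3_months"), (99, "established")):
                for arm in range(len(self.p_ltfu_by_arm)):
                    for event, p in self.event_probs(st, months_on_art, arm).items():
                        rows.append(
                            {
                                "strategy": self.strategy_id,
                                "cd4_band": st.cd4_band,
                                "care_status": st.care_status,
                                "phase": label,
                                "arm": arm,
                                "event": event,
                                "probability": p,
                            }
                        )
        return pd.DataFrame(rows)


def _arm_ltfu_monthly(params: ParameterSet, setting: str, interval: int) -> float:
    """Monthly LTFU hazard for one delivery arm at steady state."""
    risk_12m = params.ltfu_12m_risk_1month.base
    if setting == "community":
        return rate_to_monthly_prob(params.ltfu_rate_community_3m.base)
    if interval == 1:
        return risk_to_monthly_prob(risk_12m, 12)
    # multi-month clinical arms: OR-adjusted 2-year risk, de-compounded
    base_24m = 1.0 - (1.0 - risk_12m) ** 2
    if base_24m == 0.0:
        return 0.0
    OR = params.or_ltfu_3m.base if interval == 3 else params.or_ltfu_6m.base
    return risk_to_monthly_prob(apply_odds_ratio(base_24m, OR), 24)


def build_transition_model(
    params: ParameterSet, strategy: StrategyDefinition
) -> TransitionModel:
    """Compose the elementary conversions into the per-cycle model."""
    p_death = np.array(
        [
            rate_to_monthly_prob(params.mortality_rate_by_cd4_untreated[b].base)
            for b in CD4_BANDS
        ]
    )
    p_ltfu_forced = risk_to_monthly_prob(params.ltfu_12m_risk_1month.base, 12)
    p_ltfu_by_arm = np.array(
        [
            _arm_ltfu_monthly(params, arm.setting, arm.refill_interval_months)
            for arm in strategy.arms
        ]
    )
    reengage_12m = (
        params.reengage_12m_with_tracing.base
        if strategy.tracing_enabled
        else params.reengage_12m_without_tracing.base
    )
    p_reengage = risk_to_monthly_prob(reengage_12m, 12)
    p_switch = np.array(
        [
            risk_to_monthly_prob(params.annual_switch_risk_dtg.base, 12),
            risk_to_monthly_prob(params.annual_switch_risk_efv.base, 12),
            0.0,
        ]
    )
    p_fail = rate_to_monthly_prob(params.second_line_failure_rate.base)

    def drift_probs(annual_drift: float) -> np.ndarray:
        return np.array(
            [cd4_band_transition_probs(annual_drift, b)[1] for b in CD4_BANDS]
        )

    model = TransitionModel(
        strategy_id=strategy.id,
        p_death_by_band=p_death,
        p_ltfu_forced=p_ltfu_forced,
        p_ltfu_by_arm=p_ltfu_by_arm,
        p_reengage=p_reengage,
        p_switch_by_regimen=p_switch,
        p_fail_second=p_fail,
        p_up_gain=drift_probs(+params.cd4_gain_on_art.base),
        p_down_fail=drift_probs(-params.cd4_decline_on_art_failing.base),
        p_down_offart=drift_probs(-params.cd4_decline_no_art.base),
    )
    model.validate()
    return model
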