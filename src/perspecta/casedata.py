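"""Published results of the Mozambique HIV treatment case study.

These are the reported per-person lifetime outcomes of the six ARV delivery
strategies under each perspective (costs discounted at 5%/year, 2020 USD),
used as deterministic inputs to the ICER/annualization/affordability
analytics and as cross-checks for the simulation's qualitative orderings.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

__all__ = [
    "PATIENT_RESULTS",
    "HEALTH_SECTOR_RESULTS",
    "OOP_THRESHOLD",
    "GDP_PC",
    "WTP_THRESHOLD",
    "DISCOUNT_RATE",
    "icer_points",
]

#: strategy -> (lifetime cost C_T, DALYs averted, survival years,
#:              years on ART Y_T, reported annual cost on ART)
PATIENT_RESULTS: Dict[str, Tuple[float, float, float, float, float]] = {
    "clinical_6m": (24.15, 10.79, 24.6, 16.9, 2.16),
    "mixed_6m_community_3m": (25.29, 11.21, 25.9, 19.2, 2.08),
    "community_3m": (26.82, 11.74, 27.6, 22.5, 2.01),
    "clinical_3m": (33.49, 9.86, 21.9, 12.2, 3.72),
    "clinical_3m_case_mgmt": (47.03, 11.92, 28.5, 20.7, 3.69),
    "clinical_1m": (77.92, 9.37, 20.5, 10.3, 9.83),
}

HEALTH_SECTOR_RESULTS: Dict[str, Tuple[float, float, float, float, float]] = {
    "clinical_3m": (1284.0, 9.87, 21.9, 12.2, 142.0),
    "clinical_6m": (1405.0, 10.80, 24.6, 16.8, 125.0),
    "clinical_1m": (1548.0, 9.39, 20.6, 10.4, 195.0),
    "mixed_6m_community_3m": (2073.0, 11.22, 25.9, 19.2, 170.0),
    "community_3m": (2905.0, 11.74, 27.6, 22.5, 218.0),
    "clinical_3m_case_mgmt": (6203.0, 11.93, 28.5, 20.8, 486.0),
}

#: Average annual out-of-pocket health expenditure per capita (USD/year),
#: the affordability threshold of the case study.
OOP_THRESHOLD: float = 4.14

GDP_PC: float = 467.0

#: Willingness-to-pay threshold: 0.3 x GDP per capita per DALY averted.
WTP_THRESHOLD: float = 0.3 * GDP_PC

DISCOUNT_RATE: float = 0.05


def icer_points(perspective: str) -> List[Tuple[str, float, float]]:
    """(strategy, cost, effect) points for :func:`perspecta.cea.build_icer_table`."""
    table = {
        "patient": PATIENT_RESULTS,
        "health_sector": HEALTH_SECTOR_RESULTS,
    }[perspective]
    return [(s, v[0], v[1]) for s, v in table.items()]
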