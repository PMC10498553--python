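"""Five-pattern congruence classification of dual-perspective CEA results.

Given the health-sector and patient ICER tables, the classifier asks three
questions about the health-sector-optimal strategy: is it also optimal from
the patient perspective, is it on the patient efficiency frontier, and is
its equivalent annual patient cost affordable? The answers map onto five
patterns, each carrying a recommendation for decision-makers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

from .cea import IcerTable, optimal_at_wtp

__all__ = ["PATTERNS", "AlignmentVerdict", "classify_alignment", "render_report"]

PATTERNS = (
    "perfectly_congruent",
    "weakly_congruent",
    "incongruent",
    "consistent",
    "inconsistent",
)

_RECOMMENDATIONS: Dict[str, str] = {
    "perfectly_congruent": (
        "recommend_optimal: both perspectives identify the same intervention "
        "as optimal and it is affordable; recommend it."
    ),
    "weakly_congruent": (
        "recommend_hs_optimal_with_incentives: the health-sector-optimal "
        "intervention is efficient and affordable from the patient "
        "perspective but not the patient optimum; recommend it, and redesign "
        "or implement interventions to maximize patient incentive to choose it."
    ),
    "incongruent": (
        "recommend_hs_optimal_consider_redesign: the health-sector-optimal "
        "intervention is affordable but inefficient from the patient "
        "perspective; consider redesign to improve patient value."
    ),
    "consistent": (
        "redesign_for_affordability: the health-sector-optimal intervention "
        "is efficient from the patient perspective but unaffordable; redesign "
        "to decrease or offset patient out-of-pocket expenditures, otherwise "
        "eliminate it (without recalculating ICERs) and recommend the next "
        "most cost-effective intervention that is efficient and affordable "
        "for patients."
    ),
    "inconsistent": (
        "redesign_for_affordability: the health-sector-optimal intervention "
        "is neither efficient nor affordable from the patient perspective; "
        "redesign to decrease or offset patient out-of-pocket expenditures, "
        "otherwise eliminate it (without recalculating ICERs) and recommend "
        "the next most cost-effective intervention that is efficient and "
        "affordable for patients."
    ),
}


def classify_pattern(same_optimal: bool, on_patient_frontier: bool, affordable: bool) -> str:
    """Pure mapping from the three booleans to the five patterns.

    ``same_optimal`` implies ``on_patient_frontier`` (an optimum is by
    definition on its frontier); that impossible cell is rejected.
    """
    if same_optimal and not on_patient_frontier:
        raise ValueError("an optimal strategy is necessarily on the frontier")
    if affordable:
        if same_optimal:
            return "perfectly_congruent"
        return "weakly_congruent" if on_patient_frontier else "incongruent"
    return "consistent" if on_patient_frontier else "inconsistent"


@dataclass(frozen=True)
class AlignmentVerdict:
    pattern: str
    hs_optimal: str
    patient_optimal: str
    hs_optimal_on_patient_frontier: bool
    hs_optimal_affordable: bool
    affordability_ratio: float
    recommendation: str


def classify_alignment(
    hs_table: IcerTable,
    patient_table: IcerTable,
    wtp: float,
    affordability: Tuple[bool, float],
    *,
    patient_wtp: float | None = None,
) -> AlignmentVerdict:
    """Classify perspective congruence at a willingness-to-pay threshold.

    ``affordability`` is (affordable, ratio) for the health-sector-optimal
    strategy's equivalent annual cost under the patient perspective. A
    distinct ``patient_wtp`` may be supplied when payers' thresholds differ;
    by default one shared threshold is used.
    """
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    hs_opt = optimal_at_wtp(hs_table, wtp)
    pat_opt = optimal_at_wtp(patient_table, patient_wtp if patient_wtp is not None else wtp)
    same = hs_opt == pat_opt
    on_frontier = patient_table.on_frontier(hs_opt)
    affordable, ratio = affordability
    pattern = classify_pattern(same, on_frontier, affordable)
    return AlignmentVerdict(
        pattern=pattern,
        hs_optimal=hs_opt,
        patient_optimal=pat_opt,
        hs_optimal_on_patient_frontier=on_frontier,
        hs_optimal_affordable=affordable,
        affordability_ratio=ratio,
        recommendation=_RECOMMENDATIONS[pattern],
    )


def _format_table(table: IcerTable) -> str:
    lines = [
        f"{'strategy':<24}{'cost':>12}{'effect':>10}{'status':>24}{'ICER':>12}"
    ]
    for r in table:
        icer = f"{r.icer:,.2f}" if r.icer is not None else "-"
        lines.append(
            f"{r.strategy:<24}{r.cost:>12,.2f}{r.effect:>10.2f}{r.status:>24}{icer:>12}"
        )
    return "\n".join(lines)


def render_report(
    verdict: AlignmentVerdict,
    hs_table: IcerTable,
    patient_table: IcerTable,
    affordability_rows: Sequence[Tuple[str, float, bool, float]] = (),
    threshold: float | None = None,
) -> str:
    """Deterministic plain-text report of both ladders, affordability, and
    the verdict. ``affordability_rows`` holds (strategy, annual_cost,
    affordable, ratio) per strategy under the patient perspective."""
    parts = [
        "PERSPECTIVE CONGRUENCE REPORT",
        "=============================",
        "",
        "Health sector perspective",
        "-------------------------",
        _format_table(hs_table),
        "",
        "Patient perspective",
        "-------------------",
        _format_table(patient_table),
        "",
    ]
    if affordability_rows:
        hdr = "Annualized patient cost vs threshold"
        if threshold is not None:
            hdr += f" (${threshold:,.2f}/year)"
        parts += [hdr, "-" * len(hdr)]
        for strategy, annual, ok, ratio in affordability_rows:
            flag = "affordable" if ok else "UNAFFORDABLE"
            parts.append(
                f"{strategy:<24}${annual:>8,.2f}/yr  {ratio * 100:>6.0f}%  {flag}"
            )
        parts.append("")
    same = verdict.hs_optimal == verdict.patient_optimal
    efficiency = (
        "optimal from both perspectives"
        if same
        else (
            "efficient and affordable from the patient perspective"
            if verdict.hs_optimal_on_patient_frontier and verdict.hs_optimal_affordable
            else "efficient from the patient perspective"
            if verdict.hs_optimal_on_patient_frontier
            else "not efficient from the patient perspective"
        )
    )
    parts += [
        "Verdict",
        "-------",
        f"pattern: {verdict.pattern}",
        f"health-sector optimal: {verdict.hs_optimal} ({efficiency})",
        f"patient optimal: {verdict.patient_optimal}",
        f"on patient frontier: {verdict.hs_optimal_on_patient_frontier}",
        f"affordable: {verdict.hs_optimal_affordable} "
        f"(ratio {verdict.affordability_ratio * 100:.0f}% of threshold)",
        "",
        f"Next steps: {verdict.recommendation}",
        "",
    ]
    return "\n".join(parts)
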