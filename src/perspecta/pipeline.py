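"""End-to-end orchestration: config -> simulation -> PSA -> CEA -> verdict.

All randomness flows from one master seed. Within each PSA draw the same
cohort seed is shared across strategies (common random numbers), which
sharply reduces Monte Carlo noise on the incremental costs and effects that
ICERs and CEACs are built from.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cea import (
    CEAC,
    IcerTable,
    affordability_check,
    annualize_cost,
    build_icer_table,
    compute_ceac,
)
from .engine import CohortSummary, simulate_cohort
from .framework import AlignmentVerdict, classify_alignment, render_report
from .params import (
    ParameterSet,
    RunConfig,
    StrategyDefinition,
    load_config,
    sample_parameter_set,
)

__all__ = ["RunManifest", "AnalysisResults", "run_full_analysis", "run_base_case", "run_psa"]

log = logging.getLogger("perspecta")

PERSPECTIVES = ("patient", "health_sector")
_COST_FIELD = {
    "patient": "discounted_cost_patient",
    "health_sector": "discounted_cost_health_sector",
}


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    n_individuals: int
    psa_draws: int
    psa_n_per_draw: int
    scale: float
    version: str
    started_utc: float
    outputs: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass(frozen=True)
class AnalysisResults:
    summaries: Dict[str, CohortSummary]
    icer_tables: Dict[str, IcerTable]
    ceacs: Dict[str, CEAC]
    affordability: pd.DataFrame
    verdict: AlignmentVerdict
    report: str
    manifest: RunManifest
    psa_results: pd.DataFrame


def _reference_strategy(
    summaries: Dict[str, CohortSummary], reference: Optional[str]
) -> str:
    if reference is not None and reference in summaries:
        return reference
    # fall back to the arm with the most DALYs (least healthy counterfactual)
    return max(summaries, key=lambda s: summaries[s].mean_dalys)


def _points(
    summaries: Dict[str, CohortSummary], perspective: str, reference: str
):
    ref_dalys = summaries[reference].mean_dalys
    return [
        (
            sid,
            s.means[_COST_FIELD[perspective]],
            ref_dalys - s.mean_dalys,  # DALYs averted vs the reference arm
        )
        for sid, s in summaries.items()
    ]


def run_base_case(
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition],
    *,
    n: int,
    horizon_years: float,
    seed: int,
) -> Dict[str, CohortSummary]:
    """Simulate every strategy once with a shared cohort seed (CRN)."""
    out: Dict[str, CohortSummary] = {}
    for strat in strategies:
        t0 = time.perf_counter()
        res = simulate_cohort(
            params, strat, n=n, horizon_years=horizon_years, seed=seed
        )
        out[strat.id] = res.summary()
        log.info(
            "base case %s: n=%d, %.1fs, mean survival %.2fy",
            strat.id, n, time.perf_counter() - t0, out[strat.id].mean_survival_years,
        )
    return out


def run_psa(
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition],
    *,
    draws: int,
    n_per_draw: int,
    horizon_years: float,
    seed: int,
    reference: Optional[str] = None,
) -> pd.DataFrame:
    """Probabilistic sensitivity analysis.

    Returns a long DataFrame with one row per (draw, strategy, perspective)
    carrying cost and effect (DALYs averted vs the within-draw reference).
    """
    master = np.random.default_rng(seed)
    rows: List[dict] = []
    for j in range(draws):
        param_seed = int(master.integers(0, 2**63 - 1))
        cohort_seed = int(master.integers(0, 2**63 - 1))
        drawn = sample_parameter_set(params, param_seed)
        summaries = {
            s.id: simulate_cohort(
                drawn, s, n=n_per_draw, horizon_years=horizon_years, seed=cohort_seed
            ).summary()
            for s in strategies
        }
        ref = _reference_strategy(summaries, reference)
        ref_dalys = summaries[ref].mean_dalys
        for sid, summ in summaries.items():
            for persp in PERSPECTIVES:
                rows.append(
                    {
                        "draw": j,
                        "strategy": sid,
                        "perspective": persp,
                        "cost": summ.means[_COST_FIELD[persp]],
                        "effect": ref_dalys - summ.mean_dalys,
                    }
                )
        if (j + 1) % max(1, draws // 10) == 0:
            log.info("PSA draw %d/%d complete", j + 1, draws)
    return pd.DataFrame(rows)


def run_full_analysis(
    config_path: str | Path,
    *,
    scale: float = 1.0,
    seed: Optional[int] = None,
    outdir: Optional[str | Path] = None,
    reference: Optional[str] = "clinical_1m",
    psa_n_per_draw: Optional[int] = None,
) -> AnalysisResults:
    """Execute every stage of the analysis on a config file.

    ``scale`` divides both the cohort size and the number of PSA draws for
    desk-scale runs. PSA cohorts default to min(scaled n, 2000) persons per
    draw; the base case uses the full scaled n.
    """
    params, strategies, run = load_config(config_path)
    seed = run.seed if seed is None else seed
    n = max(2, int(round(run.n_individuals * scale)))
    draws = max(1, int(round(run.psa_draws * scale)))
    n_psa = psa_n_per_draw if psa_n_per_draw is not None else min(n, 2000)
    config_hash = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    manifest = RunManifest(
        config_hash=config_hash,
        seed=seed,
        n_individuals=n,
        psa_draws=draws,
        psa_n_per_draw=n_psa,
        scale=scale,
        version=__version__,
        started_utc=time.time(),
    )
    master = np.random.default_rng(seed)
    base_seed = int(master.integers(0, 2**63 - 1))
    psa_seed = int(master.integers(0, 2**63 - 1))

    log.info("stage 1/5: base-case simulation (n=%d, %d strategies)", n, len(strategies))
    summaries = run_base_case(
        params, strategies, n=n, horizon_years=run.horizon_years, seed=base_seed
    )
    ref = _reference_strategy(summaries, reference)

    log.info("stage 2/5: efficiency frontiers and ICERs (reference=%s)", ref)
    tables = {
        p: build_icer_table(_points(summaries, p, ref)) for p in PERSPECTIVES
    }

    log.info("stage 3/5: affordability")
    d = params.discount_rate.base
    threshold = run.resolved_affordability_threshold(params)
    afford_rows = []
    for sid, summ in summaries.items():
        annual = annualize_cost(
            summ.mean_cost_patient, max(summ.mean_years_on_art, 1e-9), d
        )
        ok, ratio = affordability_check(annual, threshold)
        afford_rows.append(
            {
                "strategy": sid,
                "annual_patient_cost": annual,
                "years_on_art": summ.mean_years_on_art,
                "affordable": ok,
                "ratio": ratio,
            }
        )
    affordability = pd.DataFrame(afford_rows).set_index("strategy")

    wtp = run.resolved_wtp_threshold(params)
    log.info("stage 4/5: congruence classification (wtp=%.1f)", wtp)
    hs_opt_candidate = tables["health_sector"]
    from .cea import optimal_at_wtp  # local import to avoid cycle noise

    hs_opt = optimal_at_wtp(hs_opt_candidate, wtp)
    verdict = classify_alignment(
        tables["health_sector"],
        tables["patient"],
        wtp,
        (
            bool(affordability.loc[hs_opt, "affordable"]),
            float(affordability.loc[hs_opt, "ratio"]),
        ),
    )
    report = render_report(
        verdict,
        tables["health_sector"],
        tables["patient"],
        [
            (sid, row["annual_patient_cost"], bool(row["affordable"]), row["ratio"])
            for sid, row in affordability.iterrows()
        ],
        threshold=threshold,
    )

    log.info("stage 5/5: PSA (%d draws x n=%d) and CEACs", draws, n_psa)
    psa = run_psa(
        params,
        strategies,
        draws=draws,
        n_per_draw=n_psa,
        horizon_years=run.horizon_years,
        seed=psa_seed,
        reference=reference,
    )
    ceacs = {
        p: compute_ceac(
            psa[psa.perspective == p][["draw", "strategy", "cost", "effect"]],
            run.wtp_grid,
        )
        for p in PERSPECTIVES
    }

    results = AnalysisResults(
        summaries=summaries,
        icer_tables=tables,
        ceacs=ceacs,
        affordability=affordability,
        verdict=verdict,
        report=report,
        manifest=manifest,
        psa_results=psa,
    )
    if outdir is not None:
        _write_outputs(results, Path(outdir))
    return results


def _write_outputs(results: AnalysisResults, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}
    for p in PERSPECTIVES:
        path = outdir / f"icer_{p}.csv"
        results.icer_tables[p].to_frame().to_csv(path, index=False)
        outputs[f"icer_{p}"] = str(path)
        path = outdir / f"ceac_{p}.csv"
        results.ceacs[p].to_frame().to_csv(path, index=False)
        outputs[f"ceac_{p}"] = str(path)
    path = outdir / "affordability.csv"
    results.affordability.to_csv(path)
    outputs["affordability"] = str(path)
    path = outdir / "psa_results.csv"
    results.psa_results.to_csv(path, index=False)
    outputs["psa_results"] = str(path)
    path = outdir / "verdict.txt"
    path.write_text(results.report)
    outputs["verdict"] = str(path)
    manifest = RunManifest(**{**results.manifest.__dict__, "outputs": outputs})
    (outdir / "manifest.json").write_text(manifest.to_json())
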