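"""Parameter data model, distribution specs, config I/O, and fixtures.

Every uncertain scalar in the model is a :class:`DistributionSpec` — either a
point value or a three-point PERT range sampled in probabilistic sensitivity
analysis. :class:`ParameterSet` is the single authoritative home of every
model input; the packaged Mozambique HIV treatment case ships as
``data/mozambique.yaml``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Sequence, Tuple

import numpy as np
import yaml

__all__ = [
    "CD4_BANDS",
    "STRATEGY_IDS",
    "DistributionSpec",
    "ParameterSet",
    "StrategyArm",
    "StrategyDefinition",
    "RunConfig",
    "ConfigError",
    "pert_to_beta",
    "sample_parameter_set",
    "load_config",
    "validate_config",
    "save_config",
    "make_fixture",
    "mozambique_path",
    "builtin_strategies",
    "draws_to_frame",
]

#: CD4 bands ordered high to low; index 0..3 is used throughout the engine.
CD4_BANDS: Tuple[str, ...] = ("gt500", "c350_500", "c200_349", "lt200")

STRATEGY_IDS: Tuple[str, ...] = (
    "clinical_1m",
    "clinical_3m",
    "clinical_6m",
    "clinical_3m_case_mgmt",
    "community_3m",
    "mixed_6m_community_3m",
)


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


# ---------------------------------------------------------------------------
# Distribution specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """A point value or a PERT(min, mode, max) uncertainty specification."""

    kind: str  # "point" | "pert"
    value: float | None = None
    min: float | None = None
    mode: float | None = None
    max: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "point":
            if self.value is None or not np.isfinite(self.value):
                raise ValueError("point spec requires a finite value")
        elif self.kind == "pert":
            if self.min is None or self.mode is None or self.max is None:
                raise ValueError("pert spec requires min, mode, max")
            if not (self.min <= self.mode <= self.max):
                raise ValueError(
                    f"pert spec requires min <= mode <= max, got "
                    f"({self.min}, {self.mode}, {self.max})"
                )
            if self.min >= self.max:
                raise ValueError("pert spec requires min < max (degenerate support)")
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    @staticmethod
    def point(value: float) -> "DistributionSpec":
        return DistributionSpec(kind="point", value=float(value))

    @staticmethod
    def pert(min: float, mode: float, max: float) -> "DistributionSpec":
        return DistributionSpec(
            kind="pert", min=float(min), mode=float(mode), max=float(max)
        )

    @property
    def base(self) -> float:
        """Base-case value: the point value, or the PERT mode."""
        return self.value if self.kind == "point" else self.mode  # type: ignore[return-value]

    @property
    def mean(self) -> float:
        if self.kind == "point":
            return self.value  # type: ignore[return-value]
        return (self.min + 4.0 * self.mode + self.max) / 6.0  # type: ignore[operator]

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return self.value  # type: ignore[return-value]
        alpha, beta, lo, hi = pert_to_beta(self)
        return lo + (hi - lo) * rng.beta(alpha, beta)


def pert_to_beta(spec: DistributionSpec) -> Tuple[float, float, float, float]:
    """Convert a PERT(min, mode, max) spec to beta shapes on its support.

    Uses the classic lambda = 4 parameterization::

        alpha = 1 + 4 (mode - min) / (max - min)
        beta  = 1 + 4 (max - mode) / (max - min)

    so the distribution mean is (min + 4 mode + max) / 6.

    Returns
    -------
    (alpha, beta, min, max)
    """
    if spec.kind != "pert":
        raise ValueError("pert_to_beta requires a pert spec")
    span = spec.max - spec.min  # type: ignore[operator]
    alpha = 1.0 + 4.0 * (spec.mode - spec.min) / span  # type: ignore[operator]
    beta = 1.0 + 4.0 * (spec.max - spec.mode) / span  # type: ignore[operator]
    return alpha, beta, spec.min, spec.max  # type: ignore[return-value]


BandMap = Dict[str, DistributionSpec]


# ---------------------------------------------------------------------------
# Parameter set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSet:
    """All model inputs, one authoritative home per symbol.

    Scalar epidemiological/cost parameters are :class:`DistributionSpec`;
    the four-band parameters are mappings keyed by :data:`CD4_BANDS`;
    categorical distributions are plain probability mappings (summing to 1).
    """

    # epidemiology
    mortality_rate_by_cd4_untreated: BandMap  # per 100 person-years
    cd4_decline_no_art: DistributionSpec  # cells/uL/year
    cd4_decline_on_art_failing: DistributionSpec  # cells/uL/year
    cd4_gain_on_art: DistributionSpec  # cells/uL/year
    ltfu_12m_risk_1month: DistributionSpec  # probability / 12 months
    ltfu_rate_community_3m: DistributionSpec  # per 100 person-years
    or_ltfu_3m: DistributionSpec  # odds ratio vs 1-month, 2 years
    or_ltfu_6m: DistributionSpec
    reengage_12m_with_tracing: DistributionSpec  # probability / 12 months
    reengage_12m_without_tracing: DistributionSpec
    pct_first_line: DistributionSpec  # proportion on first-line ARVs
    pct_dolutegravir: DistributionSpec  # share of first line that is DTG
    second_line_failure_rate: DistributionSpec  # per 100 person-years
    annual_switch_risk_dtg: DistributionSpec  # probability / year
    annual_switch_risk_efv: DistributionSpec
    discount_rate: DistributionSpec  # annual fraction
    # health effects
    daly_weight_on_art: BandMap
    daly_weight_off_art: BandMap
    # costs
    facility_cost_1m_annual: DistributionSpec  # USD/person-year excl. ARVs
    community_cost_3m_annual: DistributionSpec
    arv_cost_monthly_dtg: DistributionSpec  # USD/month
    arv_cost_monthly_efv: DistributionSpec
    arv_cost_monthly_second_line: DistributionSpec
    vl_test_cost_annual: DistributionSpec  # USD/person-year
    case_mgmt_cost_monthly: DistributionSpec  # USD/month
    chapa_cost_per_hour: DistributionSpec  # USD/h
    transit_time_distribution: Dict[str, float]  # bands lt60min/m60_240/gt240min
    walk_roundtrip_hours: DistributionSpec
    pct_travel_by_chapa: DistributionSpec
    brigade_distance_fraction: DistributionSpec
    wait_time_hours: DistributionSpec
    oop_health_expenditure_annual: DistributionSpec  # USD/year
    net_national_income_pc: DistributionSpec  # USD/year
    gdp_pc: DistributionSpec  # USD/year
    # populations
    age_distribution: Dict[str, float]
    cd4_distribution_at_init: Dict[str, float]
    n_plhiv: int

    # -- convenience views ------------------------------------------------

    def band_base(self, name: str) -> np.ndarray:
        """Base values of a four-band parameter as an array ordered by CD4_BANDS."""
        m: BandMap = getattr(self, name)
        return np.array([m[b].base for b in CD4_BANDS], dtype=float)

    def cd4_init_probs(self) -> np.ndarray:
        return np.array([self.cd4_distribution_at_init[b] for b in CD4_BANDS])

    def iter_specs(self) -> Iterator[Tuple[str, DistributionSpec]]:
        """Yield (dotted name, spec) for every scalar spec, in field order."""
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, DistributionSpec):
                yield f.name, v
            elif isinstance(v, dict) and v and isinstance(
                next(iter(v.values())), DistributionSpec
            ):
                for k in v:
                    yield f"{f.name}.{k}", v[k]

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def validate(self) -> List[str]:
        """Return a list of human-readable invariant violations (empty if valid)."""
        problems: List[str] = []
        nonneg = [
            "mortality_rate_by_cd4_untreated",
            "cd4_decline_no_art",
            "cd4_decline_on_art_failing",
            "cd4_gain_on_art",
            "ltfu_rate_community_3m",
            "second_line_failure_rate",
            "facility_cost_1m_annual",
            "community_cost_3m_annual",
            "arv_cost_monthly_dtg",
            "arv_cost_monthly_efv",
            "arv_cost_monthly_second_line",
            "vl_test_cost_annual",
            "case_mgmt_cost_monthly",
            "chapa_cost_per_hour",
            "walk_roundtrip_hours",
            "wait_time_hours",
            "oop_health_expenditure_annual",
            "net_national_income_pc",
            "gdp_pc",
            "discount_rate",
            "or_ltfu_3m",
            "or_ltfu_6m",
        ]
        probs = [
            "ltfu_12m_risk_1month",
            "reengage_12m_with_tracing",
            "reengage_12m_without_tracing",
            "pct_first_line",
            "pct_dolutegravir",
            "annual_switch_risk_dtg",
            "annual_switch_risk_efv",
            "pct_travel_by_chapa",
            "brigade_distance_fraction",
        ]
        for name, spec in self.iter_specs():
            base = name.split(".", 1)[0]
            lo = spec.value if spec.kind == "point" else spec.min
            hi = spec.value if spec.kind == "point" else spec.max
            if base in nonneg and lo < 0:  # type: ignore[operator]
                problems.append(f"{name}: must be >= 0, support reaches {lo}")
            if base in probs and (lo < 0 or hi > 1):  # type: ignore[operator]
                problems.append(f"{name}: probability outside [0, 1]")
            if base.startswith("daly_weight") and (lo < 0 or hi > 1):  # type: ignore[operator]
                problems.append(f"{name}: DALY weight outside [0, 1]")
        for name in ("mortality_rate_by_cd4_untreated", "daly_weight_on_art",
                     "daly_weight_off_art"):
            m = getattr(self, name)
            if set(m) != set(CD4_BANDS):
                problems.append(f"{name}: must have exactly the 4 CD4 bands")
        for name in ("age_distribution", "cd4_distribution_at_init",
                     "transit_time_distribution"):
            dist = getattr(self, name)
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                problems.append(f"{name}: probabilities sum to {total:.6f}, not 1")
            if any(v < 0 for v in dist.values()):
                problems.append(f"{name}: negative probability mass")
        if set(self.cd4_distribution_at_init) != set(CD4_BANDS):
            problems.append("cd4_distribution_at_init: must have exactly the 4 CD4 bands")
        if self.n_plhiv < 0:
            problems.append("n_plhiv: must be >= 0")
        return problems


def sample_parameter_set(base: ParameterSet, rng_seed: int) -> ParameterSet:
    """Draw one PSA realization of ``base``.

    Point parameters pass through; PERT parameters are drawn independently
    from their lambda=4 beta distributions. A pure function of (base, seed).
    """
    rng = np.random.default_rng(rng_seed)
    changes: Dict[str, object] = {}
    for f in dataclasses.fields(base):
        v = getattr(base, f.name)
        if isinstance(v, DistributionSpec):
            if v.kind == "pert":
                changes[f.name] = DistributionSpec.point(v.sample(rng))
        elif isinstance(v, dict) and v and isinstance(
            next(iter(v.values())), DistributionSpec
        ):
            if any(s.kind == "pert" for s in v.values()):
                changes[f.name] = {
                    k: (DistributionSpec.point(s.sample(rng)) if s.kind == "pert" else s)
                    for k, s in v.items()
                }
    return base.replace(**changes) if changes else base


def draws_to_frame(draws: Sequence[ParameterSet]):
    """Flatten PSA draws to a DataFrame: one row per draw, one column per parameter."""
    import pandas as pd

    rows = [{name: spec.base for name, spec in ps.iter_specs()} for ps in draws]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Strategies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrategyArm:
    """One delivery arm: where refills happen, how often, and for whom."""

    setting: str  # "clinic" | "community"
    refill_interval_months: int
    allocation: float = 1.0


@dataclass(frozen=True)
class StrategyDefinition:
    """An ARV delivery model.

    All strategies force 1-month clinical refills during the first 3 months
    on ART and while CD4 < 200 (severe-disease proxy). The mixed strategy
    permanently assigns persons to one of its two arms at baseline.
    """

    id: str
    refill_interval_months: int
    setting: str  # "clinic" | "community" | "mixed"
    tracing_enabled: bool = False
    mixed_allocation: float = 1.0
    arms: Tuple[StrategyArm, ...] = ()

    def __post_init__(self) -> None:
        if self.refill_interval_months not in (1, 3, 6):
            raise ValueError("refill_interval_months must be one of 1, 3, 6")
        if not self.arms:
            object.__setattr__(
                self,
                "arms",
                (StrategyArm(self.setting, self.refill_interval_months, 1.0),),
            )
        total = sum(a.allocation for a in self.arms)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"arm allocations sum to {total}, not 1")


def builtin_strategies() -> Dict[str, StrategyDefinition]:
    """The six packaged ARV delivery strategies."""
    return {
        "clinical_1m": StrategyDefinition("clinical_1m", 1, "clinic"),
        "clinical_3m": StrategyDefinition("clinical_3m", 3, "clinic"),
        "clinical_6m": StrategyDefinition("clinical_6m", 6, "clinic"),
        "clinical_3m_case_mgmt": StrategyDefinition(
            "clinical_3m_case_mgmt", 3, "clinic", tracing_enabled=True
        ),
        "community_3m": StrategyDefinition("community_3m", 3, "community"),
        "mixed_6m_community_3m": StrategyDefinition(
            "mixed_6m_community_3m",
            6,
            "mixed",
            mixed_allocation=0.5,
            arms=(
                StrategyArm("clinic", 6, 0.5),
                StrategyArm("community", 3, 0.5),
            ),
        ),
    }


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


def _default_wtp_grid() -> List[float]:
    return [round(float(x), 6) for x in np.geomspace(0.25, 25000.0, 101)]


@dataclass(frozen=True)
class RunConfig:
    n_individuals: int = 200_000
    horizon_years: float = 100.0
    cycle_months: int = 1
    seed: int = 1
    psa_draws: int = 1000
    wtp_grid: Tuple[float, ...] = ()
    wtp_threshold: float | None = None  # defaults to 0.3 x GDP pc
    affordability_threshold: float | None = None  # defaults to annual OOP

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")
        if self.cycle_months != 1:
            raise ValueError("only 1-month cycles are supported")
        if not self.wtp_grid:
            object.__setattr__(self, "wtp_grid", tuple(_default_wtp_grid()))
        grid = np.asarray(self.wtp_grid)
        if not np.all(np.diff(grid) > 0):
            raise ValueError("wtp_grid must be strictly increasing")

    def resolved_wtp_threshold(self, params: ParameterSet) -> float:
        if self.wtp_threshold is not None:
            return self.wtp_threshold
        return 0.3 * params.gdp_pc.base

    def resolved_affordability_threshold(self, params: ParameterSet) -> float:
        if self.affordability_threshold is not None:
            return self.affordability_threshold
        return params.oop_health_expenditure_annual.base


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------

_BANDED_FIELDS = (
    "mortality_rate_by_cd4_untreated",
    "daly_weight_on_art",
    "daly_weight_off_art",
)
_CATEGORICAL_FIELDS = (
    "transit_time_distribution",
    "age_distribution",
    "cd4_distribution_at_init",
)


def _parse_spec(name: str, node, problems: List[str]) -> DistributionSpec | None:
    try:
        if isinstance(node, (int, float)):
            return DistributionSpec.point(float(node))
        if isinstance(node, dict):
            if "value" in node:
                return DistributionSpec.point(float(node["value"]))
            if {"min", "mode", "max"} <= set(node):
                return DistributionSpec.pert(node["min"], node["mode"], node["max"])
        problems.append(f"{name}: malformed distribution {node!r}")
    except (ValueError, TypeError) as exc:
        problems.append(f"{name}: {exc}")
    return None


def _normalize(name: str, dist: Mapping[str, float], problems: List[str]) -> Dict[str, float]:
    total = float(sum(dist.values()))
    if any(v < 0 for v in dist.values()):
        problems.append(f"{name}: negative probability mass")
        return dict(dist)
    if abs(total - 1.0) > 0.02:
        problems.append(f"{name}: probabilities sum to {total:.4f}, not 1")
        return dict(dist)
    if abs(total - 1.0) <= 1e-9:  # already normalized; keep values bit-exact
        return {k: float(v) for k, v in dist.items()}
    return {k: float(v) / total for k, v in dist.items()}


def _parameters_from_mapping(raw: Mapping, problems: List[str]) -> ParameterSet | None:
    kwargs: Dict[str, object] = {}
    for f in dataclasses.fields(ParameterSet):
        if f.name not in raw:
            problems.append(f"parameters.{f.name}: missing field")
            continue
        node = raw[f.name]
        if f.name in _BANDED_FIELDS:
            if not isinstance(node, dict) or set(node) != set(CD4_BANDS):
                problems.append(f"parameters.{f.name}: expected the 4 CD4 bands")
                continue
            parsed = {
                b: _parse_spec(f"parameters.{f.name}.{b}", node[b], problems)
                for b in CD4_BANDS
            }
            if all(v is not None for v in parsed.values()):
                kwargs[f.name] = parsed
        elif f.name in _CATEGORICAL_FIELDS:
            if not isinstance(node, dict):
                problems.append(f"parameters.{f.name}: expected a probability mapping")
                continue
            kwargs[f.name] = _normalize(f"parameters.{f.name}", node, problems)
        elif f.name == "n_plhiv":
            kwargs[f.name] = int(node)
        else:
            spec = _parse_spec(f"parameters.{f.name}", node, problems)
            if spec is not None:
                kwargs[f.name] = spec
    extra = set(raw) - {f.name for f in dataclasses.fields(ParameterSet)}
    for name in sorted(extra):
        problems.append(f"parameters.{name}: unknown field")
    if problems:
        return None
    ps = ParameterSet(**kwargs)  # type: ignore[arg-type]
    problems.extend(ps.validate())
    return None if problems else ps


def validate_config(path: str | Path) -> List[str]:
    """Validate a config file; return diagnostics (empty list means valid)."""
    try:
        load_config(path)
    except ConfigError as exc:
        return list(exc.args[0]) if isinstance(exc.args[0], list) else [str(exc)]
    return []


def load_config(path: str | Path):
    """Load and validate a YAML config.

    Returns
    -------
    (ParameterSet, list[StrategyDefinition], RunConfig)
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(["config root must be a mapping"])
    problems: List[str] = []
    params = _parameters_from_mapping(doc.get("parameters", {}), problems)

    registry = builtin_strategies()
    strategies: List[StrategyDefinition] = []
    for sid in doc.get("strategies", list(STRATEGY_IDS)):
        if sid not in registry:
            problems.append(f"strategies: unknown strategy id {sid!r}")
        else:
            strategies.append(registry[sid])

    run_raw = dict(doc.get("run", {}))
    run = None
    try:
        if "wtp_grid" in run_raw:
            run_raw["wtp_grid"] = tuple(run_raw["wtp_grid"])
        run = RunConfig(**run_raw)
    except (TypeError, ValueError) as exc:
        problems.append(f"run: {exc}")

    if problems:
        raise ConfigError(problems)
    assert params is not None and run is not None
    return params, strategies, run


def _spec_to_node(spec: DistributionSpec):
    if spec.kind == "point":
        return float(spec.value)  # type: ignore[arg-type]
    return {"min": float(spec.min), "mode": float(spec.mode), "max": float(spec.max)}  # type: ignore[arg-type]


def save_config(
    path: str | Path,
    params: ParameterSet,
    strategies: Sequence[StrategyDefinition],
    run: RunConfig,
) -> None:
    """Write a config round-trippable through :func:`load_config`."""
    pdoc: Dict[str, object] = {}
    for f in dataclasses.fields(ParameterSet):
        v = getattr(params, f.name)
        if f.name in _BANDED_FIELDS:
            pdoc[f.name] = {b: _spec_to_node(v[b]) for b in CD4_BANDS}
        elif f.name in _CATEGORICAL_FIELDS:
            pdoc[f.name] = {k: float(x) for k, x in v.items()}
        elif f.name == "n_plhiv":
            pdoc[f.name] = int(v)
        else:
            pdoc[f.name] = _spec_to_node(v)
    doc = {
        "parameters": pdoc,
        "strategies": [s.id for s in strategies],
        "run": {
            "n_individuals": run.n_individuals,
            "horizon_years": run.horizon_years,
            "cycle_months": run.cycle_months,
            "seed": run.seed,
            "psa_draws": run.psa_draws,
            "wtp_grid": [float(x) for x in run.wtp_grid],
            **(
                {"wtp_threshold": run.wtp_threshold}
                if run.wtp_threshold is not None
                else {}
            ),
            **(
                {"affordability_threshold": run.affordability_threshold}
                if run.affordability_threshold is not None
                else {}
            ),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def mozambique_path() -> Path:
    """Path to the packaged Mozambique parameter file."""
    return Path(str(resources.files("perspecta").joinpath("data/mozambique.yaml")))


def load_mozambique():
    """Load the packaged Mozambique case: (ParameterSet, strategies, RunConfig)."""
    return load_config(mozambique_path())


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


def _jitter_pert(rng: np.random.Generator, spec: DistributionSpec,
                 lo_bound: float = 0.0, hi_bound: float | None = None) -> DistributionSpec:
    scale = rng.uniform(0.8, 1.2)
    mode = spec.base * scale
    lo = mode * rng.uniform(0.5, 0.95)
    hi = mode * rng.uniform(1.05, 1.5) + 1e-6
    lo = max(lo, lo_bound)
    if hi_bound is not None:
        hi = min(hi, hi_bound)
        mode = min(mode, hi - 1e-9) if hi > 0 else mode
        lo = min(lo, mode)
    return DistributionSpec.pert(lo, mode, hi)


def make_fixture(seed: int, size: str = "tiny"):
    """Generate a randomized, internally consistent parameter set for tests.

    ``tiny`` uses 500 individuals over a 10-year horizon; ``small`` uses
    2000 individuals over 25 years. Pure function of (seed, size).
    """
    if size not in ("tiny", "small"):
        raise ValueError("size must be 'tiny' or 'small'")
    rng = np.random.default_rng(seed)
    base, strategies, _ = load_mozambique()

    changes: Dict[str, object] = {}
    for f in dataclasses.fields(base):
        v = getattr(base, f.name)
        if isinstance(v, DistributionSpec) and v.kind == "pert":
            name = f.name
            hi = 1.0 if name in (
                "ltfu_12m_risk_1month", "reengage_12m_with_tracing",
                "reengage_12m_without_tracing", "pct_first_line",
                "annual_switch_risk_dtg", "annual_switch_risk_efv",
                "pct_travel_by_chapa", "brigade_distance_fraction",
            ) else None
            changes[name] = _jitter_pert(rng, v, hi_bound=hi)
        elif f.name in _BANDED_FIELDS and f.name == "mortality_rate_by_cd4_untreated":
            changes[f.name] = {b: _jitter_pert(rng, v[b]) for b in CD4_BANDS}
    # random but valid categorical distributions
    cd4 = rng.dirichlet(np.ones(4) * 8.0)
    changes["cd4_distribution_at_init"] = {
        b: float(p) for b, p in zip(CD4_BANDS, cd4 / cd4.sum())
    }
    params = base.replace(**changes)

    n, horizon = (500, 10.0) if size == "tiny" else (2000, 25.0)
    run = RunConfig(
        n_individuals=n,
        horizon_years=horizon,
        seed=int(rng.integers(0, 2**31 - 1)),
        psa_draws=5 if size == "tiny" else 20,
    )
    return params, strategies, run
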