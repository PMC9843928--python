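"""Scenario-grid orchestration: replication loops, power and type-I rates.

The study grid crosses two age ranges (3-6 and 12-16 years) with five
impairment levels (1-5 SD below the normative mean) and every subdomain in
the table set; cells whose target v-scale band is unattainable are skipped
and logged.  Each feasible scenario is replicated (5,000 datasets under the
large-effect condition, 10,000 under the zero-effect condition used for
type I error), every dataset analyzed by ANCOVA on both endpoint scales,
and power estimated as the fraction of two-sided p-values below alpha —
with degenerate fits and complete-floor replications coded as failures to
reject.

Both endpoint scales are computed from the same simulated datasets, so the
GSV/V-scale power comparison is paired within scenario.  Replication streams
are derived from the root seed and a scenario fingerprint, making results
independent of the order in which scenarios are run.
"""

from __future__ import annotations

import logging
import sys
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .generative import (
    AGE_RANGES,
    IMPAIRMENT_VSCALE,
    DesignConfig,
    InfeasibleScenarioError,
    Scenario,
    build_generative_params,
)
from .inference import fit_ancova_batch
from .score_tables import TableSet, load_table_set
from .synthetic_tables import SynthConfig, generate_table_set
from .trial_sim import simulate_trial_batch

__all__ = [
    "ScenarioResult",
    "ConditionSummary",
    "StudyConfig",
    "build_scenario_grid",
    "scenario_rng",
    "run_scenario",
    "summarize_by_condition",
    "run_study",
]

logger = logging.getLogger("abilitysim")

DEFAULT_REPS_EFFECT = 5000
DEFAULT_REPS_NULL = 10000


@dataclass(frozen=True)
class ScenarioResult:
    """Monte-Carlo summary of one scenario."""

    scenario: Scenario
    n_reps: int
    mu_gsv: float
    sigma_gsv: float
    delta: float
    power_gsv: float
    power_vscale: float  # NaN when the v-scale pipeline was not run
    type_i: bool  # True when this is a zero-effect (null) scenario
    floor_rate_vscale: float
    degenerate_rate_gsv: float
    degenerate_rate_vscale: float
    median_diff_gsv: float
    median_diff_vscale: float

    def to_row(self) -> dict:
        s = self.scenario
        row = {
            "age_range": f"{s.age_range[0]}-{s.age_range[1]}",
            "impairment_sd": s.impairment_sd,
            "subdomain": s.subdomain,
            "effect_condition": s.effect_condition,
        }
        row.update(
            {k: v for k, v in asdict(self).items() if k != "scenario"}
        )
        return row


@dataclass(frozen=True)
class ConditionSummary:
    """Per (age range x impairment) summary across subdomains."""

    age_range: tuple[int, int]
    impairment_sd: int
    n_subdomains: int
    median_power_gsv: float
    median_power_vscale: float
    decrease_min: float
    decrease_q1: float
    decrease_median: float
    decrease_q3: float
    decrease_max: float


def build_scenario_grid(
    tables: TableSet,
    design: DesignConfig,
    effect_condition: str = "large",
    age_ranges=None,
    impairments=None,
    subdomains=None,
) -> tuple[list[Scenario], list[tuple[Scenario, str]]]:
    """All feasible scenarios plus a log of skipped (infeasible) cells.

    A cell is infeasible when the generative parameters cannot be built —
    typically because the target v-scale band is absent at the midpoint age
    of the range or of an overlapping normative band.
    """
    age_ranges = list(age_ranges or AGE_RANGES)
    impairments = list(impairments or IMPAIRMENT_VSCALE)
    subdomains = list(subdomains or tables.subdomains)
    grid, skipped = [], []
    for ar in age_ranges:
        for imp in impairments:
            for sd in subdomains:
                scenario = Scenario(tuple(ar), imp, sd, effect_condition)
                try:
                    build_generative_params(tables, scenario, design)
                except InfeasibleScenarioError as exc:
                    skipped.append((scenario, str(exc)))
                    logger.info("skipping %s: %s", scenario.label, exc)
                else:
                    grid.append(scenario)
    return grid, skipped


def scenario_rng(root_seed: int, scenario: Scenario) -> np.random.Generator:
    """Scenario-specific stream: root seed + CRC32 fingerprint of the label.

    Keying on the scenario's identity (not its position in the grid) makes
    results invariant to grid order and to other scenarios being present.
    """
    fingerprint = zlib.crc32(scenario.label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((root_seed, fingerprint)))


def _median_group_diff(endpoint: np.ndarray, arm: np.ndarray) -> float:
    trt = endpoint[:, arm == 1].mean(axis=1)
    pbo = endpoint[:, arm == 0].mean(axis=1)
    return float(np.median(trt - pbo))


def _complete_floor_mask(vb, ve, arm, floor) -> np.ndarray:
    pbo, trt = arm == 0, arm == 1
    pbo_floor = np.all(vb[:, pbo] == floor, axis=1) & np.all(
        ve[:, pbo] == floor, axis=1
    )
    trt_floor = np.all(vb[:, trt] == floor, axis=1) & np.all(
        ve[:, trt] == floor, axis=1
    )
    return pbo_floor | trt_floor


def run_scenario(
    scenario: Scenario,
    tables: TableSet,
    design: DesignConfig,
    n_reps: int,
    root_seed: int,
    compute_vscale: bool = True,
) -> ScenarioResult:
    """Replicate one scenario and estimate power (or type-I rate) per scale."""
    params = build_generative_params(tables, scenario, design)
    rng = scenario_rng(root_seed, scenario)
    batch = simulate_trial_batch(
        params, design, scenario, tables, rng, n_reps,
        convert_vscale=compute_vscale,
    )
    arm = batch["arm"]
    alpha = design.alpha

    fit_g = fit_ancova_batch(batch["gsv_e"], batch["gsv_b"], arm)
    floor_g = _complete_floor_mask(
        batch["gsv_b_tab"], batch["gsv_e_tab"], arm, batch["gsv_min"]
    )
    ok_g = ~fit_g["degenerate"] & ~floor_g
    reject_g = np.zeros(n_reps, dtype=bool)
    reject_g[ok_g] = fit_g["p"][ok_g] < alpha

    power_v = degen_v = floor_v = med_v = float("nan")
    if compute_vscale:
        fit_v = fit_ancova_batch(
            batch["vscale_e"].astype(float), batch["vscale_b"].astype(float), arm
        )
        floor_mask = _complete_floor_mask(
            batch["vscale_b"], batch["vscale_e"], arm, 1
        )
        ok_v = ~fit_v["degenerate"] & ~floor_mask
        reject_v = np.zeros(n_reps, dtype=bool)
        reject_v[ok_v] = fit_v["p"][ok_v] < alpha
        power_v = float(reject_v.mean())
        degen_v = float(fit_v["degenerate"].mean())
        floor_v = float(floor_mask.mean())
        med_v = _median_group_diff(batch["vscale_e"], arm)

    return ScenarioResult(
        scenario=scenario,
        n_reps=n_reps,
        mu_gsv=params.mu_gsv,
        sigma_gsv=params.sigma_gsv,
        delta=params.delta,
        power_gsv=float(reject_g.mean()),
        power_vscale=power_v,
        type_i=scenario.effect_condition == "zero",
        floor_rate_vscale=floor_v,
        degenerate_rate_gsv=float(fit_g["degenerate"].mean()),
        degenerate_rate_vscale=degen_v,
        median_diff_gsv=_median_group_diff(batch["gsv_e"], arm),
        median_diff_vscale=med_v,
    )


def summarize_by_condition(results: list[ScenarioResult]) -> list[ConditionSummary]:
    """Median powers and the five-number summary of the GSV-to-V-scale
    power decrease, per (age range x impairment) condition."""
    by_condition: dict[tuple, list[ScenarioResult]] = {}
    for r in results:
        key = (tuple(r.scenario.age_range), r.scenario.impairment_sd)
        by_condition.setdefault(key, []).append(r)
    out = []
    for (ar, imp), group in sorted(by_condition.items()):
        pg = np.array([g.power_gsv for g in group])
        pv = np.array([g.power_vscale for g in group])
        dec = pg - pv
        out.append(
            ConditionSummary(
                age_range=ar,
                impairment_sd=imp,
                n_subdomains=len(group),
                median_power_gsv=float(np.median(pg)),
                median_power_vscale=float(np.median(pv)),
                decrease_min=float(np.min(dec)),
                decrease_q1=float(np.quantile(dec, 0.25)),
                decrease_median=float(np.median(dec)),
                decrease_q3=float(np.quantile(dec, 0.75)),
                decrease_max=float(np.max(dec)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# study driver

@dataclass
class StudyConfig:
    """Configuration of a full study run (mirrors the YAML config file)."""

    tables_mode: str = "synthetic"  # "synthetic" | "files"
    table_paths: dict = field(default_factory=dict)  # gsv/vscale/sem paths
    synth: SynthConfig | None = None
    design: DesignConfig = field(default_factory=DesignConfig)
    age_ranges: list = field(default_factory=lambda: list(AGE_RANGES))
    impairments: list = field(default_factory=lambda: list(IMPAIRMENT_VSCALE))
    subdomains: list | None = None
    effect_conditions: list = field(default_factory=lambda: ["large", "zero"])
    reps_effect: int = DEFAULT_REPS_EFFECT
    reps_null: int = DEFAULT_REPS_NULL
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        tables = raw.get("tables", {})
        design = DesignConfig(**raw.get("design", {}))
        grid = raw.get("grid", {})
        reps = raw.get("reps", {})
        synth = raw.get("synthetic", {})
        return cls(
            tables_mode=tables.get("mode", "synthetic"),
            table_paths=tables.get("paths", {}),
            synth=SynthConfig(**synth) if synth else None,
            design=design,
            age_ranges=[tuple(a) for a in grid.get("age_ranges", list(AGE_RANGES))],
            impairments=list(grid.get("impairments", list(IMPAIRMENT_VSCALE))),
            subdomains=grid.get("subdomains"),
            effect_conditions=list(
                raw.get("effect_conditions", ["large", "zero"])
            ),
            reps_effect=int(reps.get("effect", DEFAULT_REPS_EFFECT)),
            reps_null=int(reps.get("null", DEFAULT_REPS_NULL)),
            seed=int(raw.get("seed", 0)),
        )

    def load_tables(self) -> TableSet:
        if self.tables_mode == "synthetic":
            synth = self.synth or SynthConfig(seed=self.seed)
            return generate_table_set(synth)
        paths = self.table_paths
        return load_table_set(paths["gsv"], paths["vscale"], paths["sem"])


def run_study(config: StudyConfig, out_dir, reps: int | None = None) -> dict:
    """Run the full grid and write scenario- and condition-level CSVs.

    ``reps`` overrides both replication counts (smoke testing).  Returns the
    scenario results, summaries and skip log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = config.load_tables()
    logger.info(
        "tables: %s, %d subdomains; seed=%d",
        tables.provenance, len(tables.subdomains), config.seed,
    )

    results: list[ScenarioResult] = []
    all_skipped = []
    for condition in config.effect_conditions:
        n_reps = reps or (
            config.reps_null if condition == "zero" else config.reps_effect
        )
        grid, skipped = build_scenario_grid(
            tables, config.design, condition,
            config.age_ranges, config.impairments, config.subdomains,
        )
        all_skipped.extend(skipped)
        for scenario in grid:
            results.append(
                run_scenario(scenario, tables, config.design, n_reps, config.seed)
            )
            logger.info("done %s", scenario.label)

    scen_df = pd.DataFrame([r.to_row() for r in results])
    scen_df.to_csv(out_dir / "scenario_results.csv", index=False)

    effect_results = [r for r in results if not r.type_i]
    summaries = summarize_by_condition(effect_results) if effect_results else []
    cond_df = pd.DataFrame(
        [
            {
                "age_range": f"{c.age_range[0]}-{c.age_range[1]}",
                "impairment_sd": c.impairment_sd,
                "n_subdomains": c.n_subdomains,
                "median_power_gsv": round(c.median_power_gsv, 2),
                "median_power_vscale": round(c.median_power_vscale, 2),
                "decrease_min": round(c.decrease_min, 2),
                "decrease_q1": round(c.decrease_q1, 2),
                "decrease_median": round(c.decrease_median, 2),
                "decrease_q3": round(c.decrease_q3, 2),
                "decrease_max": round(c.decrease_max, 2),
            }
            for c in summaries
        ]
    )
    null_results = [r for r in results if r.type_i]
    if null_results and not effect_results:
        cond_df = pd.DataFrame(
            [
                {
                    "age_range": f"{s.age_range[0]}-{s.age_range[1]}",
                    "impairment_sd": s.impairment_sd,
                    "n_subdomains": s.n_subdomains,
                    "median_type_i_gsv": round(s.median_power_gsv, 3),
                    "median_type_i_vscale": round(s.median_power_vscale, 3),
                }
                for s in summarize_by_condition(null_results)
            ]
        )
    cond_df.to_csv(out_dir / "condition_summary.csv", index=False)

    for scenario, reason in all_skipped:
        logger.info("skipped %s: %s", scenario.label, reason)
    return {"results": results, "summaries": summaries, "skipped": all_skipped}


def _configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
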