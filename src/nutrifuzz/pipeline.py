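"""End-to-end orchestration: data -> ion split -> ANOVA -> training -> rules.

A single :class:`PipelineConfig` drives the whole analysis; every stage is
deterministic given the config and seed, so two runs write byte-identical
stats and rules files.  A failure inside one response's ANOVA or training is
recorded and does not abort the sibling responses; a failure of a whole
stage raises :class:`StageError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asmod import TrainingConfig, train_all_outputs
from .media import MICRO_IONS
from .rules import dominant_rules, extract_rules
from .simulate import OUTPUTS, SimConfig, generate_dataset
from .stats import StatConfig, factorial_anova

__all__ = ["PipelineConfig", "RunReport", "StageError", "run_pipeline"]

REPORT_INPUT_NAMES = {"genotype": "Genotype", "subculture": "Subculture"}


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Exactly one input source: a simulation config, or a factor-table CSV."""

    sim: SimConfig | None = None
    factor_table: str | Path | None = None
    training: TrainingConfig = field(default_factory=TrainingConfig)
    stat: StatConfig = field(default_factory=StatConfig)
    outputs: tuple[str, ...] = OUTPUTS
    min_membership: float = 0.7
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.factor_table is None):
            raise ValueError("provide exactly one input source (sim or factor_table)")


@dataclass
class RunReport:
    """All pipeline products: per-output fit statistics (submodels,
    significant inputs, MSE, R2, f-ratio, df, f-critical), the rule tables,
    ANOVA summaries, and a config/seed echo."""

    stats_table: pd.DataFrame
    rules_table: pd.DataFrame
    anova_table: pd.DataFrame
    results: dict
    rulesets: dict
    truth: object | None
    meta: dict


def _display_input(name: str) -> str:
    return REPORT_INPUT_NAMES.get(name, name)


def _stats_rows(output: str, result, alpha: float) -> list[dict]:
    if result.error is not None:
        return [{"output": output, "submodel": "", "significant_inputs": "",
                 "error": str(result.error)}]
    model, stats = result.model, result.stats
    if model.uninformative:
        return [{"output": output, "submodel": "", "significant_inputs": "(none)",
                 "mse": round(stats.mse, 2), "r2_percent": 0.0, "error": "uninformative"}]
    rows = []
    for j, sm in enumerate(model.submodels, start=1):
        row = {
            "output": output,
            "submodel": j,
            "significant_inputs": " x ".join(_display_input(n) for n in sm.inputs),
        }
        if j == 1:  # quality metrics describe the whole output model
            row.update(
                mse=round(stats.mse, 2),
                r2_percent=round(stats.r2_percent, 2),
                f_ratio=round(stats.f_ratio, 2),
                df=f"{stats.df1}, {stats.df2}",
                f_critical=round(stats.f_critical, 2),
                quality=stats.quality,
            )
        rows.append(row)
    return rows


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and, if ``config.outdir`` is set, write the
    stats/rules/ANOVA CSVs plus a JSON report there."""
    # --- ingest ------------------------------------------------------------
    truth = None
    if config.sim is not None:
        table, truth = generate_dataset(config.sim)
        seed = config.sim.seed
    else:
        try:
            table = pd.read_csv(config.factor_table)
        except Exception as exc:
            raise StageError("ingest", f"cannot read factor table: {exc}") from exc
        seed = config.training.random_seed
    for required in ("genotype", "subculture"):
        if required not in table.columns:
            raise StageError("ingest", f"factor table lacks required column {required!r}")
    outputs = [o for o in config.outputs if o in table.columns]
    missing = [o for o in config.outputs if o not in table.columns]
    if missing and not outputs:
        raise StageError("ingest", f"no requested output columns present (missing {missing})")

    # --- anova (per-response isolation) ------------------------------------
    factors = ["genotype", "medium", "subculture"]
    factors = [f for f in factors if f in table.columns and table[f].nunique() > 1]
    anova_frames = []
    for output in outputs:
        try:
            frame = factorial_anova(table, output, factors=factors)
            frame = frame.reset_index(names="term")
            frame.insert(0, "output", output)
            anova_frames.append(frame)
        except Exception as exc:
            anova_frames.append(
                pd.DataFrame([{"output": output, "term": "(failed)", "error": str(exc)}])
            )
    anova_table = (
        pd.concat(anova_frames, ignore_index=True) if anova_frames else pd.DataFrame()
    )

    # --- train --------------------------------------------------------------
    candidate_inputs = [
        c for c in table.columns
        if c not in OUTPUTS and c not in outputs and c not in ("medium", "replicate")
    ]
    results = train_all_outputs(
        table, outputs, config.training, candidate_inputs=candidate_inputs
    )

    # --- rules ---------------------------------------------------------------
    rulesets = {}
    rule_rows = []
    for output in outputs:
        res = results[output]
        if res.error is not None or res.model is None:
            continue
        ruleset = dominant_rules(extract_rules(res.model), config.min_membership)
        rulesets[output] = ruleset
        for rule in ruleset.rules:
            rule_rows.append(
                {
                    "output": rule.output,
                    "submodel": rule.submodel,
                    "antecedents": " AND ".join(
                        f"{_display_input(n)} is {lab}" for n, lab in rule.antecedents
                    ),
                    "consequent": rule.consequent,
                    "membership": round(rule.membership, 2),
                }
            )
    rules_table = pd.DataFrame(rule_rows)

    # --- report ---------------------------------------------------------------
    stats_rows = []
    for output in outputs:
        stats_rows.extend(_stats_rows(output, results[output], config.stat.alpha_model))
    stats_table = pd.DataFrame(stats_rows)

    meta = {
        "version": __version__,
        "seed": int(seed),
        "outputs": outputs,
        "training": dataclasses.asdict(config.training),
        "stat": dataclasses.asdict(config.stat),
        "min_membership": config.min_membership,
        "source": "simulation" if config.sim is not None else str(config.factor_table),
        "errors": {o: str(results[o].error) for o in outputs if results[o].error},
    }
    report = RunReport(stats_table, rules_table, anova_table, results, rulesets, truth, meta)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stats_table.to_csv(outdir / "stats.csv", index=False)
        rules_table.to_csv(outdir / "rules.csv", index=False)
        anova_table.to_csv(outdir / "anova.csv", index=False)
        models_payload = {
            o: results[o].model.to_dict() for o in outputs if results[o].model is not None
        }
        (outdir / "models.json").write_text(json.dumps(models_payload, indent=1, sort_keys=True))
        (outdir / "report.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return report


def micro_ion_display(ion: str, mM: float) -> str:
    """Format an ion concentration the way results are reported: micronutrient
    ions in uM to two decimals, macronutrient ions in mM to two decimals."""
    if ion in MICRO_IONS:
        return f"{mM * 1000.0:.2f} uM"
    return f"{mM:.2f} mM"
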