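"""Synthetic factorial nutrition datasets with planted interaction structure.

The generator emulates the structure of the *Bryophyllum* mineral-nutrition
experiment: 3 genotypes x 9 MS-based media x 4 subcultures (108 treatments),
six growth responses (SL, RL, PN, LN, AFW, RFW), with ion inputs computed
from the media table and responses built from a catalog of planted effect
surfaces plus homoscedastic Gaussian noise.  The default planted structure
mirrors the interactions the neurofuzzy analysis reports for the real data
(genotype x Cu2+ on shoot length, genotype x SO42- x MoO42- on rooting and
biomass, subculture x Na+ on rooting, genotype x NH4+ on leaf number,
monotone-negative molybdate on root weight), so that downstream recovery of
inputs and rule directions is a meaningful check.

Count-like outputs (PN, LN) are rounded to non-negative integers, and PN is
additionally gated to zero on the media lacking all macronutrients or all
micronutrients, emulating the total inhibition of plantlet formation there.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .asmod import OutputResult
from .media import build_factor_table, load_ms_media, load_salt_registry

__all__ = [
    "PlantedEffect",
    "SimConfig",
    "Truth",
    "OUTPUTS",
    "default_effects",
    "generate_dataset",
    "recovery_report",
]

OUTPUTS = ("SL", "RL", "PN", "LN", "AFW", "RFW")
COUNT_OUTPUTS = ("PN", "LN")
GATED_OUTPUTS = ("PN",)


@dataclass(frozen=True)
class PlantedEffect:
    """One planted response surface: 1-3 active inputs, catalog id, amplitude
    in output units."""

    output: str
    inputs: tuple[str, ...]
    surface: str
    amplitude: float

    def __post_init__(self) -> None:
        if not 1 <= len(self.inputs) <= 3:
            raise ValueError("a planted effect uses 1-3 inputs")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def _tri(z: np.ndarray) -> np.ndarray:
    """Triangular bump peaking at mid-range."""
    return np.maximum(0.0, 1.0 - 2.0 * np.abs(z - 0.5))


def _per_genotype(genotype: np.ndarray, coef: Mapping[str, float]) -> np.ndarray:
    return np.asarray([coef[g] for g in genotype])


# Catalog of effect surfaces.  Each takes (ctx, inputs) where ctx maps
# "genotype" -> level array, "subculture" -> [0,1] array, ion name -> [0,1]
# array, and returns values in roughly [0, 1] before amplitude scaling.
def _surface_linear_up(ctx, inputs):
    return ctx[inputs[0]]


def _surface_linear_down(ctx, inputs):
    return 1.0 - ctx[inputs[0]]


def _surface_genotype_cu_shoot(ctx, inputs):
    # BT elongates only at low copper (toxicity at excess) while BD and BH
    # respond mildly positively; the asymmetry keeps the copper marginal
    # visible so the stepwise learner can reach the tensor term.
    cu = ctx[inputs[1]]
    base = _per_genotype(ctx["genotype"], {"BT": 1.0, "BD": 0.35, "BH": 0.6})
    slope = _per_genotype(ctx["genotype"], {"BT": -0.9, "BD": 0.15, "BH": 0.1})
    return base + slope * cu


def _surface_genotype_sulfate_molybdate(ctx, inputs):
    # Sulfate promotes the response in every genotype (macronutrient arm of
    # the design); molybdate modulates it in the micronutrient arm with a
    # genotype-dependent shape: BT peaks at mid molybdate, BH declines
    # monotonically, BD sits in between.
    s, m = ctx[inputs[1]], ctx[inputs[2]]
    a = _per_genotype(ctx["genotype"], {"BT": 0.45, "BD": 0.55, "BH": 0.65})
    b = _per_genotype(ctx["genotype"], {"BT": 0.55, "BD": 0.25, "BH": 0.0})
    c = _per_genotype(ctx["genotype"], {"BT": 0.0, "BD": 0.20, "BH": 0.35})
    return a * s + b * _tri(m) + c * (1.0 - m) * s


def _surface_subculture_sodium(ctx, inputs):
    # High sodium raises the response in every subculture; a mild increase
    # with subculture number models long-term adaptation.
    return 0.85 * ctx[inputs[1]] + 0.15 * ctx[inputs[0]]


def _surface_genotype_ammonium_leaf(ctx, inputs):
    # Only BT profits from ammonium; BD and BH stay low throughout.
    a = ctx[inputs[1]]
    slope = _per_genotype(ctx["genotype"], {"BT": 0.9, "BD": 0.1, "BH": 0.05})
    base = _per_genotype(ctx["genotype"], {"BT": 0.1, "BD": 0.1, "BH": 0.3})
    return base + slope * a


def _surface_genotype_copper_sulfate_root(ctx, inputs):
    # Root biomass needs sulfate and tolerates copper; low only when both
    # are low, strongest in BH.
    cu, s = ctx[inputs[1]], ctx[inputs[2]]
    coef = _per_genotype(ctx["genotype"], {"BH": 1.0, "BD": 0.8, "BT": 0.55})
    return coef * (0.65 * s + 0.35 * cu - 0.25 * s * cu)


SURFACES: dict[str, Callable] = {
    "linear_up": _surface_linear_up,
    "linear_down": _surface_linear_down,
    "genotype_cu_shoot": _surface_genotype_cu_shoot,
    "genotype_sulfate_molybdate": _surface_genotype_sulfate_molybdate,
    "subculture_sodium": _surface_subculture_sodium,
    "genotype_ammonium_leaf": _surface_genotype_ammonium_leaf,
    "genotype_copper_sulfate_root": _surface_genotype_copper_sulfate_root,
}

# Baseline levels (output units) added to every treatment.
DEFAULT_BASELINES = {"SL": 0.5, "RL": 0.3, "PN": 2.0, "LN": 3.0, "AFW": 0.10, "RFW": 0.005}

# Monotone planted directions used by the recovery report (+1 up, -1 down).
DEFAULT_DIRECTIONS = {
    "SL": {"NH4+": +1},
    "RL": {"Na+": +1},
    "PN": {"Na+": +1},
    "LN": {"NH4+": +1},
    "AFW": {},
    "RFW": {"MoO42-": -1},
}


def default_effects() -> dict[str, list[PlantedEffect]]:
    """The default planted structure, mirroring the reported interactions."""
    return {
        "SL": [
            PlantedEffect("SL", ("genotype", "Cu2+"), "genotype_cu_shoot", 3.0),
            PlantedEffect("SL", ("NH4+",), "linear_up", 1.5),
        ],
        "RL": [
            PlantedEffect("RL", ("genotype", "SO42-", "MoO42-"), "genotype_sulfate_molybdate", 3.0),
            PlantedEffect("RL", ("subculture", "Na+"), "subculture_sodium", 1.5),
        ],
        "PN": [
            PlantedEffect("PN", ("genotype", "SO42-", "MoO42-"), "genotype_sulfate_molybdate", 18.0),
            PlantedEffect("PN", ("subculture", "Na+"), "subculture_sodium", 7.0),
        ],
        "LN": [
            PlantedEffect("LN", ("genotype", "NH4+"), "genotype_ammonium_leaf", 9.0),
        ],
        "AFW": [
            PlantedEffect("AFW", ("genotype", "SO42-", "MoO42-"), "genotype_sulfate_molybdate", 1.2),
        ],
        "RFW": [
            PlantedEffect("RFW", ("genotype", "Cu2+", "SO42-"), "genotype_copper_sulfate_root", 0.08),
            PlantedEffect("RFW", ("MoO42-",), "linear_down", 0.03),
        ],
    }


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults reproduce the experimental design: 3 genotypes x the nine
    MS-based media x 4 subcultures, treatment means of 20 replicates, the
    default planted effect structure, and Gaussian noise with standard
    deviation equal to ``noise_fraction`` of each output's signal range.
    """

    genotypes: tuple[str, ...] = ("BD", "BH", "BT")
    media: Sequence | None = None  # None -> the packaged nine-media table
    subcultures: int = 4
    replicates: int = 20
    means_only: bool = True
    effects: Mapping[str, list[PlantedEffect]] | None = None
    baselines: Mapping[str, float] | None = None
    noise_fraction: float = 0.10
    seed: int = 42

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class Truth:
    """Ground truth recorded alongside a generated dataset."""

    effects: dict[str, list[PlantedEffect]]
    active_inputs: dict[str, tuple[str, ...]]
    directions: dict[str, dict[str, int]]
    signal_ranges: dict[str, float]
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "active_inputs": {k: list(v) for k, v in self.active_inputs.items()},
            "directions": self.directions,
            "signal_ranges": self.signal_ranges,
            "effects": {
                k: [
                    {"inputs": list(e.inputs), "surface": e.surface, "amplitude": e.amplitude}
                    for e in v
                ]
                for k, v in self.effects.items()
            },
        }


def _normalized_context(table: pd.DataFrame) -> dict:
    ctx: dict = {"genotype": table["genotype"].to_numpy()}
    ctx["subculture"] = (table["subculture"].to_numpy(dtype=float) - table["subculture"].min()) / max(
        1.0, float(table["subculture"].max() - table["subculture"].min())
    )
    for col in table.columns:
        if col in ("genotype", "medium", "subculture"):
            continue
        x = table[col].to_numpy(dtype=float)
        span = x.max() - x.min()
        ctx[col] = (x - x.min()) / span if span > 0 else np.zeros_like(x)
    return ctx


def generate_dataset(config: SimConfig | None = None) -> tuple[pd.DataFrame, Truth]:
    """Generate a factorial dataset with responses, plus its ground truth.

    Responses are the sum of the planted effect surfaces (evaluated on
    normalized ion and factor values, scaled by their amplitudes) plus a
    baseline and Gaussian noise; identical seed and config give a
    bit-identical table.
    """
    if config is None:
        config = SimConfig()
    registry = load_salt_registry()
    media = list(config.media) if config.media is not None else load_ms_media()
    subcultures = list(range(1, config.subcultures + 1))
    design = build_factor_table(config.genotypes, media, subcultures, registry)

    effects = dict(config.effects) if config.effects is not None else default_effects()
    baselines = dict(DEFAULT_BASELINES)
    if config.baselines:
        baselines.update(config.baselines)

    for output, effect_list in effects.items():
        for effect in effect_list:
            for name in effect.inputs:
                if name not in design.columns:
                    raise ValueError(
                        f"planted effect for {output!r} references input {name!r} "
                        "absent from the design"
                    )

    ctx = _normalized_context(design)
    # viability gate: no plantlets form when all macro- or all micronutrients
    # are absent (detected via representative macro and micro ions)
    gate = ((design["NH4+"] > 0) & (design["Mn2+"] > 0)).to_numpy(dtype=float)

    n = len(design)
    reps = 1 if config.means_only else config.replicates
    table = design.loc[design.index.repeat(reps)].reset_index(drop=True)
    if not config.means_only:
        table.insert(3, "replicate", np.tile(np.arange(1, reps + 1), n))

    rng = np.random.default_rng(config.seed)
    active: dict[str, tuple[str, ...]] = {}
    ranges: dict[str, float] = {}
    outputs = [o for o in OUTPUTS if o in effects] + [
        o for o in effects if o not in OUTPUTS
    ]
    for output in outputs:
        signal = np.full(n, baselines.get(output, 0.0))
        for effect in effects[output]:
            signal = signal + effect.amplitude * SURFACES[effect.surface](ctx, effect.inputs)
        if output in GATED_OUTPUTS:
            signal = signal * gate
        span = float(signal.max() - signal.min())
        scale = span if span > 0 else 1.0  # pure-noise outputs get unit scale
        sd = config.noise_fraction * scale

        values = np.repeat(signal, reps)
        if sd > 0:
            values = values + rng.normal(0.0, sd, size=n * reps)
        if output in COUNT_OUTPUTS:
            values = np.maximum(0.0, np.round(values))
        table[output] = values
        active[output] = tuple(sorted({i for e in effects[output] for i in e.inputs}))
        ranges[output] = span

    truth = Truth(
        effects=effects,
        active_inputs=active,
        directions={o: dict(DEFAULT_DIRECTIONS.get(o, {})) for o in outputs},
        signal_ranges=ranges,
        seed=config.seed,
    )
    return table, truth


def _partial_dependence_sign(model, name: str) -> int:
    """Sign of the model's partial dependence of a continuous input over its
    domain, averaging over categorical inputs and holding other continuous
    inputs at mid-range."""
    specs = model.input_specs
    cat_specs = [s for s in specs.values() if s.kind == "categorical"]
    combos = list(itertools.product(*[s.domain for s in cat_specs])) if cat_specs else [()]
    diffs = []
    for combo in combos:
        # frame in normalized coordinates: target input at its extremes,
        # other continuous inputs at mid-range
        rows = {}
        for s in specs.values():
            if s.kind == "categorical":
                level = combo[[c.name for c in cat_specs].index(s.name)]
                rows[s.name] = [level, level]
            elif s.name == name:
                rows[s.name] = [0.0, 1.0]
            else:
                rows[s.name] = [0.5, 0.5]
        at_lo, at_hi = model.predict(pd.DataFrame(rows))
        diffs.append(at_hi - at_lo)
    return int(np.sign(float(np.mean(diffs))))


def _design_correlation(table: pd.DataFrame, a: str, b: str) -> float:
    """Pearson correlation of two design columns (0 for factor columns)."""
    if a == b:
        return 1.0
    factor_cols = ("genotype", "subculture", "medium")
    if a in factor_cols or b in factor_cols:
        return 0.0
    x = table[a].to_numpy(dtype=float)
    y = table[b].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def recovery_report(
    results: Mapping[str, OutputResult],
    truth: Truth,
    table: pd.DataFrame | None = None,
    collinearity: float = 0.95,
) -> dict:
    """Compare trained models with the planted ground truth.

    Per output: recall of planted inputs, count of false (spurious) inputs,
    and agreement of the model's monotone directions with the planted signs;
    plus aggregate means.  Because the dilution design moves whole salt
    groups together, many ion columns are (nearly) collinear and the planted
    ion is not identifiable from its proxies; a selected input therefore
    counts as recovering a planted input when their design columns correlate
    with |r| >= ``collinearity`` (factor inputs require an exact match).
    ``table`` supplies the design for these correlations (default: the
    packaged design).  Models and truth must cover the same outputs.
    """
    missing = set(truth.active_inputs) - set(results)
    if missing:
        raise ValueError(f"no trained model for outputs {sorted(missing)}")
    if table is None:
        registry = load_salt_registry()
        table = build_factor_table(
            ("BD", "BH", "BT"), load_ms_media(), [1, 2, 3, 4], registry
        )

    def matches(selected: str, planted: str) -> bool:
        return abs(_design_correlation(table, selected, planted)) >= collinearity

    per_output = {}
    for output, planted in truth.active_inputs.items():
        res = results[output]
        if res.error is not None or res.model is None:
            per_output[output] = {"recall": 0.0, "false_inputs": 0, "error": str(res.error)}
            continue
        selected = set(res.model.active_inputs)
        planted_set = set(planted)
        recovered = {
            t for t in planted_set if any(matches(s, t) for s in selected)
        }
        false_inputs = {
            s for s in selected if not any(matches(s, t) for t in planted_set)
        }
        recall = len(recovered) / len(planted_set) if planted_set else 1.0
        hits, total = 0, 0
        for name, sign in truth.directions.get(output, {}).items():
            total += 1
            proxies = sorted(s for s in selected if matches(s, name))
            if not proxies:
                continue
            proxy = name if name in proxies else proxies[0]
            flip = 1 if proxy == name else int(
                np.sign(_design_correlation(table, proxy, name))
            )
            if _partial_dependence_sign(res.model, proxy) * flip == sign:
                hits += 1
        per_output[output] = {
            "recall": recall,
            "false_inputs": len(false_inputs),
            "direction_agreement": hits / total if total else None,
            "r2_percent": res.stats.r2_percent if res.stats else None,
            "quality": res.stats.quality if res.stats else None,
        }
    recalls = [v["recall"] for v in per_output.values()]
    return {
        "per_output": per_output,
        "mean_recall": float(np.mean(recalls)),
        "total_false_inputs": int(
            sum(v.get("false_inputs", 0) for v in per_output.values())
        ),
    }
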