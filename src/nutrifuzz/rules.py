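"""Linguistic IF-THEN rules read out of trained B-spline submodels.

Order-2 B-spline basis functions are triangular fuzzy sets, so each
continuous input of a submodel induces an ordered linguistic partition
(Low / Mid / High...), and categorical inputs contribute their level names.
Each combination of antecedent labels is evaluated at its characteristic
point (the basis-function peaks), positioned within the model's fitted-value
range, and emitted as a rule whose consequent is High (membership m) when
the normalized position m is >= 0.5, otherwise Low (membership 1 - m).
Memberships of the two consequents always sum to one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .asmod import AdditiveModel, InputSpec, Submodel

__all__ = [
    "LinguisticPartition",
    "Rule",
    "RuleSet",
    "linguistic_partition",
    "extract_rules",
    "dominant_rules",
]


@dataclass(frozen=True)
class LinguisticPartition:
    """Ordered fuzzy labels for one submodel input.

    For continuous inputs, ``supports`` maps each label to the interval of
    the original units where its triangular set is non-zero (neighbouring
    labels overlap); ``peaks`` maps each label to the point of full
    membership.  Categorical inputs use their level names with no supports.
    """

    input: str
    kind: str
    labels: tuple[str, ...]
    peaks: tuple | None = None
    supports: tuple[tuple[float, float], ...] | None = None


def _labels_for(count: int) -> tuple[str, ...]:
    if count < 2:
        raise ValueError("a linguistic partition needs at least two sets")
    if count == 2:
        return ("Low", "High")
    if count == 3:
        return ("Low", "Mid", "High")
    mids = tuple(f"Mid{i}" for i in range(1, count - 1))
    return ("Low", *mids, "High")


def linguistic_partition(submodel: Submodel, input_name: str, spec: InputSpec) -> LinguisticPartition:
    """Label the basis functions of one submodel input in knot order."""
    bases = dict(submodel.bases)
    if input_name not in bases:
        raise KeyError(f"{input_name!r} is not an input of this submodel")
    knots = bases[input_name]
    if knots is None:
        return LinguisticPartition(input_name, "categorical", tuple(str(v) for v in spec.domain))
    lo, hi = spec.domain

    def orig(t: float) -> float:
        return lo + t * (hi - lo)

    k = len(knots)
    labels = _labels_for(k)
    peaks = tuple(orig(t) for t in knots)
    supports = tuple(
        (orig(knots[max(i - 1, 0)]), orig(knots[min(i + 1, k - 1)])) for i in range(k)
    )
    return LinguisticPartition(input_name, "continuous", labels, peaks, supports)


@dataclass(frozen=True)
class Rule:
    """One IF-THEN rule: antecedent labels -> output Low/High with membership."""

    output: str
    submodel: int
    antecedents: tuple[tuple[str, str], ...]
    consequent: str
    membership: float
    value: float  # the submodel-plus-context prediction at the antecedent point

    def as_text(self) -> str:
        ifs = " AND ".join(f"{name} is {label}" for name, label in self.antecedents)
        return f"IF {ifs} THEN {self.output} is {self.consequent} ({self.membership:.2f})"


@dataclass
class RuleSet:
    """Rules grouped by output and submodel, with provenance and flags."""

    output: str
    rules: list[Rule] = field(default_factory=list)
    partitions: dict[int, dict[str, LinguisticPartition]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        records = [
            {
                "output": r.output,
                "submodel": r.submodel,
                **{name: label for name, label in r.antecedents},
                "consequent": r.consequent,
                "membership": r.membership,
            }
            for r in self.rules
        ]
        return pd.DataFrame(records)


def extract_rules(
    model: AdditiveModel,
    output_range: tuple[float, float] | None = None,
) -> RuleSet:
    """Read the fuzzy rule table out of a trained additive model.

    For each submodel and each combination of antecedent labels, the
    submodel is evaluated at the combination's characteristic point (basis
    peaks; categorical level), the model bias and the mean contribution of
    the other submodels are added, and the result v is normalized against
    the model's fitted-value range (``output_range`` overrides it) to
    ``m = (v - v_min) / (v_max - v_min)``.  The rule's consequent is High
    with membership m when m >= 0.5, else Low with membership 1 - m, so the
    two consequent memberships of any combination sum to one.
    """
    ruleset = RuleSet(output=model.output, provenance={"bias": model.bias})
    if not model.submodels:
        ruleset.flags.append("uninformative-model")
        return ruleset
    v_min, v_max = output_range if output_range is not None else model.fitted_range
    flat = not v_max > v_min
    if flat:
        ruleset.flags.append("flat-submodel")
    for j, sm in enumerate(model.submodels):
        parts = {
            name: linguistic_partition(sm, name, model.input_specs[name])
            for name, _ in sm.bases
        }
        ruleset.partitions[j] = parts
        sizes = sm.basis_sizes(model.input_specs)
        weights = np.asarray(sm.weights).reshape(sizes)
        context = model.bias + sum(
            mean for k, mean in enumerate(model.submodel_means) if k != j
        )
        names = [name for name, _ in sm.bases]
        label_axes = [parts[name].labels for name in names]
        for idx in itertools.product(*(range(s) for s in sizes)):
            v = float(weights[idx]) + context
            if flat:
                m = 0.5
            else:
                m = float(np.clip((v - v_min) / (v_max - v_min), 0.0, 1.0))
            consequent = "High" if m >= 0.5 else "Low"
            membership = m if m >= 0.5 else 1.0 - m
            antecedents = tuple(
                (name, label_axes[a][idx[a]]) for a, name in enumerate(names)
            )
            ruleset.rules.append(
                Rule(model.output, j + 1, antecedents, consequent, membership, v)
            )
    return ruleset


def dominant_rules(ruleset: RuleSet, min_membership: float) -> RuleSet:
    """Filter to rules with membership >= threshold, keeping stable order."""
    if not 0.0 <= min_membership <= 1.0:
        raise ValueError("min_membership must be in [0, 1]")
    kept = [r for r in ruleset.rules if r.membership >= min_membership]
    return RuleSet(
        output=ruleset.output,
        rules=kept,
        partitions=ruleset.partitions,
        flags=list(ruleset.flags),
        provenance={**ruleset.provenance, "min_membership": min_membership},
    )
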