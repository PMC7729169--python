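"""ASMOD: adaptive B-spline modeling of data with complexity-penalized selection.

The learner builds an additive model

    y = bias + f_1(x_a) + f_2(x_b, x_c) + ...

where each submodel f_j is a tensor product of per-input order-2 B-spline
bases (categorical inputs use indicator bases).  Structure is found by a
stepwise search — add a univariate submodel, merge two submodels into a
tensor product (up to three inputs), insert a knot on a continuous input, or
prune — accepting at each step the move that most improves a
complexity-penalized criterion.  The default criterion is a structural risk
minimization (SRM) guaranteed-risk bound; MDL, BIC, k-fold CV and LOOCV are
available alternatives.  Weights are fitted by ridge regression throughout.

The module exposes both a functional surface (:func:`asmod_search`,
:func:`train_all_outputs`) and a scikit-learn estimator
(:class:`ASMODRegressor`) wrapping it.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .splines import hat_basis, initial_knots, insert_node, one_hot, tensor_basis

__all__ = [
    "TrainingConfig",
    "InputSpec",
    "Submodel",
    "AdditiveModel",
    "FitStats",
    "InsufficientDFError",
    "infer_input_specs",
    "normalize_inputs",
    "basis_activations",
    "fit_weights",
    "fit_stats",
    "criterion_score",
    "effective_parameters",
    "asmod_search",
    "train_all_outputs",
    "ASMODRegressor",
]

MODEL_SCHEMA_VERSION = 1

_CRITERIA = ("SRM", "MDL", "BIC", "CV", "LOOCV")


class InsufficientDFError(ValueError):
    """Fit statistics require more observations than coefficients."""


@dataclass
class TrainingConfig:
    """Training parameters for the neurofuzzy learner.

    Defaults follow the published training setup: ridge factor 1e-6, SRM
    selection with C1 = 0.95 and C2 = 4.8, two initial fuzzy sets per
    continuous input, node adaptation enabled, at most three inputs per
    submodel and fifteen nodes per input, order-2 (triangular) splines.
    """

    ridge_factor: float = 1e-6
    model_selection: str = "SRM"
    srm_c1: float = 0.95
    srm_c2: float = 4.8
    initial_set_density: int = 2
    adapt_nodes: bool = True
    max_inputs_per_submodel: int = 3
    max_nodes_per_input: int = 15
    spline_order: int = 2
    cv_folds: int = 5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.ridge_factor <= 0:
            raise ValueError("ridge_factor must be positive")
        if self.model_selection not in _CRITERIA:
            raise ValueError(f"model_selection must be one of {_CRITERIA}")
        if not 2 <= self.initial_set_density <= self.max_nodes_per_input:
            raise ValueError("initial_set_density must be in [2, max_nodes_per_input]")
        if self.max_inputs_per_submodel < 1:
            raise ValueError("max_inputs_per_submodel must be >= 1")
        if self.spline_order != 2:
            raise ValueError("only order-2 (piecewise-linear) splines are supported")


@dataclass(frozen=True)
class InputSpec:
    """A candidate input: continuous with an observed domain, or categorical."""

    name: str
    kind: str  # "continuous" | "categorical"
    domain: tuple  # (min, max) for continuous; level tuple for categorical

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            lo, hi = self.domain
            if not lo < hi:
                raise ValueError(f"{self.name}: degenerate continuous domain {self.domain}")
        elif self.kind == "categorical":
            if len(self.domain) < 2:
                raise ValueError(f"{self.name}: categorical input needs >= 2 levels")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class Submodel:
    """One additive term: 1-3 inputs, per-input basis, optional fitted weights.

    ``bases`` maps input name -> knot tuple (continuous) or None (categorical,
    which uses the indicator basis over the input's levels).
    """

    inputs: tuple[str, ...]
    bases: tuple[tuple[str, tuple | None], ...]
    weights: tuple[float, ...] | None = None

    @staticmethod
    def make(bases: Mapping[str, tuple | None], weights=None) -> "Submodel":
        items = tuple(sorted(bases.items()))
        return Submodel(tuple(k for k, _ in items), items, weights)

    def basis_sizes(self, specs: Mapping[str, InputSpec]) -> list[int]:
        return [
            len(knots) if knots is not None else len(specs[name].domain)
            for name, knots in self.bases
        ]

    def size(self, specs: Mapping[str, InputSpec]) -> int:
        return int(np.prod(self.basis_sizes(specs)))


@dataclass
class AdditiveModel:
    """A fitted additive spline model for one output."""

    output: str
    input_specs: dict[str, InputSpec]
    submodels: list[Submodel]
    bias: float
    output_range: tuple[float, float]
    fitted_range: tuple[float, float]
    submodel_means: list[float]
    uninformative: bool = False

    @property
    def active_inputs(self) -> list[str]:
        return sorted({name for sm in self.submodels for name in sm.inputs})

    def predict_components(self, normalized: pd.DataFrame) -> np.ndarray:
        """Per-submodel contributions, shape ``(n, n_submodels)``."""
        n = len(normalized)
        out = np.zeros((n, len(self.submodels)))
        for j, sm in enumerate(self.submodels):
            design = basis_activations(sm, normalized, self.input_specs)
            out[:, j] = design @ np.asarray(sm.weights)
        return out

    def predict(self, normalized: pd.DataFrame) -> np.ndarray:
        if not self.submodels:
            return np.full(len(normalized), self.bias)
        return self.bias + self.predict_components(normalized).sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "output": self.output,
            "bias": self.bias,
            "output_range": list(self.output_range),
            "fitted_range": list(self.fitted_range),
            "submodel_means": list(self.submodel_means),
            "uninformative": self.uninformative,
            "input_specs": [
                {"name": s.name, "kind": s.kind, "domain": list(s.domain)}
                for s in self.input_specs.values()
            ],
            "submodels": [
                {
                    "bases": [
                        {"input": name, "knots": list(k) if k is not None else None}
                        for name, k in sm.bases
                    ],
                    "weights": list(sm.weights),
                }
                for sm in self.submodels
            ],
        }

    @staticmethod
    def from_dict(payload: dict) -> "AdditiveModel":
        if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {payload.get('schema_version')!r}")
        specs = {
            s["name"]: InputSpec(s["name"], s["kind"], tuple(s["domain"]))
            for s in payload["input_specs"]
        }
        submodels = [
            Submodel.make(
                {b["input"]: tuple(b["knots"]) if b["knots"] is not None else None
                 for b in sm["bases"]},
                weights=tuple(sm["weights"]),
            )
            for sm in payload["submodels"]
        ]
        return AdditiveModel(
            output=payload["output"],
            input_specs=specs,
            submodels=submodels,
            bias=payload["bias"],
            output_range=tuple(payload["output_range"]),
            fitted_range=tuple(payload["fitted_range"]),
            submodel_means=list(payload["submodel_means"]),
            uninformative=payload["uninformative"],
        )


@dataclass
class FitStats:
    """Goodness-of-fit summary for one trained output.

    ``mse`` is the mean squared training error; ``r2_percent`` the train-set
    coefficient of determination in percent; ``f_ratio`` the regression mean
    square over the residual mean square, compared against the F critical
    value at ``alpha``.  ``quality`` applies the acceptance gate: accepted if
    R2 > 70% and the f-ratio exceeds both 4 and the critical value, rejected
    as overfitted if R2 > 99.9%.
    """

    n: int
    p: int
    mse: float
    r2_percent: float
    f_ratio: float
    df1: int
    df2: int
    f_critical: float
    quality: str


def infer_input_specs(
    table: pd.DataFrame,
    inputs: Sequence[str],
    categorical: Sequence[str] = (),
) -> dict[str, InputSpec]:
    """Derive :class:`InputSpec` per column; constant continuous columns are
    dropped with a warning (they carry no information for the learner)."""
    specs: dict[str, InputSpec] = {}
    for name in inputs:
        col = table[name]
        if name in categorical or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = tuple(
                v.item() if hasattr(v, "item") else v
                for v in sorted(col.unique(), key=str)
            )
            specs[name] = InputSpec(name, "categorical", levels)
        else:
            lo, hi = float(col.min()), float(col.max())
            if not lo < hi:
                warnings.warn(f"dropping constant input {name!r}", stacklevel=2)
                continue
            specs[name] = InputSpec(name, "continuous", (lo, hi))
    return specs


def normalize_inputs(table: pd.DataFrame, specs: Mapping[str, InputSpec]) -> pd.DataFrame:
    """Affinely map continuous inputs onto [0, 1] over their spec domain.

    Categorical columns pass through.  Values outside the domain (new data
    beyond the training range) are clamped with a warning.
    """
    out = pd.DataFrame(index=table.index)
    for name, spec in specs.items():
        if spec.kind == "categorical":
            out[name] = table[name]
            continue
        lo, hi = spec.domain
        z = (table[name].to_numpy(dtype=float) - lo) / (hi - lo)
        if (z < -1e-9).any() or (z > 1 + 1e-9).any():
            warnings.warn(f"clamping {name!r} values outside the training domain", stacklevel=2)
        out[name] = np.clip(z, 0.0, 1.0)
    return out


def basis_activations(
    submodel: Submodel,
    normalized: pd.DataFrame,
    specs: Mapping[str, InputSpec],
) -> np.ndarray:
    """Tensor-product basis activations for each row; rows sum to one."""
    blocks = []
    for name, knots in submodel.bases:
        spec = specs[name]
        if knots is None:
            blocks.append(one_hot(spec.domain, normalized[name].to_numpy()))
        else:
            blocks.append(hat_basis(knots, normalized[name].to_numpy(dtype=float)))
    return tensor_basis(blocks)


def fit_weights(design: np.ndarray, y: np.ndarray, ridge_factor: float) -> np.ndarray:
    """Ridge solution of ``min ||y - Xw||^2 + ridge_factor ||w||^2``."""
    x = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    gram = x.T @ x + ridge_factor * np.eye(x.shape[1])
    return linalg.solve(gram, x.T @ y, assume_a="pos")


def effective_parameters(sizes: Sequence[int]) -> int:
    """Count of distinct model coefficients for submodels with these basis sizes.

    One global bias plus all basis coefficients, with one constant-function
    redundancy absorbed per submodel after the first (every tensor-product
    spline basis spans the constant).  This bookkeeping reproduces the
    published degrees of freedom, e.g. a 3x2 submodel plus a 2-set submodel
    gives p = 8 (df1 = 7), while a single 3x2 submodel gives p = 7 (df1 = 6).
    """
    s = len(sizes)
    if s == 0:
        return 1
    return int(sum(sizes)) + 2 - s


def fit_stats(
    y: np.ndarray,
    y_pred: np.ndarray,
    p: int,
    alpha: float = 0.05,
) -> FitStats:
    """Train-set MSE, R2 (percent), f-ratio and the quality gate.

    ``f_ratio = (R2/df1) / ((100-R2)/df2)`` with df1 = p-1, df2 = n-p, using
    the unrounded R2.
    """
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = y.size
    if n <= p:
        raise InsufficientDFError(f"n={n} observations cannot support p={p} coefficients")
    sse = float(np.sum((y - y_pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    mse = sse / n
    r2 = (1.0 - sse / sst) * 100.0 if sst > 0 else 0.0
    df1, df2 = p - 1, n - p
    if df1 >= 1 and r2 < 100.0:
        f_ratio = (r2 / df1) / ((100.0 - r2) / df2)
    else:
        f_ratio = np.inf if r2 >= 100.0 else np.nan
    f_crit = float(sps.f.ppf(1.0 - alpha, df1, df2)) if df1 >= 1 else np.nan
    if r2 > 99.9:
        quality = "rejected_overfit"
    elif r2 > 70.0 and f_ratio > 4.0 and f_ratio > f_crit:
        quality = "accepted"
    else:
        quality = "rejected_low"
    return FitStats(n, p, mse, r2, f_ratio, df1, df2, f_crit, quality)


def criterion_score(mse: float, p: int, n: int, config: TrainingConfig) -> float:
    """Complexity-penalized selection score (lower is better).

    SRM uses the guaranteed-risk form ``MSE / max(1 - sqrt(eps), 1e-6)`` with
    ``eps = C1 * (p * (ln(2n/p) + 1) + C2) / n``; the score is +inf once the
    capacity term reaches one (the structure is too rich for n).  MDL is
    ``(n/2) ln MSE + (p/2) ln n`` and BIC ``n ln MSE + p ln n``.  The CV and
    LOOCV criteria are data-dependent and computed inside the search.
    """
    if p < 1 or n < 1:
        raise ValueError("p and n must be positive")
    kind = config.model_selection
    if kind == "SRM":
        if mse == 0.0:
            return 0.0
        eps = config.srm_c1 * (p * (np.log(2.0 * n / p) + 1.0) + config.srm_c2) / n
        denom = 1.0 - np.sqrt(eps)
        if denom <= 0.0:
            return np.inf
        return mse / max(denom, 1e-6)
    safe_mse = max(mse, 1e-300)
    if kind == "MDL":
        return (n / 2.0) * np.log(safe_mse) + (p / 2.0) * np.log(n)
    if kind == "BIC":
        return n * np.log(safe_mse) + p * np.log(n)
    raise ValueError(f"{kind} is a data-dependent criterion; use asmod_search")


# ---------------------------------------------------------------------------
# structure search


def _structure_key(structure: tuple[Submodel, ...]) -> tuple:
    return tuple(sorted(sm.bases for sm in structure))


def _build_design(structure, normalized, specs):
    n = len(normalized)
    blocks = [np.ones((n, 1))]
    for sm in structure:
        blocks.append(basis_activations(sm, normalized, specs))
    return np.hstack(blocks)


class _Fitter:
    """Fits and scores candidate structures, caching by canonical key."""

    def __init__(self, normalized, y, specs, config, folds=None):
        self.normalized = normalized
        self.y = np.asarray(y, dtype=float)
        self.n = len(self.y)
        self.specs = specs
        self.config = config
        self.folds = folds  # list of index arrays, for the CV criterion
        self._cache: dict[tuple, tuple] = {}

    def fit(self, structure: tuple[Submodel, ...]):
        """Return (score, p, mse, weights, design) for a structure."""
        key = _structure_key(structure)
        if key in self._cache:
            return self._cache[key]
        design = _build_design(structure, self.normalized, self.specs)
        w = fit_weights(design, self.y, self.config.ridge_factor)
        resid = self.y - design @ w
        mse = float(np.mean(resid**2))
        sizes = [sm.size(self.specs) for sm in structure]
        p = effective_parameters(sizes)
        score = self._score(design, w, resid, mse, p)
        result = (score, p, mse, w, design)
        self._cache[key] = result
        return result

    def _score(self, design, w, resid, mse, p):
        kind = self.config.model_selection
        if kind in ("SRM", "MDL", "BIC"):
            return criterion_score(mse, p, self.n, self.config)
        if kind == "LOOCV":
            gram = design.T @ design + self.config.ridge_factor * np.eye(design.shape[1])
            hat_diag = np.einsum("ij,ji->i", design, linalg.solve(gram, design.T, assume_a="pos"))
            denom = 1.0 - hat_diag
            if np.any(denom < 1e-10):
                return np.inf
            return float(np.mean((resid / denom) ** 2))
        # k-fold CV on pre-drawn folds
        if p >= self.n - max(len(f) for f in self.folds):
            return np.inf
        sq_errors = np.empty(self.n)
        for fold in self.folds:
            mask = np.ones(self.n, dtype=bool)
            mask[fold] = False
            w_fold = fit_weights(design[mask], self.y[mask], self.config.ridge_factor)
            sq_errors[fold] = (self.y[fold] - design[fold] @ w_fold) ** 2
        return float(np.mean(sq_errors))


def _candidate_moves(structure, candidate_inputs, specs, config):
    """Enumerate legal moves in deterministic order; yields new structures."""
    used = {name for sm in structure for name in sm.inputs}

    def univariate(name):
        spec = specs[name]
        knots = initial_knots(config.initial_set_density) if spec.kind == "continuous" else None
        return Submodel.make({name: knots})

    # (a) add a univariate submodel on an unused input
    for name in candidate_inputs:
        if name in specs and name not in used:
            yield structure + (univariate(name),)
    # (b) merge two submodels into a tensor product
    for i, j in itertools.combinations(range(len(structure)), 2):
        a, b = structure[i], structure[j]
        if len(a.inputs) + len(b.inputs) <= config.max_inputs_per_submodel:
            merged = Submodel.make(dict(a.bases) | dict(b.bases))
            rest = tuple(sm for k, sm in enumerate(structure) if k not in (i, j))
            yield rest + (merged,)
    # (c) insert a node on a continuous input of an existing submodel
    if config.adapt_nodes:
        for i, sm in enumerate(structure):
            for name, knots in sm.bases:
                if knots is not None and len(knots) < config.max_nodes_per_input:
                    refined = dict(sm.bases)
                    refined[name] = insert_node(knots)
                    yield structure[:i] + (Submodel.make(refined),) + structure[i + 1:]
    # (d) prune: delete a submodel
    for i in range(len(structure)):
        yield structure[:i] + structure[i + 1:]
    # (d) prune: split a tensor submodel into its marginal parts
    for i, sm in enumerate(structure):
        if len(sm.inputs) >= 2:
            parts = tuple(Submodel.make({name: knots}) for name, knots in sm.bases)
            yield structure[:i] + structure[i + 1:] + parts
    # (d) prune: remove an interior node
    for i, sm in enumerate(structure):
        for name, knots in sm.bases:
            if knots is not None and len(knots) > 2:
                for interior in knots[1:-1]:
                    coarse = dict(sm.bases)
                    coarse[name] = tuple(k for k in knots if k != interior)
                    yield structure[:i] + (Submodel.make(coarse),) + structure[i + 1:]


def _draw_folds(n, k, rng, strat_labels=None):
    """Deterministic fold assignment, optionally stratified by a label array."""
    if strat_labels is None:
        order = rng.permutation(n)
    else:
        labels = np.asarray([str(lab) for lab in strat_labels])
        order = np.concatenate(
            [rng.permutation(np.flatnonzero(labels == lab)) for lab in np.unique(labels)]
        )
    # round-robin so each fold mixes strata evenly
    return [np.sort(order[i::k]) for i in range(k)]


def asmod_search(
    table: pd.DataFrame,
    output: str,
    candidate_inputs: Sequence[str],
    config: TrainingConfig | None = None,
    categorical: Sequence[str] = ("genotype", "subculture"),
) -> tuple[AdditiveModel, FitStats]:
    """Run the stepwise structure search for one output.

    Starting from the bias-only model, the best strictly-improving move
    (add / merge / refine / prune, each candidate ridge-fitted and scored) is
    accepted until no move improves the selection criterion.  Ties are broken
    by score, then fewest parameters, then enumeration order (which follows
    the candidate-input order).  Returns the fitted additive model — its
    submodels ordered by criterion contribution (drop-one score increase) —
    together with its fit statistics.
    """
    if config is None:
        config = TrainingConfig()
    if output not in table.columns:
        raise KeyError(f"output column {output!r} missing")
    candidate_inputs = [c for c in candidate_inputs if c != output]
    if not candidate_inputs:
        raise ValueError("at least one candidate input is required")
    y = table[output].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"output {output!r} contains missing values")

    specs = infer_input_specs(table, candidate_inputs, categorical=categorical)
    normalized = normalize_inputs(table, specs)

    folds = None
    if config.model_selection == "CV":
        rng = np.random.default_rng(config.random_seed)
        strat = table["genotype"].to_numpy() if "genotype" in table.columns else None
        folds = _draw_folds(len(y), config.cv_folds, rng, strat)

    fitter = _Fitter(normalized, y, specs, config, folds=folds)
    structure: tuple[Submodel, ...] = ()
    best_score = fitter.fit(structure)[0]

    while True:
        best_move = None
        for idx, cand in enumerate(_candidate_moves(structure, candidate_inputs, specs, config)):
            score, p, _, _, _ = fitter.fit(cand)
            rank = (score, p, idx)
            if best_move is None or rank < best_move[0]:
                best_move = (rank, cand)
        if best_move is None:
            break
        (score, _, _), cand = best_move
        if score < best_score - 1e-12 * max(1.0, abs(best_score)):
            structure, best_score = cand, score
        else:
            break

    return _finalize(fitter, structure, output, y, normalized, specs, config)


def _finalize(fitter, structure, output, y, normalized, specs, config):
    score, p, mse, w, design = fitter.fit(structure)

    # order submodels by drop-one criterion contribution (largest first)
    if len(structure) > 1:
        contributions = []
        for i in range(len(structure)):
            reduced = structure[:i] + structure[i + 1:]
            contributions.append(fitter.fit(reduced)[0] - score)
        order = sorted(range(len(structure)), key=lambda i: (-contributions[i], i))
        structure = tuple(structure[i] for i in order)
        score, p, mse, w, design = fitter.fit(structure)

    # split the weight vector back into bias + per-submodel weights
    bias = float(w[0])
    submodels = []
    offset = 1
    for sm in structure:
        size = sm.size(specs)
        submodels.append(Submodel(sm.inputs, sm.bases, tuple(w[offset:offset + size])))
        offset += size

    fitted = design @ w
    components = np.zeros((len(y), len(submodels)))
    model = AdditiveModel(
        output=output,
        input_specs=dict(specs),
        submodels=submodels,
        bias=bias,
        output_range=(float(np.min(y)), float(np.max(y))),
        fitted_range=(float(np.min(fitted)), float(np.max(fitted))),
        submodel_means=[],
        uninformative=not submodels,
    )
    if submodels:
        components = model.predict_components(normalized)
    model.submodel_means = [float(m) for m in components.mean(axis=0)] if submodels else []

    if not submodels:
        sse = float(np.sum((y - fitted) ** 2))
        stats = FitStats(
            n=len(y), p=1, mse=sse / len(y), r2_percent=0.0, f_ratio=np.nan,
            df1=0, df2=len(y) - 1, f_critical=np.nan, quality="rejected_low",
        )
    else:
        stats = fit_stats(y, fitted, p)
    return model, stats


@dataclass
class OutputResult:
    """Per-output training result; ``error`` is set when training failed."""

    model: AdditiveModel | None = None
    stats: FitStats | None = None
    error: Exception | None = None


def train_all_outputs(
    table: pd.DataFrame,
    outputs: Sequence[str],
    config: TrainingConfig | None = None,
    candidate_inputs: Sequence[str] | None = None,
    categorical: Sequence[str] = ("genotype", "subculture"),
) -> dict[str, OutputResult]:
    """Independently train one additive model per output.

    Each output gets its own deterministic seed derived from the shared
    ``random_seed`` and the output name, so results do not depend on the
    order outputs are listed in.  A failure on one output is recorded in its
    :class:`OutputResult` without aborting the siblings.
    """
    if config is None:
        config = TrainingConfig()
    if candidate_inputs is None:
        candidate_inputs = [
            c for c in table.columns if c not in outputs and c != "medium"
        ]
    results: dict[str, OutputResult] = {}
    for output in outputs:
        child_seed = np.random.SeedSequence(
            [config.random_seed, zlib.crc32(output.encode())]
        ).generate_state(1)[0] % (2**31)
        cfg = TrainingConfig(**{**asdict(config), "random_seed": int(child_seed)})
        try:
            model, stats = asmod_search(
                table, output, candidate_inputs, cfg, categorical=categorical
            )
            results[output] = OutputResult(model=model, stats=stats)
        except Exception as exc:  # noqa: BLE001 - per-output isolation is the contract
            results[output] = OutputResult(error=exc)
    return results


class ASMODRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator wrapping the ASMOD neurofuzzy learner.

    Parameters mirror :class:`TrainingConfig`; fitting expects a DataFrame
    ``X`` so that categorical inputs (object/category dtype, or columns named
    in ``categorical_features``) keep their levels.

    Attributes set by :meth:`fit`
    -----------------------------
    model_ : AdditiveModel
        The fitted additive spline structure.
    fit_stats_ : FitStats
        Train-set MSE, R2 (percent), f-ratio and quality gate.
    feature_names_in_ : ndarray of str
        Input column names seen during fit.

    Examples
    --------
    >>> est = ASMODRegressor(random_state=0).fit(X_train, y_train)  # doctest: +SKIP
    >>> est.model_.active_inputs  # doctest: +SKIP
    ['Cu2+', 'genotype']
    """

    def __init__(
        self,
        ridge_factor: float = 1e-6,
        model_selection: str = "SRM",
        srm_c1: float = 0.95,
        srm_c2: float = 4.8,
        initial_set_density: int = 2,
        adapt_nodes: bool = True,
        max_inputs_per_submodel: int = 3,
        max_nodes_per_input: int = 15,
        spline_order: int = 2,
        cv_folds: int = 5,
        categorical_features: Sequence[str] | None = None,
        random_state: int | None = None,
    ):
        self.ridge_factor = ridge_factor
        self.model_selection = model_selection
        self.srm_c1 = srm_c1
        self.srm_c2 = srm_c2
        self.initial_set_density = initial_set_density
        self.adapt_nodes = adapt_nodes
        self.max_inputs_per_submodel = max_inputs_per_submodel
        self.max_nodes_per_input = max_nodes_per_input
        self.spline_order = spline_order
        self.cv_folds = cv_folds
        self.categorical_features = categorical_features
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            ridge_factor=self.ridge_factor,
            model_selection=self.model_selection,
            srm_c1=self.srm_c1,
            srm_c2=self.srm_c2,
            initial_set_density=self.initial_set_density,
            adapt_nodes=self.adapt_nodes,
            max_inputs_per_submodel=self.max_inputs_per_submodel,
            max_nodes_per_input=self.max_nodes_per_input,
            spline_order=self.spline_order,
            cv_folds=self.cv_folds,
            random_seed=0 if self.random_state is None else int(self.random_state),
        )

    def fit(self, X: pd.DataFrame, y) -> "ASMODRegressor":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("ASMODRegressor requires a pandas DataFrame for X")
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or len(y) != len(X):
            raise ValueError("y must be one-dimensional and aligned with X")
        categorical = tuple(self.categorical_features or ())
        frame = X.copy()
        frame["__y__"] = y
        model, stats = asmod_search(
            frame,
            "__y__",
            list(X.columns),
            self._config(),
            categorical=categorical
            or tuple(c for c in X.columns if X[c].dtype == object),
        )
        model.output = "y"
        self.model_ = model
        self.fit_stats_ = stats
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("this ASMODRegressor instance is not fitted yet")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("ASMODRegressor requires a pandas DataFrame for X")
        normalized = normalize_inputs(X, self.model_.input_specs)
        return self.model_.predict(normalized)
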