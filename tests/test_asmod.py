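"""ASMOD learner: weights, statistics, criteria, structure search, estimator."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from nutrifuzz.asmod import (
    ASMODRegressor,
    AdditiveModel,
    InsufficientDFError,
    Submodel,
    TrainingConfig,
    _Fitter,
    asmod_search,
    criterion_score,
    effective_parameters,
    fit_stats,
    fit_weights,
    infer_input_specs,
    normalize_inputs,
)


# --- ridge weights ----------------------------------------------------------


def test_ridge_recovers_exact_solution_in_column_space():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 4))
    w_true = np.array([1.0, -2.0, 0.5, 3.0])
    y = X @ w_true
    w = fit_weights(X, y, 1e-6)
    assert np.allclose(X @ w, y, atol=1e-6)


def test_ridge_limit_equals_ols_and_zero_response_gives_zero_weights():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 3))
    y = rng.normal(size=40)
    w_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert np.allclose(fit_weights(X, y, 1e-12), w_ols, atol=1e-6)
    assert np.allclose(fit_weights(X, np.zeros(40), 1e-6), 0.0, atol=1e-12)


# --- fit statistics ---------------------------------------------------------


def test_f_ratio_consistent_with_published_shoot_length_row():
    """R2 = 74.97% at df (7, 100) implies the printed f-ratio 42.79."""
    r2, df1, df2 = 74.97, 7, 100
    f_ratio = (r2 / df1) / ((100.0 - r2) / df2)
    assert round(f_ratio, 2) == 42.79


def test_fit_stats_quality_gate():
    rng = np.random.default_rng(2)
    y = rng.normal(size=108)
    # perfect prediction -> overfit flag
    stats = fit_stats(y, y, p=8)
    assert stats.r2_percent == pytest.approx(100.0)
    assert stats.quality == "rejected_overfit"
    # mean prediction -> zero R2
    stats = fit_stats(y, np.full_like(y, y.mean()), p=8)
    assert stats.r2_percent == pytest.approx(0.0, abs=1e-9)
    assert stats.quality == "rejected_low"
    assert stats.df1 == 7 and stats.df2 == 100
    with pytest.raises(InsufficientDFError):
        fit_stats(y[:5], y[:5] * 0.9, p=8)


def test_parameter_bookkeeping_matches_published_df_pairs():
    """Submodel basis sizes imply the published (df1, df2) pairs at n=108:
    3x2 + 2 -> p=8 (7,100); 3x2x3 + 4x2 -> p=26 (25,82); single 3x2 -> p=7
    (6,101); single 3x2x3 -> p=19 (18,89); 3x2x2 + 3 -> p=15 (14,93)."""
    n = 108
    for sizes, df_pair in [
        ([6, 2], (7, 100)),
        ([18, 8], (25, 82)),
        ([6], (6, 101)),
        ([18], (18, 89)),
        ([12, 3], (14, 93)),
    ]:
        p = effective_parameters(sizes)
        assert (p - 1, n - p) == df_pair
    assert effective_parameters([]) == 1


# --- selection criteria -----------------------------------------------------


def test_srm_score_matches_hand_evaluated_formula():
    cfg = TrainingConfig()
    mse, p, n = 1.0, 8, 108
    eps = 0.95 * (p * (np.log(2 * n / p) + 1.0) + 4.8) / n
    expected = mse / (1.0 - np.sqrt(eps))
    assert criterion_score(mse, p, n, cfg) == pytest.approx(expected, rel=1e-12)
    assert criterion_score(0.0, 50, 10, cfg) == 0.0  # zero error -> zero score
    # capacity term >= 1 -> infeasible structure
    assert criterion_score(1.0, 200, 108, cfg) == np.inf


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    mse=st.floats(1e-6, 1e3),
    p1=st.integers(1, 20),
    dp=st.integers(1, 10),
    n=st.integers(60, 500),
)
def test_penalty_is_monotone_in_parameter_count(mse, p1, dp, n):
    for criterion in ("SRM", "MDL", "BIC"):
        cfg = TrainingConfig(model_selection=criterion)
        assert criterion_score(mse, p1 + dp, n, cfg) >= criterion_score(mse, p1, n, cfg)


def test_node_insertion_never_increases_training_mse():
    """Refining a knot vector nests the basis, so training MSE cannot rise,
    while the SRM score may (and here does) rise."""
    rng = np.random.default_rng(5)
    table = pd.DataFrame({"x": rng.uniform(0, 1, 60)})
    table["y"] = np.sin(3 * table["x"]) + rng.normal(0, 0.05, 60)
    cfg = TrainingConfig()
    specs = infer_input_specs(table, ["x"])
    norm = normalize_inputs(table, specs)
    fitter = _Fitter(norm, table["y"].to_numpy(), specs, cfg)
    knots = (0.0, 1.0)
    prev_mse = np.inf
    for _ in range(6):
        structure = (Submodel.make({"x": knots}),)
        _, _, mse, _, _ = fitter.fit(structure)
        assert mse <= prev_mse + 1e-12
        prev_mse = mse
        from nutrifuzz.splines import insert_node

        knots = insert_node(knots)


# --- structure search -------------------------------------------------------


def test_search_recovers_planted_univariate_effect():
    rng = np.random.default_rng(7)
    table = pd.DataFrame({f"x{i}": rng.uniform(0, 1, 108) for i in range(5)})
    table["y"] = 3.0 * table["x1"] + rng.normal(0, 0.01, 108)
    model, stats = asmod_search(table, "y", [f"x{i}" for i in range(5)],
                                TrainingConfig(), categorical=())
    assert [sm.inputs for sm in model.submodels] == [("x1",)]
    assert stats.r2_percent > 99.0


def test_search_recovers_planted_interaction_without_spurious_inputs():
    rng = np.random.default_rng(8)
    table = pd.DataFrame({f"x{i}": rng.uniform(0, 1, 108) for i in range(5)})
    table["y"] = table["x1"] * table["x2"] + rng.normal(0, 0.01, 108)
    model, _ = asmod_search(table, "y", [f"x{i}" for i in range(5)],
                            TrainingConfig(), categorical=())
    assert model.active_inputs == ["x1", "x2"]
    assert any(set(sm.inputs) == {"x1", "x2"} for sm in model.submodels)


def test_constant_response_yields_uninformative_bias_only_model():
    table = pd.DataFrame({"x": np.linspace(0, 1, 30), "y": np.ones(30)})
    model, stats = asmod_search(table, "y", ["x"], TrainingConfig(), categorical=())
    assert model.uninformative
    assert model.submodels == []
    assert stats.quality == "rejected_low"


def test_search_criterion_equals_exhaustive_enumeration_on_toy_instances():
    """On two-input instances with a 3-node cap, the greedy search attains
    the global SRM optimum over all enumerable structures."""

    def enumerate_structures():
        knot_opts = [(0.0, 1.0), (0.0, 0.5, 1.0)]
        yield ()
        for ka in knot_opts:
            yield (Submodel.make({"a": ka}),)
        for kb in knot_opts:
            yield (Submodel.make({"b": kb}),)
        for ka in knot_opts:
            for kb in knot_opts:
                yield (Submodel.make({"a": ka}), Submodel.make({"b": kb}))
                yield (Submodel.make({"a": ka, "b": kb}),)

    for seed in range(5):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame({"a": rng.uniform(0, 1, 30), "b": rng.uniform(0, 1, 30)})
        table["y"] = 2.0 * table["a"] + rng.normal(0, 0.05, 30)
        cfg = TrainingConfig(max_nodes_per_input=3)
        model, _ = asmod_search(table, "y", ["a", "b"], cfg, categorical=())
        specs = infer_input_specs(table, ["a", "b"])
        norm = normalize_inputs(table, specs)
        fitter = _Fitter(norm, table["y"].to_numpy(), specs, cfg)
        best = min(fitter.fit(s)[0] for s in enumerate_structures())
        reached = fitter.fit(
            tuple(Submodel.make(dict(sm.bases)) for sm in model.submodels)
        )[0]
        assert reached == pytest.approx(best, rel=1e-10)


def test_search_is_deterministic_and_caps_inputs_per_submodel(trained):
    results, _, table = trained
    from nutrifuzz.asmod import train_all_outputs
    from nutrifuzz.simulate import OUTPUTS

    repeat = train_all_outputs(table, list(OUTPUTS), TrainingConfig(random_seed=42))
    for output in OUTPUTS:
        a, b = results[output].model, repeat[output].model
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(
            b.to_dict(), sort_keys=True
        )
        assert all(len(sm.inputs) <= 3 for sm in a.submodels)
        assert all(
            len(k) <= 15 for sm in a.submodels for _, k in sm.bases if k is not None
        )


def test_submodels_are_ordered_by_criterion_contribution(trained):
    results, _, table = trained
    cfg = TrainingConfig(random_seed=42)
    for output, res in results.items():
        model = res.model
        if len(model.submodels) < 2:
            continue
        y = table[output].to_numpy(dtype=float)
        specs = model.input_specs
        norm = normalize_inputs(table, specs)
        fitter = _Fitter(norm, y, specs, cfg)
        full = tuple(Submodel.make(dict(sm.bases)) for sm in model.submodels)
        base = fitter.fit(full)[0]
        drops = [
            fitter.fit(full[:i] + full[i + 1:])[0] - base for i in range(len(full))
        ]
        assert all(x >= y - 1e-9 for x, y in zip(drops, drops[1:]))


def test_normalize_inputs_affine_map_and_constant_column_warning():
    table = pd.DataFrame({"a": [0.0, 10.31, 20.62], "c": [5.0, 5.0, 5.0]})
    with pytest.warns(UserWarning, match="constant input"):
        specs = infer_input_specs(table, ["a", "c"])
    assert "c" not in specs
    norm = normalize_inputs(table, specs)
    assert np.allclose(norm["a"], [0.0, 0.5, 1.0])


def test_per_output_failures_do_not_abort_siblings():
    from nutrifuzz.asmod import train_all_outputs

    rng = np.random.default_rng(9)
    table = pd.DataFrame({"x": rng.uniform(0, 1, 40)})
    table["good"] = 2 * table["x"] + rng.normal(0, 0.01, 40)
    table["bad"] = np.nan
    results = train_all_outputs(table, ["good", "bad"], TrainingConfig(), categorical=())
    assert results["good"].error is None
    assert results["good"].stats.r2_percent > 95
    assert results["bad"].error is not None


# --- scikit-learn estimator -------------------------------------------------


def test_estimator_fit_predict_and_clone():
    rng = np.random.default_rng(10)
    X = pd.DataFrame(
        {
            "dose": rng.uniform(0, 1, 90),
            "geno": rng.choice(["BD", "BH", "BT"], 90),
        }
    )
    y = 2.0 * X["dose"] + (X["geno"] == "BT") * 1.5 + rng.normal(0, 0.05, 90)
    est = ASMODRegressor(random_state=0)
    est.fit(X, y)
    assert hasattr(est, "model_") and hasattr(est, "fit_stats_")
    assert est.n_features_in_ == 2
    pred = est.predict(X)
    assert 1 - np.var(y - pred) / np.var(y) > 0.9
    assert est.score(X, y) > 0.9
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    with pytest.raises(TypeError):
        ASMODRegressor().fit(np.zeros((5, 2)), np.zeros(5))


def test_model_json_round_trip(trained):
    results, _, _ = trained
    model = results["SL"].model
    payload = json.dumps(model.to_dict(), sort_keys=True)
    restored = AdditiveModel.from_dict(json.loads(payload))
    assert json.dumps(restored.to_dict(), sort_keys=True) == payload


def test_training_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(ridge_factor=0.0)
    with pytest.raises(ValueError):
        TrainingConfig(model_selection="AIC")
    with pytest.raises(ValueError):
        TrainingConfig(spline_order=3)
    with pytest.raises(ValueError):
        TrainingConfig(initial_set_density=1)


def test_cv_and_loocv_criteria_run_and_select_signal():
    rng = np.random.default_rng(12)
    table = pd.DataFrame({"x0": rng.uniform(0, 1, 60), "x1": rng.uniform(0, 1, 60)})
    table["y"] = 2.5 * table["x0"] + rng.normal(0, 0.05, 60)
    for criterion in ("CV", "LOOCV"):
        model, stats = asmod_search(
            table, "y", ["x0", "x1"],
            TrainingConfig(model_selection=criterion, random_seed=3),
            categorical=(),
        )
        assert "x0" in model.active_inputs
        assert stats.r2_percent > 95
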