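import numpy as np
import pytest

import kinlearn as kl
from kinlearn.errors import NumericError, UnknownReferenceError, ValidationError
from kinlearn.fixtures import CARRIER_PRODUCTION, light_grid, toy_petc_cbb
from kinlearn.surrogate import AffineScaler, smoothed_loss


# ------------------------------------------------------------------ #
# training sets
# ------------------------------------------------------------------ #
def test_function_mode_evaluates_rows():
    ts = kl.make_training_set(lambda x: 2 * x, np.array([[0.0], [1.0], [2.0]]),
                              "evaluate-function", feature_names=["x"],
                              target_names=["y"])
    assert ts.X[:, 0].tolist() == [0.0, 1.0, 2.0]
    assert ts.Y[:, 0].tolist() == [0.0, 2.0, 4.0]


def test_steady_state_mode_matches_closed_form(pathway):
    ts = kl.make_training_set(pathway, np.array([[1.0], [2.0], [4.0]]),
                              "model-steady-state",
                              feature_names=["k2"], target_names=["S1"])
    assert ts.Y[:, 0] == pytest.approx([2.0, 1.0, 0.5], abs=1e-8)


def test_non_converging_rows_dropped_and_logged():
    # constant production with no sink: never converges
    m = (kl.Model().add_parameter("k", 1.0).add_variable("S", 0.0)
         .add_law_reaction("v", "constant", ["k"], {"S": 1}))
    pathway_like = (kl.Model().add_parameter("k", 1.0).add_variable("S", 0.0)
                    .add_law_reaction("vin", "constant", ["k"], {"S": 1})
                    .add_law_reaction("vout", "mass_action", ["k", "S"], {"S": -1}))
    ts = kl.make_training_set(pathway_like, np.array([[1.0], [0.0]]),
                              "model-steady-state", feature_names=["k"],
                              target_names=["S"], t_max=5.0)
    # k=0 row: zero rates converge trivially; use diverging model instead
    ts2_failed = False
    try:
        kl.make_training_set(m, np.array([[1.0]]), "model-steady-state",
                             feature_names=["k"], target_names=["S"], t_max=5.0)
    except ValidationError:
        ts2_failed = True
    assert ts2_failed  # all rows failing is an error
    assert ts.n >= 1


def test_timecourse_endpoint_mode(decay):
    ts = kl.make_training_set(decay, np.array([[0.5], [1.0]]),
                              "model-timecourse-endpoint", feature_names=["k"],
                              target_names=["S"], t_end=1.0)
    assert ts.Y[:, 0] == pytest.approx(np.exp(-np.array([0.5, 1.0])), abs=1e-6)


def test_training_set_csv_round_trip(tmp_path):
    ts = kl.TrainingSet([[1.0, 2.0]], [[3.0]], ["a", "b"], ["y"])
    ts.to_csv(tmp_path / "ts.csv")
    back = kl.TrainingSet.from_csv(tmp_path / "ts.csv")
    assert back.feature_names == ["a", "b"] and back.target_names == ["y"]
    assert np.array_equal(back.X, ts.X) and np.array_equal(back.Y, ts.Y)


# ------------------------------------------------------------------ #
# polynomial surrogates
# ------------------------------------------------------------------ #
def test_linear_function_recovered_exactly():
    x = np.linspace(0, 1, 9)[:, None]
    ts = kl.TrainingSet(x, 2 * x, ["x"], ["y"])
    p = kl.train_polynomial(ts, 1)
    assert p.coefficients[:, 0] == pytest.approx([0.0, 2.0], abs=1e-10)
    assert p.training_rmse[0] == pytest.approx(0.0, abs=1e-10)


def test_quadratic_needs_degree_two():
    x = np.linspace(-1, 1, 11)[:, None]
    ts = kl.TrainingSet(x, x**2, ["x"], ["y"])
    exact = kl.train_polynomial(ts, 2)
    under = kl.train_polynomial(ts, 1)
    assert exact.training_rmse[0] == pytest.approx(0.0, abs=1e-10)
    assert under.training_rmse[0] > 0.01
    # cross-check against the normal-equation oracle for the degree-2 fit
    design = np.column_stack([np.ones(11), x[:, 0], x[:, 0] ** 2])
    oracle = np.linalg.solve(design.T @ design, design.T @ ts.Y[:, 0])
    assert exact.coefficients[:, 0] == pytest.approx(oracle, abs=1e-8)


def test_duplicate_constant_feature_is_rank_deficient():
    X = np.column_stack([np.linspace(0, 1, 8), np.ones(8)])
    ts = kl.TrainingSet(X, X[:, :1], ["x", "const"], ["y"])
    with pytest.raises(ValidationError, match="rank deficient"):
        kl.train_polynomial(ts, 1)


def test_polynomial_serialization_round_trip(tmp_path):
    x = np.linspace(0, 2, 12)[:, None]
    ts = kl.TrainingSet(x, 1 + 3 * x - x**2, ["x"], ["y"])
    p = kl.train_polynomial(ts, 2)
    kl.save_surrogate(p, tmp_path / "p.json")
    back = kl.load_surrogate(tmp_path / "p.json")
    q = np.array([[0.37], [1.91]])
    assert back.predict(q) == pytest.approx(p.predict(q), abs=0.0)


# ------------------------------------------------------------------ #
# spline surrogate (single input)
# ------------------------------------------------------------------ #
def test_spline_interpolates_and_rejects_multi_input():
    x = np.linspace(0, np.pi, 15)[:, None]
    ts = kl.TrainingSet(x, np.sin(x), ["x"], ["y"])
    s = kl.train_spline(ts)
    assert s.predict([[1.0]])[0, 0] == pytest.approx(np.sin(1.0), abs=1e-3)
    multi = kl.TrainingSet(np.ones((4, 2)) * np.arange(4)[:, None],
                           np.ones((4, 1)), ["a", "b"], ["y"])
    with pytest.raises(ValidationError):
        kl.train_spline(multi)


# ------------------------------------------------------------------ #
# MLP surrogates
# ------------------------------------------------------------------ #
def test_mlp_learns_linear_map():
    x = np.linspace(0, 1, 64)[:, None]
    ts = kl.TrainingSet(x, 2 * x, ["x"], ["y"])
    mlp = kl.train_mlp(ts, (16,), epochs=500, seed=0)
    grid = np.linspace(0, 1, 101)[:, None]
    rmse = np.sqrt(np.mean((mlp.predict(grid) - 2 * grid) ** 2))
    assert rmse < 0.05
    assert mlp.training_log[-1] <= mlp.training_log[0]


def test_mlp_on_constant_data_predicts_the_constant():
    X = np.tile([[1.0, 2.0]], (32, 1))
    Y = np.full((32, 1), 0.7)
    ts = kl.TrainingSet(X, Y, ["a", "b"], ["y"])
    mlp = kl.train_mlp(ts, (8,), epochs=300, seed=1)
    assert mlp.predict([[1.0, 2.0]])[0, 0] == pytest.approx(0.7, abs=1e-2)


def test_mlp_deterministic_given_seed():
    x = np.linspace(0, 1, 32)[:, None]
    ts = kl.TrainingSet(x, np.sin(3 * x), ["x"], ["y"])
    a = kl.train_mlp(ts, (8,), epochs=100, seed=5)
    b = kl.train_mlp(ts, (8,), epochs=100, seed=5)
    grid = np.linspace(0, 1, 17)[:, None]
    assert np.array_equal(a.predict(grid), b.predict(grid))


def test_mlp_minibatch_mode_trains():
    x = np.linspace(0, 1, 64)[:, None]
    ts = kl.TrainingSet(x, 2 * x, ["x"], ["y"])
    mlp = kl.train_mlp(ts, (16,), epochs=300, batch_mode=16, seed=0)
    assert mlp.training_log[-1] < mlp.training_log[0]


def test_mlp_aborts_on_divergent_loss():
    x = np.linspace(0, 1, 16)[:, None]
    ts = kl.TrainingSet(x, 2 * x, ["x"], ["y"])
    # a pathological learning rate blows the weights up; the trainer must
    # abort with a diagnostic naming the epoch, not return garbage
    with np.errstate(all="ignore"), pytest.raises(NumericError, match="epoch"):
        kl.train_mlp(ts, (8,), epochs=50, learning_rate=1e80,
                     activation="relu", seed=0)


def test_scaler_round_trip_identity():
    rng = np.random.default_rng(0)
    X = rng.normal(3.0, 2.0, size=(50, 3))
    sc = AffineScaler.fit(X)
    assert sc.inverse(sc.transform(X)) == pytest.approx(X, abs=1e-12)


def test_smoothed_loss_is_monotone():
    log = [5.0, 3.0, 4.0, 2.0, 2.5]
    assert smoothed_loss(log).tolist() == [5.0, 3.0, 3.0, 2.0, 2.0]


def test_mlp_serialization_round_trip(tmp_path):
    x = np.linspace(0, 1, 32)[:, None]
    ts = kl.TrainingSet(x, 2 * x, ["x"], ["y"])
    mlp = kl.train_mlp(ts, (8,), epochs=100, seed=2)
    kl.save_surrogate(mlp, tmp_path / "m.json")
    back = kl.load_surrogate(tmp_path / "m.json")
    grid = np.linspace(0, 1, 13)[:, None]
    assert np.array_equal(back.predict(grid), mlp.predict(grid))


def test_extrapolation_is_flagged():
    x = np.linspace(0, 1, 16)[:, None]
    ts = kl.TrainingSet(x, 2 * x, ["x"], ["y"])
    mlp = kl.train_mlp(ts, (8,), epochs=50, seed=0)
    assert not mlp.extrapolation_seen
    mlp.predict([[5.0]])
    assert mlp.extrapolation_seen


# ------------------------------------------------------------------ #
# embedding into models
# ------------------------------------------------------------------ #
def _zero_surrogate():
    x = np.array([[0.0], [1.0]])
    return kl.train_polynomial(kl.TrainingSet(x, 0 * x, ["S1"], ["z"]), 1)


def test_zero_surrogate_is_identity(pathway):
    hybrid = kl.add_surrogate(pathway, _zero_surrogate(), inputs=["S1"],
                              mode="additive", outputs={"z": {"S1": 1.0}})
    for s in (0.1, 0.5, 2.0):
        state = np.array([s])
        assert hybrid.rhs(0.0, state) == pytest.approx(
            pathway.rhs(0.0, state), abs=0.0)


def test_additive_contribution_is_exactly_the_surrogate_term(pathway):
    x = np.linspace(0, 2, 8)[:, None]
    surr = kl.train_polynomial(kl.TrainingSet(x, 3 * x, ["S1"], ["boost"]), 1)
    hybrid = kl.add_surrogate(pathway, surr, inputs=["S1"], mode="additive",
                              outputs={"boost": {"S1": 0.5}})
    for s in (0.2, 1.1):
        state = np.array([s])
        delta = hybrid.rhs(0.0, state) - pathway.rhs(0.0, state)
        assert delta[0] == pytest.approx(0.5 * 3 * s, abs=1e-9)


def test_exact_replacement_leaves_rhs_invariant(pathway):
    # reaction v2 = k2*S1 = 4*S1; a degree-1 fit on exact fluxes is exact
    grid = np.linspace(0.0, 1.0, 6)[:, None]
    ts = kl.TrainingSet(grid, 4.0 * grid, ["S1"], ["v2"])
    surr = kl.train_polynomial(ts, 1)
    hybrid = kl.add_surrogate(pathway, surr, inputs=["S1"], mode="replacement",
                              replaced_reactions=["v2"])
    assert "v2" not in hybrid.reaction_names
    for s in (0.1, 0.5, 0.9):
        state = np.array([s])
        assert hybrid.rhs(0.0, state) == pytest.approx(
            pathway.rhs(0.0, state), abs=1e-8)


def test_replacement_steady_state_matches_original(pathway):
    grid = np.linspace(0.0, 1.0, 6)[:, None]
    surr = kl.train_polynomial(kl.TrainingSet(grid, 4.0 * grid, ["S1"], ["v2"]), 1)
    hybrid = kl.add_surrogate(pathway, surr, inputs=["S1"], mode="replacement",
                              replaced_reactions=["v2"])
    ss = kl.steady_state(hybrid)
    assert ss.state[0] == pytest.approx(0.5, abs=1e-6)


def test_replacing_nonexistent_reaction_rejected(pathway):
    with pytest.raises(UnknownReferenceError):
        kl.add_surrogate(pathway, _zero_surrogate(), inputs=["S1"],
                         mode="replacement", replaced_reactions=["nope"])


def test_mismatched_surrogate_output_names_rejected():
    full, build = toy_petc_cbb()
    x = np.array([[0.0], [1.0]])
    wrong = kl.train_polynomial(kl.TrainingSet(x, np.hstack([x, x]),
                                               ["L"], ["a", "b"]), 1)
    with pytest.raises(ValidationError):
        build(wrong)


def test_hybrid_usable_by_other_modules(pathway):
    grid = np.linspace(0.0, 1.0, 6)[:, None]
    surr = kl.train_polynomial(kl.TrainingSet(grid, 4.0 * grid, ["S1"], ["v2"]), 1)
    hybrid = kl.add_surrogate(pathway, surr, inputs=["S1"], mode="replacement",
                              replaced_reactions=["v2"])
    tc = kl.time_course(hybrid, [1.0, 2.0])
    assert np.isfinite(tc.variables.to_numpy()).all()
    from kinlearn.distributions import DistributionSpec

    sample = kl.sample_parameters([DistributionSpec("k1", "uniform", (0.5, 2))], 4, 0)
    ens = kl.mc_time_course(hybrid, sample, [1.0])
    assert ens.n_successful == 4


def test_toy_hybrid_matches_full_model_within_two_percent():
    full, build = toy_petc_cbb()
    grid = light_grid(25)
    ts = kl.make_training_set(full, grid, "model-steady-state",
                              feature_names=["L"],
                              target_names=list(CARRIER_PRODUCTION))
    mlp = kl.train_mlp(ts, (32,), epochs=5000, learning_rate=5e-3, seed=0)
    hybrid = build(mlp)
    eval_grid = light_grid(13)[:, 0]
    vf = np.array([
        kl.steady_state(full.copy().update_parameter("L", float(L)))
        .flux_dict()["v_carboxylation"] for L in eval_grid])
    vh = np.array([
        kl.steady_state(hybrid.copy().update_parameter("L", float(L)))
        .flux_dict()["v_carboxylation"] for L in eval_grid])
    substantive = vf > 0.01 * vf.max()
    rel = np.abs(vh - vf)[substantive] / vf[substantive]
    assert rel.max() < 0.02
    assert (np.abs(vh - vf) / vf.max()).max() < 0.02


def test_hybrid_steady_state_needs_fewer_rhs_evaluations():
    full, build = toy_petc_cbb()
    grid = light_grid(25)
    ts = kl.make_training_set(full, grid, "model-steady-state",
                              feature_names=["L"],
                              target_names=list(CARRIER_PRODUCTION))
    surr = kl.train_polynomial(ts, 3)
    hybrid = build(surr)

    def count_rhs(model):
        counter = {"n": 0}
        orig = model.rhs

        def counting(t, s):
            counter["n"] += 1
            return orig(t, s)

        model.rhs = counting
        kl.steady_state(model)
        return counter["n"]

    assert count_rhs(hybrid) < count_rhs(full)
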