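import numpy as np
import pytest

import kinlearn as kl
from kinlearn.errors import MappingError, ValidationError
from kinlearn.fitting import Dataset, ExperimentSpec, SharedParameterMap, dataset_from_csv, dataset_to_csv


def _decay_dataset(k: float, s0: float = 1.0, noise: float = 0.0,
                   rng=None) -> Dataset:
    times = np.linspace(0.5, 3.0, 6)
    values = s0 * np.exp(-k * times)
    if noise > 0:
        values = values * (1 + noise * rng.standard_normal(times.shape))
    return Dataset.time_series(times, ["S"] * len(times), values)


# ------------------------------------------------------------------ #
# shared-parameter map: pack / unpack
# ------------------------------------------------------------------ #
def test_single_experiment_round_trip():
    pm = SharedParameterMap(["k", "a"], [{"k": "k1", "a": "k2"}])
    vec = np.array([1.5, 0.3])
    assignments = pm.unpack(vec)
    assert assignments == [{"k1": 1.5, "k2": 0.3}]
    assert np.array_equal(pm.pack(assignments), vec)


def test_shared_plus_local_vector_length():
    # two experiments share "k"; each has one local parameter -> length 3
    pm = SharedParameterMap(
        ["k", "loc1", "loc2"],
        [{"k": "k", "loc1": "s0"}, {"k": "k", "loc2": "s0"}])
    assert len(pm.global_names) == 3
    out = pm.unpack(np.array([1.0, 2.0, 3.0]))
    assert out == [{"k": 1.0, "s0": 2.0}, {"k": 1.0, "s0": 3.0}]


def test_double_binding_one_model_parameter_rejected():
    with pytest.raises(MappingError):
        SharedParameterMap(["a", "b"], [{"a": "k", "b": "k"}])


def test_wrong_vector_length_rejected():
    pm = SharedParameterMap(["k"], [{"k": "k"}])
    with pytest.raises(MappingError):
        pm.unpack(np.array([1.0, 2.0]))


# ------------------------------------------------------------------ #
# residuals
# ------------------------------------------------------------------ #
def test_noiseless_data_gives_zero_residuals(decay):
    spec = ExperimentSpec(decay, _decay_dataset(1.0))
    pm = SharedParameterMap(["k"], [{"k": "k"}])
    r = kl.residuals([spec], pm, np.array([1.0]))
    assert np.max(np.abs(r)) < 1e-6


def test_wrong_parameter_gives_signed_residuals(decay):
    # at k=2 the model under-predicts: observed - predicted > 0 at all times
    spec = ExperimentSpec(decay, _decay_dataset(1.0))
    pm = SharedParameterMap(["k"], [{"k": "k"}])
    r = kl.residuals([spec], pm, np.array([2.0]))
    assert np.all(r > 0)


def test_mixed_time_series_and_steady_state_residual_length(decay, pathway):
    ts_spec = ExperimentSpec(decay, _decay_dataset(1.0))
    ss_spec = ExperimentSpec(
        pathway, Dataset.steady_state_data(["S1", "v1"], [0.5, 2.0]))
    pm = SharedParameterMap(
        ["k", "k2"], [{"k": "k"}, {"k2": "k2"}])
    r = kl.residuals([ts_spec, ss_spec], pm, np.array([1.0, 4.0]))
    assert len(r) == 6 + 2
    assert np.max(np.abs(r)) < 1e-6


def test_simulation_failure_yields_penalty_residuals(decay):
    bad = (kl.Model("bad").add_parameter("k", 1.0).add_variable("S", 1.0)
           .add_reaction("v", lambda k, s: float("nan") if k > 5 else -k * s,
                         ["k", "S"], {"S": 1}))
    spec = ExperimentSpec(bad, _decay_dataset(1.0))
    pm = SharedParameterMap(["k"], [{"k": "k"}])
    r = kl.residuals([spec], pm, np.array([10.0]))
    assert np.all(np.abs(r) == 1e6)
    with pytest.raises(Exception):
        kl.residuals([spec], pm, np.array([10.0]), strict=True)


def test_observed_name_must_exist(decay):
    with pytest.raises(ValidationError):
        ExperimentSpec(decay, Dataset.time_series([1.0], ["X"], [0.5]))


def test_weights_must_be_positive():
    with pytest.raises(ValidationError):
        Dataset.time_series([1.0], ["S"], [0.5], weights=[0.0])


# ------------------------------------------------------------------ #
# fitting
# ------------------------------------------------------------------ #
def test_noiseless_recovery_from_far_start(decay):
    spec = ExperimentSpec(decay, _decay_dataset(1.0))
    pm = SharedParameterMap(["k"], [{"k": "k"}])
    res = kl.fit([spec], pm, np.array([3.0]), bounds=[(0.01, 10.0)])
    assert res.converged
    assert res.global_vector[0] == pytest.approx(1.0, abs=1e-3)


def test_two_parameter_pathway_recovery():
    truth = {"k1": 1.3, "k2": 2.7}
    model = kl.linear_pathway(**{"k1": 1.0, "k2": 4.0})
    true_model = kl.linear_pathway(k1=truth["k1"], k2=truth["k2"])
    times = np.linspace(0.2, 3.0, 8)
    tc = kl.time_course(true_model, times)
    rec_names, rec_times, rec_vals = [], [], []
    for rxn in ("v1", "v2"):
        rec_names += [rxn] * len(times)
        rec_times += list(times)
        rec_vals += list(tc.fluxes[rxn])
    ds = Dataset.time_series(rec_times, rec_names, rec_vals)
    spec = ExperimentSpec(model, ds)
    pm = SharedParameterMap(["k1", "k2"], [{"k1": "k1", "k2": "k2"}])
    res = kl.fit([spec], pm, np.array([0.5, 5.0]),
                 bounds=[(0.1, 10.0), (0.1, 10.0)])
    assert res.global_vector == pytest.approx([1.3, 2.7], rel=1e-3)


def test_objective_equals_recomputed_residual_sum(decay):
    spec = ExperimentSpec(decay, _decay_dataset(1.0))
    pm = SharedParameterMap(["k"], [{"k": "k"}])
    res = kl.fit([spec], pm, np.array([2.0]), bounds=[(0.1, 5.0)])
    r = kl.residuals([spec], pm, res.global_vector)
    assert res.objective == pytest.approx(float(np.sum(r**2)), abs=1e-10)


def test_zero_iteration_minimizer_stub_returns_initial_non_converged(decay):
    spec = ExperimentSpec(decay, _decay_dataset(1.0))
    pm = SharedParameterMap(["k"], [{"k": "k"}])

    def stub(residual_fn, x0, bounds):
        return x0, ["stub: 0 iterations"], False

    res = kl.fit([spec], pm, np.array([2.5]), minimizer=stub)
    assert not res.converged
    assert res.global_vector[0] == 2.5


def test_shared_map_with_one_experiment_equals_plain_fit(decay):
    spec = ExperimentSpec(decay, _decay_dataset(1.0))
    shared = kl.fit([spec], SharedParameterMap(["k"], [{"k": "k"}]),
                    np.array([2.0]), bounds=[(0.1, 5.0)])
    again = kl.fit([spec], SharedParameterMap(["k"], [{"k": "k"}]),
                   np.array([2.0]), bounds=[(0.1, 5.0)])
    assert shared.global_vector[0] == again.global_vector[0]
    assert shared.objective == again.objective


def test_shared_fit_beats_worse_independent_fit_in_most_seeds():
    """Pooling two noisy experiments sharing k should beat the worse of
    the two independent estimates in >= 18/20 seeds (1% noise)."""
    wins = 0
    k_true = 1.0
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        ds1 = _decay_dataset(k_true, s0=1.0, noise=0.01, rng=rng)
        ds2 = _decay_dataset(k_true, s0=2.0, noise=0.01, rng=rng)
        m1 = kl.decay_model(s0=1.0)
        m2 = kl.decay_model(s0=2.0)
        spec1, spec2 = ExperimentSpec(m1, ds1), ExperimentSpec(m2, ds2)
        bounds = [(0.1, 5.0)]
        ind1 = kl.fit([spec1], SharedParameterMap(["k"], [{"k": "k"}]),
                      np.array([2.0]), bounds=bounds)
        ind2 = kl.fit([spec2], SharedParameterMap(["k"], [{"k": "k"}]),
                      np.array([2.0]), bounds=bounds)
        shared = kl.fit([spec1, spec2],
                        SharedParameterMap(["k"], [{"k": "k"}, {"k": "k"}]),
                        np.array([2.0]), bounds=bounds)
        worse = max(abs(ind1.global_vector[0] - k_true),
                    abs(ind2.global_vector[0] - k_true))
        if abs(shared.global_vector[0] - k_true) < worse:
            wins += 1
    assert wins >= 18


def test_multi_start_fit_finds_recovery(decay):
    spec = ExperimentSpec(decay, _decay_dataset(1.0))
    pm = SharedParameterMap(["k"], [{"k": "k"}])
    res = kl.multi_start_fit([spec], pm, bounds=[(0.1, 5.0)], n_starts=3, seed=1)
    assert res.global_vector[0] == pytest.approx(1.0, abs=1e-3)


def test_dataset_csv_round_trip(tmp_path):
    d1 = _decay_dataset(1.0)
    d2 = Dataset.steady_state_data(["S1"], [0.5])
    dataset_to_csv({"exp1": d1, "exp2": d2}, tmp_path / "d.csv")
    back = dataset_from_csv(tmp_path / "d.csv")
    assert back["exp1"].kind == "time-series"
    assert back["exp2"].kind == "steady-state"
    assert back["exp1"].records["value"].to_numpy() == pytest.approx(
        d1.records["value"].to_numpy(), rel=1e-12)


def test_fit_report_json(tmp_path, decay):
    spec = ExperimentSpec(decay, _decay_dataset(1.0))
    pm = SharedParameterMap(["k"], [{"k": "k"}])
    res = kl.fit([spec], pm, np.array([2.0]), bounds=[(0.1, 5.0)])
    res.to_json(tmp_path / "fit.json")
    import json

    with open(tmp_path / "fit.json") as fh:
        report = json.load(fh)
    assert report["parameters"]["k"] == pytest.approx(1.0, abs=1e-3)
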