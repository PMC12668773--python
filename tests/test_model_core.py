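import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinlearn as kl
from kinlearn.errors import (
    DependencyError,
    DuplicateNameError,
    EmptyModelError,
    NumericError,
    UnknownReferenceError,
)
from kinlearn.units import mM, mM_per_second, per_second


# ------------------------------------------------------------------ #
# registration round-trips and namespace rules
# ------------------------------------------------------------------ #
def test_parameter_round_trip_with_unit():
    m = kl.Model().add_parameter("k1", 2.0, per_second)
    assert m.get("k1") == 2.0
    assert m.unit_of("k1") == per_second


@pytest.mark.parametrize("second_add", [
    lambda m: m.add_parameter("k1", 3.0),
    lambda m: m.add_variable("k1", 1.0),
    lambda m: m.add_derived("k1", lambda x: x, ["k1"]),
])
def test_flat_namespace_rejects_any_shadowing(second_add):
    m = kl.Model().add_parameter("k1", 2.0)
    with pytest.raises(DuplicateNameError):
        second_add(m)


def test_non_finite_values_rejected():
    with pytest.raises(ValueError):
        kl.Model().add_parameter("k", np.nan)
    with pytest.raises(ValueError):
        kl.Model().add_variable("S", np.inf)


def test_variables_preserve_insertion_order():
    m = kl.Model().add_variable("B", 2.0).add_variable("A", 1.0)
    assert m.variable_names == ["B", "A"]
    assert m.initial_state.tolist() == [2.0, 1.0]


def test_reaction_with_unknown_dependency_rejected():
    m = kl.Model().add_parameter("k", 1.0).add_variable("S", 1.0)
    with pytest.raises(UnknownReferenceError):
        m.add_reaction("v", lambda k, x: k * x, ["k", "X"], {"S": -1})
    with pytest.raises(UnknownReferenceError):
        m.add_reaction("v", lambda k: k, ["k"], {"X": -1})


def test_stoichiometric_matrix_shape_and_signs():
    m = (
        kl.Model()
        .add_parameter("k", 1.0)
        .add_variable("A", 1.0)
        .add_variable("B", 0.0)
        .add_law_reaction("v1", "mass_action", ["k", "A"], {"A": -1, "B": 1})
        .add_law_reaction("v2", "mass_action", ["k", "B"], {"B": -2, "A": 1})
    )
    N = m.stoichiometric_matrix
    assert N.shape == (2, 2)
    assert N.tolist() == [[-1.0, 1.0], [1.0, -2.0]]


# ------------------------------------------------------------------ #
# derived quantities: lazy static/dynamic classification
# ------------------------------------------------------------------ #
def test_parameter_only_derived_is_static():
    m = (kl.Model().add_parameter("k1", 2.0).add_parameter("k2", 4.0)
         .add_derived("keq", lambda a, b: a / b, ["k1", "k2"]))
    assert m.derived["keq"].kind == "static"
    assert m.get("keq") == 0.5


def test_variable_dependent_derived_is_dynamic():
    m = (kl.Model().add_variable("S1", 1.0).add_variable("S2", 2.0)
         .add_derived("ratio", lambda a, b: a / b, ["S1", "S2"]))
    assert m.derived["ratio"].kind == "dynamic"


def test_dynamic_status_propagates_through_derived_chain():
    # "a" depends only on the derived "ratio", which is dynamic through S1
    m = (kl.Model().add_parameter("k", 2.0).add_variable("S1", 1.0)
         .add_derived("ratio", lambda s, k: s / k, ["S1", "k"])
         .add_derived("a", lambda r: 2 * r, ["ratio"]))
    assert m.derived["a"].kind == "dynamic"
    m2 = (kl.Model().add_parameter("k", 2.0)
          .add_derived("half", lambda k: k / 2, ["k"])
          .add_derived("quarter", lambda h: h / 2, ["half"]))
    assert m2.derived["quarter"].kind == "static"


def test_time_dependent_derived_is_dynamic():
    m = kl.Model().add_derived("clock", lambda t: 2 * t, ["time"])
    assert m.derived["clock"].kind == "dynamic"


@settings(derandomize=True, max_examples=40)
@given(data=st.data())
def test_derived_kind_matches_reachability_oracle_on_random_dags(data):
    """Classification equals brute-force reachability to {time, variables}
    on random DAGs of up to 20 nodes."""
    n = data.draw(st.integers(3, 20))
    kinds = data.draw(st.lists(st.sampled_from(["param", "var", "derived"]),
                               min_size=n, max_size=n))
    m = kl.Model()
    deps_of: dict[str, list[str]] = {}
    names: list[str] = []
    for i, kind in enumerate(kinds):
        name = f"n{i}"
        if kind == "param":
            m.add_parameter(name, 1.0)
            deps_of[name] = []
        elif kind == "var":
            m.add_variable(name, 1.0)
            deps_of[name] = []
        else:
            pool = names + ["time"]
            deps = data.draw(st.lists(st.sampled_from(pool), min_size=0,
                                      max_size=min(4, len(pool)), unique=True))
            m.add_derived(name, lambda *a: float(sum(a)) if a else 0.0, deps)
            deps_of[name] = list(deps)
        names.append(name)

    def reaches_dynamic(node: str) -> bool:
        stack, seen = [node], set()
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            if cur == "time" or cur in m.variables:
                return True
            stack.extend(deps_of.get(cur, []))
        return False

    for name in m.derived:
        expected = "dynamic" if reaches_dynamic(name) else "static"
        assert m.derived[name].kind == expected


def test_derived_usable_inside_rate_laws():
    m = (kl.Model().add_parameter("k1", 6.0).add_parameter("k2", 3.0)
         .add_variable("S", 1.0)
         .add_derived("keq", lambda a, b: a / b, ["k1", "k2"])
         .add_reaction("v", lambda keq, s: keq * s, ["keq", "S"], {"S": -1}))
    assert m.rhs(0.0, np.array([2.0]))[0] == pytest.approx(-4.0)


def test_dynamic_stoichiometric_coefficient_rejected():
    m = (kl.Model().add_parameter("k", 1.0).add_variable("S", 1.0)
         .add_derived("dyn", lambda s: s, ["S"]))
    with pytest.raises(DependencyError):
        m.add_law_reaction("v", "mass_action", ["k", "S"], {"S": "dyn"})


def test_static_derived_stoichiometry_resolved_at_compile_time():
    m = (kl.Model().add_parameter("k", 1.0).add_parameter("n_sites", 3.0)
         .add_variable("S", 1.0)
         .add_derived("minus_n", lambda n: -n, ["n_sites"])
         .add_law_reaction("v", "constant", ["k"], {"S": "minus_n"}))
    assert m.rhs(0.0, np.array([1.0]))[0] == pytest.approx(-3.0)


# ------------------------------------------------------------------ #
# right-hand side
# ------------------------------------------------------------------ #
def test_rhs_decay_by_hand(decay):
    # N = [-1], v = k*S = 2*3 with k=2
    decay.update_parameter("k", 2.0)
    assert decay.rhs(0.0, np.array([3.0]))[0] == pytest.approx(-6.0)


def test_rhs_linear_pathway_balances_at_closed_form(pathway):
    # v1 = k1*A = 2, v2 = k2*S1 = 4*0.5 -> dS1/dt = 0
    assert pathway.rhs(0.0, np.array([0.5]))[0] == pytest.approx(0.0)


def test_rhs_zero_rate_constants_give_zero_vector(pathway):
    pathway.update_parameters({"k1": 0.0, "k2": 0.0})
    assert np.all(pathway.rhs(0.0, np.array([0.7])) == 0.0)


def test_rhs_names_offending_reaction_on_non_finite_rate():
    m = (kl.Model().add_parameter("k", 1.0).add_variable("S", 1.0)
         .add_reaction("bad_rxn", lambda k, s: float("nan"), ["k", "S"], {"S": -1}))
    with pytest.raises(NumericError, match="bad_rxn"):
        m.rhs(0.0, np.array([1.0]))


def test_rhs_is_linear_in_mass_action_rate_constants(pathway):
    state = np.array([0.3])
    base = pathway.rhs(0.0, state)
    doubled = pathway.copy().update_parameters({"k1": 2.0, "k2": 8.0})
    assert doubled.rhs(0.0, state) == pytest.approx(2.0 * base, abs=0.0)


def test_reaction_insertion_order_permutes_columns_but_not_rhs():
    def build(order):
        m = (kl.Model().add_parameter("k1", 1.5).add_parameter("k2", 0.7)
             .add_variable("A", 1.0).add_variable("B", 2.0))
        rxns = {
            "v1": (["k1", "A"], {"A": -1, "B": 1}),
            "v2": (["k2", "B"], {"B": -1}),
        }
        for name in order:
            m.add_law_reaction(name, "mass_action", *rxns[name])
        return m

    m12, m21 = build(["v1", "v2"]), build(["v2", "v1"])
    state = np.array([0.4, 1.3])
    assert m12.rhs(0.0, state) == pytest.approx(m21.rhs(0.0, state), abs=0.0)
    assert m12.stoichiometric_matrix.tolist() == [
        [c for c in row] for row in np.fliplr(m21.stoichiometric_matrix).tolist()
    ]


# ------------------------------------------------------------------ #
# unit checking
# ------------------------------------------------------------------ #
def test_consistent_flux_units_pass():
    m = (kl.Model().add_parameter("k", 1.0, per_second)
         .add_variable("S", 1.0, mM)
         .add_law_reaction("v", "mass_action", ["k", "S"], {"S": -1},
                           unit=mM_per_second))
    assert m.check_units() == []


def test_missing_per_time_flagged_with_both_units():
    m = (kl.Model().add_parameter("k", 1.0)
         .add_variable("S", 1.0, mM)
         .add_law_reaction("v", "mass_action", ["k", "S"], {"S": -1}, unit=mM))
    issues = [i for i in m.check_units() if i.kind == "mismatch"]
    assert len(issues) == 1
    assert issues[0].reaction == "v"
    assert "mM" in issues[0].actual and issues[0].expected


def test_unit_built_by_exponent_arithmetic_checks_consistent():
    # derived flux unit constructed as (mM) * (1/s)
    m = (kl.Model().add_parameter("c", 2.0, mM).add_parameter("r", 0.1, per_second)
         .add_variable("S", 1.0, mM)
         .add_derived("influx", lambda c, r: c * r, ["c", "r"], unit=mM * per_second)
         .add_reaction("v", lambda f: f, ["influx"], {"S": 1}, unit=mM * per_second))
    assert m.check_units() == []


def test_unannotated_components_yield_unchecked_notes_not_failures():
    m = (kl.Model().add_parameter("k", 1.0)
         .add_variable("S", 1.0, mM)
         .add_law_reaction("v", "mass_action", ["k", "S"], {"S": -1}))
    issues = m.check_units()
    assert [i.kind for i in issues] == ["unchecked"]


# ------------------------------------------------------------------ #
# LaTeX export
# ------------------------------------------------------------------ #
def test_latex_decay_contains_derivative_and_signed_term(decay):
    tex = decay.to_latex()
    assert r"\frac{dS}{dt}" in tex
    assert "- k S" in tex


def test_latex_empty_model_raises():
    with pytest.raises(EmptyModelError):
        kl.Model().to_latex()


def test_latex_two_reaction_pathway_one_line_per_variable_in_order():
    m = (kl.Model().add_parameter("k", 1.0)
         .add_variable("A", 1.0).add_variable("B", 0.0)
         .add_law_reaction("v1", "mass_action", ["k", "A"], {"A": -1, "B": 1})
         .add_law_reaction("v2", "mass_action", ["k", "B"], {"B": -1}))
    tex = m.to_latex()
    lines = [ln for ln in tex.splitlines() if "frac" in ln]
    assert len(lines) == 2
    assert "dA" in lines[0] and "dB" in lines[1]
    assert lines[0].strip() == r"\frac{dA}{dt} &= - k A \\"
    assert lines[1].strip() == r"\frac{dB}{dt} &= k A - k B"


def test_latex_never_drops_surrogate_terms(pathway):
    ts = kl.TrainingSet([[0.0], [1.0]], [[0.0], [0.0]], ["S1"], ["extra"])
    surr = kl.train_polynomial(ts, 1)
    hybrid = kl.add_surrogate(pathway, surr, inputs=["S1"], mode="additive",
                              outputs={"extra": {"S1": 1.0}}, name="aug")
    assert "aug" in hybrid.to_latex()


# ------------------------------------------------------------------ #
# serialization
# ------------------------------------------------------------------ #
def test_registered_law_model_round_trips_bit_exactly(tmp_path, pathway):
    path = tmp_path / "m.json"
    pathway.to_json(path)
    loaded = kl.Model.from_json(path)
    assert loaded.to_dict() == pathway.to_dict()
    state = np.array([0.37])
    assert loaded.rhs(0.0, state) == pytest.approx(pathway.rhs(0.0, state), abs=0.0)


def test_code_defined_rate_serializes_structure_only(tmp_path, stomatal):
    path = tmp_path / "s.json"
    stomatal.to_json(path)
    loaded = kl.Model.from_json(path)
    assert loaded.to_dict()["reactions"]["v_sig"].get("code_defined") is True
    with pytest.raises(NumericError, match="code-defined"):
        loaded.rhs(0.0, loaded.initial_state)
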