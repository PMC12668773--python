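"""Programmatic construction of kinetic ODE models.

A model is a set of parameters ``k``, variables ``S``, derived
quantities, and reactions with rate laws ``v(t, S, k)`` and rational
stoichiometries collected in the stoichiometric matrix ``N``.  The
compiled right-hand side is

    dS/dt = N · v(t, S, k)  (+ optional surrogate contributions)

All components live in one flat namespace: a parameter may not share a
name with a variable, derived quantity or reaction.  Rate laws and
derived quantities are pure positional functions whose dependencies are
declared explicitly at registration; the reserved name ``"time"``
refers to simulation time.  Declared dependencies drive the automatic
static/dynamic classification of derived quantities (lazy evaluation):
a derived quantity is *dynamic* iff its transitive dependency closure
contains time, a variable, or another dynamic derived quantity.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import (
    DependencyError,
    DuplicateNameError,
    EmptyModelError,
    NumericError,
    UnknownReferenceError,
)
from .ratelaws import RATE_LAWS, expression_tree
from .units import Unit

TIME = "time"


@dataclass
class Parameter:
    name: str
    value: float
    unit: Unit | None = None


@dataclass
class Variable:
    name: str
    initial: float
    unit: Unit | None = None
    signed: bool = False  # True permits negative initial values (potentials etc.)


@dataclass
class Reaction:
    name: str
    fn: Callable[..., float]
    args: tuple[str, ...]
    stoichiometry: dict[str, Fraction | str]  # str names a static derived quantity
    unit: Unit | None = None
    law: tuple[str, tuple[str, ...]] | None = None  # (registered-law id, args)


@dataclass
class DerivedQuantity:
    name: str
    fn: Callable[..., float]
    dependencies: tuple[str, ...]
    kind: str = "static"  # computed, not user-set
    unit: Unit | None = None


@dataclass
class UnitIssue:
    """One unit-consistency finding; ``kind`` is 'mismatch' or 'unchecked'."""

    kind: str
    reaction: str
    variable: str | None
    expected: str
    actual: str
    message: str


def _code_defined_placeholder(name: str) -> Callable[..., float]:
    def _raise(*_args: float) -> float:
        raise NumericError(
            f"{name!r} was deserialized structure-only (code-defined function); "
            "re-attach its function before evaluation"
        )

    return _raise


class Model:
    """Container and compiler for a kinetic model (builder-style API).

    All ``add_*`` methods return the model itself so construction chains::

        m = (Model("decay")
             .add_parameter("k", 2.0)
             .add_variable("S", 3.0)
             .add_reaction("v1", lambda k, s: k * s, args=["k", "S"],
                           stoichiometry={"S": -1}))
    """

    def __init__(self, name: str = "model", annotations: dict | None = None) -> None:
        self.name = name
        self.annotations: dict = dict(annotations or {})
        self.parameters: dict[str, Parameter] = {}
        self.variables: dict[str, Variable] = {}
        self.derived: dict[str, DerivedQuantity] = {}
        self.reactions: dict[str, Reaction] = {}
        self.surrogate_bindings: list = []  # populated via kinlearn.surrogate
        self.time_unit: Unit = Unit({"time": 1}, display="s")
        self._rate_scales: dict[str, float] = {}  # per-reaction multipliers (MCA)
        self._compiled: dict | None = None

    # ------------------------------------------------------------------ #
    # registration
    # ------------------------------------------------------------------ #
    def _check_name_free(self, name: str) -> None:
        if not name or not isinstance(name, str):
            raise DuplicateNameError(f"invalid component name {name!r}")
        if name == TIME:
            raise DuplicateNameError("'time' is reserved for simulation time")
        for registry in (self.parameters, self.variables, self.derived, self.reactions):
            if name in registry:
                raise DuplicateNameError(f"name {name!r} already used in this model")

    def add_parameter(self, name: str, value: float, unit: Unit | None = None) -> "Model":
        self._check_name_free(name)
        if not np.isfinite(value):
            raise ValueError(f"parameter {name!r}: value must be finite, got {value!r}")
        self.parameters[name] = Parameter(name, float(value), unit)
        self._compiled = None
        return self

    def add_variable(
        self, name: str, initial: float, unit: Unit | None = None, signed: bool = False
    ) -> "Model":
        self._check_name_free(name)
        if not np.isfinite(initial):
            raise ValueError(f"variable {name!r}: initial value must be finite")
        if initial < 0 and not signed:
            raise ValueError(
                f"variable {name!r}: negative initial value requires signed=True"
            )
        self.variables[name] = Variable(name, float(initial), unit, signed)
        self._compiled = None
        return self

    def add_derived(
        self,
        name: str,
        fn: Callable[..., float],
        dependencies: Sequence[str],
        unit: Unit | None = None,
    ) -> "Model":
        self._check_name_free(name)
        deps = tuple(dependencies)
        for dep in deps:
            if dep != TIME and not self._name_exists(dep):
                raise UnknownReferenceError(
                    f"derived {name!r}: unknown dependency {dep!r}"
                )
            if dep in self.reactions:
                raise DependencyError(
                    f"derived {name!r}: reactions cannot be dependencies"
                )
        kind = "dynamic" if self._closure_is_dynamic(deps) else "static"
        self.derived[name] = DerivedQuantity(name, fn, deps, kind, unit)
        self._compiled = None
        return self

    def add_reaction(
        self,
        name: str,
        fn: Callable[..., float],
        args: Sequence[str],
        stoichiometry: Mapping[str, float | Fraction | str],
        unit: Unit | None = None,
        law: tuple[str, Sequence[str]] | None = None,
    ) -> "Model":
        self._check_name_free(name)
        if not stoichiometry:
            raise ValueError(f"reaction {name!r}: stoichiometry must be nonempty")
        arg_names = tuple(args)
        for dep in arg_names:
            if dep != TIME and not self._name_exists(dep):
                raise UnknownReferenceError(f"reaction {name!r}: unknown dependency {dep!r}")
        stoich: dict[str, Fraction | str] = {}
        for var, coeff in stoichiometry.items():
            if var not in self.variables:
                raise UnknownReferenceError(
                    f"reaction {name!r}: stoichiometry references unknown variable {var!r}"
                )
            if isinstance(coeff, str):
                dq = self.derived.get(coeff)
                if dq is None:
                    raise UnknownReferenceError(
                        f"reaction {name!r}: stoichiometric coefficient names unknown "
                        f"derived quantity {coeff!r}"
                    )
                if dq.kind != "static":
                    raise DependencyError(
                        f"reaction {name!r}: stoichiometric coefficient {coeff!r} is a "
                        "dynamic derived quantity; N must be constant, so dynamic "
                        "stoichiometries are rejected"
                    )
                stoich[var] = coeff
            else:
                stoich[var] = Fraction(coeff).limit_denominator(10**9) if isinstance(
                    coeff, float
                ) else Fraction(coeff)
        self.reactions[name] = Reaction(
            name, fn, arg_names, stoich, unit,
            (law[0], tuple(law[1])) if law is not None else None,
        )
        self._compiled = None
        return self

    def add_law_reaction(
        self,
        name: str,
        law_id: str,
        args: Sequence[str],
        stoichiometry: Mapping[str, float | Fraction | str],
        unit: Unit | None = None,
    ) -> "Model":
        """Register a reaction from the registered rate-law library.

        Such reactions serialize round-trip bit-exactly and render
        symbolically in the LaTeX export.
        """
        law = RATE_LAWS[law_id]
        if law.arity is not None and len(args) != law.arity:
            raise ValueError(
                f"rate law {law_id!r} takes {law.arity} arguments, got {len(args)}"
            )
        return self.add_reaction(name, law.fn, args, stoichiometry, unit, law=(law_id, args))

    # ------------------------------------------------------------------ #
    # lookup & mutation
    # ------------------------------------------------------------------ #
    def _name_exists(self, name: str) -> bool:
        return (
            name in self.parameters or name in self.variables or name in self.derived
        )

    def get(self, name: str) -> float:
        """Value of a parameter, a variable's initial, or a static derived."""
        if name in self.parameters:
            return self.parameters[name].value
        if name in self.variables:
            return self.variables[name].initial
        if name in self.derived:
            dq = self.derived[name]
            if dq.kind != "static":
                raise DependencyError(f"{name!r} is dynamic; evaluate it along a trajectory")
            return self._static_env()[name]
        raise UnknownReferenceError(name)

    def unit_of(self, name: str) -> Unit | None:
        for registry in (self.parameters, self.variables, self.derived, self.reactions):
            if name in registry:
                return registry[name].unit
        raise UnknownReferenceError(name)

    def update_parameter(self, name: str, value: float) -> "Model":
        if name not in self.parameters:
            raise UnknownReferenceError(f"unknown parameter {name!r}")
        if not np.isfinite(value):
            raise ValueError(f"parameter {name!r}: value must be finite")
        self.parameters[name].value = float(value)
        self._compiled = None
        return self

    def update_parameters(self, values: Mapping[str, float]) -> "Model":
        for name, value in values.items():
            self.update_parameter(name, value)
        return self

    def update_initial(self, name: str, value: float) -> "Model":
        if name not in self.variables:
            raise UnknownReferenceError(f"unknown variable {name!r}")
        self.variables[name].initial = float(value)
        return self

    def scale_reaction(self, name: str, factor: float) -> "Model":
        """Multiply a reaction's rate by ``factor`` (perturbation hook for MCA)."""
        if name not in self.reactions:
            raise UnknownReferenceError(f"unknown reaction {name!r}")
        self._rate_scales[name] = float(factor)
        return self

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    @property
    def variable_names(self) -> list[str]:
        return list(self.variables)

    @property
    def reaction_names(self) -> list[str]:
        return list(self.reactions)

    @property
    def parameter_values(self) -> dict[str, float]:
        return {n: p.value for n, p in self.parameters.items()}

    @property
    def initial_state(self) -> np.ndarray:
        return np.array([v.initial for v in self.variables.values()], dtype=float)

    def dynamic_derived_names(self) -> list[str]:
        return [n for n, d in self.derived.items() if d.kind == "dynamic"]

    # ------------------------------------------------------------------ #
    # evaluation
    # ------------------------------------------------------------------ #
    def _closure_is_dynamic(self, deps: Sequence[str]) -> bool:
        stack = list(deps)
        seen: set[str] = set()
        while stack:
            dep = stack.pop()
            if dep in seen:
                continue
            seen.add(dep)
            if dep == TIME or dep in self.variables:
                return True
            if dep in self.derived:
                dq = self.derived[dep]
                if dq.kind == "dynamic":
                    return True
                stack.extend(dq.dependencies)
        return False

    def _static_env(self) -> dict[str, float]:
        env = {n: p.value for n, p in self.parameters.items()}
        for name, dq in self.derived.items():  # insertion order topological by construction
            if dq.kind == "static":
                env[name] = float(dq.fn(*(env[d] for d in dq.dependencies)))
        return env

    def _env(self, t: float, state: np.ndarray) -> dict[str, float]:
        env: dict[str, float] = {TIME: float(t)}
        env.update((n, p.value) for n, p in self.parameters.items())
        env.update(zip(self.variables, state))
        for name, dq in self.derived.items():
            env[name] = float(dq.fn(*(env[d] for d in dq.dependencies)))
        return env

    def _compile(self) -> dict:
        if self._compiled is None:
            static_env = self._static_env()
            n_var = len(self.variables)
            var_index = {n: i for i, n in enumerate(self.variables)}
            N = np.zeros((n_var, len(self.reactions)))
            for j, rxn in enumerate(self.reactions.values()):
                for var, coeff in rxn.stoichiometry.items():
                    value = static_env[coeff] if isinstance(coeff, str) else float(coeff)
                    N[var_index[var], j] = value
            self._compiled = {"N": N, "var_index": var_index}
        return self._compiled

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        """N with one row per variable, one column per reaction (insertion order)."""
        return self._compile()["N"].copy()

    def rates(self, t: float, state: np.ndarray) -> np.ndarray:
        env = self._env(t, state)
        out = np.empty(len(self.reactions))
        for j, rxn in enumerate(self.reactions.values()):
            value = rxn.fn(*(env[a] for a in rxn.args))
            scale = self._rate_scales.get(rxn.name)
            if scale is not None:
                value *= scale
            if not np.isfinite(value):
                raise NumericError(
                    f"reaction {rxn.name!r} evaluated to a non-finite rate at t={t}"
                )
            out[j] = value
        return out

    def rhs(self, t: float, state: np.ndarray) -> np.ndarray:
        """Right-hand side N·v(t, S, k) plus any surrogate contributions."""
        state = np.asarray(state, dtype=float)
        if state.shape != (len(self.variables),):
            raise ValueError(
                f"state has length {state.shape}, model has {len(self.variables)} variables"
            )
        comp = self._compile()
        dsdt = comp["N"] @ self.rates(t, state)
        for binding in self.surrogate_bindings:
            dsdt = dsdt + binding.contribution(self, t, state)
        return dsdt

    def derived_values(self, t: float, state: np.ndarray) -> dict[str, float]:
        env = self._env(t, state)
        return {n: env[n] for n in self.derived}

    # ------------------------------------------------------------------ #
    # unit checking
    # ------------------------------------------------------------------ #
    def check_units(self) -> list[UnitIssue]:
        """Check flux-unit consistency: unit(v_j) must equal unit(X)/unit(time)
        for every variable X the reaction j changes.

        Components lacking annotations produce 'unchecked' notes; genuine
        inconsistencies produce 'mismatch' reports.  An empty list means
        every annotated pairing is consistent and nothing was skipped.
        """
        issues: list[UnitIssue] = []
        for rxn in self.reactions.values():
            for var in rxn.stoichiometry:
                v_unit = self.variables[var].unit
                if rxn.unit is None or v_unit is None:
                    issues.append(
                        UnitIssue(
                            "unchecked", rxn.name, var,
                            expected="?", actual="?",
                            message=f"reaction {rxn.name!r} / variable {var!r}: "
                                    "missing unit annotation",
                        )
                    )
                    continue
                expected = v_unit / self.time_unit
                if rxn.unit != expected:
                    issues.append(
                        UnitIssue(
                            "mismatch", rxn.name, var,
                            expected=str(expected), actual=str(rxn.unit),
                            message=f"reaction {rxn.name!r} has unit {rxn.unit} but "
                                    f"variable {var!r} requires flux unit {expected}",
                        )
                    )
        return issues

    # ------------------------------------------------------------------ #
    # LaTeX export
    # ------------------------------------------------------------------ #
    def to_latex(self) -> str:
        r"""Render the ODE system as an aligned LaTeX fragment.

        One equation per variable in insertion order.  Registered rate
        laws render symbolically; code-defined rates render as opaque
        terms ``v_{name}(deps)``; surrogate contributions render as
        opaque named terms and are never dropped.
        """
        if not self.variables:
            raise EmptyModelError("cannot render an empty model")
        lines = []
        for var in self.variables:
            terms: list[str] = []
            for rxn in self.reactions.values():
                coeff = rxn.stoichiometry.get(var)
                if coeff is None:
                    continue
                if rxn.law is not None:
                    body = RATE_LAWS[rxn.law[0]].latex(rxn.law[1])
                else:
                    body = rf"v_{{\mathrm{{{rxn.name}}}}}\left({', '.join(rxn.args)}\right)"
                terms.append(_signed_term(coeff, body, first=not terms))
            for binding in self.surrogate_bindings:
                term = binding.latex_term(var)
                if term:
                    terms.append(("+ " if terms else "") + term)
            body = " ".join(terms) if terms else "0"
            lines.append(rf"\frac{{d{var}}}{{dt}} &= {body}")
        return "\\begin{align}\n" + " \\\\\n".join(lines) + "\n\\end{align}"

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        def frac(x: Fraction | str):
            return x if isinstance(x, str) else [x.numerator, x.denominator]

        reactions = {}
        for name, rxn in self.reactions.items():
            entry: dict = {
                "stoichiometry": {v: frac(c) for v, c in rxn.stoichiometry.items()},
                "args": list(rxn.args),
                "unit": rxn.unit.to_dict() if rxn.unit else None,
            }
            if rxn.law is not None:
                entry["law"] = rxn.law[0]
            else:
                entry["code_defined"] = True
            reactions[name] = entry
        return {
            "name": self.name,
            "annotations": self.annotations,
            "parameters": {
                n: {"value": p.value, "unit": p.unit.to_dict() if p.unit else None}
                for n, p in self.parameters.items()
            },
            "variables": {
                n: {
                    "initial": v.initial,
                    "signed": v.signed,
                    "unit": v.unit.to_dict() if v.unit else None,
                }
                for n, v in self.variables.items()
            },
            "derived": {
                n: {"dependencies": list(d.dependencies), "kind": d.kind,
                    "code_defined": True}
                for n, d in self.derived.items()
            },
            "reactions": reactions,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Model":
        m = cls(data.get("name", "model"), data.get("annotations"))
        unit = lambda u: Unit.from_dict(u) if u else None  # noqa: E731
        for n, p in data.get("parameters", {}).items():
            m.add_parameter(n, p["value"], unit(p.get("unit")))
        for n, v in data.get("variables", {}).items():
            m.add_variable(n, v["initial"], unit(v.get("unit")), v.get("signed", False))
        for n, d in data.get("derived", {}).items():
            m.add_derived(n, _code_defined_placeholder(n), d["dependencies"])
        for n, r in data.get("reactions", {}).items():
            stoich = {
                v: (c if isinstance(c, str) else Fraction(c[0], c[1]))
                for v, c in r["stoichiometry"].items()
            }
            if "law" in r:
                m.add_law_reaction(n, r["law"], r["args"], stoich, unit(r.get("unit")))
            else:
                m.add_reaction(
                    n, _code_defined_placeholder(n), r["args"], stoich, unit(r.get("unit"))
                )
        return m

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Model":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def rate_expression_trees(self) -> dict[str, tuple]:
        """Expression trees of registered-law reactions (symbolic extension hook)."""
        return {
            n: expression_tree(r.law[0], r.law[1])
            for n, r in self.reactions.items()
            if r.law is not None
        }

    def __repr__(self) -> str:
        return (
            f"Model({self.name!r}: {len(self.parameters)} parameters, "
            f"{len(self.variables)} variables, {len(self.reactions)} reactions, "
            f"{len(self.derived)} derived, {len(self.surrogate_bindings)} surrogates)"
        )


def _signed_term(coeff: Fraction | str, body: str, first: bool) -> str:
    if isinstance(coeff, str):
        prefix = "" if first else "+ "
        return rf"{prefix}\mathrm{{{coeff}}} \cdot {body}"
    sign = "- " if coeff < 0 else ("" if first else "+ ")
    mag = abs(coeff)
    if mag == 1:
        return f"{sign}{body}"
    mag_str = str(mag.numerator) if mag.denominator == 1 else rf"\frac{{{mag.numerator}}}{{{mag.denominator}}}"
    return f"{sign}{mag_str} \\cdot {body}"
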