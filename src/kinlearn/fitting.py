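"""Multi-experiment parameter estimation.

An *experiment* pairs a model with a dataset (time series and/or
steady-state observations) and optional local parameter overrides.  A
:class:`SharedParameterMap` defines one global parameter vector and how
it distributes onto each experiment's model parameters, enabling
ensembles where some parameters are shared across models while others
stay experiment-local.  The default objective is weighted least
squares; minimizer, residual method and integrator options are all
injectable, so likelihood-based objectives or custom optimizers slot in
without touching the plumbing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import MappingError, ValidationError
from .model import Model
from .simulate import IntegratorOptions, steady_state, time_course

PENALTY = 1e6  # residual magnitude (× weight) substituted on simulation failure


@dataclass
class Dataset:
    """Observations for one experiment.

    kind "time-series": records (time, name, value, weight);
    kind "steady-state": records (name, value, weight).
    """

    kind: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in ("time-series", "steady-state"):
            raise ValidationError(f"unknown dataset kind {self.kind!r}")
        required = {"name", "value", "weight"} | (
            {"time"} if self.kind == "time-series" else set()
        )
        missing = required - set(self.records.columns)
        if missing:
            raise ValidationError(f"dataset missing columns {sorted(missing)}")
        if (self.records["weight"] <= 0).any():
            raise ValidationError("weights must be positive")

    @classmethod
    def time_series(cls, times, names, values, weights=None) -> "Dataset":
        n = len(times)
        return cls("time-series", pd.DataFrame({
            "time": times, "name": names, "value": values,
            "weight": weights if weights is not None else np.ones(n),
        }))

    @classmethod
    def steady_state_data(cls, names, values, weights=None) -> "Dataset":
        return cls("steady-state", pd.DataFrame({
            "name": names, "value": values,
            "weight": weights if weights is not None else np.ones(len(names)),
        }))

    @property
    def n_observations(self) -> int:
        return len(self.records)

    def validate_against(self, model: Model) -> None:
        for name in self.records["name"].unique():
            if name not in model.variables and name not in model.reactions:
                raise ValidationError(
                    f"observed name {name!r} is neither variable nor reaction"
                )


@dataclass
class ExperimentSpec:
    model: Model
    dataset: Dataset
    local_overrides: dict[str, float] = field(default_factory=dict)
    residual_method: Callable | None = None  # (predicted, observed, weight) -> residuals
    options: IntegratorOptions | None = None

    def __post_init__(self) -> None:
        self.dataset.validate_against(self.model)
        for name in self.local_overrides:
            if name not in self.model.parameters:
                raise ValidationError(f"local override {name!r} not a model parameter")


@dataclass
class SharedParameterMap:
    """Bijection between one global vector and per-experiment parameters.

    ``global_names`` orders the vector; ``bindings[e]`` maps global name
    -> that experiment's model parameter name; ``fixed`` pins model
    parameters to constants outside the fit.
    """

    global_names: list[str]
    bindings: list[dict[str, str]]
    fixed: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fixed:
            self.fixed = [{} for _ in self.bindings]
        if len(self.fixed) != len(self.bindings):
            raise MappingError("fixed list must align with bindings")
        for e, binding in enumerate(self.bindings):
            targets = list(binding.values())
            if len(set(targets)) != len(targets):
                raise MappingError(
                    f"experiment {e}: a model parameter is bound more than once"
                )
            unknown = set(binding) - set(self.global_names)
            if unknown:
                raise MappingError(f"experiment {e}: unknown global names {unknown}")

    def validate_against(self, specs: Sequence[ExperimentSpec]) -> None:
        if len(specs) != len(self.bindings):
            raise MappingError("one binding dict per experiment required")
        for e, (spec, binding, fixed) in enumerate(zip(specs, self.bindings, self.fixed)):
            for target in list(binding.values()) + list(fixed):
                if target not in spec.model.parameters:
                    raise MappingError(
                        f"experiment {e}: {target!r} is not a model parameter"
                    )
            overlap = set(binding.values()) & set(fixed)
            if overlap:
                raise MappingError(
                    f"experiment {e}: parameters {overlap} both bound and fixed"
                )

    def pack(self, assignments: Sequence[Mapping[str, float]]) -> np.ndarray:
        """Collect per-experiment parameter assignments into the global vector."""
        vector = np.full(len(self.global_names), np.nan)
        for e, binding in enumerate(self.bindings):
            for g, target in binding.items():
                idx = self.global_names.index(g)
                value = assignments[e][target]
                if not np.isnan(vector[idx]) and vector[idx] != value:
                    raise MappingError(
                        f"inconsistent values for shared parameter {g!r}"
                    )
                vector[idx] = value
        if np.any(np.isnan(vector)):
            missing = [g for g, v in zip(self.global_names, vector) if np.isnan(v)]
            raise MappingError(f"global parameters {missing} not bound anywhere")
        return vector

    def unpack(self, vector: np.ndarray) -> list[dict[str, float]]:
        """Distribute the global vector onto per-experiment assignments."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (len(self.global_names),):
            raise MappingError(
                f"vector length {vector.shape[0]} != {len(self.global_names)} globals"
            )
        lookup = dict(zip(self.global_names, vector))
        out = []
        for binding, fixed in zip(self.bindings, self.fixed):
            assign = {target: lookup[g] for g, target in binding.items()}
            assign.update(fixed)
            out.append(assign)
        return out


def residuals(
    specs: Sequence[ExperimentSpec],
    pmap: SharedParameterMap,
    global_vector: np.ndarray,
    strict: bool = False,
) -> np.ndarray:
    """Weighted residual vector, concatenated in experiment order.

    Per experiment the model is simulated at exactly the observed times
    (or to steady state) and residual = weight·(observed − predicted).
    Simulation failures yield penalty residuals so local search can
    retreat; ``strict=True`` re-raises instead.
    """
    pmap.validate_against(specs)
    assignments = pmap.unpack(global_vector)
    out: list[np.ndarray] = []
    for spec, assign in zip(specs, assignments):
        model = spec.model.copy()
        model.update_parameters(spec.local_overrides)
        model.update_parameters(assign)
        rec = spec.dataset.records
        method = spec.residual_method or (
            lambda predicted, observed, weight: weight * (observed - predicted)
        )
        try:
            if spec.dataset.kind == "time-series":
                times = np.sort(rec["time"].unique())
                tc = time_course(model, times, spec.options)
                lut = {}
                for name in rec["name"].unique():
                    series = (tc.variables[name] if name in tc.variables.columns
                              else tc.fluxes[name])
                    lut[name] = dict(zip(tc.times, series))
                predicted = np.array(
                    [lut[n][t] for n, t in zip(rec["name"], rec["time"])]
                )
            else:
                ss = steady_state(model, spec.options)
                if not ss.converged:
                    raise ValidationError("steady state did not converge")
                values = {**ss.state_dict(), **ss.flux_dict()}
                predicted = np.array([values[n] for n in rec["name"]])
            out.append(method(predicted, rec["value"].to_numpy(),
                              rec["weight"].to_numpy()))
        except Exception:
            if strict:
                raise
            out.append(PENALTY * rec["weight"].to_numpy())
    return np.concatenate(out)


@dataclass
class FitResult:
    global_vector: np.ndarray
    objective: float
    per_experiment_norms: list[float]
    trace: list
    converged: bool
    global_names: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.global_names, self.global_vector))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "parameters": self.as_dict(), "objective": self.objective,
                "per_experiment_norms": self.per_experiment_norms,
                "converged": self.converged,
            }, fh, indent=2)


def _default_minimizer(residual_fn, x0, bounds):
    lo = [b[0] if b is not None else -np.inf for b in bounds]
    hi = [b[1] if b is not None else np.inf for b in bounds]
    res = least_squares(residual_fn, x0, bounds=(lo, hi))
    return res.x, [f"least_squares: {res.message}"], bool(res.success)


def fit(
    specs: Sequence[ExperimentSpec],
    pmap: SharedParameterMap,
    initial_vector: np.ndarray,
    minimizer: Callable | None = None,
    bounds: Sequence[tuple[float, float] | None] | None = None,
) -> FitResult:
    """Minimize the weighted least-squares objective over the global vector.

    ``minimizer`` follows the contract
    ``minimizer(residual_fn, x0, bounds) -> (optimum, trace, converged)``;
    the default is bounded local least squares.  A failing minimizer
    yields a non-converged result carrying the best point seen.
    """
    x0 = np.asarray(initial_vector, dtype=float)
    if x0.shape != (len(pmap.global_names),):
        raise MappingError("initial vector length must match the global names")
    bounds = list(bounds) if bounds is not None else [None] * len(x0)
    for xi, b in zip(x0, bounds):
        if b is not None and not (b[0] <= xi <= b[1]):
            raise ValidationError("initial vector must lie within bounds")
    best: dict = {"x": x0.copy(), "obj": np.inf}

    def residual_fn(x: np.ndarray) -> np.ndarray:
        r = residuals(specs, pmap, x)
        obj = float(np.sum(r**2))
        if obj < best["obj"]:
            best["x"], best["obj"] = np.asarray(x, dtype=float).copy(), obj
        return r

    minimizer = minimizer or _default_minimizer
    try:
        x_opt, trace, converged = minimizer(residual_fn, x0, bounds)
        x_opt = np.asarray(x_opt, dtype=float)
    except Exception as exc:
        x_opt, trace, converged = best["x"], [f"minimizer failed: {exc}"], False
    r = residuals(specs, pmap, x_opt)
    norms = []
    offset = 0
    for spec in specs:
        n = spec.dataset.n_observations
        norms.append(float(np.linalg.norm(r[offset : offset + n])))
        offset += n
    return FitResult(x_opt, float(np.sum(r**2)), norms, list(trace), converged,
                     list(pmap.global_names))


def multi_start_fit(
    specs: Sequence[ExperimentSpec],
    pmap: SharedParameterMap,
    bounds: Sequence[tuple[float, float]],
    n_starts: int = 5,
    seed: int = 0,
    minimizer: Callable | None = None,
) -> FitResult:
    """Seeded multi-start wrapper: uniform starts within bounds, best fit wins."""
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best: FitResult | None = None
    for _ in range(n_starts):
        x0 = rng.uniform(lo, hi)
        result = fit(specs, pmap, x0, minimizer, bounds)
        if best is None or result.objective < best.objective:
            best = result
    assert best is not None
    return best


def dataset_to_csv(datasets: Mapping[str, Dataset], path) -> None:
    """Tidy CSV export: experiment, kind, time?, name, value, weight."""
    frames = []
    for exp, ds in datasets.items():
        rec = ds.records.copy()
        rec.insert(0, "experiment", exp)
        rec.insert(1, "kind", ds.kind)
        frames.append(rec)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def dataset_from_csv(path) -> dict[str, Dataset]:
    df = pd.read_csv(path)
    out = {}
    for (exp, kind), sub in df.groupby(["experiment", "kind"]):
        cols = ["time", "name", "value", "weight"] if kind == "time-series" else [
            "name", "value", "weight"]
        out[exp] = Dataset(kind, sub[cols].reset_index(drop=True))
    return out
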