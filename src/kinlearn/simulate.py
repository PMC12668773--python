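"""Numerical integration of kinetic models.

Three entry points:

* :func:`time_course` — plain integration on a user grid.
* :func:`protocol_time_course` — integration under a piecewise-constant
  schedule of parameter overrides (light/dark phases, perturbation
  protocols).  The parameter switch is instantaneous; each boundary time
  point belongs to the *later* segment, and the final state of one
  segment seeds the next, so trajectories are continuous across
  boundaries by construction.
* :func:`steady_state` — "integrate-then-refine": integrate until the
  right-hand side is small, then polish with damped Newton on
  N·v(S) = 0.  A singular Jacobian (the signature of a conservation
  relation) is reported as a diagnostic, never silently ignored.

Fluxes in a :class:`TimeCourse` are always recomputed from the returned
states, never interpolated, so the container is self-consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import NumericError, UnknownReferenceError, ValidationError
from .model import Model


@dataclass
class IntegratorOptions:
    """Solver configuration.

    ``method="stiff"`` selects a stiff-capable adaptive solver (LSODA);
    ``method="explicit"`` selects an explicit Runge-Kutta pair (RK45).
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float | None = None
    method: str = "stiff"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValidationError("integrator tolerances must be positive")
        if self.method not in ("stiff", "explicit"):
            raise ValidationError(f"unknown method {self.method!r}")

    @property
    def scipy_method(self) -> str:
        return "LSODA" if self.method == "stiff" else "RK45"

    def solve_kwargs(self) -> dict:
        kw = {"method": self.scipy_method, "rtol": self.rtol, "atol": self.atol}
        if self.max_step is not None:
            kw["max_step"] = self.max_step
        return kw


@dataclass
class TimeCourse:
    """A single trajectory: states, recomputed fluxes and dynamic derived."""

    times: np.ndarray
    variables: pd.DataFrame  # time × variable
    fluxes: pd.DataFrame  # time × reaction
    derived: pd.DataFrame  # time × dynamic derived quantity
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("time axis must be strictly increasing")
        for df in (self.variables, self.fluxes, self.derived):
            if len(df) != len(self.times):
                raise ValidationError("row counts of times and value tables must match")

    @property
    def final_state(self) -> np.ndarray:
        return self.variables.iloc[-1].to_numpy()

    def to_tidy(self) -> pd.DataFrame:
        frames = []
        for kind, df in (("variable", self.variables), ("flux", self.fluxes),
                         ("derived", self.derived)):
            if df.shape[1] == 0:
                continue
            long = df.melt(ignore_index=False, var_name="name", value_name="value")
            long.insert(0, "time", np.tile(self.times, df.shape[1]))
            long.insert(1, "kind", kind)
            frames.append(long.reset_index(drop=True))
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["time", "kind", "name", "value"]
        )

    def to_csv(self, path, sidecar_path=None) -> None:
        self.to_tidy().to_csv(path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.provenance, fh, indent=2, default=str)

    @classmethod
    def from_csv(cls, path, sidecar_path=None) -> "TimeCourse":
        tidy = pd.read_csv(path)
        prov = {}
        if sidecar_path is not None:
            with open(sidecar_path) as fh:
                prov = json.load(fh)
        times = np.sort(tidy["time"].unique())
        tables = {}
        for kind in ("variable", "flux", "derived"):
            sub = tidy[tidy["kind"] == kind]
            tables[kind] = (
                sub.pivot(index="time", columns="name", values="value").reindex(times)
                if len(sub)
                else pd.DataFrame(index=times)
            )
        return cls(times, tables["variable"].reset_index(drop=True),
                   tables["flux"].reset_index(drop=True),
                   tables["derived"].reset_index(drop=True), prov)


@dataclass
class Protocol:
    """Ordered piecewise-constant parameter schedule."""

    segments: list[tuple[float, dict[str, float]]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("protocol needs at least one segment")
        for duration, overrides in self.segments:
            if not duration > 0:
                raise ValidationError("segment durations must be positive")
            if not isinstance(overrides, Mapping):
                raise ValidationError("segment overrides must be a mapping")

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _ in self.segments))

    def validate_against(self, model: Model) -> None:
        for _, overrides in self.segments:
            for name in overrides:
                if name not in model.parameters:
                    raise UnknownReferenceError(
                        f"protocol overrides unknown parameter {name!r}"
                    )


@dataclass
class SteadyStateResult:
    state: np.ndarray
    fluxes: np.ndarray
    residual_norm: float
    converged: bool
    method_trace: list[str]
    variable_names: list[str] = field(default_factory=list)
    reaction_names: list[str] = field(default_factory=list)

    def state_dict(self) -> dict[str, float]:
        return dict(zip(self.variable_names, self.state))

    def flux_dict(self) -> dict[str, float]:
        return dict(zip(self.reaction_names, self.fluxes))


def _assemble(model: Model, times: np.ndarray, states: np.ndarray,
              provenance: dict) -> TimeCourse:
    fluxes = np.array([model.rates(t, s) for t, s in zip(times, states)]) \
        if model.reactions else np.empty((len(times), 0))
    dyn = model.dynamic_derived_names()
    derived = np.array(
        [[model.derived_values(t, s)[n] for n in dyn] for t, s in zip(times, states)]
    ) if dyn else np.empty((len(times), 0))
    return TimeCourse(
        times=np.asarray(times, dtype=float),
        variables=pd.DataFrame(states, columns=model.variable_names),
        fluxes=pd.DataFrame(fluxes, columns=model.reaction_names),
        derived=pd.DataFrame(derived, columns=dyn),
        provenance=provenance,
    )


def time_course(
    model: Model,
    t_eval: Sequence[float],
    options: IntegratorOptions | None = None,
    y0: np.ndarray | None = None,
) -> TimeCourse:
    """Integrate dS/dt = N·v from t=0 over a strictly increasing grid."""
    options = options or IntegratorOptions()
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.ndim != 1 or len(t_eval) == 0:
        raise ValidationError("t_eval must be a nonempty 1-D grid")
    if not np.all(np.diff(t_eval) > 0):
        raise ValidationError("t_eval must be strictly increasing")
    if t_eval[0] < 0:
        raise ValidationError("t_eval must start at t >= 0")
    y0 = model.initial_state if y0 is None else np.asarray(y0, dtype=float)

    sol = solve_ivp(model.rhs, (0.0, float(t_eval[-1])), y0, t_eval=t_eval,
                    **options.solve_kwargs())
    if not sol.success:
        last_t = sol.t[-1] if len(sol.t) else 0.0
        raise NumericError(
            f"integration of {model.name!r} failed: {sol.message} "
            f"(last successful time t={last_t})"
        )
    states = sol.y.T.copy()
    if t_eval[0] == 0.0:
        states[0] = y0  # the t=0 row is the initial state, exactly
    provenance = {
        "model": model.name,
        "parameters": model.parameter_values,
        "options": vars(options).copy(),
        "seed_irrelevant": True,
    }
    return _assemble(model, sol.t, states, provenance)


def protocol_time_course(
    model: Model,
    protocol: Protocol,
    points_per_segment: int = 50,
    options: IntegratorOptions | None = None,
) -> TimeCourse:
    """Integrate under a piecewise-constant parameter schedule.

    The time axis is cumulative over segments; each internal boundary
    point belongs to the later segment and the final state of segment i
    seeds segment i+1 (continuity by construction).
    """
    options = options or IntegratorOptions()
    protocol.validate_against(model)
    work = model.copy()
    state = work.initial_state
    t_offset = 0.0
    all_times: list[np.ndarray] = []
    all_states: list[np.ndarray] = []
    snapshots = []
    for i, (duration, overrides) in enumerate(protocol.segments):
        work.update_parameters(overrides)
        local = np.linspace(0.0, duration, points_per_segment + 1)
        sol = solve_ivp(work.rhs, (0.0, duration), state, t_eval=local,
                        **options.solve_kwargs())
        if not sol.success:
            raise NumericError(
                f"protocol segment {i} failed: {sol.message} "
                f"(last successful time t={t_offset + sol.t[-1]})"
            )
        # each boundary appears once; flux assembly below assigns it to the
        # later segment, implementing the boundary-belongs-to-later convention
        keep = slice(0, None) if i == 0 else slice(1, None)
        all_times.append(local[keep] + t_offset)
        all_states.append(sol.y.T[keep])
        state = sol.y.T[-1]
        t_offset += duration
        snapshots.append({"segment": i, "duration": duration,
                          "parameters": work.parameter_values})
    times = np.concatenate(all_times)
    states = np.concatenate(all_states, axis=0)
    provenance = {
        "model": model.name,
        "segments": snapshots,
        "options": vars(options).copy(),
        "seed_irrelevant": True,
    }
    # assemble fluxes segment-wise so per-segment parameters apply
    return _assemble_protocol(model, protocol, times, states, provenance)


def _assemble_protocol(model: Model, protocol: Protocol, times, states,
                       provenance) -> TimeCourse:
    work = model.copy()
    boundaries = np.cumsum([d for d, _ in protocol.segments])
    seg_of_time = np.searchsorted(boundaries, times, side="right")
    seg_of_time = np.minimum(seg_of_time, len(protocol.segments) - 1)
    fluxes = np.empty((len(times), len(model.reactions)))
    dyn = model.dynamic_derived_names()
    derived = np.empty((len(times), len(dyn)))
    current = -1
    for row, (t, s) in enumerate(zip(times, states)):
        seg = int(seg_of_time[row])
        if seg != current:
            work.update_parameters(protocol.segments[seg][1])
            current = seg
        if model.reactions:
            fluxes[row] = work.rates(t, s)
        if dyn:
            vals = work.derived_values(t, s)
            derived[row] = [vals[n] for n in dyn]
    return TimeCourse(
        times=np.asarray(times, dtype=float),
        variables=pd.DataFrame(states, columns=model.variable_names),
        fluxes=pd.DataFrame(fluxes, columns=model.reaction_names),
        derived=pd.DataFrame(derived, columns=dyn),
        provenance=provenance,
    )


def steady_state(
    model: Model,
    options: IntegratorOptions | None = None,
    strategy: str = "integrate-then-refine",
    t_max: float = 1e5,
    coarse_tol: float = 1e-6,
    newton_tol: float = 1e-10,
    max_newton: int = 50,
) -> SteadyStateResult:
    """Locate a steady state by integration followed by Newton refinement.

    Integrates in geometrically growing windows until ``‖dS/dt‖∞ <
    coarse_tol`` or ``t_max`` is reached, then runs Newton iterations on
    N·v(S) = 0.  A singular Jacobian during refinement — typical when
    the model carries a conservation relation — yields a non-converged
    result holding the integrated fixed point plus a diagnostic.
    """
    if not model.variables:
        raise ValidationError("steady state requires at least one variable")
    if strategy != "integrate-then-refine":
        raise ValidationError(f"unknown strategy {strategy!r}")
    options = options or IntegratorOptions()
    trace: list[str] = []
    state = model.initial_state
    n = len(state)

    def residual(s: np.ndarray) -> np.ndarray:
        return model.rhs(0.0, s)

    r = residual(state)
    if np.linalg.norm(r) < newton_tol:
        fluxes = model.rates(0.0, state) if model.reactions else np.empty(0)
        return SteadyStateResult(
            state=state, fluxes=fluxes, residual_norm=float(np.linalg.norm(r)),
            converged=True, method_trace=["initial state is already a steady state"],
            variable_names=model.variable_names, reaction_names=model.reaction_names,
        )

    # phase 1: integrate until the rhs is small
    t, window = 0.0, 1.0
    while np.max(np.abs(r)) >= coarse_tol and t < t_max:
        sol = solve_ivp(model.rhs, (0.0, window), state, **options.solve_kwargs())
        if not sol.success:
            trace.append(f"integration failed at t={t}: {sol.message}")
            break
        state = sol.y[:, -1]
        t += window
        window = min(window * 4.0, t_max - t) if t_max - t > 0 else 0.0
        r = residual(state)
        if window == 0.0:
            break
    trace.append(f"integration phase: t={t:g}, ||rhs||_inf={np.max(np.abs(r)):.3e}")

    # phase 2: Newton refinement on N·v(S) = 0.  The Jacobian is examined
    # before declaring convergence: a singular Jacobian at the integrated
    # fixed point signals a conservation relation and is always surfaced.
    converged = False
    diagnostic_singular = False
    for it in range(max_newton):
        r = residual(state)
        J = _numerical_jacobian(residual, state)
        if not np.all(np.isfinite(J)) or np.linalg.cond(J) > 1e12:
            diagnostic_singular = True
            trace.append(
                "Newton Jacobian singular or ill-conditioned: "
                "possible conservation relation"
            )
            break
        if np.linalg.norm(r) < newton_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            diagnostic_singular = True
            trace.append("Newton solve failed: possible conservation relation")
            break
        # damped update keeping the residual decreasing
        lam = 1.0
        for _ in range(20):
            cand = state + lam * step
            if np.linalg.norm(residual(cand)) < np.linalg.norm(r):
                state = cand
                break
            lam *= 0.5
        else:
            trace.append(f"Newton stalled at iteration {it}")
            break
    r = residual(state)
    res_norm = float(np.linalg.norm(r))
    if not converged and not diagnostic_singular and res_norm < newton_tol:
        converged = True
    if not converged and not diagnostic_singular and np.max(np.abs(r)) >= coarse_tol:
        trace.append(f"t_max={t_max:g} exceeded without convergence")
    trace.append(f"final ||N v|| = {res_norm:.3e}, converged={converged}")
    fluxes = model.rates(0.0, state) if model.reactions else np.empty(0)
    return SteadyStateResult(
        state=state,
        fluxes=fluxes,
        residual_norm=res_norm,
        converged=converged,
        method_trace=trace,
        variable_names=model.variable_names,
        reaction_names=model.reaction_names,
    )


def _numerical_jacobian(fn, x: np.ndarray, h: float = 1e-7) -> np.ndarray:
    n = len(x)
    J = np.empty((n, n))
    for i in range(n):
        step = h * max(abs(x[i]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        J[:, i] = (fn(xp) - fn(xm)) / (2 * step)
    return J
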