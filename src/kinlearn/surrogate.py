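"""Surrogate models and their embedding into ODE right-hand sides.

A surrogate is a trained map from named inputs (time, variables,
parameters) to named outputs.  Two embedding semantics exist, selected
by the binding mode:

* **additive** — the surrogate's outputs are added to the mechanistic
  right-hand side: dS/dt = N·v(t,S,k) + surrogate terms.  A zero
  surrogate leaves the model exactly unchanged.
* **replacement** — named reactions are removed from the rate vector
  and the surrogate's outputs (one per replaced reaction) enter through
  the removed reactions' stoichiometric columns.  An exact surrogate of
  a reaction's rate law leaves the right-hand side invariant.

Three surrogate families are provided: least-squares polynomials,
cubic splines (single input only), and a self-contained multi-layer
perceptron trained with Adam.  The MLP standardizes inputs and outputs
internally (affine scalers stored with the weights), is deterministic
given its seed, and exposes its per-epoch training loss.  Predictions
outside the training input hull are permitted but flagged.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import NumericError, UnknownReferenceError, ValidationError
from .model import Model, TIME
from .simulate import IntegratorOptions, steady_state, time_course


# --------------------------------------------------------------------- #
# training data
# --------------------------------------------------------------------- #
@dataclass
class TrainingSet:
    X: np.ndarray  # (n, n_features)
    Y: np.ndarray  # (n, n_targets)
    feature_names: list[str]
    target_names: list[str]
    provenance: dict = field(default_factory=dict)
    dropped_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValidationError("X and Y must have equal row counts")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.Y))):
            raise ValidationError("training set contains non-finite entries")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def to_csv(self, path) -> None:
        cols = [f"in:{n}" for n in self.feature_names] + [f"out:{n}" for n in self.target_names]
        pd.DataFrame(np.hstack([self.X, self.Y]), columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrainingSet":
        df = pd.read_csv(path)
        fin = [c for c in df.columns if c.startswith("in:")]
        fout = [c for c in df.columns if c.startswith("out:")]
        return cls(df[fin].to_numpy(), df[fout].to_numpy(),
                   [c[3:] for c in fin], [c[4:] for c in fout])


def make_training_set(
    source,
    input_grid: np.ndarray | Sequence[Sequence[float]],
    mode: str,
    feature_names: Sequence[str] | None = None,
    target_names: Sequence[str] | None = None,
    options: IntegratorOptions | None = None,
    t_end: float = 10.0,
    **kwargs,
) -> TrainingSet:
    """Build a training set by evaluating a function or probing a model.

    Modes
    -----
    ``evaluate-function``
        ``source`` is a callable row -> output row (or scalar).
    ``model-steady-state``
        ``source`` is a :class:`Model`; each grid row overrides the
        parameters named in ``feature_names``, the model is driven to
        steady state and the ``target_names`` (variables or reaction
        fluxes) are read off.  Non-converged rows are dropped and logged.
    ``model-timecourse-endpoint``
        As above, but targets are read from the state at ``t_end``.
    """
    grid = np.atleast_2d(np.asarray(input_grid, dtype=float))
    if grid.size == 0:
        raise ValidationError("input grid must be nonempty")
    if grid.shape[0] == 1 and grid.shape[1] > 1 and (
        feature_names is not None and len(feature_names) == 1
    ):
        grid = grid.T
    if mode == "evaluate-function":
        rows = [np.atleast_1d(np.asarray(source(*row), dtype=float)) for row in grid]
        feature_names = list(feature_names or [f"x{i}" for i in range(grid.shape[1])])
        target_names = list(target_names or [f"y{i}" for i in range(len(rows[0]))])
        return TrainingSet(grid, np.vstack(rows), feature_names, target_names,
                           provenance={"mode": mode})
    if mode not in ("model-steady-state", "model-timecourse-endpoint"):
        raise ValidationError(f"unknown mode {mode!r}")
    model: Model = source
    feature_names = list(feature_names or [])
    target_names = list(target_names or [])
    if not feature_names or not target_names:
        raise ValidationError("model modes require feature_names and target_names")
    X_rows, Y_rows, dropped = [], [], []
    for row in grid:
        m = model.copy().update_parameters(dict(zip(feature_names, row)))
        try:
            if mode == "model-steady-state":
                ss = steady_state(m, options, **kwargs)
                if not ss.converged:
                    raise NumericError("steady state did not converge")
                values = {**ss.state_dict(), **ss.flux_dict()}
            else:
                tc = time_course(m, np.linspace(0, t_end, 50), options)
                values = dict(zip(m.variable_names, tc.final_state))
                values.update(zip(m.reaction_names, tc.fluxes.iloc[-1]))
            Y_rows.append([values[t] for t in target_names])
            X_rows.append(row)
        except Exception as exc:
            dropped.append(f"row {row.tolist()}: {type(exc).__name__}: {exc}")
    if not X_rows:
        raise ValidationError(
            "every grid row failed to converge; no training data produced"
        )
    return TrainingSet(np.vstack(X_rows), np.asarray(Y_rows, dtype=float),
                       feature_names, target_names,
                       provenance={"mode": mode, "model": model.name},
                       dropped_log=dropped)


# --------------------------------------------------------------------- #
# affine scaler
# --------------------------------------------------------------------- #
@dataclass
class AffineScaler:
    mean: np.ndarray
    scale: np.ndarray  # std with zero-variance columns set to 1

    @classmethod
    def fit(cls, X: np.ndarray) -> "AffineScaler":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
        return cls(mean, scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.scale + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineScaler":
        return cls(np.asarray(d["mean"]), np.asarray(d["scale"]))


# --------------------------------------------------------------------- #
# polynomial surrogate
# --------------------------------------------------------------------- #
def _monomials(p: int, degree: int) -> list[tuple[int, ...]]:
    """Exponent tuples of all monomials in p features up to total degree."""
    out = []
    for total in range(degree + 1):
        for combo in itertools.combinations_with_replacement(range(p), total):
            exps = [0] * p
            for i in combo:
                exps[i] += 1
            out.append(tuple(exps))
    return out


@dataclass
class PolynomialSurrogate:
    degree: int
    coefficients: np.ndarray  # (n_monomials, n_targets)
    monomials: list[tuple[int, ...]]
    feature_names: list[str]
    target_names: list[str]
    training_rmse: np.ndarray | None = None
    input_range: np.ndarray | None = None  # (2, p) training min/max
    extrapolation_seen: bool = field(default=False, compare=False)

    def _design(self, X: np.ndarray) -> np.ndarray:
        cols = [np.prod(X ** np.array(m), axis=1) for m in self.monomials]
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.input_range is not None and (
            np.any(X < self.input_range[0]) or np.any(X > self.input_range[1])
        ):
            self.extrapolation_seen = True
        return self._design(X) @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "type": "polynomial", "degree": self.degree,
            "coefficients": self.coefficients.tolist(),
            "monomials": [list(m) for m in self.monomials],
            "feature_names": self.feature_names, "target_names": self.target_names,
            "input_range": self.input_range.tolist() if self.input_range is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialSurrogate":
        return cls(
            d["degree"], np.asarray(d["coefficients"]),
            [tuple(m) for m in d["monomials"]],
            d["feature_names"], d["target_names"],
            input_range=np.asarray(d["input_range"]) if d.get("input_range") else None,
        )


def train_polynomial(ts: TrainingSet, degree: int) -> PolynomialSurrogate:
    """Least-squares polynomial fit of total degree ``degree``."""
    monos = _monomials(ts.X.shape[1], degree)
    if ts.n < len(monos):
        raise ValidationError(
            f"{ts.n} rows cannot determine {len(monos)} polynomial coefficients"
        )
    design = np.column_stack([np.prod(ts.X ** np.array(m), axis=1) for m in monos])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify degenerate columns by pivoted QR
        _, R, piv = _qr_pivot(design)
        bad = sorted(piv[rank:])
        labels = [_monomial_label(monos[i], ts.feature_names) for i in bad]
        raise ValidationError(
            f"design matrix is rank deficient; degenerate features: {labels}"
        )
    coeffs, *_ = np.linalg.lstsq(design, ts.Y, rcond=None)
    resid = design @ coeffs - ts.Y
    rmse = np.sqrt(np.mean(resid**2, axis=0))
    rng = np.vstack([ts.X.min(axis=0), ts.X.max(axis=0)])
    return PolynomialSurrogate(degree, coeffs, monos, ts.feature_names,
                               ts.target_names, rmse, rng)


def _qr_pivot(A: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(A, pivoting=True, mode="economic")
    return Q, R, piv


def _monomial_label(m: tuple[int, ...], names: list[str]) -> str:
    parts = [f"{names[i]}^{e}" if e > 1 else names[i] for i, e in enumerate(m) if e]
    return "*".join(parts) if parts else "1"


# --------------------------------------------------------------------- #
# cubic-spline surrogate (single input)
# --------------------------------------------------------------------- #
@dataclass
class SplineSurrogate:
    knots: np.ndarray
    values: np.ndarray  # (n_knots, n_targets)
    feature_names: list[str]
    target_names: list[str]
    _spline: CubicSpline | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self._spline is None:
            self._spline = CubicSpline(self.knots, self.values)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.atleast_2d(self._spline(X[:, 0]))


def train_spline(ts: TrainingSet) -> SplineSurrogate:
    """Interpolating cubic spline; restricted to single-input training sets."""
    if ts.X.shape[1] != 1:
        raise ValidationError("spline surrogates support exactly one input feature")
    order = np.argsort(ts.X[:, 0])
    return SplineSurrogate(ts.X[order, 0], ts.Y[order], ts.feature_names,
                           ts.target_names)


# --------------------------------------------------------------------- #
# multi-layer perceptron
# --------------------------------------------------------------------- #
_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
}


@dataclass
class MLPSurrogate:
    """Fully connected network with affine input/output standardization.

    Weights map standardized inputs to standardized outputs; the scalers
    fitted on the training data are stored with the network, so
    prediction is a pure deterministic function of the stored state.
    """

    widths: list[int]  # hidden-layer widths
    activation: str
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_scaler: AffineScaler
    y_scaler: AffineScaler
    feature_names: list[str]
    target_names: list[str]
    training_log: list[float] = field(default_factory=list)  # loss per epoch
    input_range: np.ndarray | None = None
    extrapolation_seen: bool = field(default=False, compare=False)

    def _forward(self, Z: np.ndarray) -> np.ndarray:
        act = _ACTIVATIONS[self.activation][0]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            Z = act(Z @ W + b)
        return Z @ self.weights[-1] + self.biases[-1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.input_range is not None and (
            np.any(X < self.input_range[0]) or np.any(X > self.input_range[1])
        ):
            self.extrapolation_seen = True
        return self.y_scaler.inverse(self._forward(self.x_scaler.transform(X)))

    def to_dict(self) -> dict:
        return {
            "type": "mlp", "widths": self.widths, "activation": self.activation,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_scaler": self.x_scaler.to_dict(), "y_scaler": self.y_scaler.to_dict(),
            "feature_names": self.feature_names, "target_names": self.target_names,
            "input_range": self.input_range.tolist() if self.input_range is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPSurrogate":
        return cls(
            d["widths"], d["activation"],
            [np.asarray(w) for w in d["weights"]],
            [np.asarray(b) for b in d["biases"]],
            AffineScaler.from_dict(d["x_scaler"]), AffineScaler.from_dict(d["y_scaler"]),
            d["feature_names"], d["target_names"],
            input_range=np.asarray(d["input_range"]) if d.get("input_range") else None,
        )


def train_mlp(
    ts: TrainingSet,
    widths: Sequence[int] = (16,),
    epochs: int = 500,
    learning_rate: float = 1e-2,
    batch_mode: str | int = "full",
    seed: int = 0,
    activation: str = "tanh",
) -> MLPSurrogate:
    """Train an MLP by Adam on mean-squared error.

    ``batch_mode`` is ``"full"`` (full-batch gradient steps) or an int
    mini-batch size.  Training is deterministic given ``seed``.  A
    non-finite loss aborts with a diagnostic naming the epoch.
    """
    if epochs < 1:
        raise ValidationError("epochs must be >= 1")
    widths = list(widths)
    if not widths:
        raise ValidationError("at least one hidden layer width is required")
    if activation not in _ACTIVATIONS:
        raise ValidationError(f"unknown activation {activation!r}")
    rng = np.random.default_rng(seed)
    x_scaler = AffineScaler.fit(ts.X)
    y_scaler = AffineScaler.fit(ts.Y)
    X = x_scaler.transform(ts.X)
    Y = y_scaler.transform(ts.Y)
    sizes = [X.shape[1], *widths, Y.shape[1]]
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / (sizes[i] + sizes[i + 1])),
                   size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    act, dact = _ACTIVATIONS[activation]

    mW = [np.zeros_like(w) for w in weights]
    vW = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    log: list[float] = []

    def batches(epoch_rng):
        if batch_mode == "full":
            yield np.arange(X.shape[0])
            return
        size = int(batch_mode)
        perm = epoch_rng.permutation(X.shape[0])
        for start in range(0, X.shape[0], size):
            yield perm[start : start + size]

    for epoch in range(epochs):
        epoch_loss = 0.0
        n_seen = 0
        for idx in batches(rng):
            xb, yb = X[idx], Y[idx]
            # forward
            zs, activs = [], [xb]
            h = xb
            for W, b in zip(weights[:-1], biases[:-1]):
                z = h @ W + b
                zs.append(z)
                h = act(z)
                activs.append(h)
            pred = h @ weights[-1] + biases[-1]
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise NumericError(f"training loss became non-finite at epoch {epoch}")
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
            # backward
            grad = 2.0 * err / err.size
            gW = [None] * len(weights)
            gb = [None] * len(biases)
            gW[-1] = activs[-1].T @ grad
            gb[-1] = grad.sum(axis=0)
            delta = grad @ weights[-1].T
            for layer in range(len(weights) - 2, -1, -1):
                delta = delta * dact(zs[layer])
                gW[layer] = activs[layer].T @ delta
                gb[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = delta @ weights[layer].T
            # Adam update
            step += 1
            for k in range(len(weights)):
                mW[k] = beta1 * mW[k] + (1 - beta1) * gW[k]
                vW[k] = beta2 * vW[k] + (1 - beta2) * gW[k] ** 2
                mb[k] = beta1 * mb[k] + (1 - beta1) * gb[k]
                vb[k] = beta2 * vb[k] + (1 - beta2) * gb[k] ** 2
                mhW = mW[k] / (1 - beta1**step)
                vhW = vW[k] / (1 - beta2**step)
                mhb = mb[k] / (1 - beta1**step)
                vhb = vb[k] / (1 - beta2**step)
                weights[k] -= learning_rate * mhW / (np.sqrt(vhW) + eps)
                biases[k] -= learning_rate * mhb / (np.sqrt(vhb) + eps)
        log.append(epoch_loss / max(n_seen, 1))
    rng_in = np.vstack([ts.X.min(axis=0), ts.X.max(axis=0)])
    return MLPSurrogate(widths, activation, weights, biases, x_scaler, y_scaler,
                        ts.feature_names, ts.target_names, log, rng_in)


def smoothed_loss(log: Sequence[float], window: int = 10) -> np.ndarray:
    """Running-minimum smoothing of a training-loss log (monotone curve)."""
    return np.minimum.accumulate(np.asarray(log, dtype=float))


# --------------------------------------------------------------------- #
# binding surrogates into models
# --------------------------------------------------------------------- #
@dataclass
class SurrogateBinding:
    """Splices a trained surrogate into a model's right-hand side.

    inputs: ordered names from {"time"} | variables | parameters, fed to
    the surrogate in that order.

    mode "additive": ``outputs`` maps each surrogate output name to a
    {variable: coefficient} dict; output values times coefficients are
    added to the named variables' derivatives.

    mode "replacement": ``replaced_reactions`` lists reaction names; the
    surrogate must expose one output per replaced reaction (matched by
    name) and the outputs enter through the removed reactions' original
    stoichiometric columns.
    """

    surrogate: object
    inputs: list[str]
    mode: str
    outputs: dict[str, dict[str, float]] | None = None
    replaced_reactions: list[str] | None = None
    name: str = "surrogate"
    _stoich_columns: dict[str, dict[str, float]] = field(default_factory=dict)

    def input_vector(self, model: Model, t: float, state: np.ndarray) -> np.ndarray:
        env = model._env(t, state)
        return np.array([env[n] for n in self.inputs], dtype=float)

    def output_values(self, model: Model, t: float, state: np.ndarray) -> dict[str, float]:
        pred = np.atleast_2d(self.surrogate.predict(
            self.input_vector(model, t, state)[None, :]
        ))[0]
        names = getattr(self.surrogate, "target_names", None) or [
            f"y{i}" for i in range(len(pred))
        ]
        return dict(zip(names, pred))

    def contribution(self, model: Model, t: float, state: np.ndarray) -> np.ndarray:
        out = self.output_values(model, t, state)
        dsdt = np.zeros(len(model.variables))
        var_index = {n: i for i, n in enumerate(model.variables)}
        if self.mode == "additive":
            for oname, targets in (self.outputs or {}).items():
                for var, coeff in targets.items():
                    dsdt[var_index[var]] += coeff * out[oname]
        else:
            for rxn in self.replaced_reactions or []:
                for var, coeff in self._stoich_columns[rxn].items():
                    if var in var_index:
                        dsdt[var_index[var]] += coeff * out[rxn]
        return dsdt

    def latex_term(self, variable: str) -> str | None:
        kind = "NN" if isinstance(self.surrogate, MLPSurrogate) else "P"
        args = ", ".join(self.inputs)
        if self.mode == "additive":
            for oname, targets in (self.outputs or {}).items():
                if variable in targets:
                    return rf"\mathrm{{{kind}}}_{{\mathrm{{{self.name}}}}}\left({args}\right)"
        else:
            for rxn in self.replaced_reactions or []:
                if variable in self._stoich_columns.get(rxn, {}):
                    return rf"\mathrm{{{kind}}}_{{\mathrm{{{self.name}}}}}\left({args}\right)"
        return None

    @property
    def extrapolation_flagged(self) -> bool:
        return bool(getattr(self.surrogate, "extrapolation_seen", False))


def add_surrogate(
    model: Model,
    surrogate,
    inputs: Sequence[str],
    mode: str = "additive",
    outputs: dict[str, dict[str, float]] | None = None,
    replaced_reactions: Sequence[str] | None = None,
    name: str = "surrogate",
) -> Model:
    """Return a hybrid model with the surrogate spliced into its rhs.

    The original model is left untouched; the hybrid is usable by every
    other module (simulation, ensembles, MCA, fitting) unchanged.
    """
    if mode not in ("additive", "replacement"):
        raise ValidationError(f"unknown binding mode {mode!r}")
    hybrid = model.copy()
    for dep in inputs:
        if dep != TIME and dep not in hybrid.variables and dep not in hybrid.parameters:
            raise UnknownReferenceError(f"surrogate input {dep!r} not in model")
    binding = SurrogateBinding(surrogate, list(inputs), mode, outputs,
                               list(replaced_reactions or []), name)
    if mode == "additive":
        if not outputs:
            raise ValidationError("additive mode requires an outputs map")
        for oname, targets in outputs.items():
            for var in targets:
                if var not in hybrid.variables:
                    raise UnknownReferenceError(
                        f"surrogate output {oname!r} targets unknown variable {var!r}"
                    )
    else:
        if not replaced_reactions:
            raise ValidationError("replacement mode requires replaced_reactions")
        target_names = getattr(surrogate, "target_names", [])
        for rxn in replaced_reactions:
            if rxn not in hybrid.reactions:
                raise UnknownReferenceError(f"cannot replace nonexistent reaction {rxn!r}")
            if target_names and rxn not in target_names:
                raise ValidationError(
                    f"surrogate outputs {target_names} lack replaced reaction {rxn!r}"
                )
            # remember the stoichiometric column, then remove the reaction once
            static_env = hybrid._static_env()
            binding._stoich_columns[rxn] = {
                var: (static_env[c] if isinstance(c, str) else float(c))
                for var, c in hybrid.reactions[rxn].stoichiometry.items()
            }
            del hybrid.reactions[rxn]
        hybrid._compiled = None
    hybrid.surrogate_bindings.append(binding)
    hybrid.annotations.setdefault("surrogates", []).append(
        {"name": name, "mode": mode, "inputs": list(inputs)}
    )
    return hybrid


# --------------------------------------------------------------------- #
# serialization helpers
# --------------------------------------------------------------------- #
def save_surrogate(surrogate, path) -> None:
    with open(path, "w") as fh:
        json.dump(surrogate.to_dict(), fh)


def load_surrogate(path):
    with open(path) as fh:
        d = json.load(fh)
    if d["type"] == "polynomial":
        return PolynomialSurrogate.from_dict(d)
    if d["type"] == "mlp":
        return MLPSurrogate.from_dict(d)
    raise ValidationError(f"unknown surrogate type {d['type']!r}")
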