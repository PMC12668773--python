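"""Neural posterior estimation (simulation-based inference).

The workflow inverts the usual simulation direction: draw parameters
from the prior, simulate the model to obtain synthetic observations,
then train a network on (observation -> parameter) pairs.  The trained
network amortizes inference — applying it to a real observation yields
a parameter estimate without further simulation:

    prior p(k) × likelihood p(S|k)  →  network ≈ p(k|S)

The default estimator is the package's reference MLP regressor.  It is
therefore an amortized *point* estimate of the posterior, optionally
wrapped in a perturbation mode that reports the spread of estimates
over noise-perturbed replicates of the observation — a crude
uncertainty surface, not a density.  Full conditional-density
estimators can be plugged in through the same training-function
interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, sample_parameters
from .errors import ValidationError
from .mca import flux_control_coefficients
from .model import Model
from .simulate import IntegratorOptions, steady_state, time_course
from .surrogate import MLPSurrogate, TrainingSet, train_mlp


@dataclass
class FeatureSpec:
    """What "an observation" is: which simulated quantities form the
    feature vector presented to the network.

    kind:
      * ``timecourse`` — observed variables at the time grid, flattened.
      * ``steady-state`` — steady-state values of the observed names
        (variables or fluxes).
      * ``control-coefficients`` — flattened flux-control matrix.
      * ``summary`` — per observed variable: mean, sd, min, max and
        final value over the time grid.
    """

    kind: str
    observed: list[str]
    times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("timecourse", "steady-state", "control-coefficients",
                            "summary"):
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.kind in ("timecourse", "summary") and not self.times:
            raise ValidationError(f"feature kind {self.kind!r} requires a time grid")

    def feature_names(self, model: Model) -> list[str]:
        if self.kind == "timecourse":
            return [f"{n}@t={t:g}" for n in self.observed for t in self.times]
        if self.kind == "steady-state":
            return list(self.observed)
        if self.kind == "control-coefficients":
            rxns = model.reaction_names
            return [f"CJ[{j},{e}]" for j in rxns for e in rxns]
        return [f"{n}:{s}" for n in self.observed
                for s in ("mean", "sd", "min", "max", "final")]

    def extract(self, model: Model, options: IntegratorOptions | None) -> np.ndarray:
        if self.kind in ("timecourse", "summary"):
            grid = np.asarray(self.times, dtype=float)
            tc = time_course(model, grid, options)
            cols = []
            for n in self.observed:
                series = (tc.variables[n] if n in tc.variables.columns
                          else tc.fluxes[n]).to_numpy()
                cols.append(series)
            if self.kind == "timecourse":
                return np.concatenate(cols)
            return np.concatenate([
                [c.mean(), c.std(), c.min(), c.max(), c[-1]] for c in cols
            ])
        if self.kind == "steady-state":
            ss = steady_state(model, options)
            if not ss.converged:
                raise ValidationError("steady state did not converge")
            values = {**ss.state_dict(), **ss.flux_dict()}
            return np.array([values[n] for n in self.observed])
        cc = flux_control_coefficients(model, options)
        return cc.flux_control.ravel()

    def to_dict(self) -> dict:
        return {"kind": self.kind, "observed": self.observed, "times": self.times}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(d["kind"], d["observed"], d.get("times", []))


@dataclass
class NPETrainingSet:
    features: np.ndarray  # (n, n_features)
    parameters: np.ndarray  # (n, p) — the prior draws that generated each row
    feature_spec: FeatureSpec
    parameter_names: list[str]
    feature_names: list[str]
    seed: int
    priors: list[DistributionSpec] = field(default_factory=list)
    n_failed: int = 0

    def to_csv(self, features_path, parameters_path, spec_path=None) -> None:
        pd.DataFrame(self.features, columns=self.feature_names).to_csv(
            features_path, index=False)
        pd.DataFrame(self.parameters, columns=self.parameter_names).to_csv(
            parameters_path, index=False)
        if spec_path is not None:
            with open(spec_path, "w") as fh:
                json.dump(self.feature_spec.to_dict(), fh)


def generate_npe_training_set(
    model: Model,
    priors: list[DistributionSpec],
    n: int,
    feature_spec: FeatureSpec,
    seed: int,
    options: IntegratorOptions | None = None,
) -> NPETrainingSet:
    """Draw parameters from the priors and simulate their observations.

    Failed simulations are dropped together with their parameter rows;
    more than 50% failures aborts with a prior diagnostic.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    names = [p.name for p in priors]
    for name in names:
        if name not in model.parameters:
            raise ValidationError(f"prior parameter {name!r} not in model")
    sample = sample_parameters(priors, n, seed)
    feat_rows, param_rows, failed = [], [], 0
    for i in range(n):
        row = sample.row(i)
        m = model.copy().update_parameters(row)
        try:
            feat_rows.append(feature_spec.extract(m, options))
            param_rows.append(sample.values[i])
        except Exception:
            failed += 1
    if failed > n / 2:
        raise ValidationError(
            f"{failed}/{n} simulations failed; the priors likely cover a regime "
            "where the model cannot be simulated — tighten the priors"
        )
    return NPETrainingSet(
        np.vstack(feat_rows), np.vstack(param_rows), feature_spec, names,
        feature_spec.feature_names(model), seed, list(priors), failed,
    )


@dataclass
class NPEEstimator:
    network: MLPSurrogate
    priors: list[DistributionSpec]
    feature_spec: FeatureSpec
    diagnostics: dict = field(default_factory=dict)

    def _clamp(self, params: np.ndarray) -> tuple[np.ndarray, bool]:
        clamped = params.copy()
        flagged = False
        for j, prior in enumerate(self.priors):
            lo, hi = prior.support
            out = (clamped[:, j] < lo) | (clamped[:, j] > hi)
            if np.any(out):
                flagged = True
                clamped[:, j] = np.clip(clamped[:, j], lo, hi)
        return clamped, flagged


def train_npe(
    ts: NPETrainingSet,
    widths: Sequence[int] = (32, 32),
    epochs: int = 400,
    learning_rate: float = 1e-2,
    batch_mode: str | int = "full",
    seed: int = 0,
) -> NPEEstimator:
    """Train the amortized estimator (features -> parameters) via the
    reference MLP; priors and feature spec are stored for validation at
    predict time."""
    if ts.features.shape[0] == 0:
        raise ValidationError("training set is empty")
    surrogate_ts = TrainingSet(ts.features, ts.parameters, ts.feature_names,
                               ts.parameter_names)
    net = train_mlp(surrogate_ts, widths=widths, epochs=epochs,
                    learning_rate=learning_rate, batch_mode=batch_mode, seed=seed)
    return NPEEstimator(net, list(ts.priors), ts.feature_spec,
                        {"final_loss": net.training_log[-1],
                         "first_loss": net.training_log[0],
                         "n_train": ts.features.shape[0]})


def predict_posterior(
    estimator: NPEEstimator,
    observation: np.ndarray,
    mode: str = "point",
    noise_scale: float = 0.0,
    n_replicates: int = 100,
    seed: int = 0,
) -> dict:
    """Map an observation to parameter estimates.

    ``mode="point"`` returns one parameter vector; ``mode="perturbation"``
    returns estimates over multiplicative-noise replicates of the
    observation (noise sd = ``noise_scale`` × |observation|) as a crude
    spread.  Out-of-prior predictions are clamped to the prior support
    and flagged.
    """
    observation = np.asarray(observation, dtype=float).ravel()
    expected = len(estimator.network.feature_names)
    if observation.shape[0] != expected:
        raise ValidationError(
            f"observation has {observation.shape[0]} features, spec requires {expected}"
        )
    if mode == "point":
        pred = estimator.network.predict(observation[None, :])
        pred, flagged = estimator._clamp(pred)
        return {"estimate": pred[0],
                "parameter_names": estimator.network.target_names,
                "out_of_prior": flagged}
    if mode != "perturbation":
        raise ValidationError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    if noise_scale == 0.0:
        # degenerate case: replicates are identical by construction
        preds = np.tile(estimator.network.predict(observation[None, :]),
                        (n_replicates, 1))
    else:
        reps = observation[None, :] * (
            1.0 + noise_scale * rng.standard_normal(
                (n_replicates, observation.shape[0]))
        )
        preds = estimator.network.predict(reps)
    preds, flagged = estimator._clamp(preds)
    return {"estimates": preds,
            "mean": preds.mean(axis=0), "sd": preds.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros(preds.shape[1]),
            "parameter_names": estimator.network.target_names,
            "out_of_prior": flagged}
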