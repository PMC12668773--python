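"""Metabolic control analysis at steady state.

Elasticities are normalized local sensitivities of rate laws to
metabolite concentrations,

    eps[j, i] = (S_i / v_j) * d v_j / d S_i,

evaluated at a given state by central finite differences.  Control
coefficients quantify the systemic response of steady-state fluxes and
concentrations to a perturbation of one reaction's activity,

    C^J[j, e] = (p_e / J_j) * d J_j / d p_e,
    C^S[i, e] = (p_e / S_i) * d S_i / d p_e,

where p_e is a dedicated multiplicative scaling factor (reference value
1) on reaction e's rate — well-defined for arbitrary rate laws, unlike
perturbing a named kinetic constant.  The steady state is recomputed
for every perturbation.  The summation theorems (rows of C^J sum to 1,
rows of C^S sum to 0) serve as built-in consistency checks.

Quantities that are undefined at zero flux/concentration are reported
as explicit undefined markers (NaN value + mask), never silently
propagated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import Model
from .simulate import IntegratorOptions, steady_state


@dataclass
class ElasticityMatrix:
    values: np.ndarray  # reaction × variable
    undefined: np.ndarray  # boolean mask, True where normalization impossible
    reaction_names: list[str]
    variable_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.reaction_names,
                            columns=self.variable_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class ControlCoefficients:
    flux_control: np.ndarray  # observed flux × perturbed reaction
    concentration_control: np.ndarray  # variable × perturbed reaction
    failed: np.ndarray  # boolean mask over perturbed reactions
    reference_state: np.ndarray
    reference_fluxes: np.ndarray
    perturbation_step: float
    reaction_names: list[str] = field(default_factory=list)
    variable_names: list[str] = field(default_factory=list)

    def flux_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flux_control, index=self.reaction_names,
                            columns=self.reaction_names)

    def concentration_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.concentration_control, index=self.variable_names,
                            columns=self.reaction_names)

    def summation_residuals(self) -> tuple[np.ndarray, np.ndarray]:
        """(row sums of C^J minus 1, row sums of C^S) — both ≈ 0 in theory."""
        return (self.flux_control.sum(axis=1) - 1.0,
                self.concentration_control.sum(axis=1))


def elasticities(model: Model, state: np.ndarray, t: float = 0.0,
                 rel_step: float = 1e-6, floor: float = 1e-8) -> ElasticityMatrix:
    """Normalized elasticities by central differences on the rate laws.

    The step for variable i is ``rel_step * max(|S_i|, floor)``.  Entries
    with v_j = 0 cannot be normalized and are marked undefined.
    """
    state = np.asarray(state, dtype=float)
    n_rxn, n_var = len(model.reactions), len(model.variables)
    v0 = model.rates(t, state)
    values = np.zeros((n_rxn, n_var))
    undefined = np.zeros((n_rxn, n_var), dtype=bool)
    for i in range(n_var):
        h = rel_step * max(abs(state[i]), floor)
        sp, sm = state.copy(), state.copy()
        sp[i] += h
        sm[i] -= h
        dv = (model.rates(t, sp) - model.rates(t, sm)) / (2 * h)
        for j in range(n_rxn):
            if v0[j] == 0.0:
                if dv[j] != 0.0:
                    undefined[j, i] = True
                    values[j, i] = np.nan
                # rate independent of S_i and zero: elasticity 0 by convention
            else:
                values[j, i] = state[i] / v0[j] * dv[j]
    return ElasticityMatrix(values, undefined, model.reaction_names,
                            model.variable_names)


def flux_control_coefficients(
    model: Model,
    options: IntegratorOptions | None = None,
    rel_step: float = 1e-4,
    ss_kwargs: dict | None = None,
) -> ControlCoefficients:
    """Flux and concentration control coefficients by central differences
    on per-reaction activity scalings, recomputing the steady state for
    each perturbation."""
    ss_kwargs = ss_kwargs or {}
    base = steady_state(model, options, **ss_kwargs)
    if not base.converged:
        raise ValidationError(
            "reference steady state did not converge; control coefficients undefined"
        )
    n_rxn = len(model.reactions)
    n_var = len(model.variables)
    CJ = np.full((n_rxn, n_rxn), np.nan)
    CS = np.full((n_var, n_rxn), np.nan)
    failed = np.zeros(n_rxn, dtype=bool)
    for e, rxn in enumerate(model.reaction_names):
        results = []
        for factor in (1.0 + rel_step, 1.0 - rel_step):
            pert = model.copy()
            pert.scale_reaction(rxn, factor)
            # warm-start from the reference steady state
            for name, value in zip(model.variable_names, base.state):
                pert.update_initial(name, value)
            results.append(steady_state(pert, options, **ss_kwargs))
        if not all(r.converged for r in results):
            failed[e] = True
            continue
        dJ = (results[0].fluxes - results[1].fluxes) / (2 * rel_step)
        dS = (results[0].state - results[1].state) / (2 * rel_step)
        with np.errstate(divide="ignore", invalid="ignore"):
            CJ[:, e] = np.where(base.fluxes != 0, dJ / base.fluxes, np.nan)
            CS[:, e] = np.where(base.state != 0, dS / base.state, np.nan)
    return ControlCoefficients(
        flux_control=CJ,
        concentration_control=CS,
        failed=failed,
        reference_state=base.state,
        reference_fluxes=base.fluxes,
        perturbation_step=rel_step,
        reaction_names=model.reaction_names,
        variable_names=model.variable_names,
    )
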