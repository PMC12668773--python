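"""Monte Carlo ensemble simulation.

Each row of a :class:`~kinlearn.distributions.ParameterSample` yields
one ensemble member: the model is re-parametrized with that row and
simulated.  Member i of the output always corresponds to row i of the
sample regardless of execution order or worker count, and member
failures are isolated and logged — they never abort the ensemble.
Summaries (per-time mean, standard deviation, quantiles) are computed
over the successful members only, and both attempted and successful
counts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import ParameterSample
from .errors import SummaryError, ValidationError
from .mca import ControlCoefficients, flux_control_coefficients
from .model import Model
from .simulate import IntegratorOptions, Protocol, protocol_time_course, steady_state, time_course


@dataclass
class EnsembleResult:
    """M member trajectories on a shared time grid plus summaries."""

    times: np.ndarray
    members: np.ndarray  # (M, T, n_var); NaN rows for failed members
    success: np.ndarray  # (M,) boolean
    variable_names: list[str]
    failure_log: list[str] = field(default_factory=list)

    @property
    def n_attempted(self) -> int:
        return self.members.shape[0]

    @property
    def n_successful(self) -> int:
        return int(self.success.sum())

    def member_frame(self, variable: str) -> pd.DataFrame:
        """Wide table (member × time) for one variable."""
        j = self.variable_names.index(variable)
        return pd.DataFrame(self.members[:, :, j], columns=self.times)

    def to_csv(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self.variable_names:
            self.member_frame(name).to_csv(directory / f"members_{name}.csv",
                                           index_label="member")
        ensemble_summary(self).to_csv(directory / "summary.csv", index=False)


def ensemble_summary(
    ensemble: EnsembleResult,
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> pd.DataFrame:
    """Per-time mean (the ensemble average mu_t = (1/M) sum_i S_{i,t}),
    standard deviation and quantiles over successful members.

    Quantiles use linear interpolation between order statistics.
    """
    if ensemble.n_successful == 0:
        raise SummaryError("no successful ensemble members to summarise")
    ok = ensemble.members[ensemble.success]
    rows = []
    for j, name in enumerate(ensemble.variable_names):
        block = ok[:, :, j]  # member × time
        entry = {
            "name": name,
            "time": ensemble.times,
            "mean": block.mean(axis=0),
            "sd": block.std(axis=0, ddof=1) if ok.shape[0] > 1 else np.zeros(block.shape[1]),
        }
        for q in quantiles:
            entry[f"q{q:g}"] = np.quantile(block, q, axis=0, method="linear")
        rows.append(pd.DataFrame(entry))
    return pd.concat(rows, ignore_index=True)


def _run_members(model: Model, sample: ParameterSample, runner) -> tuple[list, np.ndarray, list[str]]:
    for name in sample.names:
        if name not in model.parameters:
            raise ValidationError(f"sample column {name!r} is not a model parameter")
    outputs: list = [None] * sample.n
    success = np.zeros(sample.n, dtype=bool)
    log: list[str] = []
    for i in range(sample.n):
        row = sample.row(i)
        if not all(np.isfinite(v) for v in row.values()):
            log.append(f"member {i}: non-finite parameter row")
            continue
        member_model = model.copy().update_parameters(row)
        try:
            outputs[i] = runner(member_model)
            success[i] = True
        except Exception as exc:  # member isolation: log, never abort
            log.append(f"member {i}: {type(exc).__name__}: {exc}")
    return outputs, success, log


def mc_time_course(
    model: Model,
    sample: ParameterSample,
    t_eval: Sequence[float],
    options: IntegratorOptions | None = None,
    workers: int = 1,
) -> EnsembleResult:
    """Simulate one time course per sample row.

    ``workers`` is accepted for interface compatibility; execution is
    member-index-ordered so results are identical for any worker count.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    outputs, success, log = _run_members(
        model, sample, lambda m: time_course(m, t_eval, options).variables.to_numpy()
    )
    members = np.full((sample.n, len(t_eval), len(model.variables)), np.nan)
    for i, out in enumerate(outputs):
        if out is not None:
            members[i] = out
    return EnsembleResult(t_eval, members, success, model.variable_names, log)


def mc_protocol_time_course(
    model: Model,
    sample: ParameterSample,
    protocol: Protocol,
    points_per_segment: int = 50,
    options: IntegratorOptions | None = None,
    workers: int = 1,
) -> EnsembleResult:
    """Protocol-driven ensemble: one protocol simulation per sample row."""
    ref = protocol_time_course(model, protocol, points_per_segment, options)
    times = ref.times

    def runner(m: Model) -> np.ndarray:
        return protocol_time_course(m, protocol, points_per_segment, options).variables.to_numpy()

    outputs, success, log = _run_members(model, sample, runner)
    members = np.full((sample.n, len(times), len(model.variables)), np.nan)
    for i, out in enumerate(outputs):
        if out is not None:
            members[i] = out
    return EnsembleResult(times, members, success, model.variable_names, log)


def mc_steady_state(
    model: Model,
    sample: ParameterSample,
    options: IntegratorOptions | None = None,
    **ss_kwargs,
) -> pd.DataFrame:
    """Per-member steady states as a tidy table.

    Columns: member, converged, one column per variable (S*), one per
    reaction flux (J_*).  Non-converged members keep their rows with
    converged=False.
    """

    def runner(m: Model):
        ss = steady_state(m, options, **ss_kwargs)
        if not ss.converged:
            raise ValidationError("steady state did not converge")
        return ss

    outputs, success, log = _run_members(model, sample, runner)
    rows = []
    for i, out in enumerate(outputs):
        row: dict = {"member": i, "converged": bool(success[i])}
        if out is not None:
            row.update(out.state_dict())
            row.update({f"J_{k}": v for k, v in out.flux_dict().items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["failure_log"] = log
    return df


def mc_control_coefficients(
    model: Model,
    sample: ParameterSample,
    options: IntegratorOptions | None = None,
) -> tuple[list[ControlCoefficients | None], np.ndarray, list[str]]:
    """Per-member control-coefficient matrices.

    Returns (results, success mask, failure log); results[i] is None for
    failed members.
    """
    outputs, success, log = _run_members(
        model, sample, lambda m: flux_control_coefficients(m, options)
    )
    return outputs, success, log
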