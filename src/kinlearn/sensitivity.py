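"""Variance-based (Sobol) global sensitivity analysis.

The radial Saltelli design draws two independent sample matrices A and
B over the parameter priors and builds, per parameter i, the hybrid
matrix AB_i equal to A with column i replaced from B — a total of
``n_base * (p + 2)`` model evaluations.  From the model outputs the
first-order and total-order indices are estimated as

    S1_i = mean(fB * (fAB_i - fA)) / V        (Saltelli et al. 2010)
    ST_i = mean((fA - fAB_i)^2) / (2 V)       (Jansen 1999)

with V the pooled sample variance of (fA, fB).  For time-resolved
outputs the estimators apply independently per time point.  Raw
estimates are reported as-is: small negative values are estimation
noise and are deliberately not clipped.  Time points with zero output
variance carry explicit undefined markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .distributions import DistributionSpec
from .errors import ValidationError


@dataclass
class SaltelliDesign:
    """Radial Sobol design: base matrices A, B and per-parameter AB_i."""

    A: np.ndarray
    B: np.ndarray
    AB: list[np.ndarray]
    names: list[str]
    n_base: int
    scheme: str
    seed: int

    @property
    def n_evaluations(self) -> int:
        return self.n_base * (len(self.names) + 2)

    def all_rows(self) -> np.ndarray:
        """Stack [A; B; AB_1; ...; AB_p] into one (n_base*(p+2), p) matrix."""
        return np.vstack([self.A, self.B, *self.AB])

    def split_outputs(self, f: np.ndarray):
        """Split outputs evaluated on :meth:`all_rows` back into (fA, fB, [fAB_i])."""
        n = self.n_base
        fA, fB = f[:n], f[n : 2 * n]
        fAB = [f[(2 + i) * n : (3 + i) * n] for i in range(len(self.names))]
        return fA, fB, fAB


def saltelli_sample(
    specs: list[DistributionSpec],
    n_base: int,
    seed: int,
    scheme: str = "pseudo-random",
) -> SaltelliDesign:
    """Build the radial design over the given priors.

    ``scheme="sobol"`` uses a scrambled low-discrepancy Sobol sequence in
    the unit cube; the default uses seeded pseudo-random uniforms.
    A non-power-of-two ``n_base`` triggers a warning (balance properties
    of the design degrade).
    """
    if not specs:
        raise ValidationError("need at least one distribution spec")
    if n_base < 1:
        raise ValidationError("n_base must be >= 1")
    if n_base & (n_base - 1):
        warnings.warn(
            f"n_base={n_base} is not a power of two; Sobol estimates may be "
            "less balanced", stacklevel=2,
        )
    p = len(specs)
    if scheme == "sobol":
        u = qmc.Sobol(d=2 * p, scramble=True, seed=seed).random(n_base)
    elif scheme == "pseudo-random":
        u = np.random.default_rng(seed).uniform(size=(n_base, 2 * p))
    else:
        raise ValidationError(f"unknown scheme {scheme!r}")
    uA, uB = u[:, :p], u[:, p:]
    A = np.column_stack([s.ppf(uA[:, j]) for j, s in enumerate(specs)])
    B = np.column_stack([s.ppf(uB[:, j]) for j, s in enumerate(specs)])
    AB = []
    for i in range(p):
        m = A.copy()
        m[:, i] = B[:, i]
        AB.append(m)
    return SaltelliDesign(A, B, AB, [s.name for s in specs], n_base, scheme, seed)


def sobol_time_resolved(
    model,
    specs: list[DistributionSpec],
    n_base: int,
    seed: int,
    output: str,
    protocol=None,
    t_eval=None,
    points_per_segment: int = 20,
    scheme: str = "pseudo-random",
    options=None,
) -> "SobolResult":
    """Time-resolved Sobol analysis of one model output.

    Evaluates the full radial design by simulating the model (under a
    protocol if given, otherwise on ``t_eval``) for every design row and
    applying the estimators independently per time point.  ``output``
    may name a variable, a reaction flux or a dynamic derived quantity.
    """
    from .simulate import protocol_time_course, time_course

    design = saltelli_sample(specs, n_base, seed, scheme=scheme)
    rows = design.all_rows()

    def run(row) -> np.ndarray:
        m = model.copy().update_parameters(dict(zip(design.names, row)))
        tc = (protocol_time_course(m, protocol, points_per_segment, options)
              if protocol is not None else time_course(m, t_eval, options))
        for table in (tc.variables, tc.fluxes, tc.derived):
            if output in table.columns:
                return table[output].to_numpy(), tc.times
        raise ValidationError(f"output {output!r} not found in time course")

    first, times = run(rows[0])
    f = np.empty((rows.shape[0], first.shape[0]))
    f[0] = first
    for i in range(1, rows.shape[0]):
        f[i] = run(rows[i])[0]
    fA, fB, fAB = design.split_outputs(f)
    return sobol_indices(fA, fB, fAB, names=design.names,
                         output_labels=list(times))


@dataclass
class SobolResult:
    """First/total-order indices, per output column (e.g. per time point)."""

    S1: np.ndarray  # (n_outputs, p)
    ST: np.ndarray  # (n_outputs, p)
    undefined: np.ndarray  # (n_outputs,) True where output variance is zero
    names: list[str]
    n_base: int
    S1_ci: np.ndarray | None = None  # bootstrap half-widths
    ST_ci: np.ndarray | None = None
    S2: np.ndarray | None = None  # (n_outputs, p, p) optional second-order
    output_labels: list | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        labels = self.output_labels or list(range(self.S1.shape[0]))
        for t, label in enumerate(labels):
            for j, name in enumerate(self.names):
                for kind, mat, ci in (("S1", self.S1, self.S1_ci),
                                      ("ST", self.ST, self.ST_ci)):
                    rows.append({
                        "output": label, "parameter": name, "index": kind,
                        "estimate": mat[t, j],
                        "ci": ci[t, j] if ci is not None else np.nan,
                        "undefined": bool(self.undefined[t]),
                    })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sobol_indices(
    fA: np.ndarray,
    fB: np.ndarray,
    fAB: list[np.ndarray],
    names: list[str] | None = None,
    n_bootstrap: int = 0,
    bootstrap_seed: int = 0,
    output_labels: list | None = None,
) -> SobolResult:
    """Estimate S1 and ST from the design outputs.

    ``fA``/``fB``/``fAB[i]`` have shape (n_base,) for scalar outputs or
    (n_base, T) for time-resolved outputs.
    """
    fA = np.atleast_2d(np.asarray(fA, dtype=float).T).T
    fB = np.atleast_2d(np.asarray(fB, dtype=float).T).T
    fAB = [np.atleast_2d(np.asarray(f, dtype=float).T).T for f in fAB]
    if fA.shape != fB.shape or any(f.shape != fA.shape for f in fAB):
        raise ValidationError("fA, fB and all fAB_i must share one shape")
    n, T = fA.shape
    p = len(fAB)
    names = names or [f"x{i}" for i in range(p)]

    def estimate(fa, fb, fab_list):
        pooled = np.concatenate([fa, fb], axis=0)
        V = pooled.var(axis=0, ddof=1)
        undefined = V == 0
        Vsafe = np.where(undefined, 1.0, V)
        S1 = np.empty((T, p))
        ST = np.empty((T, p))
        for i, fab in enumerate(fab_list):
            S1[:, i] = np.mean(fb * (fab - fa), axis=0) / Vsafe
            ST[:, i] = np.mean((fa - fab) ** 2, axis=0) / (2 * Vsafe)
        S1[undefined, :] = np.nan
        ST[undefined, :] = np.nan
        return S1, ST, undefined

    S1, ST, undefined = estimate(fA, fB, fAB)
    S1_ci = ST_ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(bootstrap_seed)
        s1_reps = np.empty((n_bootstrap, T, p))
        st_reps = np.empty((n_bootstrap, T, p))
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            s1_reps[b], st_reps[b], _ = estimate(
                fA[idx], fB[idx], [f[idx] for f in fAB]
            )
        # 95% half-widths from the bootstrap spread
        S1_ci = 1.96 * s1_reps.std(axis=0, ddof=1)
        ST_ci = 1.96 * st_reps.std(axis=0, ddof=1)
    return SobolResult(S1, ST, undefined, names, n, S1_ci, ST_ci,
                       output_labels=output_labels)
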