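"""Parameter uncertainty distributions and sampling.

A :class:`DistributionSpec` names a model parameter and attaches a
prior — uniform(a, b), normal(mu, sigma), lognormal(mu_log, sigma_log)
or a degenerate constant — optionally truncated to an interval.  Specs
feed Monte Carlo ensembles, Saltelli/Sobol sensitivity designs and
neural posterior estimation alike.

Sampling is reproducible: identical (specs, n, seed, scheme) produce
bit-identical draws.  Two schemes are provided: independent
pseudo-random draws (default) and Latin-hypercube stratification via
inverse-CDF transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .errors import ValidationError

_FAMILIES = ("uniform", "normal", "lognormal", "constant")


@dataclass(frozen=True)
class DistributionSpec:
    """Named parameter prior.

    family/params:
      * ``uniform``:   params = (a, b) with a < b
      * ``normal``:    params = (mu, sigma), sigma >= 0
      * ``lognormal``: params = (mu_log, sigma_log) of the underlying normal
      * ``constant``:  params = (c,)
    """

    name: str
    family: str
    params: tuple[float, ...]
    truncation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.family == "uniform":
            a, b = self.params
            if not a < b:
                raise ValidationError(f"uniform({a}, {b}): requires a < b")
        elif self.family == "normal":
            if self.params[1] < 0:
                raise ValidationError("normal sigma must be >= 0")
        elif self.family == "lognormal":
            if self.params[1] < 0:
                raise ValidationError("lognormal sigma_log must be >= 0")
        elif len(self.params) != 1:
            raise ValidationError("constant takes a single value")
        if self.truncation is not None:
            lo, hi = self.truncation
            if not lo < hi:
                raise ValidationError("truncation bounds must be ordered")

    # -- frozen scipy distribution (untruncated) --------------------------
    def _frozen(self):
        if self.family == "uniform":
            a, b = self.params
            return stats.uniform(loc=a, scale=b - a)
        if self.family == "normal":
            return stats.norm(loc=self.params[0], scale=self.params[1])
        if self.family == "lognormal":
            return stats.lognorm(s=self.params[1], scale=np.exp(self.params[0]))
        return None  # constant

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF, respecting truncation by restricting the u-range."""
        if self.family == "constant":
            return np.full_like(np.asarray(u, dtype=float), self.params[0])
        frozen = self._frozen()
        if self.family == "normal" and self.params[1] == 0:
            return np.full_like(np.asarray(u, dtype=float), self.params[0])
        if self.family == "lognormal" and self.params[1] == 0:
            return np.full_like(np.asarray(u, dtype=float), np.exp(self.params[0]))
        if self.truncation is None:
            return frozen.ppf(u)
        lo, hi = frozen.cdf(self.truncation[0]), frozen.cdf(self.truncation[1])
        if hi <= lo:
            raise ValidationError(
                f"truncation {self.truncation} has zero mass under {self.family}"
            )
        return frozen.ppf(lo + np.asarray(u) * (hi - lo))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.ppf(rng.uniform(size=n))

    @property
    def support(self) -> tuple[float, float]:
        if self.truncation is not None:
            return self.truncation
        if self.family == "uniform":
            return self.params
        if self.family == "constant":
            return (self.params[0], self.params[0])
        if self.family == "lognormal":
            return (0.0, np.inf)
        return (-np.inf, np.inf)

    def to_dict(self) -> dict:
        return {"name": self.name, "family": self.family,
                "params": list(self.params),
                "truncation": list(self.truncation) if self.truncation else None}

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        trunc = tuple(d["truncation"]) if d.get("truncation") else None
        return cls(d["name"], d["family"], tuple(d["params"]), trunc)


@dataclass
class ParameterSample:
    """Matrix of parameter draws (draw × parameter)."""

    values: np.ndarray
    names: list[str]
    scheme: str
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValidationError("sample matrix must be (n, p) with p = len(names)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def row(self, i: int) -> dict[str, float]:
        return dict(zip(self.names, self.values[i]))


def sample_parameters(
    specs: list[DistributionSpec],
    n: int,
    seed: int,
    scheme: str = "pseudo-random",
) -> ParameterSample:
    """Draw n independent parameter sets from the given priors."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if scheme not in ("pseudo-random", "latin-hypercube"):
        raise ValidationError(f"unknown sampling scheme {scheme!r}")
    if not specs:
        raise ValidationError("need at least one distribution spec")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate parameter names in specs")
    p = len(specs)
    if scheme == "latin-hypercube":
        u = qmc.LatinHypercube(d=p, seed=seed).random(n)
    else:
        u = np.random.default_rng(seed).uniform(size=(n, p))
    values = np.column_stack([spec.ppf(u[:, j]) for j, spec in enumerate(specs)])
    return ParameterSample(values, names, scheme, seed)
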