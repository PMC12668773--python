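"""Kinetic parameters from enzyme-database JSON exports.

Loads enzyme-kinetics entries (Km, kcat, Ki, specific activity) from a
JSON export, normalizes values to canonical units (Km in mM, kcat in
1/s), and turns the result into filterable tidy tables and distribution
fits that feed the Monte Carlo and NPE machinery.

The expected JSON dialect is::

    {"ec": "x.x.x.x",
     "entries": [{"kind": "km"|"kcat"|"ki"|"specific_activity",
                  "value": <number>, "unit": "mM"|...,
                  "organism": <str>, "substrate": <str>?, "comment": <str>?}]}

Real database exports use their own schemas; adapt them by converting to
this dialect through :func:`load_enzyme_records` with a custom
``adapter`` — the table and fitting logic below is schema-agnostic.
Everything is file-based; the package never performs network access.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import DistributionSpec
from .errors import FitError, ValidationError

KINDS = ("km", "kcat", "ki", "specific_activity")

# conversion factors into canonical units (Km-like -> mM, rate-like -> 1/s)
_UNIT_FACTORS: dict[str, float] = {
    "M": 1e3, "mM": 1.0, "µM": 1e-3, "uM": 1e-3, "nM": 1e-6,
    "1/s": 1.0, "s^-1": 1.0, "1/min": 1.0 / 60.0, "min^-1": 1.0 / 60.0,
}

CANONICAL_UNITS = {"km": "mM", "ki": "mM", "kcat": "1/s", "specific_activity": "1/s"}


@dataclass(frozen=True)
class EnzymeRecord:
    ec: str
    organism: str
    kind: str
    value: float
    unit: str
    normalized_value: float  # in the canonical unit for this kind
    substrate: str | None = None
    comment: str | None = None
    source: str = ""


def load_enzyme_json(path, adapter=None) -> list[EnzymeRecord]:
    """Parse a JSON export into records; malformed entries are skipped
    with a warning carrying the skip count."""
    with open(path) as fh:
        data = json.load(fh)
    return load_enzyme_records(data, source=str(path), adapter=adapter)


def load_enzyme_records(data: dict, source: str = "", adapter=None) -> list[EnzymeRecord]:
    if adapter is not None:
        data = adapter(data)
    ec = data.get("ec", "")
    records: list[EnzymeRecord] = []
    skipped = 0
    for entry in data.get("entries", []):
        try:
            kind = str(entry["kind"]).lower()
            if kind not in KINDS:
                raise ValueError(f"unrecognized kind {kind!r}")
            value = float(entry["value"])
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"value must be positive and finite, got {value}")
            unit = str(entry["unit"])
            if unit not in _UNIT_FACTORS:
                raise ValueError(f"unknown unit {unit!r}")
            records.append(EnzymeRecord(
                ec=ec,
                organism=str(entry.get("organism", "")),
                kind=kind,
                value=value,
                unit=unit,
                normalized_value=value * _UNIT_FACTORS[unit],
                substrate=entry.get("substrate"),
                comment=entry.get("comment"),
                source=source,
            ))
        except (KeyError, TypeError, ValueError) as exc:
            skipped += 1
            warnings.warn(f"skipping malformed entry ({exc})", stacklevel=2)
    if not records:
        warnings.warn(f"no valid entries loaded from {source or 'input'} "
                      f"({skipped} skipped)", stacklevel=2)
    return records


def to_table(records: list[EnzymeRecord], kind: str) -> pd.DataFrame:
    """Tidy table of one parameter kind, sorted by (organism, substrate, value)."""
    if kind not in KINDS:
        raise ValidationError(f"unrecognized kind {kind!r}")
    rows = [{
        "ec": r.ec, "organism": r.organism, "kind": r.kind,
        "substrate": r.substrate or "", "value": r.value, "unit": r.unit,
        "normalized_value": r.normalized_value,
        "canonical_unit": CANONICAL_UNITS[r.kind], "comment": r.comment or "",
    } for r in records if r.kind == kind]
    df = pd.DataFrame(rows, columns=[
        "ec", "organism", "kind", "substrate", "value", "unit",
        "normalized_value", "canonical_unit", "comment",
    ])
    return df.sort_values(["organism", "substrate", "normalized_value"]).reset_index(drop=True)


def filter_table(
    table: pd.DataFrame,
    organism: str | None = None,
    substrate: str | None = None,
    value_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    out = table
    if organism is not None:
        out = out[out["organism"] == organism]
    if substrate is not None:
        out = out[out["substrate"] == substrate]
    if value_range is not None:
        lo, hi = value_range
        out = out[(out["normalized_value"] >= lo) & (out["normalized_value"] <= hi)]
    return out.reset_index(drop=True)


def fit_distribution(table: pd.DataFrame, family: str,
                     parameter_name: str = "parameter") -> DistributionSpec:
    """Fit a prior to the normalized values of a table.

    * lognormal: mu_log/sigma_log from mean and sample sd (n−1 divisor)
      of log values; a single value or zero spread degenerates to a
      constant spec with a warning.
    * normal: mean and sample sd of the values.
    * uniform-range: [min, max] of the values.
    """
    if family not in ("normal", "lognormal", "uniform-range"):
        raise ValidationError(f"unknown family {family!r}")
    values = table["normalized_value"].to_numpy(dtype=float)
    if values.size == 0:
        raise FitError("cannot fit a distribution to an empty table")
    if family == "uniform-range":
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:
            warnings.warn("all values identical; returning constant spec", stacklevel=2)
            return DistributionSpec(parameter_name, "constant", (lo,))
        return DistributionSpec(parameter_name, "uniform", (lo, hi))
    if family == "lognormal":
        if values.size == 1:
            warnings.warn("single value; returning width-zero constant spec",
                          stacklevel=2)
            return DistributionSpec(parameter_name, "constant", (float(values[0]),))
        logs = np.log(values)
        mu = float(logs.mean())
        sigma = float(logs.std(ddof=1))
        if sigma == 0.0:
            warnings.warn("degenerate lognormal fit: zero spread", stacklevel=2)
        return DistributionSpec(parameter_name, "lognormal", (mu, sigma))
    if values.size == 1:
        warnings.warn("single value; returning width-zero constant spec", stacklevel=2)
        return DistributionSpec(parameter_name, "constant", (float(values[0]),))
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    if sigma == 0.0:
        warnings.warn("degenerate normal fit: zero spread", stacklevel=2)
    return DistributionSpec(parameter_name, "normal", (mu, sigma))
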