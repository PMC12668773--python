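"""Derive parameter priors from an enzyme-database JSON export.

A small synthetic export (the documented JSON dialect) is written to a
temporary file, loaded, normalized to canonical units (Km in mM, kcat
in 1/s), filtered, and fitted with a lognormal prior ready for Monte
Carlo or NPE workflows.
"""

import json
import tempfile
from pathlib import Path

import kinlearn as kl
from kinlearn.parameterise import filter_table, fit_distribution, load_enzyme_json, to_table

export = {
    "ec": "2.7.1.1",  # hexokinase-like, synthetic values
    "entries": [
        {"kind": "km", "value": 0.12, "unit": "mM", "organism": "S. cerevisiae",
         "substrate": "glucose"},
        {"kind": "km", "value": 95.0, "unit": "µM", "organism": "S. cerevisiae",
         "substrate": "glucose"},
        {"kind": "km", "value": 0.21, "unit": "mM", "organism": "E. coli",
         "substrate": "glucose"},
        {"kind": "km", "value": 300.0, "unit": "µM", "organism": "H. sapiens",
         "substrate": "glucose"},
        {"kind": "kcat", "value": 250.0, "unit": "1/s", "organism": "E. coli"},
    ],
}

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "hexokinase.json"
    path.write_text(json.dumps(export))
    records = load_enzyme_json(path)

print(f"loaded {len(records)} records")
km = to_table(records, "km")
print("\nKm table (normalized to mM):")
print(km[["organism", "substrate", "value", "unit", "normalized_value"]]
      .to_string(index=False))

yeast = filter_table(km, organism="S. cerevisiae")
prior = fit_distribution(km, "lognormal", parameter_name="Km_glucose")
print(f"\nlognormal prior over all organisms: mu_log = {prior.params[0]:.3f}, "
      f"sigma_log = {prior.params[1]:.3f}")
print(f"(yeast-only table has {len(yeast)} rows; filter before fitting to "
      "restrict the prior to one organism)")

draws = kl.sample_parameters([prior], 5, seed=0)
print(f"five prior draws (mM): {[round(float(v), 4) for v in draws.values[:, 0]]}")
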