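"""Packaged toy models, protocols and synthetic-data builders.

Everything here is generated in code — no downloads, no data files —
and every other module is testable against these fixtures.

* :func:`decay_model`, :func:`linear_pathway` — minimal models with
  closed-form solutions, the workhorses of the test suite.
* :func:`kirschbaum_style_model` — a semi-empirical stomatal
  conductance model: three first-order-relaxation ODEs driving a
  biochemical signal, the guard-cell osmotic potential and the leaf
  water potential; stomatal conductance gs is proportional to the water
  potential.  Light enters through a protocol switching the ``L``
  parameter.  The light→signal mapping and the default time constants
  are this package's own documented choices (linear target L/500;
  τ values are round numbers in minutes).
* :func:`toy_petc_cbb` — a deliberately small two-module photosynthesis
  caricature: an upstream light-driven electron-transport pool
  producing ATP-like and NADPH-like carriers, and a downstream
  carboxylation module consuming them.  Its purpose is demonstrating
  surrogate replacement of the upstream module, not quantitative
  photosynthesis.
"""

from __future__ import annotations

import numpy as np

from .distributions import DistributionSpec
from .errors import UnknownReferenceError
from .model import Model
from .ratelaws import first_order_relaxation
from .simulate import Protocol
from .surrogate import add_surrogate


# --------------------------------------------------------------------- #
# minimal closed-form models
# --------------------------------------------------------------------- #
def decay_model(k: float = 1.0, s0: float = 1.0) -> Model:
    """dS/dt = -k S; solution S(t) = s0 * exp(-k t)."""
    return (
        Model("decay")
        .add_parameter("k", k)
        .add_variable("S", s0)
        .add_law_reaction("v1", "mass_action", ["k", "S"], {"S": -1})
    )


def linear_pathway(k1: float = 1.0, A: float = 2.0, k2: float = 4.0,
                   s1_0: float = 0.0) -> Model:
    """Constant-substrate pathway A -> S1 -> ∅.

    v1 = k1·A (A a fixed parameter), v2 = k2·S1; steady state
    S1* = k1·A/k2 with flux J* = k1·A.
    """
    return (
        Model("linear_pathway")
        .add_parameter("k1", k1)
        .add_parameter("A", A)
        .add_parameter("k2", k2)
        .add_variable("S1", s1_0)
        .add_law_reaction("v1", "mass_action", ["k1", "A"], {"S1": 1})
        .add_law_reaction("v2", "mass_action", ["k2", "S1"], {"S1": -1})
    )


# --------------------------------------------------------------------- #
# stomatal conductance fixture
# --------------------------------------------------------------------- #
STOMATAL_DEFAULTS = {
    "tau_i": 1.0,   # min — signal increase
    "tau_d": 3.0,   # min — signal decrease
    "tau_pi": 2.0,  # min — osmotic potential
    "tau_w": 4.0,   # min — leaf water potential
    "g_prop": 1.0,  # conductance per unit water potential
    "L": 0.0,       # light intensity, µmol m^-2 s^-1 (protocol-driven)
    "L_ref": 500.0, # light normalization
}


def _signal_rate(target: float, sig: float, tau_i: float, tau_d: float) -> float:
    # asymmetric first-order relaxation: fast rise (tau_i), slow fall (tau_d)
    tau = tau_i if target > sig else tau_d
    return (target - sig) / tau


def kirschbaum_style_model(parameter_overrides: dict[str, float] | None = None) -> Model:
    """Three-ODE stomatal conductance model (time unit: minutes).

    dSig/dt = (L/L_ref − Sig)/τ   with τ = τi while the signal rises,
                                  τd while it falls
    dπ/dt   = (Sig − π)/τπ
    dw/dt   = (π − w)/τw
    gs      = g_prop · w   (derived, dynamic)
    """
    m = Model("stomatal", annotations={"time_unit": "min"})
    for name, value in STOMATAL_DEFAULTS.items():
        m.add_parameter(name, value)
    m.add_variable("Sig", 0.0)
    m.add_variable("pi_osm", 0.0, signed=True)
    m.add_variable("w", 0.0, signed=True)
    m.add_derived("sig_target", lambda L, L_ref: L / L_ref, ["L", "L_ref"])
    m.add_reaction("v_sig", _signal_rate, ["sig_target", "Sig", "tau_i", "tau_d"],
                   {"Sig": 1})
    m.add_law_reaction("v_pi", "first_order_relaxation", ["Sig", "pi_osm", "tau_pi"],
                       {"pi_osm": 1})
    m.add_law_reaction("v_w", "first_order_relaxation", ["pi_osm", "w", "tau_w"],
                       {"w": 1})
    m.add_derived("gs", lambda g_prop, w: g_prop * w, ["g_prop", "w"])
    if parameter_overrides:
        for name in parameter_overrides:
            if name not in m.parameters:
                raise UnknownReferenceError(f"unknown parameter {name!r}")
        m.update_parameters(parameter_overrides)
    return m


class LightProtocol(Protocol):
    """Pulsed light schedule: dark lead-in, then repeated (pulse, dark) pairs.

    Default: two 5-minute pulses at intensity 500 separated by dark
    phases, applied to a dark-adapted state.
    """

    def __init__(self, pulse_count: int = 2, pulse_duration: float = 5.0,
                 pulse_intensity: float = 500.0, dark_duration: float = 10.0,
                 lead_in: float = 15.0, parameter: str = "L") -> None:
        segments: list[tuple[float, dict[str, float]]] = [(lead_in, {parameter: 0.0})]
        for _ in range(pulse_count):
            segments.append((pulse_duration, {parameter: pulse_intensity}))
            segments.append((dark_duration, {parameter: 0.0}))
        super().__init__(segments)
        self.pulse_count = pulse_count
        self.pulse_duration = pulse_duration
        self.pulse_intensity = pulse_intensity
        self.dark_duration = dark_duration
        self.lead_in = lead_in
        self.parameter = parameter

    def pulse_windows(self) -> list[tuple[float, float]]:
        """(start, end) of each light pulse on the cumulative time axis."""
        out = []
        t = self.lead_in
        for _ in range(self.pulse_count):
            out.append((t, t + self.pulse_duration))
            t += self.pulse_duration + self.dark_duration
        return out


def default_light_protocol() -> LightProtocol:
    return LightProtocol()


def case_study_1_priors(model: Model, variation: float = 0.2) -> list[DistributionSpec]:
    """Gaussian priors on the four stomatal time constants.

    Mean = current model value; sigma chosen so 3σ spans ±`variation`
    (default 20%) of the mean — i.e. 99.7% of draws fall within
    [0.8µ, 1.2µ].
    """
    specs = []
    for name in ("tau_i", "tau_d", "tau_pi", "tau_w"):
        if name not in model.parameters:
            raise UnknownReferenceError(f"model lacks time constant {name!r}")
        mu = model.parameters[name].value
        specs.append(DistributionSpec(name, "normal", (mu, variation * mu / 3.0)))
    return specs


# --------------------------------------------------------------------- #
# toy photosynthesis fixture (two modules)
# --------------------------------------------------------------------- #
PETC_DEFAULTS = {
    "L": 500.0,      # light intensity
    "k_L": 0.025,    # light-driven charging of the electron-transport pool
    "k_t": 10.0,     # pool relaxation / turnover — fast relative to the
                     # downstream module (τ ≈ 0.04 vs ≈ 10), the physical
                     # premise of replacing the upstream module by its
                     # steady-state response
    "c_atp": 0.18,   # ATP yield per turnover
    "c_nadph": 0.12, # NADPH yield per turnover
    "Vc": 0.8,       # carboxylation capacity
    "Km_atp": 0.5,
    "Km_nadph": 0.5,
    "d_atp": 0.1,    # carrier leak rates (make the steady state unique)
    "d_nadph": 0.1,
}

UPSTREAM_REACTIONS = ("v_charge", "v_relax", "v_prod_atp", "v_prod_nadph")
CARRIER_PRODUCTION = ("v_prod_atp", "v_prod_nadph")


def _carboxylation(Vc: float, A: float, Km_a: float, N: float, Km_n: float) -> float:
    return Vc * (A / (A + Km_a)) * (N / (N + Km_n))


def _add_downstream(m: Model) -> Model:
    m.add_reaction("v_carboxylation", _carboxylation,
                   ["Vc", "ATP", "Km_atp", "NADPH", "Km_nadph"],
                   {"ATP": -3, "NADPH": -2})
    m.add_law_reaction("v_leak_atp", "mass_action", ["d_atp", "ATP"], {"ATP": -1})
    m.add_law_reaction("v_leak_nadph", "mass_action", ["d_nadph", "NADPH"],
                       {"NADPH": -1})
    return m


def _full_petc_cbb() -> Model:
    m = Model("toy_petc_cbb_full")
    for name, value in PETC_DEFAULTS.items():
        m.add_parameter(name, value)
    m.add_variable("P", 0.0)       # excited electron-transport pool (0..1)
    m.add_variable("ATP", 0.5)
    m.add_variable("NADPH", 0.5)
    m.add_reaction("v_charge", lambda k_L, L, P: k_L * L * (1.0 - P),
                   ["k_L", "L", "P"], {"P": 1})
    m.add_law_reaction("v_relax", "mass_action", ["k_t", "P"], {"P": -1})
    m.add_law_reaction("v_prod_atp", "mass_action", ["c_atp", "k_t", "P"], {"ATP": 1})
    m.add_law_reaction("v_prod_nadph", "mass_action", ["c_nadph", "k_t", "P"],
                       {"NADPH": 1})
    return _add_downstream(m)


def _downstream_only() -> Model:
    """Downstream module with placeholder carrier-production reactions
    (meant to be replaced by a trained surrogate)."""
    m = Model("toy_petc_cbb_hybrid")
    for name, value in PETC_DEFAULTS.items():
        m.add_parameter(name, value)
    m.add_variable("ATP", 0.5)
    m.add_variable("NADPH", 0.5)
    m.add_law_reaction("v_prod_atp", "constant", ["L"], {"ATP": 1})
    m.add_law_reaction("v_prod_nadph", "constant", ["L"], {"NADPH": 1})
    return _add_downstream(m)


def toy_petc_cbb():
    """(full model, hybrid builder).

    The hybrid builder takes a surrogate trained to map light intensity
    ``L`` to the steady-state carrier-production fluxes (output names
    ``v_prod_atp``, ``v_prod_nadph``) and splices it into the downstream
    module in replacement mode.  Both variants expose the downstream
    flux ``v_carboxylation``.
    """
    full = _full_petc_cbb()

    def build_hybrid(surrogate) -> Model:
        base = _downstream_only()
        return add_surrogate(
            base, surrogate, inputs=["L"], mode="replacement",
            replaced_reactions=list(CARRIER_PRODUCTION), name="petc",
        )

    return full, build_hybrid


def light_grid(n: int = 13, low: float = 0.0, high: float = 1200.0) -> np.ndarray:
    """Default light-intensity grid for surrogate training/evaluation."""
    return np.linspace(low, high, n)[:, None]
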