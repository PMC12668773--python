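import numpy as np
import pytest

import kinlearn as kl


@pytest.fixture
def decay():
    """dS/dt = -k S with k=1, S0=1; solution e^{-t}."""
    return kl.decay_model()


@pytest.fixture
def pathway():
    """A -> S1 -> 0 with v1 = k1*A = 2 (constant), v2 = k2*S1, k2 = 4.

    Closed forms: S1*(t->inf) = k1*A/k2 = 0.5, J* = 2,
    S1(t) = (k1 A / k2)(1 - e^{-k2 t}).
    """
    return kl.linear_pathway()


@pytest.fixture
def conserved_pair():
    """Closed interconversion A <-> B; A+B conserved, singular Jacobian."""
    return (
        kl.Model("ab")
        .add_parameter("kf", 1.0)
        .add_parameter("kr", 0.5)
        .add_variable("A", 1.0)
        .add_variable("B", 0.0)
        .add_law_reaction("vf", "mass_action", ["kf", "A"], {"A": -1, "B": 1})
        .add_law_reaction("vr", "mass_action", ["kr", "B"], {"A": 1, "B": -1})
    )


@pytest.fixture
def stomatal():
    return kl.kirschbaum_style_model()


def random_mass_action_pathway(rng: np.random.Generator, n_species: int) -> kl.Model:
    """Open linear mass-action chain: constant inflow, first-order steps,
    first-order outflow — always reaches a unique steady state."""
    m = kl.Model(f"chain{n_species}")
    m.add_parameter("k0", float(rng.uniform(0.5, 2.0)))
    for i in range(n_species):
        m.add_parameter(f"k{i + 1}", float(rng.uniform(0.5, 3.0)))
        m.add_variable(f"S{i}", float(rng.uniform(0.1, 1.0)))
    m.add_law_reaction("v0", "constant", ["k0"], {"S0": 1})
    for i in range(n_species):
        target = {f"S{i}": -1}
        if i + 1 < n_species:
            target[f"S{i + 1}"] = 1
        m.add_law_reaction(f"v{i + 1}", "mass_action", [f"k{i + 1}", f"S{i}"], target)
    return m
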