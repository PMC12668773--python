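"""Registered rate laws.

A registered rate law couples a pure evaluator with a LaTeX template and
a serialization identifier, so models built exclusively from registered
laws round-trip through JSON bit-exactly and render symbolically in the
LaTeX export.  Arbitrary in-code rate functions remain first-class; they
simply serialize structure-only and render as opaque named terms.

Evaluators are pure positional functions: the argument order is the
dependency list declared when the reaction is registered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence


@dataclass(frozen=True)
class RateLaw:
    identifier: str
    fn: Callable[..., float]
    arity: int | None  # None = variadic
    latex: Callable[[Sequence[str]], str]


def _mass_action(k: float, *concentrations: float) -> float:
    out = k
    for c in concentrations:
        out *= c
    return out


def _michaelis_menten(vmax: float, km: float, s: float) -> float:
    return vmax * s / (km + s)


def _constant(k: float) -> float:
    return k


def _first_order_relaxation(target: float, x: float, tau: float) -> float:
    return (target - x) / tau


def _latex_mass_action(args: Sequence[str]) -> str:
    return " ".join(args)


def _latex_michaelis_menten(args: Sequence[str]) -> str:
    vmax, km, s = args
    return rf"\frac{{{vmax} \cdot {s}}}{{{km} + {s}}}"


def _latex_constant(args: Sequence[str]) -> str:
    return args[0]


def _latex_relaxation(args: Sequence[str]) -> str:
    target, x, tau = args
    return rf"\frac{{{target} - {x}}}{{{tau}}}"


RATE_LAWS: dict[str, RateLaw] = {
    "mass_action": RateLaw("mass_action", _mass_action, None, _latex_mass_action),
    "michaelis_menten": RateLaw("michaelis_menten", _michaelis_menten, 3, _latex_michaelis_menten),
    "constant": RateLaw("constant", _constant, 1, _latex_constant),
    "first_order_relaxation": RateLaw(
        "first_order_relaxation", _first_order_relaxation, 3, _latex_relaxation
    ),
}

mass_action = _mass_action
michaelis_menten = _michaelis_menten
constant = _constant
first_order_relaxation = _first_order_relaxation


def expression_tree(identifier: str, args: Sequence[str]):
    """Export a registered rate law as a nested-tuple expression tree.

    Extension hook for symbolic tooling: ("mul", ...), ("div", a, b),
    ("sub", a, b), ("sym", name).
    """
    sym = lambda n: ("sym", n)  # noqa: E731
    if identifier == "mass_action":
        return ("mul", *[sym(a) for a in args])
    if identifier == "michaelis_menten":
        vmax, km, s = args
        return ("div", ("mul", sym(vmax), sym(s)), ("add", sym(km), sym(s)))
    if identifier == "constant":
        return sym(args[0])
    if identifier == "first_order_relaxation":
        target, x, tau = args
        return ("div", ("sub", sym(target), sym(x)), sym(tau))
    raise KeyError(identifier)
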