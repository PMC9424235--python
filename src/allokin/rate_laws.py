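"""Steady-state rate laws for nonessential enzyme activation.

Three rapid-equilibrium binding schemes for an enzyme E, substrate S and
activator A are covered, differing in the order in which S and A may bind:

* ``random`` — A binds free enzyme and the ES complex (general modifier
  scheme).  The ternary ESA complex turns over at ``beta * kcat``; activator
  binding changes substrate affinity by the coupling factor ``alpha``::

      v = V * S * (1 + beta*A/(alpha*Ka)) /
          ( Km*(1 + A/Ka) + S*(1 + A/(alpha*Ka)) )

* ``ordered_substrate_first`` — A binds only the ES complex, so activation
  can only raise kcat (``beta``); ``alpha`` does not appear::

      v = V * S * (1 + beta*A/Ka) / ( Km + S*(1 + A/Ka) )

* ``ordered_activator_first`` — S binds only after A, so the rate vanishes
  at A = 0 for every S.  An enzyme with measurable basal activity is
  therefore incompatible with this scheme, which is why the package carries
  it: fitting it lets the incompatibility be demonstrated quantitatively. ::

      v = beta*V * (S*A/(alpha*Km*Ka)) / ( 1 + A/Ka + S*A/(alpha*Km*Ka) )

Symbols: V = kcat*Et is the maximal basal rate, Km the Michaelis constant,
Ka the activation (binding) constant, alpha the dimensionless substrate–
activator interaction coefficient, beta the dimensionless fold-change of
kcat in the ternary complex.  All concentrations are carried in molar and
rates in molar/second internally; the I/O layer converts from the nM / μM
conventions of bench work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

import numpy as np

__all__ = [
    "Mechanism",
    "ActivationParameters",
    "AssayCondition",
    "rate",
    "rate_random",
    "rate_ordered_substrate_first",
    "rate_ordered_activator_first",
    "basal_rate",
]


class Mechanism(str, Enum):
    """Order of substrate/activator binding in the activation scheme."""

    RANDOM = "random"
    ORDERED_SUBSTRATE_FIRST = "ordered_substrate_first"
    ORDERED_ACTIVATOR_FIRST = "ordered_activator_first"


#: free parameters of each mechanism's rate law (beyond V, Km, Ka)
_MECHANISM_USES_ALPHA = {
    Mechanism.RANDOM: True,
    Mechanism.ORDERED_SUBSTRATE_FIRST: False,
    Mechanism.ORDERED_ACTIVATOR_FIRST: True,
}


@dataclass(frozen=True)
class ActivationParameters:
    """Full parameter set of one activation mechanism.

    Parameters
    ----------
    mechanism : Mechanism or str
        Binding scheme the parameters belong to.
    V : float, optional
        Maximal basal rate, molar/second (``V = kcat * Et``).  May be
        omitted when both ``kcat`` and ``Et`` are given.
    kcat : float, optional
        Basal catalytic constant, 1/s.
    Et : float, optional
        Total enzyme concentration, molar.
    Km : float
        Michaelis constant, molar.
    Ka : float
        Activation constant, molar.
    alpha : float, optional
        Substrate–activator binding interaction coefficient
        (dimensionless).  Required for the random and
        activator-first schemes; must be absent for substrate-first.
    beta : float, optional
        Fold-change of kcat in the activator-bound complex
        (dimensionless).  Required for every scheme.
    """

    mechanism: Mechanism
    Km: float = 0.0
    Ka: float = 0.0
    V: Optional[float] = None
    kcat: Optional[float] = None
    Et: Optional[float] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        if self.V is None:
            if self.kcat is None or self.Et is None:
                raise ValueError("either V or both kcat and Et must be given")
            object.__setattr__(self, "V", self.kcat * self.Et)
        elif self.kcat is not None and self.Et is not None:
            if not math.isclose(self.V, self.kcat * self.Et, rel_tol=1e-9):
                raise ValueError(
                    f"inconsistent parameters: V={self.V} but "
                    f"kcat*Et={self.kcat * self.Et}"
                )
        for name in ("V", "Km", "Ka"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"{name} must be finite and strictly positive, got {val}")
        if self.beta is None:
            raise ValueError("beta is required for every mechanism")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be finite and strictly positive, got {self.beta}")
        if _MECHANISM_USES_ALPHA[self.mechanism]:
            if self.alpha is None:
                raise ValueError(f"alpha is required for mechanism {self.mechanism.value}")
            if not (np.isfinite(self.alpha) and self.alpha > 0):
                raise ValueError(
                    f"alpha must be finite and strictly positive, got {self.alpha}"
                )
        elif self.alpha is not None:
            raise ValueError(
                f"alpha is not a parameter of mechanism {self.mechanism.value}; "
                "leave it unset"
            )

    def replace(self, **changes) -> "ActivationParameters":
        """Return a copy with the given fields replaced."""
        from dataclasses import replace as _replace

        if "V" in changes and "kcat" not in changes:
            changes.setdefault("kcat", None)
        return _replace(self, **changes)


@dataclass(frozen=True)
class AssayCondition:
    """One well's condition: substrate, activator and enzyme concentration (molar)."""

    S: float
    A: float = 0.0
    Et: float = 0.0
    activator_id: str = ""

    def __post_init__(self) -> None:
        for name in ("S", "A", "Et"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {val}")


ArrayLike = Union[float, np.ndarray]


def _check_conc(name: str, x: ArrayLike) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError(f"{name} must be finite and non-negative")
    return arr


def _require(params: ActivationParameters, mechanism: Mechanism) -> None:
    if params.mechanism is not mechanism:
        raise ValueError(
            f"parameters are for mechanism {params.mechanism.value!r}, "
            f"expected {mechanism.value!r}"
        )


def rate_random(params: ActivationParameters, S: ArrayLike, A: ArrayLike) -> ArrayLike:
    """Rate of the random-binding (general modifier) scheme, molar/second.

    Reduces to the Michaelis–Menten basal rate ``V*S/(Km+S)`` at A = 0 and
    to ``beta*V*S/(alpha*Km + S)`` as A → ∞.
    """
    _require(params, Mechanism.RANDOM)
    S = _check_conc("S", S)
    A = _check_conc("A", A)
    aKa = params.alpha * params.Ka
    num = params.V * S * (1.0 + params.beta * A / aKa)
    den = params.Km * (1.0 + A / params.Ka) + S * (1.0 + A / aKa)
    return _safe_div(num, den)


def rate_ordered_substrate_first(
    params: ActivationParameters, S: ArrayLike, A: ArrayLike
) -> ArrayLike:
    """Rate when the activator binds only the ES complex, molar/second.

    Activation acts purely through kcat (beta); with beta = 1 the rate is
    independent of A.
    """
    _require(params, Mechanism.ORDERED_SUBSTRATE_FIRST)
    S = _check_conc("S", S)
    A = _check_conc("A", A)
    num = params.V * S * (1.0 + params.beta * A / params.Ka)
    den = params.Km + S * (1.0 + A / params.Ka)
    return _safe_div(num, den)


def rate_ordered_activator_first(
    params: ActivationParameters, S: ArrayLike, A: ArrayLike
) -> ArrayLike:
    """Rate when substrate binds only after the activator, molar/second.

    Zero at A = 0 for every S — the scheme admits no basal activity, which
    is what rules it out for an enzyme that is active without activator.
    """
    _require(params, Mechanism.ORDERED_ACTIVATOR_FIRST)
    S = _check_conc("S", S)
    A = _check_conc("A", A)
    x = S * A / (params.alpha * params.Km * params.Ka)
    num = params.beta * params.V * x
    den = 1.0 + A / params.Ka + x
    return _safe_div(num, den)


_DISPATCH = {
    Mechanism.RANDOM: rate_random,
    Mechanism.ORDERED_SUBSTRATE_FIRST: rate_ordered_substrate_first,
    Mechanism.ORDERED_ACTIVATOR_FIRST: rate_ordered_activator_first,
}


def rate(params: ActivationParameters, S: ArrayLike, A: ArrayLike) -> ArrayLike:
    """Evaluate the rate law of ``params.mechanism`` at (S, A)."""
    return _DISPATCH[params.mechanism](params, S, A)


def basal_rate(params: ActivationParameters, S: ArrayLike) -> ArrayLike:
    """Activator-free limit of the mechanism's rate law (A = 0)."""
    S = _check_conc("S", S)
    return rate(params, S, np.zeros_like(np.asarray(S, dtype=float)))


def _safe_div(num: np.ndarray, den: np.ndarray) -> ArrayLike:
    # den > 0 whenever num > 0 for all three laws; 0/0 (e.g. S=A=0 for the
    # activator-first scheme with its unit constant term absent) cannot
    # occur, but guard scalar/array return type uniformly.
    out = num / den
    if out.ndim == 0:
        return float(out)
    return out
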