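"""Simulation of the molecular-beacon fluorescent cleavage assay.

A hairpin DNA substrate carries a fluorophore–quencher pair (5'-FAM /
3'-DAB).  Enzymatic strand cleavage releases the FAM-bearing arm from the
quencher, so product formation reads out as rising fluorescence.  Two
features of real beacons are modeled:

* substrate depletion — product accumulates as dP/dt = v(S0 − P, A) under
  the chosen activation mechanism, so progress curves bend over as
  substrate runs out;
* incomplete dissociation — only a fraction ``phi`` of the cleaved
  FAM-arm duplex is released at equilibrium.  A beacon with a long stem
  5' of the lesion holds on to its cleavage product and plateaus below
  stoichiometric signal; trimming the stem raises ``phi``.

Observed fluorescence is ``F(t) = F_b + m * phi * P(t)`` plus optional
Gaussian read noise.  Enzyme is not consumed and product inhibition is not
modeled, matching the assumptions of initial-rate analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .rate_laws import ActivationParameters, AssayCondition, rate

__all__ = [
    "BeaconDesign",
    "FluorescenceModel",
    "ProgressCurve",
    "simulate_progress",
    "equilibrium_release_fraction",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)


@dataclass(frozen=True)
class BeaconDesign:
    """Hairpin-beacon design parameters.

    ``stem_bp_5prime`` counts base pairs 5' of the lesion (3 in the
    trimmed design, 5 in the original); other values are allowed but
    flagged as nonstandard.  ``dissociation_fraction`` (phi) is the
    fraction of cleaved product whose FAM arm is released at equilibrium.
    """

    stem_bp_5prime: int = 3
    dissociation_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.stem_bp_5prime < 1:
            raise ValueError("stem_bp_5prime must be a positive integer")
        phi = self.dissociation_fraction
        if not (0.0 < phi <= 1.0):
            raise ValueError(f"dissociation_fraction must be in (0, 1], got {phi}")

    @property
    def is_standard(self) -> bool:
        """True for the two bench designs (3 or 5 bp stems)."""
        return self.stem_bp_5prime in (3, 5)


@dataclass(frozen=True)
class FluorescenceModel:
    """Observation model mapping released product to plate-reader signal.

    ``gain`` is in fluorescence units per molar of released product;
    ``background`` in fluorescence units; ``noise_sd`` is the additive
    Gaussian read-noise standard deviation.  ``noise_kind`` may be set to
    ``"proportional"`` (sd scales with the noiseless signal), but additive
    read noise is the default as it dominates plate readers.
    """

    background: float = 0.0
    gain: float = 1.0e9
    noise_sd: float = 0.0
    noise_kind: str = "additive"

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_kind not in ("additive", "proportional"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")


@dataclass(frozen=True)
class ProgressCurve:
    """One well's fluorescence time course with its assay condition.

    ``product`` is the underlying cleaved-product concentration (molar)
    at each time point; simulations carry it so downstream checks can see
    through the observation model.  Real data would leave it None.
    """

    condition: AssayCondition
    design: BeaconDesign
    times: np.ndarray
    fluorescence: np.ndarray
    seed: Optional[int] = None
    product: Optional[np.ndarray] = None
    well: str = ""
    compound_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape:
            raise ValueError("times and fluorescence must have equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", f)


def simulate_progress(
    params: Optional[ActivationParameters],
    condition: AssayCondition,
    design: BeaconDesign,
    fluor: FluorescenceModel,
    times: Sequence[float],
    seed: Optional[int] = None,
    rtol: float = 1e-8,
) -> ProgressCurve:
    """Integrate substrate depletion and return the observed fluorescence.

    Product obeys dP/dt = v(S0 − P, A) with P(0) = 0, where v is the
    mechanism's rate law; the reported signal is
    ``F = background + gain * phi * P`` plus seeded Gaussian noise.  The
    noiseless plateau is ``background + gain * phi * S0``.

    ``params=None`` simulates an enzyme-free control well: no catalysis,
    the noiseless signal stays at the background.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("times must be a 1-D vector of at least two points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if t[0] != 0.0:
        raise ValueError("times must start at 0")
    s0 = condition.S
    if s0 <= 0:
        raise ValueError("condition.S must be positive")

    if params is None:
        product = np.zeros_like(t)
    else:
        def dPdt(_t: float, y: np.ndarray) -> np.ndarray:
            s = min(max(s0 - y[0], 0.0), s0)
            return np.array([rate(params, s, condition.A)])

        sol = solve_ivp(
            dPdt,
            (0.0, float(t[-1])),
            np.array([0.0]),
            t_eval=t,
            method="LSODA",
            rtol=rtol,
            atol=s0 * 1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"progress-curve integration failed: {sol.message}")
        product = np.clip(sol.y[0], 0.0, s0)
    phi = design.dissociation_fraction
    signal = fluor.background + fluor.gain * phi * product
    if seed is not None and fluor.noise_sd > 0:
        rng = np.random.default_rng(seed)
        if fluor.noise_kind == "proportional":
            noise = rng.normal(0.0, fluor.noise_sd, size=t.size) * signal
        else:
            noise = rng.normal(0.0, fluor.noise_sd, size=t.size)
        signal = signal + noise
    return ProgressCurve(
        condition=condition,
        design=design,
        times=t,
        fluorescence=signal,
        seed=seed if fluor.noise_sd > 0 else None,
        product=product,
    )


def equilibrium_release_fraction(
    stem_bp: int,
    delta_g_per_bp: float,
    temperature: float = 295.15,
) -> float:
    """Two-state estimate of the released fraction phi for a given stem.

    Treats the cleaved FAM arm as a duplex of ``stem_bp`` base pairs with
    per-pair formation free energy ``delta_g_per_bp`` (J/mol; negative for
    a stabilizing pair)::

        phi = 1 / (1 + exp(-stem_bp * delta_g_per_bp / (R * T)))

    A stabilizing stem (negative free energy) retains product, so phi
    falls as the stem lengthens — the rationale for trimming the stem from
    five to three pairs.  This is a convenience default for
    ``BeaconDesign.dissociation_fraction``, not a fitted quantity.
    """
    if stem_bp < 1:
        raise ValueError("stem_bp must be a positive integer")
    if temperature <= 0:
        raise ValueError("temperature must be strictly positive (kelvin)")
    x = -stem_bp * delta_g_per_bp / (GAS_CONSTANT * temperature)
    return float(1.0 / (1.0 + np.exp(x)))
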