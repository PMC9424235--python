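"""Synthetic data generators emulating the bench study's designs.

Everything the rest of the package consumes can be generated here: initial
rates on substrate × activator grids, beacon progress curves, FAM
calibration standards and 1536-well screening plates.  All generators are
pure functions of their arguments including the seed, so identical calls
reproduce identical data bit for bit.

``fixtures()`` carries the two reference activator parameter sets the
study conditions are built around:

* 8-bromoguanine — Km 15 nM, kcat 0.009 s⁻¹, Ka 12 μM, α 1.2, β 36,
  at 10 nM enzyme, doses 0–20 μM;
* 9-deazaguanine — Km 12 nM, kcat 0.006 s⁻¹, Ka 333 μM, β 18, at 10 nM
  enzyme, doses 0–2500 μM.  Its α is taken as 1 (the interaction
  coefficient was reported near unity for the reference activator and not
  separately for this one); override the preset to explore other values.

The default substrate series is a two-fold dilution spanning the Michaelis
constant, 3.75–240 nM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .beacon import BeaconDesign, FluorescenceModel, ProgressCurve, simulate_progress
from .fitting import RateTable
from .rate_laws import ActivationParameters, AssayCondition, Mechanism, rate

__all__ = [
    "NoiseModel",
    "FixtureSet",
    "fixtures",
    "generate_rate_grid",
    "generate_progress_curves",
    "generate_fam_standards",
    "generate_screen_plate",
    "NM",
    "UM",
]

NM = 1e-9  # molar per nanomolar
UM = 1e-6  # molar per micromolar


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for generated data.

    ``kind`` is "additive" (sd in the data's own units) or "proportional"
    (sd as a fraction of the true value).  The same seed always reproduces
    the same dataset.
    """

    kind: str = "proportional"
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def apply(self, values: np.ndarray, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        if self.sd == 0:
            return np.asarray(values, dtype=float).copy()
        values = np.asarray(values, dtype=float)
        eps = rng.normal(0.0, self.sd, size=values.shape)
        if self.kind == "proportional":
            return values * (1.0 + eps)
        return values + eps


@dataclass(frozen=True)
class FixtureSet:
    """Reference parameter presets and dose grids for the two activators."""

    bromoguanine: ActivationParameters
    deazaguanine: ActivationParameters
    bromoguanine_doses: Tuple[float, ...]  # molar
    deazaguanine_doses: Tuple[float, ...]  # molar
    substrate_series: Tuple[float, ...]  # molar
    screening_positive_dose: float  # molar
    screening_compound_dose: float  # molar
    screening_substrate: float  # molar


def fixtures() -> FixtureSet:
    """Return the reference activator presets and study dose grids."""
    et = 10 * NM
    bromo = ActivationParameters(
        mechanism=Mechanism.RANDOM,
        Km=15 * NM,
        Ka=12 * UM,
        kcat=0.009,
        Et=et,
        alpha=1.2,
        beta=36.0,
    )
    deaza = ActivationParameters(
        mechanism=Mechanism.RANDOM,
        Km=12 * NM,
        Ka=333 * UM,
        kcat=0.006,
        Et=et,
        alpha=1.0,
        beta=18.0,
    )
    return FixtureSet(
        bromoguanine=bromo,
        deazaguanine=deaza,
        bromoguanine_doses=tuple(a * UM for a in (0.0, 0.63, 2.5, 5.0, 10.0, 20.0)),
        deazaguanine_doses=tuple(
            a * UM for a in (0.0, 39.0, 78.0, 156.0, 313.0, 625.0, 1250.0, 2500.0)
        ),
        substrate_series=tuple(s * NM for s in (3.75, 7.5, 15.0, 30.0, 60.0, 120.0, 240.0)),
        screening_positive_dose=500 * UM,
        screening_compound_dose=20 * UM,
        screening_substrate=100 * NM,
    )


def generate_rate_grid(
    params: ActivationParameters,
    S_list: Sequence[float],
    A_list: Sequence[float],
    noise: Optional[NoiseModel] = None,
    replicates: int = 2,
    activator_id: str = "",
) -> RateTable:
    """Initial rates on the full S × A grid under ``params``'s mechanism.

    Duplicate wells are the default replicate structure.  With a zero-sd
    (or absent) noise model the table equals the rate law exactly.
    """
    if len(S_list) == 0 or len(A_list) == 0:
        raise ValueError("S_list and A_list must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    Sg, Ag = np.meshgrid(np.asarray(S_list, float), np.asarray(A_list, float))
    S = np.tile(Sg.ravel(), replicates)
    A = np.tile(Ag.ravel(), replicates)
    v = rate(params, S, A)
    if noise is not None and noise.sd > 0:
        v = noise.apply(v)
    return RateTable.from_arrays(S, A, v, activator_id=activator_id, Et=params.Et)


def generate_progress_curves(
    params: ActivationParameters,
    conditions: Sequence[AssayCondition],
    times: Sequence[float],
    design: Optional[BeaconDesign] = None,
    fluor: Optional[FluorescenceModel] = None,
    seed: int = 0,
) -> list:
    """Beacon progress curves for a list of conditions, one sub-seed each."""
    design = design or BeaconDesign()
    fluor = fluor or FluorescenceModel()
    seeds = np.random.SeedSequence(seed).spawn(len(conditions))
    curves = []
    for i, (cond, ss) in enumerate(zip(conditions, seeds)):
        sub = int(ss.generate_state(1)[0] % (2**31))
        c = simulate_progress(params, cond, design, fluor, times, seed=sub)
        object.__setattr__(c, "well", f"W{i + 1:04d}")
        curves.append(c)
    return curves


def generate_fam_standards(
    concentrations: Sequence[float],
    gain: float = 1.0e9,
    background: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """FAM fluorophore standards: fluorescence = background + gain*conc + noise."""
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    fl = background + gain * conc + rng.normal(0.0, noise_sd, size=conc.shape)
    return pd.DataFrame({"concentration": conc, "fluorescence": fl})


def _default_active_sampler(rng: np.random.Generator) -> ActivationParameters:
    """Plausible activator parameter draw for a planted screening active."""
    ref = fixtures().bromoguanine
    beta = float(np.exp(rng.uniform(np.log(10.0), np.log(60.0))))
    Ka = float(np.exp(rng.uniform(np.log(1 * UM), np.log(30 * UM))))
    return ActivationParameters(
        mechanism=Mechanism.RANDOM,
        Km=ref.Km,
        Ka=Ka,
        kcat=ref.kcat,
        Et=ref.Et,
        alpha=1.0,
        beta=beta,
    )


def generate_screen_plate(
    n_compounds: int = 1408,
    hit_fraction: float = 0.01,
    active_params_sampler: Optional[
        Callable[[np.random.Generator], ActivationParameters]
    ] = None,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    n_basal: int = 64,
    n_positive: int = 64,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one screening plate of per-well initial rates.

    Wells are basal (no activator), positive control (reference activator
    at its saturating screening dose) and compounds at the screening dose.
    A ``hit_fraction`` of compounds are planted actives whose parameters
    come from ``active_params_sampler``; the rest are inert (basal rate).

    Returns ``(plate, truth)``: the assay frame (well, compound_id, role,
    rate in molar/second) and a ground-truth sidecar (compound_id,
    is_active, true beta/Ka) kept separate from the assay data.
    """
    if not 0.0 <= hit_fraction <= 1.0:
        raise ValueError("hit_fraction must be in [0, 1]")
    fx = fixtures()
    sampler = active_params_sampler or _default_active_sampler
    rng = np.random.default_rng(seed)
    S = fx.screening_substrate
    ref = fx.bromoguanine
    v_basal = rate(ref, S, 0.0)
    v_pos = rate(ref, S, fx.screening_positive_dose)

    rows = []
    for i in range(n_basal):
        rows.append(("basal", f"B{i + 1:03d}", "", v_basal))
    for i in range(n_positive):
        rows.append(("positive", f"P{i + 1:03d}", "8-bromoguanine", v_pos))
    n_active = int(round(hit_fraction * n_compounds))
    active_idx = set(rng.choice(n_compounds, size=n_active, replace=False).tolist())
    truth_rows = []
    for i in range(n_compounds):
        cid = f"C{i + 1:05d}"
        if i in active_idx:
            p = sampler(rng)
            v = rate(p, S, fx.screening_compound_dose)
            truth_rows.append((cid, True, p.beta, p.Ka))
        else:
            v = v_basal
            truth_rows.append((cid, False, np.nan, np.nan))
        rows.append(("compound", f"W{i + 1:05d}", cid, v))
    plate = pd.DataFrame(rows, columns=["role", "well", "compound_id", "rate"])
    # controls use compound_id for their label; compounds carry their id
    plate.loc[plate["role"] == "basal", "compound_id"] = "DMSO"
    plate.loc[plate["role"] == "positive", "compound_id"] = "8-bromoguanine"
    if noise is not None and noise.sd > 0:
        plate["rate"] = noise.apply(plate["rate"].to_numpy(), rng=rng)
    truth = pd.DataFrame(truth_rows, columns=["compound_id", "is_active", "beta", "Ka"])
    return plate, truth
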