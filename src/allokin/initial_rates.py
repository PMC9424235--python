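"""Initial-rate extraction from fluorescence progress curves.

Initial rates are computed from the linear phase of each progress curve
and converted to molar units with a FAM standard curve (a straight-line
calibration of fluorescence against fluorophore concentration).

The linear phase is detected with an expanding window anchored at t = 0:
the longest window whose straight-line fit has r² above a threshold and
whose quadratic term is statistically insignificant is kept.  If no window
qualifies, the earliest minimal window is used and the measurement is
flagged — never silently passed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .beacon import ProgressCurve
from .rate_laws import AssayCondition

__all__ = [
    "FamCalibration",
    "LinearPhasePolicy",
    "RateMeasurement",
    "calibrate_fam",
    "extract_initial_rate",
    "rates_from_curves",
]


@dataclass(frozen=True)
class FamCalibration:
    """Straight-line FAM standard curve: fluorescence = slope*conc + intercept."""

    slope: float  # fluorescence units per molar
    intercept: float  # fluorescence units
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    def to_concentration(self, fluorescence: np.ndarray) -> np.ndarray:
        """Invert the standard curve (molar)."""
        return (np.asarray(fluorescence, dtype=float) - self.intercept) / self.slope


def calibrate_fam(
    standards: Iterable[Tuple[float, float]]
) -> FamCalibration:
    """Ordinary-least-squares fit of the FAM standard curve.

    Parameters
    ----------
    standards : iterable of (concentration, fluorescence)
        At least two distinct concentrations (molar).
    """
    pts = np.asarray(list(standards), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("standards must be >= 2 (concentration, fluorescence) pairs")
    conc, fl = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("degenerate design: all standard concentrations identical")
    res = stats.linregress(conc, fl)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return FamCalibration(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)


@dataclass(frozen=True)
class LinearPhasePolicy:
    """Window-selection policy for the linear phase.

    ``r2_threshold`` is the minimum segment r²; ``curvature_p`` the
    significance level above which a fitted quadratic term is accepted as
    noise (i.e. the segment counts as linear); ``min_points`` the smallest
    admissible window.
    """

    min_points: int = 5
    r2_threshold: float = 0.995
    curvature_p: float = 0.05


@dataclass(frozen=True)
class RateMeasurement:
    """A molar initial rate with the window it came from and quality flags."""

    condition: AssayCondition
    rate: float  # molar / second, >= 0
    window: Tuple[float, float]
    r_squared_window: float
    flag: str = ""
    compound_id: str = ""
    well: str = ""

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative after background handling")
        if not self.window[1] > self.window[0]:
            raise ValueError("window end must exceed window start")


def _linfit(t: np.ndarray, f: np.ndarray) -> Tuple[float, float, float]:
    """Slope, intercept and r² of an OLS line; flat data count as perfect."""
    slope, intercept = np.polyfit(t, f, 1)
    resid = f - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    if ss_tot <= np.finfo(float).tiny * max(1.0, float(np.abs(f).max())):
        return float(slope), float(intercept), 1.0
    return float(slope), float(intercept), 1.0 - ss_res / ss_tot

def _curvature_insignificant(t: np.ndarray, f: np.ndarray, p_threshold: float) -> bool:
    """t-test on the quadratic coefficient of an OLS parabola fit."""
    n = t.size
    dof = n - 3
    if dof < 1:
        return True
    # center/scale time for conditioning
    ts = (t - t.mean()) / max(np.ptp(t) / 2.0, np.finfo(float).tiny)
    X = np.column_stack([np.ones(n), ts, ts**2])
    coef, _, _, _ = np.linalg.lstsq(X, f, rcond=None)
    resid = f - X @ coef
    s2 = float(resid @ resid) / dof
    scale = max(float(np.abs(f).max()), 1.0)
    if s2 <= (1e-10 * scale) ** 2:  # numerically perfect fit, no evidence of curvature
        return True
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(cov[2, 2])
    if se == 0:
        return True
    tval = abs(coef[2]) / se
    p = 2.0 * stats.t.sf(tval, dof)
    return p > p_threshold


def extract_initial_rate(
    curve: ProgressCurve,
    cal: FamCalibration,
    policy: Optional[LinearPhasePolicy] = None,
) -> RateMeasurement:
    """Extract the molar initial rate from one progress curve.

    The fluorescence slope over the detected linear window is divided by
    the calibration slope; the window's own intercept absorbs any
    background, so no separate blank subtraction is needed.  Negative
    slopes are clipped to zero and flagged.
    """
    policy = policy or LinearPhasePolicy()
    t, f = curve.times, curve.fluorescence
    if t.size < policy.min_points:
        raise ValueError(
            f"curve has {t.size} points; policy requires at least {policy.min_points}"
        )
    best_end = None
    best_fit: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    for end in range(policy.min_points, t.size + 1):
        tw, fw = t[:end], f[:end]
        slope, intercept, r2 = _linfit(tw, fw)
        if r2 >= policy.r2_threshold and _curvature_insignificant(
            tw, fw, policy.curvature_p
        ):
            best_end = end
            best_fit = (slope, intercept, r2)
    flag = ""
    if best_end is None:
        best_end = policy.min_points
        slope, intercept, r2 = _linfit(t[:best_end], f[:best_end])
        best_fit = (slope, intercept, r2)
        flag = "no_linear_window"
    slope, _, r2 = best_fit
    if slope < 0:
        flag = (flag + ";" if flag else "") + "negative_slope"
        slope = 0.0
    return RateMeasurement(
        condition=curve.condition,
        rate=slope / cal.slope,
        window=(float(t[0]), float(t[best_end - 1])),
        r_squared_window=float(r2),
        flag=flag,
        compound_id=curve.compound_id,
        well=curve.well,
    )


def rates_from_curves(
    curves: Sequence[ProgressCurve],
    cal: FamCalibration,
    policy: Optional[LinearPhasePolicy] = None,
    average_replicates: bool = True,
) -> pd.DataFrame:
    """Extract rates for many curves and optionally average replicate wells.

    Rates are extracted per well first and then averaged over wells
    sharing (compound_id, activator label, S, A); the per-condition
    standard deviation and replicate count are reported alongside.
    Returns a tidy frame with molar columns ``S``, ``A``, ``rate``.
    """
    rows = []
    for curve in curves:
        m = extract_initial_rate(curve, cal, policy)
        rows.append(
            {
                "well": m.well,
                "compound_id": m.compound_id,
                "activator_id": m.condition.activator_id,
                "S": m.condition.S,
                "A": m.condition.A,
                "rate": m.rate,
                "window_start": m.window[0],
                "window_end": m.window[1],
                "r2": m.r_squared_window,
                "flag": m.flag,
            }
        )
    df = pd.DataFrame(rows)
    if not average_replicates or df.empty:
        return df
    grouped = (
        df.groupby(["compound_id", "activator_id", "S", "A"], as_index=False)
        .agg(
            rate=("rate", "mean"),
            rate_sd=("rate", "std"),
            n_wells=("rate", "size"),
            r2=("r2", "min"),
            flag=("flag", lambda s: ";".join(sorted({x for x in s if x}))),
        )
    )
    return grouped
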