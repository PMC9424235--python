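"""Activator screening: percent-activation normalization, hit calling and
Hill dose-response fitting.

Each plate carries basal wells (enzyme + substrate, no activator),
positive-control wells (a reference activator at a saturating dose) and
compound wells.  Raw rates are normalized so the basal aggregate maps to
0 % and the positive-control aggregate to 100 %::

    percent = 100 * (v_sample - v_basal) / (v_positive - v_basal)

Compounds with activation strictly greater than the threshold (20 % by
default) are called hits.  Hits are then characterized by a four-parameter
Hill dose-response model::

    v([A]) = (Emax - B) / (1 + (EC50/[A])**n) + B

where Emax is the maximal activity, EC50 the half-maximally activating
concentration, n the Hill coefficient and B the background.  At
[A] = EC50 the model returns (Emax + B)/2 identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ControlFailureError",
    "ScreenRecord",
    "DoseResponseParameters",
    "percent_activation",
    "normalize_plate",
    "call_hits",
    "HillRegressor",
    "fit_hill",
    "hill_response",
]

HIT_THRESHOLD_PERCENT = 20.0


class ControlFailureError(ValueError):
    """Positive control did not exceed basal: the plate is rejected."""


@dataclass(frozen=True)
class ScreenRecord:
    """One compound's screening outcome."""

    compound_id: str
    raw_rate: float
    percent_activation: float
    is_hit: bool


@dataclass(frozen=True)
class DoseResponseParameters:
    """Hill-model estimates with asymptotic standard errors."""

    Emax: float
    EC50: float
    n: float
    B: float
    standard_errors: Dict[str, float]
    sse: float = 0.0
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.EC50 <= 0:
            raise ValueError("EC50 must be positive")
        if self.n <= 0:
            raise ValueError("Hill coefficient must be positive")
        if not self.Emax > self.B:
            raise ValueError("Emax must exceed the background B")


def percent_activation(v_sample, v_basal: float, v_positive: float):
    """Normalize a rate to percent of the positive-control window.

    The basal rate maps to 0 %, the positive control to 100 %.
    Vectorized over ``v_sample``.
    """
    if not v_positive > v_basal:
        raise ControlFailureError(
            f"positive control ({v_positive}) does not exceed basal ({v_basal}); "
            "plate rejected"
        )
    out = 100.0 * (np.asarray(v_sample, dtype=float) - v_basal) / (v_positive - v_basal)
    if out.ndim == 0:
        return float(out)
    return out


def normalize_plate(
    plate: pd.DataFrame,
    rate_col: str = "rate",
    role_col: str = "role",
) -> pd.DataFrame:
    """Add a ``percent_activation`` column to a per-well plate frame.

    ``role`` must be one of ``basal``, ``positive``, ``compound``.  Plate
    aggregates are the medians of the basal and positive wells (robust to
    single-well failures).  Raises :class:`ControlFailureError` when the
    positive-control median does not exceed the basal median.
    """
    roles = set(plate[role_col].unique())
    for needed in ("basal", "positive"):
        if needed not in roles:
            raise ValueError(f"plate has no {needed!r} wells")
    v_basal = float(plate.loc[plate[role_col] == "basal", rate_col].median())
    v_pos = float(plate.loc[plate[role_col] == "positive", rate_col].median())
    out = plate.copy()
    out["percent_activation"] = percent_activation(
        out[rate_col].to_numpy(dtype=float), v_basal, v_pos
    )
    return out


def call_hits(
    records: pd.DataFrame,
    threshold_percent: float = HIT_THRESHOLD_PERCENT,
    role_col: str = "role",
) -> pd.DataFrame:
    """Flag compounds whose activation is strictly above the threshold.

    The comparison is a strict ``>``: a compound at exactly the threshold
    is not a hit.  Control wells are never flagged.
    """
    out = records.copy()
    is_hit = out["percent_activation"].to_numpy(dtype=float) > threshold_percent
    if role_col in out.columns:
        is_hit &= (out[role_col] == "compound").to_numpy()
    out["is_hit"] = is_hit
    return out


def hill_response(A, Emax: float, EC50: float, n: float, B: float):
    """Four-parameter Hill dose-response curve."""
    A = np.asarray(A, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(A > 0, EC50 / np.maximum(A, np.finfo(float).tiny), np.inf)
    out = (Emax - B) / (1.0 + ratio**n) + B
    out = np.where(A > 0, out, B)
    if out.ndim == 0:
        return float(out)
    return out


class HillRegressor(RegressorMixin, BaseEstimator):
    """Least-squares fit of the Hill dose-response model.

    Parameters
    ----------
    n_bounds : tuple, default (0.3, 4.0)
        Bounds on the Hill coefficient.
    n_starts : int, default 8
        Multi-start budget; starts jitter a data-driven seed
        (B from the low-dose response, Emax from the plateau, EC50 from
        the half-effect dose, n = 1) log-uniformly within a factor of 3.
    random_state : int, optional
        Seed for the start jitter.

    Attributes
    ----------
    Emax_, EC50_, n_, B_ : float
        Point estimates (response units / dose units as given).
    standard_errors_ : dict
    sse_ : float
    low_confidence_ : bool
        Set when the dose range does not bracket the fitted EC50 or the
        Hill coefficient sits at a bound — the data show no inflection or
        no plateau, so the estimates are extrapolations.
    """

    def __init__(
        self,
        n_bounds: Sequence[float] = (0.3, 4.0),
        n_starts: int = 8,
        random_state: Optional[int] = None,
        max_nfev: int = 5000,
    ):
        self.n_bounds = n_bounds
        self.n_starts = n_starts
        self.random_state = random_state
        self.max_nfev = max_nfev

    def fit(self, X, y) -> "HillRegressor":
        """Fit to doses X (1-d or (n, 1), concentration) and responses y (%)."""
        A = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if A.size != y.size:
            raise ValueError("doses and responses must have equal length")
        if np.unique(A).size < 4:
            raise ValueError("need at least 4 distinct doses")
        if np.any(A < 0) or not np.all(np.isfinite(A)) or not np.all(np.isfinite(y)):
            raise ValueError("doses must be non-negative and all inputs finite")
        n_lo, n_hi = float(self.n_bounds[0]), float(self.n_bounds[1])

        # theta = [B, log(Emax - B), log(EC50), log(n)]
        def unpack(theta):
            B = theta[0]
            Emax = B + np.exp(theta[1])
            EC50 = np.exp(theta[2])
            n = np.exp(theta[3])
            return Emax, EC50, n, B

        def residuals(theta):
            Emax, EC50, n, B = unpack(theta)
            return hill_response(A, Emax, EC50, n, B) - y

        ymin, ymax = float(y.min()), float(y.max())
        span0 = max(ymax - ymin, 1e-6)
        pos = A > 0
        order = np.argsort(A[pos])
        A_pos, y_pos = A[pos][order], y[pos][order]
        mid = (ymin + ymax) / 2.0
        if y_pos.size and y_pos.max() > y_pos.min():
            EC50_0 = float(A_pos[np.argmin(np.abs(y_pos - mid))])
        else:
            EC50_0 = float(np.median(A_pos)) if y_pos.size else 1.0
        EC50_0 = EC50_0 if EC50_0 > 0 else float(np.median(A_pos))
        theta0 = np.array([ymin, np.log(span0), np.log(EC50_0), 0.0])
        lo = np.array([-np.inf, -np.inf, -np.inf, np.log(n_lo)])
        hi = np.array([np.inf, np.inf, np.inf, np.log(n_hi)])
        rng = np.random.default_rng(self.random_state)
        best, best_sse = None, np.inf
        for i in range(self.n_starts):
            th = theta0.copy()
            if i:
                th[1:] += rng.uniform(-np.log(3.0), np.log(3.0), size=3)
                th[0] += rng.normal(0.0, 0.1 * span0)
                th[3] = np.clip(th[3], lo[3], hi[3])
            try:
                res = optimize.least_squares(
                    residuals, th, bounds=(lo, hi), method="trf",
                    x_scale="jac", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                    max_nfev=self.max_nfev,
                )
            except Exception:
                continue
            sse = float(res.fun @ res.fun)
            if sse < best_sse:
                best, best_sse = res, sse
        if best is None:
            raise RuntimeError("Hill fit failed from every start")
        Emax, EC50, n, B = unpack(best.x)
        self.Emax_, self.EC50_, self.n_, self.B_ = (
            float(Emax), float(EC50), float(n), float(B),
        )
        self.sse_ = best_sse
        self.n_obs_ = y.size
        self.standard_errors_ = self._standard_errors(best, y.size)
        at_bound = n <= n_lo * (1 + 1e-6) or n >= n_hi * (1 - 1e-6)
        bracketed = (A_pos.size > 0) and (A_pos.min() <= EC50 <= A_pos.max())
        self.low_confidence_ = bool(at_bound or not bracketed)
        return self

    def _standard_errors(self, res, n_obs: int) -> Dict[str, float]:
        k = res.x.size
        if n_obs <= k or res.fun @ res.fun <= 0:
            return {nm: float("nan") for nm in ("Emax", "EC50", "n", "B")}
        s2 = float(res.fun @ res.fun) / (n_obs - k)
        try:
            cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        except np.linalg.LinAlgError:
            return {nm: float("nan") for nm in ("Emax", "EC50", "n", "B")}
        d = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        span = self.Emax_ - self.B_
        # delta method back to natural scale; Emax = B + exp(theta1)
        se_B = d[0]
        grad_Emax = np.array([1.0, span, 0.0, 0.0])
        se_Emax = float(np.sqrt(max(grad_Emax @ cov @ grad_Emax, 0.0)))
        return {
            "Emax": se_Emax,
            "EC50": float(self.EC50_ * d[2]),
            "n": float(self.n_ * d[3]),
            "B": float(se_B),
        }

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "Emax_")
        A = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray(hill_response(A, self.Emax_, self.EC50_, self.n_, self.B_))


def fit_hill(
    doses: Sequence[float],
    responses: Sequence[float],
    n_bounds: Sequence[float] = (0.3, 4.0),
    random_state: Optional[int] = 0,
) -> DoseResponseParameters:
    """Fit the Hill model and return its parameter set."""
    est = HillRegressor(n_bounds=n_bounds, random_state=random_state)
    est.fit(np.asarray(doses, dtype=float), np.asarray(responses, dtype=float))
    return DoseResponseParameters(
        Emax=est.Emax_,
        EC50=est.EC50_,
        n=est.n_,
        B=est.B_,
        standard_errors=est.standard_errors_,
        sse=est.sse_,
        low_confidence=est.low_confidence_,
    )
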