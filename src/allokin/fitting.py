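"""Global least-squares fitting of activation mechanisms to rate grids.

The fitting unit is a table of initial rates measured on a grid of
substrate and activator concentrations.  Each candidate binding scheme is
fit by multi-start nonlinear least squares on log-scale parameters
(positivity without active bounds), and candidates are ranked by the
small-sample corrected information criterion (AICc).  The nested pair —
the substrate-first scheme is the Ka → ∞ limit of the random scheme at
fixed alpha*Ka — is additionally compared with an extra-sum-of-squares
F-test.

Free parameters per mechanism:

* ``random`` — V, Km, Ka, alpha, beta
* ``ordered_substrate_first`` — V, Km, Ka, beta (no alpha in the law)
* ``ordered_activator_first`` — V, Km, Ka only: beta*V and alpha*Km enter
  the law only as products, so the fitted V and Km are those lumped
  effective constants and alpha = beta = 1 is reported.

A grid with fewer than two distinct substrate or activator concentrations
cannot separate the activation parameters and raises
:class:`IdentifiabilityError` naming the unresolvable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .rate_laws import ActivationParameters, Mechanism

__all__ = [
    "RateTable",
    "FitResult",
    "ModelComparison",
    "IdentifiabilityError",
    "GeneralModifierRegressor",
    "fit_mechanism",
    "predict_rates",
    "compare_mechanisms",
    "aicc",
]


class IdentifiabilityError(ValueError):
    """Raised when the design cannot resolve one or more parameters."""

    def __init__(self, parameters: Sequence[str], message: str):
        self.parameters = tuple(parameters)
        super().__init__(f"{message} (unresolvable: {', '.join(parameters)})")


@dataclass
class RateTable:
    """Initial rates on a substrate × activator grid (molar, molar/second).

    ``data`` must carry columns ``S``, ``A`` and ``rate``; replicate rows
    (repeated S, A) are allowed and enter the fit individually.
    """

    data: pd.DataFrame
    activator_id: str = ""
    Et: Optional[float] = None

    def __post_init__(self) -> None:
        missing = {"S", "A", "rate"} - set(self.data.columns)
        if missing:
            raise ValueError(f"rate table lacks columns: {sorted(missing)}")
        for col in ("S", "A", "rate"):
            vals = self.data[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite values in column {col!r}")
        if np.any(self.data["S"].to_numpy() < 0) or np.any(self.data["A"].to_numpy() < 0):
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def from_arrays(
        cls,
        S: Sequence[float],
        A: Sequence[float],
        rate: Sequence[float],
        activator_id: str = "",
        Et: Optional[float] = None,
    ) -> "RateTable":
        return cls(
            pd.DataFrame({"S": S, "A": A, "rate": rate}),
            activator_id=activator_id,
            Et=Et,
        )

    @property
    def S(self) -> np.ndarray:
        return self.data["S"].to_numpy(dtype=float)

    @property
    def A(self) -> np.ndarray:
        return self.data["A"].to_numpy(dtype=float)

    @property
    def rate(self) -> np.ndarray:
        return self.data["rate"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class FitResult:
    """One mechanism's least-squares fit: estimates, uncertainty, fit quality."""

    mechanism: Mechanism
    estimates: ActivationParameters
    standard_errors: Dict[str, float]
    sse: float
    n_obs: int
    n_params: int
    aicc: float
    converged: bool
    n_starts_used: int


@dataclass(frozen=True)
class ModelComparison:
    """Per-mechanism fits ranked by AICc, with a selection verdict.

    ``ambiguous`` is True when the best and runner-up are within 2 AICc
    units (statistically indistinguishable) or when the design itself
    cannot separate the candidates.  ``f_test`` reports the
    extra-sum-of-squares test for the nested substrate-first ⊂ random
    pair when both candidates were fit.
    """

    fits: Dict[str, FitResult]
    failures: Dict[str, str]
    selected: Optional[str]
    delta_aicc: Dict[str, float]
    ambiguous: bool
    f_test: Optional[Dict[str, float]] = None


_FREE_PARAMS: Dict[Mechanism, Tuple[str, ...]] = {
    Mechanism.RANDOM: ("V", "Km", "Ka", "alpha", "beta"),
    Mechanism.ORDERED_SUBSTRATE_FIRST: ("V", "Km", "Ka", "beta"),
    Mechanism.ORDERED_ACTIVATOR_FIRST: ("V", "Km", "Ka"),
}


def _model_rate(mechanism: Mechanism, p: np.ndarray, S: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Vectorized rate law on the raw free-parameter vector (natural scale)."""
    if mechanism is Mechanism.RANDOM:
        V, Km, Ka, alpha, beta = p
        aKa = alpha * Ka
        return V * S * (1.0 + beta * A / aKa) / (Km * (1.0 + A / Ka) + S * (1.0 + A / aKa))
    if mechanism is Mechanism.ORDERED_SUBSTRATE_FIRST:
        V, Km, Ka, beta = p
        return V * S * (1.0 + beta * A / Ka) / (Km + S * (1.0 + A / Ka))
    V, Km, Ka = p
    x = S * A / (Km * Ka)
    return V * x / (1.0 + A / Ka + x)


def aicc(sse: float, n_obs: int, n_params: int) -> float:
    """Corrected Akaike information criterion for a Gaussian least-squares fit.

    The error variance counts as a parameter, so k = n_params + 1.
    Returns +inf when n_obs <= k + 1 (correction undefined) or sse is 0
    to machine noise (log undefined; the model interpolates).
    """
    k = n_params + 1
    if n_obs <= k + 1:
        return float("inf")
    if sse <= 0:
        return float("-inf")
    return n_obs * float(np.log(sse / n_obs)) + 2 * k + 2 * k * (k + 1) / (n_obs - k - 1)


class GeneralModifierRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of an activation rate law to (S, A) rates.

    Parameters
    ----------
    mechanism : str, default "random"
        Binding scheme to fit: "random", "ordered_substrate_first" or
        "ordered_activator_first".
    n_starts : int, default 16
        Start budget for multi-start optimization.  Structured starts
        (basal Michaelis–Menten pre-fit for V and Km, half-effect of the
        activator profile for Ka, rate-ratio for beta, alpha = 1) are
        jittered log-uniformly within a factor of 3.  Starting stops early
        once the best SSE has been reproduced by a second start.
    starts : list of dict, optional
        Explicit starting parameter sets (natural scale, keyed by
        parameter name); overrides the structured strategy.
    weighting : {"none", "proportional"}, default "none"
        "proportional" divides residuals by the observed rates
        (floored at 1e-3 of their maximum).
    Et : float, optional
        Total enzyme concentration (molar); when given, kcat = V/Et is
        carried in the fitted parameters.
    random_state : int, optional
        Seed for the start jitter.

    Attributes
    ----------
    params_ : ActivationParameters
        Point estimates on the natural scale.
    standard_errors_ : dict
        Asymptotic standard errors (delta method from the log-scale
        covariance at the optimum, scaled by residual variance).
    sse_, aicc_, n_obs_, n_params_, converged_, n_starts_used_
    """

    def __init__(
        self,
        mechanism: str = "random",
        n_starts: int = 16,
        starts: Optional[List[Dict[str, float]]] = None,
        weighting: str = "none",
        Et: Optional[float] = None,
        random_state: Optional[int] = None,
        max_nfev: int = 5000,
    ):
        self.mechanism = mechanism
        self.n_starts = n_starts
        self.starts = starts
        self.weighting = weighting
        self.Et = Et
        self.random_state = random_state
        self.max_nfev = max_nfev

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "GeneralModifierRegressor":
        """Fit the rate law.  X is (n, 2) with columns (S, A) in molar;
        y the observed rates in molar/second."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of (S, A) concentrations")
        if y.shape != (X.shape[0],):
            raise ValueError("y must be a vector matching X")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite inputs")
        if np.any(X < 0):
            raise ValueError("concentrations must be non-negative")
        mech = Mechanism(self.mechanism)
        S, A = X[:, 0], X[:, 1]
        self._check_design(mech, S, A)
        names = _FREE_PARAMS[mech]
        k = len(names)

        if self.weighting == "proportional":
            floor = 1e-3 * max(float(np.abs(y).max()), np.finfo(float).tiny)
            w = 1.0 / np.maximum(np.abs(y), floor)
        elif self.weighting == "none":
            w = np.ones_like(y)
        else:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        # rates are ~1e-10 M/s; rescale residuals to O(1) so the optimizer's
        # absolute ftol/gtol thresholds are meaningful (same optimum)
        y_scale = max(float(np.abs(w * y).max()), np.finfo(float).tiny)
        w = w / y_scale

        def residuals(theta: np.ndarray) -> np.ndarray:
            return w * (_model_rate(mech, np.exp(theta), S, A) - y)

        starts = self._build_starts(mech, S, A, y)
        best = None
        best_sse = np.inf
        best_reproduced = 0
        n_used = 0
        for p0 in starts:
            n_used += 1
            theta0 = np.log(p0)
            try:
                res = optimize.least_squares(
                    residuals,
                    theta0,
                    method="trf",
                    x_scale="jac",
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                    max_nfev=self.max_nfev,
                )
            except Exception:  # singular steps from absurd jitters
                continue
            sse = float(res.fun @ res.fun)
            if sse < best_sse - 1e-12 * (1.0 + sse):
                best, best_sse = res, sse
                best_reproduced = 1
            elif abs(sse - best_sse) <= 1e-8 * (1.0 + sse):
                best_reproduced += 1
            if best_reproduced >= 2:
                break
        if best is None:
            raise RuntimeError("all optimization starts failed")

        p_hat = np.exp(best.x)
        sse_scaled = float(best.fun @ best.fun)
        sse = sse_scaled * y_scale**2  # back to (molar/second)^2
        n = y.size
        self._finalize(mech, names, p_hat, best, sse, sse_scaled, n, n_used)
        return self

    # ------------------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Predicted rates (molar/second) at the (S, A) rows of X."""
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        mech = Mechanism(self.mechanism)
        p = np.array([getattr(self.params_, nm) for nm in _FREE_PARAMS[mech]])
        return _model_rate(mech, p, X[:, 0], X[:, 1])

    # ------------------------------------------------------------------
    @staticmethod
    def _check_design(mech: Mechanism, S: np.ndarray, A: np.ndarray) -> None:
        bad: List[str] = []
        if np.unique(S[S >= 0]).size < 2:
            bad.append("Km")
        if np.unique(A).size < 2:
            bad.extend([nm for nm in _FREE_PARAMS[mech] if nm in ("Ka", "alpha", "beta")])
        if bad:
            raise IdentifiabilityError(
                bad,
                "the design needs at least two distinct substrate and two "
                "distinct activator concentrations",
            )

    def _build_starts(
        self, mech: Mechanism, S: np.ndarray, A: np.ndarray, y: np.ndarray
    ) -> List[np.ndarray]:
        names = _FREE_PARAMS[mech]
        if self.starts is not None:
            out = []
            for d in self.starts:
                missing = set(names) - set(d)
                if missing:
                    raise ValueError(f"start lacks parameters {sorted(missing)}")
                out.append(np.array([float(d[nm]) for nm in names]))
            return out

        tiny = np.finfo(float).tiny
        basal = A == 0
        if basal.any() and np.any(y[basal] > 0):
            yb, Sb = y[basal], S[basal]
            V0 = 1.05 * float(yb.max())
            order = np.argsort(Sb)
            half = V0 / 2.0
            Km0 = float(np.interp(half, yb[order], Sb[order])) if yb.max() > half else float(
                np.median(Sb[Sb > 0])
            )
            Km0 = Km0 if Km0 > 0 else float(np.median(S[S > 0]))
        else:
            V0 = float(y.max()) / 2.0 + tiny
            Km0 = float(np.median(S[S > 0])) if np.any(S > 0) else 1.0
        # activator profile at the highest substrate concentration
        Smax = S.max()
        prof_mask = S == Smax
        Ap, yp = A[prof_mask], y[prof_mask]
        order = np.argsort(Ap)
        Ap, yp = Ap[order], yp[order]
        if np.unique(Ap).size >= 2 and yp.max() > yp.min():
            mid = (yp.max() + yp.min()) / 2.0
            idx = int(np.argmin(np.abs(yp - mid)))
            Ka0 = float(Ap[idx]) if Ap[idx] > 0 else float(np.median(A[A > 0]))
        else:
            Ka0 = float(np.median(A[A > 0])) if np.any(A > 0) else 1.0
        if basal.any() and np.any(y[basal] > 0):
            beta0 = max(float(y.max()) / max(float(y[basal].max()), tiny), 1.5)
        else:
            beta0 = 10.0
        base = {"V": V0, "Km": Km0, "Ka": Ka0, "alpha": 1.0, "beta": beta0}
        if mech is Mechanism.ORDERED_ACTIVATOR_FIRST:
            base["V"] = float(y.max()) + tiny
        p_base = np.array([max(base[nm], tiny) for nm in names])
        starts = [p_base]
        rng = np.random.default_rng(self.random_state)
        for _ in range(max(self.n_starts - 1, 0)):
            jitter = np.exp(rng.uniform(-np.log(3.0), np.log(3.0), size=p_base.size))
            starts.append(p_base * jitter)
        return starts

    def _finalize(
        self,
        mech: Mechanism,
        names: Tuple[str, ...],
        p_hat: np.ndarray,
        res,
        sse: float,
        sse_scaled: float,
        n: int,
        n_used: int,
    ) -> None:
        k = len(names)
        J = res.jac  # in rescaled-residual units, matching sse_scaled
        sv = np.linalg.svd(J, compute_uv=False)
        if sv.size and sv[0] > 0 and sv[-1] / sv[0] < 1e-12:
            _, _, Vt = np.linalg.svd(J)
            null_vec = np.abs(Vt[-1])
            bad = [names[i] for i in np.where(null_vec > 0.3)[0]] or list(names)
            raise IdentifiabilityError(bad, "rank-deficient Jacobian at the optimum")
        ses: Dict[str, float] = {}
        if n > k and sse > 0:
            s2 = sse_scaled / (n - k)
            try:
                cov_log = s2 * np.linalg.inv(J.T @ J)
                se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, np.inf))
                ses = {nm: float(p_hat[i] * se_log[i]) for i, nm in enumerate(names)}
            except np.linalg.LinAlgError:
                ses = {nm: float("nan") for nm in names}
        else:
            ses = {nm: float("nan") for nm in names}

        vals = dict(zip(names, (float(v) for v in p_hat)))
        kw = dict(V=vals["V"], Km=vals["Km"], Ka=vals["Ka"])
        if mech is Mechanism.RANDOM:
            kw.update(alpha=vals["alpha"], beta=vals["beta"])
        elif mech is Mechanism.ORDERED_SUBSTRATE_FIRST:
            kw.update(beta=vals["beta"])
        else:  # lumped effective constants; see module docstring
            kw.update(alpha=1.0, beta=1.0)
        if self.Et is not None and self.Et > 0:
            kw.update(Et=float(self.Et), kcat=kw["V"] / float(self.Et))
        self.params_ = ActivationParameters(mechanism=mech, **kw)
        if "kcat" in kw:
            ses["kcat"] = ses.get("V", float("nan")) / float(self.Et)
        self.standard_errors_ = ses
        self.sse_ = sse
        self.n_obs_ = n
        self.n_params_ = k
        self.aicc_ = aicc(sse, n, k)
        self.converged_ = bool(res.status > 0)
        self.n_starts_used_ = n_used


# ----------------------------------------------------------------------
# functional wrappers over the estimator


def fit_mechanism(
    table: RateTable,
    mechanism: Union[str, Mechanism],
    starts: Optional[List[Dict[str, float]]] = None,
    n_starts: int = 16,
    weighting: str = "none",
    random_state: Optional[int] = 0,
) -> FitResult:
    """Fit one mechanism's rate law to a rate table by multi-start least squares."""
    mech = Mechanism(mechanism)
    est = GeneralModifierRegressor(
        mechanism=mech.value,
        n_starts=n_starts,
        starts=starts,
        weighting=weighting,
        Et=table.Et,
        random_state=random_state,
    )
    X = np.column_stack([table.S, table.A])
    est.fit(X, table.rate)
    return FitResult(
        mechanism=mech,
        estimates=est.params_,
        standard_errors=est.standard_errors_,
        sse=est.sse_,
        n_obs=est.n_obs_,
        n_params=est.n_params_,
        aicc=est.aicc_,
        converged=est.converged_,
        n_starts_used=est.n_starts_used_,
    )


def predict_rates(
    params: ActivationParameters, grid: Iterable[Tuple[float, float]]
) -> RateTable:
    """Evaluate a mechanism's rate law on a list of (S, A) pairs."""
    from .rate_laws import rate as _rate

    pts = np.asarray(list(grid), dtype=float)
    v = _rate(params, pts[:, 0], pts[:, 1])
    return RateTable.from_arrays(pts[:, 0], pts[:, 1], np.atleast_1d(v), Et=params.Et)


def compare_mechanisms(
    table: RateTable,
    candidates: Sequence[Union[str, Mechanism]] = (
        Mechanism.RANDOM,
        Mechanism.ORDERED_SUBSTRATE_FIRST,
    ),
    n_starts: int = 16,
    weighting: str = "none",
    random_state: Optional[int] = 0,
) -> ModelComparison:
    """Fit every candidate mechanism and rank by AICc.

    Individual fit failures are recorded, not fatal; only total failure
    raises.  The nested pair (substrate-first as the Ka → ∞ boundary of
    random) also gets an extra-sum-of-squares F-test when both converge.
    """
    cands = [Mechanism(c) for c in candidates]
    if len(cands) < 2:
        raise ValueError("need at least two candidate mechanisms")
    fits: Dict[str, FitResult] = {}
    failures: Dict[str, str] = {}
    for mech in cands:
        try:
            fits[mech.value] = fit_mechanism(
                table, mech, n_starts=n_starts, weighting=weighting,
                random_state=random_state,
            )
        except Exception as exc:  # recorded, not fatal
            failures[mech.value] = f"{type(exc).__name__}: {exc}"
    degenerate = (
        np.unique(table.A).size < 2 or np.unique(table.S).size < 2
    )
    if not fits:
        if degenerate:
            return ModelComparison(
                fits={}, failures=failures, selected=None,
                delta_aicc={}, ambiguous=True,
            )
        raise RuntimeError(f"every candidate fit failed: {failures}")
    best_aicc = min(f.aicc for f in fits.values())
    delta = {name: f.aicc - best_aicc for name, f in fits.items()}
    selected = min(fits, key=lambda nm: fits[nm].aicc)
    runner_up = sorted(d for nm, d in delta.items() if nm != selected)
    ambiguous = degenerate or bool(failures) and len(fits) < 2
    if runner_up:
        ambiguous = ambiguous or runner_up[0] < 2.0
    f_test = None
    r, o = Mechanism.RANDOM.value, Mechanism.ORDERED_SUBSTRATE_FIRST.value
    if r in fits and o in fits:
        full, reduced = fits[r], fits[o]
        df1 = full.n_params - reduced.n_params
        df2 = full.n_obs - full.n_params
        if df1 > 0 and df2 > 0 and full.sse > 0:
            F = ((reduced.sse - full.sse) / df1) / (full.sse / df2)
            F = max(F, 0.0)
            f_test = {
                "F": float(F),
                "df1": float(df1),
                "df2": float(df2),
                "p_value": float(stats.f.sf(F, df1, df2)),
            }
    return ModelComparison(
        fits=fits,
        failures=failures,
        selected=selected,
        delta_aicc=delta,
        ambiguous=bool(ambiguous),
        f_test=f_test,
    )
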