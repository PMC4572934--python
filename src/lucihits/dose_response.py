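"""Four-parameter logistic (4PL) dose-response fitting.

The 4PL model is ``response = bottom + (top - bottom) / (1 + (ec50/conc)^hill)``:
``bottom``/``top`` are the lower/upper response asymptotes, ``ec50`` the
concentration of half-maximal response, and ``hill`` the slope. Positive
hill rises with concentration (activation curves, e.g. coactivator
recruitment); negative hill falls (inhibition curves), and the fitted
midpoint of an inhibition curve is the IC50. Least squares on
log-concentration is multimodal, so fits are multi-start over a grid of
hill signs/magnitudes and midpoint guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .synthetic_screen import four_pl

__all__ = [
    "DoseResponseCurve",
    "FourPLFit",
    "FourPLRegressor",
    "fit_4pl",
    "relative_efficacy",
    "bootstrap_ci",
]

ORIENTATIONS = ("ACTIVATION", "INHIBITION")


@dataclass
class DoseResponseCurve:
    """Replicate dose-response measurements for one compound."""

    compound_id: str
    points: pd.DataFrame  # columns: concentration_M, response, replicate
    orientation: str = "ACTIVATION"

    def __post_init__(self):
        self.orientation = self.orientation.upper()
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        conc = self.points["concentration_M"].to_numpy(dtype=float)
        if (conc <= 0).any():
            raise ValueError("concentrations must be > 0")

    @property
    def n_distinct_concentrations(self) -> int:
        return self.points["concentration_M"].nunique()


@dataclass
class FourPLFit:
    """Fitted 4PL parameters; canonicalized so that ``top >= bottom``.

    ``ec50`` is flagged ``extrapolated`` when it falls more than one
    log-unit outside the fitted concentration range. ``ci_ec50`` is an
    optional bootstrap percentile interval.
    """

    bottom: float
    top: float
    hill: float
    ec50: float
    sse: float
    converged: bool
    extrapolated: bool = False
    ci_ec50: tuple[float, float] | None = None
    compound_id: str = ""

    @property
    def span(self) -> float:
        return self.top - self.bottom

    def predict(self, conc) -> np.ndarray:
        return four_pl(conc, self.bottom, self.top, self.hill, self.ec50)


def _initial_grid(logc: np.ndarray, y: np.ndarray, bottom_min):
    """Multi-start initial points: hill in {+-0.5, +-1, +-2}, log-ec50 at
    the data quartiles."""
    lo, hi = float(y.min()), float(y.max())
    if bottom_min is not None:
        lo = max(lo, bottom_min)
        hi = max(hi, lo + max(1e-9, abs(hi)))
    q = np.quantile(logc, [0.25, 0.5, 0.75])
    starts = []
    for hill in (0.5, -0.5, 1.0, -1.0, 2.0, -2.0):
        for le in q:
            starts.append(np.array([lo, hi, hill, le]))
    return starts


class FourPLRegressor(RegressorMixin, BaseEstimator):
    """Least-squares 4PL dose-response fit as an estimator.

    Parameters
    ----------
    orientation : {"activation", "inhibition"}, default "activation"
        Expected curve direction. Handled by the sign of the fitted hill
        slope, never by reflecting the data; the reported midpoint of an
        inhibition fit is the IC50.
    bottom_min : float or None, default 0.0
        Lower bound on the bottom asymptote; 0 is appropriate for
        luminescence readouts. ``None`` removes the constraint.
    max_nfev : int, default 2000
        Per-start function-evaluation budget.

    Attributes
    ----------
    bottom_, top_, hill_, ec50_ : float
        Canonical parameters (``top_ >= bottom_``; orientation lives in
        the sign of ``hill_``).
    sse_ : float
        Residual sum of squares at the optimum.
    converged_ : bool
        Whether any start converged; on failure the best attempt is kept.
    extrapolated_ : bool
        True when ec50 lies more than one log-unit outside the data range.

    Notes
    -----
    The model is fit on log10(concentration): with ``le = log10(ec50)``,
    ``response = bottom + (top - bottom) / (1 + 10^(hill (le - log10 c)))``,
    algebraically identical to the concentration-space form. The
    reparameterization ``(b, t, h, e) == (t, b, -h, e)`` makes the
    parameter pair orderings equivalent; fits are canonicalized to
    ``top >= bottom`` afterwards. The fit is deterministic given the data.
    """

    def __init__(self, orientation: str = "activation",
                 bottom_min: float | None = 0.0, max_nfev: int = 2000):
        self.orientation = orientation
        self.bottom_min = bottom_min
        self.max_nfev = max_nfev

    @staticmethod
    def _model(params: np.ndarray, logc: np.ndarray) -> np.ndarray:
        b, t, h, le = params
        return b + (t - b) / (1.0 + 10.0 ** (h * (le - logc)))

    def fit(self, X, y) -> "FourPLRegressor":
        conc = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if conc.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if (conc <= 0).any():
            raise ValueError("concentrations must be > 0")
        if np.unique(conc).size < 4:
            raise ValueError("need >= 4 distinct concentrations for a 4PL fit")
        logc = np.log10(conc)

        bmin = -np.inf if self.bottom_min is None else self.bottom_min
        # ec50 may wander one log-unit past the data before being flagged
        lo = np.array([bmin, bmin, -10.0, logc.min() - 3.0])
        hi = np.array([np.inf, np.inf, 10.0, logc.max() + 3.0])

        best, best_cost = None, np.inf
        converged = False
        for x0 in _initial_grid(logc, y, self.bottom_min):
            x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
            try:
                res = least_squares(
                    lambda p: self._model(p, logc) - y,
                    x0, bounds=(lo, hi), max_nfev=self.max_nfev,
                    ftol=1e-14, xtol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            if res.cost < best_cost:
                best, best_cost = res, res.cost
                converged = converged or res.success
        if best is None:
            raise RuntimeError("4PL optimization failed from every start")

        b, t, h, le = best.x
        if t < b:  # canonical form: top above bottom, direction in hill sign
            b, t, h = t, b, -h
        self.bottom_, self.top_, self.hill_ = float(b), float(t), float(h)
        self.ec50_ = float(10.0**le)
        self.sse_ = float(2.0 * best.cost)
        self.converged_ = bool(converged)
        self.extrapolated_ = not (
            logc.min() - 1.0 <= le <= logc.max() + 1.0
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        conc = np.asarray(X, dtype=float).reshape(-1)
        return four_pl(conc, self.bottom_, self.top_, self.hill_, self.ec50_)

    def to_fit(self, compound_id: str = "") -> FourPLFit:
        return FourPLFit(
            bottom=self.bottom_,
            top=self.top_,
            hill=self.hill_,
            ec50=self.ec50_,
            sse=self.sse_,
            converged=self.converged_,
            extrapolated=self.extrapolated_,
            compound_id=compound_id,
        )


def fit_4pl(curve: DoseResponseCurve, bottom_min: float | None = 0.0) -> FourPLFit:
    """Fit a 4PL model to a dose-response curve.

    Multi-start deterministic least squares; see :class:`FourPLRegressor`.
    """
    if curve.n_distinct_concentrations < 4:
        raise ValueError(
            f"{curve.compound_id}: {curve.n_distinct_concentrations} distinct "
            "concentrations is too few for a 4PL fit (need >= 4)"
        )
    reg = FourPLRegressor(orientation=curve.orientation, bottom_min=bottom_min)
    reg.fit(curve.points["concentration_M"], curve.points["response"])
    return reg.to_fit(curve.compound_id)


def relative_efficacy(fit: FourPLFit, reference: FourPLFit) -> float:
    """Fitted response span as a percentage of a reference compound's span.

    ``100 (fit.top - fit.bottom) / (reference.top - reference.bottom)`` --
    e.g. a partial agonist's recruitment span relative to a full agonist.
    """
    if not (fit.converged and reference.converged):
        raise ValueError("both fits must have converged")
    if reference.span <= 0:
        raise ValueError("reference span must be > 0")
    return 100.0 * fit.span / reference.span


def bootstrap_ci(curve: DoseResponseCurve, n_boot: int = 200, seed: int = 0,
                 level: float = 0.95,
                 bottom_min: float | None = 0.0) -> tuple[float, float] | None:
    """Case-resampling bootstrap percentile interval for the fitted ec50.

    Resamples the (concentration, response) points with replacement,
    refits, and returns the percentile interval of the resampled ec50s;
    ``n_boot = 0`` returns ``None``. Resamples with fewer than 4 distinct
    concentrations are redrawn.
    """
    if n_boot == 0:
        return None
    rng = np.random.default_rng(seed)
    pts = curve.points.reset_index(drop=True)
    n = len(pts)
    ec50s = []
    attempts = 0
    while len(ec50s) < n_boot and attempts < 20 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, n)
        sample = pts.iloc[idx]
        if sample["concentration_M"].nunique() < 4:
            continue
        try:
            reg = FourPLRegressor(orientation=curve.orientation,
                                  bottom_min=bottom_min)
            reg.fit(sample["concentration_M"], sample["response"])
        except Exception:
            continue
        ec50s.append(reg.ec50_)
    if len(ec50s) < n_boot:
        raise RuntimeError("bootstrap failed to accumulate enough refits")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(ec50s, [a, 1.0 - a])
    return float(lo), float(hi)
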