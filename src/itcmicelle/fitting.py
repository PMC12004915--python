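"""Sigmoid fit of the enthalpogram and CMC / ΔH extraction.

The enthalpogram of a demicellization titration is fitted with a
six-parameter Boltzmann sigmoid bridging two linear baselines,

    q(C) = (a3 + a4·C) + [(a1 + a2·C) − (a3 + a4·C)] / (1 + exp((C − a5)/a6))

where a1, a2 describe the pre-transition baseline (cell below the CMC,
injected micelles dissolve), a3, a4 the post-transition baseline, a5 the
transition centre and a6 > 0 its width.  The CMC is the concentration at
which |dq/dC| is largest within the data range, and the demicellization
enthalpy is the gap between the two baselines evaluated at the CMC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from lmfit import Parameters, minimize
from scipy.optimize import minimize_scalar

from .containers import Enthalpogram

__all__ = ["SigmoidFit", "FitError", "NoTransitionError", "eval_sigmoid",
           "sigmoid_derivative", "fit_sigmoid", "cmc_from_fit", "dh_from_fit"]

PARAM_NAMES = ("a1", "a2", "a3", "a4", "a5", "a6")


class FitError(RuntimeError):
    """Fit did not converge after multi-start."""


class NoTransitionError(FitError):
    """Data carry no resolvable sigmoidal transition."""


class FitWarning(UserWarning):
    pass


def eval_sigmoid(params: Sequence[float], conc) -> np.ndarray:
    """Evaluate the two-baseline Boltzmann sigmoid at ``conc``."""
    a1, a2, a3, a4, a5, a6 = params
    if not a6 > 0:
        raise ValueError("transition width a6 must be positive")
    c = np.asarray(conc, dtype=float)
    u = np.clip((c - a5) / a6, -500.0, 500.0)
    pre = a1 + a2 * c
    post = a3 + a4 * c
    out = post + (pre - post) / (1.0 + np.exp(u))
    return out if out.shape else float(out)


def sigmoid_derivative(params: Sequence[float], conc) -> np.ndarray:
    """Analytic dq/dC of the sigmoid."""
    a1, a2, a3, a4, a5, a6 = params
    c = np.asarray(conc, dtype=float)
    u = np.clip((c - a5) / a6, -500.0, 500.0)
    e = np.exp(u)
    sig = 1.0 / (1.0 + e)
    gap = (a1 + a2 * c) - (a3 + a4 * c)
    out = a4 + (a2 - a4) * sig - gap * e * sig ** 2 / a6
    return out if out.shape else float(out)


@dataclass
class SigmoidFit:
    """Result of fitting the six-parameter sigmoid to an enthalpogram."""

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float
    covariance: Optional[np.ndarray]
    rss: float
    converged: bool
    conc_range: Tuple[float, float]
    cmc: float = np.nan
    dh_demic: float = np.nan
    boundary_extremum: bool = False
    n_points: int = 0

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.a4,
                         self.a5, self.a6])

    def __call__(self, conc):
        return eval_sigmoid(self.params, conc)

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v)
                       for k, v in zip(PARAM_NAMES, self.params)},
            "covariance": None if self.covariance is None
            else self.covariance.tolist(),
            "rss": float(self.rss),
            "converged": bool(self.converged),
            "cmc_mol_per_L": float(self.cmc),
            "dH_demic_J_per_mol": float(self.dh_demic),
            "boundary_extremum": bool(self.boundary_extremum),
            "conc_range_mol_per_L": [float(x) for x in self.conc_range],
            "n_points": int(self.n_points),
        }


def _initial_guess(c: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Steepest-slope centre, 10%-span width, end-segment baselines."""
    span = c[-1] - c[0]
    dq = np.gradient(q, c)
    a5 = c[int(np.argmax(np.abs(dq)))]
    a6 = 0.1 * span
    k = max(2, len(c) // 4)
    pre = np.polyfit(c[:k], q[:k], 1)
    post = np.polyfit(c[-k:], q[-k:], 1)
    return np.array([pre[1], pre[0], post[1], post[0], a5, a6])


def _check_transition(c: np.ndarray, q: np.ndarray) -> None:
    steps = np.abs(np.diff(q))
    med = float(np.median(steps))
    swing = float(np.ptp(q))
    if swing == 0.0 or (med > 0 and swing <= 3.0 * med):
        raise NoTransitionError(
            "no transition detected: heat range does not exceed 3x the "
            "median successive difference")


def fit_sigmoid(e: Enthalpogram, *, n_starts: int = 5, jitter_seed: int = 0,
                bounds: Optional[dict] = None,
                weights: Optional[np.ndarray] = None) -> SigmoidFit:
    """Least-squares fit of the two-baseline sigmoid.

    Unit weights by default.  The fit is restarted from ``n_starts``
    deterministically jittered initializations (seeded by
    ``jitter_seed``) and the lowest-RSS converged solution is kept; a
    :class:`FitError` carrying the best diagnostics is raised if none
    converges.  Bounds keep a5 within the data range and a6 in (0, span]
    to exclude degenerate step or flat solutions.
    """
    c = e.concentrations
    q = e.heats
    if len(c) < 8:
        raise FitError(f"need at least 8 points, got {len(c)}")
    _check_transition(c, q)
    span = c[-1] - c[0]
    p0 = _initial_guess(c, q)
    w = np.ones_like(q) if weights is None else np.asarray(weights, float)

    lo = {"a5": c[0], "a6": 1e-6 * span}
    hi = {"a5": c[-1], "a6": span}
    if bounds:
        for k, (a, b) in bounds.items():
            lo[k], hi[k] = a, b

    def residual(params):
        p = [params[k].value for k in PARAM_NAMES]
        return (eval_sigmoid(p, c) - q) * w

    rng = np.random.default_rng(int(jitter_seed))
    best = None
    q_scale = max(np.ptp(q), 1.0)
    for start in range(max(1, n_starts)):
        init = p0.copy()
        if start > 0:  # deterministic multiplicative/additive jitter
            init[:4] = init[:4] + rng.normal(0, 0.1, 4) * q_scale * 0.1
            init[4] = np.clip(init[4] * (1 + 0.3 * rng.standard_normal()),
                              c[0], c[-1])
            init[5] = np.clip(init[5] * 10 ** rng.uniform(-1, 0.5),
                              lo["a6"], hi["a6"])
        params = Parameters()
        for name, val in zip(PARAM_NAMES, init):
            params.add(name, value=float(val),
                       min=lo.get(name, -np.inf), max=hi.get(name, np.inf))
        try:
            # errstate: lmfit's correlation post-processing divides by zero
            # stderr for parameters pinned at a bound
            with np.errstate(invalid="ignore", divide="ignore"):
                res = minimize(residual, params, method="least_squares",
                               xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        rss = float(np.sum(np.asarray(res.residual) ** 2))
        if best is None or rss < best[0]:
            best = (rss, res)

    if best is None:
        raise FitError("all fit starts failed")
    rss, res = best
    pvals = np.array([res.params[k].value for k in PARAM_NAMES])
    converged = bool(res.success)
    if not converged:
        raise FitError(
            f"sigmoid fit did not converge after {n_starts} starts "
            f"(best rss={rss:.3g}, params={dict(zip(PARAM_NAMES, pvals))})")
    covar = getattr(res, "covar", None)
    fit = SigmoidFit(*pvals, covariance=None if covar is None
                     else np.asarray(covar),
                     rss=rss, converged=converged,
                     conc_range=(float(c[0]), float(c[-1])),
                     n_points=len(c))
    fit.cmc = cmc_from_fit(fit)
    fit.dh_demic = dh_from_fit(fit)
    return fit


def cmc_from_fit(fit: SigmoidFit, grid_size: int = 4096) -> float:
    """CMC as the extremum of |dq/dC| within the fitted range.

    The analytic derivative is scanned on a dense grid (tie-break: the
    largest |dq/dC| wins when sloping baselines create two local
    extrema) and polished with a bounded scalar optimisation.  An
    extremum sitting at the data boundary sets ``boundary_extremum``
    (transition not bracketed) with a warning.
    """
    if not fit.converged:
        raise FitError("cmc_from_fit requires a converged fit")
    c0, c1 = fit.conc_range
    grid = np.linspace(c0, c1, grid_size)
    mag = np.abs(sigmoid_derivative(fit.params, grid))
    i = int(np.argmax(mag))
    if i in (0, grid_size - 1):
        fit.boundary_extremum = True
        warnings.warn("derivative extremum at the data boundary; the "
                      "transition is not bracketed", FitWarning)
        return float(grid[i])
    lo, hi = grid[i - 1], grid[i + 1]
    res = minimize_scalar(
        lambda c: -abs(sigmoid_derivative(fit.params, c)),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12 * max(abs(c1), 1e-30)})
    return float(res.x)


def dh_from_fit(fit: SigmoidFit) -> float:
    """Demicellization enthalpy: baseline gap at the CMC.

    (a1 + a2·CMC) − (a3 + a4·CMC); pre-transition minus post-transition
    line.  The micellization enthalpy is the negative of this value.
    """
    if not fit.converged:
        raise FitError("dh_from_fit requires a converged fit")
    cmc = fit.cmc if np.isfinite(fit.cmc) else cmc_from_fit(fit)
    return float((fit.a1 + fit.a2 * cmc) - (fit.a3 + fit.a4 * cmc))
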