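"""Length-dependent catch comparison rate: polynomial-logit models and AIC selection.

The catch comparison rate at length *l* is the probability that a fish caught
by either trawl ends up in the experimental (large-mesh panel) codend:

    rate(l) = exp(f(l)) / (1 + exp(f(l))),   f(l) = sum_i q_i * l^i

with the polynomial order up to 4.  Every subset of the coefficients
{q0..q4} — including the empty one, which pins the curve at the no-effect
value 0.5 — defines a candidate model, giving a family of 32.  Each candidate
is fitted by maximising the binomial log-likelihood of codend membership,
pooled over hauls, and the candidate with the lowest AIC wins.

Lengths are rescaled by 1/100 before polynomial evaluation to condition the
fit (l^4 at l ~ 112 is numerically hostile); reported coefficients are on the
original length scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .io import HaulRecord, SpeciesDataset, pool_hauls

__all__ = [
    "FitError",
    "RateModel",
    "FitStatistics",
    "observed_rate",
    "rate_eval",
    "negloglik",
    "fit_rate_model",
    "select_rate_model",
    "rate_model_candidates",
    "fit_statistics",
    "make_rate_selector",
]

LENGTH_SCALE = 100.0
#: |linear predictor| beyond which a fit is flagged as separated/degenerate
_ETA_BOUNDARY = 15.0


class FitError(RuntimeError):
    """A model fit failed or is unusable for selection."""


@dataclass
class RateModel:
    """A fitted polynomial-logit catch comparison curve.

    ``coefficients`` holds q_i on the original length scale; internally the
    model keeps the rescaled coefficients used for stable evaluation.
    """

    active_terms: tuple[int, ...]
    coefficients: dict[int, float]
    loglik: float
    aic: float
    window: tuple[float, float] | None = None
    degenerate: bool = False
    scaled_coefficients: dict[int, float] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.active_terms)

    @property
    def label(self) -> str:
        return "+".join(f"q{i}" for i in self.active_terms) if self.active_terms else "null"

    @property
    def params(self) -> dict[str, float]:
        return {f"q{i}": v for i, v in self.coefficients.items()}

    def linear_predictor(self, lengths) -> np.ndarray:
        x = np.asarray(lengths, dtype=float) / LENGTH_SCALE
        eta = np.zeros_like(x)
        for i, b in self.scaled_coefficients.items():
            eta += b * x**i
        return eta

    def rate_at(self, lengths) -> np.ndarray:
        """Evaluate rate(l); overflow-safe logistic, result strictly in (0, 1)."""
        return special.expit(self.linear_predictor(lengths))


@dataclass(frozen=True)
class FitStatistics:
    """Goodness of fit of a length-based model against pooled counts."""

    deviance: float
    dof: int
    p_value: float


def observed_rate(n1: float, n2: float) -> float:
    """Experimental catch comparison rate n1 / (n1 + n2) for one length class."""
    total = n1 + n2
    if total <= 0:
        raise ZeroDivisionError("undefined rate: no fish in either codend")
    return n1 / total


def rate_eval(model: RateModel, lengths) -> np.ndarray:
    """Modelled rate(l); equals 0.5 everywhere when all coefficients are zero."""
    return model.rate_at(lengths)


def _window_mask(midpoints: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones_like(midpoints, dtype=bool)
    lo, hi = window
    return (midpoints >= lo) & (midpoints <= hi)


def _pooled_arrays(
    ds: SpeciesDataset, window: tuple[float, float] | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(midpoints, n_exp, n_std) for informative classes inside the window."""
    pooled = pool_hauls(ds)
    classes = np.array(pooled.classes())
    mids = classes + 0.5 * ds.class_width
    n1 = np.array([pooled.counts_exp.get(m, 0.0) for m in classes])
    n2 = np.array([pooled.counts_std.get(m, 0.0) for m in classes])
    keep = _window_mask(mids, window) & ((n1 + n2) > 0)
    return mids[keep], n1[keep], n2[keep]


def _binom_loglik(eta: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> float:
    # kernel only: sum n1*log(p) + n2*log(1-p); stable via log1p(exp(.))
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    return float(np.sum(n1 * log_p + n2 * log_q))


def negloglik(model: RateModel, pooled: HaulRecord, window=None, class_width: float = 1.0) -> float:
    """Negative binomial log-likelihood of codend membership, summed over classes.

    Classes with zero total count are skipped.  Counts may be non-integer
    (subsampling-raised); they enter the likelihood linearly.
    """
    classes = np.array(pooled.classes())
    mids = classes + 0.5 * class_width
    n1 = np.array([pooled.counts_exp.get(m, 0.0) for m in classes])
    n2 = np.array([pooled.counts_std.get(m, 0.0) for m in classes])
    keep = _window_mask(mids, window) & ((n1 + n2) > 0)
    if not keep.any():
        raise FitError("no informative length classes in window")
    eta = model.linear_predictor(mids[keep])
    return -_binom_loglik(eta, n1[keep], n2[keep])


def _irls(X: np.ndarray, n1: np.ndarray, n2: np.ndarray, max_iter: int = 60, tol: float = 1e-10):
    """Fisher scoring for the binomial-logit fit; the objective is concave, so
    the stationary point is the global maximum.  Returns (beta, loglik, ok)."""
    n = n1 + n2
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    ll = _binom_loglik(X @ beta, n1, n2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = n * mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (n1 - n * mu) / w
        XtW = X.T * w
        A = XtW @ X + 1e-10 * np.eye(p_dim)
        try:
            new_beta = np.linalg.solve(A, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, ll, False
        new_ll = _binom_loglik(X @ new_beta, n1, n2)
        # step-halving keeps the ascent monotone near separation
        step = 1.0
        while new_ll < ll - 1e-12 and step > 1e-6:
            step *= 0.5
            new_beta = beta + step * (new_beta - beta)
            new_ll = _binom_loglik(X @ new_beta, n1, n2)
        converged = abs(new_ll - ll) < tol * (abs(ll) + 1.0)
        beta, ll = new_beta, new_ll
        if converged:
            return beta, ll, True
    return beta, ll, True  # flat likelihood; accept last iterate


def fit_rate_model(
    ds: SpeciesDataset,
    active_terms,
    window: tuple[float, float] | None = None,
) -> RateModel:
    """Maximum-likelihood fit of one polynomial-logit candidate, pooled over hauls.

    ``active_terms`` is the subset of polynomial orders whose coefficients are
    free; all others are fixed at zero.  The empty subset is the no-effect
    null with rate identically 0.5.
    """
    active = tuple(sorted(set(int(t) for t in active_terms)))
    if any(t < 0 or t > 4 for t in active):
        raise ValueError(f"polynomial orders must be in 0..4, got {active}")
    mids, n1, n2 = _pooled_arrays(ds, window)
    if mids.size == 0:
        raise FitError("no informative length classes in window")
    if len(active) > mids.size:
        raise FitError(
            f"{len(active)} free coefficients but only {mids.size} informative classes"
        )
    x = mids / LENGTH_SCALE
    if active:
        X = np.column_stack([x**i for i in active])
        beta, ll, ok = _irls(X, n1, n2)
        if not ok:
            raise FitError(f"IRLS failed for terms {active}")
        degenerate = bool(np.max(np.abs(X @ beta)) > _ETA_BOUNDARY)
        scaled = dict(zip(active, beta))
    else:
        ll = _binom_loglik(np.zeros_like(mids), n1, n2)
        degenerate = False
        scaled = {}
    coefs = {i: b / LENGTH_SCALE**i for i, b in scaled.items()}
    aic = 2.0 * len(active) - 2.0 * ll
    return RateModel(
        active_terms=active,
        coefficients=coefs,
        loglik=ll,
        aic=aic,
        window=window,
        degenerate=degenerate,
        scaled_coefficients=scaled,
    )


def rate_model_candidates(max_order: int = 4, include_empty: bool = True) -> list[tuple[int, ...]]:
    """All subsets of {q0..q_max_order}: 32 candidates at the default order 4."""
    orders = range(max_order + 1)
    subsets: list[tuple[int, ...]] = []
    for k in range(0 if include_empty else 1, max_order + 2):
        subsets.extend(itertools.combinations(orders, k))
    return subsets


def select_rate_model(
    ds: SpeciesDataset,
    window: tuple[float, float] | None = None,
    max_order: int = 4,
    include_empty: bool = True,
) -> RateModel:
    """Fit every candidate subset and return the lowest-AIC model.

    Ties are broken toward fewer parameters, then lower polynomial order.
    Degenerate (separated) fits are excluded from selection; if every
    candidate is degenerate a :class:`FitError` is raised.  The per-candidate
    AIC table is attached as ``selection_table`` on the returned model.
    """
    table: dict[str, float] = {}
    fits: list[RateModel] = []
    for active in rate_model_candidates(max_order, include_empty):
        try:
            m = fit_rate_model(ds, active, window)
        except FitError:
            continue
        table[m.label] = m.aic
        if not m.degenerate:
            fits.append(m)
    if not fits:
        raise FitError("all candidate rate models failed or were degenerate")
    best = min(fits, key=lambda m: (m.aic, m.n_params, m.active_terms))
    best.selection_table = table  # type: ignore[attr-defined]
    return best


def make_rate_selector(window=None, max_order: int = 4, include_empty: bool = True):
    """A dataset -> RateModel callable, for use as a bootstrap fitting procedure."""

    def fit(ds: SpeciesDataset) -> RateModel:
        return select_rate_model(ds, window=window, max_order=max_order, include_empty=include_empty)

    return fit


def saturated_loglik(n1: np.ndarray, n2: np.ndarray) -> float:
    """Log-likelihood of the model matching every observed proportion exactly."""
    n = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(n1 > 0, n1 * np.log(n1 / n), 0.0)
        t2 = np.where(n2 > 0, n2 * np.log(n2 / n), 0.0)
    return float(np.sum(t1 + t2))


def fit_statistics(
    model,
    pooled: HaulRecord,
    window: tuple[float, float] | None = None,
    class_width: float = 1.0,
    n_params: int | None = None,
) -> FitStatistics:
    """Deviance, degrees of freedom and chi-square p-value for a fitted curve.

    deviance = 2 * (saturated loglik - model loglik); dof = informative
    classes - number of free parameters; the p-value is the chi-square
    upper-tail probability.  A non-positive dof yields p_value = nan.
    """
    classes = np.array(pooled.classes())
    mids = classes + 0.5 * class_width
    n1 = np.array([pooled.counts_exp.get(m, 0.0) for m in classes])
    n2 = np.array([pooled.counts_std.get(m, 0.0) for m in classes])
    keep = _window_mask(mids, window) & ((n1 + n2) > 0)
    mids, n1, n2 = mids[keep], n1[keep], n2[keep]
    if mids.size == 0:
        raise FitError("no informative length classes in window")
    rate = np.clip(model.rate_at(mids), 1e-300, 1.0 - 1e-16)
    ll = float(np.sum(n1 * np.log(rate) + n2 * np.log(1.0 - rate)))
    dev = max(2.0 * (saturated_loglik(n1, n2) - ll), 0.0)
    k = n_params if n_params is not None else model.n_params
    dof = int(mids.size - k)
    p = float(stats.chi2.sf(dev, dof)) if dof > 0 else math.nan
    return FitStatistics(deviance=dev, dof=dof, p_value=p)
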