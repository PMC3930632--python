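"""Bootstrap uncertainty for catch comparison and contact curves.

The double bootstrap resamples hauls with replacement (outer level, capturing
between-haul variation) and then, within each selected haul, resamples
individual fish records (length class, codend) with replacement to the haul's
total (inner level, capturing within-haul sampling noise).  The entire
fitting procedure — including model selection, when the supplied procedure
performs one — is re-run in every replicate, so the intervals carry
model-selection uncertainty as well.  Confidence limits are Efron percentile
intervals: empirical quantiles of the replicate estimates.

When haul-level data are too weak to support outer resampling, the single
bootstrap pools all hauls and resamples fish only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .io import HaulRecord, SpeciesDataset, pool_hauls, replace_dataset
from .ratemodel import FitError

__all__ = ["BootstrapResult", "double_bootstrap", "single_bootstrap", "efron_percentile"]


def efron_percentile(samples, level: float = 0.95) -> tuple[float, float]:
    """Empirical ((1-level)/2, (1+level)/2) quantiles of replicate values.

    Quantiles use linear interpolation between order statistics, so bands are
    reproducible across implementations.  Identical samples give a zero-width
    interval.
    """
    s = np.asarray(samples, dtype=float)
    s = s[np.isfinite(s)]
    if s.size < 2:
        raise ValueError("need at least two finite replicate values")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(s, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


@dataclass
class BootstrapResult:
    """Replicate summaries of a bootstrapped fitting procedure.

    Percentile bands need not contain the point estimate.  ``model_freq``
    gives the selection frequency of each candidate model across replicates
    and sums to 1.
    """

    reps: int
    level: float
    seed: int
    mode: str  # "double" | "single"
    point_estimate: object
    lengths: np.ndarray
    rate_point: np.ndarray
    rate_lower: np.ndarray
    rate_upper: np.ndarray
    contact_point: np.ndarray | None
    contact_lower: np.ndarray | None
    contact_upper: np.ndarray | None
    param_intervals: dict[str, tuple[float, float]]
    model_freq: dict[str, float]
    n_failed: int = 0
    warnings: list[str] = field(default_factory=list)

    def rate_band_at(self, length: float) -> tuple[float, float]:
        i = int(np.argmin(np.abs(self.lengths - length)))
        return float(self.rate_lower[i]), float(self.rate_upper[i])

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "length": self.lengths,
            "rate": self.rate_point,
            "rate_lower": self.rate_lower,
            "rate_upper": self.rate_upper,
        }
        if self.contact_point is not None:
            cols.update(
                contact=self.contact_point,
                contact_lower=self.contact_lower,
                contact_upper=self.contact_upper,
            )
        return pd.DataFrame(cols)

    def summary(self) -> dict:
        return {
            "reps": self.reps,
            "level": self.level,
            "seed": self.seed,
            "mode": self.mode,
            "model": getattr(self.point_estimate, "label", None),
            "model_freq": self.model_freq,
            "param_intervals": {k: list(v) for k, v in self.param_intervals.items()},
            "n_failed": self.n_failed,
            "warnings": self.warnings,
        }


def _param_dict(fit) -> dict[str, float]:
    """Uniform parameter mapping across fit types (rate models, contact fits)."""
    p = getattr(fit, "params", None)
    if p is None:
        return {}
    if hasattr(p, "as_dict"):
        return p.as_dict()
    return dict(p)


def _haul_cells(h: HaulRecord):
    """Flatten a haul into ((class, codend) cells, probabilities, total n).

    Subsampling-raised counts may be fractional; the resample size is the
    rounded total and cell probabilities are proportional to the counts.
    """
    classes = h.classes()
    counts = np.array(
        [h.counts_exp.get(m, 0.0) for m in classes] + [h.counts_std.get(m, 0.0) for m in classes]
    )
    total = counts.sum()
    n = int(round(total))
    if n == 0 or total == 0:
        return classes, None, 0
    return classes, counts / total, n


def _resample_haul(h: HaulRecord, haul_id: str, rng: np.random.Generator) -> HaulRecord:
    classes, probs, n = _haul_cells(h)
    if n == 0:
        return HaulRecord(haul_id=haul_id, counts_exp={}, counts_std={})
    draw = rng.multinomial(n, probs)
    k = len(classes)
    exp = {m: float(c) for m, c in zip(classes, draw[:k]) if c > 0}
    std = {m: float(c) for m, c in zip(classes, draw[k:]) if c > 0}
    return HaulRecord(haul_id=haul_id, counts_exp=exp, counts_std=std)


def _run_bootstrap(
    ds: SpeciesDataset,
    fit: Callable[[SpeciesDataset], object],
    reps: int,
    level: float,
    seed: int,
    mode: str,
) -> BootstrapResult:
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    point = fit(ds)

    pooled = pool_hauls(ds)
    classes = np.array(pooled.classes())
    totals = np.array([sum(pooled.count_pair(m)) for m in classes])
    lengths = (classes + 0.5 * ds.class_width)[totals > 0]

    has_contact = hasattr(point, "contact_at")
    rate_mat = np.empty((reps, lengths.size))
    contact_mat = np.empty((reps, lengths.size)) if has_contact else None
    params: dict[str, list[float]] = {}
    labels: list[str] = []
    n_failed = 0
    max_attempts = 20 + 10 * reps

    n_hauls = len(ds.hauls)
    done = 0
    attempts = 0
    while done < reps:
        attempts += 1
        if attempts > max_attempts:
            raise FitError(
                f"bootstrap exceeded {max_attempts} attempts ({n_failed} failed fits)"
            )
        if mode == "double":
            chosen = rng.integers(0, n_hauls, size=n_hauls)
            hauls = [
                _resample_haul(ds.hauls[i], f"b{j}", rng) for j, i in enumerate(chosen)
            ]
        else:
            hauls = [_resample_haul(pooled, "b0", rng)]
        rep_ds = replace_dataset(ds, hauls)
        try:
            f = fit(rep_ds)
        except (FitError, ValueError):
            n_failed += 1
            continue
        rate_mat[done] = f.rate_at(lengths)
        if has_contact:
            contact_mat[done] = f.contact_at(lengths)
        for name, value in _param_dict(f).items():
            params.setdefault(name, []).append(float(value))
        labels.append(getattr(f, "label", "fit"))
        done += 1

    warnings = []
    if reps == 1:
        warnings.append("single replicate: zero-width bands are degenerate, not informative")
        band = lambda col: (float(col[0]), float(col[0]))  # noqa: E731
    else:
        band = lambda col: efron_percentile(col, level)  # noqa: E731

    rate_lo, rate_hi = np.array([band(rate_mat[:, j]) for j in range(lengths.size)]).T
    if has_contact:
        c_lo, c_hi = np.array([band(contact_mat[:, j]) for j in range(lengths.size)]).T
    uniq, counts = np.unique(labels, return_counts=True)
    model_freq = {str(u): float(c) / reps for u, c in zip(uniq, counts)}
    param_intervals = {
        name: (band(np.asarray(v)) if len(v) >= 2 else (v[0], v[0]))
        for name, v in params.items()
    }

    return BootstrapResult(
        reps=reps,
        level=level,
        seed=seed,
        mode=mode,
        point_estimate=point,
        lengths=lengths,
        rate_point=np.asarray(point.rate_at(lengths), dtype=float),
        rate_lower=rate_lo,
        rate_upper=rate_hi,
        contact_point=np.asarray(point.contact_at(lengths), dtype=float) if has_contact else None,
        contact_lower=c_lo if has_contact else None,
        contact_upper=c_hi if has_contact else None,
        param_intervals=param_intervals,
        model_freq=model_freq,
        n_failed=n_failed,
        warnings=warnings,
    )


def double_bootstrap(
    ds: SpeciesDataset,
    fit: Callable[[SpeciesDataset], object],
    reps: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Haul-and-fish double bootstrap with the fit re-run per replicate.

    Requires at least two hauls; with one, between-haul variation cannot be
    resampled — use :func:`single_bootstrap`.  Replicates whose fit fails
    (boundary/separation at small n) are redrawn and counted in
    ``n_failed``.  Output is a pure function of (data, fit, reps, level,
    seed).
    """
    if len(ds.hauls) < 2:
        raise FitError("double bootstrap needs >= 2 hauls; use single_bootstrap")
    return _run_bootstrap(ds, fit, reps, level, seed, "double")


def single_bootstrap(
    ds: SpeciesDataset,
    fit: Callable[[SpeciesDataset], object],
    reps: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Fish-only bootstrap on the pooled hauls (no between-haul variation)."""
    if not ds.hauls or pool_hauls(ds).total() <= 0:
        raise FitError("cannot bootstrap an empty dataset")
    return _run_bootstrap(ds, fit, reps, level, seed, "single")
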