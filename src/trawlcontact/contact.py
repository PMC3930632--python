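"""Panel-contact (escape) likelihood inferred from catch comparison data.

A fish entering the paired rig picks the experimental trawl with probability
sp (the split).  Inside the experimental trawl it contacts the large-mesh
panel with length-dependent probability c(l) and — because the panel meshes
release every size — escapes on contact.  Restricting the data to lengths the
standard trawl retains completely, the catch comparison rate is

    rate(l) = sp * (1 - c(l)) / (1 - sp * c(l)),

which this module inverts and fits.  Four nested shapes for c(l) are
considered (M1 full logistic; M2 knife edge between two plateaus; M3 knife
edge to zero; M4 constant) and compared by AIC.

The same machinery accepts explicit per-panel retention curves, in which case
the general paired-gear factorisation (see :mod:`trawlcontact.simulate`) is
used instead of the restricted-window relation — needed when fitting to
simulated data where the standard trawl is itself selective.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import optimize

from .curves import ContactParams, RetentionLogit, contact_curve
from .io import SpeciesDataset, pool_hauls, replace_dataset
from .ratemodel import FitError, FitStatistics, _pooled_arrays, fit_statistics

__all__ = [
    "ContactNotApplicable",
    "ContactParams",
    "ContactFit",
    "SpeciesCutoff",
    "load_cutoffs",
    "rate_from_contact",
    "contact_from_rate",
    "contact_curve",
    "restrict_length_window",
    "exclude_sparse_hauls",
    "fit_contact_model",
    "select_contact_model",
    "make_contact_selector",
    "MODEL_N_PARAMS",
]

MODEL_N_PARAMS = {"M1": 4, "M2": 3, "M3": 2, "M4": 1}


class ContactNotApplicable(ValueError):
    """Contact inference cannot be applied to this species."""


@dataclass(frozen=True)
class SpeciesCutoff:
    """Largest length able to pass the standard trawl's netting.

    ``max_escape_length`` is in the dataset's length unit; ``None`` encodes
    the "all sizes can escape" sentinel (e.g. *Nephrops*), for which contact
    inference is not applicable.
    """

    species: str
    max_escape_length: float | None
    note: str = ""


def load_cutoffs(path=None) -> dict[str, SpeciesCutoff]:
    """Species cutoff table; the packaged default can be overridden by path."""
    if path is None:
        raw = resources.files("trawlcontact.data").joinpath("cutoffs.json").read_text()
    else:
        with open(path) as fh:
            raw = fh.read()
    data = json.loads(raw)
    out = {}
    for row in data["cutoffs"]:
        mel = row["max_escape_length"]
        out[row["species"].lower()] = SpeciesCutoff(
            species=row["species"],
            max_escape_length=None if mel == "all" else float(mel),
            note=row.get("note", ""),
        )
    return out


def rate_from_contact(c, sp: float):
    """Catch comparison rate implied by contact likelihood c under split sp.

    Valid inside the restricted length window where the standard trawl
    retains all fish and every panel contact escapes.
    """
    c = np.asarray(c, dtype=float)
    out = sp * (1.0 - c) / (1.0 - sp * c)
    return out if out.ndim else float(out)


def contact_from_rate(rate, sp: float, clamp: bool = False):
    """Invert :func:`rate_from_contact`: c = (sp - rate) / (sp * (1 - rate)).

    Only rates in [0, sp] map into [0, 1]; a larger rate means the
    experimental trawl out-caught the standard one, which the contact model
    cannot represent.  Such values raise unless ``clamp=True``.
    """
    rate = np.asarray(rate, dtype=float)
    out = (sp - rate) / (sp * (1.0 - rate))
    if clamp:
        out = np.clip(out, 0.0, 1.0)
    elif np.any(out < 0.0) or np.any(out > 1.0):
        raise ValueError(
            "rate outside [0, sp]: observed rate exceeds the split, no contact "
            "likelihood in [0, 1] reproduces it (pass clamp=True to truncate)"
        )
    return out if out.ndim else float(out)


def restrict_length_window(
    ds: SpeciesDataset,
    cutoff: SpeciesCutoff,
    upper: float | None = None,
    rule: str = "strict",
) -> SpeciesDataset:
    """Drop length classes the standard trawl's netting could release.

    ``rule='strict'`` keeps measured lengths strictly greater than the
    cutoff; ``'inclusive'`` keeps the boundary class too.  ``upper`` (default
    none: the large-mesh panel releases every size) truncates from above.
    """
    if cutoff.max_escape_length is None:
        raise ContactNotApplicable(
            f"all sizes of {cutoff.species} can escape the standard trawl's netting, "
            "so its selectivity cannot be excluded by windowing; panel-contact "
            "inference is not applicable to this species"
        )
    if rule not in ("strict", "inclusive"):
        raise ValueError(f"rule must be 'strict' or 'inclusive', got {rule!r}")
    lo = cutoff.max_escape_length

    def keep(measured: int) -> bool:
        if rule == "strict" and measured <= lo:
            return False
        if rule == "inclusive" and measured < lo:
            return False
        return upper is None or measured <= upper

    hauls = []
    for h in ds.hauls:
        hauls.append(
            type(h)(
                haul_id=h.haul_id,
                counts_exp={m: n for m, n in h.counts_exp.items() if keep(m)},
                counts_std={m: n for m, n in h.counts_std.items() if keep(m)},
                frac_exp=h.frac_exp,
                frac_std=h.frac_std,
                raw_exp=h.raw_exp,
                raw_std=h.raw_std,
            )
        )
    out = replace_dataset(ds, hauls, window_rule=rule, cutoff=lo)
    if not out.classes():
        raise FitError(f"length window above {lo} {ds.length_unit} is empty")
    return out


def exclude_sparse_hauls(ds: SpeciesDataset, min_n: float = 10) -> SpeciesDataset:
    """Remove hauls with fewer than ``min_n`` individuals (both codends).

    Excluded haul ids are recorded in ``meta['excluded_hauls']`` of the
    returned dataset.
    """
    kept, dropped = [], []
    for h in ds.hauls:
        (kept if h.total() >= min_n else dropped).append(h)
    if not kept:
        raise FitError(f"all hauls have fewer than {min_n} individuals")
    return replace_dataset(ds, kept, excluded_hauls=[h.haul_id for h in dropped])


def _general_rate(c: np.ndarray, sp: float, r_exp: np.ndarray, r_std: np.ndarray) -> np.ndarray:
    """Probability of the experimental codend given caught, with explicit
    per-panel retention of contacting fish."""
    p_exp = sp * (1.0 - c * (1.0 - r_exp))
    p_std = (1.0 - sp) * (1.0 - c * (1.0 - r_std))
    return p_exp / (p_exp + p_std)


def _loglik_for_contact(c, sp, r_exp, r_std, n1, n2) -> float:
    rate = np.clip(_general_rate(np.asarray(c, float), sp, r_exp, r_std), 1e-12, 1 - 1e-12)
    return float(np.sum(n1 * np.log(rate) + n2 * np.log(1.0 - rate)))


@dataclass
class ContactFit:
    """A fitted panel-contact model (one of M1..M4)."""

    model_id: str
    params: ContactParams
    sp: float
    loglik: float
    aic: float
    window: tuple[float, float]
    stats: FitStatistics | None = None
    boundary: bool = False
    retention_exp: RetentionLogit = field(default_factory=RetentionLogit.release_all)
    retention_std: RetentionLogit = field(default_factory=RetentionLogit.retain_all)

    @property
    def n_params(self) -> int:
        return MODEL_N_PARAMS[self.model_id]

    @property
    def label(self) -> str:
        return self.model_id

    def contact_at(self, lengths) -> np.ndarray:
        return contact_curve(self.params, lengths)

    def rate_at(self, lengths) -> np.ndarray:
        l = np.asarray(lengths, dtype=float)
        c = np.asarray(contact_curve(self.params, l), dtype=float)
        return _general_rate(c, self.sp, self.retention_exp(l), self.retention_std(l))

    def as_dict(self) -> dict:
        return {
            "model": self.model_id,
            **self.params.as_dict(),
            "sp": self.sp,
            "loglik": self.loglik,
            "aic": self.aic,
            "window": list(self.window),
            "boundary": self.boundary,
            "deviance": self.stats.deviance if self.stats else None,
            "dof": self.stats.dof if self.stats else None,
            "p_value": self.stats.p_value if self.stats else None,
        }


def _scalar_c_mle(side_n1, side_n2, sp, r_exp, r_std) -> tuple[float, bool]:
    """MLE of a constant contact likelihood on one set of classes.

    With the sentinel retentions (release-all experimental panel, retain-all
    standard panel) the rate is constant in c, so the MLE inverts the pooled
    proportion in closed form; otherwise a bounded scalar search is used.
    """
    n1s, n2s = float(np.sum(side_n1)), float(np.sum(side_n2))
    if n1s + n2s == 0:
        return 0.0, False
    sentinel = bool(np.all(r_exp == 0.0) and np.all(r_std == 1.0))
    if sentinel:
        p_hat = n1s / (n1s + n2s)
        c = (sp - p_hat) / (sp * (1.0 - p_hat)) if p_hat < 1.0 else 0.0
        c_clipped = min(max(c, 0.0), 1.0)
        return c_clipped, c_clipped != c or c_clipped in (0.0, 1.0)
    res = optimize.minimize_scalar(
        lambda c: -_loglik_for_contact(np.full_like(r_exp, c), sp, r_exp, r_std, side_n1, side_n2),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    c = float(res.x)
    return c, c < 1e-8 or c > 1 - 1e-8


def fit_contact_model(
    ds: SpeciesDataset,
    sp: float = 0.5,
    model_id: str = "M1",
    retention_exp: RetentionLogit | None = None,
    retention_std: RetentionLogit | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> ContactFit:
    """Maximum-likelihood fit of one contact model to a windowed dataset.

    The dataset should already be length-windowed and haul-filtered for
    field data.  ``sp`` is fixed, not estimated.  Free parameters: M1
    {c1, c2, L50c, SRc}; M2 {c1, c2, L50c} with SRc = 0; M3 {c1, L50c} with
    c2 = 0, SRc = 0; M4 a single constant contact likelihood.  c1 and c2 are
    box-constrained to [0, 1]; estimates at a bound set ``boundary=True``.
    """
    if not 0.0 < sp < 1.0:
        raise ValueError(f"sp must be in (0, 1), got {sp}")
    if model_id not in MODEL_N_PARAMS:
        raise ValueError(f"model_id must be one of {sorted(MODEL_N_PARAMS)}, got {model_id!r}")
    r_exp_curve = retention_exp if retention_exp is not None else RetentionLogit.release_all()
    r_std_curve = retention_std if retention_std is not None else RetentionLogit.retain_all()

    mids, n1, n2 = _pooled_arrays(ds, None)
    if mids.size == 0:
        raise FitError("no informative length classes")
    r_exp = np.asarray(r_exp_curve(mids), dtype=float)
    r_std = np.asarray(r_std_curve(mids), dtype=float)
    window = (float(mids.min()), float(mids.max()))
    span = max(window[1] - window[0], 1.0)

    if model_id == "M4":
        c_hat, boundary = _scalar_c_mle(n1, n2, sp, r_exp, r_std)
        params = ContactParams(c1=c_hat, c2=c_hat, l50=float(np.median(mids)), sr=0.0)
        ll = _loglik_for_contact(np.full_like(mids, c_hat), sp, r_exp, r_std, n1, n2)
    elif model_id in ("M2", "M3"):
        # knife edge: profile the likelihood over breakpoints between classes
        best = None
        edges = 0.5 * (mids[:-1] + mids[1:])
        for bp in edges:
            below = mids < bp
            if model_id == "M2":
                c1_hat, b1 = _scalar_c_mle(n1[below], n2[below], sp, r_exp[below], r_std[below])
                c2_hat, b2 = _scalar_c_mle(n1[~below], n2[~below], sp, r_exp[~below], r_std[~below])
            else:  # M3: plateau drops to zero contact above the edge
                c1_hat, b1 = _scalar_c_mle(n1[below], n2[below], sp, r_exp[below], r_std[below])
                c2_hat, b2 = 0.0, False
            c_vec = np.where(below, c1_hat, c2_hat)
            ll_bp = _loglik_for_contact(c_vec, sp, r_exp, r_std, n1, n2)
            cand = (ll_bp, float(bp), c1_hat, c2_hat, b1 or b2)
            if best is None or ll_bp > best[0]:
                best = cand
        if best is None:
            raise FitError("too few length classes for a knife-edge fit")
        ll, bp, c1_hat, c2_hat, boundary = best
        params = ContactParams(c1=c1_hat, c2=c2_hat, l50=bp, sr=0.0)
    else:  # M1
        rng = np.random.default_rng(seed)
        p_hat = np.clip((n1 + 1e-3) / (n1 + n2 + 2e-3), 1e-3, 1 - 1e-3)
        c_emp = np.clip((sp - p_hat) / (sp * (1.0 - p_hat)), 0.0, 1.0)
        k = max(mids.size // 4, 1)
        x0 = np.array(
            [float(np.mean(c_emp[:k])), float(np.mean(c_emp[-k:])), float(np.median(mids)), span / 5.0]
        )
        bounds = [
            (0.0, 1.0),
            (0.0, 1.0),
            (window[0] - span, window[1] + span),
            (1e-2, 3.0 * span),
        ]

        def nll(theta):
            p = ContactParams(
                c1=min(max(theta[0], 0.0), 1.0),
                c2=min(max(theta[1], 0.0), 1.0),
                l50=theta[2],
                sr=max(theta[3], 1e-2),
            )
            c = np.asarray(contact_curve(p, mids), dtype=float)
            return -_loglik_for_contact(c, sp, r_exp, r_std, n1, n2)

        best = None
        starts = [x0]
        for _ in range(max(n_starts - 1, 0)):
            pert = x0 + rng.normal(0, [0.15, 0.15, span / 4.0, span / 6.0])
            starts.append(np.clip(pert, [b[0] for b in bounds], [b[1] for b in bounds]))
        for s in starts:
            res = optimize.minimize(nll, s, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise FitError("M1 optimisation failed to converge")
        c1_hat, c2_hat, l50_hat, sr_hat = best.x
        c1_hat = min(max(c1_hat, 0.0), 1.0)
        c2_hat = min(max(c2_hat, 0.0), 1.0)
        params = ContactParams(c1=c1_hat, c2=c2_hat, l50=float(l50_hat), sr=float(max(sr_hat, 1e-2)))
        ll = -float(best.fun)
        boundary = bool(
            c1_hat in (0.0, 1.0) or c2_hat in (0.0, 1.0) or sr_hat <= 1e-2 + 1e-9
        )

    k = MODEL_N_PARAMS[model_id]
    fit = ContactFit(
        model_id=model_id,
        params=params,
        sp=sp,
        loglik=ll,
        aic=2.0 * k - 2.0 * ll,
        window=window,
        boundary=boundary,
        retention_exp=r_exp_curve,
        retention_std=r_std_curve,
    )
    fit.stats = fit_statistics(fit, pool_hauls(ds), None, ds.class_width, n_params=k)
    return fit


def select_contact_model(
    ds: SpeciesDataset,
    sp: float = 0.5,
    retention_exp: RetentionLogit | None = None,
    retention_std: RetentionLogit | None = None,
    seed: int = 0,
) -> ContactFit:
    """Fit M1..M4 and return the lowest-AIC fit (ties -> fewer parameters).

    The per-model AIC table is attached as ``aic_table`` on the result.
    """
    fits: list[ContactFit] = []
    errors: list[str] = []
    for mid in ("M1", "M2", "M3", "M4"):
        try:
            fits.append(
                fit_contact_model(
                    ds, sp=sp, model_id=mid, retention_exp=retention_exp,
                    retention_std=retention_std, seed=seed,
                )
            )
        except (FitError, ValueError) as exc:  # keep going; report at the end
            errors.append(f"{mid}: {exc}")
    if not fits:
        raise FitError("all contact models failed: " + "; ".join(errors))
    best = min(fits, key=lambda f: (f.aic, f.n_params))
    best.aic_table = {f.model_id: f.aic for f in fits}  # type: ignore[attr-defined]
    return best


def make_contact_selector(sp: float = 0.5, seed: int = 0, **kwargs):
    """A dataset -> ContactFit callable, for use as a bootstrap fitting procedure."""

    def fit(ds: SpeciesDataset) -> ContactFit:
        return select_contact_model(ds, sp=sp, seed=seed, **kwargs)

    return fit
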