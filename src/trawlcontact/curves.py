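"""Parametric curves shared by the contact model and the gear simulator.

Both the panel-contact curve and mesh retention use the logit convention
standard in size-selectivity work: L50 is the length at the midpoint of the
transition and SR (selection range) is the length span between the 25% and
75% points, so the steepness is ln(9)/SR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

LN9 = float(np.log(9.0))

__all__ = ["ContactParams", "RetentionLogit", "contact_curve", "retention"]


@dataclass(frozen=True)
class ContactParams:
    """Parameters of the length-dependent panel-contact likelihood c(l).

    c1 and c2 are the contact asymptotes at small and large lengths, both in
    [0, 1]; L50c is the length at which c(l) = (c1 + c2) / 2; SRc >= 0 sets
    how quickly contact shifts from c1 to c2 (SRc = 0 is a knife edge).
    """

    c1: float
    c2: float
    l50: float
    sr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.c1 <= 1.0 or not 0.0 <= self.c2 <= 1.0:
            raise ValueError(f"c1, c2 must lie in [0, 1]; got {self.c1}, {self.c2}")
        if self.sr < 0.0:
            raise ValueError(f"SRc must be >= 0; got {self.sr}")

    def as_dict(self) -> dict[str, float]:
        return {"c1": self.c1, "c2": self.c2, "L50c": self.l50, "SRc": self.sr}


def contact_curve(p: ContactParams, lengths) -> np.ndarray:
    """Contact likelihood c(l): logistic blend from c1 to c2.

    c(l) = c1 + (c2 - c1) * expit((ln9 / SRc) * (l - L50c)); at SRc = 0 the
    blend degenerates to a knife edge at L50c, taking the exact mean of c1
    and c2 at l = L50c.
    """
    l = np.asarray(lengths, dtype=float)
    if p.sr == 0.0:
        out = np.where(l < p.l50, p.c1, np.where(l > p.l50, p.c2, 0.5 * (p.c1 + p.c2)))
        return out if out.ndim else float(out)
    s = special.expit((LN9 / p.sr) * (l - p.l50))
    out = p.c1 + (p.c2 - p.c1) * s
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RetentionLogit:
    """Mesh retention probability for a fish that contacts a netting panel.

    The logit form 1 / (1 + exp(-(ln9/SRp) * (l - L50p))) rises with length:
    small fish slip through (escape), large fish are retained.  The sentinels
    ``retain_all`` (no escape through this panel) and ``release_all`` (every
    contacting fish escapes, e.g. 800 mm meshes) avoid degenerate parameter
    values.
    """

    l50: float = 0.0
    sr: float = 1.0
    mode: str = "logit"  # "logit" | "retain_all" | "release_all"

    def __post_init__(self) -> None:
        if self.mode == "logit" and self.sr <= 0.0:
            raise ValueError(f"SRp must be > 0; got {self.sr}")
        if self.mode not in ("logit", "retain_all", "release_all"):
            raise ValueError(f"unknown retention mode {self.mode!r}")

    @classmethod
    def retain_all(cls) -> "RetentionLogit":
        return cls(mode="retain_all")

    @classmethod
    def release_all(cls) -> "RetentionLogit":
        return cls(mode="release_all")

    def __call__(self, lengths) -> np.ndarray:
        return retention(lengths, self)


def retention(lengths, r: RetentionLogit) -> np.ndarray:
    """Retention probability at length l for a contacting fish."""
    l = np.asarray(lengths, dtype=float)
    if r.mode == "retain_all":
        out = np.ones_like(l)
    elif r.mode == "release_all":
        out = np.zeros_like(l)
    else:
        out = special.expit((LN9 / r.sr) * (l - r.l50))
    return out if out.ndim else float(out)
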