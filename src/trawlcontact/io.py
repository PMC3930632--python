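"""Reading, validating and normalising paired-trawl catch tables.

The canonical on-disk format is a CSV with one row per haul x length class:

    haul_id,species,length,count_exp,count_std[,frac_exp,frac_std]

``length`` is the measured length class (integer cm for fish, integer mm for
*Nephrops* carapace length).  Model evaluation always uses the class midpoint,
i.e. measured length + half the class width (0.5 cm is added to each measured
fish length, 0.5 mm for *Nephrops*).  ``count_exp`` / ``count_std`` are the
numbers of individuals collected in the experimental (large-mesh panel) and
standard codend; ``frac_exp`` / ``frac_std`` are optional subsampling
fractions in (0, 1], defaulting to 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CatchDataError",
    "HaulRecord",
    "SpeciesDataset",
    "read_catch_table",
    "write_catch_table",
    "scale_subsampled_counts",
    "pool_hauls",
]

REQUIRED_COLUMNS = ("haul_id", "length", "count_exp", "count_std")


class CatchDataError(ValueError):
    """Malformed or inconsistent catch-table input."""


@dataclass(frozen=True)
class HaulRecord:
    """Counts per length class in the two codends for one haul.

    ``counts_exp`` / ``counts_std`` map measured length class -> count.
    Counts are non-negative; they may be non-integer after subsampling
    correction, in which case the original measured counts are preserved in
    ``raw_exp`` / ``raw_std``.
    """

    haul_id: str
    counts_exp: dict[int, float]
    counts_std: dict[int, float]
    frac_exp: float = 1.0
    frac_std: float = 1.0
    raw_exp: dict[int, float] | None = None
    raw_std: dict[int, float] | None = None

    def classes(self) -> list[int]:
        return sorted(set(self.counts_exp) | set(self.counts_std))

    def count_pair(self, length: int) -> tuple[float, float]:
        return (self.counts_exp.get(length, 0.0), self.counts_std.get(length, 0.0))

    def total(self) -> float:
        return float(sum(self.counts_exp.values()) + sum(self.counts_std.values()))


@dataclass
class SpeciesDataset:
    """All hauls for one species, sharing a length-class convention."""

    species: str
    hauls: list[HaulRecord]
    length_unit: str = "cm"  # "cm" for fish, "mm" for Nephrops
    class_width: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [h.haul_id for h in self.hauls]
        if len(ids) != len(set(ids)):
            raise CatchDataError(f"duplicate haul ids in dataset for {self.species!r}")
        for h in self.hauls:
            for frac in (h.frac_exp, h.frac_std):
                if not 0.0 < frac <= 1.0:
                    raise CatchDataError(
                        f"haul {h.haul_id!r}: sampling fraction {frac} outside (0, 1]"
                    )
            for counts in (h.counts_exp, h.counts_std):
                for length, n in counts.items():
                    if length <= 0:
                        raise CatchDataError(f"haul {h.haul_id!r}: length {length} <= 0")
                    if n < 0:
                        raise CatchDataError(
                            f"haul {h.haul_id!r}: negative count {n} at length {length}"
                        )

    def midpoint(self, measured: int) -> float:
        """Class midpoint: measured length + half the class width."""
        return measured + 0.5 * self.class_width

    def classes(self) -> list[int]:
        out: set[int] = set()
        for h in self.hauls:
            out.update(h.classes())
        return sorted(out)

    def midpoints(self) -> np.ndarray:
        return np.array([self.midpoint(m) for m in self.classes()])

    def zero_total_classes(self) -> list[int]:
        """Length classes present in the table but with zero total count."""
        pooled = pool_hauls(self)
        return [m for m in pooled.classes() if sum(pooled.count_pair(m)) == 0]


def read_catch_table(path, species: str | None = None) -> SpeciesDataset:
    """Read a catch-comparison CSV into a :class:`SpeciesDataset`.

    Parameters
    ----------
    path
        CSV file with columns ``haul_id,length,count_exp,count_std`` and
        optionally ``species``, ``frac_exp``, ``frac_std``, ``length_unit``.
    species
        Species to extract.  Required if the file contains more than one.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CatchDataError(f"empty catch table: {path}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CatchDataError(f"missing required columns {missing} in {path}")
    if df.empty:
        raise CatchDataError(f"catch table has no data rows: {path}")

    if "species" in df.columns:
        present = sorted(df["species"].unique())
        if species is None:
            if len(present) > 1:
                raise CatchDataError(
                    f"file contains multiple species {present}; pass species="
                )
            species = present[0]
        df = df[df["species"] == species]
        if df.empty:
            raise CatchDataError(f"species {species!r} not found (have {present})")
    elif species is None:
        species = "unknown"

    if (df["count_exp"] < 0).any() or (df["count_std"] < 0).any():
        raise CatchDataError("negative counts in catch table")
    dup = df.duplicated(subset=["haul_id", "length"])
    if dup.any():
        pairs = df.loc[dup, ["haul_id", "length"]].values.tolist()
        raise CatchDataError(f"duplicate (haul, length) rows (no silent summing): {pairs}")

    length_unit = "cm"
    if "length_unit" in df.columns:
        units = set(df["length_unit"].unique())
        if len(units) > 1:
            raise CatchDataError(f"mixed length units {units}")
        length_unit = units.pop()

    hauls: list[HaulRecord] = []
    for haul_id, grp in df.groupby("haul_id", sort=True):
        fe = float(grp["frac_exp"].iloc[0]) if "frac_exp" in grp.columns else 1.0
        fs = float(grp["frac_std"].iloc[0]) if "frac_std" in grp.columns else 1.0
        hauls.append(
            HaulRecord(
                haul_id=str(haul_id),
                counts_exp={int(l): float(n) for l, n in zip(grp["length"], grp["count_exp"])},
                counts_std={int(l): float(n) for l, n in zip(grp["length"], grp["count_std"])},
                frac_exp=fe,
                frac_std=fs,
            )
        )
    return SpeciesDataset(species=species, hauls=hauls, length_unit=length_unit)


def write_catch_table(ds: SpeciesDataset, path) -> None:
    """Write a dataset back to the canonical CSV dialect."""
    rows = []
    for h in ds.hauls:
        for m in h.classes():
            ne, ns = h.count_pair(m)
            rows.append(
                {
                    "haul_id": h.haul_id,
                    "species": ds.species,
                    "length": m,
                    "count_exp": ne,
                    "count_std": ns,
                    "frac_exp": h.frac_exp,
                    "frac_std": h.frac_std,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def scale_subsampled_counts(ds: SpeciesDataset) -> SpeciesDataset:
    """Raise subsampled counts to haul totals (divide by the codend fraction).

    Scaled counts may be non-integer; the original counts are preserved in
    ``raw_exp`` / ``raw_std`` on each haul.  Hauls with both fractions 1.0 are
    returned unchanged.
    """
    hauls = []
    for h in ds.hauls:
        if h.frac_exp == 1.0 and h.frac_std == 1.0:
            hauls.append(h)
            continue
        hauls.append(
            replace(
                h,
                counts_exp={m: n / h.frac_exp for m, n in h.counts_exp.items()},
                counts_std={m: n / h.frac_std for m, n in h.counts_std.items()},
                raw_exp=dict(h.counts_exp),
                raw_std=dict(h.counts_std),
            )
        )
    return replace_dataset(ds, hauls)


def pool_hauls(ds: SpeciesDataset) -> HaulRecord:
    """Sum (scaled) counts per length class over all hauls."""
    if not ds.hauls:
        raise CatchDataError("cannot pool an empty dataset")
    if len(ds.hauls) == 1:
        return ds.hauls[0]
    exp: dict[int, float] = {}
    std: dict[int, float] = {}
    for h in ds.hauls:
        for m, n in h.counts_exp.items():
            exp[m] = exp.get(m, 0.0) + n
        for m, n in h.counts_std.items():
            std[m] = std.get(m, 0.0) + n
    return HaulRecord(haul_id="pooled", counts_exp=exp, counts_std=std)


def replace_dataset(ds: SpeciesDataset, hauls: list[HaulRecord], **meta) -> SpeciesDataset:
    new = SpeciesDataset(
        species=ds.species,
        hauls=hauls,
        length_unit=ds.length_unit,
        class_width=ds.class_width,
        meta={**ds.meta, **meta},
    )
    return new
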