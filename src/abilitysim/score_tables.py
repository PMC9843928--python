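"""Lookup-table data model and conversion operations for subdomain scoring.

Three structures drive all score conversion for a subdomain of an adaptive
behavior instrument such as the Vineland-3:

* a raw-score -> GSV table (GSV = growth scale value, the Rasch person-ability
  score; minimum 10, subdomain-specific maximum between 110 and 197),
* an age-banded raw-score -> V-scale table (the norm-referenced subdomain
  score: population mean 15, SD 3, floor 1),
* a per-age-band table of GSV standard errors of measurement (SEM) and
  internal-consistency reliabilities.

The real instrument tables are copyrighted and are not shipped; users either
supply their own CSV files (schemas below) or generate structurally faithful
synthetic stand-ins with :mod:`abilitysim.synthetic_tables`.

CSV schemas (UTF-8, header row required, integer columns strict):

* ``gsv_table.csv``: subdomain, raw, gsv — one row per raw score.
* ``vscale_table.csv``: subdomain, age_min_months, age_max_months, vscale,
  raw_min, raw_max — one row per (age band, attainable v-scale value).
* ``sem_reliability.csv``: subdomain, age_min_months, age_max_months,
  sem_gsv, reliability.

Ages are integer months throughout; age bands are half-open ``[min, max)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AgeBand",
    "GSVTable",
    "VScaleTable",
    "SEMReliabilityTable",
    "TableSet",
    "TableValidationError",
    "load_table_set",
    "write_table_set",
    "gsv_from_raw",
    "raw_from_gsv",
    "vscale_from_raw",
    "mean_raw_for_vscale",
]

GSV_MIN = 10
GSV_MAX_RANGE = (110, 197)
VSCALE_MIN = 1
VSCALE_MAX = 24


class TableValidationError(ValueError):
    """A lookup table violates a structural invariant.

    Carries the offending subdomain and, where meaningful, the row or raw
    score at which the violation was detected.
    """

    def __init__(self, message: str, subdomain: str | None = None, row=None):
        self.subdomain = subdomain
        self.row = row
        prefix = f"[{subdomain}] " if subdomain else ""
        suffix = f" (row: {row})" if row is not None else ""
        super().__init__(f"{prefix}{message}{suffix}")


@dataclass(frozen=True, order=True)
class AgeBand:
    """Half-open age interval ``[min_months, max_months)`` in integer months."""

    min_months: int
    max_months: int

    def __post_init__(self):
        if self.min_months >= self.max_months:
            raise TableValidationError(
                f"empty age band [{self.min_months}, {self.max_months})"
            )

    def contains(self, age_months: int) -> bool:
        return self.min_months <= age_months < self.max_months

    @property
    def midpoint(self) -> float:
        return (self.min_months + self.max_months) / 2.0

    def overlap_months(self, lo: int, hi: int) -> int:
        """Months of overlap with the half-open interval ``[lo, hi)``."""
        return max(0, min(self.max_months, hi) - max(self.min_months, lo))


def _check_age_partition(bands: list[AgeBand], subdomain: str) -> None:
    bands = sorted(bands)
    for prev, cur in zip(bands, bands[1:]):
        if cur.min_months < prev.max_months:
            raise TableValidationError(
                f"overlapping age bands [{prev.min_months},{prev.max_months}) "
                f"and [{cur.min_months},{cur.max_months})",
                subdomain,
            )
        if cur.min_months > prev.max_months:
            raise TableValidationError(
                f"gap between age bands at {prev.max_months} months", subdomain
            )


@dataclass
class GSVTable:
    """Monotone raw-score -> GSV lookup for one subdomain.

    ``raw`` must be contiguous integers from 0 to the subdomain maximum and
    ``gsv`` nondecreasing, starting at the scale floor of 10.
    """

    subdomain: str
    raw: np.ndarray
    gsv: np.ndarray
    _gsv_values: np.ndarray = field(init=False, repr=False, default=None)
    _median_raws: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=np.int64)
        self.gsv = np.asarray(self.gsv, dtype=np.int64)
        self.validate()
        self._build_index()

    def validate(self) -> None:
        sd = self.subdomain
        if self.raw.shape != self.gsv.shape or self.raw.ndim != 1:
            raise TableValidationError("raw and gsv must be 1-d and equal length", sd)
        if not np.array_equal(self.raw, np.arange(len(self.raw))):
            raise TableValidationError(
                "raw scores must be unique and contiguous from 0", sd
            )
        steps = np.diff(self.gsv)
        if np.any(steps < 0):
            bad = int(self.raw[1:][steps < 0][0])
            raise TableValidationError(
                f"gsv decreases at raw={bad}", sd, row=bad
            )
        if self.gsv[0] != GSV_MIN:
            raise TableValidationError(
                f"minimum gsv must be {GSV_MIN}, got {self.gsv[0]}", sd
            )
        lo, hi = GSV_MAX_RANGE
        if not (lo <= self.gsv[-1] <= hi):
            raise TableValidationError(
                f"maximum gsv {self.gsv[-1]} outside [{lo}, {hi}]", sd
            )

    def _build_index(self) -> None:
        values, start = np.unique(self.gsv, return_index=True)
        # raw scores mapping to each gsv form a contiguous run; the median
        # (lower-central for even runs) is start + (run_length - 1) // 2
        end = np.r_[start[1:], len(self.gsv)]
        self._gsv_values = values
        self._median_raws = start + (end - start - 1) // 2

    @property
    def max_raw(self) -> int:
        return int(self.raw[-1])

    @property
    def gsv_min(self) -> int:
        return int(self.gsv[0])

    @property
    def gsv_max(self) -> int:
        return int(self.gsv[-1])

    @property
    def gsv_values(self) -> np.ndarray:
        """Sorted unique tabulated GSV values."""
        return self._gsv_values

    def round_to_table(self, values) -> np.ndarray:
        """Map continuous GSV values to the nearest tabulated GSV.

        Ties go to the larger tabulated value; values beyond the table
        extremes are clipped to the floor / ceiling GSV.
        """
        values = np.asarray(values, dtype=float)
        mids = (self._gsv_values[:-1] + self._gsv_values[1:]) / 2.0
        idx = np.searchsorted(mids, values, side="right")
        return self._gsv_values[idx]

    def median_raw(self, gsv_values) -> np.ndarray:
        """Median raw score for each tabulated GSV (vectorized)."""
        gsv_values = np.asarray(gsv_values, dtype=np.int64)
        idx = np.searchsorted(self._gsv_values, gsv_values)
        idx_c = np.clip(idx, 0, len(self._gsv_values) - 1)
        if np.any(self._gsv_values[idx_c] != gsv_values):
            bad = gsv_values[self._gsv_values[idx_c] != gsv_values].flat[0]
            raise TableValidationError(
                f"gsv={bad} is not tabulated", self.subdomain
            )
        return self._median_raws[idx_c]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subdomain": self.subdomain, "raw": self.raw, "gsv": self.gsv}
        )


@dataclass
class VScaleTable:
    """Age-banded raw-score -> V-scale lookup for one subdomain.

    Within each age band the raw intervals of successive v-scale values are
    disjoint, ordered and jointly cover ``[0, max_raw]``; some v-scale values
    may be unattainable in a band (no row).  For a fixed raw score the
    v-scale is nonincreasing across older age bands: the same absolute
    performance ranks lower against older peers.
    """

    subdomain: str
    frame: pd.DataFrame  # columns: age_min_months, age_max_months, vscale, raw_min, raw_max
    _bands: list = field(init=False, repr=False, default=None)
    _index: dict = field(init=False, repr=False, default=None)

    def __post_init__(self):
        cols = ["age_min_months", "age_max_months", "vscale", "raw_min", "raw_max"]
        self.frame = (
            self.frame[cols]
            .astype(np.int64)
            .sort_values(["age_min_months", "vscale"])
            .reset_index(drop=True)
        )
        self.validate()
        self._build_index()

    def validate(self) -> None:
        sd = self.subdomain
        pairs = self.frame[["age_min_months", "age_max_months"]].drop_duplicates()
        bands = [AgeBand(int(a), int(b)) for a, b in pairs.itertuples(index=False)]
        _check_age_partition(bands, sd)
        max_raws = set()
        for (lo, hi), grp in self.frame.groupby(["age_min_months", "age_max_months"]):
            v = grp["vscale"].to_numpy()
            rmin = grp["raw_min"].to_numpy()
            rmax = grp["raw_max"].to_numpy()
            if v.min() < VSCALE_MIN or v.max() > VSCALE_MAX:
                raise TableValidationError(
                    f"vscale outside [{VSCALE_MIN}, {VSCALE_MAX}] in band [{lo},{hi})", sd
                )
            if len(np.unique(v)) != len(v):
                raise TableValidationError(
                    f"duplicate vscale in band [{lo},{hi})", sd
                )
            if np.any(rmin > rmax):
                raise TableValidationError(
                    f"raw_min > raw_max in band [{lo},{hi})", sd
                )
            if rmin[0] != 0:
                raise TableValidationError(
                    f"lowest raw band does not start at 0 in band [{lo},{hi})", sd
                )
            gaps = rmin[1:] - rmax[:-1]
            if np.any(gaps != 1):
                at = int(rmax[:-1][gaps != 1][0]) + 1
                raise TableValidationError(
                    f"raw coverage broken at raw={at} in band [{lo},{hi})",
                    sd,
                    row=at,
                )
            max_raws.add(int(rmax[-1]))
        if len(max_raws) != 1:
            raise TableValidationError(
                f"age bands disagree on maximum raw: {sorted(max_raws)}", sd
            )
        # cross-age monotonicity: vscale(raw) nonincreasing with age
        self._build_index()
        max_raw = max_raws.pop()
        raws = np.arange(max_raw + 1)
        prev = None
        for band in self._bands:
            cur = self._lookup_in_band(band, raws)
            if prev is not None and np.any(cur > prev):
                bad = int(raws[cur > prev][0])
                raise TableValidationError(
                    f"vscale increases with age at raw={bad}", sd, row=bad
                )
            prev = cur

    def _build_index(self) -> None:
        self._bands = []
        self._index = {}
        for (lo, hi), grp in self.frame.groupby(["age_min_months", "age_max_months"]):
            band = AgeBand(int(lo), int(hi))
            self._bands.append(band)
            self._index[band] = (
                grp["raw_max"].to_numpy(),
                grp["vscale"].to_numpy(),
                grp["raw_min"].to_numpy(),
            )
        self._bands.sort()

    @property
    def age_bands(self) -> list[AgeBand]:
        return list(self._bands)

    @property
    def max_raw(self) -> int:
        return int(self.frame["raw_max"].max())

    def band_for_age(self, age_months: int) -> AgeBand:
        for band in self._bands:
            if band.contains(int(age_months)):
                return band
        raise TableValidationError(
            f"age {age_months} months outside supported range", self.subdomain
        )

    def _lookup_in_band(self, band: AgeBand, raws: np.ndarray) -> np.ndarray:
        raw_max, vscale, _ = self._index[band]
        idx = np.searchsorted(raw_max, raws, side="left")
        return vscale[np.clip(idx, 0, len(vscale) - 1)]

    def lookup(self, age_months, raw) -> np.ndarray:
        """Vectorized v-scale lookup for parallel arrays of ages and raws."""
        age_months = np.atleast_1d(np.asarray(age_months, dtype=np.int64))
        raw = np.atleast_1d(np.asarray(raw, dtype=np.int64))
        age_months, raw = np.broadcast_arrays(age_months, raw)
        if np.any(raw < 0) or np.any(raw > self.max_raw):
            raise TableValidationError(
                f"raw outside [0, {self.max_raw}]", self.subdomain
            )
        out = np.empty(age_months.shape, dtype=np.int64)
        seen = np.zeros(age_months.shape, dtype=bool)
        for band in self._bands:
            mask = (age_months >= band.min_months) & (age_months < band.max_months)
            if mask.any():
                out[mask] = self._lookup_in_band(band, raw[mask])
                seen |= mask
        if not seen.all():
            bad = int(age_months[~seen].flat[0])
            raise TableValidationError(
                f"age {bad} months outside supported range", self.subdomain
            )
        return out

    def band_row(self, age_months: int, vscale: int):
        """(raw_min, raw_max) of the v-scale band at an age, or None if absent."""
        band = self.band_for_age(age_months)
        raw_max, vs, raw_min = self._index[band]
        hit = np.flatnonzero(vs == vscale)
        if len(hit) == 0:
            return None
        i = hit[0]
        return int(raw_min[i]), int(raw_max[i])

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.insert(0, "subdomain", self.subdomain)
        return out


@dataclass
class SEMReliabilityTable:
    """Per-age-band GSV SEM and internal-consistency reliability."""

    subdomain: str
    frame: pd.DataFrame  # columns: age_min_months, age_max_months, sem_gsv, reliability

    def __post_init__(self):
        cols = ["age_min_months", "age_max_months", "sem_gsv", "reliability"]
        self.frame = self.frame[cols].copy()
        self.frame[["age_min_months", "age_max_months"]] = self.frame[
            ["age_min_months", "age_max_months"]
        ].astype(np.int64)
        self.frame[["sem_gsv", "reliability"]] = self.frame[
            ["sem_gsv", "reliability"]
        ].astype(float)
        self.frame = self.frame.sort_values("age_min_months").reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        sd = self.subdomain
        bands = [
            AgeBand(int(a), int(b))
            for a, b in self.frame[["age_min_months", "age_max_months"]].itertuples(
                index=False
            )
        ]
        _check_age_partition(bands, sd)
        if np.any(self.frame["sem_gsv"].to_numpy() <= 0):
            raise TableValidationError("sem_gsv must be positive", sd)
        r = self.frame["reliability"].to_numpy()
        if np.any((r <= 0) | (r >= 1)):
            raise TableValidationError("reliability must be in (0, 1)", sd)

    @property
    def age_bands(self) -> list[AgeBand]:
        return [
            AgeBand(int(a), int(b))
            for a, b in self.frame[["age_min_months", "age_max_months"]].itertuples(
                index=False
            )
        ]

    def row_for_age(self, age_months: int) -> tuple[float, float]:
        """(sem_gsv, reliability) for the band containing ``age_months``."""
        for _, row in self.frame.iterrows():
            if row["age_min_months"] <= age_months < row["age_max_months"]:
                return float(row["sem_gsv"]), float(row["reliability"])
        raise TableValidationError(
            f"no SEM/reliability row for age {age_months} months", self.subdomain
        )

    def row_for_band(self, band: AgeBand) -> tuple[float, float]:
        hit = self.frame[
            (self.frame["age_min_months"] == band.min_months)
            & (self.frame["age_max_months"] == band.max_months)
        ]
        if hit.empty:
            raise TableValidationError(
                f"no SEM/reliability row for band [{band.min_months},"
                f"{band.max_months})",
                self.subdomain,
            )
        return float(hit["sem_gsv"].iloc[0]), float(hit["reliability"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.insert(0, "subdomain", self.subdomain)
        return out


@dataclass
class TableSet:
    """The three lookup structures for a set of subdomains."""

    gsv_tables: dict[str, GSVTable]
    vscale_tables: dict[str, VScaleTable]
    sem_tables: dict[str, SEMReliabilityTable]
    provenance: str = "user-supplied"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        keys = set(self.gsv_tables)
        if keys != set(self.vscale_tables) or keys != set(self.sem_tables):
            raise TableValidationError(
                "subdomain keys differ across gsv/vscale/sem tables"
            )
        for sd in keys:
            g, v = self.gsv_tables[sd], self.vscale_tables[sd]
            if g.max_raw != v.max_raw:
                raise TableValidationError(
                    f"gsv table max raw {g.max_raw} != vscale table max raw "
                    f"{v.max_raw}",
                    sd,
                )

    @property
    def subdomains(self) -> list[str]:
        return sorted(self.gsv_tables)


# ---------------------------------------------------------------------------
# conversions

def gsv_from_raw(table: GSVTable, raw: int) -> int:
    """Exact table lookup of the GSV for a raw score."""
    raw = int(raw)
    if not 0 <= raw <= table.max_raw:
        raise TableValidationError(
            f"raw={raw} outside [0, {table.max_raw}]", table.subdomain
        )
    return int(table.gsv[raw])


def raw_from_gsv(table: GSVTable, gsv: int) -> int:
    """Median raw score among those mapping to ``gsv``.

    When an even number of raw scores share the GSV, the lower of the two
    central values is returned, keeping the result an attainable integer
    count (conservative near score floors).
    """
    return int(table.median_raw(int(gsv)))


def vscale_from_raw(table: VScaleTable, age_months: int, raw: int) -> int:
    """Norm-referenced v-scale for a raw score at a chronological age."""
    return int(table.lookup(int(age_months), int(raw))[0])


def mean_raw_for_vscale(table: VScaleTable, age_months: int, vscale: int) -> int:
    """Average raw score of a v-scale band (rounded half-up).

    Raises :class:`TableValidationError` when the band is unattainable at the
    given age, which downstream code treats as an infeasible scenario.
    """
    row = table.band_row(int(age_months), int(vscale))
    if row is None:
        raise TableValidationError(
            f"vscale={vscale} unattainable at age {age_months} months",
            table.subdomain,
        )
    raw_min, raw_max = row
    return (raw_min + raw_max + 1) // 2


# ---------------------------------------------------------------------------
# I/O

def _read_csv_strict(path, int_cols, float_cols=()):
    df = pd.read_csv(path)
    missing = set(int_cols) | set(float_cols) | {"subdomain"}
    missing -= set(df.columns)
    if missing:
        raise TableValidationError(
            f"{Path(path).name}: missing columns {sorted(missing)}"
        )
    for c in int_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any() or np.any(vals != vals.round()):
            raise TableValidationError(f"{Path(path).name}: column {c} not integer")
        df[c] = vals.astype(np.int64)
    for c in float_cols:
        df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
    return df


def load_table_set(
    gsv_path, vscale_path, sem_path, provenance: str = "user-supplied"
) -> TableSet:
    """Read and validate the three CSV tables into a :class:`TableSet`."""
    gsv_df = _read_csv_strict(gsv_path, ["raw", "gsv"])
    vs_df = _read_csv_strict(
        vscale_path,
        ["age_min_months", "age_max_months", "vscale", "raw_min", "raw_max"],
    )
    sem_df = _read_csv_strict(
        sem_path, ["age_min_months", "age_max_months"], ["sem_gsv", "reliability"]
    )
    gsv_tables = {}
    for sd, grp in gsv_df.groupby("subdomain"):
        grp = grp.sort_values("raw")
        gsv_tables[sd] = GSVTable(sd, grp["raw"].to_numpy(), grp["gsv"].to_numpy())
    vscale_tables = {
        sd: VScaleTable(sd, grp) for sd, grp in vs_df.groupby("subdomain")
    }
    sem_tables = {
        sd: SEMReliabilityTable(sd, grp) for sd, grp in sem_df.groupby("subdomain")
    }
    return TableSet(gsv_tables, vscale_tables, sem_tables, provenance=provenance)


def write_table_set(tables: TableSet, gsv_path, vscale_path, sem_path) -> None:
    """Write a TableSet back to the three CSV schemas (bit-exact round-trip)."""
    pd.concat(
        [tables.gsv_tables[sd].to_frame() for sd in tables.subdomains]
    ).to_csv(gsv_path, index=False)
    pd.concat(
        [tables.vscale_tables[sd].to_frame() for sd in tables.subdomains]
    ).to_csv(vscale_path, index=False)
    pd.concat(
        [tables.sem_tables[sd].to_frame() for sd in tables.subdomains]
    ).to_csv(sem_path, index=False)
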