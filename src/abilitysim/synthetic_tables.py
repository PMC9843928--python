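"""Synthetic lookup-table generator.

The real instrument's conversion tables are copyrighted, so this module
builds structurally faithful stand-ins: for each subdomain a saturating
logistic developmental curve gives the median raw score at each age; V-scale
bands per normative age band are normal-quantile cuts of the age-specific
raw-score distribution mapped onto the discrete mean-15/SD-3 scale with
floor 1; the raw -> GSV map is a monotone linear/logit blend from the GSV
floor of 10 up to a subdomain-specific maximum; SEM is drawn per age band
within a configured range, with reliability tied to it by classical test
theory so that the SEM-implied GSV SD matches the normative within-age SD.

Default growth-curve parameters are spread so that language- and motor-like
subdomains saturate early (producing wide v-scale=1 bands — strong floors —
by adolescence) while academic-like subdomains saturate late (so low
v-scale values are unattainable at preschool ages and the corresponding
scenarios are infeasible, as with the real instrument).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .score_tables import (
    GSVTable,
    SEMReliabilityTable,
    TableSet,
    TableValidationError,
    VScaleTable,
    VSCALE_MAX,
)

__all__ = ["SynthConfig", "generate_table_set", "validate_table_set"]

# Vineland-like subdomain names with (growth midpoint months, growth rate /month).
# Midpoint = age at which the median child attains half the maximum raw score.
_DEFAULT_SUBDOMAINS = (
    ("receptive", 30.0, 0.070),
    ("expressive", 42.0, 0.050),
    ("written", 166.0, 0.020),
    ("personal", 72.0, 0.030),
    ("domestic", 144.0, 0.022),
    ("community", 132.0, 0.024),
    ("interpersonal", 60.0, 0.040),
    ("play_leisure", 54.0, 0.045),
    ("coping", 96.0, 0.028),
    ("gross_motor", 24.0, 0.090),
    ("fine_motor", 36.0, 0.060),
)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic table generator.

    ``within_age_raw_sd`` is the SD of the raw-score distribution at a given
    age, expressed as a fraction of the subdomain's maximum raw score; one
    v-scale unit then spans a third of that SD.  ``growth_midpoints`` /
    ``growth_rates`` default to the built-in spread of 11 subdomains; when
    ``n_subdomains`` differs they are respaced over the same envelope.

    ``age_support`` extends one band past the oldest study age range so that
    6-month-endpoint ages of participants enrolled at the top of the range
    still fall inside a normative band.
    """

    n_subdomains: int = 11
    max_raw_range: tuple[int, int] = (60, 160)
    age_support: tuple[int, int] = (24, 240)
    band_width: int = 12
    growth_midpoints: tuple[float, ...] | None = None
    growth_rates: tuple[float, ...] | None = None
    within_age_raw_sd: float = 0.12
    gsv_max_range: tuple[int, int] = (110, 197)
    sem_range: tuple[float, float] = (2.0, 9.0)
    reliability_range: tuple[float, float] = (0.69, 0.97)
    seed: int = 0

    def __post_init__(self):
        if self.n_subdomains < 1:
            raise ValueError("n_subdomains must be >= 1")
        for name in ("max_raw_range", "gsv_max_range", "sem_range",
                     "reliability_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        lo, hi = self.age_support
        if (hi - lo) % self.band_width != 0 or hi <= lo:
            raise ValueError(
                "band_width must evenly divide the age support span"
            )
        if not 0 < self.within_age_raw_sd < 1:
            raise ValueError("within_age_raw_sd must be a fraction in (0, 1)")

    def resolve_subdomains(self) -> list[tuple[str, float, float]]:
        """(name, growth_midpoint, growth_rate) per subdomain."""
        if self.n_subdomains == len(_DEFAULT_SUBDOMAINS) and (
            self.growth_midpoints is None and self.growth_rates is None
        ):
            return list(_DEFAULT_SUBDOMAINS)
        n = self.n_subdomains
        if self.growth_midpoints is not None:
            mids = list(self.growth_midpoints)
        else:
            mids = list(np.linspace(24.0, 166.0, n))
        if self.growth_rates is not None:
            rates = list(self.growth_rates)
        else:
            rates = list(np.geomspace(0.09, 0.02, n))
        if len(mids) != n or len(rates) != n:
            raise ValueError(
                "growth_midpoints / growth_rates must match n_subdomains"
            )
        names = [f"subdomain_{i + 1:02d}" for i in range(n)]
        return list(zip(names, mids, rates))

    @property
    def age_bands(self) -> list[tuple[int, int]]:
        lo, hi = self.age_support
        edges = list(range(lo, hi + 1, self.band_width))
        return list(zip(edges[:-1], edges[1:]))


def _logistic_median_raw(age: float, midpoint: float, rate: float,
                         max_raw: int) -> float:
    return max_raw / (1.0 + np.exp(-rate * (age - midpoint)))


def _build_gsv_curve(max_raw: int, gsv_max: int) -> np.ndarray:
    """Monotone raw -> GSV map from 10 to gsv_max.

    A linear ramp blended with a logit curve: the ability metric stretches
    at the raw-score extremes (Rasch-like) while the slope in the bulk stays
    near the mean GSV-per-raw slope, so that one normative raw-score SD
    spans about one normative GSV SD everywhere on the scale.
    """
    x = (np.arange(max_raw + 1) + 0.5) / (max_raw + 1)
    logit = np.log(x / (1.0 - x))
    curve = (logit - logit[0]) / (logit[-1] - logit[0])
    linear = np.arange(max_raw + 1) / max_raw
    g = 10 + (gsv_max - 10) * (0.75 * linear + 0.25 * curve)
    g = np.round(g).astype(np.int64)
    return np.maximum.accumulate(g)


def _build_vscale_rows(max_raw: int, sd_raw: float, band_edges,
                       mid_age_raw) -> pd.DataFrame:
    """Quantile-cut v-scale bands per age band, partitioning [0, max_raw]."""
    rows = []
    for (lo, hi), m in zip(band_edges, mid_age_raw):
        # upper raw cut for each v-scale value v: the raw at z = (v + .5 - 15)/3
        z_upper = (np.arange(1, VSCALE_MAX + 1) + 0.5 - 15.0) / 3.0
        cuts = np.round(m + sd_raw * z_upper).astype(np.int64)
        cuts = np.clip(cuts, -1, max_raw)
        cuts = np.maximum.accumulate(cuts)
        cuts[-1] = max_raw
        prev = -1
        for v, u in zip(range(1, VSCALE_MAX + 1), cuts):
            if u >= prev + 1:
                rows.append((lo, hi, v, prev + 1, int(u)))
            prev = max(prev, int(u))
    return pd.DataFrame(
        rows,
        columns=["age_min_months", "age_max_months", "vscale",
                 "raw_min", "raw_max"],
    )


def generate_table_set(config: SynthConfig | None = None) -> TableSet:
    """Generate a validated synthetic :class:`~abilitysim.score_tables.TableSet`.

    Deterministic given ``config.seed``: the seed drives the per-subdomain
    maximum raw score, GSV maximum, and the per-age-band SEM and reliability
    draws; the developmental curves themselves are fixed by the config.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    band_edges = config.age_bands
    midpoints = [(lo + hi) / 2.0 for lo, hi in band_edges]

    gsv_tables, vscale_tables, sem_tables = {}, {}, {}
    for name, mid, rate in config.resolve_subdomains():
        max_raw = int(rng.integers(config.max_raw_range[0],
                                   config.max_raw_range[1] + 1))
        gsv_max = int(rng.integers(config.gsv_max_range[0],
                                   config.gsv_max_range[1] + 1))
        sd_raw = config.within_age_raw_sd * max_raw
        mid_age_raw = [
            _logistic_median_raw(a, mid, rate, max_raw) for a in midpoints
        ]
        gsv_tables[name] = GSVTable(
            name, np.arange(max_raw + 1), _build_gsv_curve(max_raw, gsv_max)
        )
        vs_frame = _build_vscale_rows(max_raw, sd_raw, band_edges, mid_age_raw)
        vscale_tables[name] = VScaleTable(name, vs_frame)
        # Classical test theory ties the three quantities: SEM = SD sqrt(1-r),
        # where SD is the normative within-age population SD on the GSV scale
        # (the raw-score SD times the mean GSV-per-raw slope).  SEM is drawn
        # per band within sem_range, restricted so the implied reliability
        # lands inside reliability_range; drawing SEM and reliability
        # independently instead would make the generative SD inconsistent
        # with the v-scale band widths (the norm population would no longer
        # have SD 3 on its own v-scale).
        sd_gsv = config.within_age_raw_sd * (gsv_max - 10)
        rel_lo, rel_hi = config.reliability_range
        sem_lo = max(config.sem_range[0], sd_gsv * np.sqrt(1.0 - rel_hi))
        sem_hi = min(config.sem_range[1], sd_gsv * np.sqrt(1.0 - rel_lo))
        if not sem_lo < sem_hi:
            raise TableValidationError(
                f"sem_range and reliability_range are jointly infeasible for "
                f"normative SD {sd_gsv:.1f}",
                name,
            )
        sem = rng.uniform(sem_lo, sem_hi, len(band_edges))
        sem_tables[name] = SEMReliabilityTable(
            name,
            pd.DataFrame(
                {
                    "age_min_months": [lo for lo, _ in band_edges],
                    "age_max_months": [hi for _, hi in band_edges],
                    "sem_gsv": sem,
                    "reliability": 1.0 - (sem / sd_gsv) ** 2,
                }
            ),
        )
    return TableSet(gsv_tables, vscale_tables, sem_tables, provenance="synthetic")


def validate_table_set(tables: TableSet) -> list[str]:
    """Re-run every structural invariant; return violations (empty = valid).

    Unlike the constructors, this never raises, so it can be used to report
    on hand-edited or user-supplied tables.
    """
    report: list[str] = []
    try:
        tables.validate()
    except TableValidationError as exc:
        report.append(str(exc))
    for group in (tables.gsv_tables, tables.vscale_tables, tables.sem_tables):
        for table in group.values():
            try:
                table.validate()
            except TableValidationError as exc:
                report.append(str(exc))
    return report
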