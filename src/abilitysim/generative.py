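"""Generative parameters and design-planning arithmetic.

A scenario (age range x impairment level x subdomain x effect condition) is
turned into the parameters of the bivariate-normal GSV generator:

* the mean is obtained through the table chain
  midpoint age -> target v-scale -> average raw of its band -> GSV;
* the SD pools the normative age bands overlapping the design age range,
  converting each band's SEM and reliability to an SD via
  ``SD = SEM / sqrt(1 - r)`` and combining bands with the mixture variance
  ``sum(w s^2) + (sum(w m^2) - (sum(w m))^2)``;
* the treatment shift is ``0.8 * SD`` (Cohen's d = 0.8) or zero.

The planning arithmetic reproduces the study design: a two-arm trial needs
66 participants for 90% power at d = 0.8 and two-sided alpha = .05 (normal
approximation), reduced by the factor ``1 - rho^2`` for the baseline
covariate (rho = 0.8), giving N = 24 with balanced arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .score_tables import (
    AgeBand,
    TableSet,
    TableValidationError,
    gsv_from_raw,
    mean_raw_for_vscale,
)

__all__ = [
    "AGE_RANGES",
    "IMPAIRMENT_VSCALE",
    "Scenario",
    "GenerativeParams",
    "BandWeights",
    "DesignConfig",
    "InfeasibleScenarioError",
    "sd_from_sem",
    "mixture_variance",
    "band_weights",
    "scenario_mean_gsv",
    "scenario_sigma",
    "treatment_delta",
    "required_total_n",
    "ancova_adjusted_n",
    "build_generative_params",
    "ancova_power",
]

#: Study age ranges in years; (min, max) inclusive of the max year, so the
#: month interval is [min*12, (max+1)*12) and its midpoints are 60 and 174
#: months ("5 years, 0 months" and "14 years, 6 months").
AGE_RANGES: dict[tuple[int, int], tuple[int, int]] = {
    (3, 6): (36, 84),
    (12, 16): (144, 204),
}

#: Impairment level (SD below the normative mean) -> target v-scale score.
IMPAIRMENT_VSCALE: dict[int, int] = {1: 12, 2: 9, 3: 6, 4: 3, 5: 1}

EFFECT_CONDITIONS = ("large", "zero")


class InfeasibleScenarioError(ValueError):
    """The score tables cannot realize this scenario (e.g. v-scale band absent)."""


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation design grid."""

    age_range: tuple[int, int]
    impairment_sd: int
    subdomain: str
    effect_condition: str = "large"

    def __post_init__(self):
        if tuple(self.age_range) not in AGE_RANGES:
            raise ValueError(f"unsupported age range {self.age_range}")
        if self.impairment_sd not in IMPAIRMENT_VSCALE:
            raise ValueError(f"impairment_sd must be in 1..5, got {self.impairment_sd}")
        if self.effect_condition not in EFFECT_CONDITIONS:
            raise ValueError(f"effect_condition must be one of {EFFECT_CONDITIONS}")

    @property
    def months_range(self) -> tuple[int, int]:
        return AGE_RANGES[tuple(self.age_range)]

    @property
    def midpoint_age_months(self) -> int:
        lo, hi = self.months_range
        return (lo + hi) // 2

    @property
    def target_vscale(self) -> int:
        return IMPAIRMENT_VSCALE[self.impairment_sd]

    @property
    def label(self) -> str:
        a, b = self.age_range
        return f"{a}-{b}y/imp{self.impairment_sd}/{self.subdomain}/{self.effect_condition}"


@dataclass(frozen=True)
class GenerativeParams:
    """Bivariate-normal GSV generator parameters for one scenario.

    ``mu_gsv`` is the shared baseline and placebo-endpoint mean, ``sigma_gsv``
    the mixture SD, ``rho`` the within-subject baseline/endpoint correlation
    and ``delta`` the endpoint mean shift in the treatment arm.
    """

    mu_gsv: float
    sigma_gsv: float
    rho: float
    delta: float

    def __post_init__(self):
        if self.sigma_gsv <= 0:
            raise ValueError("sigma_gsv must be positive")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")


@dataclass(frozen=True)
class BandWeights:
    """Proportional coverage of normative age bands by a design age range."""

    entries: tuple[tuple[AgeBand, float], ...]

    def __post_init__(self):
        w = np.array([e[1] for e in self.entries])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def bands(self) -> list[AgeBand]:
        return [b for b, _ in self.entries]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.entries])


@dataclass(frozen=True)
class DesignConfig:
    """Study-design constants: effect size, alpha, target power, correlation."""

    d: float = 0.80
    alpha: float = 0.05
    target_power: float = 0.90
    rho: float = 0.8
    followup_months: int = 6
    n_total: int | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.target_power < 1:
            raise ValueError("alpha and target_power must be in (0, 1)")
        if self.n_total is None:
            n = ancova_adjusted_n(
                required_total_n(self.d, self.alpha, self.target_power), self.rho
            )
            object.__setattr__(self, "n_total", n)
        if self.n_total % 2:
            raise ValueError("n_total must be even (balanced arms)")


# ---------------------------------------------------------------------------
# arithmetic

def sd_from_sem(sem: float, reliability: float) -> float:
    """SD of the score distribution implied by its SEM: SEM / sqrt(1 - r)."""
    if sem <= 0:
        raise ValueError("sem must be positive")
    if not 0 <= reliability < 1:
        raise ValueError("reliability must be in [0, 1)")
    return sem / math.sqrt(1.0 - reliability)


def mixture_variance(weights, means, variances) -> float:
    """Variance of a mixture: sum(w s^2) + (sum(w m^2) - (sum(w m))^2)."""
    w = np.asarray(weights, dtype=float)
    m = np.asarray(means, dtype=float)
    v = np.asarray(variances, dtype=float)
    if not (w.shape == m.shape == v.shape):
        raise ValueError("weights, means and variances must have equal length")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return float(w @ v + (w @ m**2 - (w @ m) ** 2))


def band_weights(months_range: tuple[int, int], bands: list[AgeBand]) -> BandWeights:
    """Weight each age band by its months of overlap with the design range."""
    lo, hi = months_range
    entries = []
    covered = 0
    for band in sorted(bands):
        ov = band.overlap_months(lo, hi)
        if ov > 0:
            entries.append((band, ov))
            covered += ov
    if covered != hi - lo:
        raise TableValidationError(
            f"age bands do not cover the range [{lo}, {hi}) months"
        )
    total = hi - lo
    return BandWeights(tuple((b, ov / total) for b, ov in entries))


def _chain_mean_gsv(tables: TableSet, subdomain: str, age_months: int,
                    target_vscale: int) -> float:
    try:
        raw = mean_raw_for_vscale(
            tables.vscale_tables[subdomain], age_months, target_vscale
        )
        return float(gsv_from_raw(tables.gsv_tables[subdomain], raw))
    except TableValidationError as exc:
        raise InfeasibleScenarioError(str(exc)) from exc


def scenario_mean_gsv(tables: TableSet, scenario: Scenario) -> float:
    """Generative mean GSV: midpoint age -> target v-scale -> mean raw -> GSV."""
    return _chain_mean_gsv(
        tables, scenario.subdomain, scenario.midpoint_age_months,
        scenario.target_vscale,
    )


def scenario_sigma(tables: TableSet, scenario: Scenario) -> float:
    """Generative SD: mixture over the age bands spanned by the age range.

    Each overlapping band contributes its SEM-derived SD and the table-chain
    mean evaluated at the band's midpoint age; weights are proportional
    months of overlap.
    """
    sem_table = tables.sem_tables[scenario.subdomain]
    bw = band_weights(scenario.months_range, sem_table.age_bands)
    means, variances = [], []
    for band in bw.bands:
        sem, rel = sem_table.row_for_band(band)
        variances.append(sd_from_sem(sem, rel) ** 2)
        means.append(
            _chain_mean_gsv(
                tables, scenario.subdomain, int(band.midpoint),
                scenario.target_vscale,
            )
        )
    return math.sqrt(mixture_variance(bw.weights, means, variances))


def treatment_delta(sigma: float, condition: str) -> float:
    """Endpoint mean shift: 0.8 * sigma under 'large', 0 under 'zero'."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if condition not in EFFECT_CONDITIONS:
        raise ValueError(f"condition must be one of {EFFECT_CONDITIONS}")
    return 0.8 * sigma if condition == "large" else 0.0


def build_generative_params(
    tables: TableSet, scenario: Scenario, design: DesignConfig
) -> GenerativeParams:
    """Assemble mu, sigma, rho and delta for one scenario."""
    sigma = scenario_sigma(tables, scenario)
    return GenerativeParams(
        mu_gsv=scenario_mean_gsv(tables, scenario),
        sigma_gsv=sigma,
        rho=design.rho,
        delta=treatment_delta(sigma, scenario.effect_condition),
    )


def _even_ceil(x: float) -> int:
    n = math.ceil(x - 1e-12)
    return n + (n % 2)


def required_total_n(d: float, alpha: float, power: float) -> int:
    """Total N for a two-sample comparison (normal approximation).

    ``4 (z_{1-alpha/2} + z_{power})^2 / d^2``, rounded up to an even total
    for balanced arms.  At d = 0.8, alpha = .05, power = .90 this gives 66.
    """
    if d <= 0 or not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("need d > 0 and alpha, power in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return _even_ceil(4 * z**2 / d**2)


def ancova_adjusted_n(n_total: int, rho: float) -> int:
    """Reduce N by the factor 1 - rho^2 for a baseline covariate; even-ceil."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    return _even_ceil(n_total * (1.0 - rho**2))


# ---------------------------------------------------------------------------
# analytic power

def ancova_power(
    d: float,
    rho: float,
    n_per_arm: int,
    alpha: float = 0.05,
    random_covariate: bool = True,
) -> float:
    """Closed-form power of the two-arm ANCOVA with a baseline covariate.

    The residual SD after adjusting for baseline is ``sigma sqrt(1 - rho^2)``,
    so the adjusted standardized effect is ``d' = d / sqrt(1 - rho^2)`` with
    noncentrality ``d' sqrt(n/2)`` on n_total - 3 degrees of freedom.  With
    ``random_covariate=True`` (the default, matching simulation) the power is
    averaged over the F(1, N-2) distribution of chance baseline imbalance
    between arms, which inflates the arm-coefficient variance by
    ``1 + F/(N-2)``; the fixed-covariate formula ignores this and overstates
    power by roughly 1.5 points at N = 24.
    """
    n_total = 2 * n_per_arm
    df = n_total - 3
    dprime = d / math.sqrt(1.0 - rho**2)
    ncp0 = dprime * math.sqrt(n_per_arm / 2.0)
    crit = stats.t.ppf(1 - alpha / 2, df)

    def _power(ncp):
        return stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)

    if not random_covariate:
        return float(_power(ncp0))

    def integrand(f):
        r2 = f / (f + (n_total - 2))
        return _power(ncp0 * math.sqrt(1.0 - r2)) * stats.f.pdf(f, 1, n_total - 2)

    value, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return float(value)
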