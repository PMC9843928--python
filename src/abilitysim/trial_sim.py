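"""Simulation of one parallel-arm trial dataset (and vectorized batches).

Each simulated participant has a baseline and a 6-month-endpoint GSV drawn
from a bivariate normal (common SD, within-subject correlation rho; the
treatment arm's endpoint mean is shifted by delta), a baseline age drawn
uniformly in months over the design age range, and v-scale scores obtained
by pushing each GSV back through the lookup tables: round to the nearest
tabulated GSV (ties up, clipped to the table extremes), take the median raw
score for that GSV, then look up the v-scale for the participant's age at
that timepoint.

The GSV endpoint analysis uses the continuous drawn values; the tabulated
(rounded) GSVs are retained alongside for floor classification.  The
v-scale columns are a deterministic function of (gsv, age, tables) and the
GSV analysis path never consults the v-scale table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generative import DesignConfig, GenerativeParams, Scenario
from .score_tables import TableSet

__all__ = [
    "TrialDataset",
    "draw_correlated_pairs",
    "draw_ages",
    "gsv_to_vscale",
    "simulate_trial",
    "simulate_trial_batch",
]

PBO, TRT = 0, 1


@dataclass
class TrialDataset:
    """Per-participant records of one simulated trial."""

    subdomain: str
    arm: np.ndarray  # 0 = placebo, 1 = active
    age_baseline_months: np.ndarray
    age_endpoint_months: np.ndarray
    gsv_baseline: np.ndarray  # continuous draws
    gsv_endpoint: np.ndarray
    gsv_baseline_tab: np.ndarray  # rounded to tabulated GSV
    gsv_endpoint_tab: np.ndarray
    vscale_baseline: np.ndarray
    vscale_endpoint: np.ndarray
    gsv_min: int

    @property
    def n_total(self) -> int:
        return len(self.arm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arm": np.where(self.arm == TRT, "TRT", "PBO"),
                "age_b": self.age_baseline_months,
                "age_e": self.age_endpoint_months,
                "gsv_b": self.gsv_baseline,
                "gsv_e": self.gsv_endpoint,
                "vscale_b": self.vscale_baseline,
                "vscale_e": self.vscale_endpoint,
            }
        )


def draw_correlated_pairs(mu_b, mu_e, sigma, rho, n, rng) -> np.ndarray:
    """n i.i.d. bivariate-normal (baseline, endpoint) pairs, shape (n, 2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    z = rng.standard_normal((n, 2))
    b = mu_b + sigma * z[:, 0]
    e = mu_e + sigma * (rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1])
    return np.column_stack([b, e])


def draw_ages(months_range, n, followup_months, rng):
    """Baseline ages uniform on the integer months of [lo, hi); endpoint = +followup."""
    lo, hi = months_range
    if hi <= lo:
        raise ValueError("empty age range")
    baseline = rng.integers(lo, hi, size=n)
    return baseline, baseline + followup_months


def gsv_to_vscale(tables: TableSet, subdomain: str, gsv_value, age_months):
    """Convert continuous GSV to (v-scale, at_floor) at a given age.

    Accepts scalars or arrays.  ``at_floor`` flags the v-scale minimum of 1.
    """
    gsv_table = tables.gsv_tables[subdomain]
    scalar = np.isscalar(gsv_value) and np.isscalar(age_months)
    tab = gsv_table.round_to_table(np.atleast_1d(gsv_value))
    raw = gsv_table.median_raw(tab)
    vs = tables.vscale_tables[subdomain].lookup(np.atleast_1d(age_months), raw)
    if scalar:
        return int(vs[0]), bool(vs[0] == 1)
    return vs, vs == 1


def simulate_trial_batch(
    params: GenerativeParams,
    design: DesignConfig,
    scenario: Scenario,
    tables: TableSet,
    rng,
    n_reps: int,
    convert_vscale: bool = True,
) -> dict[str, np.ndarray]:
    """Vectorized simulation of ``n_reps`` trials; arrays shaped (n_reps, N).

    Participants 0..N/2-1 are placebo, the rest active treatment.  Returns
    continuous and tabulated GSVs and (optionally) the v-scale conversions.
    """
    n = design.n_total
    arm = np.zeros(n, dtype=np.int64)
    arm[n // 2:] = TRT
    mu_e = params.mu_gsv + params.delta * arm

    z = rng.standard_normal((n_reps, n, 2))
    gsv_b = params.mu_gsv + params.sigma_gsv * z[:, :, 0]
    gsv_e = mu_e[None, :] + params.sigma_gsv * (
        params.rho * z[:, :, 0] + np.sqrt(1 - params.rho**2) * z[:, :, 1]
    )
    lo, hi = scenario.months_range
    age_b = rng.integers(lo, hi, size=(n_reps, n))
    age_e = age_b + design.followup_months

    gsv_table = tables.gsv_tables[scenario.subdomain]
    out = {
        "arm": arm,
        "age_b": age_b,
        "age_e": age_e,
        "gsv_b": gsv_b,
        "gsv_e": gsv_e,
        "gsv_b_tab": gsv_table.round_to_table(gsv_b),
        "gsv_e_tab": gsv_table.round_to_table(gsv_e),
        "gsv_min": gsv_table.gsv_min,
    }
    if convert_vscale:
        vs_table = tables.vscale_tables[scenario.subdomain]
        raw_b = gsv_table.median_raw(out["gsv_b_tab"].ravel())
        raw_e = gsv_table.median_raw(out["gsv_e_tab"].ravel())
        out["vscale_b"] = vs_table.lookup(age_b.ravel(), raw_b).reshape(age_b.shape)
        out["vscale_e"] = vs_table.lookup(age_e.ravel(), raw_e).reshape(age_e.shape)
    return out


def simulate_trial(
    params: GenerativeParams,
    design: DesignConfig,
    scenario: Scenario,
    tables: TableSet,
    rng,
) -> TrialDataset:
    """Simulate a single trial dataset (thin wrapper over the batched path)."""
    batch = simulate_trial_batch(
        params, design, scenario, tables, rng, n_reps=1, convert_vscale=True
    )
    return TrialDataset(
        subdomain=scenario.subdomain,
        arm=batch["arm"],
        age_baseline_months=batch["age_b"][0],
        age_endpoint_months=batch["age_e"][0],
        gsv_baseline=batch["gsv_b"][0],
        gsv_endpoint=batch["gsv_e"][0],
        gsv_baseline_tab=batch["gsv_b_tab"][0],
        gsv_endpoint_tab=batch["gsv_e_tab"][0],
        vscale_baseline=batch["vscale_b"][0],
        vscale_endpoint=batch["vscale_e"][0],
        gsv_min=batch["gsv_min"],
    )
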