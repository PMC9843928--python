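"""ANCOVA inference with floor-effect and degenerate-fit handling.

Each simulated trial is analyzed with a linear model of the endpoint score
on an intercept, the treatment-arm indicator and the baseline score; the
two-sided p-value for the arm coefficient uses the t distribution with
N - 3 degrees of freedom.  Fits are flagged degenerate when the design
matrix is rank-deficient (constant baseline, or baseline collinear with
arm) or the residual variance is zero — the situations in which the model
cannot be estimated, as happens under complete floor effects.  Degenerate
fits and replications where a whole arm sits at the scale floor at both
timepoints are coded as failures to reject the null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "FitResult",
    "fit_ancova",
    "fit_ancova_batch",
    "classify_floor",
    "decide_rejection",
]

FLOOR_CLASSES = ("none", "pbo_floor", "trt_floor", "both_floor")


@dataclass(frozen=True)
class FitResult:
    """Arm-coefficient inference from one ANCOVA fit."""

    scale: str  # "GSV" or "VScale"
    beta_group: float
    se: float
    t_stat: float
    p_value: float
    status: str = "ok"  # "ok" or "degenerate"
    floor_class: str = "none"


def fit_ancova_batch(endpoint: np.ndarray, baseline: np.ndarray,
                     arm: np.ndarray) -> dict[str, np.ndarray]:
    """Closed-form least squares for many replications at once.

    ``endpoint`` and ``baseline`` are (n_reps, N); ``arm`` is a shared 0/1
    indicator of length N.  Returns per-replication arrays ``beta``, ``se``,
    ``t``, ``p`` and a boolean ``degenerate`` mask (rank-deficient design or
    zero residual variance; their ``p`` is NaN).
    """
    e = np.asarray(endpoint, dtype=float)
    b = np.asarray(baseline, dtype=float)
    if e.ndim == 1:
        e, b = e[None, :], b[None, :]
    arm = np.asarray(arm, dtype=float)
    n = arm.shape[0]
    if e.shape != b.shape or e.shape[1] != n:
        raise ValueError("endpoint, baseline and arm shapes are inconsistent")
    if n < 6:
        raise ValueError("need at least 6 participants")
    if len(np.unique(arm)) != 2:
        raise ValueError("both arms must be present")
    df = n - 3

    zc = arm - arm.mean()
    szz = float(zc @ zc)
    bc = b - b.mean(axis=1, keepdims=True)
    ec = e - e.mean(axis=1, keepdims=True)
    szb = bc @ zc
    sbb = np.einsum("ij,ij->i", bc, bc)
    szy = ec @ zc
    sby = np.einsum("ij,ij->i", ec, bc)
    syy = np.einsum("ij,ij->i", ec, ec)

    det = szz * sbb - szb**2
    # rank deficiency: constant baseline, or baseline collinear with arm
    b_scale = n * np.maximum(np.einsum("ij,ij->i", b, b) / n, 1.0)
    scale_det = szz * np.maximum(sbb, 1e-300)
    degenerate = (sbb <= 1e-12 * b_scale) | (det <= 1e-12 * scale_det)

    det_safe = np.where(degenerate, 1.0, det)
    beta = (szy * sbb - szb * sby) / det_safe
    gamma = (szz * sby - szb * szy) / det_safe
    rss = syy - beta * szy - gamma * sby
    rss = np.maximum(rss, 0.0)
    # zero residual variance: endpoint an exact linear function of the design
    degenerate |= rss <= 1e-12 * np.maximum(syy, 1e-30)
    s2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2 * sbb / det_safe)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    for a in (se, t, p):
        a[degenerate] = np.nan
    return {"beta": beta, "se": se, "t": t, "p": p, "degenerate": degenerate}


def fit_ancova(endpoint, baseline, arm, scale: str = "GSV") -> FitResult:
    """ANCOVA of a single dataset; see :func:`fit_ancova_batch`."""
    endpoint = np.asarray(endpoint, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if endpoint.shape != baseline.shape or endpoint.ndim != 1:
        raise ValueError("endpoint and baseline must be 1-d of equal length")
    res = fit_ancova_batch(endpoint[None, :], baseline[None, :], arm)
    degenerate = bool(res["degenerate"][0])
    return FitResult(
        scale=scale,
        beta_group=float(res["beta"][0]),
        se=float(res["se"][0]),
        t_stat=float(res["t"][0]),
        p_value=float(res["p"][0]),
        status="degenerate" if degenerate else "ok",
    )


def _arm_at_floor(values_b, values_e, floor, timepoints: str) -> bool:
    at_b = np.all(values_b == floor)
    at_e = np.all(values_e == floor)
    return bool(at_b and at_e) if timepoints == "both" else bool(at_e)


def classify_floor(dataset, scale: str = "VScale",
                   timepoints: str = "both") -> str:
    """Complete-floor classification of a trial dataset.

    An arm is at complete floor when every member scores the scale minimum —
    by default at both timepoints (``timepoints="endpoint"`` relaxes to the
    endpoint only).  The v-scale floor is 1; the GSV floor is the tabulated
    minimum GSV of the subdomain, assessed on the rounded (tabulated) GSVs.
    """
    if timepoints not in ("both", "endpoint"):
        raise ValueError("timepoints must be 'both' or 'endpoint'")
    if scale == "VScale":
        vb, ve, floor = dataset.vscale_baseline, dataset.vscale_endpoint, 1
    elif scale == "GSV":
        vb, ve = dataset.gsv_baseline_tab, dataset.gsv_endpoint_tab
        floor = dataset.gsv_min
    else:
        raise ValueError("scale must be 'GSV' or 'VScale'")
    pbo = dataset.arm == 0
    pbo_floor = _arm_at_floor(vb[pbo], ve[pbo], floor, timepoints)
    trt_floor = _arm_at_floor(vb[~pbo], ve[~pbo], floor, timepoints)
    if pbo_floor and trt_floor:
        return "both_floor"
    if pbo_floor:
        return "pbo_floor"
    if trt_floor:
        return "trt_floor"
    return "none"


def decide_rejection(fit: FitResult, alpha: float = 0.05) -> bool:
    """Reject iff the fit is non-degenerate, floor-free and p < alpha (strict)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if fit.status != "ok" or fit.floor_class != "none":
        return False
    return bool(fit.p_value < alpha)


def attach_floor(fit: FitResult, floor_class: str) -> FitResult:
    """Return a copy of ``fit`` annotated with a floor classification."""
    if floor_class not in FLOOR_CLASSES:
        raise ValueError(f"floor_class must be one of {FLOOR_CLASSES}")
    return replace(fit, floor_class=floor_class)
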