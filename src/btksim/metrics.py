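"""Summary statistics on occupancy distributions and ED90 estimation.

The dose-response endpoint is the proportion of subjects whose intrinsic
trough occupancy exceeds 90% (strict inequality).  ED90 is the dose at which
a fitted sigmoid Emax (Hill) curve reaches 90% of its own plateau,

    p(d) = pmax * d^h / (d50^h + d^h),   ED90 = d50 * 9^(1/h),

with the plateau ``pmax`` left free because the curves' asymptotes differ
between turnover scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseCurve",
    "Ed90Estimate",
    "EstimationError",
    "summarize",
    "hill",
    "fit_hill",
    "estimate_ed90",
    "ed90_from_sweep",
    "curve_difference",
]


class EstimationError(RuntimeError):
    """Raised when a dose-response fit fails or is unusable."""


@dataclass
class DoseResponseCurve:
    """Proportion of responders (>90% occupancy) versus dose.

    ``n_subjects`` (subjects per dose) enables binomial weighting of fits.
    """

    doses: np.ndarray        # mg
    proportions: np.ndarray  # fraction in [0, 1]
    scenario: str = ""
    percentile: int | None = None
    n_subjects: int | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.doses.shape != self.proportions.shape:
            raise ValueError("doses and proportions must have equal length")
        if np.any((self.proportions < 0) | (self.proportions > 1)):
            raise ValueError("proportions must lie in [0, 1]")


@dataclass
class Ed90Estimate:
    """ED90 with its uncertainty interval and the fitted Hill parameters."""

    ed90: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    pmax: float = float("nan")
    d50: float = float("nan")
    hill_coef: float = float("nan")
    scenario: str = ""


def summarize(occupancies, grid_occupancies=None) -> dict[str, float]:
    """Median, 5th/95th percentiles and responder proportion of a distribution.

    ``grid_occupancies`` may be a mapping of uncertainty-percentile label to
    occupancy array; if given, the 5th-95th spread of the responder
    proportion (and median) across those scenarios is reported as well.
    """
    occ = np.asarray(occupancies, dtype=float)
    if occ.size == 0:
        raise ValueError("empty occupancy distribution")
    out = {
        "median": float(np.median(occ)),
        "p5": float(np.percentile(occ, 5)),
        "p95": float(np.percentile(occ, 95)),
        "prop_gt90": 100.0 * float(np.mean(occ > 90.0)),
    }
    if grid_occupancies is not None:
        props = [100.0 * float(np.mean(np.asarray(o) > 90.0))
                 for o in grid_occupancies.values()]
        medians = [float(np.median(np.asarray(o))) for o in grid_occupancies.values()]
        out["prop_gt90_p5"] = float(np.min(props))
        out["prop_gt90_p95"] = float(np.max(props))
        out["median_p5"] = float(np.min(medians))
        out["median_p95"] = float(np.max(medians))
    return out


def hill(d, pmax, d50, h):
    """Sigmoid Emax: pmax * d^h / (d50^h + d^h)."""
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d50 / np.maximum(d, 1e-300)) ** h, np.inf)
    return pmax / (1.0 + ratio)


def fit_hill(doses, proportions, n_subjects=None) -> tuple[float, float, float]:
    """Least-squares Hill fit; returns (pmax, d50, h).

    When ``n_subjects`` is given, residuals are weighted by the binomial
    standard error ``sqrt(p(1-p)/n)`` (floored near the 0/1 boundaries), the
    natural weighting for responder proportions - it lets the precisely
    determined plateau points anchor pmax.
    """
    doses = np.asarray(doses, dtype=float)
    props = np.asarray(proportions, dtype=float)
    if doses.size < 5:
        raise EstimationError("need at least 5 doses to fit the dose-response curve")
    pmax0 = max(props.max(), 1e-3)
    above = doses[props >= 0.5 * pmax0]
    d50_0 = float(above.min()) if above.size else float(np.median(doses))
    sigma = None
    if n_subjects is not None:
        sigma = np.sqrt(np.clip(props * (1.0 - props), 1e-4, None) / n_subjects)
    try:
        popt, _ = curve_fit(
            hill, doses, props,
            p0=[pmax0, max(d50_0, 1.0), 1.5],
            sigma=sigma,
            bounds=([1e-6, 1e-3, 0.1], [1.0, 1e5, 20.0]),
            maxfev=20_000,
        )
    except (RuntimeError, ValueError) as exc:
        raise EstimationError(f"Hill fit did not converge: {exc}") from exc
    return float(popt[0]), float(popt[1]), float(popt[2])


def estimate_ed90(curve: DoseResponseCurve) -> Ed90Estimate:
    """ED90 (dose at 90% of the fitted plateau) of one dose-response curve.

    Requires the curve to approach its plateau: the top observed dose must
    reach at least ~95% of the fitted pmax, otherwise the plateau - and with
    it ED90 - is extrapolation and an error is raised.
    """
    pmax, d50, h = fit_hill(curve.doses, curve.proportions, curve.n_subjects)
    top = hill(curve.doses.max(), pmax, d50, h)
    if top < 0.95 * pmax:
        raise EstimationError(
            f"plateau not approached within the dose range "
            f"(top dose reaches {top:.3f} of fitted pmax {pmax:.3f})"
        )
    ed90 = d50 * 9.0 ** (1.0 / h)
    return Ed90Estimate(ed90=ed90, pmax=pmax, d50=d50, hill_coef=h,
                        scenario=curve.scenario)


def ed90_from_sweep(sweep: pd.DataFrame, scenario: str = "") -> Ed90Estimate:
    """ED90 from a tidy sweep frame (as returned by ``dose_response_sweep``).

    The point estimate comes from the median-percentile curve; when several
    uncertainty percentiles are present, the 5th/95th of the per-percentile
    ED90s form the confidence interval.
    """
    pcts = sorted(sweep["percentile"].unique())
    per_pct: dict[int, Ed90Estimate] = {}
    for p in pcts:
        sub = sweep[sweep["percentile"] == p].sort_values("dose_mg")
        curve = DoseResponseCurve(
            sub["dose_mg"].to_numpy(), sub["prop_gt90"].to_numpy() / 100.0,
            scenario=scenario, percentile=int(p),
            n_subjects=int(sub["n"].iloc[0]) if "n" in sub else None,
        )
        per_pct[p] = estimate_ed90(curve)
    mid = pcts[int(np.argmin(np.abs(np.asarray(pcts) - 50)))]
    est = per_pct[mid]
    if len(pcts) > 1:
        values = np.array([e.ed90 for e in per_pct.values()])
        est.ci_low = float(np.percentile(values, 5))
        est.ci_high = float(np.percentile(values, 95))
    return est


def curve_difference(
    curve_a: DoseResponseCurve, curve_b: DoseResponseCurve, doses=None
) -> pd.DataFrame:
    """Percentage-point difference a - b per dose (linear interpolation).

    ``doses`` defaults to curve_a's grid restricted to the overlap of both
    dose ranges; disjoint ranges raise.
    """
    lo = max(curve_a.doses.min(), curve_b.doses.min())
    hi = min(curve_a.doses.max(), curve_b.doses.max())
    if lo > hi:
        raise ValueError("curves have disjoint dose ranges")
    if doses is None:
        doses = curve_a.doses[(curve_a.doses >= lo) & (curve_a.doses <= hi)]
    doses = np.asarray(doses, dtype=float)
    if np.any((doses < lo) | (doses > hi)):
        raise ValueError("requested doses outside the common dose range")
    pa = np.interp(doses, curve_a.doses, curve_a.proportions)
    pb = np.interp(doses, curve_b.doses, curve_b.proportions)
    return pd.DataFrame({"dose_mg": doses, "difference_pp": 100.0 * (pa - pb)})
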