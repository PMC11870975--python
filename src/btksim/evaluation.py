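"""Observed BTK-occupancy data, dose-group pooling, residual error, and
observed-versus-predicted comparison.

The embedded fixture is the published per-dose summary of 320 BTK occupancy
observations (pre-dose of days 2, 8, 15 and/or 29) across 21 QD doses from
80 to 1400 mg: for each dose, the number of observations and the percent
with more than 90% occupancy.  Responder counts are reconstructed from the
rounded percentages.  Doses are pooled into five groups for comparison
because many individual doses have fewer than 10 observations.

Observed occupancies carry residual unexplained variability (RUV), modelled
as additive Gaussian noise with variance 27.1 on the percent scale; model
predictions are compared against observations with this noise applied (and
clipped to the physical [0, 100] range).

A synthetic-study generator emulates such an occupancy study from the model
itself, providing a fully in-silico test path for the evaluation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import beta

from .parameters import RUV_VARIANCE
from .population import PopulationSpec, sample_individuals
from .engine import simulate_population_qd

__all__ = [
    "ObservedDoseRecord",
    "DOSE_GROUP_BOUNDS",
    "RuvModel",
    "load_observed_fixture",
    "observed_frame",
    "pool_dose_groups",
    "clopper_pearson",
    "add_ruv",
    "predicted_vs_observed",
    "generate_synthetic_study",
]


@dataclass(frozen=True)
class ObservedDoseRecord:
    """One dose level of the observed occupancy table."""

    dose_mg: float
    n_obs: int
    pct_gt90: float

    @property
    def responders(self) -> int:
        """Responder count reconstructed from the rounded printed percent."""
        return int(round(self.pct_gt90 * self.n_obs / 100.0))


#: Pooling bounds (mg): lower exclusive except the first group, upper inclusive.
DOSE_GROUP_BOUNDS: tuple[tuple[float, float], ...] = (
    (80.0, 140.0),
    (140.0, 300.0),
    (300.0, 500.0),
    (500.0, 800.0),
    (800.0, 1400.0),
)


@dataclass(frozen=True)
class RuvModel:
    """Additive residual error on the occupancy percent scale."""

    variance: float = RUV_VARIANCE

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def load_observed_fixture() -> list[ObservedDoseRecord]:
    """The embedded observed occupancy records (21 doses, 320 observations)."""
    with resources.files("btksim.data").joinpath("observed_occupancy.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        ObservedDoseRecord(float(r.dose_mg), int(r.n_obs), float(r.pct_gt90))
        for r in df.itertuples()
    ]


def observed_frame() -> pd.DataFrame:
    """Fixture as a DataFrame with reconstructed responder counts."""
    recs = load_observed_fixture()
    return pd.DataFrame({
        "dose_mg": [r.dose_mg for r in recs],
        "n_obs": [r.n_obs for r in recs],
        "pct_gt90": [r.pct_gt90 for r in recs],
        "responders": [r.responders for r in recs],
    })


def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) two-sided confidence interval."""
    if not 0 <= successes <= n or n < 1:
        raise ValueError("need 0 <= successes <= n, n >= 1")
    lo = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


def _in_group(dose: float, lo: float, hi: float, first: bool) -> bool:
    return (lo <= dose <= hi) if first else (lo < dose <= hi)


def pool_dose_groups(
    records: list[ObservedDoseRecord] | None = None,
    bounds: tuple[tuple[float, float], ...] = DOSE_GROUP_BOUNDS,
) -> pd.DataFrame:
    """Pool observed records into dose groups with exact binomial 95% CIs.

    Group membership: ``low < dose <= high`` (first group includes its lower
    bound).  Every record must fall in exactly one group.
    """
    records = records if records is not None else load_observed_fixture()
    rows = []
    assigned = 0
    for i, (lo, hi) in enumerate(bounds):
        members = [r for r in records if _in_group(r.dose_mg, lo, hi, i == 0)]
        n = sum(r.n_obs for r in members)
        resp = sum(r.responders for r in members)
        assigned += len(members)
        ci_lo, ci_hi = clopper_pearson(resp, n) if n else (float("nan"),) * 2
        label = f"{lo:g}-{hi:g} mg" if i == 0 else f">{lo:g}-{hi:g} mg"
        rows.append({
            "group": label,
            "low_mg": lo,
            "high_mg": hi,
            "n": n,
            "responders": resp,
            "pct_gt90": 100.0 * resp / n if n else float("nan"),
            "ci_low_pct": 100.0 * ci_lo,
            "ci_high_pct": 100.0 * ci_hi,
        })
    if assigned != len(records):
        strays = [
            r.dose_mg for r in records
            if not any(_in_group(r.dose_mg, lo, hi, i == 0)
                       for i, (lo, hi) in enumerate(bounds))
        ]
        raise ValueError(f"records outside all dose groups: {strays}")
    return pd.DataFrame(rows)


def add_ruv(
    occupancies,
    ruv: RuvModel | None = None,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Add iid residual error to occupancy percents and clip to [0, 100]."""
    ruv = ruv or RuvModel()
    occ = np.asarray(occupancies, dtype=float)
    if ruv.variance == 0.0:
        return occ.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return np.clip(occ + rng.normal(0.0, ruv.sd, occ.shape), 0.0, 100.0)


def predicted_vs_observed(
    sweep: pd.DataFrame,
    pooled: pd.DataFrame | None = None,
    records: list[ObservedDoseRecord] | None = None,
    prop_column: str = "prop_gt90_ruv",
) -> pd.DataFrame:
    """Compare pooled observed proportions against the predicted band.

    ``sweep`` is a tidy dose-response frame covering the observed dose range,
    with one curve per uncertainty percentile.  The prediction for a dose
    group is the n-weighted mean of the per-dose predicted responder
    proportions over the group's member doses (interpolated on the sweep
    grid); the band is its spread across the percentile curves.  A group is
    flagged covered when the observed proportion lies inside the predicted
    5th-95th band.
    """
    records = records if records is not None else load_observed_fixture()
    pooled = pooled if pooled is not None else pool_dose_groups(records)
    if prop_column not in sweep.columns:
        raise ValueError(f"sweep has no column {prop_column!r}")
    lo_d, hi_d = sweep["dose_mg"].min(), sweep["dose_mg"].max()
    member_doses = np.array([r.dose_mg for r in records])
    if member_doses.min() < lo_d or member_doses.max() > hi_d:
        raise ValueError("sweep does not cover the observed dose range")

    rows = []
    for g in pooled.itertuples():
        members = [
            r for r in records
            if _in_group(r.dose_mg, g.low_mg, g.high_mg, g.Index == 0)
        ]
        weights = np.array([r.n_obs for r in members], dtype=float)
        doses = np.array([r.dose_mg for r in members], dtype=float)
        preds = []
        for pct in sorted(sweep["percentile"].unique()):
            sub = sweep[sweep["percentile"] == pct].sort_values("dose_mg")
            p = np.interp(doses, sub["dose_mg"], sub[prop_column])
            preds.append(float(np.average(p, weights=weights)))
        preds = np.asarray(preds)
        band_lo, band_hi = float(preds.min()), float(preds.max())
        pred_median = float(np.median(preds))
        eps = 1e-9  # guard float round-off at degenerate (zero-width) bands
        covered = band_lo - eps <= g.pct_gt90 <= band_hi + eps
        rows.append({
            "group": g.group,
            "n": g.n,
            "observed_pct": g.pct_gt90,
            "ci_low_pct": g.ci_low_pct,
            "ci_high_pct": g.ci_high_pct,
            "pred_median_pct": pred_median,
            "pred_p5_pct": band_lo,
            "pred_p95_pct": band_hi,
            "covered": covered,
            "ci_within_band": band_lo <= g.ci_low_pct and g.ci_high_pct <= band_hi,
        })
    return pd.DataFrame(rows)


def generate_synthetic_study(
    allocation: dict[float, int],
    sampling_days=(2, 8, 15, 29),
    *,
    scenario: str = "uniform",
    ruv: RuvModel | None = None,
    seed: int = 0,
    dt: float = 0.05,
) -> pd.DataFrame:
    """Simulate an in-silico occupancy study (synthetic observed dataset).

    ``allocation`` maps QD dose (mg) to the number of subjects.  Each subject
    is dosed daily through the last sampling day and measured at pre-dose
    times ``24*(day-1)`` h; residual error is added to the measured
    occupancies and values are clipped to [0, 100].  Returns tidy records:
    subject_id, dose_mg, day, occupancy_pct, gt90.
    """
    ruv = ruv if ruv is not None else RuvModel()
    days = sorted(int(d) for d in sampling_days)
    if days[0] < 2:
        raise ValueError("sampling days must be >= 2 (pre-dose trough sampling)")
    n_dosing_days = days[-1] - 1
    obs_times = [24.0 * (d - 1) for d in days]
    rng = np.random.default_rng(seed)
    spec = PopulationSpec(scenario=scenario)

    frames = []
    subject_offset = 0
    for dose, n in sorted(allocation.items()):
        if n < 1:
            continue
        ind = sample_individuals(spec, n, rng)
        res = simulate_population_qd(ind, dose, n_dosing_days, obs_times, dt=dt)
        occ = res.occupancy  # (n_days, n)
        noisy = add_ruv(occ, ruv, rng)
        for i, day in enumerate(days):
            frames.append(pd.DataFrame({
                "subject_id": subject_offset + np.arange(n),
                "dose_mg": dose,
                "day": day,
                "occupancy_pct": noisy[i],
                "gt90": noisy[i] > 90.0,
            }))
        subject_offset += n
    return pd.concat(frames, ignore_index=True)
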