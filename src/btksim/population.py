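"""Virtual-population sampling: between-subject variability, BTK half-life
scenarios, and the k_on/k_inact uncertainty grid.

Between-subject variability (BSV) is lognormal: each parameter ``p`` with a
reported %CV ``c`` is drawn as ``typical * exp(eta)``, ``eta ~ N(0, (c/100)^2)``
(the standard exponential IIV model; the typical value is the population
median).  ``ka`` carries no BSV.  BTK half-life follows one of three
scenarios: lognormal around 60 h ("slow") or 24 h ("fast") with 25% CV, or a
uniform distribution over 12-120 h ("uniform") with no extra BSV, emulating a
population heterogeneous in BTK turnover.

Parameter uncertainty in the binding constants is represented by 11 paired
percentiles (5th...95th) of 100,000 draws from the published normal
distributions, truncated to positive support by rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parameters import (
    BSV_CV_PERCENT,
    KINACT_MEAN,
    KINACT_SD,
    KON_MEAN,
    KON_SD,
    PDParameters,
    PKParameters,
)

__all__ = [
    "HalfLifeScenario",
    "SCENARIOS",
    "PopulationSpec",
    "IndividualParameters",
    "sample_half_lives",
    "sample_individuals",
    "UncertaintyGrid",
    "uncertainty_grid",
    "UNCERTAINTY_PERCENTILES",
]

UNCERTAINTY_PERCENTILES = (5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95)


@dataclass(frozen=True)
class HalfLifeScenario:
    """Distribution of the free-BTK half-life across the population (hours)."""

    kind: str                     # "fixed" or "uniform"
    typical: float = 60.0         # median of the lognormal (fixed scenarios)
    cv_percent: float = 25.0      # BSV of the fixed scenarios
    low: float = 12.0             # uniform bounds
    high: float = 120.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "uniform"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "uniform" and not (0 < self.low < self.high):
            raise ValueError("uniform scenario requires 0 < low < high")


#: The three turnover scenarios studied: slow (60 h), fast (24 h), and a
#: uniform spread of turnovers from 12 h to 120 h.
SCENARIOS: dict[str, HalfLifeScenario] = {
    "slow": HalfLifeScenario("fixed", typical=60.0, cv_percent=25.0),
    "fast": HalfLifeScenario("fixed", typical=24.0, cv_percent=25.0),
    "uniform": HalfLifeScenario("uniform"),
}


def resolve_scenario(scenario) -> HalfLifeScenario:
    if isinstance(scenario, HalfLifeScenario):
        return scenario
    try:
        return SCENARIOS[scenario]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIOS)}"
        ) from None


def sample_half_lives(scenario, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` BTK half-lives (h) under a turnover scenario."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sc = resolve_scenario(scenario)
    if sc.kind == "uniform":
        return rng.uniform(sc.low, sc.high, size=n)
    omega = sc.cv_percent / 100.0
    return sc.typical * np.exp(rng.normal(0.0, omega, size=n)) if omega > 0 else np.full(n, sc.typical)


@dataclass
class PopulationSpec:
    """Recipe for a virtual population.

    ``bsv_cv`` maps parameter names to %CV; keys must be known parameters.
    ``f1_bsv`` toggles the (large, 62.8 %CV) bioavailability BSV, which the
    source model reports alongside a fixed fed typical value of 1.
    """

    pk: PKParameters = field(default_factory=PKParameters)
    pd_: PDParameters = field(default_factory=PDParameters)
    bsv_cv: dict[str, float] = field(default_factory=lambda: dict(BSV_CV_PERCENT))
    scenario: HalfLifeScenario | str = "uniform"
    fed: bool = True
    antacid: bool = False
    f1_bsv: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.bsv_cv) - set(BSV_CV_PERCENT)
        if unknown:
            raise ValueError(f"unknown parameters in bsv_cv: {sorted(unknown)}")
        if any(v < 0 for v in self.bsv_cv.values()):
            raise ValueError("%CV values must be >= 0")

    def with_cv(self, **overrides: float) -> "PopulationSpec":
        cv = dict(self.bsv_cv)
        cv.update(overrides)
        return replace(self, bsv_cv=cv)

    @classmethod
    def from_yaml(cls, path) -> "PopulationSpec":
        """Load a population config (scenario, fed/antacid flags, CV
        overrides, optional pk/pd typical-value overrides) from YAML."""
        import yaml
        from pathlib import Path

        payload = yaml.safe_load(Path(path).read_text()) or {}
        spec = cls(
            pk=PKParameters(**payload.get("pk", {})),
            pd_=PDParameters(**payload.get("pd", {})),
            scenario=payload.get("scenario", "uniform"),
            fed=payload.get("fed", True),
            antacid=payload.get("antacid", False),
            f1_bsv=payload.get("f1_bsv", True),
        )
        return spec.with_cv(**payload.get("bsv_cv", {}))


@dataclass
class IndividualParameters:
    """A batch of sampled virtual subjects (arrays of length ``n``).

    Volumes are post-allometric-scaling; ``d_zero`` and ``f1`` are the
    effective per-subject values for the study's fed/antacid status;
    ``conc_factor`` converts central amount (ug) to free concentration (nM).
    """

    cl_f: np.ndarray
    v2: np.ndarray
    v3: np.ndarray
    q_f: np.ndarray
    ka: np.ndarray
    tlag: np.ndarray
    d_zero: np.ndarray
    f1: np.ndarray
    btk0: np.ndarray
    t_half_btk: np.ndarray
    kon: np.ndarray
    koff: np.ndarray
    kinact: np.ndarray
    fu: float
    mw: float

    @property
    def n(self) -> int:
        return self.cl_f.shape[0]

    @property
    def kel(self) -> np.ndarray:
        return self.cl_f / self.v2

    @property
    def k23(self) -> np.ndarray:
        return self.q_f / self.v2

    @property
    def k32(self) -> np.ndarray:
        return self.q_f / self.v3

    @property
    def kdeg(self) -> np.ndarray:
        return np.log(2.0) / self.t_half_btk

    @property
    def ksyn(self) -> np.ndarray:
        return self.btk0 * self.kdeg

    @property
    def conc_factor(self) -> np.ndarray:
        return 1000.0 * self.fu / (self.v2 * self.mw)

    def with_binding(self, kon: float, kinact: float) -> "IndividualParameters":
        """Same subjects with a different (kon, kinact) uncertainty scenario."""
        n = self.n
        return replace(
            self,
            kon=np.full(n, float(kon)),
            kinact=np.full(n, float(kinact)),
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per subject, one column per parameter."""
        return pd.DataFrame({
            "cl_f": self.cl_f, "v2": self.v2, "v3": self.v3, "q_f": self.q_f,
            "ka": self.ka, "tlag": self.tlag, "d_zero": self.d_zero,
            "f1": self.f1, "btk0": self.btk0, "t_half_btk": self.t_half_btk,
            "kon": self.kon, "koff": self.koff, "kinact": self.kinact,
        })


def _lognormal(rng, typical, cv_percent, n):
    omega = cv_percent / 100.0
    if omega == 0.0:
        return np.full(n, typical)
    return typical * np.exp(rng.normal(0.0, omega, size=n))


def sample_individuals(
    spec: PopulationSpec, n: int, rng: np.random.Generator | int
) -> IndividualParameters:
    """Sample ``n`` virtual subjects under ``spec``.

    Parameters are sampled independently (no published IIV correlation).
    Reproducible given the same generator state or integer seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pk, pd_ = spec.pk, spec.pd_
    cv = spec.bsv_cv

    cl_f = _lognormal(rng, pk.cl_f, cv.get("cl_f", 0.0), n)
    v2 = _lognormal(rng, pk.v2, cv.get("v2_f", 0.0), n)
    v3 = _lognormal(rng, pk.v3, cv.get("v3_f", 0.0), n)
    q_f = _lognormal(rng, pk.q_f, cv.get("q_f", 0.0), n)
    tlag = _lognormal(rng, pk.tlag, cv.get("tlag", 0.0), n)
    d_zero = _lognormal(
        rng, pk.d_zero(fed=spec.fed, antacid=spec.antacid), cv.get("d_zero", 0.0), n
    )
    f1_cv = cv.get("f1", 0.0) if spec.f1_bsv else 0.0
    f1 = _lognormal(rng, pk.f1(fed=spec.fed), f1_cv, n)
    btk0 = _lognormal(rng, pd_.btk0, cv.get("btk0", 0.0), n)
    t_half = sample_half_lives(spec.scenario, n, rng)
    sc = resolve_scenario(spec.scenario)
    if sc.kind == "fixed" and "t_half_btk" in cv and cv["t_half_btk"] != sc.cv_percent:
        # explicit override of the scenario's own BSV
        t_half = _lognormal(rng, sc.typical, cv["t_half_btk"], n)

    return IndividualParameters(
        cl_f=cl_f, v2=v2, v3=v3, q_f=q_f,
        ka=np.full(n, pk.ka), tlag=tlag, d_zero=d_zero, f1=f1,
        btk0=btk0, t_half_btk=t_half,
        kon=np.full(n, pd_.kon), koff=np.full(n, pd_.koff),
        kinact=np.full(n, pd_.kinact),
        fu=pd_.fu, mw=pd_.mw,
    )


@dataclass
class UncertaintyGrid:
    """Paired percentile scenarios of the binding-constant uncertainty.

    ``kon[i]`` and ``kinact[i]`` are the ``percentiles[i]``-th empirical
    percentiles of 100,000 positive-truncated normal draws; scenarios are
    coupled by shared percentile rank, the middle pair being the central
    scenario.
    """

    percentiles: np.ndarray
    kon: np.ndarray
    kinact: np.ndarray

    @property
    def median_index(self) -> int:
        return int(np.argmin(np.abs(self.percentiles - 50)))

    def pairs(self):
        """Iterate (percentile, kon, kinact) scenarios."""
        for p, ko, ki in zip(self.percentiles, self.kon, self.kinact):
            yield int(p), float(ko), float(ki)


def _truncated_normal(rng, mean, sd, n):
    """Rejection-sample N(mean, sd) conditioned on strictly positive values."""
    if sd == 0.0:
        if mean <= 0:
            raise ValueError("degenerate distribution has no positive support")
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n - filled)
        draw = draw[draw > 0]
        out[filled:filled + draw.size] = draw
        filled += draw.size
    return out


def uncertainty_grid(
    rng: np.random.Generator | int,
    kon_mean: float = KON_MEAN,
    kon_sd: float = KON_SD,
    kinact_mean: float = KINACT_MEAN,
    kinact_sd: float = KINACT_SD,
    n_draws: int = 100_000,
    percentiles=UNCERTAINTY_PERCENTILES,
) -> UncertaintyGrid:
    """Build the 11-point percentile grid of k_on / k_inact uncertainty."""
    if kon_sd < 0 or kinact_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pct = np.asarray(percentiles, dtype=float)
    kon = np.percentile(_truncated_normal(rng, kon_mean, kon_sd, n_draws), pct)
    kinact = np.percentile(_truncated_normal(rng, kinact_mean, kinact_sd, n_draws), pct)
    return UncertaintyGrid(percentiles=pct, kon=kon, kinact=kinact)
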