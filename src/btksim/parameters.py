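"""Model parameters for the ibrutinib-BTK covalent binding model.

The pharmacokinetic side is an open two-compartment disposition model with
sequential zero/first-order oral absorption after a lag time, parameterized in
apparent (oral) terms (CL/F, V2/F, Q/F, V3/F).  The pharmacodynamic side is a
turnover model of free Bruton's tyrosine kinase (BTK) coupled to a covalent
binding step: free drug and free BTK form a reversible complex (k_on, k_off)
which is irreversibly inactivated at rate k_inact.  Because k_inact >> k_off,
k_on is well approximated by the published second-order efficiency constant
k_inact/K_I.

Typical values, between-subject variabilities (BSV, %CV on the log scale) and
the covalent-binding constants are the published population estimates for
ibrutinib in B-cell malignancy patients; they are embedded here as defaults so
the package runs without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "PKParameters",
    "PDParameters",
    "BSV_CV_PERCENT",
    "KON_MEAN",
    "KON_SD",
    "KINACT_MEAN",
    "KINACT_SD",
    "RUV_VARIANCE",
    "derive_pk_rates",
    "derive_btk_rates",
    "free_concentration_nM",
    "load_parameters",
    "save_parameters",
]

#: Uncertainty distribution of the association rate constant k_on (1/nM/h).
KON_MEAN = 1.72
KON_SD = 0.60
#: Uncertainty distribution of the inactivation rate constant k_inact (1/h).
KINACT_MEAN = 95.76
KINACT_SD = 88.56
#: Residual unexplained variability of observed occupancy, additive variance
#: on the percent scale (used for model evaluation only, never for the
#: intrinsic occupancy statistic).
RUV_VARIANCE = 27.1

#: Between-subject variability (%CV, interpreted as 100*omega on the log
#: scale) of the population model parameters.  k_a carries no BSV.
BSV_CV_PERCENT: dict[str, float] = {
    "cl_f": 21.9,
    "v2_f": 153.0,
    "q_f": 60.7,
    "v3_f": 47.3,
    "tlag": 27.8,
    "d_zero": 20.9,
    "f1": 62.8,
    "btk0": 78.9,
    "t_half_btk": 25.0,
}


class ParameterError(ValueError):
    """Raised for invalid (non-positive, out of range) model parameters."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0 and math.isfinite(value)):
            raise ParameterError(f"{name} must be strictly positive, got {value!r}")


@dataclass
class PKParameters:
    """Typical ibrutinib population-PK parameters (apparent oral scale).

    Volumes are allometrically scaled by body weight with exponent
    ``wt_v_exp`` around the reference weight; clearances are not.
    Fed/fasted status switches the relative bioavailability ``f1`` and the
    duration of the zero-order absorption phase ``d_zero``; antacid
    co-administration stretches ``d_zero`` by a fixed factor.
    """

    cl_f: float = 1060.0     # apparent clearance CL/F, L/h
    v2_f: float = 246.0      # apparent central volume V2/F, L
    q_f: float = 865.0       # apparent intercompartmental clearance Q/F, L/h
    v3_f: float = 9620.0     # apparent peripheral volume V3/F, L
    ka: float = 0.463        # first-order absorption rate, 1/h
    tlag: float = 0.283      # absorption lag time, h
    d_zero_fed: float = 3.29     # zero-order input duration, fed, h
    d_zero_fasted: float = 1.10  # zero-order input duration, fasted, h
    f1_fed: float = 1.0      # relative bioavailability, fed (reference)
    f1_fasted: float = 0.67  # relative bioavailability, fasted
    antacid_d_factor: float = 1.61  # multiplier on d_zero with antacids
    weight: float = 80.4     # body weight, kg
    ref_weight: float = 80.4  # reference (median) body weight, kg
    wt_v_exp: float = 0.641  # allometric exponent on volumes

    def __post_init__(self) -> None:
        _require_positive(
            cl_f=self.cl_f, v2_f=self.v2_f, q_f=self.q_f, v3_f=self.v3_f,
            ka=self.ka, d_zero_fed=self.d_zero_fed,
            d_zero_fasted=self.d_zero_fasted, f1_fed=self.f1_fed,
            f1_fasted=self.f1_fasted, antacid_d_factor=self.antacid_d_factor,
            weight=self.weight, ref_weight=self.ref_weight,
        )
        if self.tlag < 0:
            raise ParameterError(f"tlag must be non-negative, got {self.tlag}")

    @property
    def allometric_factor(self) -> float:
        """Body-weight scaling factor applied to V2/F and V3/F only."""
        return (self.weight / self.ref_weight) ** self.wt_v_exp

    @property
    def v2(self) -> float:
        """Allometrically scaled central volume, L."""
        return self.v2_f * self.allometric_factor

    @property
    def v3(self) -> float:
        """Allometrically scaled peripheral volume, L."""
        return self.v3_f * self.allometric_factor

    def f1(self, fed: bool = True) -> float:
        return self.f1_fed if fed else self.f1_fasted

    def d_zero(self, fed: bool = True, antacid: bool = False) -> float:
        d = self.d_zero_fed if fed else self.d_zero_fasted
        if antacid:
            d *= self.antacid_d_factor
        return d


@dataclass
class PDParameters:
    """Free-BTK turnover and covalent binding parameters.

    Derived quantities follow the turnover identities
    ``kdeg = ln(2)/t_half`` and ``ksyn = btk0 * kdeg``; the covalent complex
    degrades at ``kdegc = kdeg``.
    """

    btk0: float = 1.04       # baseline free BTK, nM
    t_half_btk: float = 60.0  # free-BTK half-life, h
    kon: float = KON_MEAN    # association rate, 1/nM/h
    koff: float = 0.205      # dissociation rate, 1/h
    kinact: float = KINACT_MEAN  # inactivation rate, 1/h
    fu: float = 0.03         # unbound fraction in plasma
    mw: float = 440.5        # molecular weight, g/mol

    def __post_init__(self) -> None:
        _require_positive(
            btk0=self.btk0, t_half_btk=self.t_half_btk, kon=self.kon,
            koff=self.koff, kinact=self.kinact, fu=self.fu, mw=self.mw,
        )

    @property
    def kdeg(self) -> float:
        """First-order degradation rate of free BTK, 1/h."""
        return math.log(2.0) / self.t_half_btk

    @property
    def kdegc(self) -> float:
        """Degradation rate of the covalent complex (equal to kdeg), 1/h."""
        return self.kdeg

    @property
    def ksyn(self) -> float:
        """Zero-order BTK synthesis rate, nM/h."""
        return self.btk0 * self.kdeg

    @property
    def ki(self) -> float:
        """Reversible binding constant K_I = (koff + kinact)/kon, nM."""
        return (self.koff + self.kinact) / self.kon


def derive_pk_rates(pk: PKParameters) -> dict[str, float]:
    """First-order disposition micro-constants from apparent parameters.

    ``kel = CL/V2``, ``k23 = Q/V2``, ``k32 = Q/V3`` with volumes taken after
    allometric scaling.
    """
    v2, v3 = pk.v2, pk.v3
    _require_positive(v2=v2, v3=v3)
    return {"kel": pk.cl_f / v2, "k23": pk.q_f / v2, "k32": pk.q_f / v3}


def derive_btk_rates(btk0: float, t_half_btk: float) -> dict[str, float]:
    """Turnover rates from baseline and half-life: kdeg = ln2/t_half, ksyn = btk0*kdeg."""
    _require_positive(btk0=btk0, t_half_btk=t_half_btk)
    kdeg = math.log(2.0) / t_half_btk
    return {"kdeg": kdeg, "ksyn": btk0 * kdeg}


def free_concentration_nM(a2, v2: float, fu: float = 0.03, mw: float = 440.5):
    """Free drug concentration (nM) from the central-compartment amount.

    With ``a2`` in ug and ``v2`` in L, ``a2/v2`` is in ug/L = ng/mL, so
    ``1000 * fu * (a2/v2) / mw`` is nmol/L.
    """
    _require_positive(v2=v2, mw=mw)
    return 1000.0 * fu * (a2 / v2) / mw


def save_parameters(path: str | Path, pk: PKParameters, pd_: PDParameters) -> None:
    """Write a YAML parameter file mirroring the dataclass field names."""
    payload = {"pk": asdict(pk), "pd": asdict(pd_)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_parameters(path: str | Path) -> tuple[PKParameters, PDParameters]:
    """Read a YAML parameter file written by :func:`save_parameters`."""
    payload = yaml.safe_load(Path(path).read_text())
    return PKParameters(**payload.get("pk", {})), PDParameters(**payload.get("pd", {}))
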