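"""The ibrutinib-BTK covalent binding ODE system and its reference solver.

Six states: drug amounts in depot (A1), central (A2) and peripheral (A3)
compartments (ug), and BTK pools in nM - free (BTKf), reversible drug-BTK
complex (BTKrc) and covalent complex (BTKcc):

    dA1/dt    = in(t) - ka*A1
    dA2/dt    = ka*A1 - kel*A2 - k23*A2 + k32*A3
    dA3/dt    = k23*A2 - k32*A3
    dBTKf/dt  = ksyn - kon*BTKf*C2 + koff*BTKrc - kdeg*BTKf
    dBTKrc/dt = kon*BTKf*C2 - koff*BTKrc - kinact*BTKrc
    dBTKcc/dt = kinact*BTKrc - kdeg*BTKcc

with ``C2 = 1000*fu*(A2/V2)/MW`` the free drug concentration in nM and
``in(t)`` the piecewise-constant zero-order depot input generated by the
dose events.  Binding does not deplete the drug amounts (the free-drug pool
is large relative to the nanomolar BTK pool), so the PK block is linear and
autonomous and the BTK block is linear given C2(t).

Occupancy is the bound fraction of total BTK,
``100*(BTKrc + BTKcc)/(BTKf + BTKrc + BTKcc)`` in percent, evaluated here
without any residual error.

:func:`simulate_individual` integrates the full system with LSODA at tight
tolerances, restarting at every input discontinuity; it is the single-subject
reference implementation against which the fast vectorized population
integrator (:mod:`btksim.engine`) is validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dosing import DoseEvent, infusion_window
from .parameters import (
    PDParameters,
    PKParameters,
    derive_pk_rates,
    free_concentration_nM,
)

__all__ = [
    "ModelState",
    "Trajectory",
    "IntegrationError",
    "ode_rhs",
    "occupancy_percent",
    "steady_state_occupancy_constant_C",
    "simulate_individual",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to converge."""


@dataclass
class ModelState:
    """One instantaneous state of the six-compartment system."""

    a1: float = 0.0      # depot amount, ug
    a2: float = 0.0      # central amount, ug
    a3: float = 0.0      # peripheral amount, ug
    btk_f: float = 0.0   # free BTK, nM
    btk_rc: float = 0.0  # reversible complex, nM
    btk_cc: float = 0.0  # covalent complex, nM

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.btk_f, self.btk_rc, self.btk_cc])


def ode_rhs(
    t: float,
    y: np.ndarray,
    pk: PKParameters,
    pd_: PDParameters,
    input_rate: float = 0.0,
) -> np.ndarray:
    """Right-hand side of the six-state system at time ``t``.

    ``input_rate`` is the zero-order depot input (ug/h) active at ``t``.
    """
    rates = derive_pk_rates(pk)
    kel, k23, k32 = rates["kel"], rates["k23"], rates["k32"]
    a1, a2, a3, btk_f, btk_rc, btk_cc = y
    c2 = free_concentration_nM(a2, pk.v2, pd_.fu, pd_.mw)
    bind = pd_.kon * btk_f * c2
    return np.array([
        input_rate - pk.ka * a1,
        pk.ka * a1 - kel * a2 - k23 * a2 + k32 * a3,
        k23 * a2 - k32 * a3,
        pd_.ksyn - bind + pd_.koff * btk_rc - pd_.kdeg * btk_f,
        bind - pd_.koff * btk_rc - pd_.kinact * btk_rc,
        pd_.kinact * btk_rc - pd_.kdegc * btk_cc,
    ])


def occupancy_percent(btk_f, btk_rc, btk_cc):
    """Bound fraction of total BTK in percent: 100*(rc+cc)/(f+rc+cc).

    Accepts scalars or arrays; raises if total BTK is zero anywhere.
    """
    btk_f = np.asarray(btk_f, dtype=float)
    total = btk_f + btk_rc + btk_cc
    if np.any(total <= 0):
        raise ValueError("occupancy undefined: total BTK must be positive")
    return 100.0 * (btk_rc + btk_cc) / total


def steady_state_occupancy_constant_C(c_free: float, pd_: PDParameters) -> float:
    """Analytic occupancy plateau under a constant free drug concentration.

    Setting the BTK-block derivatives to zero at constant C gives

        BTKf*  = ksyn / (kdeg + kon*C*kinact/(koff + kinact))
        BTKrc* = kon*C*BTKf* / (koff + kinact)
        BTKcc* = kinact*BTKrc* / kdeg

    This closed form is the independent oracle for the numeric integrators'
    constant-infusion plateaus.
    """
    if c_free < 0:
        raise ValueError("c_free must be >= 0")
    f = pd_.ksyn / (pd_.kdeg + pd_.kon * c_free * pd_.kinact / (pd_.koff + pd_.kinact))
    rc = pd_.kon * c_free * f / (pd_.koff + pd_.kinact)
    cc = pd_.kinact * rc / pd_.kdeg
    return float(occupancy_percent(f, rc, cc))


@dataclass
class Trajectory:
    """Simulated time course of all states plus derived quantities."""

    times: np.ndarray       # h
    a1: np.ndarray          # ug
    a2: np.ndarray          # ug
    a3: np.ndarray          # ug
    btk_f: np.ndarray       # nM
    btk_rc: np.ndarray      # nM
    btk_cc: np.ndarray      # nM
    c2_free: np.ndarray     # nM
    occupancy: np.ndarray   # percent

    def to_frame(self) -> pd.DataFrame:
        """Tidy export with one row per output time."""
        return pd.DataFrame({
            "time_h": self.times,
            "a1_ug": self.a1,
            "a2_ug": self.a2,
            "a3_ug": self.a3,
            "btkf_nM": self.btk_f,
            "btkrc_nM": self.btk_rc,
            "btkcc_nM": self.btk_cc,
            "c2free_nM": self.c2_free,
            "occupancy_pct": self.occupancy,
        })

    def at(self, t: float) -> ModelState:
        """State at an output time (must be on the grid)."""
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size == 0:
            raise KeyError(f"time {t} not on output grid")
        i = int(idx[0])
        return ModelState(self.a1[i], self.a2[i], self.a3[i],
                          self.btk_f[i], self.btk_rc[i], self.btk_cc[i])


def _input_segments(
    regimen: Sequence[DoseEvent], pk: PKParameters, t_end: float
) -> list[tuple[float, float, float]]:
    """Piecewise-constant depot input rate as (t0, t1, rate) segments covering [0, t_end]."""
    edges = {0.0, t_end}
    windows = []
    for ev in regimen:
        w0, w1, rate = infusion_window(ev, pk)
        if w0 >= t_end:
            continue
        windows.append((w0, min(w1, t_end), rate))
        edges.add(w0)
        edges.add(min(w1, t_end))
    cuts = sorted(e for e in edges if 0.0 <= e <= t_end)
    segments = []
    for t0, t1 in zip(cuts[:-1], cuts[1:]):
        if t1 <= t0:
            continue
        mid = 0.5 * (t0 + t1)
        rate = sum(r for (w0, w1, r) in windows if w0 <= mid < w1)
        segments.append((t0, t1, rate))
    return segments


def simulate_individual(
    pk: PKParameters,
    pd_: PDParameters,
    regimen: Sequence[DoseEvent],
    t_out: np.ndarray,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate one subject's regimen at high accuracy.

    Initial state: empty drug compartments, free BTK at baseline, no
    complexes.  The solver is restarted at every discontinuity of the
    zero-order input so the stated tolerances hold across dose events.
    ``t_out`` is the requested output grid (h, strictly increasing, from 0).
    """
    t_out = np.asarray(t_out, dtype=float)
    if t_out.ndim != 1 or t_out.size < 1 or np.any(np.diff(t_out) <= 0):
        raise ValueError("t_out must be a strictly increasing 1-D grid")
    if t_out[0] < 0:
        raise ValueError("t_out must start at or after 0")
    t_end = float(t_out[-1])
    for ev in regimen:
        if ev.time < 0 or ev.time > t_end:
            raise ValueError(f"dose event at t={ev.time} outside output span")

    y = np.array([0.0, 0.0, 0.0, pd_.btk0, 0.0, 0.0])
    out = np.empty((6, t_out.size))
    if t_out[0] == 0.0:
        out[:, 0] = y
    for t0, t1, rate in _input_segments(regimen, pk, t_end):
        mask = (t_out > t0) & (t_out <= t1)
        te = t_out[mask]
        # always evaluate the segment endpoint so the restart state is exact
        t_eval = te if (te.size and te[-1] == t1) else np.append(te, t1)
        sol = solve_ivp(
            ode_rhs, (t0, t1), y, method=method, rtol=rtol, atol=atol,
            t_eval=t_eval, args=(pk, pd_, rate),
        )
        if not sol.success:
            raise IntegrationError(f"solver failed on [{t0}, {t1}]: {sol.message}")
        if te.size:
            out[:, mask] = sol.y[:, : te.size]
        y = sol.y[:, -1]

    a1, a2, a3, f, rc, cc = out
    # clamp solver-level negative roundoff in the complex pools
    f = np.maximum(f, 0.0)
    rc = np.maximum(rc, 0.0)
    cc = np.maximum(cc, 0.0)
    c2 = free_concentration_nM(np.maximum(a2, 0.0), pk.v2, pd_.fu, pd_.mw)
    occ = occupancy_percent(f, rc, cc)
    return Trajectory(t_out, a1, a2, a3, f, rc, cc, c2, occ)
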