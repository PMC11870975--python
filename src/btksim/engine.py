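"""Vectorized population integrator for the covalent binding model.

The model has a special structure that permits an exact exponential stepping
scheme, vectorized across an entire virtual population:

* Drug binding does not deplete the drug amounts, so the three-compartment PK
  block is linear and autonomous.  Its central-compartment response is a sum
  of three exponential modes (rates ka and the two disposition eigenvalues
  lambda1, lambda2).  The modal amplitudes are advanced exactly from step to
  step, and the zero-order absorption windows - whose per-subject lag and
  duration need not align with the step grid - are injected with their exact
  within-step convolution integrals.

* Given the free concentration C2(t), the BTK block is linear: the
  (free, reversible-complex) pair evolves under a 2x2 constant-coefficient
  system whose matrix exponential has a closed form, and the covalent complex
  is driven by the reversible complex with an analytic convolution integral.
  Holding C2 at its step-midpoint value makes each step exact up to the
  O(dt^2) variation of C2 within the step.

The only discretization error is therefore the piecewise-constant treatment
of C2 in the stiff binding block (k_inact ~ 96 1/h); with the default step
of 0.05 h the trough occupancy agrees with the LSODA reference solver to
well below 0.01 percentage points (asserted in the test suite).

All operations are numpy-vectorized over subjects, so a 10,000-subject,
7-day trial integrates in seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PopulationResult", "simulate_population_qd", "simulate_population"]

# guard for removable singularities (repeated exponential rates)
_RATE_EPS = 1e-6


@dataclass
class PopulationResult:
    """States of every subject at the requested observation times.

    Arrays are shaped ``(n_obs_times, n_subjects)``.
    """

    obs_times: np.ndarray
    btk_f: np.ndarray
    btk_rc: np.ndarray
    btk_cc: np.ndarray
    c2_free: np.ndarray
    a2: np.ndarray

    @property
    def occupancy(self) -> np.ndarray:
        """Intrinsic occupancy (%) at each observation time, no residual error."""
        total = self.btk_f + self.btk_rc + self.btk_cc
        return 100.0 * (self.btk_rc + self.btk_cc) / total


def _separate_rates(ka, lam1, lam2):
    """Nudge ka away from the disposition eigenvalues so the three-exponential
    partial fractions stay well conditioned (degeneracy is measure-zero under
    continuous between-subject variability, but guard anyway)."""
    ka = ka.copy()
    for lam in (lam1, lam2):
        close = np.abs(ka - lam) < _RATE_EPS * np.maximum(ka, lam)
        ka[close] *= 1.0 + 10.0 * _RATE_EPS
    return ka


def simulate_population(
    *,
    kel: np.ndarray,
    k23: np.ndarray,
    k32: np.ndarray,
    ka: np.ndarray,
    tlag: np.ndarray,
    d_zero: np.ndarray,
    f1: np.ndarray,
    conc_factor: np.ndarray,
    kdeg: np.ndarray,
    ksyn: np.ndarray,
    btk0: np.ndarray,
    kon,
    koff,
    kinact,
    dose_times: np.ndarray,
    dose_amounts_ug: np.ndarray,
    obs_times: np.ndarray,
    dt: float = 0.05,
) -> PopulationResult:
    """Integrate the full model for ``n`` subjects in lock-step.

    Parameters are 1-D arrays of length ``n`` (``kon``/``koff``/``kinact``
    may be scalars, broadcast to all subjects).  ``dose_times`` and
    ``dose_amounts_ug`` describe a shared regimen; per-subject
    bioavailability ``f1``, lag and zero-order duration individualize the
    input.  ``conc_factor`` converts the central amount to free nM
    (``1000*fu/(v2*mw)``).  ``obs_times`` must be multiples of ``dt``.
    """
    kel = np.asarray(kel, dtype=float)
    n = kel.shape[0]

    def _vec(x):
        return np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()

    k23, k32, ka = _vec(k23), _vec(k32), _vec(ka)
    tlag, d_zero, f1 = _vec(tlag), _vec(d_zero), _vec(f1)
    conc_factor = _vec(conc_factor)
    kdeg, ksyn, btk0 = _vec(kdeg), _vec(ksyn), _vec(btk0)
    kon, koff, kinact = _vec(kon), _vec(koff), _vec(kinact)

    obs_times = np.asarray(obs_times, dtype=float)
    dose_times = np.asarray(dose_times, dtype=float)
    dose_amounts_ug = np.broadcast_to(
        np.asarray(dose_amounts_ug, dtype=float), dose_times.shape
    )
    if obs_times.size == 0:
        raise ValueError("obs_times must be non-empty")
    t_end = float(obs_times.max())
    n_steps = int(round(t_end / dt))
    if abs(n_steps * dt - t_end) > 1e-9:
        raise ValueError("obs_times must be multiples of dt")
    obs_steps = np.rint(obs_times / dt).astype(int)
    if np.any(np.abs(obs_steps * dt - obs_times) > 1e-9):
        raise ValueError("obs_times must be multiples of dt")
    obs_lookup = {int(s): i for i, s in enumerate(obs_steps)}

    # --- PK block: modal decomposition of the central-compartment response
    s = kel + k23 + k32
    disc = np.sqrt(np.maximum(s * s - 4.0 * kel * k32, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    ka = _separate_rates(ka, lam1, lam2)
    # unit-bolus (into depot) central-amount response: sum_i B_i exp(-alpha_i t)
    alpha = np.stack([ka, lam1, lam2])                          # (3, n)
    b_ka = ka * (k32 - ka) / ((lam1 - ka) * (lam2 - ka))
    b_l1 = ka * (k32 - lam1) / ((ka - lam1) * (lam2 - lam1))
    b_l2 = ka * (k32 - lam2) / ((ka - lam2) * (lam1 - lam2))
    b_over_a = np.stack([b_ka, b_l1, b_l2]) / alpha             # (3, n)
    decay = np.exp(-alpha * dt)

    # per-event subject-level infusion windows and rates
    w_start = dose_times[:, None] + tlag[None, :]               # (n_dose, n)
    w_end = w_start + d_zero[None, :]
    rate = f1[None, :] * dose_amounts_ug[:, None] / d_zero[None, :]
    # steps each event can touch
    ev_lo = np.floor(w_start.min(axis=1) / dt).astype(int)
    ev_hi = np.ceil(w_end.max(axis=1) / dt).astype(int)
    events_by_step: dict[int, list[int]] = {}
    for j in range(dose_times.size):
        if dose_amounts_ug[j] == 0.0:
            continue
        for k in range(max(ev_lo[j], 0), min(ev_hi[j], n_steps)):
            events_by_step.setdefault(k, []).append(j)

    # --- BTK block constants
    a22 = -(koff + kinact)
    e_kdeg = np.exp(-kdeg * dt)
    growth = (1.0 - e_kdeg) / kdeg

    m = np.zeros((3, n))     # modal amplitudes of A2
    f = btk0.copy()
    rc = np.zeros(n)
    cc = np.zeros(n)
    c_prev = np.zeros(n)

    n_obs = obs_times.size
    out_f = np.empty((n_obs, n))
    out_rc = np.empty((n_obs, n))
    out_cc = np.empty((n_obs, n))
    out_c2 = np.empty((n_obs, n))
    out_a2 = np.empty((n_obs, n))
    if 0 in obs_lookup:
        i = obs_lookup[0]
        out_f[i], out_rc[i], out_cc[i] = f, rc, cc
        out_c2[i], out_a2[i] = 0.0, 0.0

    for k in range(n_steps):
        t1 = (k + 1) * dt
        # exact PK step: decay existing modes, inject this step's input windows
        m *= decay
        for j in events_by_step.get(k, ()):
            u1 = np.clip(w_start[j], t1 - dt, t1)
            u2 = np.clip(w_end[j], t1 - dt, t1)
            active = u2 > u1
            if not np.any(active):
                continue
            contrib = (
                rate[j]
                * b_over_a
                * (np.exp(-alpha * (t1 - u2)) - np.exp(-alpha * (t1 - u1)))
            )
            m += np.where(active[None, :], contrib, 0.0)
        a2 = m.sum(axis=0)
        c_new = np.maximum(conc_factor * a2, 0.0)

        # exact BTK step at the midpoint concentration
        c_mid = 0.5 * (c_prev + c_new)
        c_prev = c_new
        konc = kon * c_mid
        a11 = -(kdeg + konc)
        tr = a11 + a22
        d2 = np.sqrt((a11 - a22) ** 2 + 4.0 * koff * konc)
        mu1 = 0.5 * (tr + d2)
        mu2 = 0.5 * (tr - d2)
        det = mu1 * mu2
        f_ss = -a22 * ksyn / det
        rc_ss = konc * ksyn / det
        yf = f - f_ss
        yr = rc - rc_ss
        inv_d = 1.0 / np.maximum(d2, 1e-300)
        # spectral projections of the deviation from steady state
        cf1 = ((a11 - mu2) * yf + koff * yr) * inv_d
        cf2 = ((mu1 - a11) * yf - koff * yr) * inv_d
        cr1 = (konc * yf + (a22 - mu2) * yr) * inv_d
        cr2 = (-konc * yf + (mu1 - a22) * yr) * inv_d
        e1 = np.exp(mu1 * dt)
        e2 = np.exp(mu2 * dt)
        f = f_ss + cf1 * e1 + cf2 * e2
        rc = rc_ss + cr1 * e1 + cr2 * e2
        # covalent pool: exact convolution of the rc transient against e^{-kdeg t}
        j1 = _phi(mu1 + kdeg, dt, e1, e_kdeg)
        j2 = _phi(mu2 + kdeg, dt, e2, e_kdeg)
        cc = cc * e_kdeg + kinact * (rc_ss * growth + cr1 * j1 + cr2 * j2)

        i = obs_lookup.get(k + 1)
        if i is not None:
            out_f[i], out_rc[i], out_cc[i] = f, rc, cc
            out_c2[i], out_a2[i] = c_new, a2

    return PopulationResult(obs_times, out_f, out_rc, out_cc, out_c2, out_a2)


def _phi(shift, dt, e_mu, e_kdeg):
    """Stable evaluation of (exp(mu*dt) - exp(-kdeg*dt)) / (mu + kdeg).

    ``shift = mu + kdeg`` vanishes exactly at zero drug concentration (the
    slow BTK eigenvalue is then -kdeg); a second-order series takes over
    near the removable singularity.
    """
    small = np.abs(shift) * dt < 1e-6
    safe = np.where(small, 1.0, shift)
    direct = (e_mu - e_kdeg) / safe
    series = dt * e_kdeg * (1.0 + 0.5 * shift * dt)
    return np.where(small, series, direct)


def simulate_population_qd(individuals, dose_mg, days, obs_times, dt=0.05):
    """Convenience wrapper: once-daily ``dose_mg`` for ``days`` days.

    ``individuals`` is an :class:`btksim.population.IndividualParameters`
    batch; ``dose_mg`` may be a scalar or one amount per dosing day
    (dose-reduction schedules).
    """
    dose_times = 24.0 * np.arange(days, dtype=float)
    amounts = np.broadcast_to(np.asarray(dose_mg, dtype=float) * 1000.0, dose_times.shape)
    return simulate_population(
        kel=individuals.kel,
        k23=individuals.k23,
        k32=individuals.k32,
        ka=individuals.ka,
        tlag=individuals.tlag,
        d_zero=individuals.d_zero,
        f1=individuals.f1,
        conc_factor=individuals.conc_factor,
        kdeg=individuals.kdeg,
        ksyn=individuals.ksyn,
        btk0=individuals.btk0,
        kon=individuals.kon,
        koff=individuals.koff,
        kinact=individuals.kinact,
        dose_times=dose_times,
        dose_amounts_ug=amounts,
        obs_times=np.asarray(obs_times, dtype=float),
        dt=dt,
    )
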