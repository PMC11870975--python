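# btksim

Virtual-trial simulation of Bruton's tyrosine kinase (BTK) occupancy under
once-daily ibrutinib dosing in chronic lymphocytic leukemia (CLL).

Ibrutinib inactivates BTK irreversibly by covalent binding at Cys481, so the
usual reversible-inhibition potency measure (IC50) does not describe it well:
inhibition depends on the inactivation efficiency k_inact/K_I and on how fast
the cell resynthesizes BTK. `btksim` couples a published population
pharmacokinetic model of oral ibrutinib to a turnover + covalent binding
model of BTK, and uses Monte-Carlo populations of virtual patients to ask
the clinically relevant question: *which once-daily doses keep more than 90%
of BTK occupied at trough in more than 90% of patients* — in particular,
whether dose reductions from the standard 420 mg to 280 mg or 140 mg still
maintain deep BTK inhibition.

It is intended for pharmacometricians and quantitative clinical
pharmacologists who want a reproducible, tested implementation of this
model — to rerun the published scenarios, vary the assumptions (BTK
turnover, binding-constant uncertainty, bioavailability variability), or
reuse the fast population ODE engine.

## Model

**Pharmacokinetics** — open two-compartment disposition with sequential
zero/first-order oral absorption after a lag time, parameterized as apparent
oral quantities (typical values: CL/F = 1060 L/h, V2/F = 246 L,
Q/F = 865 L/h, V3/F = 9620 L, ka = 0.463 h⁻¹, Tlag = 0.283 h; zero-order
input duration D = 3.29 h fed / 1.10 h fasted, F1 = 1 fed / 0.67 fasted;
volumes scale allometrically with body weight, exponent 0.641, reference
80.4 kg). Free drug concentration is C2 = 1000·fu·(A2/V2)/MW with fu = 3%
and MW = 440.5 g/mol.

**BTK turnover** — zero-order synthesis, first-order degradation:
k_deg = ln 2 / t½,BTK, k_syn = BTK0·k_deg, with BTK0 = 1.04 nM and t½,BTK of
60 h (slow), 24 h (fast) or Uniform(12, 120) h across the population.

**Covalent binding** — free drug and free BTK form a reversible complex
(k_on = 1.72 nM⁻¹h⁻¹, k_off = 0.205 h⁻¹) that is inactivated at
k_inact = 95.76 h⁻¹; the covalent complex degrades at k_deg. Because
k_inact ≫ k_off, k_on ≈ k_inact/K_I. Binding does not deplete the
(micromolar-scale) drug amounts, so the drug block stays linear:

    dBTKf/dt  = k_syn − k_on·BTKf·C2 + k_off·BTKrc − k_deg·BTKf
    dBTKrc/dt = k_on·BTKf·C2 − (k_off + k_inact)·BTKrc
    dBTKcc/dt = k_inact·BTKrc − k_deg·BTKcc

**Endpoint** — occupancy = 100·(BTKrc + BTKcc)/(BTKf + BTKrc + BTKcc),
evaluated at the steady-state trough (24 h after the last dose of a 7-day QD
course, or the final trough of each 28-day cycle). Between-subject
variability is lognormal with the published %CVs; uncertainty in
(k_on, k_inact) is carried as 11 paired percentiles of their sampling
distributions. An additive residual error (variance 27.1 on the percent
scale) is applied only when comparing against observed occupancy data,
which ship as an embedded 320-observation fixture with exact-binomial
pooling into five dose groups.

The population engine advances the linear PK block in modal (eigen) form and
the BTK block with its exact constant-coefficient solution per 0.05 h step,
vectorized across all subjects; it matches an LSODA reference solution of
the full six-state system to < 1e-4 percentage points of occupancy, and runs
10,000 subjects × 7 days in seconds.

## Worked example

```python
from btksim import TrialDesign, run_virtual_trial, summarize, typical_patient_profiles

profiles = typical_patient_profiles(doses=(140, 420), half_lives=(24, 60))
print(profiles[["dose_mg", "t_half_btk_h", "btkf_reduction_pct", "occupancy_pct"]]
      .round(1).to_string(index=False))

design = TrialDesign(doses=(140.0, 420.0), n_subjects=2000,
                     scenario="uniform", seed=7)
for dose, dist in run_virtual_trial(design).items():
    s = summarize(dist.occupancies)
    print(f"{dose:.0f} mg QD: median {s['median']:.1f}% "
          f"({s['p5']:.1f}-{s['p95']:.1f}), >90%: {s['prop_gt90']:.1f}%")
```

prints

```
 dose_mg  t_half_btk_h  btkf_reduction_pct  occupancy_pct
     140            24                88.8           88.8
     420            24                95.5           95.5
     140            60                95.2           95.2
     420            60                98.1           98.1
140 mg QD: median 95.2% (81.5-98.7), >90%: 80.2%
420 mg QD: median 98.1% (91.2-99.5), >90%: 96.2%
```

The first block is the deterministic typical patient: at the day-7 trough,
free BTK is knocked down ~95–98% when BTK turns over slowly (t½ = 60 h) but
only ~89–96% with fast turnover (24 h) — turnover, not drug exposure, limits
the depth of inhibition. The second block is a 2,000-subject virtual trial
with heterogeneous turnover: at 420 mg about 96% of subjects keep >90%
occupancy at trough; at 140 mg that drops to ~80%, though the median subject
still sits above 95% occupancy.

The same operations are available from the shell:

```bash
btksim trial --dose 420 --n 10000 --scenario uniform --seed 1 --out out/
btksim sweep --scenario slow --n 2000 --seed 1 --out out/
btksim reduce --cycles 420:28,280:28,140:28 --n 10000 --seed 1 --out out/
btksim typical --out out/
```

Each run writes tidy CSVs plus a `manifest.json` (configuration, seed,
version) from which the output can be regenerated exactly.

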