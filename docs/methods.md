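# Methods

## Model structure

The model has three coupled pieces.

**Drug disposition.** Ibrutinib follows an open two-compartment model with
first-order elimination from the central compartment and sequential
zero/first-order oral absorption: each dose enters the depot compartment as
a zero-order input of duration D starting Tlag after administration, and the
depot empties into the central compartment at the first-order rate ka. All
disposition parameters are apparent oral quantities (CL/F, V2/F, Q/F, V3/F);
micro-constants are k_el = CL/V2, k23 = Q/V2, k32 = Q/V3 with volumes taken
after allometric body-weight scaling ((WT/80.4)^0.641, applied to volumes
only). Fed status sets the reference bioavailability (F1 = 1 fed, 0.67
fasted) and the input duration (3.29 h fed, 1.10 h fasted); antacids stretch
D by 61%. Amounts are kept in ug so that with volumes in liters the free
concentration formula C2 = 1000·fu·(A2/V2)/MW (fu = 0.03, MW = 440.5 g/mol)
is dimensionally exact in nM; doses in mg are converted on input.

**BTK turnover.** Free BTK is synthesized at the zero-order rate
k_syn = BTK0·k_deg and degraded at k_deg = ln2/t½,BTK, so the no-drug steady
state is BTK0 (1.04 nM in CLL patients). The half-life is the key
sensitivity parameter: 60 h (the value estimated from PK/PD analyses in CLL)
defines the "slow" scenario, 24 h (upper end of in-vitro measurements) the
"fast" one, and Uniform(12, 120) h represents a population heterogeneous in
turnover.

**Covalent binding.** Free drug and free BTK form a reversible complex
(k_on, k_off) which is irreversibly inactivated at k_inact; the covalent
complex degrades at k_degc = k_deg. Since k_inact ≫ k_off, k_on is
identified with the published inactivation efficiency k_inact/K_I. Binding
consumes no measurable drug (nanomolar target vs micromolar drug amounts),
so the drug equations carry no binding loss term and the PK block is linear
and autonomous. Two consequences used throughout the tests: free
concentration is exactly proportional to dose, and occupancy is independent
of BTK0 (the BTK block is linear in the BTK states).

The occupancy statistic is the bound fraction of total BTK,
100·(BTKrc + BTKcc)/(BTKf + BTKrc + BTKcc), reported in percent. The
intrinsic (noise-free) statistic is used for all simulation summaries; an
additive Gaussian residual error with variance 27.1 (percent² scale) is
applied only when comparing predictions with observed occupancy
measurements, and noisy values are clipped to [0, 100] (out-of-range
handling is not specified by the source; clipping biases proportions near
the boundaries in a predictable direction, which a test pins down).

As printed, the reversible complex carries no degradation term, so total
BTK is only approximately conserved; with the default constants the
deviation stays below 2% of baseline at steady state (asserted numerically)
because the reversible pool is transiently small (k_inact ≫ k_off).

## Virtual populations

Between-subject variability is lognormal: parameter = typical·exp(η),
η ~ N(0, ω²), with ω = %CV/100 (CL/F 21.9, V2/F 153, Q/F 60.7, V3/F 47.3,
Tlag 27.8, D 20.9, F1 62.8, BTK0 78.9, half-life 25.0; ka carries no BSV).
Parameters are sampled independently — no IIV correlation matrix is
published. The F1 variability is ambiguous in the source (typical value
"1 FIX" with a BSV column of 62.8): both readings were implemented and
compared against the published trough-occupancy table and ED90s; the
BSV-on, uncapped reading reproduces the 140 mg row almost exactly and was
kept as the default, with a `f1_bsv` toggle in `PopulationSpec`. The
remaining ~1 pp overshoot in distribution width at higher doses (responder
proportions ~1 pp below the published table at 280-560 mg) is attributed to
this ambiguity and to unpublished IIV correlations.

Uncertainty in (k_on, k_inact) is represented by the 5th…95th empirical
percentiles of 100,000 draws from N(1.72, 0.60²) and N(95.76, 88.56²).
The k_inact distribution has substantial negative mass (its untruncated 5th
percentile is negative); draws are rejection-sampled to strictly positive
support, the least-informative resolution consistent with a rate constant.
The two parameters are coupled by shared percentile rank (11 scenarios, the
median pair being the central scenario) rather than crossed, which
reproduces median-plus-band uncertainty displays with 11 curves.

Trials share one sampled population across all doses of a sweep (common
random numbers), making dose-response curves smooth and per-subject
monotone in dose. The trough is defined as 24 h after the last administered
dose (t = 168 h for 7-day QD courses; the final trough of each cycle for
dose-reduction schedules) — the only unambiguous reading of "trough of the
last dosing day". Steady state is reached by about day 4, so day-7 and
day-28 troughs agree (asserted within Monte-Carlo error).

## Numerical scheme

Two integrators share the model definition:

* **Reference path** (`simulate_individual`): LSODA on the full six-state
  system, rtol 1e-8 / atol 1e-10, restarted at every discontinuity of the
  zero-order input so local error control is never polluted by corners.
  The binding subsystem is stiff (k_inact ≈ 96 h⁻¹ against turnover rates
  of ~0.01 h⁻¹), which LSODA handles by switching to BDF.

* **Population path** (`engine.simulate_population`): an exact exponential
  stepper vectorized across subjects. The linear PK block is advanced in
  modal form — the central amount is a sum of three exponential modes
  (ka and the two disposition eigenvalues) whose amplitudes decay exactly
  per step, with each absorption window injected through its exact
  within-step convolution integral (per-subject lag and duration need not
  align with the step grid). Given the free concentration, the (free,
  reversible) BTK pair is advanced with the closed-form 2×2 matrix
  exponential and the covalent pool with an analytic convolution against
  exp(−k_deg·t); the removable singularity at zero concentration (where one
  eigenvalue equals −k_deg exactly) is handled by a series branch. The only
  discretization error is holding C2 at its step-midpoint value
  (trapezoidal, O(dt²)); at the default dt = 0.05 h the trough occupancy
  agrees with the reference path to < 1e-4 percentage points across
  variable subjects, and halving dt changes results by < 1e-4 pp. Repeated
  exponential rates (a measure-zero event under continuous BSV) are
  separated by a relative nudge of 1e-5.

Degenerate inputs are validated up front: non-positive rates, volumes or
durations raise parameter errors; observation times must sit on the step
grid; an all-zero BTK state makes occupancy undefined and raises.

## ED90 estimation

The dose-response endpoint is the proportion of subjects with occupancy
strictly above 90% at trough (ties at exactly 90 are non-responders; a
measure-zero event for the continuous model). A sigmoid Emax (Hill) curve
p(d) = pmax·d^h/(d50^h + d^h) is fitted with the plateau free, because the
scenarios' asymptotes differ; ED90 = d50·9^(1/h), the dose reaching 90% of
the fitted plateau. Residuals are weighted by the binomial standard error
sqrt(p(1−p)/n) (floored near 0/1): this is the natural weighting for
responder proportions, lets the precisely-determined plateau points anchor
pmax, and is markedly more seed-stable than unweighted least squares. The
fit refuses to extrapolate: if the top dose does not reach 95% of the
fitted plateau an estimation error is raised. Uncertainty intervals are the
5th/95th percentiles of ED90 across the 11 binding-constant percentile
curves.

The source's own fitting procedure is unpublished; reproduction of its
ED90s to within ~±15% is the realistic expectation, and the packaged
checks use that band.

## Synthetic observed studies

`generate_synthetic_study` emulates the design of the occupancy studies
used for model evaluation: subjects allocated to QD doses, occupancy read
pre-dose on days 2/8/15/29 (24·(day−1) h), residual error added, responders
binarized at >90%. It shares the simulation model with the predictor, so
round-trip agreement (generator → evaluator) demonstrates self-consistency
of the pipeline, not external validity. What passing tests show: the
sampling, integration, pooling and comparison machinery is correct, and
the embedded observed table is internally consistent (counts conserved,
proportions re-derivable). What they do not show: that real BTK occupancy
assays behave like additive-Gaussian-noise readouts of this model, that
IIV is uncorrelated lognormal, or that tumor-type strata (not broken out
in the observed table) are exchangeable.

Observed responder counts are reconstructed from the printed rounded
percentages (round(pct·N/100)); the reconstruction reproduces the printed
overall 82% (262/320). Pooled dose-group intervals are Clopper–Pearson
(exact binomial), cross-checked against statsmodels.

## Default problem sizes

Trough-occupancy trials and the dose-reduction cascade run 10,000 subjects
(the published scale) in the acceptance script; the test suite uses 2,000
subjects, where quantile and binomial Monte-Carlo error is ~1 pp and the
published values are reproduced within ±2.5 pp. ED90 sweeps use a 20-dose
grid spanning 1–1100 mg with 2,000 subjects per dose and the median
binding constants. The deterministic typical-patient profiles integrate in
well under a second each.

## Known limitations

* The typical-patient trough free-drug/free-BTK ratio spans 2.2–29.7 across
  140–560 mg (t½ = 60 h); the upper end exceeds the ~25× reported for the
  same scenario, a ~19% discrepancy at the highest dose whose origin
  (rounding, or small procedural differences in an inaccessible supplement)
  cannot be resolved from the printed record. The corresponding knockdown
  bounds (≥95% slow, ≥88% fast) do reproduce.
* Responder proportions at 280–560 mg sit ~1 pp below the published table;
  see the F1-variability discussion above.
* No parameter estimation: the PK model is taken as published, and the
  package deliberately contains no fitting machinery for it. No
  inter-occasion variability, no adherence/missed-dose modelling, no
  covariates beyond weight/fed/antacid, and no exposure–response (ORR/PFS/
  OS) claims — occupancy is the terminal endpoint here.
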