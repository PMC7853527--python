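# Methods

This note documents the models, parameter choices and numerical decisions
behind `frrfprod`, and what the synthetic campaigns do and do not establish
about real field data.

## The measurement chain

The package treats the conversion of PSII electron transport to carbon
fixation as a chain of small, separately testable models.

**Photophysiology.** From dark and ambient-light fluorescence yields the
package derives Fv/Fm = (Fm−Fo)/Fm, the open-centre fraction
qP = (F′−Fo′)/(Fm′−Fo′), and the normalised Stern–Volmer quenching
NPQ_NSV = Fo′/(Fm′−Fo′). Records with Fm′ = Fo′ have an undefined qP and are
flagged and excluded. The quality gate keeps records whose single-turnover
closure probabilities Rσ_PSII and Rσ_PSII′ lie in [0.03, 0.08], bounds
inclusive (the rejection rule is strictly outside the band). Dark-state bias
in cyanobacteria-dominated samples (overestimated Fo after brief dark
acclimation) is flagged in the QC summary but not corrected.

**RCII and electron transport.** RCII = K_R/E_FRRf × Fo/σ_PSII × 10⁻⁹, with
the instrument ratio K_R/E_FRRf a single configured scalar (default 10¹²,
constant across samples and taxa). The RCII-specific electron transport rate
is J_f = E × σ_PSII′ × qP. σ_PSII is carried in nm² while the product needs
m² and mole units; the bridge is a single constant,
`SIGMA_UNIT_SCALE = N_A × 10⁻⁶ × 10⁻¹⁸ × 10⁻³ ≈ 6.022×10⁻⁴`
(μmol photons → photons, nm² → m², e⁻ RCII⁻¹ → μmol e⁻ nmol RCII⁻¹). It is
configurable on `InstrumentConfig`; its correctness within the package is
asserted operationally by the noise-free round trip, which fails if the
generator and the analysis disagree about it.

**Light field.** PAR attenuation is log-linear per layer: ln E is regressed
on depth; every interior observed depth is tried as a breakpoint (the break
point is shared by both segments) and the two-layer model is adopted when an
F-test on residual sums of squares is significant at α = 0.05 (configurable).
Degenerate profiles (no attenuation) clamp K_d to 10⁻⁶ m⁻¹ and set a flag.
Spectral irradiance follows Beer–Lambert over a 1 nm grid on 400–700 nm with
a four-component absorption budget: pure water, CDOM
(a_CDOM(320)·e^(−0.017(λ−320)), basin-specific 1.03/2.28 m⁻¹ anchors),
non-algal particles (0.264·e^(−0.004(λ−440)) m⁻¹) and chlorophyll-scaled
phytoplankton absorption. The spectral correction factor is a ratio of plain
grid sums (the defining operator is a summation, not an integral); it is
homogeneous of degree one in each spectrum, hence invariant to any rescaling
of the inputs, and the grid step is configurable. The packaged pure-water and
phytoplankton absorption spectra are *synthetic stand-ins* shaped like the
measured curves (exponential rise for water; 440/675 nm peaks for eukaryote
communities, a 625 nm phycocyanin shoulder for cyanobacteria-dominated ones);
no literature coefficient set is reproduced, and all tests run against these
packaged shapes.

**Incubations.** Oxygen bottles: JV_O = (NP_O − R_d) × 3.47×10⁻², where the
constant is the unit chain (1/3600)·(1000/32)·4 rounded to three significant
figures, and R_d is the signed O₂ change rate in the dark bottle (negative
while respiring), so NP_O − R_d is gross evolution. ¹³C bottles use the
standard tracer mixing form GP_C = POC·(a_inc − a_nat)/(a_DIC − a_nat)/t with
a configurable natural-abundance default of 1.1 atom%; only atom-% differences
enter. PB_C = GP_C/RCII with the RCII of the source water.

**P–E curves.** Two forms through the origin: Webb
P = P_s(1−exp(−αE/P_s)) and the Platt three-parameter photoinhibition form
P = P_s(1−exp(−αE/P_s))·exp(−βE/P_s), which nests the Webb form at β = 0.
Model choice is automatic: the three-parameter form is used when the response
at the highest irradiance falls more than 5% (configurable) below the
observed maximum and at least four points are available. Initialisation is
deterministic — α₀ from the slope through the two lowest-irradiance points,
P_s0 = max response, β₀ = 0.01α₀ — with bounded trust-region least squares
(positivity constraints, tolerances 10⁻¹⁵, capped iterations), so identical
data give identical fits. Non-convergence sets a flag on the results object
rather than failing silently.

**Electron requirement.** Ф_e,C = J_f/PB_C × 43.2 (3600 s h⁻¹ × 12 mg C
mmol⁻¹ × 10⁻³), computed per FRRf record by evaluating the date's fitted
PB_C–E curve at the record's in-situ irradiance. Values below the mechanistic
floor of 4 are retained as "apparent" (bottle artifacts affect all bottles
alike) and counted in the run warnings. Ф_e,C is invariant to rescaling RCII,
which cancels between the two RCII-specific rates.

## The Ф_e,C statistical model

The response is strictly positive and right-skewed, modelled as a gamma GLM
with log link (statsmodels). The surrounding procedure:

1. **Stratified bootstrap** removes the sampling bias against bright surface
   layers: per date, 60 draws with replacement from each of four depth strata
   (0–3.75, 3.75–7.5, 7.5–12.5, 12.5–17.5 m) in the north basin and 80 from
   each of three strata (0–1, 1–3, 3–5.5 m) in the south — 240 rows per date,
   3360 for the default 14-date campaign. Each (date, stratum) has its own
   deterministic substream derived from the global seed by hashing, so the
   result is independent of iteration order.
2. **Collinearity screen**: Spearman ρ over all candidates with the
   large-sample t-approximation for p (average ranks for ties); pairs with
   |ρ| ≥ 0.7 and p < 0.05 are collinear and the lower-priority member is
   dropped. The priority order is the canonical 13-term candidate list, so
   auxiliary proxies (NPQ_NSV, RCII, the zygnematophyte fraction) are the
   ones removed when they collide with PAR/Fv/Fm, Chl-a and the diatom
   fraction respectively.
3. **Transformation**: detection-limit substitution (NH₄ → 0.1 μmol L⁻¹,
   biomass fractions → 0.1%), natural log, then per-column z-scoring. The
   transform parameters are stored so model predictions on new raw
   covariates use identical scaling.
4. **GLM + diagnostics**: ML fit, per-term SEs/t/p, AIC, VIF (OLS R² of each
   regressor on the rest), and two pseudo-R² conventions — squared Pearson
   correlation of observed vs fitted response, and 1 − D_model/D_null — both
   reported because R² is not uniquely defined for a gamma GLM and neither is
   privileged.
5. **All-subsets AIC**: every subset of the k ≤ 16 candidate terms is fitted
   and ranked (2¹³ = 8192 models for the default 13). Besides the overall
   best model, the best subsets excluding nutrients, and excluding nutrients
   plus phytoplankton composition, are extracted — the parsimonious-model
   comparison for campaigns without nutrient chemistry or microscopy.

## Daily GPP

PB_f = J_f/Ф_e,C × 43.2 uses the model-predicted Ф_e,C; PB profiles are
evaluated hourly, E(z,t) = E₀(t)·attenuation(z) with a half-sine photoperiod
(default 12 h) and the date's fitted layered K_d, and the depth integral uses
the trapezoid rule on a 1.25 m (north) / 0.5 m (south) grid down to the
deepest sampled depth. Results are reported in mg C m⁻² d⁻¹ with units
tracked end-to-end; the ratio GPP_f/GPP_13C is the model-validation summary.

## The synthetic campaign generator

The generator's defaults are the study design itself: 14 dates (7 per
basin) with each date's tabulated field sub-surface PAR and layered K_d, four
excitation combinations with per-combination Rσ centres (0.036/0.039/0.041/
0.045 dark; slightly higher ambient), five incubator light levels
(100/65/30/10/1.6% of sub-surface PAR) with station-specific source depths,
and covariates drawn uniformly within the field-observed ancillary ranges
(temperature 7.5–30.2 °C, PO₄ 0.01–0.04 μmol L⁻¹, …) composed of a
month-driven seasonal sinusoid, a per-date jitter, a linear vertical gradient
and independent per-depth patchiness. One bloom date is cyanobacteria-
dominated (fraction > 50%), which switches the phytoplankton absorption model
and scales the fluorescence sensitivity of excitation combinations lacking
the 633 nm LED.

Ground truth: Ф_e,C = exp(Xβ)·ε with X the standardised log covariate matrix
(the exact transform the analysis applies), β defaulting to the field-calibrated
best-model coefficients (intercept 1.83, temperature 0.51, …; PAR 0 since it
was not selected), and ε gamma with mean 1 and shape 5. The shape was fixed a
priori so that the log-scale signal variance implied by the default β
(≈ 0.43) against trigamma(5) ≈ 0.22 gives an explained-variance fraction of
the order the field method reports (~0.6–0.7). Fluorescence observables are
constructed so each date's J_f(E) lies exactly on a Webb curve (qP absorbs
the depth structure of the SCF), oxygen and ¹³C bottle observables are
forward-simulated from the same latent curves, and measurement noise enters
through the latent photophysiological parameters (multiplicative, CV 5% by
default) so reconstructed yields always satisfy Fm ≥ F′ ≥ Fo′.

A single global seed drives named substreams (counter-based splitting), so
identical scenarios give bit-identical tables regardless of generation order.

**The noise-free configuration** (`SyntheticScenario.noise_free`) switches
off the gamma dispersion, the FRRf noise and all vertical covariate
structure. With covariates constant within a date, Ф_e,C is constant within
each date's P–E fit group and the pipeline inverts the generator exactly
(observed round-trip error ~10⁻¹⁴ relative, asserted at ≤10⁻⁹). This
flattening is necessary: a single per-date P–E curve cannot represent a
depth-varying Ф_e,C exactly — the same approximation the field procedure
makes — so the exact-inversion check is defined where exact inversion is
mathematically possible.

**What the synthetic campaigns do not show.** Covariates are generated with
only the correlation structure needed to exercise the screen (NPQ_NSV vs
Fv/Fm and PAR, RCII vs Chl-a, zygnematophytes vs diatoms near the ρ = 0.7
threshold); real covariance structure in lakes is richer, and nothing here
validates the Ф_e,C model form against real water. Flashlet-level transients,
state transitions in cyanobacteria, bottle artifacts (UV stress, wall
growth) and diel variation of carbon fixation are all outside the generator,
as they are uncorrected in the measurement procedure itself.

## Problem sizes and runtime choices

Coefficient-recovery checks use the full default campaign (3360 bootstrap
rows) over 20 replicate seeds; at that size the gamma GLM recovers a
temperature-only generating coefficient of 0.51 to within a few hundredths
(Monte-Carlo SE ≈ 0.008 for the 20-seed mean). Model-selection consistency
is exercised with six candidate terms (64 subsets) at n = 1000, where strong
effects are recovered in ≥ 90% of replicates; the full 2¹³ enumeration is
run once at a reduced n in the unit suite and at full n in the acceptance
script. P–E recovery uses 100 replicate curves at 5% multiplicative noise.

## Known limitations

* The end-to-end covariate effects on pipeline-recovered Ф_e,C are attenuated
  relative to the generating coefficients, because the per-date P–E inversion
  smooths within-date Ф_e,C variation (visible as the difference between the
  acceptance script's `beta_temperature_recovered` — the GLM stage, ≈ 0.51 —
  and `temperature_coefficient_end_to_end`). This mirrors a genuine property
  of the field procedure, not an implementation defect.
* The two basins share covariate generators, so the synthetic basin contrast
  in mean Ф_e,C is weaker than a real oligotrophic/mesotrophic pair.
* K_R/E_FRRf is a single constant; taxon- or state-specific variation is
  deliberately left to the statistical model, not the instrument constants.
* Apparent Ф_e,C < 4 is retained, flagged, and never truncated; analyses that
  exclude sub-floor values will differ.
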