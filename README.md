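# frrfprod

Phytoplankton gross primary productivity (GPP) from active chlorophyll-*a*
fluorescence. Fast repetition rate fluorometry (FRRf) measures the electron
transport rate at photosystem II (ETR_PSII) in real time, but converting
electrons to carbon requires the **electron requirement for carbon fixation**
(Ф_e,C, mol e⁻ mol C⁻¹; mechanistically ≥ 4), which varies with environment
and community composition. `frrfprod` implements the full inference chain
from FRRf observables and bottle-incubation productivity to a statistical
Ф_e,C model and daily depth-integrated GPP, for aquatic ecologists and
bio-opticians working in lakes and coastal waters.

The chain, in the field's standard notation:

* **RCII concentration** (Oxborough-type): `RCII = K_R/E_FRRf × Fo/σ_PSII × 10⁻⁹`
* **Electron transport**: `J_f = E × σ_PSII′ × qP` with
  `qP = (F′−Fo′)/(Fm′−Fo′)`, and `JV_f = J_f × RCII`;
  quality gate `0.03 ≤ Rσ_PSII, Rσ_PSII′ ≤ 0.08`
* **Spectral correction**:
  `SCF = [Σ a*_phy E_insitu · Σ E_FRRf] / [Σ a*_phy E_FRRf · Σ E_insitu]`,
  with underwater spectra from Beer–Lambert attenuation
  `E(λ,z) = E₀(λ) exp(−[a_w + a_CDOM + a_NAP + chl·a*_phy] z)` and layered
  PAR attenuation `E_bot = E_top exp(−K_d dZ)`
* **Incubations**: `JV_O = (NP_O − R_d) × 3.47×10⁻²` (light–dark O₂ bottles,
  4 e⁻ per O₂); ¹³C tracer `GP_C`, normalised as `PB_C = GP_C / RCII`
* **P–E curves**: Webb `P = P_s(1−e^{−αE/P_s})` or, under photoinhibition,
  Platt `P = P_s(1−e^{−αE/P_s})e^{−βE/P_s}`
* **Electron requirement**: `Ф_e,C = J_f / PB_C × 43.2`, modelled by a gamma
  GLM (log link) over 13 standardised log covariates after stratified
  bootstrap resampling (240 obs/date, 3360 total), a Spearman collinearity
  screen (|ρ| ≥ 0.7, p < 0.05) and all-subsets AIC ranking with VIF checks
* **Daily GPP**: `GPP = ∫₀^Z RCII(z) Σ_t PB(z,t) dz` by both the
  fluorescence route (via the modelled Ф_e,C) and the ¹³C route

Because no raw field campaign is bundled, a first-class synthetic-data
generator (`frrfprod.synthetic`) emulates the study design — 14 sampling
dates across an oligotrophic north and mesotrophic south basin, four
excitation-wavelength combinations (444/512/633 nm), layered K_d, bottle
incubations at five light levels — with a known gamma/log-link ground truth
for Ф_e,C, so every stage is testable against latent truth.

## Worked example

```python
from frrfprod import PipelineConfig, SyntheticScenario, run_pipeline

config = PipelineConfig(scenario=SyntheticScenario(seed=1), rank_submodels=False)
result = run_pipeline(config)

print(result.glm_full.summary())
print(result.gpp_table[["date", "basin", "gpp_13c", "gpp_f_full", "ratio_full"]]
      .head(5).round(1).to_string(index=False))
```

prints (abridged):

```
Gamma GLM (log link) for the electron requirement for carbon fixation
n = 3360   AIC = 14821.0   R2(Pearson) = 0.533   R2(deviance) = 0.652
                        Coefficient  Std. Error  t value         P  VIF
const                          1.96     0.00574      341         0  NaN
temperature                    0.34      0.0127     26.8 2.31e-158 4.89
...
fraction_cyanobacteria       -0.113      0.0122    -9.23  2.83e-20 4.53

      date basin  gpp_13c  gpp_f_full  ratio_full
2018-07-23 north   3413.1      3157.6         0.9
2018-07-30 north   2608.8      1854.9         0.7
2018-08-28 south    933.9       933.2         1.0
```

The coefficient table is the fitted Ф_e,C model on the log-link scale over
standardised log covariates (here temperature is the strongest positive
driver and the cyanobacterial fraction the strongest negative one, with all
VIF < 10, i.e. negligible residual collinearity). The GPP table compares the
daily depth-integrated production of each date by the two independent routes:
`gpp_13c` and `gpp_f_full` in mg C m⁻² d⁻¹ and their ratio, which sits near 1
when the Ф_e,C model is well specified.

A CLI mirrors the stages: `frrfprod simulate | qc | optics | fit-pe |
fit-phi | gpp | run-all | report-excitation` (see `frrfprod --help`).

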