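# netpet

Reference-tissue kinetic modeling and static-window quantification of dynamic
brain PET, with a synthetic-cohort simulator and method-agreement statistics.

## The problem

Quantifying neuroreceptor or transporter availability with a reversible PET
tracer — for instance noradrenaline-transporter imaging with
(*S,S*)-[¹¹C]-*O*-methylreboxetine in people with Parkinson's disease —
classically needs a long dynamic acquisition (90–120 min) followed by
compartmental modeling against a reference region. Long protocols are a real
burden for movement-disorder patients, especially off medication. A practical
alternative is a short *static* scan late after injection, quantified as a
simple tissue-to-reference ratio. `netpet` implements both quantification
routes and the statistics needed to decide whether the short scan can replace
the full one:

1. **Kinetic route.** Per subject, the three-coefficient multilinear
   reference-tissue model (MRTM) fitted to a high-binding region (merged
   left+right thalamus) vs the reference region (occipital cortex) estimates
   the reference efflux constant *k*₂′. The cohort-mean *k*₂′ is then fixed
   and transferred to the two-parameter models MRTM2 and SRTM2, which yield
   the non-displaceable binding potential BP<sub>ND</sub> for every region
   from the 0–90-min data.
2. **Static route.** Four 30-min windows starting at 30, 40, 50 and 60 min
   post-injection, each exactly six consecutive 300-s frames, quantified as
   BP = (mean VOI − mean reference) / mean reference.
3. **Agreement.** Per region and window: Spearman's ρ and the absolute-
   agreement intraclass correlation ICC(A,1) between static and model BP;
   pooled over regions: ordinary least-squares regressions of static on model
   BP; plus Bonferroni-adjusted Spearman correlations of thalamic binding
   with clinical covariates (age, disease duration, H/Y, UPDRS-III, LEDD).

Because no patient-level data are public, the package ships a first-class
synthetic-cohort generator whose curves satisfy the models' kinetic
assumptions exactly: a Feng-type plasma input drives a one-tissue reference
region (*C*<sub>R</sub> = *K*₁′ · *C*<sub>p</sub> ⊗ e<sup>−*k*₂′*t*</sup>)
and SRTM2-kinetic targets
(*C*<sub>T</sub> = *R*₁[*C*<sub>R</sub> + (*k*₂′ − *k*₂ₐ) *C*<sub>R</sub> ⊗
e<sup>−*k*₂ₐ*t*</sup>], *k*₂ₐ = *R*₁*k*₂′/(1 + BP<sub>ND</sub>)), so every
estimator is testable against known ground truth.

## Model equations

MRTM (operational, ordinary least squares over frame mid-times ≥ *t*\*):

    C_T(T) = γ₁ ∫₀ᵀ C_R dt + γ₂ ∫₀ᵀ C_T dt + γ₃ C_R(T)
    k₂′ = γ₁/γ₃,  BP_ND = −(γ₁/γ₂ + 1)

MRTM2 (two coefficients, *k*₂′ fixed):

    C_T(T) = γ₁ (∫₀ᵀ C_R dt + C_R(T)/k₂′) + γ₂ ∫₀ᵀ C_T dt,  BP_ND = −(γ₁/γ₂ + 1)

SRTM2 (basis-function sweep over *k*₂ₐ with golden-section refinement):

    C_T = R₁ [C_R + (k₂′ − k₂ₐ)(C_R ⊗ e^{−k₂ₐ t})],  BP_ND = R₁ k₂′/k₂ₐ − 1

ICC(A,1) for *n* subjects × 2 methods from ANOVA mean squares:

    ICC(A,1) = (MS_R − MS_E) / (MS_R + MS_E + (2/n)(MS_C − MS_E))

## Worked example

Simulate the default 10-subject cohort (33-frame/120-min schedule, frame
noise α = 0.3) and run the whole chain:

```bash
netpet run --seed 1 --noise 0.3 --outdir out/
```

prints

```
population k2' = 0.0327 1/min
BP_30-60 = 0.53 x BP_SRTM2 -0.01, R2 = 0.90, p = 1.9e-50
BP_40-70 = 0.61 x BP_SRTM2 -0.01, R2 = 0.95, p = 1.8e-64
BP_50-80 = 0.67 x BP_SRTM2 -0.01, R2 = 0.96, p = 6.3e-72
BP_60-90 = 0.73 x BP_SRTM2 -0.00, R2 = 0.98, p = 2.4e-82
```

(MRTM2 lines omitted here; they are nearly identical.) Reading the numbers:
the estimated population efflux constant sits near the generating value of
0.0322 min⁻¹; the pooled regression slope of static on model BP climbs with
the window start time and stays below one — early static windows compress
the between-region BP range because high-binding regions have not yet
reached transient equilibrium, and the 60–90-min window tracks the kinetic
models most faithfully (highest slope and R²). `out/` contains the cohort
(TAC CSVs + ground truth + manifest), per-subject *k*₂′, model and static BP
tables, the region-wise ρ/ICC agreement report and the regression summary.

The same objects are available as a library:

```python
import netpet as nx
cohort = nx.generate_cohort(nx.CohortConfig(noise_alpha=0.0, seed=1))
pop = nx.estimate_population_k2p(cohort)          # MRTM, merged thalamus
model = nx.model_bp_table(cohort, pop.mean)        # MRTM2 + SRTM2 BP_ND
static = nx.static_bp_table(cohort)                # four 30-min windows
agreement, regressions = nx.build_agreement_tables(static, model)
```

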