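# Methods

## The reaction network

Both interferon pathways share one network; only parameter sharing differs
between the model variants. Per pathway *p* ∈ {IFNAR (type I), IFNLR
(type III)} the species are free receptor complex `R_p`, active
(ligand-bound) complex `RA_p`, and desensitised complex `RIN_p`; the
pathways share extracellular IFN pools `IFN_I`/`IFN_III`, a single
unphosphorylated STAT pool (duplicated pools are a configuration option),
per-pathway p-STAT, and the ISG transcript. Concentrations are in nM,
time in hours.

    dIFN_p/dt  = −k_ifn_deg · IFN_p                       (abundant bath)
    dR_p/dt    = k_rdeg (r_tot_p − R_p) − a_p IFN_p R_p + k_rec RIN_p
    dRA_p/dt   = a_p IFN_p R_p − (k_inact_p + k_rdeg) RA_p
    dRIN_p/dt  = k_inact_p RA_p − (k_rec + k_rdeg) RIN_p
    dSTAT/dt   = −Σ_p φ_p + k_dephos Σ_p pSTAT_p
    dpSTAT_p/dt = φ_p − k_dephos pSTAT_p,   φ_p = k_stat_p e_p RA_p STAT
    dISG/dt    = k_isg_deg (1 + Σ_p g_p h(pSTAT_p) − ISG)

with `h(x) = xⁿ/(Kⁿ + xⁿ)` (Hill coefficient n = 1 by default) and
`e_I = 1`, `e_III` the IFNLR efficacy factor. `ISG` is simulated directly
as fold change over its own untreated steady state, so the basal
transcription rate cancels and the zero-stimulus fixed point has
`ISG = 1` exactly. The engineered high-affinity type III ligand is a
multiplicative factor (> 1) on the IFNLR activation rate only, leaving all
downstream kinetics untouched — which is why it raises the response
magnitude at sub-saturating doses without changing its shape.

**Inactivation as desensitisation.** Active complexes convert to a
desensitised pool that recycles slowly (`k_rec`) rather than returning
directly to the free pool. If inactivation merely recycled receptors, a
fast inactivation rate would be kinetically neutral at quasi-steady state
and the transient type I response could not be produced; the desensitised
pool is what lets fast IFNAR inactivation shut the pathway down after an
initial burst. Consequently "receptor conservation" means
`R + RA + RIN = const` per pathway when synthesis and degradation are
switched off.

**Ligand bath.** Binding does not deplete extracellular IFN (a depletion
mode exists as a configuration flag). In culture the medium volume vastly
exceeds the cellular receptor content, so depletion by binding is
negligible against first-order decay of the cytokine.

**Steady state.** The zero-stimulus steady state is computed by
long-horizon integration followed by a Newton polish on the derivative
map, with an acceptance tolerance of 1e-8 nM/h; for this network the fixed
point is also available in closed form (`R_p = r_tot_p`, everything active
at zero, `ISG = 1`), which the estimation path uses directly.

## Model variants and parameter layouts

Every variant carries pathway-specific receptor abundances. M2, M3 and M4
additionally split the STAT-activation, receptor-regulation
(activation + inactivation), or ISG-expression group respectively. The
free-parameter list of a fit (`parameter_layout`) is what defines k in the
AICc; with the default estimated groups this gives k = 6, 7, 8, 7 for
M1–M4. A split group whose shared value is otherwise held fixed
contributes the pathway-III rate as its single extra free parameter.

Two estimation presets are provided:

- `DEFAULT_FREE_GROUPS` — receptor abundances plus the kinetic rates
  (activation, inactivation, ISG gain, ISG decay). Used for model
  selection, where the variants' relative fit quality is what matters.
- `RATE_FREE_GROUPS` — abundances held at their set values; free are the
  activation and inactivation rates per pathway, the ISG gain and decay,
  and the IFNLR efficacy factor. Used for the calibration and
  profile-likelihood study. The reason is structural: over most of the
  physiological dose range the transcription term operates near-linearly
  in p-STAT, so receptor abundance, STAT-activation rate and
  transcription gain enter the observable almost purely as a product —
  freeing them jointly creates an amplitude ridge along which none of
  them is individually identifiable. Receptor abundances are treated as
  measured (set) quantities, mirroring how such models are calibrated in
  practice, and one amplitude parameter per signalling chain is estimated.

## Calibration

The objective is wSSR = Σ (y_sim − y_obs)²/σ², with per-point variances
from the study's recipe σ² = mean × CV̄ (the "literal" mode; since the
recipe is dimensionally a standard deviation, a "squared" mode
(mean × CV̄)² is provided as well). Fold changes are fitted on the linear
scale. Optimisation runs in log₁₀ parameter space (rates span decades)
with box bounds of ±4 decades around the initial guess, a bounded
trust-region least-squares solver with numerical Jacobians, and seeded
Latin-hypercube multi-starts of ±1 decade (the first start is the nominal
guess). ODE tolerances during fitting are rtol 1e-6 / atol 1e-9;
user-facing simulation defaults to rtol 1e-8 / atol 1e-10 (halving the
tolerance changes reported fold changes by < 1e-4 relative).

The receptor-overexpression re-fit freezes every kinetic rate at the base
optimum and frees exactly two multiplicative abundance factors, mirroring
how overexpression data are reproduced by re-fitting receptor initial
values only.

## Model selection

AICc = n(ln(2π·wSSR/n) + 1) + 2k + 2k(k+1)/(n−k−1), where n counts the
weighted data points entering the wSSR (replicate means, not collapsed
replicates) and k the independently estimated parameters. Akaike weights
are computed after subtracting the minimum AICc for numerical stability.
Ties are broken by smaller k, then variant id.

## Uncertainty

Profile likelihoods step a parameter away from its optimum in log₁₀ space,
re-optimising all other free parameters warm-started from the neighbouring
grid point; the step adapts toward a Δχ² increment of ≈ 0.3, capped at 50
steps per direction, and a bracketed threshold crossing is refined by
Brent root finding. The pointwise threshold is the 0.95 quantile of χ²
with one degree of freedom (df = 1, standard pointwise profile-likelihood
practice). A profile that crosses the threshold on both sides is
*identifiable*; one that runs into the parameter box is *practically
non-identifiable*; a flat profile is *structurally non-identifiable*.

Confidence bands follow the approximate formula
`y ± t_{α,N−P} · sqrt(MSE · (1 + s (SᵀS)⁻¹ sᵀ))` with S the
central-finite-difference sensitivity matrix (relative step 1e-4) of the
observable at the optimum and MSE = wSSR/(N−P). The leading "1 +" makes
this a prediction band; the `mean` kind drops it and then reproduces the
textbook pointwise t band of a linear regression. The t quantile is taken
two-sided (1 − (1−α)/2), which is what makes the linear-model fixture
match the textbook band exactly. Parameters with exactly zero sensitivity
to the requested observable (e.g. the other pathway's rates under a
single-stimulus condition) are dropped from the Gram matrix; genuine
collinearity still raises an error suggesting the ridge flag.

## Reference parameterisation and synthetic data

The generators' defaults are the study conditions: working doses 0.33 nM
(type I) and 13.7 nM (type III), sampling at 3/6/12/24 h, triplicates with
average CV 0.2, a 132-gene panel with four planted temporal archetypes and
half the genes non-induced, overexpression factors 2.6 (IFNAR) and
1.5 (IFNLR), and a high-affinity type III scaling of 3. Replicate noise is
Gaussian on the linear fold-change scale with sd = mean × CV, truncated at
zero — the noise model implied by the variance-weighting recipe.

The truth parameters are an M3-style asymmetry: more abundant IFNAR
complexes (0.05 vs 0.02 nM), near-equal activation rates (10 vs
8 nM⁻¹h⁻¹), ten-fold slower IFNLR-complex inactivation (0.3 vs 0.03 h⁻¹),
and an IFNLR efficacy factor of 0.909. The efficacy factor was calibrated
once so that the equal-dose type I : type III peak-induction ratio equals
1 at the lowest dose of a three-decade range; the ratio then rises
monotonically with dose to ≈ 1.14 (a ≲ 0.5% numerical wiggle at saturating
doses is absorbed by a 1% slack in monotonicity assertions). This
reproduces the qualitative phenotype the model family is about: equal
induction at low dose, stronger type I induction at high dose, an early
transient type I response and a delayed, sustained type III response
(peaks near 3–6 h vs 12–24 h on the experimental grid). The ISG transcript
decay of 0.25 h⁻¹ (half-life ≈ 2.8 h) keeps the response integrating over
several hours, as primary-response transcripts do.

What the generator does *not* emulate: biological gene-to-gene
heterogeneity beyond the four archetypes, correlated replicate noise,
plate or batch effects, cross-talk between pathways other than the shared
STAT pool, and any absolute-copy-number realism for receptors. Passing
recovery tests therefore demonstrates the *methods* are correct and the
study design is informative under the assumed noise model — not that real
data would be as clean.

Problem sizes in the shipped studies: calibration and profiling use one
seeded dataset of 32 points (2 IFNs × 4 doses × 4 times, replicate means),
3 optimisation starts; model-selection recovery uses 10 seeded replicates
with 2 starts per variant; the inactivation-rate contrast is evaluated on
a low-noise (CV 0.05) dataset, where a 24 h observation window can bound
the slow IFNLR inactivation rate from below — at CV 0.2 its profile is
open on the lower side and the contrast is reported indeterminate rather
than forced.

## Known limitations

- The slow IFNLR-complex inactivation (half-life ≈ 23 h) sits at the edge
  of the 24 h observation window; at the study's full noise level its
  lower confidence bound is open, and only the upper bound is informative.
- With abundances and gains jointly free, amplitude parameters are
  identifiable only as products (see the estimation presets above); point
  estimates along that ridge scatter widely even when profiles cover the
  truth.
- The negative-feedback species (an ISG-driven inhibitor of STAT
  phosphorylation) is implemented but off by default in all shipped
  studies; none of the reported behaviours require it.
- EC90 by log-dose interpolation inherits the assay's dose-grid
  resolution (a few percent on ~4-points-per-decade designs); the
  four-parameter-logistic mode is exact on logistic data and is what the
  acceptance pipeline reports.
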