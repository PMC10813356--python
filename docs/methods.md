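# Methods

`immunoflux` implements a stationary ¹³C metabolic flux analysis (MFA)
pipeline for circulating immune cells incubated ex vivo with isotopic
tracers, followed by cohort-level pattern analysis. This note records the
model, its assumptions, the main numerical choices, and what the built-in
synthetic data can and cannot demonstrate.

## Metabolic network and flux parameterisation

The model is a single well-mixed compartment covering glycolysis /
gluconeogenesis, the oxidative and non-oxidative pentose phosphate
pathway (PPP), and the TCA cycle, with 14 balanced internal metabolite
pools, 23 reactions and per-carbon atom transitions for every reaction.
Fluxes are in nmol / 2 h / 10⁶ cells throughout. Reversible reactions are
reported as net fluxes and carry a `d` prefix (`dQ2`, `dTAL`, `dTKT1`,
`dAsp`, `dAcCoA` — the ASCII form of the usual Δ symbols).

Steady state imposes `S v = 0` over the internal pools; the null space
has dimension 9, and the model is parameterised by nine free fluxes
(hexose uptake, `Z3`, `dTAL`, S7P input, `F2`, `dAcCoA`, glutamine
uptake, `F6`, `dAsp`). All remaining fluxes are linear in these;
`embed_free_fluxes` completes a free assignment and rejects it if any
irreversible flux would go negative. Useful identities implied by the
stoichiometry:

* `dTKT1 = S7P_input + dTAL`, `TKT2 = −dTAL`
* `Q4 = Z3 + 3·dTAL + 2·S7P_input` (R5P loss)
* `F4 = F2 + dAcCoA`, `F3 = F4 + glutamine_uptake`
* `F5 = glutamine_uptake + F6 + dAsp`

Model choices worth flagging:

* **Acetyl exchange (`dAcCoA`).** A reversible exchange between AcCoA and
  an external acetyl pool (positive = unlabeled input from fatty-acid /
  acetate oxidation, negative = loss to lipogenesis). Without it the
  AcCoA balance pins `F4 = F2` exactly, which contradicts treating the
  two as distinct variables in the cohort analysis.
* **PGI.** A fast reversible G6P↔F6P isomerase (exchange 100) connects
  hexose uptake to the triose-forming step; TPI and the pentose
  isomerase/epimerase carry the same fast exchange, reflecting
  near-equilibrium enzymes whose pools a GC-MS fragment cannot separate.
* **Atom maps** follow canonical biochemistry: the oxidative PPP
  decarboxylates G6P C1; the lumped citrate-synthase/IDH step releases
  the OAA C1 carboxyl; the lumped Akg→Oac step releases Akg C1 and
  scrambles the remaining four carbons (two half-weighted mappings) to
  model the symmetric succinate/fumarate intermediates.
* **`F5`** (Oac → Pyr + CO₂, +1 ATP) closes a pyruvate cycle
  (PEPCK/malic-enzyme-like) and makes the whole-metabolism ATP block
  computable; at steady state its value is fixed by glutamine uptake,
  `F6` and `dAsp`.
* **Measured species** map onto network pools through fast equilibria:
  lactate/alanine report pyruvate, aspartate/malate report oxaloacetate,
  glutamate reports α-ketoglutarate, and citrate is the convolution of
  the Oac and AcCoA pools through the citrate-synthase atom map.

## Labeling simulation

Given balanced fluxes and a tracer mixture, fragment carbon mass
distributions (CMDs) are computed with the elementary metabolite unit
(EMU) decomposition: a cascade of dense linear systems, one per EMU size
(1–7 carbons here), assembled from unidirectional rates
`fwd = exchange + max(net, 0)`, `rev = exchange + max(−net, 0)`. The
implementation is batched: a matrix of flux vectors is simulated in one
set of stacked linear solves, which is what makes the MCMC affordable.

Natural ¹³C abundance (default 0.0107) is applied on the substrate side —
every unlabeled carbon position of every input, including the unlabeled
S7P/aspartate/acetyl inflows. Measured spectra are therefore corrected
only for non-carbon isotopes (below), never for backbone carbon.

A completely independent **brute-force oracle** solves the full
positional-isotopomer balance (up to 2⁷ states per pool) by Jacobi
fixed-point iteration and exists only to verify the EMU route; the two
agree to ~10⁻¹¹ across random feasible flux draws and all four tracers.
Each sweep renormalises every pool to unit mass: the fixed point is a
probability vector, and without renormalisation rounding drift is
amplified exponentially through the bilinear two-substrate production
terms.

**The oxidative-PPP fingerprint is regime-dependent.** Single-labeled
lactate from [1,2-¹³C]glucose requires (i) no pyruvate cycling through
the TCA (`F5 = 0`; otherwise TCA-scrambled carbon re-enters pyruvate and
produces M+1 on its own) and (ii) an active return path from the pentose
pool to glycolysis. With zero transketolase/transaldolase exchange that
return path exists only in the recycling regime (net transaldolase toward
F6P + E4P, `dTAL < 0`); in the R5P-production regime the oxidative-PPP
carbon leaves through the R5P sink and lactate M+1 stays zero regardless
of `Z3`. A nonzero `nonox_exchange` opens the return path in every regime
but also lets the carbon shuffles split the C1/C2 pair by themselves, so
M+1 no longer vanishes exactly at `Z3 = 0`. The default network keeps
these exchanges at zero and the fingerprint checks use the recycling
regime.

## GC-MS preprocessing

* **Correction matrices** convolve the natural-abundance mass-shift
  distributions of H, N, O, Si, P and of the derivatization-group carbons
  (total C minus backbone C); columns are truncated to the monitored
  channel window and renormalised. Correction is a least-squares solve
  followed by clip-at-zero and renormalisation; a condition-number guard
  rejects unusable windows. The round trip (convolve, then correct) is
  exact to ~10⁻¹⁶.
* **¹³CO₂**: the tracer-to-tracee ratio is the sample 45/44 intensity
  ratio minus the unenriched background ratio (m/z 45 treated as pure
  ¹³CO₂, the ¹⁷O contribution being absorbed by the background
  subtraction); absolute production is TTR × bicarbonate concentration /
  cell density. The default bicarbonate value (23.8 µmol/mL, standard
  RPMI 1640) must be overridden with the actual medium lot value.
* **Lactate** is quantified against an internal standard by ordinary
  least squares over eight calibration standards, with inverse prediction
  floored at zero and a warning outside twice the calibrated range.
  Concentration units follow the standards verbatim.

## Bayesian flux inference

The likelihood is Gaussian and independent across: every mass bin of
every fragment CMD under each of the four tracer experiments (default SD
0.005 per bin), the absolute lactate secretion, and the absolute excess
¹³CO₂ production per labeled tracer (default 5 % relative SD). The two
absolute measurements anchor the scale: with CMDs alone the likelihood is
invariant under a global flux rescaling in a net-flux-only configuration
(this invariance is verified in the test suite), and adding either
absolute measurement breaks it.

Priors are uniform on a feasibility box — [0, 100] for irreversible free
fluxes, [−100, 100] for net fluxes — far wider than any plausible
immune-cell flux; infeasible completions carry zero prior mass. These
defaults are declared stand-ins, not a reconstruction of any particular
published error model.

Sampling uses an affine-invariant ensemble (emcee) over the batched
likelihood. Walkers start from a penalised least-squares point with its
Laplace covariance inflated by 1.3 (over-dispersed initialisation);
split-R̂ (walkers as chains) and ensemble ESS are computed for every
reported flux and violations of R̂ ≤ 1.05 / ESS ≥ 400 raise a warning.
The posterior mean is the point estimate used downstream; pairwise joint
confidence regions are χ²-scaled ellipses from the 2×2 posterior
covariance, flagged as degenerate segments when the correlation is
numerically ±1.

Problem sizes: the replicate-heavy calibration experiment uses 32 walkers
× 500 steps (170 burn-in) per fit, the single-dataset recovery fit 32 ×
700; both are the package's own desk-scale defaults and can be raised via
`MCMCConfig`. Under these settings, posterior means of the five headline
fluxes (hexose uptake, Z3, lactate production, F3, glutamine uptake)
recover truth within a few percent at reference noise, and 68 % credible
intervals cover a fixed truth in roughly two-thirds of replicate
datasets.

## ATP yields

ATP-equivalents per unit flux are derived from each reaction's carrier
stoichiometry (2.5 per NADH, 1.5 per FADH₂, 1 per GTP and ATP), never
hard-coded, and summed over three blocks: glycolysis (hexose uptake,
`dQ2`, `Q11`, lactate production), TCA (`F2`, `F4`, `F3`) and whole
metabolism (both plus `F5`, `F6`). Negative glycolytic totals are legal —
ATP invested in glycolysis can be repaid by the TCA block. Posterior-draw
summaries report median and IQR per block.

## Cohort statistics

Variables are standardised to mean 0, SD 1 (ddof = 1), decomposed by PCA
(SVD; loadings on the correlation scale), and the top k = 3 components
are varimax-rotated with Kaiser normalisation. The rotation uses Kaiser's
pairwise planar algorithm with the exact per-pair angle, restarted from
eight seeded orthogonal initialisations and keeping the best criterion
value: the common simultaneous (SVD-based) update stalls on
near-degenerate loading configurations — two equally strong components
mixed at 45° leave it at a saddle point — and the stall noise would
otherwise dominate jackknife standard errors. On generic loadings the
result matches R's `stats::varimax` to ~10⁻⁶.

Loadings get leave-one-out jackknife standard errors,
`SE = sqrt((n−1)/n · Σ(θ₍ᵢ₎ − θ̄)²)`, with each replicate aligned to the
full fit by maximal absolute **cosine** similarity with sign flip —
Pearson correlation is deliberately not used for alignment, because
centring block-structured loading vectors makes orthogonal components
look perfectly anti-correlated and the matching ambiguous. A loading is
significant when SE / |loading| < 0.5. SEs decrease with measurement
noise but approach a floor set by latent sampling variation (each
replicate re-estimates the component structure from n−1 samples), so
"SE → 0" holds only for the noise-driven part.

Group differences use the two-sided Mann–Whitney U test (exact for group
sizes ≤ 8 without ties, normal approximation with continuity correction
otherwise, significance at p < 0.05); correlations use Pearson when both
variables pass Shapiro–Wilk normality at α = 0.05 and Spearman otherwise.

## Synthetic cohort

The generator emulates the study design — 12 animals (6 per sex), PBMCs
and granulocytes per animal, four tracer incubations per sample
([1,2-¹³C]-, [4,5,6-¹³C]-, [U-¹³C]glucose each 1:1 w/w with unlabeled,
converted to molar fractions via the exact molar masses, and 100 %
[U-¹³C]glutamine) — with lognormal free-flux draws around cell-type
medians (CV 0.25–0.30; infeasible draws are redrawn). The medians encode
the qualitative contrasts: granulocytes glycolytic (hexose uptake 25 vs
5, lactate production ~40 vs ~1; oxidative PPP 2.4 with a twofold
male/female effect, against 0.55 in PBMCs within the 0.3–0.8 range),
PBMCs TCA/glutamine-driven (pyruvate dehydrogenase 5.95 vs 1.35,
glutamine uptake 1.5 vs 0.35, net aspartate release larger) with the
female-elevated S7P incorporation that raises non-oxidative R5P
production. The resulting ATP-block ordering (granulocyte glycolysis >
TCA; PBMC reverse) follows from these choices. Covariates use the
reported cohort medians and IQRs verbatim — testosterone 1.20/0.72
(units carried as printed), estradiol 20/8, aldosterone 349/435 pg/mL —
with testosterone and aldosterone negatively coupled through a shared
latent factor whose weight (within-sex R² 0.5) puts the cohort-level R²
near 0.7 once the sex contrast is included. ROUTINE respiration tracks
TCA throughput and superoxide production tracks the oxidative PPP, each
with lognormal noise.

Observation noise is additive Gaussian at the CMD level (SD 0.005 per
bin) so that the fitting error model matches the generator exactly; the
exported raw-MID table is the forward convolution of those noisy CMDs
with each fragment's correction matrix and round-trips through
`correct_mid` up to the clip-at-zero convention. Technical duplicates are
not simulated (the generator emits the already-averaged observation);
the CSV reader averages duplicate rows when present.

**What passing tests show — and don't.** The synthetic data demonstrate
that the estimator chain is self-consistent: correct forward model,
correct correction algebra, calibrated posteriors *under the generating
assumptions*, and recovery of the built-in cohort structure. They cannot
demonstrate robustness to real-data pathologies that the generator omits:
chromatographic artefacts and peak-integration error, batch effects,
deviations from isotopic steady state within the 2 h incubation,
cell-type impurity, or misspecified noise. The default fragment panel is
a 12-fragment stand-in spanning all EMU sizes, not the study's exact
monitored list.

## Known limitations

* Single compartment; no mitochondrial/cytosolic duplication, no NADPH
  bookkeeping, no thermodynamic constraints.
* Exchange fluxes of reversible reactions are fixed constants, not
  estimated; reported values are net fluxes.
* The direction convention for `dTKT1` follows its reaction string
  (S7P + GAP → X5P + R5P positive); descriptions that call R5P production
  a "negative" transketolase-1 flux are the same physics under the
  opposite sign convention, and the two readings are not silently
  reconciled anywhere in the code.
* Mann–Whitney p-values with ties fall back to the normal approximation.
* The `F5` pyruvate-cycle step is a modelling device whose biochemical
  identity (PEPCK vs malic enzyme route) the data cannot resolve.
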