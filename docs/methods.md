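# Methods

This note documents the models, conventions and numerical choices behind
`coralmeta`, in the order the pipeline runs.

## Synthetic data generator

The generator emulates a nitrate-enrichment larval experiment: 5 nitrate
levels (ambient control ≈ 2.5 µM; 5, 10, 20, 40 µM) × n replicate aquaria
(default 4), one RNA sample per aquarium, with three expression
compartments (coral host, Symbiodiniaceae, prokaryotes).

**Counts.** Per-transcript baseline abundances are log-normal
(σ = 1 on the natural-log scale around a median of 200); per-sample
library sizes are log-normal around 2×10⁶ with σ = 0.15. Counts are
gamma–Poisson (negative binomial) with variance µ + φµ², φ = 0.02 by
default. These two defaults are free parameters of the generator — they
describe deeply sequenced aliquots of larvae pooled from a common larval
batch, where biological coefficient of variation is low (BCV ≈ 14%, the
regime reported for genetically homogeneous experimental units) — and they
were fixed by a design-stage power analysis: planted |log2FC| = 2 effects
must be discoverable under the strict DET rule (below) at 4 replicates,
which fails for BCV ≳ 25% with a per-transcript t-test. Passing recovery
tests therefore says the chain is correct under low-dispersion, deep
libraries; it does not say a 4-replicate t-test would recover such effects
in noisier field data.

**Planted structure.** A fraction of transcripts per compartment gets a
log2 fold change ±`effect_size_log2` (default 2, random sign) in every
non-control treatment (configurable). Cross-compartment correlated pairs
share a per-sample standard-normal latent factor added to both log2 means
with a chosen loading. Ground truth (DE transcripts with true log2FC,
correlated pairs, physiology drivers, seed) is recorded and serializable.

**Physiology.** Each response (symbiont density in cells larva⁻¹, net
photosynthesis P_N and dark respiration R_D in nmol O₂ larva⁻¹ min⁻¹) is
`intercept + scale · (Σ βₜ zₜ + u + ε)` where zₜ is the standardized
log2(CPM+1) of a driver transcript, `u ~ N(0, 0.3)` an aquarium random
intercept and `ε ~ N(0, 0.3)` residual noise (standardized units; `scale`
converts to natural units: 500 cells, 0.15 and 0.08 nmol O₂ larva⁻¹
min⁻¹). Density is centred at 1.75×10⁴ so defaults stay inside the
observed 1.6–1.9×10⁴ cells-per-larva range. The default planted structure
uses one dominant driver per response — the sparse ground truth the
recovery benchmark scores against. Oxygen time series are straight 10-min
lines with chamber slope ±rate × n_larvae around a 500 nmol baseline
(≈ 2 mL seawater at air saturation), observation noise σ = 1 nmol, and
matched zero-slope blanks. `n_measurements > 1` produces repeated
measurements per aquarium sharing the random intercept, making the
intraclass correlation estimable.

**What the generator does not emulate:** transcript-length and GC biases,
compositional coupling between compartments, overdispersion heterogeneity
across transcripts, nonlinear transcript–physiology links, and any
taxonomic structure. Conclusions from passing tests are about the
correctness of the analysis chain, not about field data.

## Differential expression

CPM = count / column-sum × 10⁶. The two-group test is pluggable; the
default is Welch's t on log2(CPM+1), chosen because the acceptance surface
is planted-signal recovery rather than replication of any particular
count-model machinery. Fold changes use a pseudo-CPM prior of 1:
`logFC = log2((mean_T + 1)/(mean_C + 1))`. Significance is the strict
conjunction `(logFC > 1 or logFC < −1) and p ≤ threshold`, thresholds
1e−4 (coral, Symbiodiniaceae) and 1e−3 (prokaryotes); the boundary value
logFC = 1 is deliberately not significant. DET = significant in ≥ 1
comparison; Venn regions are keyed by the exact comparison subset and sum
to the union size. The ordination transform is `sqrt(log2(CPM + 1))` —
log first, then square root, with +1 to handle zeros — followed by
Bray–Curtis `d(u,v) = Σ|u−v| / Σ(u+v)` between samples (scipy's
implementation; two all-zero samples are defined to have d = 0).

## Photophysiology

Rates are OLS slopes of oxygen amount against time (≥ 3 readings, strictly
increasing times), blank-corrected by subtracting the blank chamber's
slope (robust to different sampling instants), divided by larvae count.
Dark-phase slopes are negative; R_D is reported as the positive
consumption magnitude so that `P_G = P_N + R_D` holds exactly as an
additive identity and `P_G ≥ P_N` whenever `R_D ≥ 0`. Symbiont density is
aliquot concentration (cells µL⁻¹) × homogenate volume (µL, default
200) / larvae (default 20); haemocytometer grid arithmetic is the
caller's concern. `anova_by_treatment` is a standard one-way F between
one treatment and the control.

## Co-expression networks

All cross-compartment DET pairs are tested: Spearman ρ from midranks
(average ranks on ties; any monotone per-transcript transform leaves ρ
unchanged — log2(CPM+1) is used for definiteness), with the two-sided
large-sample approximation `t = ρ·sqrt((n−2)/(1−ρ²))` on n−2 degrees of
freedom. The permutation-oracle checks run at n = 8 — the 4-vs-4 scenario
and the largest small-sample case — where the mean absolute p-error of the
approximation is ≈ 0.01; at n = 5 it grows to ≈ 0.05, so the small-n
suite documents a looser bound. Constant transcripts have undefined ρ and
are excluded from edges with a logged warning but still count toward
n_pairs_tested = |A|×|B|. Edges with p ≤ 0.05 (raw, uncorrected — the
edge filter is a screening rule, not an inference) form the network.

Hub scores are *size-adjusted betweenness*: raw shortest-path betweenness
on the unweighted graph divided by the number of transcripts included in
that network. Division by node count is the only normalization that
removes the direct effect of network size while staying monotone in raw
betweenness; the conventional (N−1)(N−2)/2 normalization is available as
an option. Isolated and degree-1 nodes score 0. Core transcripts are the
top 20 by adjusted betweenness, ties broken by (score descending, id
ascending) for determinism.

## Repeated penalized mixed-model selection

For each physiology response, each of 100 runs draws a seeded random
permutation of the candidate transcripts and fits consecutive blocks of 10
(the final short block as-is, so every transcript is estimated exactly
once per run) with an L1-penalized random-intercept model

  minimize (1/2n)‖y − Xβ − Zu − b₀‖² + λ Σ|β|,

X standardized (constant columns dropped with a warning), y on its natural
scale, u a random intercept per aquarium. The solver alternates a
coordinate-descent lasso pass (soft-thresholding against the block Gram
matrix) with closed-form one-way ANOVA (method-of-moments) variance
components and BLUP shrinkage `u_g = n_g σ̂ᵤ²/(n_g σ̂ᵤ² + σ̂ₑ²)·(r̄_g − r̄)`;
convergence when the largest coefficient change is below 1e−6 in units of
the response standard deviation, with a 2000-iteration cap (rare blocks of
correlated predictors at small λ need ≈ 550 iterations; the cap is
generous so the pipeline never aborts on well-posed fits). The inner
kernel is numba-compiled. λ is chosen per fit by BIC
(`n·log(RSS/n) + (nnz+1)·log n` on conditional residuals) over the fixed
grid (1, 0.3, 0.1, 0.03, 0.01, 0.003) × λ_max with warm starts, λ_max
being the smallest penalty that zeroes every coefficient.

**Hit rule.** A transcript scores a hit in a run when |estimate| exceeds
the random-effect magnitude of its block's fit. With one sample per
aquarium — this design — the aquarium intercept is confounded with the
residual: the likelihood only identifies σᵤ² + σₑ², every σᵤ²/σₑ² split
(and hence every mean-|BLUP| value) is a convention, and a mean-|BLUP| bar
under any fixed split is an arbitrary fraction of the unexplained spread.
It is then systematically too low: datasets containing one extreme chance
correlate (|r| ≈ 0.7 arises at n = 20 somewhere among hundreds of noise
transcripts in roughly a tenth of datasets) retain it, violating the
null-calibration property the procedure is meant to have. The default
comparator is therefore the total unexplained standard deviation
`sqrt(σ̂ᵤ² + σ̂ₑ²)` — the magnitude of everything the fixed effects failed
to explain, which is what "the random effects" denote in a
singleton-group design. Under this bar, measured operating
characteristics at the study size (20 samples, 300 candidates, 100 runs,
threshold 95): sensitivity 1.0 on planted drivers, specificity 1.0, and
an empty retained set in 50/50 global-null datasets. The mean-|BLUP| and
random-intercept-sd comparators remain selectable (`comparator=` argument)
for designs with replicated groups, where they are meaningful. For fitting
itself, singleton groups use an even σᵤ²/σₑ² split (the midpoint of the
unidentifiable ridge), which keeps the BLUP update well-behaved.

Retention: hit in strictly more than `threshold_runs` runs (95 coral, 70
prokaryote); sign = sign of the mean estimate over hit runs. Raising the
threshold can only shrink the retained set.

## Symbiosis model

State: coral biomass H, Symbiodiniaceae density S, prokaryote density B.
Parameters (all ≥ 0; d, e, K > 0): r, K — coral logistic growth and
capacity; γ₁, γ₂ — capacity expansion provided by S alone and by the S×B
interaction; a₁, a₂ — per-partner costs to coral; g₁, g₂ — host-dependent
partner growth; b₁, b₂ — partner-to-partner benefits; d₁, d₂ — density-
independent death; e₁, e₂ — crowding; c₁, c₂ — interpartner competition.
The coordinate planes are invariant, so a partner absent at t = 0 stays
absent.

Integration uses LSODA with the analytic Jacobian (rtol 1e−8, atol 1e−10);
negative excursions within 100×atol are clipped to zero. Equilibria:
(0,0,0) and (K,0,0) analytically; on each boundary plane the surviving
partner's zero-growth condition gives its density as
`λ = (1/e)((g/d)H − 1)`, reducing the plane to a 1-D root-finding problem
in H solved by sign-change scanning plus Brent's method (there is no
closed form for H̄ itself after substitution into the coral equation);
interior equilibria by multistart Newton-type root-finding in
log-coordinates (which keeps iterates positive and away from the capacity
singularity), 6³ starts geometrically spaced up to ~10 K. Duplicates are
merged at 1e−6 relative distance; every reported equilibrium has
‖f‖ < 1e−7. Stability is classified from the Jacobian's eigenvalues with
a 1e−8 margin (stable / unstable / marginal).

Regime labels are the measurable counterparts of the isocline geometry:
*mutualism* when a stable equilibrium with S > 0 has H* > K, *parasitism*
when H* < K; *coexistence* when a stable equilibrium has both S, B > 0;
otherwise the excluded partner is named, and multiple stable equilibria
are all reported with basins marked unresolved. Nullclines are extracted
by sign-change interpolation on a grid restricted to a plane, for
phase-plane plotting.

The shipped `EXAMPLE_PARAMS` (mutualism, parasitism, coexistence,
exclusion) are illustrative constructions chosen so each regime is
realized with simple round numbers; they are not estimates from any
dataset.

## Pipeline, seeds, formats

A single global seed fans out to per-stage child seeds via
`numpy.random.SeedSequence.spawn`, so stages are independently
reproducible and reruns are byte-identical (verified on the manifest's
sha256 digests). All on-disk formats are plain text (TSV/CSV/JSON/YAML);
readers validate unique transcript ids, numeric cells and non-empty input
and report the offending id or line. CLI exit codes: 0 success, 2 config
error, 3 data error, 4 numerical failure.

## Problem sizes used in the checks

The test-suite and acceptance-script simulations run at the study's
design sizes — 20 samples (5 × 4), 300/120/50 transcripts (DET-scale
matrices of 310/119/46 for the network arithmetic), 100 selection runs in
blocks of 10 — with 30–50 Monte-Carlo repetitions for calibration and
recovery rates and 10,000 permutations for the Spearman oracle; these
counts give binomial standard errors comfortably below the margins being
checked while keeping a full run in minutes.

## Known limitations

- The default DE test is a per-transcript Welch t, not a shared-dispersion
  count model; its power profile differs from moderated NB tests, which is
  why the generator's default dispersion matters (see above). The test is
  pluggable.
- The Spearman p approximation degrades below n ≈ 7; exact/permutation
  p-values are not computed in the pipeline.
- With singleton aquaria the random-intercept variance is a convention,
  not an estimate; selection results should be read through the hit-rule
  discussion above.
- Equilibrium finding is multistart root-finding: it cannot prove
  exhaustiveness for pathological parameter sets, though the invariant
  planes and boundary reductions cover all equilibria with at most one
  absent partner.
- Basins of attraction are not computed; bistable reports only list the
  stable states.
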