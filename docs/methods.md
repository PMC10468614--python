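# Methods

This note records the models, estimators, numerical choices and known
limitations of `metacons`, in the order the pipeline runs.

## Conservation scores from Brownian motion

Each metabolite's trait is the mean of the log10-transformed relative levels
across biological replicates, one value per species and organ. Under the
Brownian-motion (BM) model the trait increments along a branch of length Δt
are N(0, σ²Δt), so the tip values are jointly multivariate normal
MVN(μ·**1**, σ²C), where C[i, j] is the root-to-MRCA path length shared by
tips i and j. The rate σ² is in units of squared log10 level per unit branch
length (My for real time-calibrated trees; the synthetic trees are normalized
to depth 1). The conservation score is 1/σ̂²: it needs only relative levels,
so scores are comparable across metabolites without absolute concentrations.

Estimation is plain maximum likelihood: μ is profiled by generalized least
squares and, with no measurement error, σ̂² = r'C⁻¹r/n at the GLS residual r
(denominator n, not REML, matching the common trait-fitting convention; the
choice is recorded on every fit). When per-tip sampling SDs are supplied the
covariance becomes σ²C + diag(se²) and σ² no longer has a closed form; it is
found by bounded search over log10 σ² in [−12, 6] (tolerance 1e-10 in log10
σ²), then polished by a Brent root solve of the score equation
dL/dσ² = ½(r'V⁻¹CV⁻¹r − tr(V⁻¹C)) = 0 — near the optimum the likelihood
value is flat to machine precision but its gradient is not, and the polish
brings the closed-form/numeric agreement to ~1e-10 relative.

Numerical/degenerate cases: identical tip values give σ̂² = 0 and an infinite
(censored) score, excluded from correlations with a count; a singular C
(zero-length cherries) is a hard error, never jittered; missing species are
handled by pruning the tree to the measured species per metabolite (rooted at
their MRCA), never by imputation. Scores always enter comparisons on a log
scale (log10 for correlations between score sets, log2 for the normalized
cross-organ tables) because they span several orders of magnitude and
raw-scale statistics would be leverage-dominated.

Clade-split reproducibility fits each metabolite separately on two disjoint
clades (each pruned subtree keeps its original branch lengths) and reports the
Pearson correlation of log10 scores; the clade partition is a user input.

## Replicate-noise partition

Replicates are resampled with replacement within each (species, metabolite)
pair — pairs with a single replicate are removed first, as resampling cannot
perturb them — scores are refit per bootstrap replicate (default 100), and a
one-way random-effects ANOVA on log10 scores with metabolite as the factor
splits total variance into a between-metabolite component
((MSB − MSW)/n₀, clipped at 0) and an error component (MSW). The reported
fractions sum to one. Bootstrap RNG: one master seed spawning per-replicate
child sequences, so runs are reproducible and order-independent.

## Cross-organ comparison

Scores of metabolites present in all organs are log2-transformed and centered
to zero per organ (organs differ in metabolome-wide divergence). The
organ-specific deviation is the normalized score minus the mean of the other
organs; the top 10% per organ are flagged with a ceiling(n/10) count and ties
broken by metabolite id so output is deterministic. The level/score
association uses, per metabolite and unordered organ pair (fixed alphabetical
order for reproducible signs), the species-mean log2 level fold change and
the normalized-score difference; Spearman's rho is computed over all
metabolite × pair points. Because the six pairs per metabolite are not
independent, significance comes from a one-sided permutation test that
reshuffles each metabolite's organ score labels independently (10,000
permutations by default, +1 smoothing so p > 0). Signed differences are the
default — the hypothesis is directional (more abundant where more conserved)
— with an absolute-value switch exposed.

## Feature analysis

The response is log2(MCS) pooled over organs with organ membership as a
categorical covariate. Univariate scan: per feature, ΔR² = R²(organ +
feature) − R²(organ) on that feature's complete cases, a nested-model F test,
and Benjamini–Hochberg adjustment across all tested features (significance at
FDR < 0.01); each chemical class level and each pathway is tested as its own
binary feature. Right-skewed continuous features (abundance, molecular
weight, LD50, degree) are log10-transformed before modeling. Multivariate:
the initial model holds all individually significant candidates plus organ
(never removable), chemical class as a single multilevel factor; selection is
bidirectional stepwise minimizing AIC (k = 2). Each retained feature's
independent contribution is the adjusted-R² drop when it alone is removed
(negative drops clipped to 0 and flagged); the features-total variance
explained subtracts organ's independent effect from the selected model's
adjusted R². Exact duplicate feature columns are dropped before the search.
Essential-metabolite flags: a reaction is essential iff strictly more than
half its genes are essential; a metabolite is flagged iff it touches at least
one essential reaction; reactions with no genes are excluded.

## Kinetic models and steady states

Models are declared as variable species (initial concentrations), boundary
species (fixed), and reactions with free-form infix rate laws over species,
boundary species and reaction-local parameters; parameter ids are globally
unique so ownership is unambiguous. The native YAML format round-trips with
value-identical floats (repr-based emitter); SBML Level 3 import/export keeps
parameters local to each kinetic law. Rate laws are parsed with sympy and the
ODE right-hand side, Jacobian and flux vector are compiled once per model;
mutations only change the parameter vector.

Steady states: damped Newton (max 200 steps, backtracking line search) on the
right-hand side augmented with moiety-conservation rows (left null space of
the stoichiometric matrix, totals fixed by the starting concentrations), with
least-squares steps so conserved directions stay well-posed; on stall, stiff
LSODA integration in expanding time chunks to t = 1e6 with Newton re-polish.
Convergence requires max|dx/dt| < 1e-9 and concentrations above −1e-12
(small negatives clipped to 0). Failure to converge is a returned flag, never
an exception — the simulator treats it as "no steady state".

## MCMC evolution under drift or stabilizing selection

Per iteration: pick a reaction uniformly (resampling reactions with no
parameters), one of its parameters uniformly, and multiply it by 10^α with
α ~ N(0, σ_mut²); solve the mutant's steady state, resampling the proposal
within the iteration if none exists (budget 1000 consecutive failures);
compute z = ‖(ν − ν₀)/ν₀‖₂ over the key fluxes against the wild type; accept
iff z < ω, else revert. Selection-rejected proposals consume an iteration
with the state unchanged; no-steady-state proposals do not. Defaults follow
the study conditions: ω = 1e-4, σ_mut = 1e-2, T = 10,000, 10 repetitions
(desk-scale runs here use T = 2,000 and 3–5 repetitions; the contrasts are
already decisive at that size). Mutations are cumulative on the evolved
model; effective population size is eliminated by rescaling the timescale, so
accepted neutral mutants fix with probability 1. RNG: counter-based child
seeds (master seed, repetition, iteration, attempt), making runs
bit-reproducible and trivially parallelizable.

In-silico scores: ER = var(Xᵢ(t)/Xᵢ(0))/T over the within-run trajectory
(sample variance, denominator n−1 — the variant over replicate endpoints is
the documented alternative), score = 1/ER, zero-rate metabolites flagged; for
the erythrocyte model the published five-metabolite exclusion list
(moiety-pinned cofactors and transport-pinned species) is applied.

Fitness coupling: N independent single mutations of the wild type
(non-converging mutants resampled; N = 10,000 by default), then per (key
flux, metabolite) the Spearman correlation (average ranks for ties) between
|Δν/ν₀| and |ΔX/X₀|, averaged over the key set. Reaction essentiality:
multiply one reaction's rate law by 1e-5, re-solve from the wild type, and
call it essential iff some key flux falls below 1e-3 of its wild-type
magnitude — the threshold sits below any non-essential deviation we observe
but above the floor set by the knockdown factor itself (the knocked
reaction's own flux scales with the multiplier, so a much smaller relative
tolerance could never trigger). Solver failures are reported as
non-evaluable, not as either flag. Random key-flux scans reuse one
single-mutation ensemble across combos (sizes uniform in 1..4, drawn without
replacement) and report one-sided empirical p for the designated key set.

## Disease associations

Group tests use two-sided Wilcoxon rank-sum per organ (exact for small
tie-free samples, tie-corrected normal approximation otherwise) plus a pooled
linear model log2(MCS) ~ organ + flag; class/pathway exclusion variants are
re-run and reported. Broad conditions pass a univariate filter (p < 0.05 with
the flagged group more conserved in ≥ 3 of 4 organs) before a joint linear
model; conditions with coefficient p < 0.05 are independent; duplicate
membership vectors are collapsed. The aggregate score is the per-metabolite
median of the normalized (log2, organ-centered) scores. The biomarker
classifier fits an unpenalized logistic regression on the aggregate score;
the ROC sweeps thresholds on the score itself, so AUC by trapezoid equals the
Mann–Whitney rank AUC identically (asserted to 1e-9), and negating the score
flips AUC to 1 − AUC. In-sample AUC is reported (k-fold is an exposed
option). The disease-count association is Spearman's rho plus a linear model
controlling log abundance and essentiality.

## Synthetic data: what it emulates, and what it does not

Trees are exact pure-birth (Yule) simulations, ultrametric with depth
normalized to 1. Traits evolve by BM from a root value of 0 with
per-metabolite rates sampled log-uniformly over [1e-2, 1e1] — reproducing the
~3-decade score spread seen in real organ panels — plus i.i.d. Gaussian
replicate noise (default SD 0.1 log10 units, or per-metabolite vectors, e.g.
10% of each metabolite's among-species SD) and optional constant lineage
shifts on a clade. Multi-organ tables share per-metabolite rates up to a
lognormal organ factor (SD 0.15 log10), giving positive but imperfect
cross-organ score correlations. Feature tables plant a stated partial R²
between log abundance and log score; disease labels follow a logistic
dose-response with a stated odds ratio per SD of standardized log
conservation (a continuous plant; a median-split variant wastes signal and
was rejected). All generating parameters are returned as provenance.

What passing tests on these fixtures does **not** show: the generators have no
phylogenetic signal in the noise, no lineage-specific rate shifts unless
requested, no correlated features beyond the planted ones, no LC-MS artifacts
and no dietary/environmental confounding — so real-data effect sizes
(clade-split r, feature ΔR², AUC) will differ from the synthetic ones even
when the machinery is correct.

The bundled kinetic models are desk-scale: an 8-reaction branched pathway
with an ATP/ADP moiety cycle (key fluxes: product export and cofactor
regeneration) whose wild type converges from any positive start respecting
the moiety total; a minimal source/sink model whose single mutable parameter
makes one metabolite's response exactly monotone in the key flux (coupling
= 1 by construction); and a parallel-branch model whose non-key branches are
exactly decoupled from the key flux. In the parallel model the measured
coupling of a decoupled metabolite is not exactly zero: single mutations
move either the key flux or the metabolite, never both, and this mutual
exclusivity plus rank ties biases the Spearman estimate slightly negative
(about −0.08 at 10 branches); the magnitude shrinks with the product of the
two mutation-target fractions. The 8-reaction model also has exactly
flux-neutral parameter directions (sink rate constants, cofactor-regeneration
saturation), so stabilizing selection never fully freezes it — variation
concentrates in the neutral directions, which is the mechanism that widens
between-metabolite score differences under selection.

## Limitations

- Only the BM model is fitted; Ornstein–Uhlenbeck or multi-rate comparisons
  and lineage-shift detection are out of scope (shifts are emulated in the
  generator only).
- The full 40-metabolite erythrocyte kinetic model is not shipped; it is a
  loadable input (native format or SBML), and the exclusion list for it is
  built in.
- Stepwise AIC selection admits an irrelevant regressor with probability
  ≈ 0.157 each; selection results are reported with per-feature independent
  contributions rather than treated as a final variable screen.
- Dispersion comparisons between simulation regimes use the SD of log10
  scores; raw-scale coefficients of variation are dominated by single extreme
  scores when values span many decades.
- Permutation and bootstrap defaults (10,000 / 100) are study-condition
  values; tests and the acceptance script run smaller but still decisive
  sizes, stated in their code.
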