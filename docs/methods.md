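# Methods

## Model family

All four models describe the gene content of a sample of *G* bacterial
genomes, each carrying a fixed number *M* of distinct genes, under neutral
population dynamics (Moran birth-death) coupled to gene transfer in the
infinitely-many-genes idiom: every transferred gene is new to the
population, and acquiring it displaces one uniformly chosen resident gene,
so genome size is conserved exactly.

* **Model A** — constant population size *N*. The only free parameter is the
  effective transfer rate θ = Nσ/(Mρ); the expected spectrum is the Ewens
  form `g_k = (Mθ/k)·G!/(G−k)!·(θ)_{G−k}/(θ)_G`. The model is exchangeable,
  exact for any sample size G ≤ N, and yields the stationarity identity
  φ = θ/(1+θ) for genomic fluidity.
* **Model B** — exponential growth N(t) = N₀e^{α(t−t₀)}, parameters
  θ₀ = N₀σ/(Mρ) and β = N₀α/(2ρ). Computed by Monte Carlo over
  inhomogeneous coalescent trees (details below). β = 0 reduces exactly to
  model A; this limit is the central correctness anchor and is enforced by
  tests at 3 Monte Carlo standard errors.
* **Model C** — a fraction λ₂ = 1−λ₁ of every genome is a rigid core shared
  by all genomes; the fluid fraction λ₁ follows model A with rate θ₁.
* **Model D** — both compartments are fluid with θ₂ ≤ θ₁; the spectrum is
  the sum of two model-A spectra with per-genome sizes λ₁M and λ₂M. Model D
  nests A (θ₁ = θ₂) and C (θ₂ = 0) exactly.

Compartment sizes λM are kept as real numbers: predicted spectra are
expectations, not counts.

## Numerical evaluation of the closed form

The Ewens form is evaluated in log space,

    log g_k = log M + log θ − log k + lnΓ(G+1) − lnΓ(G−k+1)
              + lnΓ(θ + (G−k)) − lnΓ(θ+G),

which is finite and accurate for G up to at least 10³ and θ across the full
supported range. Two groupings matter in floating point: `θ + (G−k)` must be
computed with the difference first, or θ below machine precision relative to
G is absorbed; and θ < 10⁻³⁰⁰ is mapped to the exact θ = 0 limit
(g = (0,…,0,M)) because lnΓ overflows on subnormal arguments while the true
difference from the limit is far below representable spacing. θ = ∞ is the
explicit all-private limit (g₁ = MG); finite θ above an internal cap of 10⁶
is treated as infinite and logged, and capped fitted values are rendered as
"inf" in reports (empirical flexible-core fits can push θ₁ to the boundary).

Pan/core curves use `pan(n) = Mθ(ψ(θ+n) − ψ(θ))` (digamma form of the
harmonic-like sum) and `core(n) = Mθ(n−1)!/(θ)_n`, again via lnΓ. A note on
asymptotics: core(n)·n^θ converges to MΓ(θ+1) quickly (within 2% by
n ≈ 10³), but pan(n)/ln n approaches Mθ only logarithmically because of the
constant offset −ψ(θ); the meaningful finite-n statement of logarithmic
growth is the local slope (pan(n) − pan(n/2))/ln 2 → Mθ, which is what the
tests check.

## Forward simulator (synthetic-data generator)

The simulator is a Gillespie event loop over three Poisson classes with
aggregate rates Nρ (Moran replacement), Nσ (transfer) and Nα (pure birth,
for optional forward growth). Genomes are rows of a preallocated integer
array; transfer writes a globally unique identifier from a monotone counter,
so identifier reuse is impossible by construction. Invariants (constant
genome size, within-genome distinctness) are asserted in tests after long
runs. Runs are reproducible bit-for-bit from the seed.

The generator's default conditions mirror the study design of the models it
emulates: clonal initialization with a burn-in of 10·N/ρ before sampling
(the closed form is a stationarity result; pilot runs show the spectrum
statistics stable well before that), sampling epochs spaced 0.5–1 relaxation
times N/ρ apart, and uniform sampling of G genomes without replacement.
Oracle tests use N = 60, M = 20, G = 10 with σ chosen so θ ∈ {0.1, 0.3, 1};
parameter-recovery tests use N = 200, M = 50, G = 20 with 100 epochs and 20
replicates. These sizes keep the full suite in minutes on one CPU while
leaving Monte Carlo standard errors small enough for 3-SE comparisons to be
sharp.

What the generator does *not* emulate about real pan-genome data: phylogenetic
structure among sequenced isolates (samples here are exchangeable),
within-species transfer and recombination, fitness effects, gene-calling and
homology-clustering noise, and unequal genome sizes (every simulated genome
has exactly M genes, whereas empirical sizes vary ~10%). Passing oracle
tests therefore validates the mathematics and the implementation, not the
biological completeness of the neutral description.

## Coalescent computation for model B

Backward in time with j lineages at depth τ, the next coalescence time
solves ∫ (j(j−1)/2)e^{βs} ds = E with E ~ Exp(1), inverted in closed form;
a uniform pair merges. Gene content along a tree: the root carries exactly
M genes (equivalent to integrating the stem acquisition process at
stationarity, and avoiding an improper integral); genes are acquired along
branches at rate Mθ₀/2 per unit τ and lost per-gene at rate θ₀/2. These
rates are the unique calibration, given pair-coalescence rate 1 at the
present, that reproduces the model-A spectrum at β = 0 with θ = θ₀.

For a given tree the expected spectrum is computed exactly by a subtree
dynamic program: p_v(k), the probability that a gene present at node v
survives in exactly k leaves below it, is built bottom-up by convolving the
two child-edge contributions (an edge loss sends the gene to k = 0); root
genes contribute M·p_root(k) and genes gained on the edge above node c
contribute M(1−e^{−θ₀ℓ/2})·p_c(k), the positional integral collapsing
because edges do not branch. This removes one layer of Monte Carlo noise —
randomness enters only through genealogies — and costs O(G²) per tree, which
is fast enough at any sample size this package targets, so no sampling
fallback is used. Per-tree conservation Σ k·g_k = GM holds exactly
(telescoping of survival probabilities along root-to-leaf paths) and is
asserted to 10⁻⁹. Defaults: 2000 trees per spectrum, per-bin standard
errors across trees always reported.

The rare-gene exponent γ is estimated by least squares of log g_k on log k
over k = 1..k_max (default flank k ≤ G/4). On the exact constant-size
spectrum at G = 20 the finite-sample curvature gives γ ≈ 0.87 rather than
1.0 exactly; γ → 1 as G grows, and growth (β > 0) raises it toward 2 and
beyond, which is the qualitative signature the tests pin down.

## Fluidity

Observed fluidity uses the exact pairwise formula with true per-genome sizes
(column sums); model-predicted fluidity uses the exchangeable equal-M
expectation φ = Σ g_k·k(G−k)/(M·G(G−1)). The two estimators are reported
under distinct labels and never silently mixed. Applied to the model-A
spectrum the exchangeable formula reproduces θ/(1+θ) to 10⁻⁹, which is the
internal consistency oracle linking the spectrum and fluidity modules.

## Fitting

The objective is Δ = (1/G)Σ(√g_obs − √g_pred)², including the k = G bin.
M defaults to the data-derived mean Σ k·g_k/G (rounded), overridable for
species with known genome sizes. Strategy per model:

* **A**: 61-point log-spaced grid on θ ∈ [10⁻⁴, 10³], then bounded Brent on
  log θ between the flanking grid points (recovers noiseless θ to ≲10⁻⁸).
  Degenerate all-core data drives θ̂ to the lower bound and sets a warning
  diagnostic.
* **C**: 7×7 grid over (log θ₁, λ₁), Nelder-Mead from the best three starts
  on (log θ₁, logit λ₁).
* **D**: 5×5×5 grid plus Nelder-Mead over (log θ₁, log θ₂, logit λ₁),
  unconstrained — model D is symmetric under swapping its compartments, so
  θ₁ ≥ θ₂ is applied as a labeling convention afterwards. The fitted A and C
  solutions are injected as exact candidates (θ₂ = θ₁ and θ₂ = 0), making
  Δ_D ≤ Δ_A, Δ_C structural. Ties on the grid resolve to the first
  (lexicographically smallest) start, for reproducibility.
* **B**: 5×5 log grid over (θ₀, β), Nelder-Mead from the best start. Every
  objective evaluation reuses one fixed seed (common random numbers), so the
  surface is deterministic and smooth; the final parameters are re-evaluated
  with twice the trees. The grid landscape ships in the diagnostics, with a
  `flat_valley` flag raised when near-minimal Δ spans a ≥10× range in θ₀ —
  the known identifiability ridge where, e.g., (θ₀ = 0.03, β = 10) and
  (θ₀ = 0.3, β = 100) produce nearly identical spectra. Predicted fluidity
  is robust across this ridge even though (θ₀, β) individually are not.

No likelihood or information-criterion machinery is provided: the fitting
criterion is least squares on √counts by design, and reports carry Δ plus
parameter counts so two-parameter models can be compared directly.

## Uptake rates

σ = −ln(1−ε)/T from a transformation frequency ε measured after exposure
time T; the division rate cancels. Orders of magnitude are reported as
round(log₁₀σ) with half-decade ties rounded away from zero (documented
because published ranges use one-significant-figure arithmetic; e.g. an
ε range of 10⁻⁴–10⁻⁸ at T = 2.5 h maps to σ spanning ~10⁻⁴–10⁻⁸·4 h⁻¹,
which one-figure rounding stretches to a 10⁻⁴–10⁻⁹ style range — the
estimator itself is exact and round-trips with ε = 1−e^{−σT} to 10⁻¹²).

## Pan/core uncertainty band (model D)

The Monte Carlo band subsamples genomes from stationary forward-simulated
populations, one Moran population per genome compartment with matched
(θ, compartment size) and N = max(4·G_max, 40), accumulating genomes in
random order per epoch and recording running union (pan) and intersection
(core) sizes. The exchangeable construction of the joint pattern
distribution is deliberately not attempted; the simulator is the ground
truth for between-sample variance. Means agree with the closed-form curves
within Monte Carlo error (tested at 3 SE with 2000 replicates); the first
genome always contributes exactly M genes, so both SD vectors start at 0.
Degenerate compartments (θ = 0 or θ = ∞) are handled analytically without
simulation.

## Known limitations

* Infinite gene pool: pan-genome diversity grows without bound; fine as long
  as the pool is much larger than the observed gene set.
* No phylogenetic correction for non-uniform sampling of isolates, no
  within-species transfer, no selection.
* Model B inherits Monte Carlo noise; fits near the identifiability ridge
  should be read through the `flat_valley` diagnostic rather than as point
  estimates.
* Empirical genome-size variation (~10%) is summarized by a single M.
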