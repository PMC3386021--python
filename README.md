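# pangenesis

Neutral models of bacterial pan-genome evolution: closed-form gene frequency
spectra, a forward-time Moran + gene-transfer simulator, a coalescent for
exponentially growing populations, genomic fluidity, pan/core genome curves,
least-squares model fitting, and gene-uptake-rate estimation — as a tested
Python library with a CLI.

## The problem

Sequenced isolates of one bacterial species can differ in a large fraction of
their gene content. Binning genes by the number of genomes they occur in
gives the **gene frequency spectrum**: for a sample of *G* genomes, *g&#8342;* is
the number of distinct genes found in exactly *k* genomes. Empirical spectra
are U-shaped — many rare genes, many universal ("core") genes, few in
between — which is often read as evidence that common genes are essential.
This package implements a family of neutral null models showing that the
U-shape arises without any selection, and provides the machinery to fit them
to real presence/absence data.

## The models

**Model A (constant population).** A Moran population of *N* organisms, each
carrying exactly *M* genes. Reproduction (rate ρ per individual) copies a
random genome over a random casualty; gene transfer (rate σ per individual)
inserts a brand-new gene — infinitely-many-genes style — displacing a random
resident gene. At stationarity the expected spectrum takes the Ewens form

```
g_k = (M θ / k) · G!/(G−k)! · (θ)_{G−k} / (θ)_G ,    θ = N σ / (M ρ),
```

with `(θ)_k = θ(θ+1)···(θ+k−1)` the rising factorial. The spectrum is
U-shaped for θ < 1 and monotonically decreasing for θ > 1. The expected pan
genome grows as *Mθ* ln *n* and the expected core genome decays as
*M*Γ(θ+1)·*n*<sup>−θ</sup>.

**Model B (exponential growth).** With *N(t) = N₀ e^{α(t−t₀)}* the spectrum
depends on θ₀ = N₀σ/(Mρ) and β = N₀α/(2ρ); it is computed by Monte Carlo
over coalescent genealogies whose pair-coalescence rate at backward time τ
is e^{βτ}, with an exact per-tree dynamic program for gene survival. Growth
steepens the rare-gene flank from g&#8342; ~ 1/k toward 1/k².

**Models C and D (explicit core).** The genome is split into a fluid fraction
λ₁ with transfer parameter θ₁ and a core fraction λ₂ = 1−λ₁ that is either
rigid (model C, θ₂ = 0) or flexible (model D, 0 ≤ θ₂ ≤ θ₁); spectra are sums
of model-A spectra.

**Genomic fluidity.** φ is the average, over genome pairs, of the fraction
of the pair's genes unique to one member. At stationarity φ = θ/(1+θ),
linking a purely statistical diversity index to the transfer/drift balance.

**Fitting.** Models are fit by minimizing the square-root-transform distance
Δ = (1/G)·Σ&#8342;(√g&#8342;ᵒᵇˢ − √g&#8342;ᵖʳᵉᵈ)², via log-spaced multi-start grids plus
local refinement (common random numbers make the model-B objective
deterministic).

**Uptake rates.** Transformation experiments (fraction ε of cells transformed
after exposure time T) give σ = −ln(1−ε)/T.

## Worked example

Simulate a stationary population at θ = 0.3, time-average sampled spectra,
and refit model A:

```python
import numpy as np
import pangenesis as pg

cfg = pg.SimConfig(N0=150, M=50, rho=1.0, sigma=0.1, seed=7)   # theta = 0.3
obs = pg.stationary_spectrum_mc(cfg, G=15, n_epochs=200, spacing=1.0)
print("observed g_1..g_5:", np.round(obs.g[:5], 1), " g_G:", round(obs.g[-1], 1))

result = pg.fit(obs, "A")
print(f"fitted theta = {result.params.theta:.3f}   Delta = {result.delta:.4f}")
print(f"predicted fluidity = {result.phi_pred():.3f}")
pan, core = pg.pan_core_curves(result.params, obs.M, 15)
print("pan(15) =", round(pan[-1], 1), " core(15) =", round(core[-1], 1))
```

prints

```
observed g_1..g_5: [14.8  8.   5.2  4.2  4.4]  g_G: 20.7
fitted theta = 0.288   Delta = 0.0087
predicted fluidity = 0.224
pan(15) = 91.5  core(15) = 20.7
```

The simulated sample shows the U-shape (g₁ = 14.8 rare genes, g₁₅ = 20.7
core genes per 50-gene genome), the fit recovers the generating θ = 0.3 to
within sampling error, and the predicted fluidity sits near the stationary
value θ/(1+θ) = 0.231. The same operations are available from the shell:

```bash
pangenesis simulate --N 100 --M 30 --theta 0.3 --G 12 --seed 42 \
    --out-matrix matrix.tsv --out-spectrum spectrum.tsv
pangenesis fit --spectrum spectrum.tsv --model all --seed 1
pangenesis fluidity --matrix matrix.tsv
pangenesis uptake --epsilon 1e-3 --T 4
# -> sigma = 2.5013e-04 /hr (~10^-4 /hr)
```

(Note that a fit to a *single* sampled epoch inherits the genealogical noise
of one population snapshot; time-averaged spectra as in the Python example
are the right input for parameter recovery.)

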