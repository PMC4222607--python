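# Methods

## Model

An organism is a pair (W, S(0)): a signed gene-interaction matrix and an
initial ("embryonic") expression state. Expression is binary, s_i ∈
{−1, +1}; development is the synchronous threshold map

    s_i(t+1) = sgn( Σ_j w_ij s_j(t) ),   sgn(0) = +1,

a random threshold network, i.e. the binary-weight, binary-state member
of the Wagner family of gene-network models. Because the state space is
finite (2^N states) the trajectory is eventually periodic; the recurrent
part is the attractor — a fixed point (the "adult" phenotype) or a limit
cycle. A pair reaching a fixed point is called *stable*. All arithmetic
is exact (integers and bit patterns), so attractor detection carries no
tolerances; a step cap of 2^N + 1 guarantees detection by pigeonhole.

Dense networks have all N² entries in {−1, +1}. Sparse networks place
entries in {−1, 0, +1} on a regular directed support built from `degree`
superposed random permutation matrices (default degree 2, density c =
degree/N); self-loops are allowed by default because the autoregulation
statistics require diagonal entries to exist.

### Summary statistics

* **p** (sign of autoregulation): fraction of positive diagonal entries.
* **q**: fraction of positive off-diagonal entries.
* **r** (indirect autoregulation): fraction of strictly positive entries
  in the strict upper triangle of W·Wᵀ — positive autoregulatory paths
  of length two. Zero sums (possible at even N) count as not positive.
  We implement the W·Wᵀ form literally; note it measures shared-target
  sign agreement, not the two-cycle products w_ij·w_ji.
* **stability** (population level): fraction of organisms whose
  development reaches a fixed point.
* **viability / robustness / retention** (single-mutant scan): every
  non-zero entry of a stable organism's matrix is sign-flipped one at a
  time (N² mutants for dense networks) and each mutant is developed from
  the *same* initial state. Viability = fraction of mutants reaching any
  fixed point; robustness = fraction of *viable* mutants reaching the
  identical fixed point (undefined when no mutant is viable — such scans
  are excluded from averages, never imputed as zero); retention =
  fraction of *all* mutants reaching the identical fixed point
  (retention = viability × robustness).

  The conditional normalisation of robustness decouples it from
  stability, but the two definitions associate with p in opposite
  directions for non-evolved stable networks: networks rich in positive
  autoregulation are multistable (positive circuits), so their viable
  mutants frequently settle into a *different* fixed point. It is the
  unconditional retention whose association with p is positive and
  maximal at p = 1, and which makes evolved networks roughly twice as
  robust as composition-matched non-evolved ones; we therefore report
  both statistics everywhere and use retention for the
  "robustness-versus-p" analyses.
* **interaction strength** o_ij: fraction of networks in a set carrying
  a positive entry at (i, j). **Conservation** between two recorded
  generations t₁ < t₂ is o₁o₂ + (1−o₁)(1−o₂), the probability that two
  networks drawn at the two times share the sign at (i, j). This is a
  definitional choice: it is 0.5 for independently random signs and 1
  for frozen signs, and x² + (1−x)² ≥ ½ guarantees values ≥ 0.5 when the
  two strength matrices coincide. Reported conservation medians are
  therefore comparable only qualitatively (diagonal vs off-diagonal,
  selective vs neutral), not digit-for-digit against other formulas.

## Evolution

Populations evolve under a Wright–Fisher loop at constant size n (500 by
default). Each population is founded in the RNIC setup: n random
networks (mean p = q = 0.5, or an exact founding composition (p₀, q₀) on
request) sharing one random initial state, which remains the development
start state for every generation. Per generation:

1. **develop** every organism to its attractor;
2. **select**: sample n offspring with replacement, probability
   proportional to fitness; if every fitness is zero the population is
   resampled uniformly (logged) rather than going extinct;
3. **recombine** (optional): shuffle into n/2 disjoint pairs; each pair
   produces two offspring by exchanging a uniformly random half of their
   matrix rows (full chromosome segregation, no crossover within rows);
4. **mutate**: each entry flips sign independently with probability
   μ/N² (sparse: μ/(cN²) per non-zero entry; zeros never change), i.e.
   μ = 0.1 expected flips per network per generation at default.

The operator order (develop → select → recombine → mutate) follows the
classical implementations of this model family; metrics are recorded on
the developed population of each generation, before selection.

Selection models: (1) *stability* — fitness 0 for cycles; fixed points
score 1 ("no target", σ = ∞) or exp(−d/σ) where d is the normalized
Hamming distance to an optimal state (σ = 0.1 "target"); (2) *cycles* —
fitness 1 iff the attractor length equals l_opt ∈ {2,…,7}, 0 otherwise
including fixed points; (3) *attractor target* — the best exp(−d/σ) over
all states of the attractor, any length; (4) *neutral* — fitness 1. The
exponential-in-Hamming-distance form is the standard choice for this
model family and satisfies both limits: σ → ∞ erases fitness
differences, σ = 0.1 selects strongly. σ = ∞ cases are computed as exact
0/1, with no floating-point leakage.

Sets of z independent populations are evolved from independent RNG
streams spawned from the master seed, so runs are bit-reproducible and
populations are statistically independent. When a target model needs an
optimal state and none is supplied, each population draws its own.

## Implementation notes

States are packed into uint16 bit codes and matrix rows into bitmasks of
their positive and non-zero entries; one update of gene i reduces to a
popcount of `(pos_i XOR s) AND nz_i` compared against ⌊nnz_i/2⌋ (which
encodes sgn(0) = +1 exactly). Attractor detection runs a fixed warm-up
of vectorised steps followed by an all-pairs revisit scan over the
recorded code history, then per-step scanning with batch compaction for
the rare organisms with long transients or cycles. The per-network
public API (`find_attractor`, `single_mutant_scan`, …) is an independent
plain implementation; the test suite cross-checks the two paths against
each other and against exhaustive enumeration of the full
state-transition graph at N = 4. Mutation draws Bernoulli flip positions
via geometric inter-success gaps (exactly equivalent, O(μ·n) per
generation), and the fitness-proportional resampling uses inverse-CDF
sampling on the cumulative fitness vector.

## Problem sizes and what the defaults represent

The original experiments used sets of z = 100–300 populations evolved
for 10⁶–10⁷ generations. The package defaults reproduce the same design
at z = 20 and 10⁴ generations, which covers every phase transition of
the dynamics: the p maximum (~generation 30–60), the q maximum
(~generation 700), and the p/stability equilibria (approached from
~10³). Quantities that only settle around 10⁵ generations (robustness
equilibrium) are measured mid-relaxation at this scale. Summary
estimators: the p peak and its stability are read at the argmax
generation of set-mean p; equilibrium p is the mean over the final 10 %
of generations; the q peak is the max over generations of set-mean q;
the cycle-selection plateau is the mean over the final half of a
3 × 10³-generation run. Position-resolved viability is summarised per
matrix *element* (median of the network-averaged stability of each
diagonal / off-diagonal position): per-network diagonal viabilities are
multiples of 1/10 and their median is too coarse to be informative.

At these sizes two quantities land near the edges of the originally
reported values: the q peak measures ≈ 0.665–0.67 (reported ≈ 0.63) and
the cycle-selection plateau ≈ 0.23–0.25 (reported ≈ 0.3). Directions and
all other quantities agree; the discrepancies persist after verifying
the mutation rate, selection and recombination semantics against
independent statistical tests and the development dynamics against
exhaustive oracles, and are documented rather than recalibrated away.

## What the generators emulate — and what they do not

All inputs are synthetic by design: the study's subject is the ensemble
of random threshold networks itself, not a particular organism's
circuit. Random networks draw every sign as a fair coin; composition
generators place exact counts of positive entries (round(p·N) diagonal,
round(q·N(N−1)) off-diagonal) at uniform positions, matching the binned
experimental design at N = 10 and removing binomial binning noise.
Real regulatory networks differ in ways deliberately out of scope:
unequal in/out-degree distributions, signed-edge frequencies far from
1/2, unequal interaction strengths, asynchronous or noisy updates, and
expression levels beyond on/off. Passing tests therefore validate the
model's internal claims (how stability, autoregulation and mutational
robustness relate *within this ensemble*), not predictions about any
specific biological network.

## Numerical and design choices

* Exact integer/bit arithmetic throughout the dynamics; no tolerances.
* Prescribed compositions use exact counts, not Bernoulli draws.
* Engineered-network donors are generated composition-first (exact
  p = 0.1, q = 48/90 ≈ 0.533) and then rejection-sampled for stability;
  conditioning commutes, and this is ~100× cheaper than filtering
  unconditioned stable networks into a narrow (p, q) window.
* Robustness scans during evolution are scheduled (they cost N²
  developments per organism); per-generation records always include p,
  q, stability and mean fitness, while r follows a log-spaced schedule
  beyond generation 200.
* `sgn(0) = +1` breaks ties toward expression "on"; with an even number
  of inputs this gives a slight systematic bias toward +1 states, which
  is part of the model definition.
* Populations never go extinct: all-zero-fitness generations resample
  uniformly and are counted in the run result.

## Limitations

* The bit engine caps networks at N = 16 genes (the per-network API has
  no such cap). The study's N = 10 fits comfortably.
* Attractor-length selection (model 2) with large l_opt can spend many
  generations in all-zero-fitness rescue at small n.
* Conservation values depend on the definitional choice above.
* No plotting: tables are the canonical outputs.
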