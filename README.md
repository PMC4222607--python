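# threshnet

Boolean threshold gene-regulatory-network dynamics, Wright–Fisher
evolution, and autoregulation/stability/robustness statistics.

`threshnet` is for computational biologists studying how network motifs
— in particular **autoregulation**, a gene regulating its own
transcription — shape the dynamics and evolution of gene regulatory
networks. It implements the binary-weight, binary-state member of the
Wagner model family (a random threshold network): an organism's
phenotype is a vector S of N on/off expression states developed under a
signed interaction matrix W by the synchronous map

    sᵢ(t+1) = sgn( Σⱼ wᵢⱼ sⱼ(t) ),   sgn(0) = +1 .

Development always reaches an attractor — a fixed point ("adult"
phenotype, the network is *stable*) or a limit cycle. The package
provides:

* exact attractor detection (bit-packed, vectorised over large batches);
* generators for random, composition-controlled (exact fractions *p* of
  positive diagonal and *q* of positive off-diagonal signs),
  pre-selected stable, "engineered", and sparse regular networks;
* the field's summary statistics: *p* (sign of autoregulation), *q*,
  *r* (positive length-2 autoregulatory paths, from W·Wᵀ), population
  stability, single-mutant viability / robustness / retention,
  interaction strength and sign conservation over evolutionary time;
* a Wright–Fisher evolutionary loop (selection for stability, for
  cycles of a chosen length, for a target phenotype, or neutral; sign
  mutation at rate μ per network; recombination by full row
  segregation) over sets of independent populations, bit-reproducible
  from a seed;
* figure-level experiment recipes with CSV outputs and JSON manifests,
  plus a small CLI.

The headline phenomenon it reproduces: selection for developmental
stability drives networks toward *positive* autoregulation (p ≈ 0.95 at
the early peak, relaxing to an equilibrium of p ≈ 0.8), mutations of
diagonal elements are more often lethal than off-diagonal ones, and
robust networks can be engineered beyond what evolution delivers by
combining low-p stable off-diagonals with a high-p diagonal.

## Worked example

```python
import numpy as np
from threshnet import (EvolutionConfig, SelectionModel, evolve,
                       find_attractor, sign_autoregulation_p,
                       single_mutant_scan, stable_network)

rng = np.random.default_rng(0)

# a stable 10-gene network found by rejection sampling
W, S0 = stable_network(10, rng)
att = find_attractor(W, S0)
print("attractor length:", att.length, "| transient:", att.transient_length)
print("p =", sign_autoregulation_p(W))

scan = single_mutant_scan(W, S0)      # flip each of the 100 entries once
print(f"viability = {scan.viability:.2f}, robustness = {scan.robustness:.2f}")

# evolve 5 populations of 500 networks under selection for stability
cfg = EvolutionConfig(generations=500, n=500, z=5, seed=42)
res = evolve(cfg, SelectionModel.no_target())
sm = res.set_mean()
print(f"founding mean p = {sm['p'].iloc[0]:.3f}")
print(f"peak mean p = {sm['p'].max():.3f} at generation "
      f"{int(sm.loc[sm['p'].idxmax(), 't'])}")
print(f"mean p at generation 500 = {sm['p'].iloc[-1]:.3f}, "
      f"stability = {sm['stability'].iloc[-1]:.3f}")
```

prints

```
attractor length: 1 | transient: 8
p = 0.9
viability = 0.95, robustness = 0.37
founding mean p = 0.502
peak mean p = 0.952 at generation 182
mean p at generation 500 = 0.870, stability = 0.990
```

Read: this particular stable network has 9 of 10 positive self-loops;
95 of its 100 single sign-flip mutants still develop to a fixed point,
and 37 % of those reach the *same* adult phenotype. Under selection for
stability a random founding population (mean p ≈ 0.5) is driven to
strongly positive autoregulation within a few hundred generations while
population stability approaches 1.

The CLI mirrors the experiment recipes:

```sh
threshnet evolve --model no-target --z 20 -g 10000 --seed 1 --out runs/nt
threshnet stability-vs-p --n-per-bin 10000 --seed 1 --out runs/fig1
threshnet robustness-vs-p --q 0.5 --seed 1 --out runs/fig6
threshnet engineered --seed 1 --out runs/eng
```

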