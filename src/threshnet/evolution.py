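"""Wright-Fisher evolution of threshold-network populations.

Each generation, every organism develops from its population's fixed
founding state (RNIC setup) to an attractor; fitness is assigned by the
selection model; the next generation is drawn by fitness-proportional
sampling with replacement at constant population size ``n``; optionally
the whole population recombines in random disjoint pairs by full-row
segregation; finally each matrix entry flips sign independently with
probability ``mu / N**2`` (sparse: ``mu / (c N**2)``, zeros never change).

Selection models
----------------
1. *Selecting for stability* (``l_opt = 1``): fitness 0 for cycles; for
   fixed points, 1 under the sigma = inf 'no target' variant, or
   ``exp(-d(S_inf, S_opt) / sigma)`` under the 'target' variant, with
   ``d`` the normalized Hamming distance to an optimal state.
2. *Selecting against stability*: fitness 1 iff the attractor length
   equals ``l_opt`` in {2, ..., 7}; 0 otherwise, including fixed points.
3. *Neutral for stability*: fitness is the maximum of
   ``exp(-d(S, S_opt) / sigma)`` over all states ``S`` of the attractor,
   for any attractor length.
4. *Random sampling*: fitness 1 for everyone (pure drift null model).

``z`` independent populations ("a set of populations") are evolved from
independent RNG streams spawned off the master seed; each population has
its own founding state (and its own random target, when one is required
but not supplied).  Runs are bit-reproducible given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _engine
from .core import Attractor, as_state
from .metrics import scan_networks
from .netgen import (Population, composed_networks, random_networks,
                     random_state, sparse_regular_network)

__all__ = [
    "SelectionModel",
    "EvolutionConfig",
    "EvolutionResult",
    "fitness",
    "wright_fisher_select",
    "mutate",
    "recombine",
    "founding_population",
    "evolve",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionModel:
    """One of the four selection regimes (see module docstring)."""

    model_id: int
    sigma: float = math.inf
    l_opt: int = 1
    target: np.ndarray | None = None

    def __post_init__(self):
        if self.model_id not in (1, 2, 3, 4):
            raise ValueError("model_id must be 1, 2, 3 or 4")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive (inf allowed)")
        if self.target is not None:
            self.target = as_state(self.target)
        if self.model_id == 1:
            if self.l_opt != 1:
                raise ValueError("selection for stability requires l_opt = 1")
            if math.isinf(self.sigma) and self.target is not None:
                raise ValueError("the 'no target' variant forbids a target")
        elif self.model_id == 2:
            if self.l_opt < 2:
                raise ValueError("cycle selection requires l_opt >= 2")
            if not math.isinf(self.sigma) or self.target is not None:
                raise ValueError("cycle selection uses sigma = inf, no target")

    # -- convenience constructors -------------------------------------
    @classmethod
    def no_target(cls) -> "SelectionModel":
        """Model 1, sigma = inf: fitness 1 for fixed points, 0 for cycles."""
        return cls(model_id=1)

    @classmethod
    def stability_target(cls, target=None, sigma: float = 0.1) -> "SelectionModel":
        """Model 1, finite sigma: selects fixed points near an optimal state."""
        return cls(model_id=1, sigma=sigma, target=target)

    @classmethod
    def cycle(cls, l_opt: int = 2) -> "SelectionModel":
        """Model 2: fitness 1 iff the attractor has length l_opt."""
        return cls(model_id=2, l_opt=l_opt)

    @classmethod
    def attractor_target(cls, target=None, sigma: float = 0.1) -> "SelectionModel":
        """Model 3: best Hamming match over the whole attractor, any length."""
        return cls(model_id=3, sigma=sigma, target=target)

    @classmethod
    def neutral(cls) -> "SelectionModel":
        """Model 4: constant fitness 1 (random sampling)."""
        return cls(model_id=4)

    @property
    def needs_target(self) -> bool:
        return self.model_id in (1, 3) and not math.isinf(self.sigma)


def _hamming_codes(a, b, n: int) -> np.ndarray:
    return np.bitwise_count(np.asarray(a, np.uint16) ^
                            np.asarray(b, np.uint16)) / n


def fitness(attractor: Attractor, model: SelectionModel,
            target=None) -> float:
    """Fitness of a developed organism under a selection model.

    ``target`` overrides ``model.target`` when given; one of the two must
    be present for the target variants.  sigma = inf cases return exact
    0/1 values with no floating-point leakage.
    """
    n = attractor.cycle.shape[1]
    if model.model_id == 4:
        return 1.0
    if model.model_id == 2:
        return 1.0 if attractor.length == model.l_opt else 0.0
    opt = target if target is not None else model.target
    if model.model_id == 1:
        if not attractor.is_fixed_point:
            return 0.0
        if math.isinf(model.sigma):
            return 1.0
        if opt is None:
            raise ValueError("this selection model requires a target state")
        d = np.mean(attractor.fixed_state != as_state(opt))
        return float(math.exp(-d / model.sigma))
    # model 3: best match over every state of the attractor
    if opt is None:
        raise ValueError("this selection model requires a target state")
    opt = as_state(opt)
    d_min = min(np.mean(s != opt) for s in attractor.cycle)
    if math.isinf(model.sigma):
        return 1.0
    return float(math.exp(-d_min / model.sigma))


# ---------------------------------------------------------------------------
# population-level operators (spec-level API on Population objects)
# ---------------------------------------------------------------------------

def wright_fisher_select(pop: Population, fitnesses,
                         rng: np.random.Generator) -> Population:
    """Resample ``n`` organisms with replacement, proportional to fitness.

    If every fitness is zero the population is resampled uniformly (it
    never goes extinct) and the event is logged.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.shape != (pop.size,):
        raise ValueError("fitnesses must align with the population")
    if pop.size == 0:
        raise ValueError("population is empty")
    total = f.sum()
    if total <= 0:
        logger.info("all fitnesses zero: uniform resampling rescue")
        idx = rng.integers(0, pop.size, pop.size)
    else:
        idx = rng.choice(pop.size, size=pop.size, p=f / total)
    return Population(pop.networks[idx], pop.initial_states[idx])


def mutate(pop: Population, mu: float, rng: np.random.Generator) -> Population:
    """Independent sign flips at rate ``mu`` per network per generation.

    Dense: each of the ``N**2`` entries flips with probability
    ``mu / N**2``.  Sparse: each non-zero entry flips with probability
    ``mu / (c N**2)`` where ``c`` is that network's density; zero entries
    never change, so the interaction topology is preserved.
    """
    if not 0 <= mu <= 1:
        raise ValueError("mu must lie in [0, 1]")
    W = pop.networks.copy()
    nz = W != 0
    nnz = nz.sum(axis=(1, 2))
    rate = np.where(nnz > 0, mu / np.maximum(nnz, 1), 0.0)
    flips = (rng.random(W.shape) < rate[:, None, None]) & nz
    W[flips] *= -1
    return Population(W, pop.initial_states)


def recombine(pop: Population, rng: np.random.Generator) -> Population:
    """Full-chromosome segregation on the whole population.

    The population is shuffled into ``n / 2`` disjoint pairs; each pair
    produces two offspring by exchanging a uniformly random half of their
    matrix rows (no crossover within rows).  Offspring replace parents,
    and each parental row appears in exactly one of the two offspring.
    """
    n_org, n = pop.size, pop.n_genes
    if n_org % 2:
        raise ValueError("recombination requires an even population size")
    W = pop.networks
    perm = rng.permutation(n_org)
    a, b = perm[0::2], perm[1::2]
    take_a = _half_row_masks(n_org // 2, n, rng)
    child_a = np.where(take_a[:, :, None], W[a], W[b])
    child_b = np.where(take_a[:, :, None], W[b], W[a])
    out = np.empty_like(W)
    out[a] = child_a
    out[b] = child_b
    return Population(out, pop.initial_states)


def _half_row_masks(pairs: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """(pairs, n) boolean masks with exactly n // 2 True per row."""
    sel = np.argsort(rng.random((pairs, n)), axis=1)[:, : n // 2]
    mask = np.zeros((pairs, n), dtype=bool)
    np.put_along_axis(mask, sel, True, axis=1)
    return mask


# ---------------------------------------------------------------------------
# full evolutionary runs
# ---------------------------------------------------------------------------

@dataclass
class EvolutionConfig:
    """Parameters of an evolutionary run of ``z`` independent populations."""

    generations: int
    n: int = 500                 # population size
    N: int = 10                  # genes per network
    mu: float = 0.1              # mutation rate per network per generation
    recombination: bool = True
    z: int = 1                   # number of independent populations
    seed: int | None = None
    p0: float | None = None      # founding sign composition (optional)
    q0: float | None = None
    sparse: bool = False         # sparse regular networks instead of dense
    degree: int = 2
    record_r: Sequence[int] | None = None        # None -> automatic schedule
    record_robustness: Sequence[int] = ()        # generations to mutant-scan
    snapshot_generations: Sequence[int] = ()     # generations to archive W
    max_scan_networks: int | None = 2000         # per-set cap for scans

    def __post_init__(self):
        if self.generations < 0 or self.n < 1 or self.z < 1:
            raise ValueError("generations, n and z must be positive")
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must lie in [0, 1]")
        if self.recombination and self.n % 2:
            raise ValueError("recombination requires an even population size")

    def r_schedule(self) -> set:
        if self.record_r is not None:
            return set(int(t) for t in self.record_r)
        dense_part = range(0, min(self.generations, 200) + 1)
        log_part = np.unique(np.geomspace(
            1, max(self.generations, 1), 120).astype(int))
        return set(dense_part) | set(log_part.tolist()) | {self.generations}


@dataclass(eq=False)
class EvolutionResult:
    """Per-generation records plus end-state and scheduled snapshots.

    ``records`` is tidy: one row per (generation, population) with the
    population means of p, q, stability and fitness, plus r / viability /
    robustness at their scheduled generations (NaN elsewhere).
    """

    records: pd.DataFrame
    final_populations: list
    founding_states: np.ndarray           # (z, N)
    snapshots: dict = field(default_factory=dict)  # t -> (z * n, N, N) int8
    rescues: np.ndarray | None = None     # per-population all-zero-fitness events
    config: EvolutionConfig | None = None
    model: SelectionModel | None = None

    def set_mean(self) -> pd.DataFrame:
        """Average the records across the set of populations."""
        return (self.records.drop(columns="pop").groupby("t", as_index=False)
                .mean())


def founding_population(config: EvolutionConfig,
                        rng: np.random.Generator) -> Population:
    """One founding population in the RNIC setup.

    Networks are uniform random (mean p and q of 0.5) unless a founding
    composition ``(p0, q0)`` is configured, in which case every organism
    gets an independent placement with exactly that composition.  All
    organisms share one random initial state.
    """
    n, N = config.n, config.N
    if config.sparse:
        W = np.stack([sparse_regular_network(N, config.degree, rng)
                      for _ in range(n)])
    elif config.p0 is not None or config.q0 is not None:
        if config.p0 is None or config.q0 is None:
            raise ValueError("set both p0 and q0, or neither")
        W = composed_networks(N, config.p0, config.q0, n, rng)
    else:
        W = random_networks(N, n, rng)
    shared = random_state(N, rng)
    return Population(W, np.tile(shared, (n, 1)))


def _fitness_batch(dev: _engine.BatchAttractors, model: SelectionModel,
                   target_codes, n_per_pop: int, n_genes: int) -> np.ndarray:
    l = dev.length
    if model.model_id == 4:
        return np.ones(l.size)
    if model.model_id == 2:
        return (l == model.l_opt).astype(float)
    stable = l == 1
    if model.model_id == 1:
        if math.isinf(model.sigma):
            return stable.astype(float)
        tc = np.repeat(target_codes, n_per_pop)
        d = _hamming_codes(dev.code, tc, n_genes)
        return np.where(stable, np.exp(-d / model.sigma), 0.0)
    # model 3
    tc = np.repeat(target_codes, n_per_pop)
    d = _hamming_codes(dev.code, tc, n_genes)
    cyclers = np.nonzero(~stable)[0]
    for k in cyclers:
        d[k] = _hamming_codes(dev.cycles[k], tc[k], n_genes).min()
    if math.isinf(model.sigma):
        return np.ones(l.size)
    return np.exp(-d / model.sigma)


def _pq_per_pop(net: _engine.CompiledNetworks, z: int, n: int):
    """Set out per-population means of p and q from the packed rows."""
    N = net.n_genes
    shifts = np.arange(N, dtype=np.uint16)
    diag_pos = ((net.pos >> shifts) & 1).astype(np.int32)   # (B, N) diag bits
    diag_nz = ((net.nz >> shifts) & 1).astype(np.int32)
    pos_tot = np.bitwise_count(net.pos).astype(np.int32).sum(axis=1)
    nz_tot = np.bitwise_count(net.nz).astype(np.int32).sum(axis=1)
    dp, dn = diag_pos.sum(axis=1), diag_nz.sum(axis=1)
    # sparse organisms may have no autoregulatory (diagonal) entries at
    # all; they carry no sign-of-autoregulation and drop out of the mean
    with np.errstate(invalid="ignore", divide="ignore"):
        p_org = np.where(dn > 0, dp / np.maximum(dn, 1), np.nan)
        q_org = (pos_tot - dp) / (nz_tot - dn)
    return (np.nanmean(p_org.reshape(z, n), axis=1),
            np.nanmean(q_org.reshape(z, n), axis=1))


def _r_per_pop(net: _engine.CompiledNetworks, z: int, n: int) -> np.ndarray:
    """Per-population mean of r computed from packed rows (exact)."""
    N = net.n_genes
    both = net.nz[:, :, None] & net.nz[:, None, :]
    inter = np.bitwise_count(both).astype(np.int16)
    mism = np.bitwise_count((net.pos[:, :, None] ^ net.pos[:, None, :]) & both
                            ).astype(np.int16)
    M = inter - 2 * mism                       # (B, N, N) == W @ W.T
    iu = np.triu_indices(N, k=1)
    r_org = (M[:, iu[0], iu[1]] > 0).mean(axis=1)
    return r_org.reshape(z, n).mean(axis=1)


def _bernoulli_positions(rng: np.random.Generator, m: int,
                         p: float) -> np.ndarray:
    """Indices of the successes among ``m`` iid Bernoulli(p) trials.

    Generated from geometric inter-success gaps, which is exactly
    equivalent to per-trial draws but costs O(m p) instead of O(m).
    """
    if p <= 0 or m == 0:
        return np.empty(0, dtype=np.int64)
    exp = m * p
    chunk = max(8, int(exp + 6 * exp ** 0.5 + 8))
    pos = np.cumsum(rng.geometric(p, size=chunk)) - 1
    while pos[-1] < m - 1:
        more = pos[-1] + np.cumsum(rng.geometric(p, size=chunk))
        pos = np.concatenate([pos, more])
    return pos[pos < m]


def evolve(config: EvolutionConfig, model: SelectionModel) -> EvolutionResult:
    """Run the full generational loop and return the metric time series.

    Per generation: develop every organism from its population's founding
    state, record metrics, then select / recombine / mutate to form the
    next generation.  Generation 0 is the founding population and
    generation ``config.generations`` is the returned end state, so the
    records span ``generations + 1`` rows per population.
    """
    z, n, N, G = config.z, config.n, config.N, config.generations
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(config.seed).spawn(z)]

    pops = [founding_population(config, rng) for rng in rngs]
    founding_states = np.stack([p.initial_states[0] for p in pops])
    net = _engine.compile_networks(np.concatenate([p.networks for p in pops]))
    codes0 = np.repeat(_engine.state_to_code(founding_states), n)

    target_codes = None
    if model.needs_target:
        if model.target is not None:
            target_codes = np.full(z, _engine.state_to_code(model.target))
        else:
            target_codes = _engine.state_to_code(
                np.stack([random_state(N, rng) for rng in rngs]))

    r_sched = config.r_schedule()
    rob_sched = set(int(t) for t in config.record_robustness)
    snap_sched = set(int(t) for t in config.snapshot_generations)
    rescues = np.zeros(z, dtype=np.int64)

    # mutation: rate per (possibly zero) matrix entry; the founding
    # generators give every organism the same non-zero count and both
    # recombination (whole rows) and mutation (sign flips) preserve it
    nnz = np.bitwise_count(net.nz).astype(np.int64).sum(axis=1)
    if not (nnz == nnz[0]).all():
        raise ValueError("organisms must share a common non-zero entry count")
    dense = int(nnz[0]) == N * N
    entry_rate = config.mu / nnz[0] if nnz[0] else 0.0
    col_idx = np.arange(N)[None, :]
    cols: dict[str, list] = {k: [] for k in
                             ("t", "pop", "p", "q", "r", "stability",
                              "mean_fitness", "viability", "robustness")}
    snapshots: dict[int, np.ndarray] = {}

    for t in range(G + 1):
        dev = _engine.attractors_batch(net, codes0,
                                       keep_cycles=model.model_id == 3)
        fit = _fitness_batch(dev, model, target_codes, n, N)

        p_pop, q_pop = _pq_per_pop(net, z, n)
        stab = dev.is_fixed.reshape(z, n).mean(axis=1)
        mfit = fit.reshape(z, n).mean(axis=1)
        r_pop = _r_per_pop(net, z, n) if t in r_sched else np.full(z, np.nan)
        viab = np.full(z, np.nan)
        rob = np.full(z, np.nan)
        if t in rob_sched:
            viab, rob = _set_robustness(net, codes0, dev, z, n,
                                        config.max_scan_networks)
        cols["t"].append(np.full(z, t))
        cols["pop"].append(np.arange(z))
        cols["p"].append(p_pop)
        cols["q"].append(q_pop)
        cols["r"].append(r_pop)
        cols["stability"].append(stab)
        cols["mean_fitness"].append(mfit)
        cols["viability"].append(viab)
        cols["robustness"].append(rob)
        if t in snap_sched:
            snapshots[t] = _engine.decode_networks(net)
        if t == G:
            break

        # build, per population, the source organism of every offspring row
        # (selection then row-segregating recombination compose into one
        # row-level gather), plus the mutation flip positions
        src = np.empty((z * n, N), dtype=np.int64)
        flip_org = []
        flip_row = []
        flip_bit = []
        for k, rng in enumerate(rngs):
            sl = slice(k * n, (k + 1) * n)
            f = fit[sl]
            total = f.sum()
            if total <= 0:
                rescues[k] += 1
                logger.info("population %d, generation %d: all fitnesses "
                            "zero, uniform resampling", k, t)
                idx = rng.integers(0, n, n)
            elif model.model_id == 4:
                idx = rng.integers(0, n, n)
            else:
                cdf = np.cumsum(f)
                idx = np.searchsorted(cdf, rng.random(n) * total,
                                      side="right").clip(max=n - 1)
            if config.recombination:
                perm = rng.permutation(n)
                a, b = perm[0::2], perm[1::2]
                take_a = _half_row_masks(n // 2, N, rng)
                srck = np.empty((n, N), dtype=np.int64)
                srck[a] = np.where(take_a, idx[a][:, None], idx[b][:, None])
                srck[b] = np.where(take_a, idx[b][:, None], idx[a][:, None])
            else:
                srck = np.broadcast_to(idx[:, None], (n, N))
            src[sl] = srck + k * n
            flat = _bernoulli_positions(rng, n * N * N, entry_rate)
            if flat.size:
                flip_org.append(flat // (N * N) + k * n)
                flip_row.append((flat // N) % N)
                flip_bit.append(np.left_shift(
                    np.uint16(1), (flat % N).astype(np.uint16)))

        net.pos = net.pos[src, col_idx]
        if not dense:
            net.nz = net.nz[src, col_idx]
            net.thresh = net.thresh[src, col_idx]
        if flip_org:
            forg = np.concatenate(flip_org)
            frow = np.concatenate(flip_row)
            fbit = np.concatenate(flip_bit)
            if not dense:  # zero entries never mutate
                keep = (net.nz[forg, frow] & fbit) != 0
                forg, frow, fbit = forg[keep], frow[keep], fbit[keep]
            np.bitwise_xor.at(net.pos, (forg, frow), fbit)

    records = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    W_final = _engine.decode_networks(net)
    finals = [Population(W_final[k * n:(k + 1) * n],
                         np.tile(founding_states[k], (n, 1)))
              for k in range(z)]
    return EvolutionResult(records=records, final_populations=finals,
                           founding_states=founding_states,
                           snapshots=snapshots, rescues=rescues,
                           config=config, model=model)


def _set_robustness(net, codes0, dev, z, n, max_scan):
    """Population-mean viability and robustness via single-mutant scans.

    Scans the stable organisms of each population (subsampled evenly down
    to ``max_scan`` networks across the set when there are more) and
    averages per network; robustness-undefined scans are excluded.
    """
    viab = np.full(z, np.nan)
    rob = np.full(z, np.nan)
    stable_idx = np.nonzero(dev.is_fixed)[0]
    if stable_idx.size == 0:
        return viab, rob
    if max_scan is not None and stable_idx.size > max_scan:
        sel = np.linspace(0, stable_idx.size - 1, max_scan).astype(int)
        stable_idx = stable_idx[sel]
    sub = net.take(stable_idx)
    states0 = _engine.code_to_state(codes0[stable_idx], net.n_genes)
    res = scan_networks(_engine.decode_networks(sub), states0,
                        ref_codes=dev.code[stable_idx])
    pop_of = stable_idx // n
    for k in range(z):
        mask = pop_of == k
        if mask.any():
            viab[k] = np.nanmean(res["viability"][mask])
            rvals = res["robustness"][mask]
            if np.isfinite(rvals).any():
                rob[k] = np.nanmean(rvals)
    return viab, rob
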