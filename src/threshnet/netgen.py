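"""Generators for networks, states and populations.

Covers uniform random dense networks, networks with an exactly prescribed
sign composition (fraction ``p`` of positive diagonal / ``q`` of positive
off-diagonal entries), rejection-sampled stable networks, "engineered"
networks (a stable donor's off-diagonal entries combined with a fresh
high-``p`` diagonal), sparse regular directed graphs, and population
initialisation in the two experimental setups:

* RNRC -- independent (random network, random initial condition) pairs,
  used for non-evolving samples;
* RNIC -- many random networks sharing one random initial condition,
  used to found evolving populations.

Prescribed compositions place exactly ``round(p * N)`` positive diagonal
and ``round(q * N * (N - 1))`` positive off-diagonal entries at uniformly
random positions, so the measured fractions equal the requested ones
exactly (the experiments bin by discrete ``p`` at ``N = 10``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from .core import as_network, as_state

__all__ = [
    "Population",
    "PopulationSetup",
    "random_state",
    "random_states",
    "random_network",
    "random_networks",
    "network_with_sign_composition",
    "composed_networks",
    "stable_network",
    "stable_networks",
    "engineered_network",
    "sparse_regular_network",
    "init_population",
]


@dataclass
class Population:
    """``n`` organisms: signed networks paired with initial states.

    ``networks`` is ``(n, N, N)`` int8 and ``initial_states`` ``(n, N)``
    int8; in the RNIC setup all rows of ``initial_states`` are identical.
    """

    networks: np.ndarray
    initial_states: np.ndarray

    def __post_init__(self):
        self.networks = np.asarray(self.networks, dtype=np.int8)
        self.initial_states = np.asarray(self.initial_states, dtype=np.int8)
        if self.networks.ndim != 3 or self.networks.shape[1] != self.networks.shape[2]:
            raise ValueError("networks must be a (n, N, N) batch")
        if self.initial_states.shape != self.networks.shape[:2]:
            raise ValueError("initial_states must be (n, N)")

    @property
    def size(self) -> int:
        return self.networks.shape[0]

    @property
    def n_genes(self) -> int:
        return self.networks.shape[1]


@dataclass
class PopulationSetup:
    """How to initialise a population: setup mode, size, gene count, seed."""

    mode: str = "RNIC"
    n: int = 500
    N: int = 10
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("RNRC", "RNIC"):
            raise ValueError("mode must be 'RNRC' or 'RNIC'")


def random_state(N: int, rng: np.random.Generator) -> np.ndarray:
    """A uniform random +/-1 state (each gene on with probability 0.5)."""
    return random_states(N, 1, rng)[0]


def random_states(N: int, count: int, rng: np.random.Generator) -> np.ndarray:
    if N < 1:
        raise ValueError("N must be >= 1")
    return (2 * rng.integers(0, 2, size=(count, N)) - 1).astype(np.int8)


def random_network(N: int, rng: np.random.Generator) -> np.ndarray:
    """A dense network with every entry +/-1 with probability 0.5."""
    return random_networks(N, 1, rng)[0]


def random_networks(N: int, count: int, rng: np.random.Generator) -> np.ndarray:
    if N < 1:
        raise ValueError("N must be >= 1")
    return (2 * rng.integers(0, 2, size=(count, N, N)) - 1).astype(np.int8)


def _count_on_grid(frac: float, slots: int, name: str) -> int:
    k = round(frac * slots)
    if abs(frac * slots - k) > 1e-9:
        raise ValueError(
            f"{name}={frac} is not on the grid of multiples of 1/{slots}")
    if not 0 <= k <= slots:
        raise ValueError(f"{name} must lie in [0, 1]")
    return k


def network_with_sign_composition(N: int, p: float, q: float | None = None,
                                  rng: np.random.Generator | None = None
                                  ) -> np.ndarray:
    """A dense network with exact sign composition.

    Exactly ``round(p * N)`` diagonal entries are +1 (the rest -1), placed
    uniformly at random.  If ``q`` is given, exactly ``round(q * N * (N-1))``
    off-diagonal entries are +1; otherwise off-diagonal signs are
    independent fair coin flips.  Off-grid ``p`` or ``q`` raise
    ``ValueError``.
    """
    return composed_networks(N, p, q, 1, rng)[0]


def composed_networks(N: int, p: float, q: float | None, count: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Vectorised batch form of :func:`network_with_sign_composition`."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    kp = _count_on_grid(p, N, "p")
    W = np.full((count, N, N), -1, dtype=np.int8)

    # diagonal: kp positive entries at uniform positions per network
    order = np.argsort(rng.random((count, N)), axis=1)
    diag_pos = order[:, :kp]
    rows = np.repeat(np.arange(count), kp)
    W[rows, diag_pos.ravel(), diag_pos.ravel()] = 1
    # start from all-(-1) diagonal for the complement (already -1)

    off = ~np.eye(N, dtype=bool)
    oi, oj = np.nonzero(off)
    m = oi.size
    if q is None:
        signs = (2 * rng.integers(0, 2, size=(count, m)) - 1).astype(np.int8)
        W[:, oi, oj] = signs
    else:
        kq = _count_on_grid(q, m, "q")
        order = np.argsort(rng.random((count, m)), axis=1)
        sel = order[:, :kq]
        rows = np.repeat(np.arange(count), kq)
        W[rows, oi[sel.ravel()], oj[sel.ravel()]] = 1
        # unselected off-diagonal entries remain -1
    return W


def stable_network(N: int, rng: np.random.Generator,
                   max_attempts: int = 10 ** 6):
    """Rejection-sample (random network, random state) pairs until stable.

    Returns the first accepted ``(W, S0)`` pair, whose development reaches
    a fixed point.  Raises ``RuntimeError`` if ``max_attempts`` pairs are
    rejected (the acceptance probability at N = 10 makes this unreachable
    in practice).
    """
    W, S = stable_networks(N, 1, rng, max_samples=max_attempts)
    return W[0], S[0]


def stable_networks(N: int, count: int, rng: np.random.Generator,
                    p: float | None = None, q: float | None = None,
                    batch: int = 8192, max_samples: int = 10 ** 6):
    """Harvest ``count`` stable (network, state) pairs by batched rejection.

    Optionally constrains the exact sign composition of the candidate
    networks (``p`` for the diagonal, ``q`` for the off-diagonal fraction
    of positive entries) before the stability rejection step.
    """
    got_W, got_S, n_got, n_drawn = [], [], 0, 0
    while n_got < count:
        if n_drawn >= max_samples:
            raise RuntimeError(
                f"found only {n_got}/{count} stable networks after "
                f"{n_drawn} samples")
        b = min(batch, max_samples - n_drawn)
        if p is None:
            W = random_networks(N, b, rng)
        else:
            W = composed_networks(N, p, q, b, rng)
        S = random_states(N, b, rng)
        n_drawn += b
        dev = _engine.attractors_batch(_engine.compile_networks(W),
                                       _engine.state_to_code(S))
        keep = dev.is_fixed
        if keep.any():
            got_W.append(W[keep])
            got_S.append(S[keep])
            n_got += int(keep.sum())
    W = np.concatenate(got_W)[:count]
    S = np.concatenate(got_S)[:count]
    return W, S


def engineered_network(offdiag_donor, diag_p: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Combine a donor's off-diagonal entries with a fresh high-``p`` diagonal.

    The donor is typically a stable network with few positive diagonal
    entries; the result keeps its off-diagonal structure (hence its ``q``)
    but carries exactly ``round(diag_p * N)`` positive diagonal entries at
    uniformly random positions.
    """
    W = as_network(offdiag_donor).copy()
    n = W.shape[0]
    k = _count_on_grid(diag_p, n, "diag_p")
    diag = np.full(n, -1, dtype=np.int8)
    diag[rng.permutation(n)[:k]] = 1
    np.fill_diagonal(W, diag)
    return W


def sparse_regular_network(N: int, degree: int = 2,
                           rng: np.random.Generator | None = None,
                           allow_self_loops: bool = True,
                           max_tries: int = 1000) -> np.ndarray:
    """A sparse network on a random regular directed graph.

    The support is the superposition of ``degree`` independent random
    permutation matrices (redrawn on collision), so every gene regulates
    exactly ``degree`` genes and is regulated by exactly ``degree`` genes;
    the density is ``degree / N``.  Non-zero entries get independent
    +/-1 signs.  With ``allow_self_loops=False``, draws containing a
    diagonal support entry are also rejected.
    """
    if not 1 <= degree < N:
        raise ValueError("degree must satisfy 1 <= degree < N")
    if rng is None:
        rng = np.random.default_rng()
    for _ in range(max_tries):
        support = np.zeros((N, N), dtype=bool)
        ok = True
        for _ in range(degree):
            perm = rng.permutation(N)
            if support[np.arange(N), perm].any():
                ok = False
                break
            support[np.arange(N), perm] = True
        if ok and not allow_self_loops and support.diagonal().any():
            ok = False
        if ok:
            signs = (2 * rng.integers(0, 2, size=(N, N)) - 1).astype(np.int8)
            return np.where(support, signs, 0).astype(np.int8)
    raise RuntimeError("could not draw a collision-free regular support")


def init_population(setup: PopulationSetup) -> Population:
    """Initialise a population of random networks in the requested setup."""
    rng = np.random.default_rng(setup.seed)
    W = random_networks(setup.N, setup.n, rng)
    if setup.mode == "RNIC":
        shared = random_state(setup.N, rng)
        states = np.tile(shared, (setup.n, 1))
    else:
        states = random_states(setup.N, setup.n, rng)
    return Population(W, states)
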