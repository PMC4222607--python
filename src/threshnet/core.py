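"""Deterministic developmental dynamics of Boolean threshold gene networks.

An organism's phenotype is a vector ``S`` of ``N`` gene expression states,
each -1 (off) or +1 (on).  A signed interaction matrix ``W`` (entry
``w_ij`` is the effect of gene *j*'s product on gene *i*) drives
*development*: the synchronous threshold map

    s_i(t+1) = sgn( sum_j w_ij * s_j(t) ),    with sgn(0) = +1.

Because the state space is finite and the map deterministic, every
trajectory is eventually periodic; its recurrent part is the *attractor*,
either a fixed point (length 1, a "mature" phenotype) or a limit cycle.
A (``W``, ``S0``) pair whose attractor is a fixed point is called *stable*.

All arithmetic here is exact integer arithmetic, and states are hashed by
their byte pattern, so attractor detection has no tolerance parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Attractor",
    "threshold_sign",
    "develop_step",
    "find_attractor",
    "is_stable",
]


def as_state(S) -> np.ndarray:
    """Validate and convert a gene expression state to an int8 +/-1 vector."""
    arr = np.asarray(S)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("a state must be a non-empty 1-d sequence")
    if not np.isin(arr, (-1, 1)).all():
        raise ValueError("state entries must all be -1 or +1")
    return arr.astype(np.int8)


def as_network(W) -> np.ndarray:
    """Validate and convert an interaction matrix to an int8 square matrix.

    Dense networks have entries in {-1, +1}; sparse ones may contain zeros.
    """
    arr = np.asarray(W)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] == 0:
        raise ValueError("a network must be a non-empty square matrix")
    if not np.isin(arr, (-1, 0, 1)).all():
        raise ValueError("network entries must all be in {-1, 0, +1}")
    return arr.astype(np.int8)


def threshold_sign(x):
    """Sign threshold with the sgn(0) = +1 convention.

    Accepts a scalar or an array of (integer) weighted sums and returns
    +1 where ``x >= 0`` and -1 elsewhere.
    """
    if np.isscalar(x):
        return 1 if x >= 0 else -1
    return np.where(np.asarray(x) >= 0, 1, -1).astype(np.int8)


def develop_step(W, S) -> np.ndarray:
    """One synchronous development step: ``S'_i = sgn(sum_j w_ij s_j)``.

    All entries of the new state are computed from the same input state.
    Raises ``ValueError`` if the network and state dimensions differ.
    """
    W = as_network(W)
    S = as_state(S)
    if W.shape[0] != S.shape[0]:
        raise ValueError(
            f"network of {W.shape[0]} genes is incompatible with a state of "
            f"length {S.shape[0]}")
    sums = W.astype(np.int32) @ S.astype(np.int32)
    return threshold_sign(sums)


@dataclass(frozen=True, eq=False)
class Attractor:
    """The recurrent part of a development trajectory.

    ``cycle`` is an ``(l, N)`` array of +/-1 states ordered so that one
    development step maps ``cycle[k]`` to ``cycle[(k + 1) % l]``;
    ``transient_length`` is the number of steps taken before the first
    recurrent state was entered.
    """

    transient_length: int
    cycle: np.ndarray = field(repr=False)

    @property
    def length(self) -> int:
        return self.cycle.shape[0]

    @property
    def is_fixed_point(self) -> bool:
        return self.length == 1

    @property
    def fixed_state(self) -> np.ndarray:
        if not self.is_fixed_point:
            raise ValueError("attractor is a limit cycle, not a fixed point")
        return self.cycle[0]


def find_attractor(W, S0, max_steps: int | None = None) -> Attractor:
    """Develop from ``S0`` until the first revisit of a previously seen state.

    The cycle returned is the trajectory segment between the two visits of
    the revisited state; ``transient_length`` is the index of its first
    occurrence.  The default step cap of ``2**N + 1`` guarantees detection
    by pigeonhole over the ``2**N`` possible states; a smaller explicit cap
    may raise ``RuntimeError``.
    """
    W = as_network(W)
    cur = as_state(S0)
    if W.shape[0] != cur.shape[0]:
        raise ValueError("network and initial state dimensions differ")
    n = cur.shape[0]
    if max_steps is None:
        max_steps = 2 ** n + 1
    seen = {cur.tobytes(): 0}
    states = [cur]
    for t in range(1, max_steps + 1):
        cur = develop_step(W, cur)
        key = cur.tobytes()
        if key in seen:
            first = seen[key]
            return Attractor(transient_length=first,
                             cycle=np.array(states[first:], dtype=np.int8))
        seen[key] = t
        states.append(cur)
    raise RuntimeError(
        "no attractor detected within max_steps; use the default cap of "
        "2**N + 1 for guaranteed detection")


def is_stable(W, S0, max_steps: int | None = None) -> bool:
    """True iff development from ``S0`` reaches a fixed point."""
    return find_attractor(W, S0, max_steps=max_steps).is_fixed_point
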