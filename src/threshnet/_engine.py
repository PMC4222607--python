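"""Bit-parallel batch engine for threshold-network development.

A length-``N`` vector of +/-1 expression states is packed into a single
``uint16`` code (bit *i* set means gene *i* is on).  Row *i* of a signed
interaction matrix ``W`` packs into two bitmasks: the positions of its
positive entries and of its non-zero entries.  One synchronous update of
gene *i* is then

    sum_j w_ij * s_j  =  k_i - 2 * popcount((pos_i XOR s) AND nz_i)

where ``k_i`` is the number of non-zero entries in row *i*.  The updated
state is +1 exactly when that sum is >= 0, i.e. when the popcount is at
most ``k_i // 2`` -- which also encodes the sgn(0) = +1 convention.

Everything here is an implementation detail; the public per-network API
lives in :mod:`threshnet.core`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: states are packed into uint16, so networks can have at most 16 genes here
N_MAX = 16


def _pow2(n: int) -> np.ndarray:
    return np.left_shift(np.uint16(1), np.arange(n, dtype=np.uint16))


def state_to_code(states) -> np.ndarray:
    """Pack +/-1 state vectors of shape ``(..., N)`` into uint16 bit codes."""
    states = np.asarray(states)
    n = states.shape[-1]
    if n > N_MAX:
        raise ValueError(f"bit engine supports at most {N_MAX} genes, got {n}")
    bits = (states > 0).astype(np.uint16)
    return (bits * _pow2(n)).sum(axis=-1).astype(np.uint16)


def code_to_state(codes, n: int) -> np.ndarray:
    """Unpack uint16 codes back into int8 +/-1 vectors of shape ``(..., n)``."""
    codes = np.asarray(codes, dtype=np.uint16)
    bits = (codes[..., None] >> np.arange(n, dtype=np.uint16)) & np.uint16(1)
    return (2 * bits.astype(np.int8) - 1)


@dataclass
class CompiledNetworks:
    """A batch of signed matrices in row-packed form.

    ``pos`` and ``nz`` are ``(B, N)`` uint16 bitmasks of the positive and
    non-zero entries of each row; ``thresh`` is ``(B, N)`` uint8 holding
    ``nnz(row) // 2`` (the popcount threshold equivalent to sgn >= 0).
    """

    pos: np.ndarray
    nz: np.ndarray
    thresh: np.ndarray
    n_genes: int

    @property
    def batch_size(self) -> int:
        return self.pos.shape[0]

    def take(self, idx) -> "CompiledNetworks":
        return CompiledNetworks(self.pos[idx], self.nz[idx], self.thresh[idx],
                                self.n_genes)

    def copy(self) -> "CompiledNetworks":
        return CompiledNetworks(self.pos.copy(), self.nz.copy(),
                                self.thresh.copy(), self.n_genes)


def compile_networks(weights) -> CompiledNetworks:
    """Pack an ``(N, N)`` or ``(B, N, N)`` signed integer matrix batch."""
    w = np.asarray(weights)
    if w.ndim == 2:
        w = w[None]
    if w.ndim != 3 or w.shape[1] != w.shape[2]:
        raise ValueError("expected an (N, N) matrix or a (B, N, N) batch")
    n = w.shape[1]
    if n > N_MAX:
        raise ValueError(f"bit engine supports at most {N_MAX} genes, got {n}")
    pow2 = _pow2(n)
    pos = ((w > 0).astype(np.uint16) * pow2).sum(axis=-1).astype(np.uint16)
    nz = ((w != 0).astype(np.uint16) * pow2).sum(axis=-1).astype(np.uint16)
    thresh = (np.bitwise_count(nz) // 2).astype(np.uint8)
    return CompiledNetworks(pos, nz, thresh, n)


def decode_networks(net: CompiledNetworks) -> np.ndarray:
    """Unpack a compiled batch back into ``(B, N, N)`` int8 matrices."""
    n = net.n_genes
    shifts = np.arange(n, dtype=np.uint16)
    posb = ((net.pos[:, :, None] >> shifts) & 1).astype(np.int8)
    nzb = ((net.nz[:, :, None] >> shifts) & 1).astype(np.int8)
    return nzb * (2 * posb - 1)


def step_codes(net: CompiledNetworks, codes: np.ndarray) -> np.ndarray:
    """One synchronous development step on a batch of packed states."""
    x = np.bitwise_count((net.pos ^ codes[:, None]) & net.nz)
    bits = (x <= net.thresh).astype(np.uint16)
    return (bits * _pow2(net.n_genes)).sum(axis=-1).astype(np.uint16)


@dataclass
class BatchAttractors:
    """Attractor summary for a batch of (network, initial state) pairs.

    ``code`` holds the state at the first revisit: for a fixed point this
    is the fixed state itself; for a limit cycle it is one (deterministic)
    anchor state of the cycle.  ``cycles`` is only populated on request and
    maps each organism to the uint16 codes of its full cycle.
    """

    transient: np.ndarray   # (B,) int32: steps before the first recurrent state
    length: np.ndarray      # (B,) int32: attractor length (1 == fixed point)
    code: np.ndarray        # (B,) uint16
    cycles: list | None = None

    @property
    def is_fixed(self) -> np.ndarray:
        return self.length == 1


def attractors_batch(net: CompiledNetworks, codes0, max_steps: int | None = None,
                     keep_cycles: bool = False,
                     warmup: int = 10) -> BatchAttractors:
    """Iterate development for every organism until its first state revisit.

    Detection is exact: each packed state code is compared against the
    organism's full visited history, and the default cap of ``2**N + 1``
    steps guarantees a revisit by pigeonhole.  For throughput the search
    runs in two phases: ``warmup`` unconditional steps followed by one
    vectorised all-pairs revisit scan (which resolves the vast majority of
    organisms, whose transients and cycles are short), then a per-step
    scan with batch compaction for the stragglers.
    """
    codes0 = np.atleast_1d(np.asarray(codes0, dtype=np.uint16))
    b = codes0.size
    n = net.n_genes
    if net.batch_size != b:
        raise ValueError("batch sizes of networks and states differ")
    if max_steps is None:
        max_steps = (1 << n) + 1

    transient = np.zeros(b, np.int32)
    length = np.zeros(b, np.int32)
    attr = np.zeros(b, np.uint16)
    cycles: list | None = [None] * b if keep_cycles else None

    # phase 1: run warmup steps for everyone, then one pairwise revisit scan
    t1 = min(warmup, max_steps)
    hist = np.empty((t1 + 1, b), np.uint16)
    hist[0] = codes0
    codes = codes0
    for t in range(1, t1 + 1):
        codes = step_codes(net, codes)
        hist[t] = codes
    # (i, j) pairs ordered by revisit step j then i; the first matching pair
    # per organism is its first revisit (the matching i is unique, since an
    # earlier duplicate would itself have been an earlier revisit)
    i_arr = np.concatenate([np.arange(j) for j in range(1, t1 + 1)])
    j_arr = np.repeat(np.arange(1, t1 + 1), np.arange(1, t1 + 1))
    eq = hist[i_arr] == hist[j_arr]
    found = eq.any(axis=0)
    first = eq.argmax(axis=0)
    cols = np.nonzero(found)[0]
    fi, fj = i_arr[first[cols]], j_arr[first[cols]]
    transient[cols] = fi
    length[cols] = fj - fi
    attr[cols] = hist[fj, cols]
    if keep_cycles:
        for c, i0, j0 in zip(cols, fi, fj):
            cycles[c] = hist[i0:j0, c].copy()

    # phase 2: stragglers, per-step scan with compaction
    idx = np.nonzero(~found)[0]
    if not idx.size:
        return BatchAttractors(transient, length, attr, cycles)
    cur = net.take(idx)
    codes = codes[idx]
    hist = np.ascontiguousarray(hist[:, idx])
    t = t1
    while idx.size:
        if t >= max_steps:
            raise RuntimeError(
                "attractor not detected within max_steps; a cap of 2**N + 1 "
                "steps guarantees detection")
        t += 1
        if t >= hist.shape[0]:
            hist = np.concatenate([hist, np.empty_like(hist)], axis=0)
        codes = step_codes(cur, codes)
        eq = hist[:t] == codes[None, :]
        found = eq.any(axis=0)
        if found.any():
            first = eq.argmax(axis=0)
            cols = np.nonzero(found)[0]
            orig = idx[cols]
            transient[orig] = first[cols]
            length[orig] = t - first[cols]
            attr[orig] = codes[cols]
            if keep_cycles:
                for c, o in zip(cols, orig):
                    cycles[o] = hist[first[c]:t, c].copy()
            keep = ~found
            idx = idx[keep]
            if not idx.size:
                break
            codes = codes[keep]
            cur = cur.take(keep)
            hist = hist[:, keep]
        hist[t] = codes
    return BatchAttractors(transient, length, attr, cycles)


def expand_single_mutants(net: CompiledNetworks):
    """Enumerate every single-sign-flip mutant of every network in a batch.

    Returns ``(mutants, owner, row, col)`` where ``owner[k]`` indexes the
    source network of mutant ``k`` and ``(row, col)`` the flipped entry.
    Only non-zero entries are flipped, so a dense network contributes
    exactly ``N**2`` mutants in row-major entry order.
    """
    n = net.n_genes
    shifts = np.arange(n, dtype=np.uint16)
    nzbits = ((net.nz[:, :, None] >> shifts) & 1).astype(bool)
    owner, row, col = np.nonzero(nzbits)
    m = owner.size
    pos = net.pos[owner].copy()
    pos[np.arange(m), row] ^= np.left_shift(np.uint16(1), col.astype(np.uint16))
    mutants = CompiledNetworks(pos, net.nz[owner], net.thresh[owner], n)
    return mutants, owner, row, col
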