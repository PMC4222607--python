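"""Summary statistics for networks, mutants and populations.

Sign-composition statistics for a signed matrix ``W``:

* ``p`` -- the *sign of autoregulation*: fraction of positive diagonal
  entries.  ``p > 0.5`` means predominantly positive autoregulation.
* ``q`` -- fraction of positive off-diagonal entries (regulation of
  other genes).
* ``r`` -- *indirect positive autoregulation*: the fraction of strictly
  positive entries in the strict upper triangle of ``W @ W.T``, a
  statistic for positive autoregulatory paths of length two.

Mutational statistics for a stable (``W``, ``S0``) pair are computed by
the single-mutant scan: every non-zero entry of ``W`` has its sign
flipped one at a time (``N**2`` mutants for a dense network) and each
mutant develops from the same ``S0``:

* *viability*  = (mutants reaching a fixed point) / (number of mutants);
* *robustness* = (mutants reaching the identical fixed point as the
  unmutated original) / (mutants reaching a fixed point), undefined when
  no mutant reaches a fixed point;
* *retention*  = (mutants reaching the identical fixed point) /
  (number of mutants) -- the unconditional fraction of mutations that
  preserve the adult phenotype.

Normalising robustness by the viable count (rather than by ``N**2``)
decouples it from stability; undefined scans are excluded from
population averages rather than imputed.  Retention couples the two
effects (retention = viability * robustness) and is the quantity whose
association with the sign of autoregulation is positive: conditioning on
mutant stability inverts the trend, because networks rich in positive
autoregulation are multistable and their viable mutants often settle
into a different fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .core import as_network, as_state, find_attractor
from .netgen import Population

__all__ = [
    "MutantScanResult",
    "InteractionStrengthMatrix",
    "hamming_normalized",
    "sign_autoregulation_p",
    "sign_offdiag_q",
    "indirect_autoregulation_r",
    "population_stability",
    "single_mutant_scan",
    "scan_networks",
    "interaction_strength",
    "conservation",
]


def hamming_normalized(S1, S2) -> float:
    """Fraction of genes whose expression differs between two states."""
    S1, S2 = as_state(S1), as_state(S2)
    if S1.shape != S2.shape:
        raise ValueError("states have different lengths")
    return float(np.mean(S1 != S2))


def sign_autoregulation_p(W) -> float:
    """Fraction of positive diagonal (autoregulatory) entries.

    For sparse networks the denominator is the number of non-zero
    diagonal entries; a network with an all-zero diagonal has no defined
    sign of autoregulation and raises ``ValueError``.
    """
    W = as_network(W)
    diag = np.diagonal(W)
    nz = np.count_nonzero(diag)
    if nz == 0:
        raise ValueError("network has no non-zero diagonal entries")
    return float(np.count_nonzero(diag > 0) / nz)


def sign_offdiag_q(W) -> float:
    """Fraction of positive off-diagonal entries (sparse: among non-zeros)."""
    W = as_network(W)
    off = W[~np.eye(W.shape[0], dtype=bool)]
    nz = np.count_nonzero(off)
    if nz == 0:
        raise ValueError("network has no non-zero off-diagonal entries")
    return float(np.count_nonzero(off > 0) / nz)


def indirect_autoregulation_r(W) -> float:
    """Fraction of positive length-2 autoregulatory path sums.

    Computes ``M = W @ W.T`` in exact integer arithmetic and returns the
    fraction of strictly positive entries among the ``N (N - 1) / 2``
    strict-upper-triangle entries of ``M`` (``M`` is symmetric).  A zero
    sum, possible at even ``N``, counts as not positive.
    """
    W = as_network(W).astype(np.int64)
    M = W @ W.T
    iu = np.triu_indices(W.shape[0], k=1)
    return float(np.mean(M[iu] > 0))


def population_stability(pop: Population) -> float:
    """Fraction of organisms whose development reaches a fixed point."""
    if pop.size == 0:
        raise ValueError("population is empty")
    dev = _engine.attractors_batch(_engine.compile_networks(pop.networks),
                                   _engine.state_to_code(pop.initial_states))
    return float(dev.is_fixed.mean())


@dataclass(eq=False)
class MutantScanResult:
    """Tallies of a single-mutant scan of one stable (W, S0) pair."""

    n_total: int
    n_fixed: int
    n_same: int
    viability: float
    robustness: float | None
    per_element_fixed: np.ndarray = field(repr=False)  # (N, N) bool


def single_mutant_scan(W, S0) -> MutantScanResult:
    """Flip every non-zero entry of ``W`` one at a time and develop each mutant.

    Requires the unmutated (``W``, ``S0``) pair to reach a fixed point
    (robustness is only defined for stable originals).  Robustness is
    ``None`` -- not zero -- when no mutant reaches a fixed point.
    """
    W = as_network(W)
    S0 = as_state(S0)
    ref = find_attractor(W, S0)
    if not ref.is_fixed_point:
        raise ValueError("single-mutant scans require a stable original")
    net = _engine.compile_networks(W)
    res = scan_networks(W[None], S0[None],
                        ref_codes=_engine.state_to_code(ref.fixed_state)[None])
    n = W.shape[0]
    per_element = np.zeros((n, n), dtype=bool)
    mutants, owner, row, col = _engine.expand_single_mutants(net)
    per_element[row, col] = res["per_mutant_fixed"]
    n_fixed = int(res["n_fixed"][0])
    n_same = int(res["n_same"][0])
    n_total = int(res["n_mutants"][0])
    return MutantScanResult(
        n_total=n_total,
        n_fixed=n_fixed,
        n_same=n_same,
        viability=n_fixed / n_total,
        robustness=(n_same / n_fixed) if n_fixed else None,
        per_element_fixed=per_element,
    )


def scan_networks(networks, initial_states, ref_codes=None,
                  chunk: int = 2000) -> dict:
    """Vectorised single-mutant scan over a batch of stable pairs.

    ``networks`` is ``(B, N, N)``, ``initial_states`` ``(B, N)``.  If
    ``ref_codes`` (the packed fixed-point states of the originals) is not
    given, the originals are developed first and must all be stable.

    Returns a dict of per-network arrays (``viability``, ``robustness``
    with NaN where undefined, diagonal / off-diagonal viability splits,
    tallies) plus the ``(N, N)`` mean per-element mutant-stability map and
    the flat ``per_mutant_fixed`` vector (chunked scans concatenate it in
    network order).
    """
    networks = np.asarray(networks, dtype=np.int8)
    initial_states = np.asarray(initial_states, dtype=np.int8)
    b, n = networks.shape[0], networks.shape[1]
    codes0 = _engine.state_to_code(initial_states)
    if ref_codes is None:
        dev = _engine.attractors_batch(_engine.compile_networks(networks), codes0)
        if not dev.is_fixed.all():
            raise ValueError("all originals must develop to a fixed point")
        ref_codes = dev.code
    ref_codes = np.asarray(ref_codes, dtype=np.uint16)

    viability = np.empty(b)
    robustness = np.full(b, np.nan)
    diag_viab = np.full(b, np.nan)
    offdiag_viab = np.full(b, np.nan)
    n_mut = np.empty(b, dtype=np.int64)
    n_fixed_arr = np.empty(b, dtype=np.int64)
    n_same_arr = np.empty(b, dtype=np.int64)
    heat_sum = np.zeros((n, n))
    heat_cnt = np.zeros((n, n))
    fixed_parts = []

    for lo in range(0, b, chunk):
        hi = min(lo + chunk, b)
        net = _engine.compile_networks(networks[lo:hi])
        mutants, owner, row, col = _engine.expand_single_mutants(net)
        reps = np.bincount(owner, minlength=hi - lo)
        mcodes0 = np.repeat(codes0[lo:hi], reps)
        dev = _engine.attractors_batch(mutants, mcodes0)
        fixed = dev.is_fixed
        same = fixed & (dev.code == np.repeat(ref_codes[lo:hi], reps))
        fixed_parts.append(fixed)

        nf = np.bincount(owner, weights=fixed, minlength=hi - lo)
        ns = np.bincount(owner, weights=same, minlength=hi - lo)
        n_mut[lo:hi] = reps
        n_fixed_arr[lo:hi] = nf.astype(np.int64)
        n_same_arr[lo:hi] = ns.astype(np.int64)
        viability[lo:hi] = nf / reps
        defined = nf > 0
        robustness[lo:hi][defined] = ns[defined] / nf[defined]

        on_diag = row == col
        d_mut = np.bincount(owner, weights=on_diag, minlength=hi - lo)
        d_fix = np.bincount(owner, weights=fixed & on_diag, minlength=hi - lo)
        o_fix = nf - d_fix
        has_d = d_mut > 0
        has_o = (reps - d_mut) > 0
        diag_viab[lo:hi][has_d] = d_fix[has_d] / d_mut[has_d]
        offdiag_viab[lo:hi][has_o] = o_fix[has_o] / (reps - d_mut)[has_o]

        np.add.at(heat_sum, (row, col), fixed)
        np.add.at(heat_cnt, (row, col), 1)

    with np.errstate(invalid="ignore"):
        heatmap = np.where(heat_cnt > 0, heat_sum / np.maximum(heat_cnt, 1),
                           np.nan)
    return {
        "viability": viability,
        "robustness": robustness,
        "retention": n_same_arr / n_mut,
        "diag_viability": diag_viab,
        "offdiag_viability": offdiag_viab,
        "n_mutants": n_mut,
        "n_fixed": n_fixed_arr,
        "n_same": n_same_arr,
        "heatmap": heatmap,
        "per_mutant_fixed": np.concatenate(fixed_parts),
    }


@dataclass(eq=False)
class InteractionStrengthMatrix:
    """Per-position fraction of positive entries across a set of networks."""

    o: np.ndarray  # (N, N) fractions in [0, 1]
    t: int | None = None  # generation stamp


def interaction_strength(networks, t: int | None = None
                         ) -> InteractionStrengthMatrix:
    """Average positive interaction strength ``o_ij`` across networks.

    ``o_ij`` is the fraction of networks in the collection whose entry
    ``(i, j)`` is positive; extreme values (0 or 1) mean the sign at that
    position is identical across the whole collection.
    """
    if isinstance(networks, Population):
        networks = networks.networks
    elif isinstance(networks, (list, tuple)) and networks and \
            isinstance(networks[0], Population):
        networks = np.concatenate([p.networks for p in networks])
    networks = np.asarray(networks)
    if networks.ndim != 3 or networks.shape[0] == 0:
        raise ValueError("expected a non-empty (B, N, N) batch of networks")
    return InteractionStrengthMatrix(o=(networks > 0).mean(axis=0), t=t)


def conservation(o1: InteractionStrengthMatrix,
                 o2: InteractionStrengthMatrix) -> np.ndarray:
    """Per-element sign conservation between two time points.

    For each position the probability that a network drawn from the
    population at ``t1`` and one drawn at ``t2`` carry the same sign:
    ``o1 * o2 + (1 - o1) * (1 - o2)``.  Independent random signs give the
    baseline 0.5; identical frozen signs give 1.
    """
    a, b = np.asarray(o1.o, dtype=float), np.asarray(o2.o, dtype=float)
    if a.shape != b.shape:
        raise ValueError("interaction-strength matrices have different shapes")
    if o1.t is not None and o2.t is not None and not o1.t < o2.t:
        raise ValueError("conservation requires o1.t < o2.t")
    return a * b + (1.0 - a) * (1.0 - b)
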