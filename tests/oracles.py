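"""Independent brute-force oracles used to validate the implementation.

Everything here is written with plain Python loops and integer
arithmetic, deliberately sharing no code with the package internals.
"""

import numpy as np


def step_bruteforce(W, S):
    """One development step computed entry by entry with Python ints."""
    n = len(S)
    out = []
    for i in range(n):
        total = sum(int(W[i][j]) * int(S[j]) for j in range(n))
        out.append(1 if total >= 0 else -1)
    return tuple(out)


def all_states(n):
    """All 2**n states as tuples of +/-1, in binary-counter order."""
    states = []
    for code in range(2 ** n):
        states.append(tuple(1 if (code >> i) & 1 else -1 for i in range(n)))
    return states


def transition_map(W):
    """The full state-transition graph as a dict state -> next state."""
    n = len(W)
    return {s: step_bruteforce(W, s) for s in all_states(n)}


def attractor_from_map(tmap, s0):
    """Walk the transition graph; return (transient, cycle states as a list).

    The cycle starts at the first revisited state and follows trajectory
    order.
    """
    seen = {s0: 0}
    path = [s0]
    s = s0
    while True:
        s = tmap[s]
        if s in seen:
            first = seen[s]
            return first, path[first:]
        seen[s] = len(path)
        path.append(s)


def mutant_scan_bruteforce(W, S0):
    """Re-enumerate all single-sign-flip mutants and tally their fates.

    Returns (n_total, n_fixed, n_same) where "same" means the mutant
    reaches the identical fixed point as the unmutated original from S0.
    """
    n = len(W)
    t0, cyc0 = attractor_from_map(transition_map(W), tuple(int(v) for v in S0))
    assert len(cyc0) == 1, "original must be stable"
    ref = cyc0[0]
    n_total = n_fixed = n_same = 0
    for i in range(n):
        for j in range(n):
            if W[i][j] == 0:
                continue
            M = [list(row) for row in W]
            M[i][j] = -M[i][j]
            n_total += 1
            _, cyc = attractor_from_map(transition_map(M),
                                        tuple(int(v) for v in S0))
            if len(cyc) == 1:
                n_fixed += 1
                if cyc[0] == ref:
                    n_same += 1
    return n_total, n_fixed, n_same


def r_bruteforce(W):
    """Fraction of positive strict-upper-triangle entries of W W^T."""
    n = len(W)
    hits = total = 0
    for i in range(n):
        for k in range(i + 1, n):
            dot = sum(int(W[i][j]) * int(W[k][j]) for j in range(n))
            total += 1
            if dot > 0:
                hits += 1
    return hits / total


def state_tuple(S):
    return tuple(int(v) for v in np.asarray(S))
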