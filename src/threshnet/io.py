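"""Reading and writing networks and states as plain-text TSV/JSON.

Networks are whitespace-delimited integer matrices (N rows by N columns)
or JSON objects ``{"n": N, "weights": [[...]]}``.  States are length-N
integer rows.  Batches of networks are written as blank-line separated
TSV blocks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import as_network, as_state


def read_network_tsv(path) -> np.ndarray:
    W = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return as_network(W)


def write_network_tsv(path, W) -> None:
    np.savetxt(path, as_network(W), fmt="%d", delimiter="\t")


def read_network_json(path) -> np.ndarray:
    obj = json.loads(Path(path).read_text())
    W = as_network(obj["weights"])
    if W.shape[0] != obj.get("n", W.shape[0]):
        raise ValueError("declared size 'n' does not match the weight matrix")
    return W


def write_network_json(path, W) -> None:
    W = as_network(W)
    Path(path).write_text(json.dumps(
        {"n": int(W.shape[0]), "weights": W.tolist()}))


def read_states_tsv(path) -> np.ndarray:
    rows = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return np.array([as_state(r) for r in rows], dtype=np.int8)


def write_states_tsv(path, states) -> None:
    states = np.atleast_2d(np.asarray(states))
    np.savetxt(path, states, fmt="%d", delimiter="\t")


def read_networks_tsv(path) -> np.ndarray:
    """Read a batch of equally-sized networks from blank-line separated TSV."""
    blocks = [b for b in Path(path).read_text().split("\n\n") if b.strip()]
    nets = [as_network(np.loadtxt(b.strip().splitlines(), dtype=np.int64,
                                  ndmin=2)) for b in blocks]
    return np.stack(nets)


def write_networks_tsv(path, networks) -> None:
    networks = np.asarray(networks)
    with open(path, "w") as fh:
        for k, W in enumerate(networks):
            if k:
                fh.write("\n")
            for row in W:
                fh.write("\t".join(str(int(v)) for v in row) + "\n")
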