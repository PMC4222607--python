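"""Reproducible figure-level analyses at configurable scale.

Each recipe returns tidy tables (pandas DataFrames) and, when given an
output directory, writes them as CSV together with a JSON manifest that
fully determines the run (parameters plus seed), so a rerun reproduces
the outputs bit for bit.  Plots are deliberately not produced here; the
CSV tables are the canonical outputs.

Default sizes are scaled down from the original large-scale experiments
(hundreds of populations evolved for millions of generations) to sizes
that equilibrate on a desktop: the evolutionary summary statistics reach
their plateaus by roughly 10^3-10^4 generations, which the defaults
cover.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _engine, __version__
from .evolution import EvolutionConfig, EvolutionResult, SelectionModel, evolve
from .metrics import (InteractionStrengthMatrix, conservation,
                      interaction_strength, scan_networks)
from .netgen import (composed_networks, engineered_network, random_states,
                     stable_networks)

__all__ = [
    "run_stability_vs_p",
    "run_robustness_vs_p",
    "run_timecourse",
    "run_mutant_position_analysis",
    "run_conservation_analysis",
    "run_engineered_comparison",
]


def _write_manifest(out_dir, name: str, params: dict) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"recipe": name, "threshnet_version": __version__,
                "params": params}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))


@dataclass(eq=False)
class StabilityVsPResult:
    """Per-bin stability plus the pooled stable/unstable p distributions."""

    per_bin: pd.DataFrame          # columns: p, n, n_stable, stability
    median_p_stable: float
    median_p_unstable: float
    samples: pd.DataFrame = field(repr=False)  # columns: p, stable


def run_stability_vs_p(n_per_bin: int = 10 ** 4, N: int = 10,
                       q: float | None = None, seed: int | None = None,
                       out_dir=None) -> StabilityVsPResult:
    """Individual-level stability across the autoregulation-sign grid.

    For each ``p`` in {0, 1/N, ..., 1}, samples ``n_per_bin`` networks
    with exactly ``p * N`` positive diagonal entries (off-diagonal signs
    random unless ``q`` is fixed), pairs each with an independent random
    initial state (RNRC setup), develops to the attractor and classifies
    the pair as stable (fixed point) or unstable (limit cycle).
    """
    rng = np.random.default_rng(seed)
    rows = []
    p_all, stable_all = [], []
    for k in range(N + 1):
        p = k / N
        W = composed_networks(N, p, q, n_per_bin, rng)
        S = random_states(N, n_per_bin, rng)
        dev = _engine.attractors_batch(_engine.compile_networks(W),
                                       _engine.state_to_code(S))
        stable = dev.is_fixed
        rows.append({"p": p, "n": n_per_bin,
                     "n_stable": int(stable.sum()),
                     "stability": float(stable.mean())})
        p_all.append(np.full(n_per_bin, p))
        stable_all.append(stable)
    per_bin = pd.DataFrame(rows)
    p_all = np.concatenate(p_all)
    stable_all = np.concatenate(stable_all)
    samples = pd.DataFrame({"p": p_all, "stable": stable_all})
    result = StabilityVsPResult(
        per_bin=per_bin,
        median_p_stable=float(np.median(p_all[stable_all])),
        median_p_unstable=float(np.median(p_all[~stable_all])),
        samples=samples,
    )
    if out_dir is not None:
        _write_manifest(out_dir, "stability_vs_p",
                        dict(n_per_bin=n_per_bin, N=N, q=q, seed=seed))
        per_bin.to_csv(Path(out_dir) / "stability_by_p.csv", index=False)
    return result


@dataclass(eq=False)
class RobustnessVsPResult:
    per_network: pd.DataFrame   # p, viability, robustness per scanned network
    per_bin: pd.DataFrame       # p, n, mean/median robustness and viability
    p_by_robustness_bin: pd.DataFrame  # 5 robustness bins of width 0.2


def run_robustness_vs_p(n_per_bin: int = 10 ** 3, q: float | None = 0.5,
                        stable_only: bool = True, N: int = 10,
                        p_grid=None, seed: int | None = None,
                        max_samples_per_bin: int = 4 * 10 ** 7,
                        out_dir=None) -> RobustnessVsPResult:
    """Single-mutant robustness of non-evolved networks across the p grid.

    With ``stable_only`` (the default), networks are pre-selected stable
    at each exact composition ``(p, q)``; otherwise plain samples are
    drawn and only the stable ones are scanned (robustness is undefined
    for unstable originals).
    """
    rng = np.random.default_rng(seed)
    if p_grid is None:
        p_grid = [k / N for k in range(N + 1)]
    frames = []
    for p in p_grid:
        if stable_only:
            W, S = stable_networks(N, n_per_bin, rng, p=p, q=q,
                                   max_samples=max_samples_per_bin)
        else:
            W = composed_networks(N, p, q, n_per_bin, rng)
            S = random_states(N, n_per_bin, rng)
            dev = _engine.attractors_batch(_engine.compile_networks(W),
                                           _engine.state_to_code(S))
            W, S = W[dev.is_fixed], S[dev.is_fixed]
        if len(W) == 0:
            continue
        res = scan_networks(W, S)
        frames.append(pd.DataFrame({"p": p,
                                    "viability": res["viability"],
                                    "robustness": res["robustness"],
                                    "retention": res["retention"]}))
    per_network = pd.concat(frames, ignore_index=True)
    per_bin = (per_network.groupby("p")
               .agg(n=("robustness", "size"),
                    mean_robustness=("robustness", "mean"),
                    median_robustness=("robustness", "median"),
                    mean_retention=("retention", "mean"),
                    median_retention=("retention", "median"),
                    mean_viability=("viability", "mean"))
               .reset_index())
    edges = np.arange(0, 1.2, 0.2)
    rb = pd.cut(per_network["robustness"], edges, include_lowest=True)
    p_by_rb = (per_network.groupby(rb, observed=False)["p"]
               .agg(["count", "mean", "median"]).reset_index()
               .rename(columns={"robustness": "robustness_bin"}))
    result = RobustnessVsPResult(per_network, per_bin, p_by_rb)
    if out_dir is not None:
        _write_manifest(out_dir, "robustness_vs_p",
                        dict(n_per_bin=n_per_bin, q=q, stable_only=stable_only,
                             N=N, p_grid=list(p_grid), seed=seed))
        per_bin.to_csv(Path(out_dir) / "robustness_by_p.csv", index=False)
        p_by_rb.to_csv(Path(out_dir) / "p_by_robustness_bin.csv", index=False)
    return result


def run_timecourse(model: SelectionModel, config: EvolutionConfig,
                   out_dir=None) -> EvolutionResult:
    """Evolve a set of populations and emit the metric time series.

    With ``out_dir``, writes ``metrics.csv`` (per generation and
    population), its set-mean aggregation, the final networks and
    per-organism founding states, any scheduled network snapshots, a
    manifest and a short plain-text log.
    """
    result = evolve(config, model)
    if out_dir is not None:
        from . import io as _io

        out_dir = Path(out_dir)
        _write_manifest(out_dir, "timecourse",
                        dict(model=asdict(model), config=asdict(config)))
        result.records.to_csv(out_dir / "metrics.csv", index=False)
        sm = result.set_mean()
        sm.to_csv(out_dir / "metrics_set_mean.csv", index=False)
        net_dir = out_dir / "networks"
        net_dir.mkdir(exist_ok=True)
        _io.write_networks_tsv(
            net_dir / "final.tsv",
            np.concatenate([p.networks for p in result.final_populations]))
        _io.write_states_tsv(
            out_dir / "initial_states.tsv",
            np.concatenate([p.initial_states
                            for p in result.final_populations]))
        for t, W in result.snapshots.items():
            _io.write_networks_tsv(net_dir / f"t{t}.tsv", W)
        tail = sm.tail(1).iloc[0]
        (out_dir / "log.txt").write_text(
            f"generations={config.generations} z={config.z} n={config.n} "
            f"model={model.model_id}\n"
            f"final set means: p={tail['p']:.4f} q={tail['q']:.4f} "
            f"stability={tail['stability']:.4f}\n"
            f"all-zero-fitness rescues per population: "
            f"{result.rescues.tolist()}\n")
    return result


@dataclass(eq=False)
class MutantPositionResult:
    """Diagonal vs off-diagonal viability of evolved stable networks.

    Two granularities are reported.  Per network: the fraction of its 10
    diagonal (respectively 90 off-diagonal) mutants that stay viable —
    coarse, multiples of 1/10 and 1/90.  Per element: the ``(N, N)``
    heat map of network-averaged mutant stability per matrix position;
    ``element_*_median`` are the medians of its diagonal / off-diagonal
    entries, the statistic usually shown as position boxplots.
    """

    per_network: pd.DataFrame
    heatmap: np.ndarray            # (N, N) mean per-element mutant stability
    overall_viability: float       # mean over networks of per-network viability
    median_diag_viability: float
    median_offdiag_viability: float
    element_diag_median: float
    element_offdiag_median: float
    n_input: int
    n_stable: int


def run_mutant_position_analysis(networks, initial_states,
                                 out_dir=None) -> MutantPositionResult:
    """Position-resolved single-mutant viability for a set of networks.

    Unstable originals are dropped (scans are defined on stable pairs);
    per network the viabilities of the ``N`` diagonal and ``N**2 - N``
    off-diagonal mutants are split out, and the per-element stability map
    is averaged into an ``(N, N)`` heat map.
    """
    networks = np.asarray(networks, dtype=np.int8)
    initial_states = np.asarray(initial_states, dtype=np.int8)
    dev = _engine.attractors_batch(_engine.compile_networks(networks),
                                   _engine.state_to_code(initial_states))
    keep = dev.is_fixed
    res = scan_networks(networks[keep], initial_states[keep],
                        ref_codes=dev.code[keep])
    per_network = pd.DataFrame({
        "viability": res["viability"],
        "diag_viability": res["diag_viability"],
        "offdiag_viability": res["offdiag_viability"],
        "robustness": res["robustness"],
    })
    heat = res["heatmap"]
    n = heat.shape[0]
    off_mask = ~np.eye(n, dtype=bool)
    result = MutantPositionResult(
        per_network=per_network,
        heatmap=heat,
        overall_viability=float(np.mean(res["viability"])),
        median_diag_viability=float(np.median(res["diag_viability"])),
        median_offdiag_viability=float(np.median(res["offdiag_viability"])),
        element_diag_median=float(np.median(np.diagonal(heat))),
        element_offdiag_median=float(np.median(heat[off_mask])),
        n_input=int(networks.shape[0]),
        n_stable=int(keep.sum()),
    )
    if out_dir is not None:
        _write_manifest(out_dir, "mutant_position_analysis",
                        dict(n_input=result.n_input))
        per_network.to_csv(Path(out_dir) / "mutant_viability.csv", index=False)
        np.savetxt(Path(out_dir) / "viability_heatmap.tsv", res["heatmap"],
                   delimiter="\t")
    return result


@dataclass(eq=False)
class ConservationResult:
    matrix: np.ndarray             # (N, N) per-element conservation
    median_diag: float
    median_offdiag: float
    o1: InteractionStrengthMatrix
    o2: InteractionStrengthMatrix


def run_conservation_analysis(result: EvolutionResult, t1: int, t2: int,
                              out_dir=None) -> ConservationResult:
    """Sign conservation of matrix elements between two recorded generations.

    Requires network snapshots at generations ``t1 < t2`` (configure
    ``snapshot_generations`` on the run).  Diagonal and off-diagonal
    elements are contrasted via their median conservation.
    """
    for t in (t1, t2):
        if t not in result.snapshots:
            raise ValueError(f"no network snapshot recorded at generation {t}")
    o1 = interaction_strength(result.snapshots[t1], t=t1)
    o2 = interaction_strength(result.snapshots[t2], t=t2)
    C = conservation(o1, o2)
    diag = np.diagonal(C)
    off = C[~np.eye(C.shape[0], dtype=bool)]
    res = ConservationResult(matrix=C,
                             median_diag=float(np.median(diag)),
                             median_offdiag=float(np.median(off)),
                             o1=o1, o2=o2)
    if out_dir is not None:
        _write_manifest(out_dir, "conservation", dict(t1=t1, t2=t2))
        np.savetxt(Path(out_dir) / "conservation.tsv", C, delimiter="\t")
    return res


@dataclass(eq=False)
class EngineeredComparisonResult:
    """Engineered networks versus matched random stable controls."""

    per_network: pd.DataFrame   # group, stable, viability, robustness, r
    medians: pd.DataFrame       # per-group median robustness and r
    engineered_stability: float  # fraction of engineered nets that are stable


def run_engineered_comparison(n_per_group: int = 10 ** 3, N: int = 10,
                              donor_p: float = 0.1, offdiag_q: float = 48 / 90,
                              diag_p: float = 0.9, seed: int | None = None,
                              out_dir=None) -> EngineeredComparisonResult:
    """Compare engineered networks against matched random stable networks.

    Donors are stable networks with a low sign of autoregulation
    (``donor_p``) and near-equilibrium off-diagonal composition; their
    off-diagonal entries are combined with a fresh high-``p`` diagonal.
    Controls are random stable networks with the same final composition
    ``(diag_p, offdiag_q)``.  Both groups get single-mutant scans (on
    their stable members, developed in the RNRC setup) and the length-2
    autoregulatory-path statistic r.
    """
    from .metrics import indirect_autoregulation_r

    rng = np.random.default_rng(seed)
    donors, _ = stable_networks(N, n_per_group, rng, p=donor_p, q=offdiag_q)
    engineered = np.stack([engineered_network(W, diag_p, rng) for W in donors])
    S_eng = random_states(N, n_per_group, rng)
    dev = _engine.attractors_batch(_engine.compile_networks(engineered),
                                   _engine.state_to_code(S_eng))
    eng_stable = dev.is_fixed

    controls, S_ctl = stable_networks(N, n_per_group, rng, p=diag_p,
                                      q=offdiag_q)

    frames = []
    for group, W, S, stable in (
            ("engineered", engineered[eng_stable], S_eng[eng_stable], None),
            ("control", controls, S_ctl, None)):
        res = scan_networks(W, S)
        r_vals = np.array([indirect_autoregulation_r(w) for w in W])
        frames.append(pd.DataFrame({"group": group,
                                    "viability": res["viability"],
                                    "robustness": res["robustness"],
                                    "retention": res["retention"],
                                    "r": r_vals}))
    per_network = pd.concat(frames, ignore_index=True)
    medians = (per_network.groupby("group")
               .agg(median_robustness=("robustness", "median"),
                    median_retention=("retention", "median"),
                    median_r=("r", "median"),
                    median_viability=("viability", "median"),
                    n=("r", "size"))
               .reset_index())
    result = EngineeredComparisonResult(
        per_network=per_network, medians=medians,
        engineered_stability=float(eng_stable.mean()))
    if out_dir is not None:
        _write_manifest(out_dir, "engineered_comparison",
                        dict(n_per_group=n_per_group, N=N, donor_p=donor_p,
                             offdiag_q=offdiag_q, diag_p=diag_p, seed=seed))
        medians.to_csv(Path(out_dir) / "engineered_medians.csv", index=False)
        per_network.to_csv(Path(out_dir) / "engineered_networks.csv",
                           index=False)
    return result
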