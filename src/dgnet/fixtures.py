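"""Deterministic toy networks and reference graphs for tests and demos.

Everything here is generated programmatically: small dentate networks with
rules scaled down to the toy population sizes, canonical graphs with known
closed-form metrics (ring lattice, complete, star, path), and a small
spike-time file for the file-driven stimulation source.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .metrics import UndirectedGraph
from .synapses import StimulusProtocol
from .topology import NetworkModel, generate_network, scaled_rules, write_edge_list, write_metadata

#: Toy population for fast end-to-end runs (20 cells).
MINI_COUNTS = {"GC": 12, "MC": 3, "BC": 2, "HIPP": 3}


def mini_network(seed: int = 0, mode: str = "healthy",
                 counts: dict[str, int] | None = None,
                 sprouting_degree: int = 2) -> NetworkModel:
    """A small dentate network with the default rules scaled to the counts."""
    counts = counts or MINI_COUNTS
    return generate_network(
        counts=counts,
        mode=mode,
        seed=seed,
        rules=scaled_rules(counts),
        sprouting_degree=sprouting_degree,
        sprouting_pool=max(2, counts["GC"] // 3),
    )


def mini_protocol(counts: dict[str, int] | None = None) -> StimulusProtocol:
    counts = counts or MINI_COUNTS
    return StimulusProtocol(
        onset=5.0,
        n_gc=max(1, counts["GC"] // 3),
        n_bc=1,
        n_mc=1,
    )


def ring_lattice(n: int = 20, k: int = 4) -> UndirectedGraph:
    """Ring of n nodes, each joined to its k nearest neighbours (k even).

    Closed forms: C = 3(k - 2) / (4(k - 1)); mean degree k.
    """
    if k % 2 or k < 2 or k >= n:
        raise ValueError("need even k with 2 <= k < n")
    a = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(1, k // 2 + 1):
            a[i, (i + j) % n] = a[(i + j) % n, i] = True
    return UndirectedGraph(a)


def complete_graph(n: int) -> UndirectedGraph:
    a = ~np.eye(n, dtype=bool)
    return UndirectedGraph(a)


def star_graph(n_leaves: int) -> UndirectedGraph:
    a = np.zeros((n_leaves + 1, n_leaves + 1), dtype=bool)
    a[0, 1:] = a[1:, 0] = True
    return UndirectedGraph(a)


def path_graph(n: int) -> UndirectedGraph:
    a = np.zeros((n, n), dtype=bool)
    idx = np.arange(n - 1)
    a[idx, idx + 1] = a[idx + 1, idx] = True
    return UndirectedGraph(a)


def random_connected_graph(n: int, p: float, rng: np.random.Generator) -> UndirectedGraph:
    """Erdős–Rényi graph forced connected by adding a random spanning path."""
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    a = a | a.T
    order = rng.permutation(n)
    a[order[:-1], order[1:]] = True
    a[order[1:], order[:-1]] = True
    np.fill_diagonal(a, False)
    return UndirectedGraph(a)


def write_graph_edges(graph: UndirectedGraph, path) -> None:
    """Generic node/node TSV for canonical graphs (ids n0, n1, ...)."""
    with open(path, "w") as fh:
        fh.write("pre_id\tpost_id\n")
        pre, post = np.nonzero(np.triu(graph.adjacency, 1))
        for i, j in zip(pre, post):
            fh.write(f"n{i}\tn{j}\n")


SPIKE_TIMES_FIXTURE = (5.0, 20.0, 40.0)


def write_spike_times(path, times=SPIKE_TIMES_FIXTURE) -> None:
    with open(path, "w") as fh:
        for t in times:
            fh.write(f"{t}\n")


def make_fixtures(seed: int, out_dir) -> list[Path]:
    """Write the full deterministic fixture set into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    net = mini_network(seed)
    write_edge_list(net, out / "mini_dentate_edges.tsv")
    write_metadata(net, out / "mini_dentate_meta.json")
    written += [out / "mini_dentate_edges.tsv", out / "mini_dentate_meta.json"]

    for name, graph in (
        ("ring_n20_k4", ring_lattice(20, 4)),
        ("complete_k10", complete_graph(10)),
        ("star_s6", star_graph(6)),
    ):
        p = out / f"{name}_edges.tsv"
        write_graph_edges(graph, p)
        written.append(p)

    p = out / "spike_times.txt"
    write_spike_times(p)
    written.append(p)
    return written
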