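"""Rank memory nodes by flow, residues by connectivity, and report paths.

A memory node (X,Y) carries flow that is explicitly attributable to
3-residue paths: every in-edge (W,X)→(X,Y) is the path W→X→Y and every
out-edge (X,Y)→(Y,Z) the path X→Y→Z.  Ranking memory nodes by their
stationary visit rate surfaces the critical junctions of the network;
ranking residues by the number of significant pairwise correlations
(with triple participation as a tie-break) surfaces the hubs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mediation import MediationResult
from .memory_network import FlowDistribution, MemoryNetwork, MemoryNode
from .rank_stats import CorrelationSet
from .shift_io import ResidueKey

__all__ = [
    "MemoryNodeRank",
    "rank_memory_nodes",
    "rank_connectivity",
    "pathway_report",
    "top_memory_nodes",
]


def _key_str(key: ResidueKey) -> str:
    return f"{key[0]}:{key[1]}"


@dataclass
class MemoryNodeRank:
    state: MemoryNode
    visit: float
    rank: int
    in_paths: list[tuple[str, str, str, float]]   # (src, mid, dst, flow)
    out_paths: list[tuple[str, str, str, float]]

    @property
    def label(self) -> str:
        return f"{_key_str(self.state[0])}->{_key_str(self.state[1])}"


def _link_flows(net: MemoryNetwork, flow: FlowDistribution) -> np.ndarray:
    out_w = np.zeros(net.n_states)
    np.add.at(out_w, net.edges_src, net.edges_weight)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(out_w > 0, 1.0 / np.where(out_w == 0, 1.0, out_w), 0.0)
    return (1.0 - flow.tau) * flow.visit[net.edges_src] \
        * net.edges_weight * inv[net.edges_src]


def rank_memory_nodes(net: MemoryNetwork, flow: FlowDistribution
                      ) -> list[MemoryNodeRank]:
    """Memory nodes in descending visit-rate order.

    Ties break lexicographically on (prev, curr).  Each entry itemizes
    the contributing 3-residue paths with their link flows; the itemized
    out-flows of a non-dangling node sum to its transition flow
    (1−τ)·visit.
    """
    f = _link_flows(net, flow)
    in_paths: dict[int, list] = {i: [] for i in range(net.n_states)}
    out_paths: dict[int, list] = {i: [] for i in range(net.n_states)}
    for s, d, fl in zip(net.edges_src, net.edges_dst, f):
        (a, b), (_, c) = net.states[s], net.states[d]
        path = (_key_str(a), _key_str(b), _key_str(c), float(fl))
        out_paths[s].append(path)
        in_paths[d].append(path)

    order = sorted(range(net.n_states),
                   key=lambda i: (-flow.visit[i], net.states[i]))
    return [
        MemoryNodeRank(state=net.states[i], visit=float(flow.visit[i]),
                       rank=r + 1, in_paths=in_paths[i], out_paths=out_paths[i])
        for r, i in enumerate(order)
    ]


def top_memory_nodes(ranks: list[MemoryNodeRank],
                     fraction: float = 0.05) -> list[MemoryNodeRank]:
    """The highly-ranked memory nodes (top ``fraction`` by flow, >= 1)."""
    k = max(1, int(np.ceil(fraction * len(ranks))))
    return ranks[:k]


def rank_connectivity(corr: CorrelationSet, mediation: MediationResult,
                      p_cutoff: float | None = None,
                      require_positive: bool = True) -> pd.DataFrame:
    """Residues ordered by number of significant pairwise correlations.

    Degree counts significant positive pairs; the number of mediated
    triples a residue participates in (any position) is the secondary
    key.  Returns a DataFrame (residue, degree, n_triples, rank).
    """
    cutoff = p_cutoff if p_cutoff is not None else mediation.config.p_cutoff
    sig = corr.significant_pairs(cutoff, require_positive)
    degree = sig.sum(axis=1)
    triple_count: dict[str, int] = {}
    for col in ("A", "B", "C"):
        if len(mediation.triples):
            for key, cnt in mediation.triples[col].value_counts().items():
                triple_count[key] = triple_count.get(key, 0) + int(cnt)
    rows = []
    for i, key in enumerate(corr.residues):
        ks = _key_str(key)
        rows.append({"residue": ks, "degree": int(degree[i]),
                     "n_triples": triple_count.get(ks, 0)})
    df = pd.DataFrame(rows).sort_values(
        ["degree", "n_triples", "residue"], ascending=[False, False, True],
        ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def pathway_report(net: MemoryNetwork, flow: FlowDistribution,
                   node: MemoryNode, depth: int = 1) -> dict:
    """Flow neighborhood of one memory node.

    Reports the residues feeding into and out of the node with their
    link-flow magnitudes, plus the chains of connected memory nodes up to
    ``depth`` hops downstream and upstream.  Serializable to JSON/DOT.
    """
    sidx = net.state_index()
    if node not in sidx:
        raise KeyError(f"unknown memory node {node}")
    i0 = sidx[node]
    f = _link_flows(net, flow)
    out_adj: dict[int, list[tuple[int, float]]] = {}
    in_adj: dict[int, list[tuple[int, float]]] = {}
    for s, d, fl in zip(net.edges_src, net.edges_dst, f):
        out_adj.setdefault(int(s), []).append((int(d), float(fl)))
        in_adj.setdefault(int(d), []).append((int(s), float(fl)))

    def label(i: int) -> str:
        prev, curr = net.states[i]
        return f"{_key_str(prev)} {_key_str(curr)}"

    incoming = [{"residue": _key_str(net.states[s][0]), "flow": fl}
                for s, fl in in_adj.get(i0, [])]
    outgoing = [{"residue": _key_str(net.states[d][1]), "flow": fl}
                for d, fl in out_adj.get(i0, [])]

    def chain(adj: dict[int, list[tuple[int, float]]]) -> list[dict]:
        seen = {i0}
        frontier = [i0]
        result = []
        for hop in range(1, depth + 1):
            nxt = []
            for i in frontier:
                for j, fl in adj.get(i, []):
                    if j not in seen:
                        seen.add(j)
                        nxt.append(j)
                        result.append({"memory_node": label(j), "hop": hop,
                                       "flow": fl,
                                       "visit": float(flow.visit[j])})
            frontier = nxt
        return result

    return {
        "memory_node": label(i0),
        "visit": float(flow.visit[i0]),
        "incoming": sorted(incoming, key=lambda r: -r["flow"]),
        "outgoing": sorted(outgoing, key=lambda r: -r["flow"]),
        "downstream": chain(out_adj),
        "upstream": chain(in_adj),
    }


def pathway_to_json(report: dict, path=None) -> str:
    text = json.dumps(report, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def pathway_to_dot(report: dict, path=None) -> str:
    """GraphViz rendering of a pathway neighborhood."""
    lines = ["digraph pathway {", "  rankdir=LR;"]
    center = report["memory_node"].replace(" ", "->")
    lines.append(f'  "{center}" [shape=box, style=bold];')
    for item in report["incoming"]:
        lines.append(f'  "{item["residue"]}" -> "{center}" '
                     f'[label="{item["flow"]:.3g}"];')
    for item in report["outgoing"]:
        lines.append(f'  "{center}" -> "{item["residue"]}" '
                     f'[label="{item["flow"]:.3g}"];')
    for item in report["downstream"]:
        nd = item["memory_node"].replace(" ", "->")
        lines.append(f'  "{center}" -> "{nd}" [style=dashed];')
    for item in report["upstream"]:
        nd = item["memory_node"].replace(" ", "->")
        lines.append(f'  "{nd}" -> "{center}" [style=dashed];')
    lines.append("}")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
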