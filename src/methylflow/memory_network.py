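"""Second-order (memory) flow network over residue pairs.

Each accepted mediated path A→B→C contributes a transition between two
*state nodes* — ordered residue pairs (A,B) → (B,C) sharing the middle
residue — weighted by the mediated effect R_AB·ρ_bc.  A state node (X,Y)
represents perturbation flow arriving at residue Y from residue X, so a
random walk on the state graph is a second-order walk on the physical
residues: where flow goes next depends on where it came from.

Teleportation makes the walk ergodic.  Rather than uniform jumps, the
teleport distribution over state nodes is proportional to the
soft-thresholded two-point correlation of each node's residue pair, so
restarts favour strongly co-perturbed pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .shift_io import ResidueKey

__all__ = [
    "MemoryNode",
    "MemoryNetwork",
    "FlowDistribution",
    "EmptyNetworkError",
    "ConvergenceError",
    "build_memory_network",
    "stationary_flow",
    "write_state_network",
    "read_state_network",
]

MemoryNode = tuple[ResidueKey, ResidueKey]  # (prev, curr)


class EmptyNetworkError(ValueError):
    """No mediated triples, hence no state network."""


class ConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"power iteration not converged after {max_iter} iterations "
            f"(L1 residual {residual:.3e})"
        )
        self.residual = residual


def _key_str(key: ResidueKey) -> str:
    return f"{key[0]}:{key[1]}"


def _parse_key(text: str) -> ResidueKey:
    rid, lab = str(text).split(":", 1)
    return int(rid), lab


@dataclass
class MemoryNetwork:
    """Directed state-node graph with walk weights and teleport weights."""

    states: list[MemoryNode]
    edges_src: np.ndarray     # int indices into states
    edges_dst: np.ndarray
    edges_weight: np.ndarray  # mediated effects, > 0
    teleport: np.ndarray      # normalized over states, sums to 1

    def __post_init__(self) -> None:
        for prev, curr in self.states:
            if prev == curr:
                raise ValueError(f"state node with prev == curr: {prev}")
        if np.any(self.edges_weight <= 0):
            raise ValueError("edge weights must be positive")
        for s, d in zip(self.edges_src, self.edges_dst):
            if self.states[s][1] != self.states[d][0]:
                raise ValueError(
                    f"edge {self.states[s]} -> {self.states[d]} does not "
                    "share the middle residue"
                )
        tot = self.teleport.sum()
        if not np.isclose(tot, 1.0):
            raise ValueError("teleport weights must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def physical_of(self) -> list[ResidueKey]:
        """Physical residue of each state node (the current residue)."""
        return [curr for _, curr in self.states]

    def state_index(self) -> dict[MemoryNode, int]:
        return {s: i for i, s in enumerate(self.states)}

    def out_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_states, dtype=int)
        np.add.at(deg, self.edges_src, 1)
        return deg

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "from_prev": [_key_str(self.states[i][0]) for i in self.edges_src],
            "from_curr": [_key_str(self.states[i][1]) for i in self.edges_src],
            "to_prev": [_key_str(self.states[i][0]) for i in self.edges_dst],
            "to_curr": [_key_str(self.states[i][1]) for i in self.edges_dst],
            "weight": self.edges_weight,
        })


@dataclass
class FlowDistribution:
    """Stationary visit rates of the teleported second-order walk."""

    visit: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        if abs(self.visit.sum() - 1.0) > 1e-10:
            raise ValueError("visit rates must sum to 1")


def build_memory_network(triples: pd.DataFrame,
                         pair_weights: np.ndarray,
                         residues: list[ResidueKey]) -> MemoryNetwork:
    """Build the state network from mediated triples.

    ``triples`` is the mediation table (columns A, B, C, effect with
    residue keys as "id:label" strings); ``pair_weights`` the symmetric
    soft-thresholded correlation matrix indexed like ``residues``, which
    sets the (unnormalized) teleport weight of each state node's pair.
    """
    if triples is None or len(triples) == 0:
        raise EmptyNetworkError("no mediated triples to build a network from")
    ridx = {k: i for i, k in enumerate(residues)}

    states: list[MemoryNode] = []
    sidx: dict[MemoryNode, int] = {}

    def state_id(prev: ResidueKey, curr: ResidueKey) -> int:
        node = (prev, curr)
        if node not in sidx:
            sidx[node] = len(states)
            states.append(node)
        return sidx[node]

    src, dst, wts = [], [], []
    for a, b, c, eff in zip(triples["A"], triples["B"], triples["C"],
                            triples["effect"]):
        ka, kb, kc = _parse_key(a), _parse_key(b), _parse_key(c)
        src.append(state_id(ka, kb))
        dst.append(state_id(kb, kc))
        wts.append(float(eff))

    teleport = np.zeros(len(states))
    for node, i in sidx.items():
        ia, ib = ridx.get(node[0]), ridx.get(node[1])
        if ia is not None and ib is not None:
            teleport[i] = pair_weights[ia, ib]
    tot = teleport.sum()
    if tot <= 0:
        # no state pair carries positive thresholded correlation; fall back
        # to uniform restarts so the walk stays ergodic
        teleport = np.full(len(states), 1.0 / len(states))
    else:
        teleport = teleport / tot
    return MemoryNetwork(states=states,
                         edges_src=np.asarray(src, dtype=int),
                         edges_dst=np.asarray(dst, dtype=int),
                         edges_weight=np.asarray(wts, dtype=float),
                         teleport=teleport)


def transition_matrix(net: MemoryNetwork) -> np.ndarray:
    """Dense row-normalized walk matrix W (dangling rows all zero)."""
    n = net.n_states
    W = np.zeros((n, n))
    np.add.at(W, (net.edges_src, net.edges_dst), net.edges_weight)
    out = W.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(out > 0, W / out, 0.0)
    return W


def stationary_flow(net: MemoryNetwork, tau: float = 0.15,
                    tol: float = 1e-12, max_iter: int = 10000
                    ) -> FlowDistribution:
    """Stationary visit rates by power iteration.

    p ← (1−τ)(p·W + dangling mass · t) + τ·t, with W the row-normalized
    edge-weight matrix and t the teleport distribution.  Dangling states
    redistribute their mass through t.  Converged when the L1 change
    drops below ``tol``.
    """
    if not 0 < tau < 1:
        raise ValueError("teleportation rate tau must lie in (0, 1)")
    if not np.all(np.isfinite(net.edges_weight)):
        raise ValueError("non-finite edge weights")
    n = net.n_states
    W = transition_matrix(net)
    dangling = W.sum(axis=1) == 0
    t = net.teleport
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        link = p @ W
        dmass = p[dangling].sum()
        p_new = (1.0 - tau) * (link + dmass * t) + tau * t
        p_new /= p_new.sum()
        delta = np.abs(p_new - p).sum()
        p = p_new
        if delta < tol:
            return FlowDistribution(visit=p, tau=tau)
    raise ConvergenceError(delta, max_iter)


# ---------------------------------------------------------------------------
# state-network file (Infomap-style) round-trip

def write_state_network(net: MemoryNetwork, path) -> None:
    """Write *Vertices / *States / *Links sections (bit-exact round-trip)."""
    phys: list[ResidueKey] = []
    pidx: dict[ResidueKey, int] = {}
    for prev, curr in net.states:
        for key in (prev, curr):
            if key not in pidx:
                pidx[key] = len(phys) + 1
                phys.append(key)
    with Path(path).open("w") as fh:
        fh.write(f"*Vertices {len(phys)}\n")
        for i, key in enumerate(phys, start=1):
            fh.write(f'{i} "{_key_str(key)}"\n')
        fh.write(f"*States {net.n_states}\n")
        for i, (prev, curr) in enumerate(net.states, start=1):
            fh.write(f'{i} {pidx[curr]} "{_key_str(prev)} {_key_str(curr)}" '
                     f"{float(net.teleport[i - 1])!r}\n")
        fh.write(f"*Links {len(net.edges_src)}\n")
        for s, d, w in zip(net.edges_src, net.edges_dst, net.edges_weight):
            fh.write(f"{s + 1} {d + 1} {float(w)!r}\n")


_STATE_LINE = re.compile(r'^(\d+)\s+(\d+)\s+"([^"]+)"\s+(\S+)$')


def read_state_network(path) -> MemoryNetwork:
    phys: dict[int, ResidueKey] = {}
    states: list[MemoryNode] = []
    teleport: list[float] = []
    src: list[int] = []
    dst: list[int] = []
    wts: list[float] = []
    section = None
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("*"):
                section = line.split()[0].lower()
                continue
            if section == "*vertices":
                num, name = line.split(" ", 1)
                phys[int(num)] = _parse_key(name.strip('"'))
            elif section == "*states":
                m = _STATE_LINE.match(line)
                if m is None:
                    raise ValueError(f"bad state line: {line!r}")
                prev_s, curr_s = m.group(3).split(" ")
                states.append((_parse_key(prev_s), _parse_key(curr_s)))
                teleport.append(float(m.group(4)))
            elif section == "*links":
                a, b, w = line.split()
                src.append(int(a) - 1)
                dst.append(int(b) - 1)
                wts.append(float(w))
    return MemoryNetwork(states=states,
                         edges_src=np.asarray(src, dtype=int),
                         edges_dst=np.asarray(dst, dtype=int),
                         edges_weight=np.asarray(wts, dtype=float),
                         teleport=np.asarray(teleport, dtype=float))
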