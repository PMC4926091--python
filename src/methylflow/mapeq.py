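"""Two-level map-equation community detection on the memory network.

The map equation scores a partition M of the state nodes by the expected
per-step description length of the random walk under a two-level
Huffman-style coding,

    L(M) = q·H(Q) + Σ_m (q_m + p_m)·H(P_m)   [bits],

where q_m is the probability per step of *exiting* module m, q = Σ q_m,
H(Q) the entropy of the normalized exit rates, and H(P_m) the entropy of
module m's normalized state-visit rates together with its exit rate.
A partition that traps the walk in modules with little cross-flow
compresses the walk and has a short codelength; minimizing L over
partitions therefore finds the flow communities.  With everything in
one module L reduces exactly to the entropy of the visit distribution.

Because state nodes are ordered residue pairs, the detected modules
induce *overlapping* communities of physical residues: a residue whose
incoming flows are split across modules belongs to all of them.

Optimization is a seeded multi-trial greedy search: from singleton
modules, repeatedly sweep the state nodes in random order moving each to
the neighboring module that most decreases L, then attempt whole-module
merges, until no move helps; the best partition across trials is kept.

Two teleportation accountings are supported: ``recorded`` counts
teleport steps as flow when tallying module exits, ``unrecorded``
counts only real link steps (plus forced dangling redistribution).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .memory_network import FlowDistribution, MemoryNetwork
from .shift_io import ResidueKey

__all__ = [
    "Partition",
    "CommunityReport",
    "codelength",
    "optimize",
    "physical_communities",
]


def _plogp(x) -> np.ndarray:
    """x·log2(x) with the 0·log 0 = 0 convention."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log2(x[pos])
    return out


@dataclass
class _FlowTerms:
    """Per-step flow decomposition used by the codelength accounting."""

    p: np.ndarray                 # state visit rates
    link_src: np.ndarray          # real link steps
    link_dst: np.ndarray
    link_flow: np.ndarray
    w_restart: np.ndarray         # factorized restart mass leaving each state
    t: np.ndarray                 # restart target distribution


def _flow_terms(net: MemoryNetwork, flow: FlowDistribution,
                teleport_mode: str = "recorded") -> _FlowTerms:
    if teleport_mode not in ("recorded", "unrecorded"):
        raise ValueError(f"unknown teleport_mode {teleport_mode!r}")
    p = flow.visit
    tau = flow.tau
    n = net.n_states
    out_w = np.zeros(n)
    np.add.at(out_w, net.edges_src, net.edges_weight)
    dangling = out_w == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(dangling, 0.0, 1.0 / np.where(out_w == 0, 1.0, out_w))
    link_flow = (1.0 - tau) * p[net.edges_src] * net.edges_weight \
        * norm[net.edges_src]
    # restart mass: teleportation proper plus dangling redistribution; both
    # land on the teleport target distribution t
    if teleport_mode == "recorded":
        w_restart = p * (tau + (1.0 - tau) * dangling)
    else:
        w_restart = p * (1.0 - tau) * dangling
    return _FlowTerms(p=p, link_src=net.edges_src, link_dst=net.edges_dst,
                      link_flow=link_flow, w_restart=w_restart,
                      t=net.teleport)


def _module_exits(terms: _FlowTerms, module_of: np.ndarray,
                  n_modules: int) -> tuple[np.ndarray, np.ndarray]:
    """Exit flow q_m and internal visit P_m per module."""
    P = np.zeros(n_modules)
    np.add.at(P, module_of, terms.p)
    W = np.zeros(n_modules)
    np.add.at(W, module_of, terms.w_restart)
    T = np.zeros(n_modules)
    np.add.at(T, module_of, terms.t)
    q = W * (1.0 - T)
    cross = module_of[terms.link_src] != module_of[terms.link_dst]
    np.add.at(q, module_of[terms.link_src[cross]], terms.link_flow[cross])
    return q, P


def _codelength_from(q: np.ndarray, P: np.ndarray, p: np.ndarray) -> float:
    total_q = q.sum()
    L = (_plogp(total_q) - 2.0 * _plogp(q).sum() + _plogp(q + P).sum()
         - _plogp(p).sum())
    return float(L)


@dataclass
class Partition:
    """Assignment of state nodes to modules with map-equation bookkeeping."""

    module_of: np.ndarray
    codelength: float
    module_flows: pd.DataFrame   # module, n_states, visit, exit
    teleport_mode: str = "recorded"

    @property
    def n_modules(self) -> int:
        return int(self.module_of.max()) + 1 if self.module_of.size else 0

    def modules(self) -> dict[int, np.ndarray]:
        return {m: np.nonzero(self.module_of == m)[0]
                for m in range(self.n_modules)}


def codelength(net: MemoryNetwork, flow: FlowDistribution,
               module_of, teleport_mode: str = "recorded") -> float:
    """Two-level map-equation description length (bits) of a partition.

    ``module_of`` assigns every state node a module id; a one-module
    partition returns exactly the entropy of the visit distribution.
    """
    module_of = np.asarray(module_of, dtype=int)
    if module_of.shape != (net.n_states,):
        raise ValueError("partition does not cover all state nodes")
    terms = _flow_terms(net, flow, teleport_mode)
    n_modules = int(module_of.max()) + 1
    q, P = _module_exits(terms, module_of, n_modules)
    return _codelength_from(q, P, terms.p)


def _renumber(module_of: np.ndarray) -> np.ndarray:
    """Relabel modules by first appearance (stable, deterministic)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(module_of)
    for i, m in enumerate(module_of):
        if m not in mapping:
            mapping[m] = len(mapping)
        out[i] = mapping[m]
    return out


class _GreedyState:
    """Mutable partition with O(degree) move evaluation."""

    def __init__(self, terms: _FlowTerms):
        self.terms = terms
        n = terms.p.size
        self.n = n
        self.out_links: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        self.in_links: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for s, d, f in zip(terms.link_src, terms.link_dst, terms.link_flow):
            self.out_links[s].append((int(d), float(f)))
            self.in_links[d].append((int(s), float(f)))
        self.out_total = np.zeros(n)
        np.add.at(self.out_total, terms.link_src, terms.link_flow)
        self.reset()

    def reset(self, init: np.ndarray | None = None) -> None:
        n = self.n
        if init is None:
            self.module_of = np.arange(n)
            self.P = self.terms.p.copy()
            self.W = self.terms.w_restart.copy()
            self.T = self.terms.t.copy()
            self.Qlink = self.out_total.copy()
        else:
            self.module_of = np.asarray(init, dtype=int).copy()
            self.P = np.zeros(n)
            np.add.at(self.P, self.module_of, self.terms.p)
            self.W = np.zeros(n)
            np.add.at(self.W, self.module_of, self.terms.w_restart)
            self.T = np.zeros(n)
            np.add.at(self.T, self.module_of, self.terms.t)
            self.Qlink = np.zeros(n)
            cross = self.module_of[self.terms.link_src] \
                != self.module_of[self.terms.link_dst]
            np.add.at(self.Qlink, self.module_of[self.terms.link_src[cross]],
                      self.terms.link_flow[cross])
        self.q = self.Qlink + self.W * (1.0 - self.T)
        self.sumQ = float(self.q.sum())

    def alive_modules(self) -> list[int]:
        return sorted(set(int(m) for m in self.module_of))

    def _neighbor_flows(self, alpha: int) -> dict[int, tuple[float, float]]:
        """module -> (link flow alpha→module, link flow module→alpha)."""
        mod = self.module_of
        flows: dict[int, list[float]] = {}
        for b, f in self.out_links[alpha]:
            rec = flows.setdefault(int(mod[b]), [0.0, 0.0])
            rec[0] += f
        for b, f in self.in_links[alpha]:
            rec = flows.setdefault(int(mod[b]), [0.0, 0.0])
            rec[1] += f
        return {m: (o, i) for m, (o, i) in flows.items()}

    def delta_move(self, alpha: int, m2: int,
                   flows: dict[int, tuple[float, float]] | None = None):
        """ΔL of moving alpha to module m2, plus cached update numbers."""
        m1 = int(self.module_of[alpha])
        if flows is None:
            flows = self._neighbor_flows(alpha)
        o1, i1 = flows.get(m1, (0.0, 0.0))
        o2, i2 = flows.get(m2, (0.0, 0.0))
        p_a = self.terms.p[alpha]
        w_a = self.terms.w_restart[alpha]
        t_a = self.terms.t[alpha]

        Q1n = self.Qlink[m1] - (self.out_total[alpha] - o1) + i1
        Q2n = self.Qlink[m2] + (self.out_total[alpha] - o2) - i2
        P1n, P2n = self.P[m1] - p_a, self.P[m2] + p_a
        W1n, W2n = self.W[m1] - w_a, self.W[m2] + w_a
        T1n, T2n = self.T[m1] - t_a, self.T[m2] + t_a
        q1n = Q1n + W1n * (1.0 - T1n)
        q2n = Q2n + W2n * (1.0 - T2n)
        q1, q2 = self.q[m1], self.q[m2]
        sumQn = self.sumQ - q1 - q2 + q1n + q2n

        def f(x: float) -> float:
            return x * np.log2(x) if x > 1e-300 else 0.0

        dL = (f(sumQn) - f(self.sumQ)
              - 2.0 * (f(q1n) + f(q2n) - f(q1) - f(q2))
              + f(q1n + P1n) + f(q2n + P2n)
              - f(q1 + self.P[m1]) - f(q2 + self.P[m2]))
        return dL, (m1, Q1n, Q2n, P1n, P2n, W1n, W2n, T1n, T2n, q1n, q2n,
                    sumQn)

    def apply_move(self, alpha: int, m2: int, cache) -> None:
        (m1, Q1n, Q2n, P1n, P2n, W1n, W2n, T1n, T2n, q1n, q2n, sumQn) = cache
        self.module_of[alpha] = m2
        self.Qlink[m1], self.Qlink[m2] = Q1n, Q2n
        self.P[m1], self.P[m2] = P1n, P2n
        self.W[m1], self.W[m2] = W1n, W2n
        self.T[m1], self.T[m2] = T1n, T2n
        self.q[m1], self.q[m2] = q1n, q2n
        self.sumQ = sumQn

    def codelength(self) -> float:
        return _codelength_from(self.q, self.P, self.terms.p)

    # -- sweeps ------------------------------------------------------------
    #: below this many modules every module is a move/merge candidate, not
    #: just link neighbors — teleport-coupled groupings become reachable
    FULL_SCAN_MODULES = 64

    def node_sweep(self, order: np.ndarray) -> int:
        moves = 0
        all_mods: list[int] | None = None
        for alpha in order:
            alpha = int(alpha)
            m1 = int(self.module_of[alpha])
            flows = self._neighbor_flows(alpha)
            if all_mods is None:
                alive = self.alive_modules()
                all_mods = alive if len(alive) <= self.FULL_SCAN_MODULES \
                    else []
            cands = all_mods if all_mods else sorted(flows)
            best_dL, best_m, best_cache = -1e-12, None, None
            for m2 in cands:
                if m2 == m1:
                    continue
                dL, cache = self.delta_move(alpha, m2, flows)
                if dL < best_dL:
                    best_dL, best_m, best_cache = dL, m2, cache
            if best_m is not None:
                self.apply_move(alpha, best_m, best_cache)
                moves += 1
                all_mods = None  # module set may have changed
        return moves

    def merge_sweep(self) -> int:
        """Greedily merge whole modules connected by link flow.

        Cross-module link flows are tallied once and maintained
        incrementally, so each merge is O(#neighbor modules).
        """
        mod = self.module_of
        cross: dict[int, dict[int, float]] = {}
        for s, d, fl in zip(self.terms.link_src, self.terms.link_dst,
                            self.terms.link_flow):
            ms, md = int(mod[s]), int(mod[d])
            if ms != md:
                cross.setdefault(ms, {})[md] = \
                    cross.setdefault(ms, {}).get(md, 0.0) + fl

        def delta_merge(m1: int, m2: int) -> tuple[float, float, float]:
            c12 = cross.get(m1, {}).get(m2, 0.0)
            c21 = cross.get(m2, {}).get(m1, 0.0)
            Qn = self.Qlink[m1] + self.Qlink[m2] - c12 - c21
            Wn = self.W[m1] + self.W[m2]
            Tn = self.T[m1] + self.T[m2]
            qn = Qn + Wn * (1.0 - Tn)
            q1, q2 = self.q[m1], self.q[m2]
            sumQn = self.sumQ - q1 - q2 + qn

            def f(x: float) -> float:
                return x * np.log2(x) if x > 1e-300 else 0.0

            dL = (f(sumQn) - f(self.sumQ)
                  - 2.0 * (f(qn) - f(q1) - f(q2))
                  + f(qn + self.P[m1] + self.P[m2])
                  - f(q1 + self.P[m1]) - f(q2 + self.P[m2]))
            return dL, Qn, qn

        def apply_merge(m1: int, m2: int, Qn: float, qn: float) -> None:
            members = np.nonzero(self.module_of == m1)[0]
            self.module_of[members] = m2
            self.sumQ += qn - self.q[m1] - self.q[m2]
            self.Qlink[m2], self.Qlink[m1] = Qn, 0.0
            self.P[m2] += self.P[m1]
            self.W[m2] += self.W[m1]
            self.T[m2] += self.T[m1]
            self.P[m1] = self.W[m1] = self.T[m1] = 0.0
            self.q[m2], self.q[m1] = qn, 0.0
            # fold m1's cross rows/columns into m2
            row1 = cross.pop(m1, {})
            for x, fl in row1.items():
                if x != m2:
                    r2 = cross.setdefault(m2, {})
                    r2[x] = r2.get(x, 0.0) + fl
            for x, row in cross.items():
                if m1 in row:
                    fl = row.pop(m1)
                    if x != m2:
                        row[m2] = row.get(m2, 0.0) + fl
            cross.get(m2, {}).pop(m2, None)

        merges = 0
        while True:
            alive_list = self.alive_modules()
            if len(alive_list) <= self.FULL_SCAN_MODULES:
                pairs = {(a, b) for i, a in enumerate(alive_list)
                         for b in alive_list[i + 1:]}
            else:
                pairs = set()
                for m1, row in cross.items():
                    for m2 in row:
                        pairs.add((min(m1, m2), max(m1, m2)))
            merged_this_pass = 0
            alive = set(alive_list)
            for m1, m2 in sorted(pairs):
                if m1 not in alive or m2 not in alive:
                    continue
                dL, Qn, qn = delta_merge(m1, m2)
                if dL < -1e-12:
                    apply_merge(m1, m2, Qn, qn)
                    alive.discard(m1)
                    merged_this_pass += 1
            if merged_this_pass == 0:
                return merges
            merges += merged_this_pass


def optimize(net: MemoryNetwork, flow: FlowDistribution,
             n_trials: int = 1000, seed: int | None = None,
             teleport_mode: str = "recorded") -> Partition:
    """Minimize the two-level codelength by seeded multi-trial greedy search.

    Each trial starts from singleton modules and alternates random-order
    node sweeps with whole-module merge sweeps until no move decreases
    the codelength; the minimum-codelength partition over all trials is
    returned.  Deterministic given ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    terms = _flow_terms(net, flow, teleport_mode)
    gs = _GreedyState(terms)
    best_L = np.inf
    best_mod: np.ndarray | None = None
    for trial in range(n_trials):
        if trial % 2 == 0:
            gs.reset()  # singleton start
        else:
            k = int(rng.integers(1, max(2, min(gs.n, 16))))
            gs.reset(rng.integers(0, k, size=gs.n))
        for _sweep in range(200):
            moves = gs.node_sweep(rng.permutation(gs.n))
            merges = gs.merge_sweep()
            if moves == 0 and merges == 0:
                break
        L = gs.codelength()
        if L < best_L - 1e-12:
            best_L = L
            best_mod = gs.module_of.copy()
    module_of = _renumber(best_mod)
    # recompute from scratch (guards against incremental drift)
    L = codelength(net, flow, module_of, teleport_mode)
    n_modules = int(module_of.max()) + 1
    q, P = _module_exits(terms, module_of, n_modules)
    counts = np.bincount(module_of, minlength=n_modules)
    mf = pd.DataFrame({"module": np.arange(n_modules), "n_states": counts,
                       "visit": P, "exit": q})
    return Partition(module_of=module_of, codelength=L, module_flows=mf,
                     teleport_mode=teleport_mode)


# ---------------------------------------------------------------------------
# physical communities

def _key_str(key: ResidueKey) -> str:
    return f"{key[0]}:{key[1]}"


@dataclass
class CommunityReport:
    """Overlapping physical-residue communities with flow bookkeeping."""

    communities: pd.DataFrame        # module, residues, n_residues, internal_flow
    small_communities: pd.DataFrame  # same columns, size <= min_size
    inter_module_flow: pd.DataFrame  # square, indexed by module id
    membership: dict[str, list[int]] # residue -> modules (overlap)
    core_assignment: dict[str, int]  # residue -> highest-flow module
    codelength: float
    min_size: int

    def to_json(self, path=None) -> str:
        payload = {
            "codelength_bits": self.codelength,
            "min_size": self.min_size,
            "communities": self.communities.to_dict(orient="records"),
            "small_communities":
                self.small_communities.to_dict(orient="records"),
            "inter_module_flow": self.inter_module_flow.to_dict(),
            "membership": self.membership,
            "core_assignment": self.core_assignment,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def write_intermodule_csv(self, path) -> None:
        self.inter_module_flow.to_csv(path)

    def write_tree(self, net: MemoryNetwork, partition: Partition,
                   flow: FlowDistribution, path) -> None:
        """module:rank flow "prev curr" physical — one line per state node."""
        order = np.argsort(-flow.visit, kind="mergesort")
        lines = []
        pos: dict[int, int] = {}
        for i in order:
            m = int(partition.module_of[i])
            pos[m] = pos.get(m, 0) + 1
            prev, curr = net.states[i]
            lines.append(f'{m + 1}:{pos[m]} {float(flow.visit[i])!r} '
                         f'"{_key_str(prev)} {_key_str(curr)}" '
                         f'{_key_str(curr)}')
        Path(path).write_text("\n".join(lines) + "\n")

    def write_pdb_bfactor(self, template_pdb, path) -> None:
        """Copy a PDB, setting each residue's B-factor to its core module id.

        Residues without a community get B-factor -1.  Matching is by
        residue sequence number only (methyl labels collapse).
        """
        core_by_resid: dict[int, int] = {}
        for key, mod in self.core_assignment.items():
            rid = int(key.split(":", 1)[0])
            core_by_resid.setdefault(rid, mod)
        out_lines = []
        for line in Path(template_pdb).read_text().splitlines():
            if line.startswith(("ATOM", "HETATM")) and len(line) >= 66:
                try:
                    rid = int(line[22:26])
                except ValueError:
                    rid = None
                b = core_by_resid.get(rid, -1)
                line = f"{line[:60]}{b:6.2f}{line[66:]}"
            out_lines.append(line)
        Path(path).write_text("\n".join(out_lines) + "\n")


def physical_communities(partition: Partition, net: MemoryNetwork,
                         flow: FlowDistribution, min_size: int = 5
                         ) -> CommunityReport:
    """Project state-node modules onto overlapping residue communities.

    A module's physical members are the current residues of its state
    nodes, so a residue whose incoming flows fall in several modules
    belongs to all of them.  Communities with more than ``min_size``
    residues form the main report; smaller ones are listed separately.
    Inter-module flow sums the link flow crossing each module pair and
    internal flow sums the visit rates within a module.
    """
    terms = _flow_terms(net, flow, partition.teleport_mode)
    n_modules = partition.n_modules
    mod = partition.module_of

    members: dict[int, set[str]] = {m: set() for m in range(n_modules)}
    membership: dict[str, list[int]] = {}
    core_flow: dict[str, np.ndarray] = {}
    for i, (_, curr) in enumerate(net.states):
        key = _key_str(curr)
        m = int(mod[i])
        members[m].add(key)
        if key not in core_flow:
            core_flow[key] = np.zeros(n_modules)
        core_flow[key][m] += flow.visit[i]
    for key, per_mod in core_flow.items():
        membership[key] = sorted(np.nonzero(per_mod > 0)[0].tolist())
    core_assignment = {key: int(np.argmax(per_mod))
                       for key, per_mod in core_flow.items()}

    internal = np.zeros(n_modules)
    np.add.at(internal, mod, flow.visit)
    F = np.zeros((n_modules, n_modules))
    np.add.at(F, (mod[terms.link_src], mod[terms.link_dst]), terms.link_flow)
    np.fill_diagonal(F, 0.0)

    rows = []
    for m in range(n_modules):
        rows.append({"module": m, "residues": sorted(members[m]),
                     "n_residues": len(members[m]),
                     "internal_flow": float(internal[m])})
    df = pd.DataFrame(rows).sort_values(
        ["internal_flow", "module"], ascending=[False, True],
        ignore_index=True)
    big = df[df["n_residues"] > min_size].reset_index(drop=True)
    small = df[df["n_residues"] <= min_size].reset_index(drop=True)
    flow_df = pd.DataFrame(F, index=range(n_modules), columns=range(n_modules))
    return CommunityReport(communities=big, small_communities=small,
                           inter_module_flow=flow_df, membership=membership,
                           core_assignment=core_assignment,
                           codelength=partition.codelength, min_size=min_size)
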