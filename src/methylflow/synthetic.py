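"""Synthetic CSP matrices with planted network structure.

The generator emulates the study conditions of a methyl-mutagenesis CSP
experiment — by default 78 methyl-bearing residues probed by 20 point
mutants — on a planted weighted interaction graph.  A mutation at site i
injects a unit perturbation that spreads by linear diffusion, so the
noise-free response of residue j is the (j, i) entry of the resolvent
kernel (I − αW)⁻¹ (every walk from i to j, geometrically damped by the
decay α).  Responses are scaled to a realistic Hz range, multiplied by
lognormal measurement noise, and thinned by a missingness mask
(overlapped/unassigned peaks plus the mutant's own residue).

The planted truth (community labels, bridge residues, pathway chains)
lets every pipeline stage be scored against ground truth without any
experimental data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .mapeq import CommunityReport
from .shift_io import CSPMatrix, ResidueKey

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "recovery_score",
    "subsample_mutants",
]

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Study-condition defaults: 78 methyls, 20 mutants, two lobes + bridge."""

    n_residues: int = 78
    n_mutants: int = 20
    module_sizes: tuple[int, ...] | None = None  # default: two equal lobes
    n_bridge: int = 6
    lobe_topology: str = "ring"   # "ring" | "clique" | "star"
    bridge_style: str = "chain"   # "chain" | "hubs"
    cross_weight: float = 0.5     # bridge-to-far-hub weight ("hubs" style)
    within_density: float = 0.15
    decay: float = 0.8            # α, relative to unit spectral radius
    noise_sigma: float = 0.3      # lognormal σ of multiplicative noise
    noise_floor_hz: float = 1.5   # additive measurement floor (~1 Hz peaks)
    missing_fraction: float = 0.05
    hz_scale: float = 60.0        # scales the strongest response, in Hz
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 3 or self.n_mutants < 3 or self.n_bridge < 0:
            raise ValueError("counts must be >= 3 (bridge >= 0)")
        if not 0 < self.decay < 1:
            raise ValueError("decay must lie in (0, 1) for convergence")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.lobe_topology not in ("ring", "clique", "star"):
            raise ValueError(f"unknown lobe_topology {self.lobe_topology!r}")
        if self.bridge_style not in ("chain", "hubs"):
            raise ValueError(f"unknown bridge_style {self.bridge_style!r}")

    def sizes(self) -> tuple[int, ...]:
        if self.module_sizes is not None:
            return tuple(self.module_sizes)
        core = self.n_residues - self.n_bridge
        return (core // 2, core - core // 2)


@dataclass
class GroundTruth:
    labels: dict[str, int]             # residue key -> planted module
    bridge: list[str]                  # bridge residue keys
    chains: list[list[str]]            # planted pathway chains
    mutation_sites: list[int]
    W: np.ndarray
    config: SyntheticConfig


def _key(i: int) -> ResidueKey:
    return (i + 1, "d1")


def _key_str(i: int) -> str:
    return f"{i + 1}:d1"


def _planted_graph(config: SyntheticConfig, rng: np.random.Generator
                   ) -> tuple[np.ndarray, dict[str, int], list[str],
                              list[list[str]]]:
    n = config.n_residues
    sizes = config.sizes()
    if sum(sizes) + config.n_bridge != n:
        raise ValueError("module sizes + bridge must equal n_residues")
    W = np.zeros((n, n))
    labels: dict[str, int] = {}
    blocks: list[np.ndarray] = []
    start = 0
    for m, size in enumerate(sizes):
        idx = np.arange(start, start + size)
        blocks.append(idx)
        for i in idx:
            labels[_key_str(i)] = m
        if config.lobe_topology == "clique":
            for a in range(size):
                for b in range(a + 1, size):
                    w = rng.uniform(0.8, 1.0)
                    W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
        elif config.lobe_topology == "star":
            hub = idx[0]
            for i in idx[1:]:
                W[hub, i] = W[i, hub] = rng.uniform(0.6, 1.0)
            n_extra = int(config.within_density * size * (size - 1) / 2)
            for _ in range(n_extra):
                i, j = rng.choice(idx, size=2, replace=False)
                w = rng.uniform(0.3, 0.6)
                W[i, j] = W[j, i] = max(W[i, j], w)
        else:
            # connected ring + random extra edges keeps modules cohesive
            for k in range(size):
                i, j = idx[k], idx[(k + 1) % size]
                W[i, j] = W[j, i] = rng.uniform(0.6, 1.0)
            n_extra = int(config.within_density * size * (size - 1) / 2)
            for _ in range(n_extra):
                i, j = rng.choice(idx, size=2, replace=False)
                w = rng.uniform(0.6, 1.0)
                W[i, j] = W[j, i] = max(W[i, j], w)
        start += size

    bridge_idx = np.arange(start, start + config.n_bridge)
    bridge = [_key_str(i) for i in bridge_idx]
    chains: list[list[str]] = []
    if config.n_bridge:
        anchor0 = blocks[0][0]
        anchor1 = blocks[-1][0]
        if config.bridge_style == "hubs":
            # each bridge residue couples strongly to its home lobe's hub
            # and weakly to the far hub: a genuine two-community membrane
            hubs = (anchor0, anchor1)
            for k, i in enumerate(bridge_idx):
                home = k % 2 if len(sizes) > 1 else 0
                labels[_key_str(i)] = home
                W[i, hubs[home]] = W[hubs[home], i] = 1.0
                W[i, hubs[1 - home]] = W[hubs[1 - home], i] = \
                    config.cross_weight
                chains.append([_key_str(hubs[home]), _key_str(i),
                               _key_str(hubs[1 - home])])
        else:
            half = config.n_bridge // 2
            for k, i in enumerate(bridge_idx):
                labels[_key_str(i)] = 0 if k < half \
                    else 1 if len(sizes) > 1 else 0
            # a chain of strong edges: lobe-0 anchor -> bridge -> lobe-1
            chain_nodes = [anchor0, *bridge_idx, anchor1]
            for a, b in zip(chain_nodes[:-1], chain_nodes[1:]):
                W[a, b] = W[b, a] = 1.0
            chains.append([_key_str(i) for i in chain_nodes])
    # scale to unit spectral radius so `decay` alone controls convergence
    radius = float(np.max(np.abs(np.linalg.eigvals(W))))
    if radius > 0:
        W = W / radius
    return W, labels, bridge, chains


def _pick_sites(n: int, n_mutants: int, rng: np.random.Generator
                ) -> list[int]:
    """Mutation sites spread evenly over the residue set, then jittered."""
    if n_mutants == n:
        return list(range(n))
    anchors = np.linspace(0, n - 1, n_mutants)
    sites: list[int] = []
    for a in anchors:
        s = int(round(a + rng.integers(-1, 2)))
        s = min(max(s, 0), n - 1)
        while s in sites:
            s = (s + 1) % n
        sites.append(s)
    return sites


def _csp_from_graph(W: np.ndarray, config: SyntheticConfig,
                    rng: np.random.Generator, sites: list[int]) -> CSPMatrix:
    """Diffuse unit perturbations from each site, add noise, apply mask."""
    n = W.shape[0]
    K = np.linalg.inv(np.eye(n) - config.decay * W)
    values = np.empty((n, len(sites)))
    for j, site in enumerate(sites):
        response = K[:, site] / K[:, site].max()
        noise = np.exp(rng.normal(0.0, config.noise_sigma, size=n))
        floor = rng.normal(0.0, config.noise_floor_hz, size=n)
        values[:, j] = np.abs(config.hz_scale * response * noise + floor)
    # masking: own-site cell plus random missing peaks
    for j, site in enumerate(sites):
        values[site, j] = np.nan
    if config.missing_fraction > 0:
        miss = rng.random(values.shape) < config.missing_fraction
        values[miss] = np.nan
    residues = [_key(i) for i in range(n)]
    mutants = [f"X{site + 1}Y" for site in sites]
    return CSPMatrix(residues=residues, mutants=mutants, values=values)


def generate(config: SyntheticConfig | None = None
             ) -> tuple[CSPMatrix, GroundTruth]:
    """Generate a CSP matrix and its planted ground truth (seeded)."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    W, labels, bridge, chains = _planted_graph(config, rng)
    sites = _pick_sites(config.n_residues, config.n_mutants, rng)
    csp = _csp_from_graph(W, config, rng, sites)
    truth = GroundTruth(labels=labels, bridge=bridge, chains=chains,
                        mutation_sites=[s + 1 for s in sites], W=W,
                        config=config)
    return csp, truth


def two_lobe_scenario(seed: int = 0, lobe_size: int = 10, n_bridge: int = 2,
                      noise_sigma: float = 0.05, noise_floor_hz: float = 0.1,
                      missing_fraction: float = 0.0
                      ) -> tuple[CSPMatrix, GroundTruth]:
    """Well-separated two-lobe + bridge validation scenario.

    Two densely coupled (clique) lobes joined only through bridge
    residues that sit between the lobe hubs; every residue is mutated
    and the noise is low.  Designed so the planted two-community
    structure is recoverable and the bridge residues straddle both
    communities.  A more permissive significance cutoff (p < 0.1) is
    appropriate here: the mutant panel is small and the partial
    correlations of an equicorrelated lobe plateau near r/(1+r).
    """
    n = 2 * lobe_size + n_bridge
    cfg = SyntheticConfig(n_residues=n, n_mutants=n,
                          module_sizes=(lobe_size, lobe_size),
                          n_bridge=n_bridge, lobe_topology="clique",
                          bridge_style="hubs", cross_weight=0.5, decay=0.7,
                          noise_sigma=noise_sigma,
                          noise_floor_hz=noise_floor_hz,
                          missing_fraction=missing_fraction, seed=seed)
    return generate(cfg)


def chain_scenario(seed: int = 0, chain_length: int = 10,
                   n_background: int = 8, noise_sigma: float = 0.05,
                   noise_floor_hz: float = 0.1
                   ) -> tuple[CSPMatrix, GroundTruth]:
    """Single dominant planted pathway plus uncoupled background residues.

    A strong linear chain (think docking site -> active site) embedded
    among residues that feel only measurement noise: all genuine
    information flow runs along the chain, so its memory nodes should
    monopolize the top of the flow ranking.
    """
    n = chain_length + n_background
    cfg = SyntheticConfig(n_residues=n, n_mutants=n,
                          module_sizes=(chain_length, n_background),
                          n_bridge=0, decay=0.7, noise_sigma=noise_sigma,
                          noise_floor_hz=noise_floor_hz,
                          missing_fraction=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    W = np.zeros((n, n))
    for i in range(chain_length - 1):
        W[i, i + 1] = W[i + 1, i] = 1.0
    radius = float(np.max(np.abs(np.linalg.eigvals(W))))
    W /= radius
    sites = list(range(n))
    csp = _csp_from_graph(W, cfg, rng, sites)
    labels = {_key_str(i): (0 if i < chain_length else 1) for i in range(n)}
    chain = [_key_str(i) for i in range(chain_length)]
    truth = GroundTruth(labels=labels, bridge=[], chains=[chain],
                        mutation_sites=[s + 1 for s in sites], W=W,
                        config=cfg)
    return csp, truth


def recovery_score(report: CommunityReport, truth: GroundTruth) -> float:
    """Adjusted Rand agreement between recovered cores and planted labels.

    Each residue is reduced to its highest-flow (core) module; scoring is
    over residues present in both the report and the truth.  1 means the
    planted partition is recovered exactly (up to label permutation);
    chance-level agreement scores about 0.
    """
    keys = sorted(set(report.core_assignment) & set(truth.labels))
    if not keys:
        return 0.0
    found = [report.core_assignment[k] for k in keys]
    planted = [truth.labels[k] for k in keys]
    return float(adjusted_rand_score(planted, found))


def _core_agreement(a: dict[str, int], b: dict[str, int]) -> float:
    keys = sorted(set(a) & set(b))
    if not keys:
        return 0.0
    return float(adjusted_rand_score([a[k] for k in keys],
                                     [b[k] for k in keys]))


def subsample_mutants(csp: CSPMatrix, ks, n_rep: int = 5,
                      seed: int | None = None, n_trials: int = 20,
                      **pipeline_kw) -> pd.DataFrame:
    """Mutant-subsampling robustness curve.

    For each panel size k, repeatedly keep k random mutant columns, rerun
    the full pipeline, and score the community core assignment against
    the full-data result (adjusted Rand).  Returns a DataFrame with one
    row per k: mean, sd, n_ok, and the replicate scores.  Replicates
    where the reduced panel yields no network are recorded as failures
    and excluded with a warning.

    The pair/triple overlap floor is reduced alongside k (an analyst
    with 8 mutants cannot demand 10 joint observations); everything else
    is held fixed so the curve isolates the effect of panel size.
    """
    from .model import CSPNetworkModel  # local import: avoid cycle

    rng = np.random.default_rng(seed)
    # one shared fit seed: identical data must give identical partitions,
    # so k = n_mutants scores exactly 1
    fit_seed = int(rng.integers(2**31))
    base_overlap = pipeline_kw.pop("min_overlap", 10)
    full = CSPNetworkModel(csp, min_overlap=base_overlap, **pipeline_kw).fit(
        n_trials=n_trials, seed=fit_seed)
    full_core = full.community_report.core_assignment

    rows = []
    for k in ks:
        if not 3 <= k <= len(csp.mutants):
            raise ValueError(f"k={k} outside [3, n_mutants]")
        overlap_k = max(4, min(base_overlap, k - 2))
        scores = []
        failures = 0
        for _ in range(n_rep):
            cols = rng.choice(len(csp.mutants), size=k, replace=False)
            sub = csp.subset_mutants([csp.mutants[c] for c in sorted(cols)])
            try:
                res = CSPNetworkModel(sub, min_overlap=overlap_k,
                                      **pipeline_kw).fit(
                    n_trials=n_trials, seed=fit_seed)
            except Exception as exc:  # degenerate subsample
                failures += 1
                logger.warning("subsample k=%d failed: %s", k, exc)
                continue
            scores.append(_core_agreement(
                full_core, res.community_report.core_assignment))
        rows.append({"k": k, "mean": float(np.mean(scores)) if scores else np.nan,
                     "sd": float(np.std(scores)) if scores else np.nan,
                     "n_ok": len(scores), "n_failed": failures,
                     "scores": scores})
    return pd.DataFrame(rows)
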