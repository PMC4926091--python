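"""Model/Results facade over the full CSP network pipeline.

``CSPNetworkModel`` is built from a residue × mutant CSP matrix (or
directly from shift tables) together with the statistical settings for
one protein state; ``fit()`` runs rank transform → pairwise correlation
→ mediation → memory network → map-equation communities → rankings and
returns a ``CSPNetworkResults`` carrying every intermediate, the
community report, and a text ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import flow_ranking, mapeq, mediation, memory_network, rank_stats
from . import shift_io
from .mediation import STATE_P_CUTOFFS, MediationConfig, MediationResult
from .memory_network import EmptyNetworkError, FlowDistribution, MemoryNetwork
from .rank_stats import CorrelationSet, RankMatrix, SoftThresholdConfig
from .shift_io import CSPMatrix

__all__ = ["CSPNetworkModel", "CSPNetworkResults"]


class CSPNetworkModel:
    """Information-flow network model of a methyl-mutagenesis CSP panel.

    Parameters
    ----------
    csp : CSPMatrix
        Residue × mutant combined shift perturbations in Hz.
    state : str, optional
        Protein-state label; known states ("apo-inactive", "ATP",
        "BIRB796", "active") set the significance cutoff.
    p_cutoff : float, optional
        Explicit significance cutoff; overrides ``state``.
    beta : float
        Soft-thresholding power for teleport weights (default 8).
    tau : float
        Teleportation rate of the second-order walk (default 0.15).
    min_overlap : int
        Minimum jointly-observed mutants for any pair/triple statistic.
    teleport_mode : {"recorded", "unrecorded"}
        Whether teleport steps count as flow in the map equation.
    min_community_size : int
        Communities must exceed this many residues for the main report.
    """

    def __init__(self, csp: CSPMatrix, state: str = "apo-inactive",
                 p_cutoff: float | None = None, beta: float = 8.0,
                 tau: float = 0.15, min_overlap: int = 10,
                 require_positive: bool = True,
                 teleport_mode: str = "recorded",
                 min_community_size: int = 5):
        self.csp = csp
        self.state = state
        if p_cutoff is None:
            p_cutoff = STATE_P_CUTOFFS.get(state, 0.02)
        self.config = MediationConfig(p_cutoff=p_cutoff,
                                      require_positive=require_positive,
                                      min_overlap=min_overlap)
        self.beta = float(beta)
        self.tau = float(tau)
        self.teleport_mode = teleport_mode
        self.min_community_size = min_community_size

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_shift_tables(cls, wildtype_path, mutant_paths: Mapping[str, str],
                          dialect: str = "csv", field_mhz: float = 750.0,
                          restrict_to_common: bool = True, **kw
                          ) -> "CSPNetworkModel":
        wt = shift_io.read_shift_table(wildtype_path, dialect)
        muts = {label: shift_io.read_shift_table(p, dialect)
                for label, p in mutant_paths.items()}
        csp = shift_io.build_csp_matrix(wt, muts, field_mhz=field_mhz,
                                        restrict_to_common=restrict_to_common)
        return cls(csp, **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, field_mhz: float = 750.0,
                       **kw) -> "CSPNetworkModel":
        """Build from a DataFrame indexed by "resid:methyl", mutant columns."""
        residues = []
        for key in df.index:
            rid, lab = str(key).split(":", 1)
            residues.append((int(rid), lab))
        csp = CSPMatrix(residues=residues,
                        mutants=[str(c) for c in df.columns],
                        values=df.to_numpy(dtype=float), field_mhz=field_mhz)
        return cls(csp, **kw)

    # -- fitting -----------------------------------------------------------
    def fit(self, n_trials: int = 100, seed: int | None = None
            ) -> "CSPNetworkResults":
        """Run the full pipeline; deterministic given data and seed."""
        ranks = rank_stats.rank_perturbations(self.csp,
                                              self.config.min_overlap)
        corr = rank_stats.correlate(ranks, self.config.min_overlap)
        weights = rank_stats.apply_soft_threshold(corr, self.beta)
        med = mediation.enumerate_mediations(ranks, corr, self.config)
        net = memory_network.build_memory_network(med.triples, weights,
                                                  corr.residues)
        flow = memory_network.stationary_flow(net, tau=self.tau)
        partition = mapeq.optimize(net, flow, n_trials=n_trials, seed=seed,
                                   teleport_mode=self.teleport_mode)
        report = mapeq.physical_communities(partition, net, flow,
                                            self.min_community_size)
        node_ranks = flow_ranking.rank_memory_nodes(net, flow)
        conn_ranks = flow_ranking.rank_connectivity(corr, med)
        return CSPNetworkResults(
            model=self, ranks=ranks, corr=corr, pair_weights=weights,
            mediation=med, network=net, flow=flow, partition=partition,
            community_report=report, memory_node_ranks=node_ranks,
            connectivity_ranks=conn_ranks, n_trials=n_trials, seed=seed,
        )


@dataclass
class CSPNetworkResults:
    """Everything the fitted network pipeline produced."""

    model: CSPNetworkModel
    ranks: RankMatrix
    corr: CorrelationSet
    pair_weights: np.ndarray
    mediation: MediationResult
    network: MemoryNetwork
    flow: FlowDistribution
    partition: mapeq.Partition
    community_report: mapeq.CommunityReport
    memory_node_ranks: list
    connectivity_ranks: pd.DataFrame
    n_trials: int
    seed: int | None

    # -- headline numbers ---------------------------------------------------
    @property
    def n_pairs(self) -> int:
        """Significant positive pairwise correlations."""
        return self.mediation.n_pairs

    @property
    def n_triples(self) -> int:
        """Accepted 3-residue mediated paths."""
        return self.mediation.n_triples

    @property
    def n_communities(self) -> int:
        """Communities larger than the size filter."""
        return len(self.community_report.communities)

    @property
    def codelength(self) -> float:
        return self.partition.codelength

    def summary(self) -> str:
        m = self.model
        rep = self.community_report
        top = flow_ranking.top_memory_nodes(self.memory_node_ranks, 0.05)
        lines = [
            "CSP information-flow network",
            "=" * 60,
            f"state:                 {m.state} (p < {m.config.p_cutoff})",
            f"residues x mutants:    {self.csp_shape[0]} x {self.csp_shape[1]}",
            f"soft threshold beta:   {m.beta}",
            f"teleportation tau:     {m.tau} ({m.teleport_mode})",
            f"significant pairs:     {self.n_pairs}",
            f"mediated 3-res paths:  {self.n_triples}",
            f"memory nodes:          {self.network.n_states}",
            f"map codelength:        {self.codelength:.4f} bits "
            f"({self.partition.n_modules} modules, {self.n_trials} trials)",
            f"communities > {m.min_community_size} res:  "
            f"{self.n_communities}",
            "",
            "top memory nodes (visit rate):",
        ]
        for r in top[:5]:
            lines.append(f"  {r.rank:3d}. {r.label:<18s} {r.visit:.4f}")
        lines.append("")
        lines.append("top residues (connectivity):")
        for _, row in self.connectivity_ranks.head(5).iterrows():
            lines.append(f"  {int(row['rank']):3d}. {row['residue']:<10s} "
                         f"degree={int(row['degree'])} "
                         f"triples={int(row['n_triples'])}")
        return "\n".join(lines)

    @property
    def csp_shape(self) -> tuple[int, int]:
        return self.model.csp.shape

    # -- persistence ---------------------------------------------------------
    def provenance(self) -> dict:
        m = self.model
        return {
            "package_version": _pkg_version,
            "state": m.state,
            "p_cutoff": m.config.p_cutoff,
            "beta": m.beta,
            "tau": m.tau,
            "min_overlap": m.config.min_overlap,
            "require_positive": m.config.require_positive,
            "teleport_mode": m.teleport_mode,
            "min_community_size": m.min_community_size,
            "n_trials": self.n_trials,
            "seed": self.seed,
            "n_residues": self.csp_shape[0],
            "n_mutants": self.csp_shape[1],
        }

    def save(self, outdir) -> None:
        """Write all intermediates and reports to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.model.csp.to_csv(outdir / "csp_matrix.csv")
        self.corr.to_frame(self.pair_weights).to_csv(
            outdir / "correlations.csv", index=False)
        self.mediation.triples.to_csv(outdir / "triples.csv", index=False)
        self.mediation.pairs.to_csv(outdir / "significant_pairs.csv",
                                    index=False)
        memory_network.write_state_network(self.network,
                                           outdir / "state_network.net")
        self.network.edges_frame().to_csv(outdir / "state_edges.csv",
                                          index=False)
        self.community_report.to_json(outdir / "communities.json")
        self.community_report.write_intermodule_csv(
            outdir / "intermodule_flow.csv")
        self.community_report.write_tree(self.network, self.partition,
                                         self.flow, outdir / "communities.tree")
        ranks_df = pd.DataFrame(
            [{"rank": r.rank, "memory_node": r.label, "visit": r.visit}
             for r in self.memory_node_ranks])
        ranks_df.to_csv(outdir / "memory_node_ranks.csv", index=False)
        self.connectivity_ranks.to_csv(outdir / "connectivity_ranks.csv",
                                       index=False)
        (outdir / "provenance.json").write_text(
            json.dumps(self.provenance(), indent=2, sort_keys=True))
        (outdir / "summary.txt").write_text(self.summary() + "\n")
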