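"""Rank transforms, two-point rank correlations, and soft-thresholding.

Perturbation magnitudes are rank-transformed per residue across the
mutant panel: ranks capture monotone co-response while damping
measurement error and the very large shifts next to each mutation site.
Spearman correlations between residue rank profiles (Pearson on ranks
over jointly-observed mutants) quantify pairwise co-perturbation; their
significance comes from the usual t statistic t = R·sqrt((n−2)/(1−R²))
with n−2 degrees of freedom.

Soft-thresholding raises positive correlations to a power β, replacing a
hard significance cutoff with a continuous 0–1 flow scale (the weighted
gene-co-expression-network convention).  β defaults to 8; an approximate
scale-free-topology selection is available as an opt-in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .shift_io import CSPMatrix, ResidueKey

__all__ = [
    "RankMatrix",
    "CorrelationSet",
    "SoftThresholdConfig",
    "rank_perturbations",
    "correlate",
    "correlation_pvalue",
    "select_soft_threshold",
    "apply_soft_threshold",
]

logger = logging.getLogger(__name__)


@dataclass
class RankMatrix:
    """Per-residue ranks of mutant perturbations (ties averaged, NaN masked)."""

    residues: list[ResidueKey]
    mutants: list[str]
    values: np.ndarray  # (n_residues, n_mutants)

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def residue_index(self) -> dict[ResidueKey, int]:
        return {k: i for i, k in enumerate(self.residues)}

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{rid}:{lab}" for rid, lab in self.residues]
        return pd.DataFrame(self.values, index=idx, columns=self.mutants)


def rank_perturbations(csp: CSPMatrix, min_overlap: int = 10) -> RankMatrix:
    """Rank each residue's perturbations across mutants, ascending.

    The smallest perturbation gets rank 1; ties receive the average of
    the ranks they span.  Residue rows with fewer than ``min_overlap``
    observed mutants are dropped with a warning (too few points for a
    stable correlation t-test downstream).
    """
    keep: list[int] = []
    n_obs = csp.mask.sum(axis=1)
    for i, key in enumerate(csp.residues):
        if n_obs[i] >= min_overlap:
            keep.append(i)
        else:
            logger.warning(
                "residue %s:%s excluded: only %d observed mutants (< %d)",
                key[0], key[1], n_obs[i], min_overlap,
            )
    vals = csp.values[keep]
    ranks = np.full_like(vals, np.nan)
    for r in range(vals.shape[0]):
        row = vals[r]
        present = np.isfinite(row)
        ranks[r, present] = stats.rankdata(row[present], method="average")
    return RankMatrix(residues=[csp.residues[i] for i in keep],
                      mutants=list(csp.mutants), values=ranks)


def correlation_pvalue(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for a (rank) correlation via t = r·sqrt((n−2)/(1−r²)).

    |r| = 1 maps to p = 0 by convention.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2.0) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2.0, 1e-300))
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return p


@dataclass
class CorrelationSet:
    """All pairwise Spearman correlations over jointly-present mutants.

    Symmetric matrices indexed like ``residues``; ``valid`` marks pairs
    with enough joint observations and non-degenerate variance.
    """

    residues: list[ResidueKey]
    R: np.ndarray
    p: np.ndarray
    n: np.ndarray
    valid: np.ndarray
    min_overlap: int = 10

    def residue_index(self) -> dict[ResidueKey, int]:
        return {k: i for i, k in enumerate(self.residues)}

    def significant_pairs(self, p_cutoff: float,
                          require_positive: bool = True) -> np.ndarray:
        """Boolean matrix of significant (optionally positive) pairs."""
        sig = self.valid & (self.p < p_cutoff)
        if require_positive:
            sig &= self.R > 0
        np.fill_diagonal(sig, False)
        return sig

    def to_frame(self, weights: np.ndarray | None = None) -> pd.DataFrame:
        """Upper-triangle pair table (res_A, res_B, R, p, n [, weight])."""
        rows = []
        m = len(self.residues)
        for i in range(m):
            for j in range(i + 1, m):
                if not self.valid[i, j]:
                    continue
                row = {
                    "res_A": f"{self.residues[i][0]}:{self.residues[i][1]}",
                    "res_B": f"{self.residues[j][0]}:{self.residues[j][1]}",
                    "R": self.R[i, j], "p": self.p[i, j],
                    "n": int(self.n[i, j]),
                }
                if weights is not None:
                    row["weight"] = weights[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def correlate(ranks: RankMatrix, min_overlap: int = 10) -> CorrelationSet:
    """Spearman correlation of every residue pair over joint mutants.

    R_AB is the Pearson correlation of the two rank rows restricted to
    mutants observed in both; pairs with fewer than ``min_overlap`` joint
    observations, or a zero-variance row on the joint set, are marked
    invalid (the latter with a warning).
    """
    X = ranks.values
    m = X.shape[0]
    if m < 2:
        raise ValueError("need at least 2 residues to correlate")
    M = np.isfinite(X)
    Z = np.where(M, X, 0.0)
    Mf = M.astype(float)

    # pairwise-complete moments by matrix products
    N = Mf @ Mf.T
    S1 = Z @ Mf.T          # S1[i,j] = sum_k x_ik over joint mask
    S2 = (Z * Z) @ Mf.T
    P = Z @ Z.T            # cross products over joint mask
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = P - S1 * S1.T / N
        var_i = S2 - S1 * S1 / N
        var_j = var_i.T
        R = cov / np.sqrt(var_i * var_j)
    R = np.clip(R, -1.0, 1.0)

    valid = (N >= max(min_overlap, 3))
    degenerate = valid & ((var_i <= 1e-12) | (var_j <= 1e-12))
    if np.any(np.triu(degenerate, 1)):
        logger.warning("%d pair(s) dropped for zero rank variance",
                       int(np.triu(degenerate, 1).sum()))
    valid &= ~degenerate
    np.fill_diagonal(valid, False)

    p = np.ones_like(R)
    p[valid] = correlation_pvalue(R[valid], N[valid])
    R = np.where(valid, R, np.nan)
    return CorrelationSet(residues=list(ranks.residues), R=R, p=p,
                          n=N.astype(int), valid=valid,
                          min_overlap=min_overlap)


@dataclass
class SoftThresholdConfig:
    beta: float = 8.0
    auto_select: bool = False
    rsq_target: float = 0.8
    candidates: tuple = tuple(range(1, 13))
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R² of the log-log regression of the degree distribution.

    Connectivities are binned into ``n_bins`` equal-count bins; log10 of
    the bin frequency is regressed on log10 of the bin-mean connectivity.
    """
    k = np.asarray(connectivity, float)
    k = k[k > 0]
    if k.size < 4:
        return 0.0
    n_bins = min(n_bins, max(2, k.size // 2))
    # equal-width bins over the connectivity range (equal-count bins would
    # flatten p(k) by construction)
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0,
                    edges.size - 2)
    xs, ys = [], []
    for b in range(edges.size - 1):
        sel = which == b
        if not np.any(sel):
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3 or np.ptp(xs) < 1e-12:
        return 0.0
    res = stats.linregress(xs, ys)
    return float(res.rvalue ** 2)


def select_soft_threshold(corr: CorrelationSet,
                          config: SoftThresholdConfig | None = None) -> float:
    """Choose β by the approximate scale-free topology criterion.

    With ``auto_select`` off (the default) returns ``config.beta``
    unchanged (default 8).  Otherwise, for each candidate β the node
    connectivity k_i = Σ_j max(R_ij, 0)^β is computed and the smallest β
    whose binned log-log degree distribution fits a line with
    R² ≥ ``rsq_target`` is returned; if none reaches the target, the
    best-fitting candidate is returned with a warning.
    """
    config = config or SoftThresholdConfig()
    if not config.auto_select:
        return config.beta
    Rpos = np.where(corr.valid, np.maximum(corr.R, 0.0), 0.0)
    best_beta, best_rsq = None, -1.0
    for beta in config.candidates:
        k = (Rpos ** beta).sum(axis=1)
        rsq = scale_free_fit(k, config.n_bins)
        if rsq > best_rsq:
            best_beta, best_rsq = beta, rsq
        if rsq >= config.rsq_target:
            return float(beta)
    warnings.warn(
        f"no candidate beta reached scale-free R^2 >= {config.rsq_target}; "
        f"returning best (beta={best_beta}, R^2={best_rsq:.3f})"
    )
    return float(best_beta)


def apply_soft_threshold(corr: CorrelationSet, beta: float) -> np.ndarray:
    """Soft-thresholded pair weights max(R, 0)^β ∈ [0, 1].

    Negative correlations are dropped (weight 0); the transform is
    monotone in R so the ordering of positive correlations is preserved.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    R = np.where(corr.valid, corr.R, 0.0)
    W = np.maximum(R, 0.0) ** beta
    np.fill_diagonal(W, 0.0)
    return W
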