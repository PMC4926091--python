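"""Directed 3-residue mediation analysis of rank-correlated perturbations.

A residue triple forms a directed information-flow path A→B→C when B
mediates the effect of A on C (the Baron–Kenny pattern applied to rank
profiles):

1. A affects B: the two-point correlation R_AB is significant;
2. B affects C given A: in the joint regression of C's ranks on A's and
   B's, the partial correlation ρ_bc is significant;
3. the effect is indirect: the direct (partial) effect ρ_ac is smaller
   than the raw two-point correlation R_AC;
4. only positive correlations are considered (R_AB, ρ_bc, R_AC > 0).

The accepted path carries the mediated effect R_AB·ρ_bc, later used as
a random-walk weight.  Significance uses uncorrected two-sided t-test
p-values: the state-specific cutoffs (0.02 inactive apo, 0.03 ATP-bound,
0.03 BIRB796-bound, 0.04 active) are chosen for enrichment in positive
correlations, and no multiplicity correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rank_stats import CorrelationSet, RankMatrix
from .shift_io import ResidueKey

__all__ = [
    "STATE_P_CUTOFFS",
    "MediationConfig",
    "MediationTriple",
    "MediationResult",
    "partial_correlations",
    "test_mediation",
    "enumerate_mediations",
]

logger = logging.getLogger(__name__)

#: Per-state significance cutoffs for correlations and partial correlations.
STATE_P_CUTOFFS = {
    "apo-inactive": 0.02,
    "ATP": 0.03,
    "BIRB796": 0.03,
    "active": 0.04,
}


@dataclass
class MediationConfig:
    p_cutoff: float = STATE_P_CUTOFFS["apo-inactive"]
    require_positive: bool = True
    min_overlap: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must lie in (0, 1)")

    @classmethod
    def for_state(cls, state: str, **kw) -> "MediationConfig":
        return cls(p_cutoff=STATE_P_CUTOFFS[state], **kw)


@dataclass(frozen=True)
class MediationTriple:
    A: ResidueKey
    B: ResidueKey
    C: ResidueKey
    R_AB: float
    R_AC: float
    rho_bc: float
    p_bc: float
    rho_ac: float
    p_ac: float
    n: int

    @property
    def effect(self) -> float:
        return self.R_AB * self.rho_bc


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom <= 0:
        return np.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def partial_correlations(xa, xb, xc, min_overlap: int = 10):
    """Partial correlations from the joint regression of C on A and B.

    Restricted to mutants observed in all three rows, ρ_bc is the partial
    correlation of B and C given A and ρ_ac that of A and C given B, via
    the first-order recursion ρ_xy·z = (r_xy − r_xz·r_yz) /
    sqrt((1−r_xz²)(1−r_yz²)) — identical to the regression-coefficient
    t-tests with df = n − 3, which supply the two-sided p-values.

    Returns ``(rho_bc, p_bc, rho_ac, p_ac, n)``.
    """
    xa = np.asarray(xa, float)
    xb = np.asarray(xb, float)
    xc = np.asarray(xc, float)
    joint = np.isfinite(xa) & np.isfinite(xb) & np.isfinite(xc)
    n = int(joint.sum())
    if n < max(min_overlap, 4):
        raise ValueError(f"only {n} jointly-observed mutants (< "
                         f"{max(min_overlap, 4)})")
    a, b, c = xa[joint], xb[joint], xc[joint]
    r_ab, r_ac, r_bc = _pearson(a, b), _pearson(a, c), _pearson(b, c)
    if not np.isfinite(r_ab) or abs(r_ab) >= 1.0 - 1e-12:
        raise np.linalg.LinAlgError("collinear predictors: |R_AB| = 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_bc = (r_bc - r_ab * r_ac) / np.sqrt((1 - r_ab**2) * (1 - r_ac**2))
        rho_ac = (r_ac - r_ab * r_bc) / np.sqrt((1 - r_ab**2) * (1 - r_bc**2))
    # one predictor already explains C perfectly: the other's partial is 0
    if abs(r_ac) >= 1.0 - 1e-12:
        rho_bc = 0.0
    if abs(r_bc) >= 1.0 - 1e-12:
        rho_ac = 0.0
    rho_bc = float(np.clip(rho_bc, -1.0, 1.0))
    rho_ac = float(np.clip(rho_ac, -1.0, 1.0))
    df = n - 3
    p_bc = _partial_p(rho_bc, df)
    p_ac = _partial_p(rho_ac, df)
    return rho_bc, p_bc, rho_ac, p_ac, n


def _partial_p(rho: float, df: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df))


@dataclass
class Rejection:
    """Why a candidate triple failed the mediation tests."""

    reason: str

    def __bool__(self) -> bool:
        return False


def test_mediation(A: ResidueKey, B: ResidueKey, C: ResidueKey,
                   ranks: RankMatrix, corr: CorrelationSet,
                   config: MediationConfig | None = None):
    """Test one ordered triple; returns a MediationTriple or a Rejection.

    R_AB, R_AC and the pairwise p-values come from the pairwise-complete
    correlation set; the partial correlations are recomputed on the
    triple's jointly-observed mutants.
    """
    config = config or MediationConfig()
    if len({A, B, C}) != 3:
        raise ValueError("A, B, C must be distinct")
    idx = corr.residue_index()
    try:
        ia, ib, ic = idx[A], idx[B], idx[C]
    except KeyError as exc:
        return Rejection(f"unknown residue {exc.args[0]}")
    if not (corr.valid[ia, ib] and corr.valid[ia, ic]):
        return Rejection("missing pair statistics")
    R_AB, p_AB = corr.R[ia, ib], corr.p[ia, ib]
    R_AC = corr.R[ia, ic]
    if p_AB >= config.p_cutoff:
        return Rejection("R_AB not significant")
    if config.require_positive and R_AB <= 0:
        return Rejection("R_AB not positive")

    ridx = ranks.residue_index()
    try:
        rho_bc, p_bc, rho_ac, p_ac, n = partial_correlations(
            ranks.values[ridx[A]], ranks.values[ridx[B]], ranks.values[ridx[C]],
            min_overlap=config.min_overlap,
        )
    except np.linalg.LinAlgError:
        logger.warning("triple %s,%s,%s skipped: collinear A,B", A, B, C)
        return Rejection("collinear predictors")
    except ValueError as exc:
        return Rejection(str(exc))

    if p_bc >= config.p_cutoff:
        return Rejection("rho_bc not significant")
    if config.require_positive and (rho_bc <= 0 or R_AC <= 0):
        return Rejection("positivity violated")
    if not rho_ac < R_AC:
        return Rejection("no indirect effect (rho_ac >= R_AC)")
    return MediationTriple(A=A, B=B, C=C, R_AB=float(R_AB), R_AC=float(R_AC),
                           rho_bc=rho_bc, p_bc=p_bc, rho_ac=rho_ac, p_ac=p_ac,
                           n=n)


@dataclass
class MediationResult:
    """Accepted triples plus the significant positive pairwise correlations."""

    triples: pd.DataFrame
    pairs: pd.DataFrame
    config: MediationConfig
    residues: list[ResidueKey] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_triples(self) -> int:
        return len(self.triples)


_TRIPLE_COLUMNS = ["A", "B", "C", "R_AB", "rho_bc", "rho_ac", "R_AC",
                   "effect", "p_AB", "p_bc", "p_ac", "n"]


def enumerate_mediations(ranks: RankMatrix, corr: CorrelationSet,
                         config: MediationConfig | None = None
                         ) -> MediationResult:
    """Test every ordered distinct triple (A, B, C) and collect paths.

    The loop runs over ordered pairs (A, B) whose two-point correlation
    already passes the significance (and positivity) gate; for each such
    pair all candidate C are evaluated at once on the triple-joint mutant
    masks.  Deterministic given inputs.
    """
    config = config or MediationConfig()
    X = ranks.values
    n_res, n_mut = X.shape
    M = np.isfinite(X)
    Z = np.where(M, X, 0.0)
    sig = corr.significant_pairs(config.p_cutoff, config.require_positive)

    keys = ranks.residues
    if corr.residues != keys:
        raise ValueError("ranks and correlation set index different residues")

    min_n = max(config.min_overlap, 4)
    rows: list[tuple] = []
    pair_idx = np.argwhere(sig)  # ordered pairs, both directions present
    for ia, ib in pair_idx:
        m_ab = M[ia] & M[ib]
        W = (M & m_ab).astype(float)          # joint mask per candidate C
        nC = W.sum(axis=1)
        x, y = Z[ia], Z[ib]
        Sx, Sy = W @ x, W @ y
        Sxx, Syy, Sxy = W @ (x * x), W @ (y * y), W @ (x * y)
        WZ = W * Z
        Sz = WZ.sum(axis=1)
        Szz = (WZ * Z).sum(axis=1)
        Sxz, Syz = WZ @ x, WZ @ y
        with np.errstate(divide="ignore", invalid="ignore"):
            vx = Sxx - Sx * Sx / nC
            vy = Syy - Sy * Sy / nC
            vz = Szz - Sz * Sz / nC
            r_ab = (Sxy - Sx * Sy / nC) / np.sqrt(vx * vy)
            r_ac = (Sxz - Sx * Sz / nC) / np.sqrt(vx * vz)
            r_bc = (Syz - Sy * Sz / nC) / np.sqrt(vy * vz)
            r_ab = np.clip(r_ab, -1, 1)
            r_ac = np.clip(r_ac, -1, 1)
            r_bc = np.clip(r_bc, -1, 1)
            rho_bc = (r_bc - r_ab * r_ac) / np.sqrt((1 - r_ab**2) * (1 - r_ac**2))
            rho_ac = (r_ac - r_ab * r_bc) / np.sqrt((1 - r_ab**2) * (1 - r_bc**2))
            # perfect-fit degeneracies: the other predictor's partial is 0
            rho_bc = np.where(np.abs(r_ac) >= 1 - 1e-12, 0.0, rho_bc)
            rho_ac = np.where(np.abs(r_bc) >= 1 - 1e-12, 0.0, rho_ac)
            rho_bc = np.clip(rho_bc, -1, 1)
            rho_ac = np.clip(rho_ac, -1, 1)
        ok = (nC >= min_n) & (np.abs(r_ab) < 1 - 1e-12)
        ok &= (vx > 1e-12) & (vy > 1e-12) & (vz > 1e-12)
        ok[ia] = ok[ib] = False
        ok &= corr.valid[ia]                   # need R_AC
        ok &= np.isfinite(rho_bc) & np.isfinite(rho_ac)

        df = nC - 3
        p_bc = np.ones(n_res)
        p_ac = np.ones(n_res)
        sel = ok & (np.abs(rho_bc) < 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_bc = rho_bc * np.sqrt(df / (1 - rho_bc**2))
            t_ac = rho_ac * np.sqrt(df / (1 - rho_ac**2))
        p_bc[sel] = 2 * stats.t.sf(np.abs(t_bc[sel]), df[sel])
        p_bc[ok & (np.abs(rho_bc) >= 1)] = 0.0
        sel2 = ok & (np.abs(rho_ac) < 1)
        p_ac[sel2] = 2 * stats.t.sf(np.abs(t_ac[sel2]), df[sel2])
        p_ac[ok & (np.abs(rho_ac) >= 1)] = 0.0

        R_AB = corr.R[ia, ib]
        R_AC = corr.R[ia]
        accept = ok & (p_bc < config.p_cutoff) & (rho_ac < R_AC)
        if config.require_positive:
            accept &= (rho_bc > 0) & (R_AC > 0)
        for ic in np.nonzero(accept)[0]:
            rows.append((
                f"{keys[ia][0]}:{keys[ia][1]}",
                f"{keys[ib][0]}:{keys[ib][1]}",
                f"{keys[ic][0]}:{keys[ic][1]}",
                R_AB, rho_bc[ic], rho_ac[ic], R_AC[ic],
                R_AB * rho_bc[ic], corr.p[ia, ib], p_bc[ic], p_ac[ic],
                int(nC[ic]),
            ))

    triples = pd.DataFrame(rows, columns=_TRIPLE_COLUMNS)
    if len(triples):
        triples = triples.sort_values(["A", "B", "C"], kind="mergesort",
                                      ignore_index=True)
    pairs = corr.to_frame()
    if len(pairs):
        keep = pairs["p"] < config.p_cutoff
        if config.require_positive:
            keep &= pairs["R"] > 0
        pairs = pairs[keep].reset_index(drop=True)
    return MediationResult(triples=triples, pairs=pairs, config=config,
                           residues=list(keys))
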