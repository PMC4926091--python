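"""Mediation tests: partial correlations and 3-residue path acceptance."""

import numpy as np
import pytest
from scipy import stats

from methylflow.mediation import (MediationConfig, MediationTriple, Rejection,
                                  STATE_P_CUTOFFS, enumerate_mediations,
                                  partial_correlations)
from methylflow.mediation import test_mediation as mediation_test
from methylflow.rank_stats import RankMatrix, correlate, rank_perturbations
from methylflow.shift_io import CSPMatrix


def regression_partials(xa, xb, xc):
    """Independent oracle: OLS of C on (1, A, B); partials from coef t."""
    X = np.column_stack([np.ones_like(xa), xa, xb])
    beta, *_ = np.linalg.lstsq(X, xc, rcond=None)
    resid = xc - X @ beta
    n = len(xc)
    df = n - 3
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t_b = beta[2] / np.sqrt(cov[2, 2])
    t_a = beta[1] / np.sqrt(cov[1, 1])
    rho_bc = t_b / np.sqrt(t_b**2 + df)
    rho_ac = t_a / np.sqrt(t_a**2 + df)
    p_bc = 2 * stats.t.sf(abs(t_b), df)
    p_ac = 2 * stats.t.sf(abs(t_a), df)
    return rho_bc, p_bc, rho_ac, p_ac


def _ranks_of(X):
    rows = np.asarray(X, dtype=float)
    csp = CSPMatrix(residues=[(i + 1, "d1") for i in range(rows.shape[0])],
                    mutants=[f"m{j}" for j in range(rows.shape[1])],
                    values=np.abs(rows))
    return rank_perturbations(csp, min_overlap=5)


class TestPartialCorrelations:
    def test_matches_regression_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(12, 25))
            xa, xb = rng.normal(size=(2, n))
            xc = 0.5 * xa + 0.7 * xb + rng.normal(size=n)
            got = partial_correlations(xa, xb, xc, min_overlap=10)
            want = regression_partials(xa, xb, xc)
            assert got[0] == pytest.approx(want[0], abs=1e-10)
            assert got[1] == pytest.approx(want[1], abs=1e-10)
            assert got[2] == pytest.approx(want[2], abs=1e-10)
            assert got[3] == pytest.approx(want[3], abs=1e-10)

    def test_identity_case(self):
        rng = np.random.default_rng(1)
        xa = rng.normal(size=20)
        xb = rng.normal(size=20)
        rho_bc, p_bc, rho_ac, p_ac, n = partial_correlations(xa, xb, xb)
        assert rho_bc == pytest.approx(1.0)
        assert p_bc == 0.0
        assert abs(rho_ac) < 1e-6

    def test_joint_mask_restriction(self):
        rng = np.random.default_rng(2)
        xa, xb, xc = rng.normal(size=(3, 20))
        xa[3] = np.nan
        xc[7] = np.nan
        got = partial_correlations(xa, xb, xc)
        joint = np.isfinite(xa) & np.isfinite(xb) & np.isfinite(xc)
        want = regression_partials(xa[joint], xb[joint], xc[joint])
        assert got[0] == pytest.approx(want[0], abs=1e-10)
        assert got[4] == joint.sum()

    def test_collinear_predictors_raise(self):
        xa = np.arange(15.0)
        with pytest.raises(np.linalg.LinAlgError):
            partial_correlations(xa, 2 * xa + 1, np.random.default_rng(3)
                                 .normal(size=15))

    def test_too_few_joint_observations(self):
        xa = np.full(12, np.nan)
        xa[:5] = np.arange(5.0)
        with pytest.raises(ValueError):
            partial_correlations(xa, np.arange(12.0) ** 2,
                                 np.arange(12.0) % 3, min_overlap=10)

    def test_null_partials_small(self):
        """Independent A, B, C: partials near 0, p roughly uniform."""
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(400):
            xa, xb, xc = rng.normal(size=(3, 20))
            rho_bc, p_bc, *_ = partial_correlations(xa, xb, xc)
            ps.append(p_bc)
        assert np.mean(np.array(ps) < 0.05) == pytest.approx(0.05, abs=0.03)


def _chain_panel(rng, n_res=3, n_mut=40, noise=0.6):
    """C = B + noise, B = A + noise rank panels."""
    a = rng.normal(size=n_mut)
    b = a + noise * rng.normal(size=n_mut)
    c = b + noise * rng.normal(size=n_mut)
    return np.vstack([np.abs(a) + 2, np.abs(b) + 2, np.abs(c) + 2])


class TestTestMediation:
    def test_linear_chain_accepted(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(20):
            ranks = _ranks_of(_chain_panel(rng))
            corr = correlate(ranks, min_overlap=5)
            res = mediation_test((1, "d1"), (2, "d1"), (3, "d1"), ranks, corr,
                                 MediationConfig(p_cutoff=0.02, min_overlap=5))
            if isinstance(res, MediationTriple):
                hits += 1
                assert res.effect > 0
                assert res.rho_ac < res.R_AC
        assert hits >= 15  # chain signal accepted far above chance

    def test_direct_only_rejected(self):
        """C = A + noise with independent B: rho_bc not significant."""
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(30):
            a = rng.normal(size=40)
            b = rng.normal(size=40)
            c = a + 0.5 * rng.normal(size=40)
            ranks = _ranks_of(np.vstack([np.abs(a) + 2, np.abs(b) + 2,
                                         np.abs(c) + 2]))
            corr = correlate(ranks, min_overlap=5)
            res = mediation_test((1, "d1"), (2, "d1"), (3, "d1"), ranks, corr,
                                 MediationConfig(p_cutoff=0.02, min_overlap=5))
            if isinstance(res, MediationTriple):
                hits += 1
        assert hits <= 3

    def test_negative_pair_rejected(self):
        rng = np.random.default_rng(7)
        a = np.abs(rng.normal(size=30)) + 1
        ranks = _ranks_of(np.vstack([a, 1.0 / a, a + 0.01]))
        corr = correlate(ranks, min_overlap=5)
        res = mediation_test((1, "d1"), (2, "d1"), (3, "d1"), ranks, corr,
                             MediationConfig(p_cutoff=0.05, min_overlap=5))
        assert isinstance(res, Rejection)

    def test_distinct_residues_required(self):
        rng = np.random.default_rng(8)
        ranks = _ranks_of(rng.random((3, 15)))
        corr = correlate(ranks, min_overlap=5)
        with pytest.raises(ValueError):
            mediation_test((1, "d1"), (1, "d1"), (3, "d1"), ranks, corr)


class TestEnumerate:
    def test_two_residues_no_triples(self):
        rng = np.random.default_rng(9)
        ranks = _ranks_of(rng.random((2, 15)))
        corr = correlate(ranks, min_overlap=5)
        res = enumerate_mediations(ranks, corr,
                                   MediationConfig(min_overlap=5))
        assert res.n_triples == 0

    def test_matches_single_triple_brute_force(self, default_synth):
        """Vectorized enumeration == per-triple test_mediation loop."""
        csp, _ = default_synth
        sub = CSPMatrix(residues=csp.residues[:14], mutants=csp.mutants,
                        values=csp.values[:14], field_mhz=csp.field_mhz)
        ranks = rank_perturbations(sub)
        corr = correlate(ranks)
        cfg = MediationConfig(p_cutoff=0.05)
        res = enumerate_mediations(ranks, corr, cfg)
        brute = set()
        keys = ranks.residues
        for A in keys:
            for B in keys:
                for C in keys:
                    if len({A, B, C}) != 3:
                        continue
                    out = mediation_test(A, B, C, ranks, corr, cfg)
                    if isinstance(out, MediationTriple):
                        brute.add((f"{A[0]}:{A[1]}", f"{B[0]}:{B[1]}",
                                   f"{C[0]}:{C[1]}"))
        got = set(zip(res.triples["A"], res.triples["B"], res.triples["C"]))
        assert got == brute

    def test_monotone_in_cutoff(self, default_synth):
        csp, _ = default_synth
        sub = CSPMatrix(residues=csp.residues[:20], mutants=csp.mutants,
                        values=csp.values[:20], field_mhz=csp.field_mhz)
        ranks = rank_perturbations(sub)
        corr = correlate(ranks)
        counts = [enumerate_mediations(ranks, corr,
                                       MediationConfig(p_cutoff=p)).n_triples
                  for p in (0.005, 0.02, 0.1)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_deterministic(self, default_synth):
        csp, _ = default_synth
        ranks = rank_perturbations(csp)
        corr = correlate(ranks)
        a = enumerate_mediations(ranks, corr)
        b = enumerate_mediations(ranks, corr)
        assert a.triples.equals(b.triples)
        assert a.pairs.equals(b.pairs)

    def test_accepted_triples_satisfy_invariants(self, two_lobe_fit):
        res, _ = two_lobe_fit
        t = res.mediation.triples
        assert (t["rho_ac"] < t["R_AC"]).all()
        assert (t["effect"] > 0).all()
        assert (t["effect"] <= 1.0 + 1e-12).all()
        assert (t["p_bc"] < res.mediation.config.p_cutoff).all()

    def test_state_cutoffs(self):
        assert STATE_P_CUTOFFS == {"apo-inactive": 0.02, "ATP": 0.03,
                                   "BIRB796": 0.03, "active": 0.04}
        assert MediationConfig.for_state("active").p_cutoff == 0.04
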