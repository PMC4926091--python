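"""Map-equation codelength, optimizer, and physical communities."""

import numpy as np
import pytest

from methylflow.mapeq import (Partition, codelength, optimize,
                              physical_communities)
from methylflow.memory_network import MemoryNetwork, stationary_flow

from conftest import make_state_chain, set_partitions


def reference_codelength(net, flow, module_of, teleport_mode="recorded"):
    """Independent entropy-form evaluation over an explicit flow matrix."""
    n = net.n_states
    p, tau, t = flow.visit, flow.tau, net.teleport
    W = np.zeros((n, n))
    np.add.at(W, (net.edges_src, net.edges_dst), net.edges_weight)
    out = W.sum(axis=1)
    dangling = out == 0
    Wn = np.where(out[:, None] > 0, W / np.where(out == 0, 1, out)[:, None],
                  0.0)
    F = (1 - tau) * p[:, None] * Wn          # real link steps
    restart = p * (tau + (1 - tau) * dangling) if teleport_mode == "recorded" \
        else p * (1 - tau) * dangling
    F = F + np.outer(restart, t)             # restart steps land on t
    mods = sorted(set(int(m) for m in module_of))
    module_of = np.asarray(module_of)
    q = {}
    for m in mods:
        inside = module_of == m
        q[m] = F[inside][:, ~inside].sum()
    q_tot = sum(q.values())

    def H(probs):
        probs = np.asarray([x for x in probs if x > 0], dtype=float)
        probs = probs / probs.sum()
        return -(probs * np.log2(probs)).sum()

    L = q_tot * H(q.values()) if q_tot > 0 else 0.0
    for m in mods:
        inside = module_of == m
        members = p[inside]
        total = q[m] + members.sum()
        L += total * H(np.concatenate([[q[m]], members]))
    return L


class TestCodelength:
    def _uniform4(self):
        # 4-state cycle over pairs of 5 residues with uniform everything
        res = [(i, "d1") for i in range(1, 6)]
        states = [(res[i], res[i + 1]) for i in range(4)]
        net = MemoryNetwork(states=states,
                            edges_src=np.array([0, 1, 2]),
                            edges_dst=np.array([1, 2, 3]),
                            edges_weight=np.ones(3),
                            teleport=np.full(4, 0.25))
        return net

    def test_four_uniform_states_one_module_two_bits(self):
        net = self._uniform4()
        flow = stationary_flow(net, tau=0.5)
        # one module: L = H(visit); with uniform visit this is 2 bits
        visit = np.full(4, 0.25)
        flow.visit = visit
        assert codelength(net, flow, [0, 0, 0, 0]) == pytest.approx(2.0)

    def test_one_module_equals_visit_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            net, flow = make_state_chain(int(rng.integers(3, 10)), rng)
            H = -(flow.visit * np.log2(flow.visit)).sum()
            for mode in ("recorded", "unrecorded"):
                assert codelength(net, flow, np.zeros(net.n_states, int),
                                  teleport_mode=mode) == pytest.approx(H)

    @pytest.mark.parametrize("mode", ["recorded", "unrecorded"])
    def test_matches_reference_formula(self, mode):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            net, flow = make_state_chain(n, rng, tau=float(rng.uniform(0.05,
                                                                       0.5)))
            module_of = rng.integers(0, max(2, n // 2), size=n)
            got = codelength(net, flow, module_of, teleport_mode=mode)
            want = reference_codelength(net, flow, module_of, mode)
            assert got == pytest.approx(want, abs=1e-10)

    def test_disconnected_cycles_prefer_two_modules(self):
        res = [(i, "d1") for i in range(1, 5)]
        states = [(res[0], res[1]), (res[1], res[0]),
                  (res[2], res[3]), (res[3], res[2])]
        net = MemoryNetwork(states=states,
                            edges_src=np.array([0, 1, 2, 3]),
                            edges_dst=np.array([1, 0, 3, 2]),
                            edges_weight=np.ones(4),
                            teleport=np.full(4, 0.25))
        flow = stationary_flow(net, tau=0.01)
        L2 = codelength(net, flow, [0, 0, 1, 1])
        L1 = codelength(net, flow, [0, 0, 0, 0])
        assert L2 < L1

    def test_uncovered_state_rejected(self):
        net = self._uniform4()
        flow = stationary_flow(net, tau=0.2)
        with pytest.raises(ValueError):
            codelength(net, flow, [0, 0, 0])


class TestOptimize:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        net, flow = make_state_chain(9, rng)
        a = optimize(net, flow, n_trials=20, seed=7)
        b = optimize(net, flow, n_trials=20, seed=7)
        np.testing.assert_array_equal(a.module_of, b.module_of)
        assert a.codelength == b.codelength

    def test_more_trials_never_worse(self):
        rng = np.random.default_rng(3)
        net, flow = make_state_chain(9, rng)
        L1 = optimize(net, flow, n_trials=1, seed=0).codelength
        L100 = optimize(net, flow, n_trials=100, seed=0).codelength
        assert L100 <= L1 + 1e-12

    def test_never_worse_than_one_module(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            net, flow = make_state_chain(int(rng.integers(4, 10)), rng)
            part = optimize(net, flow, n_trials=30, seed=1)
            H = -(flow.visit * np.log2(flow.visit)).sum()
            assert part.codelength <= H + 1e-12

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(5)
        for trial in range(15):
            n = int(rng.integers(4, 8))
            net, flow = make_state_chain(n, rng)
            best = min(codelength(net, flow, p) for p in set_partitions(n))
            part = optimize(net, flow, n_trials=60, seed=trial)
            assert part.codelength == pytest.approx(best, abs=1e-9)

    def test_recovers_planted_two_modules(self):
        res = [(i, "d1") for i in range(1, 5)]
        states = [(res[0], res[1]), (res[1], res[0]),
                  (res[2], res[3]), (res[3], res[2])]
        net = MemoryNetwork(states=states,
                            edges_src=np.array([0, 1, 2, 3]),
                            edges_dst=np.array([1, 0, 3, 2]),
                            edges_weight=np.ones(4),
                            teleport=np.full(4, 0.25))
        flow = stationary_flow(net, tau=0.01)
        part = optimize(net, flow, n_trials=50, seed=0)
        assert part.n_modules == 2
        assert part.module_of[0] == part.module_of[1]
        assert part.module_of[2] == part.module_of[3]

    def test_module_flows_bookkeeping(self):
        rng = np.random.default_rng(6)
        net, flow = make_state_chain(8, rng)
        part = optimize(net, flow, n_trials=20, seed=2)
        assert part.module_flows["visit"].sum() == pytest.approx(1.0)
        assert (part.module_flows["exit"] >= -1e-15).all()
        assert part.module_flows["n_states"].sum() == net.n_states


class TestPhysicalCommunities:
    def test_one_module_contains_everything(self):
        rng = np.random.default_rng(7)
        net, flow = make_state_chain(6, rng)
        part = Partition(module_of=np.zeros(6, int),
                         codelength=0.0, module_flows=None)
        rep = physical_communities(part, net, flow, min_size=0)
        all_res = {f"{c[0]}:{c[1]}" for _, c in net.states}
        assert set(rep.communities.iloc[0]["residues"]) == all_res

    def test_overlap_by_split_incoming_states(self):
        res = {k: (k, "d1") for k in range(1, 5)}
        states = [(res[1], res[2]), (res[3], res[2])]  # B=2 from A=1 and C=3
        net = MemoryNetwork(states=states, edges_src=np.array([], int),
                            edges_dst=np.array([], int),
                            edges_weight=np.array([]),
                            teleport=np.array([0.5, 0.5]))
        flow = stationary_flow(net, tau=0.3)
        part = Partition(module_of=np.array([0, 1]), codelength=0.0,
                         module_flows=None)
        rep = physical_communities(part, net, flow, min_size=0)
        assert rep.membership["2:d1"] == [0, 1]

    def test_every_residue_in_some_community(self, two_lobe_fit):
        res, _ = two_lobe_fit
        rep = res.community_report
        residues_with_states = {f"{c[0]}:{c[1]}"
                                for c in res.network.physical_of}
        assert set(rep.membership) == residues_with_states
        assert all(len(mods) >= 1 for mods in rep.membership.values())

    def test_flow_conservation_across_modules(self, two_lobe_fit):
        res, _ = two_lobe_fit
        from methylflow.mapeq import _flow_terms
        terms = _flow_terms(res.network, res.flow, "recorded")
        total_link = terms.link_flow.sum()
        mod = res.partition.module_of
        intra = terms.link_flow[mod[terms.link_src]
                                == mod[terms.link_dst]].sum()
        inter = res.community_report.inter_module_flow.to_numpy().sum()
        assert intra + inter == pytest.approx(total_link, abs=1e-10)

    def test_size_filter_split(self, two_lobe_fit):
        res, _ = two_lobe_fit
        rep = res.community_report
        assert (rep.communities["n_residues"] > rep.min_size).all()
        assert (rep.small_communities["n_residues"] <= rep.min_size).all()

    def test_json_serializes(self, two_lobe_fit, tmp_path):
        res, _ = two_lobe_fit
        text = res.community_report.to_json(tmp_path / "c.json")
        assert "codelength_bits" in text
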