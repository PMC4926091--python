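"""Shared fixtures: synthetic panels and fitted pipelines.

Expensive fits are session-scoped so many tests can interrogate the
same fitted network.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

import methylflow as mf
from methylflow.memory_network import MemoryNetwork, stationary_flow

logging.getLogger("methylflow").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_synth():
    """Study-scale synthetic panel (78 residues x 20 mutants)."""
    return mf.generate(mf.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def two_lobe_fit():
    """Fitted pipeline on the well-separated two-lobe validation panel."""
    csp, truth = mf.two_lobe_scenario(seed=0)
    model = mf.CSPNetworkModel(csp, p_cutoff=0.1)
    return model.fit(n_trials=30, seed=5), truth


@pytest.fixture(scope="session")
def chain_fit():
    """Fitted pipeline on the dominant planted-pathway panel."""
    csp, truth = mf.chain_scenario(seed=0)
    model = mf.CSPNetworkModel(csp, p_cutoff=0.1)
    return model.fit(n_trials=30, seed=5), truth


def make_state_chain(n_states: int, rng: np.random.Generator,
                     edge_prob: float = 0.8, tau: float = 0.2):
    """Random chain-shaped memory network over n_states residue pairs."""
    res = [(i + 1, "d1") for i in range(n_states + 1)]
    states = [(res[i], res[i + 1]) for i in range(n_states)]
    src, dst, w = [], [], []
    for i in range(n_states - 1):
        if rng.random() < edge_prob:
            src.append(i)
            dst.append(i + 1)
            w.append(float(rng.uniform(0.2, 1.0)))
    if not src:
        src, dst, w = [0], [1], [1.0]
    tele = rng.uniform(0.2, 1.0, n_states)
    tele /= tele.sum()
    net = MemoryNetwork(states=states, edges_src=np.array(src),
                        edges_dst=np.array(dst), edges_weight=np.array(w),
                        teleport=tele)
    flow = stationary_flow(net, tau=tau)
    return net, flow


def set_partitions(n: int):
    """All set partitions of range(n) as label tuples."""
    def rec(i, labels, mx):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(mx + 1):
            labels.append(lab)
            yield from rec(i + 1, labels, max(mx, lab + 1))
            labels.pop()
    yield from rec(0, [], 0)
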