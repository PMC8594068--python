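"""Shared fixtures: small trees, alignments, and frequency vectors."""

from __future__ import annotations

import numpy as np
import pytest

import hlscan as h
from hlscan.simulate import M0Params, default_tree, simulate_alignment
from hlscan.tree import parse_newick


@pytest.fixture(scope="session")
def uniform_pi():
    return h.CodonFrequencies.uniform()


@pytest.fixture(scope="session")
def four_taxon_tree():
    return parse_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.08);")


@pytest.fixture(scope="session")
def small_alignment(four_taxon_tree, uniform_pi):
    aln, _ = simulate_alignment(four_taxon_tree, "M0",
                                M0Params(2.0, 0.3, uniform_pi), 40, seed=11)
    return aln


@pytest.fixture(scope="session")
def mammal_tree():
    return default_tree()


def brute_force_loglik(alignment, tree, P_by_id, pi, chunk=2_000_000):
    """Enumeration oracle: per site, sum the joint probability over every
    assignment of states to the internal nodes (61^k terms), evaluated by
    direct gathering -- no pruning recursion.  Exponential in the number of
    internal nodes; tiny trees only."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    k = len(internals)
    pos = {id(n): i for i, n in enumerate(internals)}
    taxon_row = {n.name: alignment.taxa.index(n.name) for n in tree.leaves()}
    n_states = 61
    total_assignments = n_states ** k

    def leaf_vector(node, site):
        """P(parent_state -> observed leaf state), length 61."""
        P = P_by_id[id(node)]
        col = alignment.sites[taxon_row[node.name], site]
        if col == h.GAP:
            return np.ones(n_states)
        if col == h.AMBIGUOUS:
            compat = list(alignment.ambiguity[(taxon_row[node.name], site)])
            return P[:, compat].sum(axis=1)
        return P[:, col]

    out = []
    for site in range(alignment.n_sites):
        total = 0.0
        for lo in range(0, total_assignments, chunk):
            idx = np.arange(lo, min(lo + chunk, total_assignments))
            states = [(idx // (n_states ** i)) % n_states for i in range(k)]
            prob = pi[states[pos[id(tree.root)]]].astype(float).copy()
            for node in tree.postorder():
                if node.parent is None:
                    continue
                ps = states[pos[id(node.parent)]]
                if node.is_leaf:
                    prob *= leaf_vector(node, site)[ps]
                else:
                    prob *= P_by_id[id(node)][ps, states[pos[id(node)]]]
            total += prob.sum()
        out.append(np.log(total))
    return np.array(out)
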