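"""Felsenstein pruning over codon states, with per-branch derivatives.

Partial likelihoods are scaled per site-pattern at every internal node
(division by the per-column maximum, accumulated in log space) so that
long trees and many sites never underflow.  Two performance devices keep
repeated evaluations cheap: identical alignment columns are collapsed to
unique site patterns with multiplicities, and the engine caches per-child
"messages" ``P_c @ S_c`` from the last base pass so the derivative with
respect to one branch length only re-propagates along the path from that
branch to the root.
"""

from __future__ import annotations

import numpy as np

from .alignment import CodonAlignment
from .tree import LabeledTree, TreeNode, require_matching_taxa


class PruningEngine:
    """Reusable pruning workspace bound to one (alignment, tree) pair.

    The tree topology must not change after construction; branch lengths
    and substitution matrices are supplied per call.  Internally all work
    is done on the ``n_patterns`` unique alignment columns; per-site
    vectors are recovered through ``pattern_index``.
    """

    def __init__(self, alignment: CodonAlignment, tree: LabeledTree):
        require_matching_taxa(tree, alignment.taxa)
        self.tree = tree
        self.nodes: list[TreeNode] = tree.postorder()
        self.n_sites = alignment.n_sites

        # collapse identical columns; ambiguity sets are part of the key
        keys = [
            (tuple(alignment.sites[:, j]),
             tuple(sorted((i, alignment.ambiguity[(i, j)])
                          for i in range(alignment.n_taxa)
                          if (i, j) in alignment.ambiguity)))
            for j in range(alignment.n_sites)
        ]
        first: dict = {}
        index = np.empty(alignment.n_sites, dtype=np.int64)
        order: list[int] = []
        for j, key in enumerate(keys):
            p = first.get(key)
            if p is None:
                p = len(order)
                first[key] = p
                order.append(j)
            index[j] = p
        #: for each site, the index of its pattern
        self.pattern_index = index
        #: multiplicity of each pattern
        self.pattern_weights = np.bincount(index).astype(float)
        self.n_patterns = len(order)

        leaf_parts = alignment.leaf_partials()
        cols = np.asarray(order)
        self._leaf_partial = {
            id(n): np.ascontiguousarray(leaf_parts[n.name][:, cols])
            for n in self.nodes if n.is_leaf
        }
        # caches filled by the last site_loglik(store=True) pass
        self._partial: dict[int, np.ndarray] = {}
        self._message: dict[int, np.ndarray] = {}
        self._scale: dict[int, np.ndarray] = {}
        self._rootvec: np.ndarray | None = None

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern vector/matrix (last axis) back to sites."""
        return per_pattern[..., self.pattern_index]

    # -- base pass --------------------------------------------------------

    def pattern_loglik(self, P_of, pi: np.ndarray,
                       store: bool = False) -> np.ndarray:
        """Per-pattern log-likelihood vector (length ``n_patterns``).

        ``P_of(node)`` returns the transition matrix of the branch above
        ``node``.  With ``store=True`` the per-node partials and messages
        are retained for subsequent :meth:`branch_gradient` calls.
        """
        partial: dict[int, np.ndarray] = {}
        message: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        logscale = np.zeros(self.n_patterns)
        for node in self.nodes:
            if node.is_leaf:
                partial[id(node)] = self._leaf_partial[id(node)]
                continue
            R = None
            for ch in node.children:
                M = P_of(ch) @ partial[id(ch)]
                message[id(ch)] = M
                R = M if R is None else R * M
            m = R.max(axis=0)
            m = np.where(m > 0, m, 1.0)
            partial[id(node)] = R / m
            scale[id(node)] = m
            logscale += np.log(m)
        root = self.nodes[-1]
        rootvec = pi @ partial[id(root)]
        if store:
            self._partial, self._message, self._rootvec = partial, message, rootvec
            self._scale = scale
        with np.errstate(divide="ignore"):
            return np.log(rootvec) + logscale

    def site_loglik(self, P_of, pi: np.ndarray,
                    store: bool = False) -> np.ndarray:
        """Per-site log-likelihood vector (length ``n_sites``)."""
        return self.expand(self.pattern_loglik(P_of, pi, store=store))

    def total_loglik(self, P_of, pi: np.ndarray, store: bool = False) -> float:
        """Pattern-weighted total log-likelihood."""
        return float(self.pattern_loglik(P_of, pi, store=store)
                     @ self.pattern_weights)

    def pattern_loglik_stack(self, P_of, pi: np.ndarray) -> np.ndarray:
        """(K, n_patterns) log-likelihoods for K rate classes in one pass.

        ``P_of(node)`` returns a (K, 61, 61) stack of transition matrices
        for the branch above ``node``; classes share the pruning traversal
        through batched matmuls.
        """
        partial: dict[int, np.ndarray] = {}
        K = P_of(next(n for n in self.nodes if n.parent is not None)).shape[0]
        logscale = np.zeros((K, self.n_patterns))
        for node in self.nodes:
            if node.is_leaf:
                partial[id(node)] = self._leaf_partial[id(node)]
                continue
            R = None
            for ch in node.children:
                M = P_of(ch) @ partial[id(ch)]  # (K,61,61)@(·,61,S)->(K,61,S)
                R = M if R is None else R * M
            m = R.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            partial[id(node)] = R / m[:, None, :]
            logscale += np.log(m)
        root = self.nodes[-1]
        rootvec = np.einsum("i,kis->ks", pi, partial[id(root)])
        with np.errstate(divide="ignore"):
            return np.log(rootvec) + logscale

    def root_child_partials_stack(self, P_of, pi: np.ndarray
                                  ) -> tuple[dict[int, np.ndarray], np.ndarray]:
        """Stacked pruning stopped just below the root.

        Returns the per-pattern partials of every root child (leaf partials
        are unstacked (61, S) arrays) and the accumulated (K, n_patterns)
        log-scale.  Callers finish the root combination themselves -- used
        to share background-class work when only the root-adjacent branches
        are foreground.
        """
        partial: dict[int, np.ndarray] = {}
        K = P_of(next(n for n in self.nodes
                      if n.parent is not None and not n.foreground)).shape[0]
        logscale = np.zeros((K, self.n_patterns))
        for node in self.nodes:
            if node.is_leaf:
                partial[id(node)] = self._leaf_partial[id(node)]
                continue
            if node.parent is None:
                break
            R = None
            for ch in node.children:
                M = P_of(ch) @ partial[id(ch)]
                R = M if R is None else R * M
            m = R.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            partial[id(node)] = R / m[:, None, :]
            logscale += np.log(m)
        root = self.nodes[-1]
        return {id(c): partial[id(c)] for c in root.children}, logscale

    # -- branch derivatives ------------------------------------------------

    def branch_gradient(self, node: TreeNode, dP: np.ndarray, P_of,
                        pi: np.ndarray) -> float:
        """d(total lnL)/dt for the branch above ``node``.

        Requires a preceding ``pattern_loglik(..., store=True)`` pass with
        the same matrices; uses its cached messages so only the root path
        is re-propagated.  Scale factors cancel in the derivative ratio.
        """
        if self._rootvec is None:
            raise RuntimeError("call pattern_loglik(store=True) first")
        dmsg = dP @ self._partial[id(node)]  # derivative of node's message
        child, parent = node, node.parent
        while True:
            D = dmsg
            for ch in parent.children:
                if ch is not child:
                    D = D * self._message[id(ch)]
            D = D / self._scale[id(parent)]  # derivative of parent's partial,
            #                                  in the cached scaling frame
            if parent.parent is None:
                break
            dmsg = P_of(parent) @ D
            child, parent = parent, parent.parent
        num = pi @ D
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = num / self._rootvec
        return float(ratio @ self.pattern_weights)


def site_log_likelihood(alignment: CodonAlignment, tree: LabeledTree,
                        per_branch_matrices: dict[int, np.ndarray],
                        pi: np.ndarray) -> np.ndarray:
    """Per-site log-likelihoods given one P matrix per branch.

    ``per_branch_matrices`` is keyed by ``id(node)`` for each non-root node
    of the tree (the branch above that node).
    """
    engine = PruningEngine(alignment, tree)
    return engine.site_loglik(lambda n: per_branch_matrices[id(n)], pi)
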