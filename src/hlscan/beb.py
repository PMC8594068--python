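"""Bayes empirical Bayes site-class posteriors and PSS calls.

After a significant branch-site test, each codon site gets a posterior
probability of belonging to the positively selected classes (2a + 2b).
Rather than plugging in the mixture MLE alone, the class posteriors are
averaged over a uniform grid on (p0, p1, omega0, omega2) with equal prior
mass per grid cell, which absorbs the estimation uncertainty of the
mixture parameters; kappa and the branch lengths stay at their MLEs.
Sites whose posterior exceeds the threshold (0.95 by default) are called
positively selected sites (PSSs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import CodonAlignment
from .genetics import GAP
from .selection import (BranchSiteParams, ModelAEvaluator,
                        model_a_scale_factors)
from .tree import LabeledTree

#: Upper edge of the omega2 prior grid (lower edge is 1).
OMEGA2_GRID_MAX = 11.0


@dataclass
class SitePosterior:
    """Posterior class membership of one alignment codon column."""

    site_index: int  # 0-based alignment column
    class_posteriors: np.ndarray  # (4,) in class order 0, 1, 2a, 2b
    p_positive: float
    is_pss: bool
    reference_site: int | None = None  # 1-based codon index on the reference


def _grid(points: int, lo: float, hi: float) -> np.ndarray:
    """Cell midpoints of a uniform grid on (lo, hi)."""
    edges = np.linspace(lo, hi, points + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def reference_site_map(alignment: CodonAlignment,
                       reference_taxon: str) -> list[int | None]:
    """Alignment column -> 1-based codon position on the reference taxon,
    skipping the reference's gap columns (None there)."""
    try:
        row = alignment.taxa.index(reference_taxon)
    except ValueError as exc:
        raise ValueError(f"reference taxon '{reference_taxon}' "
                         "not in alignment") from exc
    out: list[int | None] = []
    pos = 0
    for j in range(alignment.n_sites):
        if alignment.sites[row, j] == GAP:
            out.append(None)
        else:
            pos += 1
            out.append(pos)
    return out


def beb_posteriors(alignment: CodonAlignment, tree_with_lengths: LabeledTree,
                   mle: BranchSiteParams, grid_points: int = 10,
                   threshold: float = 0.95,
                   reference_taxon: str | None = None) -> list[SitePosterior]:
    """Site-class posteriors integrated over the mixture-parameter grid.

    For each grid cell theta the class likelihoods L_k(site; theta) are
    weighted by the cell's class proportions and the uniform cell prior;
    the posterior of class k at a site is the normalized grid sum.  A
    single-point "grid" collapses to the naive empirical Bayes posterior
    at the MLE.
    """
    if grid_points < 1:
        raise ValueError("grid_points must be >= 1")
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    evaluator = ModelAEvaluator(alignment, tree_with_lengths, mle.pi)
    n_sites = alignment.n_sites

    if grid_points == 1:
        w0_grid = np.array([mle.omega0])
        w2_grid = np.array([mle.omega2])
        p_pairs = [(mle.p0, mle.p1)]
    else:
        w0_grid = _grid(grid_points, 0.0, 1.0)
        w2_grid = _grid(grid_points, 1.0, OMEGA2_GRID_MAX)
        pvals = _grid(grid_points, 0.0, 1.0)
        p_pairs = [(a, b) for a in pvals for b in pvals if a + b <= 1.0]

    # class likelihoods depend only on (omega0, omega2); share them across
    # the (p0, p1) part of the grid
    # rate normalization held at the MLE (like kappa and branch lengths)
    mle_scale = model_a_scale_factors(mle.kappa, mle.omega0, mle.omega2,
                                      mle.weights(), mle.pi)
    loglike: dict[tuple[int, int], np.ndarray] = {}
    for i, w0 in enumerate(w0_grid):
        for j, w2 in enumerate(w2_grid):
            loglike[(i, j)] = evaluator.class_ll(mle.kappa, float(w0),
                                                 float(w2),
                                                 scale_factors=mle_scale)

    # class-proportion vectors are shared by every (omega0, omega2) cell
    weight_rows = np.array([
        BranchSiteParams(kappa=mle.kappa, omega0=mle.omega0,
                         omega2=mle.omega2, p0=p0, p1=p1, pi=mle.pi).weights()
        for p0, p1 in p_pairs
    ])
    weight_sum = weight_rows.sum(axis=0)  # (4,)

    # per-pattern stabilization across the whole grid (the evaluator works
    # on unique alignment columns; expand to sites at the end)
    n_pat = evaluator.engine.n_patterns
    peak = np.full(n_pat, -np.inf)
    for ll in loglike.values():
        peak = np.maximum(peak, ll.max(axis=0))

    numer = np.zeros((4, n_pat))
    for ll in loglike.values():
        rel = np.exp(ll - peak[None, :])  # (4, patterns)
        numer += weight_sum[:, None] * rel
    denom = numer.sum(axis=0)
    if np.any(denom <= 0):
        bad = int(np.argmax(evaluator.engine.expand(denom) <= 0))
        raise ValueError(f"zero integrated likelihood at site {bad}")
    post = evaluator.engine.expand(numer / denom[None, :])

    ref_map = (reference_site_map(alignment, reference_taxon)
               if reference_taxon else [None] * n_sites)
    out = []
    for s in range(n_sites):
        p_pos = float(post[2, s] + post[3, s])
        out.append(SitePosterior(site_index=s,
                                 class_posteriors=post[:, s].copy(),
                                 p_positive=p_pos,
                                 is_pss=p_pos > threshold,
                                 reference_site=ref_map[s]))
    return out
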