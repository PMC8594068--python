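"""Branch-site positive-selection inference.

The screening statistic is the branch-site "test 2": a likelihood-ratio
test of the modified Model A alternative (a site class with omega2 >= 1 on
the designated foreground branch) against the null with omega2 fixed at 1,
referred to a chi-square distribution with one degree of freedom.  The
optimization is split in two steps, mirroring the screening pipeline: a
one-ratio (M0) fit first estimates kappa, a single omega, and all branch
lengths; the branch lengths are then frozen and only the mixture
parameters of Model A are optimized.

Model A mixes four site classes with foreground/background omega pairs

    class 0:  (omega0, omega0)      weight p0
    class 1:  (1, 1)                weight p1
    class 2a: (omega0, omega2)      weight (1-p0-p1) * p0/(p0+p1)
    class 2b: (1, omega2)           weight (1-p0-p1) * p1/(p0+p1)

with omega0 in (0, 1], omega2 >= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .alignment import CodonAlignment
from .codon_model import (CodonFrequencies, CodonRateMatrix,
                          estimate_codon_frequencies, gy94_mean_rate)
from .likelihood import PruningEngine
from .tree import LabeledTree

KAPPA_BOUNDS = (0.01, 100.0)
OMEGA0_BOUNDS = (1e-4, 1.0)
OMEGA2_BOUNDS = (1.0, 50.0)
BRANCH_BOUNDS = (1e-6, 20.0)
LNL_TOL = 1e-8


@dataclass
class BranchSiteParams:
    """Parameter vector of the branch-site Model A mixture."""

    kappa: float
    omega0: float
    omega2: float
    p0: float
    p1: float
    pi: CodonFrequencies

    def __post_init__(self) -> None:
        if not (0 < self.omega0 <= 1.0 + 1e-12):
            raise ValueError(f"omega0={self.omega0} outside (0, 1]")
        if self.omega2 < 1.0 - 1e-12:
            raise ValueError(f"omega2={self.omega2} must be >= 1")
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1 + 1e-12:
            raise ValueError("need p0, p1 >= 0 and p0 + p1 <= 1")
        if self.p0 + self.p1 <= 0:
            raise ValueError("p0 + p1 must be positive")

    @property
    def p2a(self) -> float:
        return (1.0 - self.p0 - self.p1) * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        return (1.0 - self.p0 - self.p1) * self.p1 / (self.p0 + self.p1)

    def weights(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2a, self.p2b])


@dataclass
class M0Fit:
    """One-ratio model optimum: kappa, omega, branch lengths, and lnL."""

    kappa: float
    omega: float
    lnL: float
    branch_lengths: list[float]
    tree: LabeledTree
    pi: CodonFrequencies


@dataclass
class GeneTestRecord:
    """Per-gene outcome of the branch-site LRT."""

    gene_id: str
    lnL_null: float
    lnL_alt: float
    lrt_stat: float
    p_value: float
    params_alt: BranchSiteParams
    params_null: BranchSiteParams
    n_sites: int
    n_taxa: int
    q_value: float | None = None
    alignment_method: str = "default"
    foreground_label: str = "#1"


# ---------------------------------------------------------------------------
# likelihood evaluation


class _QCache:
    """Memoized GY94 rate matrices for a fixed pi."""

    def __init__(self, pi: CodonFrequencies, maxsize: int = 256):
        self.pi = pi
        self._cache: dict[tuple[float, float], CodonRateMatrix] = {}
        self.maxsize = maxsize

    def get(self, kappa: float, omega: float) -> CodonRateMatrix:
        key = (round(kappa, 12), round(omega, 12))
        Q = self._cache.get(key)
        if Q is None:
            if len(self._cache) >= self.maxsize:
                self._cache.clear()
            Q = CodonRateMatrix(kappa=kappa, omega=omega, pi=self.pi)
            self._cache[key] = Q
        return Q


def m0_loglik(alignment: CodonAlignment, tree: LabeledTree, kappa: float,
              omega: float, pi: CodonFrequencies | None = None) -> float:
    """Total one-ratio log-likelihood at the tree's current branch lengths."""
    pi = pi or estimate_codon_frequencies(alignment)
    engine = PruningEngine(alignment, tree)
    Q = CodonRateMatrix(kappa=kappa, omega=omega, pi=pi)
    P = {id(n): Q.transition_matrix(n.length) for n in tree.branches()}
    return float(engine.site_loglik(lambda n: P[id(n)], pi.pi).sum())


def model_a_class_omegas(omega0: float, omega2: float
                         ) -> list[tuple[float, float]]:
    """(background, foreground) omega of each Model A class, in order."""
    return [(omega0, omega0), (1.0, 1.0), (omega0, omega2), (1.0, omega2)]


def model_a_scale_factors(kappa: float, omega0: float, omega2: float,
                          weights: np.ndarray, pi: CodonFrequencies
                          ) -> tuple[float, float]:
    """Mixture-average substitution rates for background and foreground
    branches.

    Site-class rate matrices are normalized by a common factor per branch
    type -- the class-proportion-weighted mean of the unscaled GY94 rates
    -- so a branch length stays the expected number of substitutions per
    codon averaged over classes while positively selected classes evolve
    faster than average.  Normalizing each class separately instead would
    erase the substitution-rate elevation that positive selection produces.
    """
    mus = {w: gy94_mean_rate(kappa, w, pi)
           for w in {omega0, 1.0, omega2}}
    pairs = model_a_class_omegas(omega0, omega2)
    f_bg = float(sum(w * mus[bg] for w, (bg, _) in zip(weights, pairs)))
    f_fg = float(sum(w * mus[fg] for w, (_, fg) in zip(weights, pairs)))
    return f_bg, f_fg


class ModelAEvaluator:
    """Cached per-class site log-likelihoods of Model A on a fixed tree.

    The four classes are pruned in one stacked pass (batched matmuls over
    a leading class axis); evaluations are memoized on the full parameter
    vector, which makes line-search re-evaluations and BEB grids cheap.
    """

    def __init__(self, alignment: CodonAlignment, tree: LabeledTree,
                 pi: CodonFrequencies):
        if not tree.foreground_branches():
            raise ValueError("Model A requires a non-empty foreground")
        self.engine = PruningEngine(alignment, tree)
        self.tree = tree
        self.branches = tree.branches()
        self.pi = pi
        self._ts = np.array([b.length for b in self.branches])
        self._fg = np.array([b.foreground for b in self.branches])
        self._index = {id(b): i for i, b in enumerate(self.branches)}
        self._qc = _QCache(pi)
        self._cache: dict[tuple, np.ndarray] = {}
        # when every foreground branch hangs off the root, the background
        # subtree work is shared between classes (0, 2a) and (1, 2b)
        fg_nodes = tree.foreground_branches()
        self._fg_at_root = (all(n.parent is tree.root for n in fg_nodes)
                            and any(not b.foreground for b in self.branches))

    def class_ll(self, kappa: float, omega0: float, omega2: float,
                 weights: np.ndarray | None = None,
                 scale_factors: tuple[float, float] | None = None
                 ) -> np.ndarray:
        """(4, n_sites) log-likelihood rows in class order 0, 1, 2a, 2b.

        Rate normalization uses the mixture-average factors derived from
        ``weights`` unless explicit ``scale_factors`` (background,
        foreground) are supplied -- the latter is how BEB holds the
        normalization at the MLE while it varies the grid parameters.
        """
        if scale_factors is None:
            if weights is None:
                raise ValueError("need weights or explicit scale_factors")
            scale_factors = model_a_scale_factors(kappa, omega0, omega2,
                                                  weights, self.pi)
        f_bg, f_fg = scale_factors
        key = tuple(round(v, 12) for v in
                    (kappa, omega0, omega2, f_bg, f_fg))
        out = self._cache.get(key)
        if out is not None:
            return out
        if len(self._cache) > 128:
            self._cache.clear()

        Q = {w: self._qc.get(kappa, w) for w in {omega0, 1.0, omega2}}
        mu = {w: Q[w].mean_rate for w in Q}
        pairs = model_a_class_omegas(omega0, omega2)
        if self._fg_at_root:
            out = self._class_ll_fg_at_root(Q, mu, pairs, f_bg, f_fg)
        else:
            out = self._class_ll_general(Q, mu, pairs, f_bg, f_fg)
        self._cache[key] = out
        return out

    def _class_ll_general(self, Q, mu, pairs, f_bg, f_fg) -> np.ndarray:
        B = len(self.branches)
        bg, fg = ~self._fg, self._fg
        # branch-major layout so each per-branch (4, 61, 61) slice is
        # contiguous for the batched matmuls
        P_all = np.empty((B, 4, 61, 61))
        built: dict[tuple[float, bool], np.ndarray] = {}
        for k, (w_bg, w_fg) in enumerate(pairs):
            for w, mask, is_fg in ((w_bg, bg, False), (w_fg, fg, True)):
                bkey = (w, is_fg)
                if bkey not in built:
                    f = f_fg if is_fg else f_bg
                    built[bkey] = Q[w].transition_matrices(
                        self._ts[mask] * (mu[w] / f))
                P_all[mask, k] = built[bkey]

        idx = self._index
        return self.engine.pattern_loglik_stack(
            lambda n: P_all[idx[id(n)]], self.pi.pi)

    def _class_ll_fg_at_root(self, Q, mu, pairs, f_bg, f_fg) -> np.ndarray:
        """Fast path: every foreground branch hangs off the root, so the
        background subtrees are identical between classes 0/2a (omega0
        background) and 1/2b (neutral background).  Prune those two stacks
        once and split into the four classes only at the root."""
        omega0 = pairs[0][0]
        bg_omegas = (omega0, 1.0)  # stack order: substack 0 -> classes 0/2a
        B = len(self.branches)
        P_bg = np.empty((B, 2, 61, 61))
        for s, w in enumerate(bg_omegas):
            P_bg[:, s] = Q[w].transition_matrices(
                self._ts * (mu[w] / f_bg))
        idx = self._index
        partials, logscale = self.engine.root_child_partials_stack(
            lambda n: P_bg[idx[id(n)]], self.pi.pi)

        root = self.tree.root
        out = np.empty((4, self.engine.n_patterns))
        for k, (w_bg, w_fg) in enumerate(pairs):
            sub = 0 if w_bg == omega0 else 1
            acc = None
            for c in root.children:
                pc = partials[id(c)]
                pc = pc if pc.ndim == 2 else pc[sub]
                if c.foreground:
                    P = Q[w_fg].transition_matrix(
                        c.length * (mu[w_fg] / f_fg))
                else:
                    P = P_bg[idx[id(c)], sub]
                M = P @ pc
                acc = M if acc is None else acc * M
            with np.errstate(divide="ignore"):
                out[k] = np.log(self.pi.pi @ acc) + logscale[sub]
        return out


def class_site_logliks(engine: PruningEngine, tree: LabeledTree, kappa: float,
                       omega0: float, omega2: float, pi: CodonFrequencies,
                       weights: np.ndarray | None = None,
                       scale_factors: tuple[float, float] | None = None
                       ) -> np.ndarray:
    """One-shot (4, n_sites) class log-likelihoods of Model A.

    ``engine`` must be bound to the same tree.  Normalization follows
    :func:`model_a_scale_factors`; equal class weights are assumed when
    neither weights nor explicit factors are given.
    """
    if scale_factors is None:
        w = np.full(4, 0.25) if weights is None else np.asarray(weights)
        scale_factors = model_a_scale_factors(kappa, omega0, omega2, w, pi)
    f_bg, f_fg = scale_factors
    qc = _QCache(pi)
    rows = []
    for w_bg, w_fg in model_a_class_omegas(omega0, omega2):
        Qb, Qf = qc.get(kappa, w_bg), qc.get(kappa, w_fg)
        P = {}
        for n in tree.branches():
            if n.foreground:
                P[id(n)] = Qf.transition_matrix(n.length * Qf.mean_rate / f_fg)
            else:
                P[id(n)] = Qb.transition_matrix(n.length * Qb.mean_rate / f_bg)
        rows.append(engine.site_loglik(lambda n: P[id(n)], pi.pi))
    return np.vstack(rows)


def _mix_loglik(class_ll: np.ndarray, weights: np.ndarray,
                column_weights: np.ndarray | None = None) -> float:
    """Total log-likelihood of the 4-class mixture given per-class column
    log-likelihoods; zero-weight classes are excluded from the logsumexp,
    and ``column_weights`` carries site-pattern multiplicities."""
    mask = weights > 0
    lw = np.log(weights[mask])
    mixed = logsumexp(class_ll[mask] + lw[:, None], axis=0)
    if column_weights is None:
        return float(mixed.sum())
    return float(mixed @ column_weights)


def branch_site_loglik(alignment: CodonAlignment, tree: LabeledTree,
                       params: BranchSiteParams) -> float:
    """Model A total log-likelihood at fixed parameters and branch lengths."""
    engine = PruningEngine(alignment, tree)
    cl = class_site_logliks(engine, tree, params.kappa, params.omega0,
                            params.omega2, params.pi,
                            weights=params.weights())
    return _mix_loglik(cl, params.weights())


# ---------------------------------------------------------------------------
# M0 fit


def fit_m0(alignment: CodonAlignment, tree: LabeledTree,
           pi: CodonFrequencies | None = None, kappa_init: float = 2.0,
           omega_init: float = 0.2, maxiter: int = 500) -> M0Fit:
    """Maximize the one-ratio likelihood over kappa, omega, and all branch
    lengths (bounded quasi-Newton in log space, analytic branch gradients).

    Branch lengths are initialized from the input tree where present
    (defaulting to 0.1), so a reasonable starting topology speeds things up
    but is not required.
    """
    if alignment.n_taxa < 2:
        raise ValueError("M0 fit needs at least 2 taxa")
    pi = pi or estimate_codon_frequencies(alignment)
    work = tree.copy()
    engine = PruningEngine(alignment, work)
    branches = work.branches()
    nb = len(branches)
    qc = _QCache(pi)

    t0 = np.array([b.length if b.length > 0 else 0.1 for b in branches])
    t0 = np.clip(t0, BRANCH_BOUNDS[0] * 10, BRANCH_BOUNDS[1] / 2)
    x0 = np.concatenate([[math.log(kappa_init), math.log(omega_init)],
                         np.log(t0)])
    bounds = ([tuple(np.log(KAPPA_BOUNDS)), (math.log(1e-4), math.log(50.0))]
              + [tuple(np.log(BRANCH_BOUNDS))] * nb)

    def lnl_at(kappa: float, omega: float, ts: np.ndarray,
               store: bool = False) -> tuple[float, dict]:
        Q = qc.get(kappa, omega)
        P = {id(n): Q.transition_matrix(t) for n, t in zip(branches, ts)}
        ll = engine.total_loglik(lambda n: P[id(n)], pi.pi, store=store)
        return ll, P

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        kappa, omega = math.exp(x[0]), math.exp(x[1])
        ts = np.exp(x[2:])
        base, P = lnl_at(kappa, omega, ts, store=True)
        grad = np.empty_like(x)
        # analytic branch-length gradients via the cached pruning pass
        Q = qc.get(kappa, omega)
        P_of = lambda n: P[id(n)]
        for k, (node, t) in enumerate(zip(branches, ts)):
            g = engine.branch_gradient(node, Q.dP_dt(t), P_of, pi.pi)
            grad[2 + k] = g * t  # chain rule for log-length coordinates
        # central differences for the two substitution parameters
        h = 1e-5
        for k in range(2):
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            fp, _ = lnl_at(math.exp(xp[0]), math.exp(xp[1]), np.exp(xp[2:]))
            fm, _ = lnl_at(math.exp(xm[0]), math.exp(xm[1]), np.exp(xm[2:]))
            grad[k] = (fp - fm) / (2 * h)
        return -base, -grad

    res = minimize(objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-6})
    kappa, omega = math.exp(res.x[0]), math.exp(res.x[1])
    ts = np.exp(res.x[2:])
    lnl, _ = lnl_at(kappa, omega, ts)
    fitted = work
    fitted.set_branch_lengths(list(ts))
    return M0Fit(kappa=kappa, omega=omega, lnL=lnl,
                 branch_lengths=list(map(float, ts)), tree=fitted, pi=pi)


# ---------------------------------------------------------------------------
# branch-site fit

_ALT_STARTS = [
    # (kappa, p0, p1, omega0, omega2)
    (2.0, 0.85, 0.10, 0.20, 3.0),
    (2.0, 0.50, 0.40, 0.05, 1.5),
    (1.0, 0.70, 0.25, 0.50, 8.0),
]


def fit_branch_site(alignment: CodonAlignment, tree_with_lengths: LabeledTree,
                    null: bool = False, pi: CodonFrequencies | None = None,
                    n_starts: int = 3, maxiter: int = 300,
                    evaluator: "ModelAEvaluator | None" = None,
                    initial: "BranchSiteParams | None" = None
                    ) -> tuple[BranchSiteParams, float]:
    """Fit branch-site Model A at fixed branch lengths.

    With ``null=True`` omega2 is pinned at 1 (the test-2 null); otherwise
    omega2 >= 1 is free.  Multiple deterministic starts guard against the
    local optima this mixture is known for; the best optimum wins.  Passing
    the same ``evaluator`` to the null and alternative fits shares their
    likelihood caches.
    """
    if not tree_with_lengths.foreground_branches():
        raise ValueError("branch-site fit requires a non-empty foreground")
    pi = pi or estimate_codon_frequencies(alignment)
    ev = evaluator or ModelAEvaluator(alignment, tree_with_lengths, pi)
    class_ll = ev.class_ll

    def decode(x: np.ndarray) -> tuple[float, float, float, float, float]:
        kappa = math.exp(x[0])
        p01 = expit(x[1])
        r = expit(x[2])
        p0, p1 = p01 * r, p01 * (1 - r)
        omega0 = math.exp(x[3])
        omega2 = 1.0 if null else 1.0 + math.exp(x[4])
        return kappa, p0, p1, omega0, omega2

    def objective(x: np.ndarray) -> float:
        kappa, p0, p1, omega0, omega2 = decode(x)
        w = BranchSiteParams(kappa=kappa, omega0=omega0, omega2=omega2,
                             p0=p0, p1=p1, pi=pi).weights()
        return -_mix_loglik(class_ll(kappa, omega0, omega2, weights=w), w,
                            ev.engine.pattern_weights)

    nfree = 4 if null else 5
    bounds = [tuple(np.log(KAPPA_BOUNDS)), (-12.0, 12.0), (-12.0, 12.0),
              (math.log(OMEGA0_BOUNDS[0]), 0.0)]
    if not null:
        bounds.append((math.log(1e-6), math.log(OMEGA2_BOUNDS[1] - 1.0)))

    starts = []
    if initial is not None:
        starts.append((initial.kappa, max(initial.p0, 1e-4),
                       max(initial.p1, 1e-4), initial.omega0,
                       max(initial.omega2, 1.5)))
    starts.extend(_ALT_STARTS)
    best = None
    for kappa0, p0s, p1s, w0s, w2s in starts[:max(1, n_starts)]:
        p01 = min(p0s + p1s, 1 - 1e-9)
        x0 = [math.log(kappa0), logit(p01), logit(p0s / p01), math.log(w0s)]
        if not null:
            x0.append(math.log(w2s - 1.0))
        x0 = np.clip(np.array(x0[:nfree]),
                     [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    kappa, p0, p1, omega0, omega2 = decode(best.x)
    params = BranchSiteParams(kappa=kappa, omega0=omega0, omega2=omega2,
                              p0=p0, p1=p1, pi=pi)
    return params, -float(best.fun)


# ---------------------------------------------------------------------------
# test statistics


def lrt(lnL_null: float, lnL_alt: float,
        boundary_mixture: bool = False) -> tuple[float, float]:
    """Likelihood-ratio statistic and p-value against chi-square df=1.

    The statistic is clamped at 0 (optimizer noise can leave the nested
    null a hair above the alternative).  ``boundary_mixture`` switches to
    the 50:50 point-mass/chi2_1 reference sometimes recommended for
    boundary tests; the plain chi2_1 reference is the default.
    """
    if not (np.isfinite(lnL_null) and np.isfinite(lnL_alt)):
        raise ValueError("log-likelihoods must be finite")
    stat = max(0.0, 2.0 * (lnL_alt - lnL_null))
    p = float(chi2.sf(stat, df=1))
    if boundary_mixture:
        p = 0.5 * p if stat > 0 else 1.0
    return stat, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def consensus(results_by_method: dict[str, list[GeneTestRecord]],
              alpha: float = 0.05, use_q: bool = True) -> set[str]:
    """Genes significant under every alignment method (intersection rule)."""
    if not results_by_method:
        raise ValueError("need at least one method")
    sets = []
    for recs in results_by_method.values():
        keep = set()
        for r in recs:
            val = r.q_value if use_q else r.p_value
            if val is not None and val < alpha:
                keep.add(r.gene_id)
        sets.append(keep)
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def run_gene_test(alignment: CodonAlignment, tree: LabeledTree,
                  gene_id: str = "gene", pi: CodonFrequencies | None = None,
                  n_starts: int = 3, fixed_lengths: bool = False
                  ) -> GeneTestRecord:
    """Two-step branch-site test for one gene.

    M0 estimates branch lengths (unless ``fixed_lengths`` says the input
    tree already carries them), which are then frozen for both Model A
    fits; the LRT compares the two.
    """
    pi = pi or estimate_codon_frequencies(alignment)
    if fixed_lengths:
        fitted_tree = tree.copy()
    else:
        fitted_tree = fit_m0(alignment, tree, pi=pi).tree
    ev = ModelAEvaluator(alignment, fitted_tree, pi)
    params_null, lnl_null = fit_branch_site(alignment, fitted_tree, null=True,
                                            pi=pi, n_starts=n_starts,
                                            evaluator=ev)
    params_alt, lnl_alt = fit_branch_site(alignment, fitted_tree, null=False,
                                          pi=pi, n_starts=n_starts,
                                          evaluator=ev, initial=params_null)
    # nested models: never let the alternative sit below the null
    if lnl_alt < lnl_null:
        alt_at_null = BranchSiteParams(
            kappa=params_null.kappa, omega0=params_null.omega0, omega2=1.0,
            p0=params_null.p0, p1=params_null.p1, pi=pi)
        params_alt, lnl_alt = alt_at_null, lnl_null
    stat, p = lrt(lnl_null, lnl_alt)
    return GeneTestRecord(gene_id=gene_id, lnL_null=lnl_null, lnL_alt=lnl_alt,
                          lrt_stat=stat, p_value=p, params_alt=params_alt,
                          params_null=params_null, n_sites=alignment.n_sites,
                          n_taxa=alignment.n_taxa)
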