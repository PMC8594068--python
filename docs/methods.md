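# Methods

## Codon substitution model

All coding-arm computations use the Goldman–Yang codon model over the 61
sense codons of the standard genetic code, indexed lexicographically
(A < C < G < T). The instantaneous rate from codon *i* to *j* is

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous]     (single-nt changes)
    q_ij = 0                                            (multi-nt changes)

with empirical codon-table equilibrium frequencies π (the F61-style
estimator: observed codon counts across all taxa and sites plus a
pseudocount, default 1e-6, which keeps the chain irreducible when short
genes leave codons unobserved). A single-ω matrix is rescaled to mean rate
1 at equilibrium, so branch lengths are expected substitutions per codon.
Transition probabilities exp(Qt) come from the symmetric eigendecomposition
of Π^½QΠ^−½ (the chain is reversible); one decomposition serves every
branch length, and the same factorization yields exact branch-length
derivatives dP/dt for the M0 optimizer.

### Rate normalization in the branch-site mixture

In mixture models the normalization convention is substantive. Normalizing
each site class separately would equalize the total substitution rate of
all classes and erase the *rate elevation* that positive selection
produces, leaving only the syn/nonsyn composition shift — the test then
has almost no power. `hlscan` therefore rescales all four Model A classes
by a common factor per branch type: the class-proportion-weighted mean of
the unscaled class rates, computed separately for background and
foreground branches (`model_a_scale_factors`). A branch length remains the
expected number of substitutions per codon averaged over site classes,
while positively selected sites evolve faster than that average on the
foreground. The simulator and the likelihood evaluator share one
implementation of this convention, so simulation-based tests probe the
statistics, not bookkeeping mismatches.

## Two-step optimization

Following the screening design, each gene is fit in two steps:

1. **M0 (one-ratio).** κ, ω, and all branch lengths are maximized jointly
   by bounded L-BFGS in log space. Branch-length gradients are analytic
   (cached pruning messages re-propagated along the root path with dP/dt);
   κ and ω use central differences. Bounds: κ ∈ [0.01, 100],
   ω ∈ [1e-4, 50], t ∈ [1e-6, 20]. M0 is single-start: its surface is
   unimodal in practice, and the multi-start machinery is reserved for the
   mixture fits, which are the documented source of local optima.
2. **Branch-site Model A.** Branch lengths are frozen at the M0 optimum.
   Free parameters are κ, ω₀ ∈ (0, 1], the simplex pair (p₀, p₁) via
   logits, and (for the alternative) ω₂ ∈ [1, 50] via log(ω₂−1). Three
   fixed deterministic starts by default, best optimum retained; the
   alternative fit is additionally warm-started from the null optimum,
   which both accelerates convergence and protects the nesting invariant
   lnL_alt ≥ lnL_null. Convergence tolerance is 1e-8 on the
   log-likelihood scale; the LRT statistic is clamped at 0.

The LRT is referred to χ²₁ as in the screening (the 50:50 point-mass/χ²₁
boundary mixture is available behind `lrt(..., boundary_mixture=True)` but
off by default, so p-values are conservative at the ω₂ = 1 boundary).
BH-FDR is the statsmodels step-up; the cross-alignment-method consensus is
the intersection of genes significant under every method.

## Likelihood engine

Felsenstein pruning over the 61 codon states with per-column max-scaling
accumulated in log space. Gaps are fully missing data (all-ones partial);
IUPAC-ambiguous codons contribute an indicator over their compatible sense
codons; terminal stop columns are stripped at read time and internal stops
are hard errors (the model has no stop state). Identical alignment columns
are collapsed into unique site patterns with multiplicities. The four
Model A classes are pruned in one stacked (batched-matmul) pass; when every
foreground branch hangs off the root — the usual basal-lineage labeling —
the background subtrees are shared between classes (0, 2a) and (1, 2b) and
the four classes are split only at the root.

## BEB site posteriors

After a significant test, each codon site receives the posterior
probability of belonging to classes 2a+2b, averaged over a uniform grid on
(p₀, p₁, ω₀, ω₂) with equal prior mass per cell: ω₀ on (0,1), ω₂ on
(1,11), and the (p₀, p₁) simplex restricted to p₀+p₁ ≤ 1; 10 points per
axis by default (tests use 4 or fewer). κ, branch lengths, and the
mixture-rate normalization factors are held at their MLEs. The posterior
for class k at site s is

    P(k | x_s) ∝ Σ_θ prior(θ) · w_k(θ) · L(x_s | class k, θ)

normalized over k — each site integrated independently against the grid
prior. (The canonical BEB additionally reweights grid cells by the
whole-alignment likelihood; the site-independent average is this package's
documented contract, checked against an exhaustive-summation oracle, and
collapses to the naive empirical-Bayes posterior when the grid is a single
MLE point.) PSS calls use posterior > 0.95 by default and are reported in
1-based codon coordinates of a configurable reference taxon, skipping the
reference's gap columns.

## Noncoding arm

Coordinates are 0-based half-open everywhere (BED convention); one
overlapping base counts, with an optional minimum-overlap fraction.
Regulatory domains follow the basal-plus-extension rule: a strand-aware
basal window (defaults 5 kb upstream / 1 kb downstream of the TSS, the
GREAT defaults) assigned regardless of neighbors, then extended on each
side to the nearest other gene's basal boundary, capped at 1 Mb from the
TSS and clipped at chromosome bounds. TAD assignment is permissive
any-base membership: a region is tied to every gene whose TSS shares a TAD
with any base of the region. Region strand is ignored. All interval
operations are validated against per-base brute-force oracles.

## Synthetic data

The generators emulate the study's raw inputs at desk scale and emit
machine-readable truth:

- **Alignments** evolve site by site along the tree by exact draws from
  exp(Qt) (no Gillespie discretization), with Model A site classes drawn
  from (p₀, p₁, p₂ₐ, p₂ᵦ) and the mixture-average rate normalization
  described above. Deterministic under the seed, byte-identical outputs.
- **Default tree**: a 14-species mammalian roster (4 primates, 3 glires,
  5 laurasiatherians, elephant, opossum) with branch lengths in
  [0.01, 0.5]. Both root-flanking branches carry the foreground mark, so
  the foreground is the full unrooted basal edge between the placental
  ancestor and the opossum lineage (total length 0.75) — the faithful
  reading of a basal-lineage label on an unrooted tree. Power against the
  planted ω₂ = 4 / 10%-of-sites signal at 500 codons is ~60–85% at
  α = 0.05; with a short (0.1) internal foreground branch the same test
  has almost no power, consistent with published branch-site power
  studies.
- **Ortholog tables** plant exact numbers of genes that fail each filter:
  ≥2 missing species without same-taxon rescue, one-to-many orthology,
  absence from the reference genome, and substitutable single-species
  gaps that a same-taxon pool donor fills.
- **Annotations** lay genes 4 Mb apart (3 exons each, a 3 Mb TAD around
  each gene) and plant five region categories — exon-overlapping,
  intronic, basal-domain-proximal, TAD-only-distal, and fully outside —
  whose intended classification under the default domain parameters is
  recorded in the truth table. Infeasible planted counts raise.

What the synthetic data do **not** model: indels and alignment error (the
dual-aligner robustness check is represented only by the consensus
operation over externally supplied alignment variants), selection on
synonymous codon usage, rate variation beyond the Model A classes, and
lineage-specific codon frequencies. Passing tests therefore demonstrate
the statistical machinery under the model's own assumptions, not
robustness to real-data misalignment.

## Problem sizes and numerical choices

The statistical test suite uses: parameter recovery on 20 alignments of
500 codons × 14 taxa (median κ̂ within ±20%, median ω̂ within ±15%);
type-I-error calibration on 200 null replicates of 200 codons × 8 taxa
with branch lengths fixed at their generating values and single-start
fits (both choices conservative for the upper-bound assertion being made:
the rejection count must not exceed the exact binomial 97.5% envelope of
the nominal 5%); power on 8 replicates of 500 codons with the full
two-step pipeline. Enumeration oracles cover all tree sizes up to 5 taxa
at 1e-8 agreement; BEB and FDR oracles are exact to 1e-10 and 1e-12.

Degenerate inputs: empty foregrounds, single-taxon fits, infeasible
planted counts, zero-length intervals, out-of-range probabilities and
malformed files raise typed errors with the offending record named;
all-gap sites have likelihood 1; identical sequences drive branch-length
estimates to the lower bound.

## Known limitations

- The foreground is whatever the input tree labels; no automatic
  unrooted-edge canonicalization is attempted beyond the default tree's
  convention.
- χ²₁ calibration is conservative at the boundary; exact size is not
  targeted.
- The BEB grid dimensionality (4 parameters) and the site-independent
  grid average are documented choices, not attempts to byte-match any
  particular external implementation.
- Per-gene parallelism is not implemented; runs are serial and therefore
  trivially reproducible.
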