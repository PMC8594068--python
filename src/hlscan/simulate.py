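"""Synthetic study inputs with machine-readable ground truth.

Three generators stand in for the screening's raw data: codon alignments
evolved along a labeled species tree under the one-ratio or branch-site
models, Ensembl-style ortholog tables with planted filtering defects, and
genome annotations (genes, accelerated regions, TADs) with planted
overlap structure.  Every generator is fully deterministic under its seed
and returns the planted truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .catalog import GeneList, OrthologTable, OrthologyStatus
from .codon_model import CodonFrequencies, CodonRateMatrix
from .intervals import GenomicInterval, TranscriptionalUnit
from .regions import AcceleratedRegion, Lineage, TadSet
from .selection import (BranchSiteParams, model_a_class_omegas,
                        model_a_scale_factors)
from .tree import LabeledTree, parse_newick


class Model(str, Enum):
    M0 = "M0"
    MODEL_A = "MODEL_A"
    MODEL_A_NULL = "MODEL_A_NULL"


@dataclass
class M0Params:
    kappa: float
    omega: float
    pi: CodonFrequencies


@dataclass
class SimulationTruth:
    model: Model
    params: object
    site_classes: np.ndarray | None
    seed: int


#: 14-species caricature of a mammalian screening roster; the branch into
#: the placental clade is the foreground lineage.
DEFAULT_TREE_NEWICK = (
    "((((((("
    "human:0.02,chimp:0.02):0.01,gorilla:0.03):0.02,macaque:0.06):0.05,"
    "((mouse:0.12,rat:0.12):0.18,rabbit:0.18):0.05):0.02,"
    "(((dog:0.08,cat:0.08):0.04,horse:0.10):0.01,"
    "(cow:0.12,pig:0.12):0.02):0.04):0.03,"
    "elephant:0.16):0.4 #1,opossum:0.35 #1);"
)

DEFAULT_ROSTER = {
    "human": "primates", "chimp": "primates", "gorilla": "primates",
    "macaque": "primates", "mouse": "glires", "rat": "glires",
    "rabbit": "glires", "dog": "laurasiatheria", "cat": "laurasiatheria",
    "horse": "laurasiatheria", "cow": "laurasiatheria",
    "pig": "laurasiatheria", "elephant": "afrotheria",
    "opossum": "marsupialia",
}

DEFAULT_POOL = {
    "orangutan": "primates", "hamster": "glires", "goat": "laurasiatheria",
    "manatee": "afrotheria", "wallaby": "marsupialia",
}


def default_tree() -> LabeledTree:
    return parse_newick(DEFAULT_TREE_NEWICK)


# ---------------------------------------------------------------------------
# codon alignments


def _sample_children(parent_states: np.ndarray, P: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Vectorized categorical draw of child states given parent states."""
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parent_states.shape[0])
    return (cum[parent_states] < u[:, None]).sum(axis=1)


def simulate_alignment(tree: LabeledTree, model: Model | str, params,
                       n_sites: int, seed: int
                       ) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve a codon alignment along ``tree`` under the given model.

    Sites draw their class from the Model A proportions (all one class for
    M0), the root codon comes from the stationary distribution, and each
    branch transition is an exact draw from exp(Qt) for the class- and
    branch-appropriate (omega, t) -- no Gillespie discretization.
    """
    model = Model(model)
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)

    if model == Model.M0:
        if not isinstance(params, M0Params):
            raise TypeError("M0 simulation needs M0Params")
        pi = params.pi
        classes = np.zeros(n_sites, dtype=np.int64)
        # class omega pairs (background, foreground); single class for M0
        class_omegas = [(params.omega, params.omega)]
        kappa = params.kappa
        scale = None  # single class: the normalized matrix is exact
    else:
        if not isinstance(params, BranchSiteParams):
            raise TypeError("Model A simulation needs BranchSiteParams")
        if model == Model.MODEL_A_NULL and abs(params.omega2 - 1.0) > 1e-12:
            raise ValueError("MODEL_A_NULL requires omega2 == 1")
        pi = params.pi
        w = params.weights()
        classes = rng.choice(4, size=n_sites, p=w / w.sum())
        class_omegas = model_a_class_omegas(params.omega0, params.omega2)
        kappa = params.kappa
        # same mixture-average rate normalization the likelihood uses
        scale = model_a_scale_factors(kappa, params.omega0, params.omega2,
                                      w, pi)

    q_cache: dict[float, CodonRateMatrix] = {}

    def Q_of(omega: float) -> CodonRateMatrix:
        if omega not in q_cache:
            q_cache[omega] = CodonRateMatrix(kappa=kappa, omega=omega, pi=pi)
        return q_cache[omega]

    def branch_time(Q: CodonRateMatrix, t: float, foreground: bool) -> float:
        if scale is None:
            return t
        f = scale[1] if foreground else scale[0]
        return t * Q.mean_rate / f

    cum_pi = np.cumsum(pi.pi)
    cum_pi[-1] = 1.0
    root_states = (cum_pi < rng.random(n_sites)[:, None]).sum(axis=1)

    states = {id(tree.root): root_states}
    order = [n for n in reversed(tree.postorder())]  # preorder
    for node in order:
        if node.parent is None:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(n_sites, dtype=np.int64)
        for k, (bg_w, fg_w) in enumerate(class_omegas):
            mask = classes == k
            if not mask.any():
                continue
            omega = fg_w if node.foreground else bg_w
            Q = Q_of(omega)
            P = Q.transition_matrix(
                branch_time(Q, node.length, node.foreground))
            child[mask] = _sample_children(parent_states[mask], P, rng)
        states[id(node)] = child

    leaves = tree.leaves()
    sites = np.vstack([states[id(n)] for n in leaves])
    aln = CodonAlignment(taxa=[n.name for n in leaves], sites=sites)
    truth = SimulationTruth(model=model, params=params,
                            site_classes=classes, seed=seed)
    return aln, truth


# ---------------------------------------------------------------------------
# ortholog tables


def simulate_ortholog_table(
    n_genes: int,
    species_roster: dict[str, str] | None = None,
    planted_missing: int = 0,
    planted_multi: int = 0,
    planted_noref: int = 0,
    planted_substitutable: int = 0,
    seed: int = 0,
) -> tuple[OrthologTable, GeneList, pd.DataFrame]:
    """Ortholog table in which exactly the planted numbers of genes fail
    each filter.

    ``planted_missing`` genes lack orthologs in two roster species with no
    same-taxon rescue; ``planted_multi`` genes have a one-to-many species;
    ``planted_noref`` genes are absent from the reference genome;
    ``planted_substitutable`` genes have one missing species that a
    same-taxon pool donor fills, so they remain analyzable.
    """
    roster = dict(species_roster or DEFAULT_ROSTER)
    pool = dict(DEFAULT_POOL)
    n_planted = (planted_missing + planted_multi + planted_noref
                 + planted_substitutable)
    if n_planted > n_genes:
        raise ValueError("planted counts exceed n_genes")
    if planted_missing and len(roster) < 2:
        raise ValueError("need >= 2 roster species to plant missing genes")
    rng = np.random.default_rng(seed)
    genes = [f"HLG{i:04d}" for i in range(1, n_genes + 1)]
    shuffled = list(genes)
    rng.shuffle(shuffled)
    it = iter(shuffled)
    missing_genes = [next(it) for _ in range(planted_missing)]
    multi_genes = [next(it) for _ in range(planted_multi)]
    noref_genes = [next(it) for _ in range(planted_noref)]
    subst_genes = [next(it) for _ in range(planted_substitutable)]

    species = sorted(roster)
    status: dict[tuple[str, str], OrthologyStatus] = {}
    pool_status: dict[tuple[str, str], OrthologyStatus] = {}
    for g in genes:
        for sp in species:
            status[(g, sp)] = OrthologyStatus.ONE2ONE
        for sp in pool:
            pool_status[(g, sp)] = OrthologyStatus.ONE2ONE
    truth_rows = [{"gene": g, "planted": "clean"} for g in genes]
    truth = {r["gene"]: r for r in truth_rows}

    for g in missing_genes:
        drop = [species[i] for i in rng.choice(len(species), 2, replace=False)]
        for sp in drop:
            status[(g, sp)] = OrthologyStatus.MISSING
            for donor, grp in pool.items():
                if grp == roster[sp]:
                    pool_status[(g, donor)] = OrthologyStatus.MISSING
        truth[g]["planted"] = "missing"
    for g in multi_genes:
        sp = species[int(rng.integers(len(species)))]
        status[(g, sp)] = OrthologyStatus.ONE2MANY
        truth[g]["planted"] = "multi"
    for g in noref_genes:
        truth[g]["planted"] = "noref"
    for g in subst_genes:
        sp = species[int(rng.integers(len(species)))]
        status[(g, sp)] = OrthologyStatus.MISSING
        # same-taxon donors stay ONE2ONE, so substitution rescues the gene
        truth[g]["planted"] = "substitutable"

    table = OrthologTable(status=status, roster=roster,
                          no_reference=frozenset(noref_genes), pool=pool,
                          pool_status=pool_status)
    gene_list = GeneList(name="synthetic", genes=frozenset(genes))
    return table, gene_list, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# genome annotation

_SPACING = 4_000_000
_BODY_LEN = 20_000
_EXON_LEN = 400
_EXON_OFFSETS = (0, 9_800, _BODY_LEN - _EXON_LEN)

#: Region categories and the assignments they are constructed to receive
#: under the default regulatory-domain parameters (5 kb up / 1 kb down,
#: 1 Mb maximum extension).
PLANTED_CATEGORIES = ("coding", "intronic", "proximal", "distal_tad", "outside")

_CAPACITY = {"coding": 3, "intronic": 25, "proximal": 10,
             "distal_tad": 100, "outside": 100}


def simulate_annotation(
    n_genes: int,
    planted: dict[str, int],
    n_tads: int | None = None,
    chrom_length: int | None = None,
    seed: int = 0,
    chrom: str = "chrS",
    lineage: Lineage = Lineage.MAMMAL_TSAR,
) -> tuple[list[TranscriptionalUnit], list[AcceleratedRegion], TadSet,
           pd.DataFrame]:
    """Gene bodies, accelerated regions, and TADs with planted overlaps.

    Genes are laid out 4 Mb apart on one chromosome, each with three exons
    and a 3 Mb TAD around it.  Planted region categories (round-robin over
    genes): ``coding`` overlaps an exon; ``intronic`` sits inside the gene
    body between exons; ``proximal`` falls in the basal regulatory domain
    upstream of the TSS; ``distal_tad`` is inside the gene's TAD but beyond
    the 1 Mb regulatory-domain cap; ``outside`` touches nothing.  The truth
    table records each region's category and target gene.
    """
    unknown = set(planted) - set(PLANTED_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown planted categories: {sorted(unknown)}")
    if n_genes < 1:
        raise ValueError("need at least one gene")
    n_tads = n_genes if n_tads is None else n_tads
    if not (0 <= n_tads <= n_genes):
        raise ValueError("n_tads must be between 0 and n_genes")
    need_len = n_genes * _SPACING
    if chrom_length is None:
        chrom_length = need_len
    if chrom_length < need_len:
        raise ValueError(
            f"chrom_length {chrom_length} too small for {n_genes} genes "
            f"(need {need_len})"
        )
    for cat, count in planted.items():
        pool = n_tads if cat == "distal_tad" else n_genes
        if pool == 0 and count > 0:
            raise ValueError(f"cannot plant {cat} regions without TADs")
        if pool and count > _CAPACITY[cat] * pool:
            raise ValueError(f"planted {cat} count {count} exceeds geometry")

    rng = np.random.default_rng(seed)
    units, tad_ivs = [], []
    for i in range(n_genes):
        base = i * _SPACING
        body = GenomicInterval(chrom, base + 1_000_000,
                               base + 1_000_000 + _BODY_LEN)
        exons = [GenomicInterval(chrom, body.start + off,
                                 body.start + off + _EXON_LEN)
                 for off in _EXON_OFFSETS]
        units.append(TranscriptionalUnit(gene_id=f"G{i:03d}", body=body,
                                         strand="+", exons=exons))
        if i < n_tads:
            tad_ivs.append(GenomicInterval(chrom, base + 500_000,
                                           base + 3_500_000,
                                           id=f"TAD{i:03d}"))

    regions: list[AcceleratedRegion] = []
    truth_rows = []
    counter = 0
    per_gene_idx: dict[tuple[str, int], int] = {}
    for cat in PLANTED_CATEGORIES:
        for _ in range(planted.get(cat, 0)):
            pool = n_tads if cat == "distal_tad" else n_genes
            g = counter % pool
            idx = per_gene_idx.get((cat, g), 0)
            per_gene_idx[(cat, g)] = idx + 1
            u = units[g]
            tss = u.tss
            if cat == "coding":
                ex = u.exons[idx % len(u.exons)]
                start = ex.start - 50 + int(rng.integers(0, 40))
                length = 200
            elif cat == "intronic":
                start = (u.body.start + 600 + idx * 320
                         + int(rng.integers(0, 40)))
                length = 150
            elif cat == "proximal":
                start = tss - 4_800 + idx * 420 + int(rng.integers(0, 40))
                length = 200
            elif cat == "distal_tad":
                start = tss + 1_500_000 + idx * 2_000 + int(rng.integers(0, 400))
                length = 400
            else:  # outside
                start = (g * _SPACING + 3_600_000 + idx * 2_000
                         + int(rng.integers(0, 400)))
                length = 300
            counter += 1
            rid = f"AR{counter:04d}"
            regions.append(AcceleratedRegion(
                interval=GenomicInterval(chrom, start, start + length, id=rid),
                lineage=lineage,
            ))
            truth_rows.append({"region_id": rid, "category": cat,
                               "gene": u.gene_id if cat != "outside" else ""})
    tads = TadSet(tads=tad_ivs)
    return units, regions, tads, pd.DataFrame(truth_rows)
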