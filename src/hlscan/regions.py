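"""Accelerated-region classification and gene assignment.

Conserved elements with accelerated substitution rates (mammal-lineage
TSARs or human-lineage HARs) are first split into coding vs noncoding by
exon overlap, then tied to candidate genes three ways of increasing reach:
direct gene-body (transcriptional-unit) overlap, GREAT-style regulatory
domains around the TSS, and shared topologically associating domains
(TADs).  All coordinates are 0-based half-open; one overlapping base
counts, unless a minimum overlap fraction is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, TranscriptionalUnit


class Lineage(str, Enum):
    MAMMAL_TSAR = "MAMMAL_TSAR"
    HUMAN_HAR = "HUMAN_HAR"


class CodingClass(str, Enum):
    CODING = "CODING"
    NONCODING = "NONCODING"
    UNSET = "UNSET"


class AssignmentMode(str, Enum):
    GENE_BODY = "GENE_BODY"
    REG_DOMAIN = "REG_DOMAIN"
    TAD = "TAD"


@dataclass
class AcceleratedRegion:
    interval: GenomicInterval
    lineage: Lineage = Lineage.MAMMAL_TSAR
    coding_class: CodingClass = CodingClass.UNSET
    assigned_genes: dict[AssignmentMode, set[str]] = field(default_factory=dict)

    @property
    def id(self) -> str:
        iv = self.interval
        return iv.id or f"{iv.chrom}:{iv.start}-{iv.end}"

    def genes(self, mode: AssignmentMode) -> set[str]:
        return self.assigned_genes.get(mode, set())


@dataclass
class RegulatoryDomain:
    """GREAT-style basal-plus-extension domain of one gene."""

    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval

    def __post_init__(self) -> None:
        if not (self.extended.start <= self.basal.start
                and self.basal.end <= self.extended.end):
            raise ValueError(f"gene {self.gene_id}: basal not inside extended")


@dataclass
class TadSet:
    """Disjoint topologically-associating-domain intervals per chromosome."""

    tads: list[GenomicInterval]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for t in self.tads:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise ValueError(
                        f"overlapping TADs on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )
        self._by_chrom = by_chrom

    def covering(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """TADs overlapping [start, end) on chrom."""
        return [t for t in self._by_chrom.get(chrom, [])
                if t.start < end and start < t.end]

    def containing_point(self, chrom: str, pos: int) -> GenomicInterval | None:
        for t in self._by_chrom.get(chrom, []):
            if t.start <= pos < t.end:
                return t
        return None


def _tree_by_chrom(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv, payload in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
    return trees


def _merged_len(segs: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open segments."""
    covered, cur_s, cur_e = 0, None, None
    for s, e in sorted(segs):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def classify_coding(regions: list[AcceleratedRegion],
                    units: list[TranscriptionalUnit],
                    min_fraction: float = 0.0) -> list[AcceleratedRegion]:
    """Set coding_class on every region by exon overlap.

    A region is CODING iff it overlaps at least one exon by >= 1 base
    (or by more than ``min_fraction`` of its own length when that is set).
    """
    exon_trees = _tree_by_chrom(
        (ex, u.gene_id) for u in units for ex in u.exons
    )
    for region in regions:
        iv = region.interval
        tree = exon_trees.get(iv.chrom)
        hits = tree.overlap(iv.start, iv.end) if tree else set()
        if not hits:
            region.coding_class = CodingClass.NONCODING
            continue
        if min_fraction > 0:
            segs = [(max(h.begin, iv.start), min(h.end, iv.end)) for h in hits]
            frac = _merged_len(segs) / len(iv)
            region.coding_class = (CodingClass.CODING if frac >= min_fraction
                                   else CodingClass.NONCODING)
        else:
            region.coding_class = CodingClass.CODING
    return regions


def assign_gene_body(regions: list[AcceleratedRegion],
                     units: list[TranscriptionalUnit],
                     noncoding_only: bool = False) -> list[AcceleratedRegion]:
    """Assign each region to every gene whose transcriptional unit it
    overlaps; with ``noncoding_only`` the overlap must include at least one
    body base outside every exon of that gene."""
    unit_by_id = {u.gene_id: u for u in units}
    body_trees = _tree_by_chrom((u.body, u.gene_id) for u in units)
    for region in regions:
        iv = region.interval
        tree = body_trees.get(iv.chrom)
        hits = tree.overlap(iv.start, iv.end) if tree else set()
        assigned = set()
        for h in hits:
            gid = h.data
            if not noncoding_only:
                assigned.add(gid)
                continue
            u = unit_by_id[gid]
            seg_s, seg_e = max(h.begin, iv.start), min(h.end, iv.end)
            covered = _merged_len(
                [(max(ex.start, seg_s), min(ex.end, seg_e))
                 for ex in u.exons if ex.start < seg_e and seg_s < ex.end]
            )
            if (seg_e - seg_s) > covered:
                assigned.add(gid)
        region.assigned_genes.setdefault(AssignmentMode.GENE_BODY,
                                         set()).update(assigned)
    return regions


def build_regulatory_domains(units: list[TranscriptionalUnit],
                             basal_up: int = 5000, basal_down: int = 1000,
                             max_extension: int = 1_000_000,
                             chrom_sizes: dict[str, int] | None = None
                             ) -> list[RegulatoryDomain]:
    """GREAT basal-plus-extension rule.

    Each gene gets a strand-aware basal window around its TSS regardless of
    neighbors; the extended domain then grows on each side to the nearest
    other gene's basal boundary, capped at ``max_extension`` from the TSS
    and clipped at chromosome bounds.
    """
    if min(basal_up, basal_down, max_extension) < 0:
        raise ValueError("domain distances must be >= 0")
    basals = {}
    for u in units:
        tss = u.tss
        if u.strand == "+":
            s, e = tss - basal_up, tss + basal_down
        else:
            s, e = tss - basal_down + 1, tss + basal_up + 1
        basals[u.gene_id] = (max(0, s), max(e, max(0, s) + 1))
    out = []
    by_chrom: dict[str, list[TranscriptionalUnit]] = {}
    for u in units:
        by_chrom.setdefault(u.body.chrom, []).append(u)
    for u in units:
        chrom = u.body.chrom
        tss = u.tss
        bs, be = basals[u.gene_id]
        left_candidates = [basals[o.gene_id][1] for o in by_chrom[chrom]
                           if o.gene_id != u.gene_id
                           and basals[o.gene_id][1] <= bs]
        right_candidates = [basals[o.gene_id][0] for o in by_chrom[chrom]
                            if o.gene_id != u.gene_id
                            and basals[o.gene_id][0] >= be]
        ext_s = max(tss - max_extension, max(left_candidates, default=0), 0)
        ext_s = min(ext_s, bs)
        limit = chrom_sizes.get(chrom) if chrom_sizes else None
        ext_e = min(tss + max_extension,
                    min(right_candidates, default=float("inf")))
        if limit is not None:
            ext_e = min(ext_e, limit)
        ext_e = max(int(ext_e), be)
        out.append(RegulatoryDomain(
            gene_id=u.gene_id,
            basal=GenomicInterval(chrom, bs, be, strand=u.strand),
            extended=GenomicInterval(chrom, ext_s, ext_e, strand=u.strand),
        ))
    return out


def assign_regulatory_domain(regions: list[AcceleratedRegion],
                             domains: list[RegulatoryDomain]
                             ) -> list[AcceleratedRegion]:
    """Assign a region to every gene whose extended regulatory domain it
    overlaps by at least one base."""
    trees = _tree_by_chrom((d.extended, d.gene_id) for d in domains)
    for region in regions:
        iv = region.interval
        tree = trees.get(iv.chrom)
        hits = tree.overlap(iv.start, iv.end) if tree else set()
        region.assigned_genes.setdefault(AssignmentMode.REG_DOMAIN,
                                         set()).update(h.data for h in hits)
    return regions


def assign_tad(regions: list[AcceleratedRegion],
               units: list[TranscriptionalUnit],
               tads: TadSet) -> list[AcceleratedRegion]:
    """Assign a region to every gene whose TSS shares a TAD with any base
    of the region; regions outside all TADs get nothing."""
    tss_by_tad: dict[tuple[str, int, int], set[str]] = {}
    for u in units:
        t = tads.containing_point(u.body.chrom, u.tss)
        if t is not None:
            tss_by_tad.setdefault((t.chrom, t.start, t.end), set()).add(u.gene_id)
    for region in regions:
        iv = region.interval
        assigned: set[str] = set()
        for t in tads.covering(iv.chrom, iv.start, iv.end):
            assigned |= tss_by_tad.get((t.chrom, t.start, t.end), set())
        region.assigned_genes.setdefault(AssignmentMode.TAD,
                                         set()).update(assigned)
    return regions


def summarize(regions: list[AcceleratedRegion]) -> pd.DataFrame:
    """Per lineage x assignment mode: region and gene counts, top genes by
    region count, and the coding/noncoding split."""
    rows = []
    for lineage in Lineage:
        sub = [r for r in regions if r.lineage == lineage]
        if not sub:
            continue
        n_coding = sum(r.coding_class == CodingClass.CODING for r in sub)
        for mode in AssignmentMode:
            gene_counts: dict[str, int] = {}
            n_assigned = 0
            for r in sub:
                gs = r.genes(mode)
                if gs:
                    n_assigned += 1
                for g in gs:
                    gene_counts[g] = gene_counts.get(g, 0) + 1
            ranking = sorted(gene_counts.items(), key=lambda kv: (-kv[1], kv[0]))
            rows.append({
                "lineage": lineage.value,
                "mode": mode.value,
                "n_regions": len(sub),
                "n_assigned_regions": n_assigned,
                "n_genes": len(gene_counts),
                "top_genes": ",".join(f"{g}:{c}" for g, c in ranking[:5]),
                "n_coding": n_coding,
                "n_noncoding": len(sub) - n_coding,
                "frac_coding": n_coding / len(sub),
            })
    return pd.DataFrame(rows)
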