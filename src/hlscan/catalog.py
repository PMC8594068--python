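"""Gene-catalog construction and the orthology filtering funnel.

The screening starts from several curated hearing-loss gene lists that are
merged into one non-redundant catalog, then filtered by Ensembl-style
orthology bookkeeping: a gene is analyzable only if, after same-taxon
species substitution, it is one-to-one in every roster species with at most
``max_missing`` species lacking an ortholog, and it has coordinates in the
reference genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd


class OrthologyStatus(str, Enum):
    ONE2ONE = "ONE2ONE"
    ONE2MANY = "ONE2MANY"
    MANY2MANY = "MANY2MANY"
    MISSING = "MISSING"


class Disposition(str, Enum):
    ANALYZED = "ANALYZED"
    EXCLUDED_ORTHOLOGY = "EXCLUDED_ORTHOLOGY"
    EXCLUDED_NO_REFERENCE = "EXCLUDED_NO_REFERENCE"


@dataclass
class GeneList:
    """A named source list of gene identifiers (post-synonym-normalization)."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GeneList":
        ids = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
        return cls(name=name or Path(path).stem, genes=frozenset(ids))


@dataclass
class OrthologTable:
    """(gene, species) -> orthology status, plus a species roster with
    taxon-group tags and the set of genes absent from the reference genome.

    ``provenance[(gene, species)]`` records the donor species when a MISSING
    cell was filled by same-taxon substitution.
    """

    status: dict[tuple[str, str], OrthologyStatus]
    roster: dict[str, str]  # species -> taxon group
    no_reference: frozenset[str] = frozenset()
    pool: dict[str, str] = field(default_factory=dict)  # extra species -> group
    pool_status: dict[tuple[str, str], OrthologyStatus] = field(default_factory=dict)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.status})

    def validate_complete(self, genes: set[str]) -> None:
        for g in genes:
            for sp in self.roster:
                if (g, sp) not in self.status:
                    raise KeyError(f"ortholog table missing cell ({g}, {sp})")

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene": g, "species": sp, "status": st.value,
             "taxon_group": self.roster.get(sp, self.pool.get(sp, ""))}
            for (g, sp), st in sorted(self.status.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 no_reference: frozenset[str] = frozenset()) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        status = {
            (r.gene, r.species): OrthologyStatus(r.status)
            for r in df.itertuples()
        }
        roster = dict(df.drop_duplicates("species")[["species", "taxon_group"]]
                      .itertuples(index=False, name=None))
        return cls(status=status, roster=roster, no_reference=no_reference)


@dataclass
class FilterLedger:
    """Per-gene disposition with a reason; dispositions partition the input."""

    disposition: dict[str, Disposition]
    reason: dict[str, str]

    def counts(self) -> dict[str, int]:
        out = {d.value: 0 for d in Disposition}
        for d in self.disposition.values():
            out[d.value] += 1
        return out

    def genes_with(self, disposition: Disposition) -> list[str]:
        return sorted(g for g, d in self.disposition.items() if d == disposition)

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"gene": g, "disposition": d.value, "reason": self.reason.get(g, "")}
                for g, d in sorted(self.disposition.items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def merge_gene_lists(
    lists: list[GeneList], synonym_map: dict[str, str] | None = None
) -> tuple[GeneList, np.ndarray, dict[str, set[str]]]:
    """Merge source lists into a non-redundant union after canonicalization.

    Returns the union list, the pairwise overlap-count matrix (in input
    order), and per-gene source provenance.
    """
    synonym_map = synonym_map or {}
    canon = [frozenset(synonym_map.get(g, g) for g in gl.genes) for gl in lists]
    union: set[str] = set()
    provenance: dict[str, set[str]] = {}
    for gl, genes in zip(lists, canon):
        union |= genes
        for g in genes:
            provenance.setdefault(g, set()).add(gl.name)
    k = len(lists)
    overlap = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(k):
            overlap[i, j] = len(canon[i] & canon[j])
    return GeneList(name="union", genes=frozenset(union)), overlap, provenance


def substitute_species(table: OrthologTable) -> OrthologTable:
    """Fill MISSING roster cells from same-taxon pool species.

    A MISSING cell (gene, species) is replaced by ONE2ONE status when the
    candidate pool contains a species of the same taxon group that is
    ONE2ONE for that gene; the donor is recorded in provenance.  Non-MISSING
    cells are never touched.
    """
    new_status = dict(table.status)
    provenance = dict(table.provenance)
    for (gene, species), st in table.status.items():
        if st != OrthologyStatus.MISSING or species not in table.roster:
            continue
        group = table.roster[species]
        for donor, donor_group in sorted(table.pool.items()):
            if donor_group != group:
                continue
            if table.pool_status.get((gene, donor)) == OrthologyStatus.ONE2ONE:
                new_status[(gene, species)] = OrthologyStatus.ONE2ONE
                provenance[(gene, species)] = donor
                break
    return OrthologTable(status=new_status, roster=table.roster,
                         no_reference=table.no_reference, pool=table.pool,
                         pool_status=table.pool_status, provenance=provenance)


def filter_orthology(
    table: OrthologTable,
    genes: GeneList,
    max_missing: int = 1,
    apply_substitution: bool = True,
) -> FilterLedger:
    """Classify every catalog gene as analyzable or excluded.

    Substitution is applied first (if requested); then a gene is
    EXCLUDED_ORTHOLOGY when more than ``max_missing`` roster species remain
    MISSING or any roster species is one-to-many / many-to-many,
    EXCLUDED_NO_REFERENCE when absent from the reference genome, and
    ANALYZED otherwise.  No-reference takes precedence so the categories
    partition the catalog.
    """
    table.validate_complete(set(genes.genes))
    if apply_substitution:
        table = substitute_species(table)
    disposition: dict[str, Disposition] = {}
    reason: dict[str, str] = {}
    for gene in sorted(genes.genes):
        if gene in table.no_reference:
            disposition[gene] = Disposition.EXCLUDED_NO_REFERENCE
            reason[gene] = "no coordinates in reference genome"
            continue
        n_missing = 0
        multi = []
        for sp in table.roster:
            st = table.status[(gene, sp)]
            if st == OrthologyStatus.MISSING:
                n_missing += 1
            elif st in (OrthologyStatus.ONE2MANY, OrthologyStatus.MANY2MANY):
                multi.append(sp)
        if multi or n_missing > max_missing:
            disposition[gene] = Disposition.EXCLUDED_ORTHOLOGY
            bits = []
            if n_missing > max_missing:
                bits.append(f"missing orthologs in {n_missing} species")
            if multi:
                bits.append(f"one-to-many/many-to-many in {len(multi)} species")
            reason[gene] = "; ".join(bits)
        else:
            disposition[gene] = Disposition.ANALYZED
            reason[gene] = ""
    return FilterLedger(disposition=disposition, reason=reason)
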