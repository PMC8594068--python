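"""Codon state space under the standard genetic code.

All 61-dimensional vectors and matrices in the package are indexed by the
lexicographic order (A < C < G < T) of the 61 sense codons.  Two sentinel
states exist outside that range: :data:`GAP` for ``---`` columns and
ambiguous codons, which carry an explicit set of compatible sense codons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable
from Bio.Data.IUPACData import ambiguous_dna_values

NUCLEOTIDES = "ACGT"

#: Sentinel codon-state index for a fully missing (gap) codon.
GAP = -1

#: Sentinel codon-state index for an ambiguous codon; the compatible sense
#: codons are stored separately (see :class:`hlscan.alignment.CodonAlignment`).
AMBIGUOUS = -2

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if nucleotides ``a`` and ``b`` differ by a transition (A<->G, C<->T)."""
    return a != b and ({a, b} <= PURINES or {a, b} <= PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code with a fixed sense-codon ordering.

    Attributes
    ----------
    table:
        Map from codon string to one-letter amino acid, or ``"*"`` for stops.
    sense_codons:
        The 61 sense codons in lexicographic order; position in this list is
        the state index used everywhere in the package.
    """

    table: dict[str, str]
    sense_codons: tuple[str, ...]
    index: dict[str, int] = field(repr=False, default_factory=dict)

    @classmethod
    def standard(cls) -> "GeneticCode":
        bio = CodonTable.unambiguous_dna_by_id[1]
        table = dict(bio.forward_table)
        for stop in bio.stop_codons:
            table[stop] = "*"
        sense = tuple(
            c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
            if table[c] != "*"
        )
        obj = cls(table=table, sense_codons=sense)
        object.__setattr__(obj, "index", {c: i for i, c in enumerate(sense)})
        return obj

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def is_stop(self, codon: str) -> bool:
        return self.table.get(codon.upper()) == "*"

    def amino_acid(self, codon: str) -> str:
        return self.table[codon.upper()]

    def compatible_sense_codons(self, codon: str) -> frozenset[int]:
        """Sense-codon indices compatible with an IUPAC-ambiguous codon.

        Stop codons are never compatible: ``TRA`` expands to TAA and TGA,
        both stops, so its compatible set is empty and the caller raises.
        """
        expansions = []
        for ch in codon.upper():
            expansions.append(ambiguous_dna_values.get(ch, ""))
        hits = set()
        for combo in itertools.product(*expansions):
            c = "".join(combo)
            idx = self.index.get(c)
            if idx is not None:
                hits.add(idx)
        return frozenset(hits)


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """Module-level cached standard :class:`GeneticCode`."""
    return GeneticCode.standard()
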