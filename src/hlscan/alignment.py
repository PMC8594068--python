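"""In-frame codon alignments and their FASTA / sequential-PHYLIP readers.

The alignment container stores one integer state per taxon per codon site:
a sense-codon index in ``[0, 61)``, :data:`~hlscan.genetics.GAP` for ``---``,
or :data:`~hlscan.genetics.AMBIGUOUS` with an explicit compatible-codon set.
Terminal stop codons are stripped on read; an internal stop is a hard error
because the substitution models have no stop state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .genetics import AMBIGUOUS, GAP, GeneticCode, standard_code


class AlignmentFormatError(ValueError):
    """Raised when a sequence file violates the codon-alignment contract."""


@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences over the 61 sense codons.

    ``sites[i, j]`` is the codon state of taxon ``i`` at codon site ``j``.
    ``ambiguity[(i, j)]`` holds the compatible sense-codon set for every
    AMBIGUOUS cell.
    """

    taxa: list[str]
    sites: np.ndarray  # (n_taxa, n_sites) int array
    ambiguity: dict[tuple[int, int], frozenset[int]] = field(default_factory=dict)
    code: GeneticCode = field(default_factory=standard_code)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            raise AlignmentFormatError("duplicate taxon names in alignment")
        self.sites = np.asarray(self.sites, dtype=np.int64)
        if self.sites.ndim != 2 or self.sites.shape[0] != len(self.taxa):
            raise AlignmentFormatError("sites matrix shape does not match taxa")

    @property
    def n_taxa(self) -> int:
        return self.sites.shape[0]

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]

    def leaf_partials(self) -> dict[str, np.ndarray]:
        """Per-taxon (61, n_sites) conditional-likelihood matrices.

        Observed codons are one-hot columns; gaps are all-ones (fully
        missing); ambiguous codons are indicators over their compatible set.
        """
        n = self.code.n_states
        out = {}
        for i, name in enumerate(self.taxa):
            m = np.zeros((n, self.n_sites))
            for j in range(self.n_sites):
                s = self.sites[i, j]
                if s == GAP:
                    m[:, j] = 1.0
                elif s == AMBIGUOUS:
                    m[list(self.ambiguity[(i, j)]), j] = 1.0
                else:
                    m[s, j] = 1.0
            out[name] = m
        return out

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, name in enumerate(self.taxa):
                fh.write(f">{name}\n{self._row_str(i)}\n")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f" {self.n_taxa} {self.n_sites * 3}\n")
            for i, name in enumerate(self.taxa):
                fh.write(f"{name}  {self._row_str(i)}\n")

    def _row_str(self, i: int) -> str:
        chunks = []
        for j in range(self.n_sites):
            s = self.sites[i, j]
            if s == GAP:
                chunks.append("---")
            elif s == AMBIGUOUS:
                chunks.append("NNN")
            else:
                chunks.append(self.code.sense_codons[s])
        return "".join(chunks)


def _encode_sequences(
    named_seqs: list[tuple[str, str]], code: GeneticCode
) -> CodonAlignment:
    if not named_seqs:
        raise AlignmentFormatError("no sequences in file")
    names = [n for n, _ in named_seqs]
    if len(names) != len(set(names)):
        raise AlignmentFormatError("duplicate taxon names in alignment")
    lengths = {len(s) for _, s in named_seqs}
    if len(lengths) != 1:
        raise AlignmentFormatError("sequences are not aligned (unequal lengths)")
    (length,) = lengths
    for name, seq in named_seqs:
        if len(seq) % 3 != 0:
            raise AlignmentFormatError(
                f"sequence length {len(seq)} of taxon '{name}' is not a multiple of 3"
            )
    n_sites = length // 3

    # Strip a terminal stop column: drop the last codon site if, for every
    # taxon, it is a stop, a gap, or ambiguous-with-stop-only resolution.
    def is_stop_column() -> bool:
        if n_sites == 0:
            return False
        any_stop = False
        for _, seq in named_seqs:
            codon = seq[-3:].upper()
            if codon == "---":
                continue
            if set(codon) <= set("ACGT"):
                if code.is_stop(codon):
                    any_stop = True
                else:
                    return False
            # ambiguous terminal codons do not veto stripping
        return any_stop

    strip_last = is_stop_column()
    if strip_last:
        n_sites -= 1

    sites = np.empty((len(named_seqs), n_sites), dtype=np.int64)
    ambiguity: dict[tuple[int, int], frozenset[int]] = {}
    for i, (name, seq) in enumerate(named_seqs):
        seq = seq.upper()
        for j in range(n_sites):
            codon = seq[3 * j : 3 * j + 3]
            if codon == "---":
                sites[i, j] = GAP
            elif set(codon) <= set("ACGT"):
                idx = code.index.get(codon)
                if idx is None:
                    raise AlignmentFormatError(
                        f"internal stop codon {codon} in taxon '{name}' "
                        f"at codon site {j}"
                    )
                sites[i, j] = idx
            else:
                compat = code.compatible_sense_codons(codon)
                if not compat:
                    raise AlignmentFormatError(
                        f"codon {codon} in taxon '{name}' at codon site {j} "
                        "is compatible with no sense codon"
                    )
                if len(compat) == 1:
                    (sites[i, j],) = compat
                else:
                    sites[i, j] = AMBIGUOUS
                    ambiguity[(i, j)] = compat
    return CodonAlignment(taxa=[n for n, _ in named_seqs], sites=sites,
                          ambiguity=ambiguity, code=code)


def _read_phylip_sequential(path: Path) -> list[tuple[str, str]]:
    text = path.read_text().strip().splitlines()
    if not text:
        raise AlignmentFormatError(f"{path}: empty file")
    header = text[0].split()
    if len(header) < 2 or not header[0].isdigit() or not header[1].isdigit():
        raise AlignmentFormatError(f"{path}: bad PHYLIP header")
    n_taxa, n_chars = int(header[0]), int(header[1])
    seqs: list[tuple[str, str]] = []
    name, chunks = None, []
    for line in text[1:]:
        if not line.strip():
            continue
        if name is None or len("".join(chunks)) >= n_chars:
            if name is not None:
                seqs.append((name, "".join(chunks)))
            parts = line.split(None, 1)
            name = parts[0]
            chunks = [re.sub(r"\s", "", parts[1])] if len(parts) > 1 else []
        else:
            chunks.append(re.sub(r"\s", "", line))
    if name is not None:
        seqs.append((name, "".join(chunks)))
    if len(seqs) != n_taxa:
        raise AlignmentFormatError(
            f"{path}: header promises {n_taxa} taxa, found {len(seqs)}"
        )
    for nm, s in seqs:
        if len(s) != n_chars:
            raise AlignmentFormatError(
                f"{path}: taxon '{nm}' has {len(s)} characters, expected {n_chars}"
            )
    return seqs


def read_codon_alignment(
    path: str | Path, code: GeneticCode | None = None
) -> CodonAlignment:
    """Read a codon alignment from FASTA or sequential PHYLIP.

    The dialect is sniffed from the first non-blank character: ``>`` means
    FASTA, a digit means PHYLIP.  Mixed case is accepted; ``---`` codons
    become GAP; codons containing IUPAC ambiguity letters become AMBIGUOUS
    with their compatible sense-codon set.
    """
    path = Path(path)
    code = code or standard_code()
    with open(path) as fh:
        head = fh.read(64).lstrip()
    if head.startswith(">"):
        named = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    elif head[:1].isdigit():
        named = _read_phylip_sequential(path)
    else:
        raise AlignmentFormatError(f"{path}: unrecognized alignment format")
    return _encode_sequences(named, code)
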