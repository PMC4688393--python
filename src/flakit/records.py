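"""Core record types shared across the pipeline.

Coordinates are 1-based inclusive throughout, matching the arithmetic of
published gene-locus tables (``end - start + 1 == gene length``).  Strand is
not modelled: all protein-level coordinates are strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGT")


class FlakitError(Exception):
    """Base class for all flakit-specific errors."""


class ValidationError(FlakitError):
    """A record violated one of its invariants."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence flowing through identification.

    ``sequence`` is uppercase, restricted to the 20 standard amino acids
    plus X.  Other non-standard letters are rejected rather than silently
    remapped.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsRecord:
    """A full-ORF coding sequence (frame 1, terminal stop allowed)."""

    id: str
    sequence: str
    description: str = ""
    frame: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"CDS {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValidationError(f"CDS {self.id!r}: illegal characters {sorted(bad)}")
        if len(self.sequence) % 3 != 0:
            raise ValidationError(
                f"CDS {self.id!r}: length {len(self.sequence)} not divisible by 3"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """One row of a gene-locus table.

    Invariants checked on construction:

    * ``end >= start``
    * ``gene_length == end - start + 1``
    * ``orf_length`` divisible by 3
    * ``protein_length == orf_length / 3 - 1`` (stop codon excluded)
    """

    gene_symbol: str
    locus_id: str
    chromosome: str
    start: int
    end: int
    gene_length: int
    orf_length: int
    protein_length: int
    mol_wt: float
    pI: float

    def __post_init__(self) -> None:
        sym = self.gene_symbol
        if self.end < self.start:
            raise ValidationError(f"{sym}: end {self.end} < start {self.start}")
        if self.gene_length != self.end - self.start + 1:
            raise ValidationError(
                f"{sym}: gene length {self.gene_length} != "
                f"end - start + 1 = {self.end - self.start + 1}"
            )
        if self.orf_length % 3 != 0:
            raise ValidationError(
                f"{sym}: ORF length {self.orf_length} not divisible by 3"
            )
        if self.protein_length != self.orf_length // 3 - 1:
            raise ValidationError(
                f"{sym}: protein length {self.protein_length} != "
                f"ORF/3 - 1 = {self.orf_length // 3 - 1}"
            )


@dataclass
class DomainAnnotation:
    """A located fasciclin domain or terminal signal on one protein.

    ``blocks`` (fasciclin only) maps conserved-block names to 1-based
    inclusive intervals: ``H1``/``H2`` to (start, end) and ``YFH`` to the
    two-residue motif interval.  Block order H1 < YFH < H2 is enforced.
    """

    protein_id: str
    kind: str  # fasciclin | signal_peptide | gpi_anchor
    start: int
    end: int
    score: float = 0.0
    source: str = "builtin"  # builtin | imported
    blocks: Optional[dict] = field(default=None)

    KINDS = ("fasciclin", "signal_peptide", "gpi_anchor")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown annotation kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.protein_id}: bad interval {self.start}-{self.end}"
            )
        if self.blocks:
            order = [self.blocks[k][0] for k in ("H1", "YFH", "H2") if k in self.blocks]
            if order != sorted(order) or len(set(order)) != len(order):
                raise ValidationError(
                    f"{self.protein_id}: fasciclin blocks out of order {self.blocks}"
                )

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)
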