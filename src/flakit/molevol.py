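"""Codon alignment, NG86 Ka/Ks, molecular-clock dating, duplication typing.

The substitution-counting method is Nei-Gojobori (1986) with Jukes-Cantor
multiple-hit correction: per-codon synonymous site fractions come from
enumerating the nine single-base mutants of each codon (stop codons
excluded so that every position still contributes one site), observed
differences are averaged with equal weight over the minimal mutational
pathways between the two codons (pathways through stop codons excluded),
and p-distances are corrected with d = -(3/4) ln(1 - 4p/3).

Duplication dating follows the synonymous molecular clock T = Ks / (2 λ),
with λ the synonymous substitution rate per site per year (9.1e-9 for
*Populus*).
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Data.CodonTable import standard_dna_table

from .records import CdsRecord, FlakitError, GeneLocus

CODON_TABLE: Dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
BASES = "ACGT"

#: synonymous substitution rate per site per year for Populus
POPULUS_LAMBDA = 9.1e-9


@dataclass(frozen=True)
class ClockParams:
    lam: float = POPULUS_LAMBDA

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise FlakitError("clock rate must be positive")


@dataclass
class CodonAlignment:
    """A pair of gap-aligned CDS rows (every column a codon or '---')."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise FlakitError("codon alignment rows differ in length")
        if len(self.row_a) % 3 != 0:
            raise FlakitError("codon alignment length not divisible by 3")

    def codon_pairs(self) -> List[Tuple[str, str]]:
        """Ungapped aligned codon pairs."""
        out = []
        for i in range(0, len(self.row_a), 3):
            ca, cb = self.row_a[i : i + 3], self.row_b[i : i + 3]
            if "-" in ca or "-" in cb:
                continue
            out.append((ca, cb))
        return out


@dataclass
class KaKsResult:
    pair_id: Tuple[str, str]
    Ka: float
    Ks: Optional[float]
    ratio: Optional[float]
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    T_mya: Optional[float] = None
    duplication_type: Optional[str] = None

    @property
    def selection(self) -> Optional[str]:
        if self.ratio is None:
            return None
        if self.ratio < 1.0:
            return "purifying"
        if self.ratio > 1.0:
            return "positive"
        return "neutral"


def translate_cds(cds: CdsRecord, trim_stop: bool = True) -> str:
    """Translate a full-ORF CDS; internal stops are an error."""
    seq = cds.sequence
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if trim_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aa = []
    for k, codon in enumerate(codons, start=1):
        if codon in STOP_CODONS:
            raise FlakitError(f"CDS {cds.id!r}: internal stop at codon {k}")
        aa.append(CODON_TABLE[codon])
    return "".join(aa)


def backtranslate_alignment(
    protein_alignment: Sequence[Tuple[str, str]],
    cds_records: Sequence[CdsRecord],
) -> CodonAlignment:
    """Expand a pairwise protein alignment to codons (PAL2NAL-style).

    Each CDS must translate exactly to its ungapped protein row (terminal
    stop trimmed); amino-acid gaps become ``---``.
    """
    if len(protein_alignment) != 2 or len(cds_records) != 2:
        raise FlakitError("backtranslate_alignment expects exactly two rows")
    rows_out = []
    for (pid, prow), cds in zip(protein_alignment, cds_records):
        protein = prow.replace("-", "")
        translated = translate_cds(cds)
        if translated != protein:
            for k, (x, y) in enumerate(zip(translated, protein), start=1):
                if x != y:
                    codon = cds.sequence[3 * (k - 1) : 3 * k]
                    raise FlakitError(
                        f"{cds.id!r}: codon {k} ({codon}) encodes {x}, "
                        f"protein row has {y}"
                    )
            raise FlakitError(
                f"{cds.id!r}: CDS length {len(cds.sequence)} does not match "
                f"protein length {len(protein)} (+ optional stop)"
            )
        out = []
        k = 0
        for aa in prow:
            if aa == "-":
                out.append("---")
            else:
                out.append(cds.sequence[3 * k : 3 * k + 3])
                k += 1
        rows_out.append("".join(out))
    return CodonAlignment(
        id_a=protein_alignment[0][0],
        id_b=protein_alignment[1][0],
        row_a=rows_out[0],
        row_b=rows_out[1],
    )


@functools.lru_cache(maxsize=None)
def codon_sites(codon: str) -> Tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) site counts for one codon.

    At each position the three single-base mutants are classified;
    mutants creating a stop codon are excluded from the denominator, so
    each position contributes exactly one site and S + N = 3.
    """
    if codon in STOP_CODONS or codon not in CODON_TABLE:
        raise FlakitError(f"cannot count sites for codon {codon!r}")
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = non = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            if CODON_TABLE[mutant] == aa:
                syn += 1
            else:
                non += 1
        if syn + non:
            s += syn / (syn + non)
    return s, 3.0 - s


def _pathway_steps(ca: str, cb: str) -> List[List[Tuple[str, str]]]:
    """All orderings of the single-base steps from ``ca`` to ``cb``;
    each pathway is a list of (from_codon, to_codon) steps."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    pathways = []
    for order in itertools.permutations(diff):
        steps = []
        cur = ca
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            cur = nxt
        pathways.append(steps)
    return pathways


def codon_differences(ca: str, cb: str) -> Tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) difference counts for a codon pair.

    Averaged with equal weight over minimal mutational pathways; pathways
    passing through a stop codon are excluded entirely (unless every
    pathway does, in which case all are kept so the differences are still
    counted).
    """
    if ca == cb:
        return 0.0, 0.0
    pathways = _pathway_steps(ca, cb)
    valid = [
        p for p in pathways
        if all(step_to not in STOP_CODONS for _, step_to in p)
    ]
    if not valid:
        valid = pathways
    sd = nd = 0.0
    for steps in valid:
        for frm, to in steps:
            aa_from = CODON_TABLE.get(frm)
            aa_to = CODON_TABLE.get(to)
            if aa_from is not None and aa_to is not None and aa_from == aa_to:
                sd += 1
            else:
                nd += 1
    k = len(valid)
    return sd / k, nd / k


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - 4p/3); undefined at p >= 3/4."""
    if p >= 0.75:
        raise FlakitError(f"saturated: proportion {p:.4f} >= 3/4")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(alignment: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori Ka/Ks for a pairwise codon alignment.

    Sites are averaged over the two sequences; gapped columns are skipped.
    When Ks = 0 the ratio is reported as missing (None), never infinity;
    identical rows give Ka = Ks = 0 with a missing ratio.
    """
    pairs = alignment.codon_pairs()
    if not pairs:
        raise FlakitError("codon alignment has no ungapped codon columns")
    S = N = Sd = Nd = 0.0
    for ca, cb in pairs:
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = codon_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ka = jukes_cantor(pN)
    Ks = jukes_cantor(pS)
    ratio = Ka / Ks if Ks > 0 else None
    return KaKsResult(
        pair_id=(alignment.id_a, alignment.id_b),
        Ka=Ka,
        Ks=Ks,
        ratio=ratio,
        S_sites=S,
        N_sites=N,
        Sd=Sd,
        Nd=Nd,
    )


def divergence_time(Ks: float, clock: Optional[ClockParams] = None) -> float:
    """Molecular-clock age of a duplication in million years: T = Ks/(2 λ)."""
    if Ks < 0:
        raise FlakitError(f"negative Ks {Ks}")
    clock = clock or ClockParams()
    return Ks / (2.0 * clock.lam) / 1e6


def classify_duplication(
    locus_a: GeneLocus,
    locus_b: GeneLocus,
    max_separation: Optional[int] = None,
) -> str:
    """``tandem`` when both loci share a chromosome, else ``segmental``.

    ``max_separation`` (bp) optionally tightens the tandem definition to
    proximal pairs only; by default chromosome sharing alone decides.
    """
    if locus_a is None or locus_b is None:
        raise FlakitError("classify_duplication: missing locus")
    if (locus_a.gene_symbol, locus_a.locus_id) == (locus_b.gene_symbol, locus_b.locus_id):
        raise FlakitError(f"self-pair {locus_a.gene_symbol}")
    if locus_a.chromosome != locus_b.chromosome:
        return "segmental"
    if max_separation is not None:
        gap = max(locus_a.start, locus_b.start) - min(locus_a.end, locus_b.end)
        if gap > max_separation:
            return "segmental"
    return "tandem"


def chromosome_counts(
    loci: Sequence[GeneLocus],
    universe: Optional[Sequence[str]] = None,
) -> Dict[str, int]:
    """Gene counts per chromosome; a supplied universe adds zero-count rows."""
    counts: Dict[str, int] = {}
    if universe is not None:
        counts = {c: 0 for c in universe}
    for locus in loci:
        counts[locus.chromosome] = counts.get(locus.chromosome, 0) + 1
    return counts
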