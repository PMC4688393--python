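"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython.  The gene-locus table is a TSV transcription
of a published table whose "Genomic position" column is formatted
``ChrNN: start–end`` (en-dash or hyphen, optional spaces); coordinates are
1-based inclusive and the printed length identities are verified on read.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .records import (
    CdsRecord,
    DomainAnnotation,
    FlakitError,
    GeneLocus,
    ProteinRecord,
    ValidationError,
)


class FastaError(FlakitError):
    pass


class LocusTableError(FlakitError):
    pass


class PredictionTableError(FlakitError):
    pass


def read_fasta(path, kind: str = "protein") -> Union[List[ProteinRecord], List[CdsRecord]]:
    """Read a FASTA file into protein or CDS records.

    Sequences are uppercased; record order is preserved; ids must be unique.
    ``kind`` is ``"protein"`` or ``"cds"``.
    """
    if kind not in ("protein", "cds"):
        raise ValueError(f"kind must be 'protein' or 'cds', got {kind!r}")
    path = Path(path)
    cls = ProteinRecord if kind == "protein" else CdsRecord
    records: list = []
    seen: dict = {}
    with open(path) as fh:
        entries = list(SimpleFastaParser(fh))
    if not entries:
        raise FastaError(f"{path}: empty or header-less FASTA")
    for n, (title, seq) in enumerate(entries, start=1):
        parts = title.split(None, 1)
        rid = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        if rid in seen:
            raise FastaError(
                f"{path}: duplicate id {rid!r} (records {seen[rid]} and {n})"
            )
        seen[rid] = n
        seq = "".join(seq.split()).upper()
        try:
            records.append(cls(id=rid, sequence=seq, description=desc))
        except ValidationError as e:
            raise FastaError(f"{path}: record {n}: {e}") from e
    return records


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequences at ``width`` columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_aligned_fasta(path) -> List[tuple]:
    """Read an aligned FASTA (gap character ``-``) as (id, row) pairs.

    All rows must have equal length.
    """
    path = Path(path)
    with open(path) as fh:
        entries = list(SimpleFastaParser(fh))
    if not entries:
        raise FastaError(f"{path}: empty alignment")
    rows = [(t.split(None, 1)[0], "".join(s.split()).upper()) for t, s in entries]
    widths = {len(s) for _, s in rows}
    if len(widths) != 1:
        raise FastaError(f"{path}: unequal alignment row lengths {sorted(widths)}")
    return rows


_POSITION_RE = re.compile(r"^\s*(Chr\d+)\s*:\s*(\d+)\s*[–—-]\s*(\d+)\s*$")


def parse_position(text: str) -> tuple:
    """Parse ``'Chr01: 32566530–32567917'`` into (chromosome, start, end)."""
    m = _POSITION_RE.match(text)
    if not m:
        raise LocusTableError(f"malformed genomic position {text!r}")
    return m.group(1), int(m.group(2)), int(m.group(3))


def parse_locus_table(path) -> List[GeneLocus]:
    """Parse a TSV gene-locus table into validated :class:`GeneLocus` rows.

    Expected columns: gene_symbol, locus_id, position, gene_length,
    orf_length, protein_length, mol_wt, pI (extra columns ignored).
    All length identities are checked; a violation names the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {
        "gene_symbol",
        "locus_id",
        "position",
        "gene_length",
        "orf_length",
        "protein_length",
        "mol_wt",
        "pi",
    }
    missing = required - set(df.columns)
    if missing:
        raise LocusTableError(f"{path}: missing columns {sorted(missing)}")
    loci = []
    for idx, row in df.iterrows():
        sym = row["gene_symbol"]
        try:
            chrom, start, end = parse_position(row["position"])
            loci.append(
                GeneLocus(
                    gene_symbol=sym,
                    locus_id=row["locus_id"],
                    chromosome=chrom,
                    start=start,
                    end=end,
                    gene_length=int(row["gene_length"]),
                    orf_length=int(row["orf_length"]),
                    protein_length=int(row["protein_length"]),
                    mol_wt=float(row["mol_wt"]),
                    pI=float(row["pi"]),
                )
            )
        except (ValidationError, LocusTableError, ValueError) as e:
            raise LocusTableError(f"{path}: row {idx + 1} ({sym}): {e}") from e
    return loci


_PREDICTION_KINDS = {
    "signal_peptide": "signal_peptide",
    "gpi": "gpi_anchor",
    "domain": "fasciclin",
}


def read_prediction_table(
    path,
    kind: str,
    protein_lengths: Optional[Mapping[str, int]] = None,
) -> List[DomainAnnotation]:
    """Import an external prediction table (signal peptide / GPI / domain).

    TSV columns: protein_id, start, end, label, score (1-based inclusive).
    Rows for ids absent from ``protein_lengths`` raise a warning and are
    kept; coordinates beyond a known protein length are an error.  An empty
    table yields an empty list so the pipeline can fall back to the
    built-in heuristics.
    """
    if kind not in _PREDICTION_KINDS:
        raise ValueError(f"kind must be one of {sorted(_PREDICTION_KINDS)}")
    ann_kind = _PREDICTION_KINDS[kind]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    df.columns = [c.strip().lower() for c in df.columns]
    out = []
    for idx, row in df.iterrows():
        pid = row["protein_id"]
        start, end = int(row["start"]), int(row["end"])
        if protein_lengths is not None:
            if pid not in protein_lengths:
                warnings.warn(f"{path}: unknown protein id {pid!r} (row {idx + 1})")
            elif end > protein_lengths[pid] or start < 1:
                raise PredictionTableError(
                    f"{path}: row {idx + 1}: interval {start}-{end} outside "
                    f"protein {pid!r} (length {protein_lengths[pid]})"
                )
        out.append(
            DomainAnnotation(
                protein_id=pid,
                kind=ann_kind,
                start=start,
                end=end,
                score=float(row.get("score", 0.0)),
                source="imported",
            )
        )
    return out


def write_prediction_table(annotations: Sequence[DomainAnnotation], path) -> None:
    """Write annotations in the same TSV dialect ``read_prediction_table`` reads."""
    rows = [
        {
            "protein_id": a.protein_id,
            "start": a.start,
            "end": a.end,
            "label": a.kind,
            "score": a.score,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["protein_id", "start", "end", "label", "score"]).to_csv(
        path, sep="\t", index=False
    )
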