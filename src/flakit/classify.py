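"""FLA membership rule and architecture groups A-D.

A protein is an FLA when it carries at least one fasciclin domain, at least
one qualifying AGP glycomodule outside the domain/terminal-signal
intervals, and an N-terminal signal peptide.  A GPI anchor is optional.

Architecture groups:

* **B** - two fasciclin domains flanking one or more glycomodules, no GPI,
  protein length inside the group-B envelope;
* **A / C** - a single fasciclin domain flanked by glycomodules on both
  sides; the two groups share this architecture and are separated by
  protein length (C members are ~400-470 aa with a GPI anchor, A members
  ~230-290 aa), so the discriminator is a configurable length threshold;
* **D** - everything else that still passes the membership rule (including
  two-domain proteins whose length or spacing falls outside B's envelope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .glyco import GlycoModule, find_glycomodules, past_fraction
from .records import DomainAnnotation, FlakitError, ProteinRecord


@dataclass
class GroupRules:
    """Thresholds for group assignment (lengths in aa)."""

    ac_length_split: int = 350  # >= split -> C, else A
    b_length_range: Tuple[int, int] = (400, 500)


@dataclass
class FlaClassification:
    protein_id: str
    is_fla: bool
    group: Optional[str] = None  # A | B | C | D
    n_fasciclin: int = 0
    n_glycomodules: int = 0
    has_signal: bool = False
    has_gpi: bool = False
    architecture_string: str = ""
    past_percent: float = 0.0


def _architecture_string(
    signal: Optional[DomainAnnotation],
    domains: Sequence[DomainAnnotation],
    modules: Sequence[GlycoModule],
    gpi: Optional[DomainAnnotation],
) -> str:
    tokens = []
    if signal is not None:
        tokens.append((signal.start, "SP"))
    tokens += [(d.start, "FAS") for d in domains]
    tokens += [(m.start, "AGP") for m in modules]
    if gpi is not None:
        tokens.append((gpi.start, "GPI"))
    return "–".join(t for _, t in sorted(tokens))


def decide_membership(
    record: ProteinRecord,
    domains: Sequence[DomainAnnotation],
    signal: Optional[DomainAnnotation],
    gpi: Optional[DomainAnnotation],
    modules: Optional[Sequence[GlycoModule]] = None,
) -> FlaClassification:
    """Apply the membership rule; the group is left unset.

    When ``modules`` is not given, glycomodules are scanned here with the
    fasciclin domains and terminal signals excluded.
    """
    fas = sorted((d for d in domains if d.kind == "fasciclin"), key=lambda d: d.start)
    if modules is None:
        excluded = [d.interval for d in fas]
        if signal is not None:
            excluded.append(signal.interval)
        if gpi is not None:
            excluded.append(gpi.interval)
        modules = find_glycomodules(record.sequence, _merge_intervals(excluded))
    is_fla = bool(fas) and bool(modules) and signal is not None
    return FlaClassification(
        protein_id=record.id,
        is_fla=is_fla,
        n_fasciclin=len(fas),
        n_glycomodules=len(modules),
        has_signal=signal is not None,
        has_gpi=gpi is not None,
        architecture_string=_architecture_string(signal, fas, modules, gpi),
        past_percent=past_fraction(record.sequence).past_percent,
    )


def _merge_intervals(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge possibly-overlapping 1-based intervals into disjoint ones."""
    merged: List[List[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def assign_group(
    classification: FlaClassification,
    protein_length: int,
    domains: Sequence[DomainAnnotation],
    modules: Sequence[GlycoModule],
    rules: Optional[GroupRules] = None,
) -> FlaClassification:
    """Assign group A/B/C/D to a protein already judged to be an FLA."""
    if not classification.is_fla:
        raise FlakitError(
            f"{classification.protein_id}: group assignment requires is_fla"
        )
    rules = rules or GroupRules()
    fas = sorted((d for d in domains if d.kind == "fasciclin"), key=lambda d: d.start)

    group = "D"
    if len(fas) == 2:
        between = [
            m for m in modules if m.start > fas[0].end and m.end < fas[1].start
        ]
        b_lo, b_hi = rules.b_length_range
        if between and not classification.has_gpi and b_lo <= protein_length <= b_hi:
            group = "B"
    elif len(fas) == 1:
        before = [m for m in modules if m.end < fas[0].start]
        after = [m for m in modules if m.start > fas[0].end]
        if before and after:
            group = "C" if protein_length >= rules.ac_length_split else "A"
    classification.group = group
    return classification


def classify_protein(
    record: ProteinRecord,
    imported: Optional[Sequence[DomainAnnotation]] = None,
    profiles=None,
    scan_config=None,
    signal_config=None,
    rules: Optional[GroupRules] = None,
) -> FlaClassification:
    """Full per-protein pipeline: domains, signals, glycomodules, verdict, group.

    ``imported`` annotations (from external predictors) take precedence
    over the built-in heuristics for signals; imported fasciclin domains
    are used alongside the profile scan only when the scan finds none.
    """
    from .domains import detect_gpi_signal, detect_signal_peptide, scan_fasciclin

    fas = scan_fasciclin(record, profiles, scan_config)
    if not fas and imported:
        fas = [
            a for a in imported
            if a.protein_id == record.id and a.kind == "fasciclin"
        ]
    signal = detect_signal_peptide(record, imported, signal_config)
    gpi = detect_gpi_signal(record, imported, signal_config)
    excluded = [d.interval for d in fas]
    if signal is not None:
        excluded.append(signal.interval)
    if gpi is not None:
        excluded.append(gpi.interval)
    modules = find_glycomodules(record.sequence, _merge_intervals(excluded))
    c = decide_membership(record, fas, signal, gpi, modules)
    if c.is_fla:
        c = assign_group(c, len(record), fas, modules, rules)
    return c


def classify_proteome(
    records: Sequence[ProteinRecord],
    imported: Optional[Sequence[DomainAnnotation]] = None,
    **kwargs,
) -> List[FlaClassification]:
    """Classify every protein; exactly one verdict per record."""
    return [classify_protein(r, imported, **kwargs) for r in records]


def classification_report(classifications: Sequence[FlaClassification]) -> List[dict]:
    """Rows for the TSV classification report."""
    return [
        {
            "protein_id": c.protein_id,
            "is_fla": c.is_fla,
            "group": c.group or "",
            "architecture_string": c.architecture_string,
            "n_fasciclin": c.n_fasciclin,
            "n_glycomodules": c.n_glycomodules,
            "has_signal": c.has_signal,
            "has_gpi": c.has_gpi,
            "past_percent": round(c.past_percent, 2),
        }
        for c in classifications
    ]
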