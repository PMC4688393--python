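"""AGP glycomodule grammar and PAST composition.

Arabinogalactan glycosylation happens on hydroxyproline in short
[Ala/Ser/Thr]-Pro contexts.  Hydroxylation is not observable from sequence,
so Pro is used as the Hyp proxy throughout (the standard convention for
sequence-level AGP scans).  An O-glycosylation site is an [A/S/T]-Pro
dipeptide; a region qualifies as an AGP-like glycomodule when it contains
either one [A/S/T]-Pro(2-4) run or two or more non-contiguous sites whose
spacing obeys [A/S/T]-Pro-X(0-10)-[A/S/T]-Pro.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .records import FlakitError

AST = frozenset("AST")
PAST = frozenset("PAST")

#: maximum number of residues allowed between one site's final Pro and the
#: next site's [A/S/T] for the two sites to belong to the same module
MAX_SITE_GAP = 10

#: reported run lengths are capped here; longer Pro runs still qualify
RUN_CAP = 4


@dataclass(frozen=True)
class OGlycoSite:
    """One [A/S/T]-Pro O-glycosylation site.

    ``position`` is the 1-based index of the [A/S/T] residue.  ``full_run``
    is the complete count of consecutive Pro after it; ``run_length`` is the
    same count capped at 4 (the grammar names runs of 2-4, but longer runs
    still qualify).
    """

    position: int
    full_run: int

    @property
    def run_length(self) -> int:
        return min(self.full_run, RUN_CAP)

    @property
    def pattern(self) -> str:
        return "AP_run" if self.full_run >= 2 else "AP_pair"

    @property
    def span(self) -> Tuple[int, int]:
        """1-based inclusive interval from the [A/S/T] to the last Pro."""
        return (self.position, self.position + self.full_run)


@dataclass(frozen=True)
class GlycoModule:
    """A detected AGP-like glycosylated region (1-based inclusive)."""

    start: int
    end: int
    sites: Tuple[OGlycoSite, ...]
    qualifying_rule: str  # single_run | paired_sites


@dataclass(frozen=True)
class CompositionProfile:
    past_percent: float
    per_residue_counts: dict
    length: int


def past_fraction(sequence: str) -> CompositionProfile:
    """Percentage of Pro+Ala+Ser+Thr residues.

    X residues count toward the length but never toward PAST.  FLAs sit
    below roughly 35-43% PAST; classical AGPs above 50%.
    """
    if not sequence:
        raise FlakitError("past_fraction: empty sequence")
    counts = Counter(sequence)
    n_past = sum(counts[r] for r in PAST)
    return CompositionProfile(
        past_percent=100.0 * n_past / len(sequence),
        per_residue_counts=dict(counts),
        length=len(sequence),
    )


def find_oglyco_sites(sequence: str) -> List[OGlycoSite]:
    """All [A/S/T]-Pro sites, sorted by position."""
    sites = []
    n = len(sequence)
    for i, aa in enumerate(sequence):
        if aa in AST and i + 1 < n and sequence[i + 1] == "P":
            run = 0
            j = i + 1
            while j < n and sequence[j] == "P":
                run += 1
                j += 1
            sites.append(OGlycoSite(position=i + 1, full_run=run))
    return sites


def _check_intervals(intervals: Sequence[Tuple[int, int]], length: int) -> list:
    ivs = sorted(tuple(iv) for iv in intervals)
    for s, e in ivs:
        if s > e:
            raise FlakitError(f"inverted exclusion interval {s}-{e}")
        if s < 1 or e > length:
            raise FlakitError(f"exclusion interval {s}-{e} outside sequence 1-{length}")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise FlakitError(f"overlapping exclusion intervals {s1}-{e1} and {s2}-{e2}")
    return ivs


def find_glycomodules(
    sequence: str,
    excluded_intervals: Sequence[Tuple[int, int]] = (),
) -> List[GlycoModule]:
    """Scan for AGP-like glycomodules outside excluded intervals.

    Exclusions (fasciclin domains, N-terminal signal, C-terminal GPI
    signal) discard any site whose [A/S/T]-Pro(n) span overlaps them.
    Remaining sites are clustered transitively: consecutive sites merge
    when the gap between one site's final Pro and the next site's [A/S/T]
    is at most 10 residues.  A cluster becomes a module if it holds >= 2
    sites (``paired_sites``) or one site with a Pro run >= 2
    (``single_run``); the module spans the first [A/S/T] to the last Pro.
    """
    exclusions = _check_intervals(excluded_intervals, len(sequence))

    def excluded(site: OGlycoSite) -> bool:
        s, e = site.span
        return any(s <= xe and xs <= e for xs, xe in exclusions)

    sites = [s for s in find_oglyco_sites(sequence) if not excluded(s)]

    clusters: List[List[OGlycoSite]] = []
    for site in sites:
        if clusters:
            prev = clusters[-1][-1]
            gap = site.position - prev.span[1] - 1
            if gap <= MAX_SITE_GAP:
                clusters[-1].append(site)
                continue
        clusters.append([site])

    modules = []
    for cluster in clusters:
        if len(cluster) >= 2:
            rule = "paired_sites"
        elif cluster[0].full_run >= 2:
            rule = "single_run"
        else:
            continue
        modules.append(
            GlycoModule(
                start=cluster[0].position,
                end=cluster[-1].span[1],
                sites=tuple(cluster),
                qualifying_rule=rule,
            )
        )
    return modules


def glycomodule_report(protein_id: str, modules: Sequence[GlycoModule]) -> List[dict]:
    """Rows for the TSV report (one row per module)."""
    return [
        {
            "protein_id": protein_id,
            "module_start": m.start,
            "module_end": m.end,
            "n_sites": len(m.sites),
            "qualifying_rule": m.qualifying_rule,
            "site_positions": ",".join(str(s.position) for s in m.sites),
        }
        for m in modules
    ]
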