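"""Seed-deterministic generators for every input the pipeline assumes.

Proteins are assembled from the same architectural vocabulary the
classifier looks for - an N-terminal signal peptide (hydrophobic core
preceded by positives), one or two fasciclin domains whose conserved
blocks are sampled from the packaged seed alignment, AGP glycomodules
obeying the [A/S/T]-Pro grammar, and an optional GPI tail (small
omega-site residues followed by a hydrophobic stretch).  Filler sequence
contains no Pro, so every glycosylation site in a generated protein is a
planted one, and non-GPI proteins end in charged residues so the
hydrophobic-tail heuristic cannot fire by accident.

Ground truth is recorded next to every generated object; all generators
are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .domains import SEED_ALIGNMENT, BLOCK_INTERVALS
from .molevol import CODON_TABLE, STOP_CODONS, BASES, codon_sites
from .expression import CtTable
from .phylo import DistanceMatrix, PhyloTree, TreeNode
from .records import CdsRecord, FlakitError, ProteinRecord

# Pro-free filler alphabet: no [A/S/T]-Pro site can arise outside planted
# modules.  Weights loosely follow globular-protein composition.
_FILLER = "GEDKNQRHSTAYWMFLVI"
_FILLER_W = np.array(
    [0.10, 0.09, 0.08, 0.09, 0.07, 0.06, 0.07, 0.04, 0.05, 0.05, 0.05,
     0.04, 0.02, 0.03, 0.05, 0.08, 0.07, 0.06]
)
_FILLER_W = _FILLER_W / _FILLER_W.sum()

_SEED_COLUMNS = {
    name: [
        [row[c] for _, row in SEED_ALIGNMENT]
        for c in range(cs - 1, ce)
    ]
    for name, (cs, ce) in BLOCK_INTERVALS.items()
}


@dataclass
class ProteinTruth:
    """Planted architecture for one generated protein (1-based intervals)."""

    protein_id: str
    group: str  # A | B | C | D | nonFLA
    signal: Optional[Tuple[int, int]] = None
    fasciclin: List[Tuple[int, int]] = field(default_factory=list)
    modules: List[Tuple[int, int]] = field(default_factory=list)
    gpi: Optional[Tuple[int, int]] = None

    @property
    def is_fla(self) -> bool:
        return self.group in "ABCD"


class _Builder:
    """Accumulates sequence segments while tracking 1-based intervals."""

    def __init__(self) -> None:
        self.parts: List[str] = []
        self.length = 0

    def add(self, segment: str) -> Tuple[int, int]:
        start = self.length + 1
        self.parts.append(segment)
        self.length += len(segment)
        return (start, self.length)

    def sequence(self) -> str:
        return "".join(self.parts)


def _filler(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(list(_FILLER), size=n, p=_FILLER_W))


def _signal_peptide(rng: np.random.Generator) -> str:
    positives = "".join(rng.choice(["K", "R"], size=rng.integers(1, 3)))
    core = "".join(rng.choice(list("LVIAF"), size=rng.integers(10, 15)))
    return "M" + positives + core + "SG"


def _sample_block(name: str, rng: np.random.Generator) -> str:
    """Sample one block sequence column-wise from the seed alignment."""
    return "".join(rng.choice(col) for col in _SEED_COLUMNS[name])


def _fasciclin_domain(rng: np.random.Generator) -> str:
    h1 = _sample_block("H1", rng)
    yfh = _sample_block("YFH", rng)
    h2 = _sample_block("H2", rng)
    total = int(rng.integers(110, 151))
    linker_total = total - len(h1) - len(yfh) - len(h2)
    l1 = int(rng.integers(linker_total // 4, 3 * linker_total // 4 + 1))
    return h1 + _filler(rng, l1) + yfh + _filler(rng, linker_total - l1) + h2


def _glycomodule(rng: np.random.Generator) -> str:
    """A qualifying glycomodule: paired [A/S/T]P sites or one Pro run."""
    if rng.random() < 0.5:
        n_sites = int(rng.integers(2, 5))
        parts = []
        for k in range(n_sites):
            parts.append(str(rng.choice(list("AST"))) + "P")
            if k < n_sites - 1:
                parts.append(_filler(rng, int(rng.integers(0, 4))))
        return "".join(parts)
    return str(rng.choice(list("AST"))) + "P" * int(rng.integers(2, 4))


def _gpi_tail(rng: np.random.Generator) -> str:
    omega = str(rng.choice(list("ASG")))
    spacer = _filler(rng, int(rng.integers(2, 5)))
    tail = "".join(rng.choice(list("LVIF"), size=rng.integers(9, 13)))
    return omega + "G" + str(rng.choice(list("ASG"))) + spacer + tail


_NON_GPI_CAP = "DEK"  # charged C-terminus so the GPI heuristic cannot fire


def _assemble(group: str, rng: np.random.Generator, with_gpi: bool) -> Tuple[str, dict]:
    b = _Builder()
    truth: dict = {"fasciclin": [], "modules": [], "signal": None, "gpi": None}
    truth["signal"] = b.add(_signal_peptide(rng))
    pad = lambda lo, hi: b.add(_filler(rng, int(rng.integers(lo, hi + 1))))

    if group in ("A", "C"):
        pad(4, 10)
        truth["modules"].append(b.add(_glycomodule(rng)))
        pad(4, 10)
        truth["fasciclin"].append(b.add(_fasciclin_domain(rng)))
        pad(4, 10)
        truth["modules"].append(b.add(_glycomodule(rng)))
        if group == "C":
            target = int(rng.integers(390, 441))
            pad_len = max(0, target - b.length - 18)
            b.add(_filler(rng, pad_len))
    elif group == "B":
        pad(3, 8)
        truth["fasciclin"].append(b.add(_fasciclin_domain(rng)))
        pad(2, 6)
        truth["modules"].append(b.add(_glycomodule(rng)))
        pad(2, 6)
        truth["fasciclin"].append(b.add(_fasciclin_domain(rng)))
        target = int(rng.integers(430, 481))
        b.add(_filler(rng, max(0, target - b.length - 3)))
    elif group == "D":
        if rng.random() < 0.5:
            # one domain, glycomodules on one side only
            pad(4, 10)
            truth["fasciclin"].append(b.add(_fasciclin_domain(rng)))
            pad(2, 8)
            truth["modules"].append(b.add(_glycomodule(rng)))
            pad(6, 20)
        else:
            # two domains but far below the group-B length envelope
            pad(2, 5)
            truth["fasciclin"].append(b.add(_fasciclin_domain(rng)))
            pad(2, 5)
            truth["modules"].append(b.add(_glycomodule(rng)))
            pad(2, 5)
            truth["fasciclin"].append(b.add(_fasciclin_domain(rng)))
            pad(3, 8)
    else:  # pragma: no cover
        raise FlakitError(f"unknown group {group!r}")

    if with_gpi:
        pad(2, 6)
        truth["gpi"] = b.add(_gpi_tail(rng))
    else:
        b.add(_NON_GPI_CAP)
    return b.sequence(), truth


DEFAULT_GROUP_MIX: Dict[str, float] = {
    # the published family: 23 A, 4 B, 4 C, 4 D of 35, plus distractors
    "A": 0.23, "B": 0.04, "C": 0.04, "D": 0.04, "nonFLA": 0.65,
}

#: fraction of group-A members carrying a GPI anchor (18 of 23 published)
GPI_PROB = {"A": 18 / 23, "B": 0.0, "C": 1.0, "D": 0.25}


def make_proteome(
    n: int,
    group_mix: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> Tuple[List[ProteinRecord], List[ProteinTruth]]:
    """Generate ``n`` proteins with planted, recorded architectures.

    ``group_mix`` gives proportions over A/B/C/D/nonFLA and must sum to 1.
    Non-FLA distractors are composition-matched: a residue permutation of
    a freshly assembled FLA-style sequence (so PAST content matches but
    no architecture survives).
    """
    mix = dict(group_mix) if group_mix is not None else dict(DEFAULT_GROUP_MIX)
    for g in ("A", "B", "C", "D", "nonFLA"):
        mix.setdefault(g, 0.0)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise FlakitError(f"group_mix sums to {total}, expected 1")
    rng = np.random.default_rng(seed)
    groups = list(mix)
    probs = np.array([mix[g] for g in groups])
    records, truths = [], []
    for i in range(n):
        group = str(rng.choice(groups, p=probs))
        pid = f"syn{i + 1:04d}"
        if group == "nonFLA":
            template, _ = _assemble("A", rng, with_gpi=True)
            letters = list(template)
            rng.shuffle(letters)
            seq = "".join(letters) + _NON_GPI_CAP
            records.append(ProteinRecord(id=pid, sequence=seq))
            truths.append(ProteinTruth(protein_id=pid, group="nonFLA"))
        else:
            with_gpi = bool(rng.random() < GPI_PROB[group])
            seq, t = _assemble(group, rng, with_gpi)
            records.append(ProteinRecord(id=pid, sequence=seq))
            truths.append(
                ProteinTruth(
                    protein_id=pid,
                    group=group,
                    signal=t["signal"],
                    fasciclin=t["fasciclin"],
                    modules=t["modules"],
                    gpi=t["gpi"],
                )
            )
    return records, truths


def truth_table(truths: Sequence[ProteinTruth]) -> pd.DataFrame:
    """Truth records as a flat DataFrame (for the TSV truth file)."""
    rows = []
    for t in truths:
        rows.append(
            {
                "protein_id": t.protein_id,
                "group": t.group,
                "is_fla": t.is_fla,
                "signal": f"{t.signal[0]}-{t.signal[1]}" if t.signal else "",
                "fasciclin": ";".join(f"{s}-{e}" for s, e in t.fasciclin),
                "modules": ";".join(f"{s}-{e}" for s, e in t.modules),
                "gpi": f"{t.gpi[0]}-{t.gpi[1]}" if t.gpi else "",
            }
        )
    return pd.DataFrame(rows)


#: the published family composition: (group, n_members, n_with_gpi)
REFERENCE_FAMILY = (("A", 23, 18), ("B", 4, 0), ("C", 4, 4), ("D", 4, 1))


def make_reference_family(
    seed: int = 0,
    n_distractors: int = 65,
) -> Tuple[List[ProteinRecord], List[ProteinTruth]]:
    """A proteome planting the published family structure with exact counts.

    35 FLA proteins - 23 group A (18 of them GPI-anchored), 4 B (none),
    4 C (all), 4 D (one) - interleaved with composition-matched non-FLA
    distractors.  23 of the 35 members carry a GPI anchor, matching the
    reported proportion.
    """
    rng = np.random.default_rng(seed)
    spec: List[Tuple[str, bool]] = [("nonFLA", False)] * n_distractors
    for group, n_members, n_gpi in REFERENCE_FAMILY:
        spec += [(group, k < n_gpi) for k in range(n_members)]
    order = rng.permutation(len(spec))
    records, truths = [], []
    for i, idx in enumerate(order):
        group, with_gpi = spec[idx]
        pid = f"ref{i + 1:04d}"
        if group == "nonFLA":
            template, _ = _assemble("A", rng, with_gpi=True)
            letters = list(template)
            rng.shuffle(letters)
            records.append(ProteinRecord(id=pid, sequence="".join(letters) + _NON_GPI_CAP))
            truths.append(ProteinTruth(protein_id=pid, group="nonFLA"))
        else:
            seq, t = _assemble(group, rng, with_gpi)
            records.append(ProteinRecord(id=pid, sequence=seq))
            truths.append(
                ProteinTruth(
                    protein_id=pid,
                    group=group,
                    signal=t["signal"],
                    fasciclin=t["fasciclin"],
                    modules=t["modules"],
                    gpi=t["gpi"],
                )
            )
    return records, truths


# ---------------------------------------------------------------------------
# codon-pair generator
# ---------------------------------------------------------------------------

_SENSE_CODONS = sorted(set(CODON_TABLE) - STOP_CODONS)


def _mutation_choices(codon: str, synonymous: bool) -> List[str]:
    aa = CODON_TABLE[codon]
    out = []
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            if (CODON_TABLE[mut] == aa) == synonymous:
                out.append(mut)
    return out


@dataclass
class CdsPairTruth:
    pair_id: str
    n_syn_events: int
    n_nonsyn_events: int
    syn_rate: float
    nonsyn_rate: float


def make_cds_pairs(
    n_pairs: int,
    codons: int = 300,
    syn_rate: float = 0.1,
    nonsyn_rate: float = 0.0,
    seed: int = 0,
) -> Tuple[List[Tuple[CdsRecord, CdsRecord]], List[CdsPairTruth]]:
    """CDS pairs diverged from a common ancestor at controlled rates.

    ``syn_rate`` / ``nonsyn_rate`` are expected substitutions per
    synonymous / nonsynonymous site *between* the two sequences.  Events
    are Poisson in number, assigned to a random lineage, target codons in
    proportion to their current mutable-site counts, and may stack or
    revert, so the realised divergence follows a multiple-hit process the
    Jukes-Cantor correction is designed for.  Rates implying saturation
    (p >= 0.7) trigger a warning.
    """
    import warnings

    if syn_rate >= 0.7 or nonsyn_rate >= 0.7:
        warnings.warn("requested divergence approaches saturation (p >= 0.7)")
    rng = np.random.default_rng(seed)
    pairs, truths = [], []
    for ip in range(n_pairs):
        ancestor = [str(c) for c in rng.choice(_SENSE_CODONS, size=codons)]
        lineages = [list(ancestor), list(ancestor)]
        n_events = {}
        for synonymous, rate in ((True, syn_rate), (False, nonsyn_rate)):
            site_counts = np.array(
                [codon_sites(c)[0 if synonymous else 1] for c in ancestor]
            )
            n_ev = int(rng.poisson(rate * site_counts.sum()))
            n_events[synonymous] = n_ev
            for _ in range(n_ev):
                lin = lineages[int(rng.integers(0, 2))]
                weights = np.array(
                    [codon_sites(c)[0 if synonymous else 1] for c in lin]
                )
                weights = weights / weights.sum()
                idx = int(rng.choice(codons, p=weights))
                choices = _mutation_choices(lin[idx], synonymous)
                if not choices:
                    continue
                lin[idx] = str(rng.choice(choices))
        id_a, id_b = f"pair{ip + 1:03d}a", f"pair{ip + 1:03d}b"
        pairs.append(
            (
                CdsRecord(id=id_a, sequence="".join(lineages[0])),
                CdsRecord(id=id_b, sequence="".join(lineages[1])),
            )
        )
        truths.append(
            CdsPairTruth(
                pair_id=f"pair{ip + 1:03d}",
                n_syn_events=n_events[True],
                n_nonsyn_events=n_events[False],
                syn_rate=syn_rate,
                nonsyn_rate=nonsyn_rate,
            )
        )
    return pairs, truths


# ---------------------------------------------------------------------------
# Ct-table generator
# ---------------------------------------------------------------------------

def make_ct_table(
    genes: Sequence[str],
    samples: Sequence[str],
    true_folds: Mapping[str, Mapping[str, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    reference_gene: str = "actin",
    reference_ct: float = 20.0,
    base_dct: float = 5.0,
) -> Tuple[CtTable, pd.DataFrame]:
    """Invert the 2^-ddCt model to produce a Ct table with known folds.

    ``true_folds[gene][sample]`` is the fold change relative to the
    lowest-expressed sample (which should carry fold 1).  Gaussian noise
    of ``noise_sd`` cycles is added per replicate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample in samples:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "gene": reference_gene,
                    "sample": sample,
                    "replicate": rep,
                    "ct": reference_ct + rng.normal(0.0, noise_sd),
                }
            )
    truth_rows = []
    for gene in genes:
        folds = true_folds[gene]
        for sample in samples:
            fold = float(folds[sample])
            if fold <= 0:
                raise FlakitError(f"non-positive fold {fold} for {gene}/{sample}")
            dct = base_dct - np.log2(fold)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene": gene,
                        "sample": sample,
                        "replicate": rep,
                        "ct": reference_ct + dct + rng.normal(0.0, noise_sd),
                    }
                )
            truth_rows.append({"gene": gene, "sample": sample, "fold": fold})
    table = CtTable(pd.DataFrame(rows), reference_gene=reference_gene)
    return table, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# random additive trees (for NJ recovery and bootstrap tests)
# ---------------------------------------------------------------------------

def tree_distances(tree: PhyloTree) -> DistanceMatrix:
    """Exact additive leaf-to-leaf path lengths of a tree."""
    labels = sorted(tree.root.leaves())
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))

    def collect(node: TreeNode) -> Dict[str, float]:
        if not node.children:
            return {node.name: 0.0}
        child_maps = []
        for child, bl in node.children:
            m = collect(child)
            child_maps.append({leaf: depth + bl for leaf, depth in m.items()})
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                for la, da in child_maps[i].items():
                    for lb, db in child_maps[j].items():
                        d[index[la], index[lb]] = d[index[lb], index[la]] = da + db
        merged: Dict[str, float] = {}
        for m in child_maps:
            merged.update(m)
        return merged

    collect(tree.root)
    return DistanceMatrix(labels=labels, d=d)


def make_random_tree(
    n_leaves: int,
    seed: int = 0,
    branch_range: Tuple[float, float] = (0.05, 0.5),
) -> Tuple[PhyloTree, DistanceMatrix]:
    """A random unrooted binary tree and its exact additive distances."""
    if n_leaves < 3:
        raise FlakitError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_leaves)]
    lo, hi = branch_range
    nodes: List[TreeNode] = [TreeNode(name=lab) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        bi, bj = rng.uniform(lo, hi, size=2)
        parent = TreeNode(children=[(nodes[i], float(bi)), (nodes[j], float(bj))])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    bl = rng.uniform(lo, hi, size=3)
    root = TreeNode(children=[(nd, float(b)) for nd, b in zip(nodes, bl)])
    tree = PhyloTree(root=root, labels=labels)
    dm = tree_distances(tree)
    tree.labels = dm.labels
    return tree, dm


def make_clade_alignment(
    n_per_clade: int = 10,
    length: int = 200,
    divergence: float = 0.5,
    within_noise: float = 0.02,
    seed: int = 0,
) -> List[Tuple[str, str]]:
    """Two strongly separated clades of protein sequences.

    Clade anchors differ at a ``divergence`` fraction of positions; each
    leaf mutates its anchor at a ``within_noise`` fraction.  The edge
    separating the clades should earn near-100% bootstrap support.
    """
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    anchor1 = rng.choice(aas, size=length)
    anchor2 = anchor1.copy()
    flip = rng.random(length) < divergence
    for i in np.nonzero(flip)[0]:
        anchor2[i] = rng.choice([a for a in aas if a != anchor1[i]])
    rows = []
    for c, anchor in ((1, anchor1), (2, anchor2)):
        for k in range(n_per_clade):
            leaf = anchor.copy()
            for i in np.nonzero(rng.random(length) < within_noise)[0]:
                leaf[i] = rng.choice([a for a in aas if a != anchor[i]])
            rows.append((f"c{c}_{k + 1}", "".join(leaf)))
    return rows
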