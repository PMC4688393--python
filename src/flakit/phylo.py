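"""Pairwise alignment, distance matrices, neighbor joining, bootstrap.

Global alignment is Needleman-Wunsch with affine gaps (BLOSUM62, gap open
10, extension 0.1 - the Clustal-style penalties), provided through
Biopython's PairwiseAligner.  Neighbor joining is the Saitou-Nei
Q-criterion algorithm with deterministic tie-breaking; negative branch
lengths are clamped to zero with the deficit moved onto the sister edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import FlakitError, ProteinRecord


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    percent_similarity: float


def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.1
    return aligner


def global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> AlignmentResult:
    """Global alignment with percent identity and similarity.

    Identity = matches / alignment columns (dual-gap columns excluded);
    similarity additionally counts residue pairs with a positive
    substitution score.
    """
    if not a.sequence or not b.sequence:
        raise FlakitError("global_align: empty sequence")
    aligner = aligner or _default_aligner()
    aln = aligner.align(a.sequence, b.sequence)[0]
    ra, rb = str(aln[0]), str(aln[1])
    matrix = aligner.substitution_matrix
    cols = matches = similar = 0
    for x, y in zip(ra, rb):
        if x == "-" and y == "-":
            continue
        cols += 1
        if x == "-" or y == "-":
            continue
        if x == y:
            matches += 1
            similar += 1
        elif matrix[x, y] > 0:
            similar += 1
    return AlignmentResult(
        aligned_a=ra,
        aligned_b=rb,
        score=float(aln.score),
        percent_identity=100.0 * matches / cols,
        percent_similarity=100.0 * similar / cols,
    )


@dataclass
class DistanceMatrix:
    labels: List[str]
    d: np.ndarray
    zero_variation: bool = False

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise FlakitError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.all(np.isfinite(self.d)):
            raise FlakitError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise FlakitError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise FlakitError("nonzero diagonal")
        if np.any(self.d < 0):
            raise FlakitError("negative distances")


def msa_to_distances(
    alignment: Sequence[Tuple[str, str]],
    model: str = "p_distance",
) -> DistanceMatrix:
    """p-distance or Poisson-corrected distances with pairwise gap deletion."""
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    labels = [lab for lab, _ in alignment]
    rows = [row for _, row in alignment]
    arr = np.array([list(r) for r in rows])
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != "-") & (arr[j] != "-")
            compared = int(ok.sum())
            if compared == 0:
                raise FlakitError(
                    f"no comparable columns for pair {labels[i]}/{labels[j]}"
                )
            p = float((arr[i][ok] != arr[j][ok]).sum()) / compared
            if model == "poisson":
                if p >= 1.0:
                    raise FlakitError(
                        f"poisson distance undefined (p={p}) for pair "
                        f"{labels[i]}/{labels[j]}"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    zero_var = bool(np.all(d == 0))
    return DistanceMatrix(labels=labels, d=d, zero_variation=zero_var)


@dataclass
class TreeNode:
    name: Optional[str] = None
    children: List[Tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    def leaves(self) -> List[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree, represented with a trifurcating root."""

    root: TreeNode
    labels: List[str]
    zero_variation: bool = False
    supports: Optional[Dict[FrozenSet[str], float]] = None

    def newick(self, decimals: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return node.name
            inner = ",".join(
                f"{fmt(c)}:{bl:.{decimals}f}" for c, bl in node.children
            )
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def bipartitions(self) -> Dict[FrozenSet[str], float]:
        """Non-trivial bipartitions, each keyed by the side not holding the
        reference (lexicographically smallest) leaf; value = branch length."""
        ref = min(self.labels)
        total = set(self.labels)
        out: Dict[FrozenSet[str], float] = {}

        def walk(node: TreeNode) -> None:
            for child, bl in node.children:
                side = set(child.leaves())
                if 2 <= len(side) <= len(total) - 2:
                    key = frozenset(side if ref not in side else total - side)
                    out[key] = bl
                walk(child)

        walk(self.root)
        return out

    def total_length(self) -> float:
        def walk(node: TreeNode) -> float:
            return sum(bl + walk(c) for c, bl in node.children)

        return walk(self.root)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Tie-breaking in the Q minimisation is by lowest (i, j) index pair so
    output is deterministic.  Negative branch lengths are clamped to zero
    and the deficit transferred to the sister edge, keeping the path
    length between the joined pair intact.
    """
    n = len(dm.labels)
    if n < 3:
        raise FlakitError(f"neighbor joining needs >= 3 taxa, got {n}")
    D = dm.d.astype(float).copy()
    nodes: List[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i, j] - vi
        if vi < 0:
            vj, vi = vj + vi, 0.0
        if vj < 0:
            vi, vj = vi + vj, 0.0
        parent = TreeNode(children=[(nodes[i], vi), (nodes[j], vj)])
        new_d = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = new_d[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-way join
    a, b, c = nodes
    va = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    vb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    vc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    root = TreeNode(
        children=[(a, max(va, 0.0)), (b, max(vb, 0.0)), (c, max(vc, 0.0))]
    )
    return PhyloTree(root=root, labels=list(dm.labels),
                     zero_variation=dm.zero_variation)


def bootstrap_support(
    alignment: Sequence[Tuple[str, str]],
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "p_distance",
) -> PhyloTree:
    """NJ tree with bootstrap supports (percent of replicates containing
    each original bipartition).

    Columns are resampled with replacement; each replicate is rebuilt with
    the same distance model.  A zero-variation alignment is flagged via
    ``tree.zero_variation`` rather than raising.
    """
    if n_replicates < 1:
        raise FlakitError("n_replicates must be >= 1")
    tree = neighbor_joining(msa_to_distances(alignment, model))
    original = tree.bipartitions()
    counts = {bp: 0 for bp in original}
    rng = np.random.default_rng(seed)
    labels = [lab for lab, _ in alignment]
    arr = np.array([list(row) for _, row in alignment])
    width = arr.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, width, size=width)
        rep = [(lab, "".join(arr[i, cols])) for i, lab in enumerate(labels)]
        try:
            rep_tree = neighbor_joining(msa_to_distances(rep, model))
        except FlakitError:
            continue
        rep_bps = set(rep_tree.bipartitions())
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    tree.supports = supports

    ref = min(tree.labels)
    total = set(tree.labels)

    def annotate(node: TreeNode) -> None:
        for child, _ in node.children:
            side = set(child.leaves())
            if 2 <= len(side) <= len(total) - 2:
                key = frozenset(side if ref not in side else total - side)
                child.support = supports.get(key)
            annotate(child)

    annotate(tree.root)
    return tree
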