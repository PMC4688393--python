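"""Alignment, distances, NJ and bootstrap against independent oracles."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from flakit.phylo import (
    DistanceMatrix,
    bootstrap_support,
    global_align,
    msa_to_distances,
    neighbor_joining,
)
from flakit.records import FlakitError, ProteinRecord
from flakit.synthetic import make_clade_alignment, make_random_tree

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_score(a, b, open_score=-10.0, ext_score=-0.1):
    """Textbook affine-gap global DP (score of the first gap residue =
    open_score, each further residue ext_score); independent oracle."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_score + (i - 1) * ext_score
    for j in range(1, m + 1):
        Y[0, j] = open_score + (j - 1) * ext_score
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(
                M[i - 1, j] + open_score,
                X[i - 1, j] + ext_score,
                Y[i - 1, j] + open_score,
            )
            Y[i, j] = max(
                M[i, j - 1] + open_score,
                Y[i, j - 1] + ext_score,
                X[i, j - 1] + open_score,
            )
    return max(M[n, m], X[n, m], Y[n, m])


def test_self_alignment_is_100_percent_identity():
    r = ProteinRecord(id="a", sequence="MKVLATPQW")
    res = global_align(r, r)
    assert res.percent_identity == 100.0


def test_single_mismatch_identity():
    res = global_align(
        ProteinRecord(id="a", sequence="AAAA"), ProteinRecord(id="b", sequence="AATA")
    )
    assert res.percent_identity == pytest.approx(75.0)
    assert "-" not in res.aligned_a + res.aligned_b


def test_empty_sequence_rejected():
    with pytest.raises(Exception):
        global_align(
            ProteinRecord(id="a", sequence="A"), ProteinRecord(id="b", sequence="")
        )


def test_alignment_score_matches_dp_oracle_on_random_pairs():
    rng = np.random.default_rng(17)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(100):
        a = "".join(rng.choice(aas, size=rng.integers(5, 30)))
        b = "".join(rng.choice(aas, size=rng.integers(5, 30)))
        res = global_align(
            ProteinRecord(id="a", sequence=a), ProteinRecord(id="b", sequence=b)
        )
        assert res.score == pytest.approx(gotoh_score(a, b), abs=1e-6)


def test_distances_identical_and_quarter():
    dm = msa_to_distances([("a", "AAAA"), ("b", "AAAA")])
    assert dm.d[0, 1] == 0.0 and dm.zero_variation
    dm = msa_to_distances([("a", "AAAA"), ("b", "AAAT")])
    assert dm.d[0, 1] == pytest.approx(0.25)
    dmp = msa_to_distances([("a", "AAAA"), ("b", "AAAT")], model="poisson")
    assert dmp.d[0, 1] == pytest.approx(-math.log(0.75))


def test_poisson_saturation_names_pair():
    with pytest.raises(FlakitError, match="x/y"):
        msa_to_distances([("x", "AAAA"), ("y", "TTTT")], model="poisson")


def test_pairwise_gap_deletion():
    dm = msa_to_distances([("a", "A-AT"), ("b", "AAAA")])
    assert dm.d[0, 1] == pytest.approx(1 / 3)


def test_three_taxon_closed_form():
    d = np.array([[0, 4.0, 6.0], [4.0, 0, 8.0], [6.0, 8.0, 0]])
    tree = neighbor_joining(DistanceMatrix(labels=["A", "B", "C"], d=d))
    lengths = {child.name: bl for child, bl in tree.root.children}
    assert lengths["A"] == pytest.approx((4 + 6 - 8) / 2)
    assert lengths["B"] == pytest.approx((4 + 8 - 6) / 2)
    assert lengths["C"] == pytest.approx((6 + 8 - 4) / 2)


def test_fewer_than_three_taxa_rejected():
    d = np.array([[0, 1.0], [1.0, 0]])
    with pytest.raises(FlakitError):
        neighbor_joining(DistanceMatrix(labels=["A", "B"], d=d))


def test_four_taxon_additive_recovery():
    # hand-drawn tree: (A:1,B:2):1 joined to (C:3,D:4) via internal edge 1
    labels = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    # four-point condition: AB|CD is the split
    assert d[0, 1] + d[2, 3] < d[0, 2] + d[1, 3] == d[0, 3] + d[1, 2]
    tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
    bps = tree.bipartitions()
    (split,) = bps.keys()
    assert split in (frozenset({"A", "B"}), frozenset({"C", "D"}))
    assert bps[split] == pytest.approx(1.0)


@pytest.mark.parametrize("n_leaves", [8, 20, 30])
def test_additive_matrix_reproduces_generating_tree(n_leaves):
    truth, dm = make_random_tree(n_leaves, seed=n_leaves)
    nj = neighbor_joining(dm)
    tb, nb = truth.bipartitions(), nj.bipartitions()
    assert set(tb) == set(nb)  # Robinson-Foulds distance 0
    for bp, bl in tb.items():
        assert nb[bp] == pytest.approx(bl, abs=1e-9)


def test_nj_matches_scikit_bio_topology():
    import io as _io

    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    truth, dm = make_random_tree(12, seed=99)
    mine = neighbor_joining(dm)
    sk_tree = sk_nj(SkDM(dm.d, ids=dm.labels))
    ref = min(dm.labels)
    total = set(dm.labels)
    sk_bps = set()
    for node in sk_tree.non_tips():
        side = {t.name for t in node.tips()}
        if 2 <= len(side) <= len(total) - 2:
            sk_bps.add(frozenset(side if ref not in side else total - side))
    assert set(mine.bipartitions()) == sk_bps


def test_total_length_invariant_under_label_permutation():
    _, dm = make_random_tree(10, seed=5)
    base = neighbor_joining(dm).total_length()
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(dm.labels))
    dm2 = DistanceMatrix(
        labels=[dm.labels[i] for i in perm], d=dm.d[np.ix_(perm, perm)]
    )
    assert neighbor_joining(dm2).total_length() == pytest.approx(base)


def test_bootstrap_determinism_and_range():
    rows = make_clade_alignment(n_per_clade=4, length=80, seed=2)
    t1 = bootstrap_support(rows, n_replicates=50, seed=11)
    t2 = bootstrap_support(rows, n_replicates=50, seed=11)
    assert t1.supports == t2.supports
    assert all(0 <= v <= 100 for v in t1.supports.values())
    with pytest.raises(FlakitError):
        bootstrap_support(rows, n_replicates=0)


def test_zero_variation_alignment_is_flagged_not_fatal():
    rows = [(f"t{i}", "AAAA") for i in range(4)]
    tree = bootstrap_support(rows, n_replicates=10, seed=0)
    assert tree.zero_variation


def test_clade_separating_edge_gets_high_support():
    rows = make_clade_alignment(n_per_clade=10, length=200, seed=3)
    tree = bootstrap_support(rows, n_replicates=200, seed=5)
    labels = {lab for lab, _ in rows}
    clade2 = frozenset(l for l in labels if l.startswith("c2"))
    ref = min(labels)
    key = clade2 if ref not in clade2 else frozenset(labels - clade2)
    assert tree.supports[key] >= 95.0
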