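"""Fasciclin block profiles, domain scan, terminal-signal heuristics."""

import numpy as np
import pytest

from flakit.domains import (
    BLOCK_INTERVALS,
    SEED_ALIGNMENT,
    build_block_profiles,
    default_block_profiles,
    detect_gpi_signal,
    detect_signal_peptide,
    permutation_null_scores,
    scan_fasciclin,
    DomainScanConfig,
)
from flakit.records import DomainAnnotation, FlakitError, ProteinRecord
from flakit.synthetic import make_proteome


def test_unanimous_column_puts_maximum_weight_on_observed_letter():
    aln = [("a", "AITAPNDT"), ("b", "AITAPNDT"), ("c", "AITAPNDT")]
    (profile,) = build_block_profiles(aln, {"H1": (1, 8)})
    for k, expected in enumerate("AITAPNDT"):
        col = profile.columns[k]
        assert max(col, key=col.get) == expected
    assert all(abs(sum(c.values()) - 1) < 1e-12 for c in profile.columns)


def test_add_one_smoothing_weights():
    aln = [("a", "A"), ("b", "A"), ("c", "S"), ("d", "T")]
    (profile,) = build_block_profiles(aln, {"H1": (1, 1)})
    col = profile.columns[0]
    assert col["A"] == pytest.approx(3 / 24)
    assert col["S"] == col["T"] == pytest.approx(2 / 24)
    assert col["A"] > col["S"] == col["T"] > col["G"]


def test_profile_preconditions():
    with pytest.raises(FlakitError):
        build_block_profiles([], {"H1": (1, 8)})
    with pytest.raises(FlakitError):
        build_block_profiles([("a", "AAAA")], {"H1": (1, 9)})
    gappy = [("a", "A-"), ("b", "A-"), ("c", "AC")]
    with pytest.raises(FlakitError, match="gaps"):
        build_block_profiles(gappy, {"H1": (1, 2)})


def test_seed_alignment_h1_thr_is_invariant():
    h1_cols = BLOCK_INTERVALS["H1"]
    thr_col = [row[1] for _, row in SEED_ALIGNMENT]  # column 2 of H1
    assert set(thr_col) == {"T"}
    assert h1_cols == (1, 10)


def test_planted_domains_located_and_blocks_ordered():
    records, truths = make_proteome(60, seed=9)
    profiles = default_block_profiles()
    for rec, truth in zip(records, truths):
        if truth.group == "nonFLA":
            continue
        anns = scan_fasciclin(rec, profiles)
        assert len(anns) == len(truth.fasciclin)
        for ann, (ps, pe) in zip(anns, truth.fasciclin):
            assert ann.start == ps and ann.end == pe
            h1, yfh, h2 = ann.blocks["H1"], ann.blocks["YFH"], ann.blocks["H2"]
            assert h1[1] < yfh[0] and yfh[1] < h2[0]


def test_two_domain_proteins_report_two_ordered_annotations():
    records, truths = make_proteome(120, seed=13)
    profiles = default_block_profiles()
    seen_two = 0
    for rec, truth in zip(records, truths):
        if len(truth.fasciclin) == 2:
            anns = scan_fasciclin(rec, profiles)
            assert len(anns) == 2
            assert anns[0].end < anns[1].start
            seen_two += 1
    assert seen_two > 0


def test_shuffled_protein_scores_below_threshold():
    records, truths = make_proteome(40, seed=21)
    rec = next(r for r, t in zip(records, truths) if t.group != "nonFLA")
    rng = np.random.default_rng(0)
    letters = list(rec.sequence)
    rng.shuffle(letters)
    shuffled = ProteinRecord(id="shuf", sequence="".join(letters))
    assert scan_fasciclin(shuffled) == []
    # default total threshold sits above the permutation null
    null = permutation_null_scores(rec, n_permutations=30, seed=1)
    assert np.nanmax(null) < DomainScanConfig().min_total_score


def test_scan_recall_and_precision_on_planted_truth():
    records, truths = make_proteome(200, seed=31)
    profiles = default_block_profiles()
    tp = fp = fn = 0
    for rec, truth in zip(records, truths):
        anns = scan_fasciclin(rec, profiles)
        found = [(a.start, a.end) for a in anns]
        planted = list(truth.fasciclin)
        for ps, pe in planted:
            if any(s <= pe and ps <= e for s, e in found):
                tp += 1
            else:
                fn += 1
        for s, e in found:
            if not any(s <= pe and ps <= e for ps, pe in planted):
                fp += 1
    recall = tp / (tp + fn)
    precision = tp / (tp + fp)
    assert recall >= 0.95 and precision >= 0.95


def test_signal_peptide_heuristic_and_precedence():
    pos = ProteinRecord(id="p", sequence="MKK" + "L" * 12 + "DEDNQNKRSGED" * 5)
    ann = detect_signal_peptide(pos)
    assert ann is not None and ann.start == 1 and ann.source == "builtin"
    neg = ProteinRecord(id="n", sequence="MDEDEDEDED" + "GNQKRSDE" * 6)
    assert detect_signal_peptide(neg) is None
    imported = DomainAnnotation(
        protein_id="p", kind="signal_peptide", start=1, end=25,
        score=0.9, source="imported",
    )
    got = detect_signal_peptide(pos, [imported])
    assert got.end == 25 and got.source == "imported"


def test_gpi_heuristic_and_precedence():
    pos = ProteinRecord(
        id="g", sequence="M" + "GNQKRSDE" * 8 + "SSASAG" + "LLLLVVLLL"
    )
    ann = detect_gpi_signal(pos)
    assert ann is not None and ann.end == len(pos)
    neg = ProteinRecord(id="ng", sequence="M" + "GNQKRSDE" * 8 + "DEDEDEDE")
    assert detect_gpi_signal(neg) is None
    imported = DomainAnnotation(
        protein_id="g", kind="gpi_anchor", start=60, end=80,
        score=0.8, source="imported",
    )
    got = detect_gpi_signal(pos, [imported])
    assert (got.start, got.end, got.source) == (60, 80, "imported")
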