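"""NG86 counting vs a pathway-enumeration oracle; dating; duplication."""

import numpy as np
import pytest

from flakit.molevol import (
    CODON_TABLE,
    STOP_CODONS,
    ClockParams,
    CodonAlignment,
    backtranslate_alignment,
    chromosome_counts,
    classify_duplication,
    codon_differences,
    codon_sites,
    divergence_time,
    jukes_cantor,
    ng86,
)
from flakit.records import CdsRecord, FlakitError
from flakit.synthetic import make_cds_pairs

from tests_oracles import ng86_oracle_pair as oracle_pair

SENSE = sorted(set(CODON_TABLE) - STOP_CODONS)


# --- examples ---------------------------------------------------------------

def test_phe_codon_site_partition():
    s, n = codon_sites("TTT")
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)


def test_sites_always_sum_to_three():
    for codon in SENSE:
        s, n = codon_sites(codon)
        assert s + n == pytest.approx(3.0)
        assert 0 <= s <= 3


def test_identical_rows_zero_divergence_missing_ratio():
    ca = CodonAlignment("a", "b", "ATGAAATTT", "ATGAAATTT")
    res = ng86(ca)
    assert res.Ka == 0.0 and res.Ks == 0.0 and res.ratio is None
    assert res.selection is None


def test_counts_match_oracle_on_random_codon_pairs():
    rng = np.random.default_rng(12)
    for _ in range(500):
        ca, cb = rng.choice(SENSE, size=2)
        S_o, N_o, Sd_o, Nd_o = oracle_pair(ca, cb)
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        assert 0.5 * (sa + sb) == pytest.approx(S_o)
        sd, nd = codon_differences(ca, cb)
        assert sd == pytest.approx(Sd_o) and nd == pytest.approx(Nd_o)


def test_saturation_raises():
    with pytest.raises(FlakitError, match="saturated"):
        jukes_cantor(0.8)


def test_gapped_columns_skipped():
    ca = CodonAlignment("a", "b", "ATG---AAA", "ATGGCTAAA")
    res = ng86(ca)
    assert res.S_sites + res.N_sites == pytest.approx(3 * 2)


def test_synonymous_only_simulation_recovers_ks():
    pairs, _ = make_cds_pairs(8, codons=800, syn_rate=0.1, nonsyn_rate=0.0, seed=4)
    ks, ka = [], []
    for a, b in pairs:
        res = ng86(CodonAlignment(a.id, b.id, a.sequence, b.sequence))
        ks.append(res.Ks)
        ka.append(res.Ka)
    assert abs(np.mean(ks) - 0.1) / 0.1 < 0.10
    assert np.mean(ka) < 0.005


# --- backtranslation --------------------------------------------------------

def test_single_gap_expansion():
    ca = backtranslate_alignment(
        [("a", "M-K"), ("b", "MAK")],
        [CdsRecord(id="a", sequence="ATGAAA"), CdsRecord(id="b", sequence="ATGGCTAAA")],
    )
    assert ca.row_a == "ATG---AAA" and ca.row_b == "ATGGCTAAA"


def test_translation_mismatch_names_codon():
    with pytest.raises(FlakitError, match="codon 2"):
        backtranslate_alignment(
            [("a", "MK"), ("b", "MK")],
            [CdsRecord(id="a", sequence="ATGCCC"),
             CdsRecord(id="b", sequence="ATGAAA")],
        )


def test_backtranslation_roundtrip_on_synthetic_pairs():
    from flakit.molevol import translate_cds

    pairs, _ = make_cds_pairs(20, codons=60, syn_rate=0.05, nonsyn_rate=0.05, seed=9)
    for a, b in pairs:
        pa, pb = translate_cds(a), translate_cds(b)
        ca = backtranslate_alignment([(a.id, pa), (b.id, pb)], [a, b])
        assert ca.row_a.replace("-", "") == a.sequence
        assert translate_cds(CdsRecord(id="x", sequence=ca.row_b.replace("-", ""))) == pb


# --- dating -----------------------------------------------------------------

@pytest.mark.parametrize(
    "ks,expected",
    [(0.2364, 13.0), (0.0858, 4.7), (0.3306, 18.2), (0.0909, 5.0), (0.0, 0.0)],
)
def test_divergence_time_published_spot_checks(ks, expected):
    assert round(divergence_time(ks), 1) == expected


def test_divergence_time_full_published_column(ptrfla_pairs):
    hits = sum(
        abs(divergence_time(row.ks) - row.mya) <= 0.1
        for row in ptrfla_pairs.itertuples()
    )
    assert hits >= 11


def test_divergence_time_linearity():
    assert divergence_time(0.2) == pytest.approx(2 * divergence_time(0.1))
    assert divergence_time(0.2, ClockParams(lam=4.55e-9)) == pytest.approx(
        2 * divergence_time(0.2)
    )
    with pytest.raises(FlakitError):
        divergence_time(-0.1)


# --- duplication & chromosome summaries -------------------------------------

def test_duplication_typing_from_published_loci(ptrfla_loci):
    by_symbol = {l.gene_symbol: l for l in ptrfla_loci}
    assert classify_duplication(by_symbol["PtrFLA17"], by_symbol["PtrFLA18"]) == "tandem"
    assert (
        classify_duplication(by_symbol["PtrFLA2"], by_symbol["PtrFLA12"]) == "segmental"
    )
    with pytest.raises(FlakitError, match="self-pair"):
        classify_duplication(by_symbol["PtrFLA2"], by_symbol["PtrFLA2"])


def test_same_chromosome_pair_count_matches_published(ptrfla_loci, ptrfla_pairs):
    by_symbol = {l.gene_symbol: l for l in ptrfla_loci}
    kinds = [
        classify_duplication(by_symbol[r.gene_a], by_symbol[r.gene_b])
        for r in ptrfla_pairs.itertuples()
    ]
    assert kinds.count("tandem") == 3 and kinds.count("segmental") == 9


def test_chromosome_counts_match_published(ptrfla_loci):
    counts = chromosome_counts(ptrfla_loci)
    assert counts["Chr19"] == 8 and counts["Chr13"] == 5
    assert len(counts) == 16
    for absent in ("Chr03", "Chr07", "Chr18"):
        assert absent not in counts
    universe = [f"Chr{i:02d}" for i in range(1, 20)]
    full = chromosome_counts(ptrfla_loci, universe)
    assert full["Chr03"] == 0 and full["Chr18"] == 0
    assert chromosome_counts([]) == {}
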