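"""ddCt quantification, matrix transforms, group significance tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flakit.expression import (
    CtTable,
    ExpressionMatrix,
    ddct,
    group_tests,
    log2_matrix,
)
from flakit.records import FlakitError
from flakit.synthetic import make_ct_table


def _table(rows, ref="actin"):
    return CtTable(pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"]),
                   reference_gene=ref)


def test_equal_cts_give_fold_one_everywhere():
    rows = [
        (g, s, r, 22.0)
        for g in ("actin", "fla1")
        for s in ("s1", "s2", "s3")
        for r in (1, 2, 3)
    ]
    out = ddct(_table(rows), "fla1")
    assert np.allclose(out["fold"], 1.0)


def test_ddct_minus_one_doubles():
    rows = [("actin", "a", 1, 20.0), ("actin", "b", 1, 20.0),
            ("g", "a", 1, 25.0), ("g", "b", 1, 24.0)]
    out = ddct(_table(rows), "g", calibrator="a").set_index("sample")
    assert out.loc["b", "ddct"] == pytest.approx(-1.0)
    assert out.loc["b", "fold"] == pytest.approx(2.0)
    assert out.loc["a", "fold"] == pytest.approx(1.0)


def test_missing_reference_is_error():
    rows = [("actin", "a", 1, 20.0), ("g", "a", 1, 25.0), ("g", "b", 1, 24.0)]
    with pytest.raises(FlakitError):
        ddct(_table(rows), "g")


def test_zero_noise_generation_inverts_exactly():
    folds = {"g1": {"s1": 1.0, "s2": 2.0, "s3": 8.0}}
    table, truth = make_ct_table(["g1"], ["s1", "s2", "s3"], folds, noise_sd=0.0)
    out = ddct(table, "g1").set_index("sample")
    for s, f in folds["g1"].items():
        assert out.loc[s, "fold"] == pytest.approx(f)


def test_ddct_invariant_to_per_sample_ct_shift():
    folds = {"g1": {"s1": 1.0, "s2": 4.0}}
    table, _ = make_ct_table(["g1"], ["s1", "s2"], folds, noise_sd=0.0)
    shifted = table.data.copy()
    shifted.loc[shifted["sample"] == "s2", "ct"] += 3.7
    out_a = ddct(table, "g1").set_index("sample")["fold"]
    out_b = ddct(CtTable(shifted, "actin"), "g1").set_index("sample")["fold"]
    assert np.allclose(out_a, out_b)


def test_noisy_recovery_within_tolerance():
    samples = ["s1", "s2", "s3"]
    folds = {"g1": {"s1": 1.0, "s2": 2.0, "s3": 8.0}}
    errs = []
    for seed in range(20):
        table, _ = make_ct_table(["g1"], samples, folds, noise_sd=0.1, seed=seed)
        out = ddct(table, "g1", calibrator="s1").set_index("sample")
        for s in ("s2", "s3"):
            errs.append(abs(out.loc[s, "fold"] - folds["g1"][s]) / folds["g1"][s])
    assert max(errs) < 0.25


def test_log2_matrix_and_double_application():
    m = ExpressionMatrix(pd.DataFrame([[8.0, 0.0]], index=["g"], columns=["a", "b"]))
    out = log2_matrix(m, pseudocount=1.0)
    assert out.values.loc["g", "a"] == pytest.approx(np.log2(9.0))
    assert out.transform == "log2"
    m8 = ExpressionMatrix(pd.DataFrame([[8.0]]))
    assert log2_matrix(m8).values.iloc[0, 0] == pytest.approx(3.0)
    with pytest.raises(FlakitError):
        log2_matrix(out)


def test_t_test_null_and_strong_effect():
    res = group_tests({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]}, design="t_test")
    assert res["stars"] == "" and np.isnan(res["t"]) or res["t"] == 0.0
    res = group_tests(
        {"a": [0.01, -0.02, 0.0], "b": [10.0, 10.02, 9.98]}, design="t_test"
    )
    assert res["stars"] == "**" and res["p"] <= 0.01


def test_anova_requires_replicates():
    with pytest.raises(FlakitError, match="replicates"):
        group_tests({"a": [1.0], "b": [1.0, 2.0]})


def test_tukey_letters_are_consistent():
    rng = np.random.default_rng(8)
    groups = {
        "low1": list(rng.normal(0, 0.2, 5)),
        "low2": list(rng.normal(0.1, 0.2, 5)),
        "high": list(rng.normal(5, 0.2, 5)),
    }
    res = group_tests(groups)
    letters = res["letters"]
    sig = {
        frozenset((p["group1"], p["group2"])): p["significant"]
        for p in res["pairwise"]
    }
    for g1 in letters:
        for g2 in letters:
            if g1 >= g2:
                continue
            shared = set(letters[g1]) & set(letters[g2])
            if shared:
                assert not sig[frozenset((g1, g2))]
    # the separated group must not share any letter with the others
    assert not (set(letters["high"]) & set(letters["low1"]))


def test_anova_type_i_error_under_null():
    rng = np.random.default_rng(123)
    n_sim, n_rep = 1000, 5
    a = rng.normal(size=(n_sim, n_rep))
    b = rng.normal(size=(n_sim, n_rep))
    c = rng.normal(size=(n_sim, n_rep))
    _, p = stats.f_oneway(a, b, c, axis=1)
    # sanity of the simulation itself
    assert 0.03 <= np.mean(p <= 0.05) <= 0.07
    # and the packaged ANOVA agrees with the vectorised computation
    res = group_tests({"a": list(a[0]), "b": list(b[0]), "c": list(c[0])})
    assert res["p"] == pytest.approx(p[0])
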