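"""qRT-PCR relative quantification (2^-ddCt) and significance tests.

Relative expression follows the Livak method: per sample, replicate Ct
values are averaged, the reference gene's Ct is subtracted (dCt), the
calibrator sample's dCt is subtracted (ddCt), and fold change = 2^-ddCt.
Amplification efficiency is assumed to be a perfect doubling per cycle.
The calibrator defaults to the lowest-expressed sample (maximum dCt), the
convention used when plotting tissue panels relative to the weakest
transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .records import FlakitError


@dataclass
class CtTable:
    """Long-format Ct measurements.

    ``data`` columns: gene, sample, replicate, ct.  ``reference_gene``
    names the internal-control gene (e.g. actin), which must be measured
    in every sample.
    """

    data: pd.DataFrame
    reference_gene: str

    REQUIRED = ("gene", "sample", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise FlakitError(f"Ct table missing columns {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise FlakitError("Ct values must be positive")
        ref = self.data[self.data["gene"] == self.reference_gene]
        samples = set(self.data["sample"])
        if set(ref["sample"]) != samples:
            missing_s = samples - set(ref["sample"])
            raise FlakitError(
                f"reference gene {self.reference_gene!r} missing for "
                f"samples {sorted(missing_s)}"
            )

    @classmethod
    def from_tsv(cls, path, reference_gene: str) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), reference_gene)

    def mean_ct(self) -> pd.DataFrame:
        """Replicate-averaged Ct per (gene, sample), with SD."""
        return (
            self.data.groupby(["gene", "sample"])["ct"]
            .agg(mean="mean", sd="std", n="count")
            .reset_index()
        )


def ddct(
    table: CtTable,
    target: str,
    calibrator: Optional[str] = None,
) -> pd.DataFrame:
    """Per-sample fold changes for ``target`` by the 2^-ddCt method.

    Returns a DataFrame with columns sample, dct, ddct, fold.  The
    calibrator sample's fold is 1 by construction.  When ``calibrator`` is
    None the sample with the maximum dCt (lowest expression) is used.
    """
    means = table.mean_ct()
    tgt = means[means["gene"] == target].set_index("sample")["mean"]
    ref = means[means["gene"] == table.reference_gene].set_index("sample")["mean"]
    if tgt.empty:
        raise FlakitError(f"no Ct rows for target gene {target!r}")
    missing = set(tgt.index) - set(ref.index)
    if missing:
        raise FlakitError(f"missing reference Ct for samples {sorted(missing)}")
    dct = (tgt - ref.loc[tgt.index]).rename("dct")
    if calibrator is None:
        calibrator = dct.idxmax()
    elif calibrator not in dct.index:
        raise FlakitError(f"calibrator sample {calibrator!r} not measured")
    ddct_vals = dct - dct.loc[calibrator]
    out = pd.DataFrame(
        {
            "sample": dct.index,
            "dct": dct.values,
            "ddct": ddct_vals.values,
            "fold": np.power(2.0, -ddct_vals.values),
        }
    ).reset_index(drop=True)
    return out


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a transform tag."""

    values: pd.DataFrame
    transform: str = "linear"  # linear | log2

    def __post_init__(self) -> None:
        if self.transform not in ("linear", "log2"):
            raise FlakitError(f"unknown transform {self.transform!r}")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise FlakitError("non-finite expression values")


def log2_matrix(m: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """Elementwise log2(x + pseudocount); refuses to double-transform."""
    if m.transform == "log2":
        raise FlakitError("matrix is already log2-transformed")
    vals = m.values.to_numpy(dtype=float) + pseudocount
    if np.any(vals <= 0):
        raise FlakitError("log2 of non-positive value; raise the pseudocount")
    return ExpressionMatrix(
        values=pd.DataFrame(
            np.log2(vals), index=m.values.index, columns=m.values.columns
        ),
        transform="log2",
    )


def _tukey_letters(groups: List[str], nsd_pairs: set) -> Dict[str, str]:
    """Compact letter display from the not-significantly-different graph.

    Each maximal clique of mutually indistinguishable groups receives one
    letter, so two groups share a letter only if their difference is not
    significant.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(nsd_pairs)
    cliques = sorted(nx.find_cliques(g), key=lambda c: min(groups.index(x) for x in c))
    letters: Dict[str, list] = {grp: [] for grp in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        for grp in clique:
            letters[grp].append(alphabet[i % len(alphabet)])
    return {grp: "".join(sorted(ls)) for grp, ls in letters.items()}


def group_tests(
    values_by_group: Mapping[str, Sequence[float]],
    design: str = "anova_tukey",
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA with Tukey HSD letters, or a two-sample t-test.

    ``anova_tukey`` returns the F statistic, its p-value, the pairwise
    Tukey table and per-group significance letters.  ``t_test`` (exactly
    two groups) returns t, p and a star annotation: ``**`` at p <= 0.01,
    ``*`` at p <= 0.05, empty otherwise.
    """
    groups = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if design == "t_test":
        if len(groups) != 2:
            raise FlakitError("t_test design needs exactly two groups")
        t, p = stats.ttest_ind(arrays[0], arrays[1])
        stars = "**" if p <= 0.01 else "*" if p <= 0.05 else ""
        return {"design": "t_test", "t": float(t), "p": float(p), "stars": stars}
    if design != "anova_tukey":
        raise ValueError(f"unknown design {design!r}")
    if len(groups) < 2:
        raise FlakitError("ANOVA needs at least two groups")
    for g, a in zip(groups, arrays):
        if len(a) < 2:
            raise FlakitError(f"group {g!r} has < 2 replicates")
    f, p = stats.f_oneway(*arrays)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    flat = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
    tukey = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    pairs = []
    nsd = set()
    res = tukey.summary().data[1:]
    for row in res:
        g1, g2, meandiff, p_adj, lo, hi, reject = row
        pairs.append(
            {"group1": str(g1), "group2": str(g2), "p_adj": float(p_adj),
             "significant": bool(reject)}
        )
        if not reject:
            nsd.add((str(g1), str(g2)))
    letters = _tukey_letters(groups, nsd)
    return {
        "design": "anova_tukey",
        "F": float(f),
        "p": float(p),
        "pairwise": pairs,
        "letters": letters,
    }
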