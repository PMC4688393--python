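"""qRT-PCR fold changes by 2^-ddCt, with a salt-stress style design.

Generates a Ct table for one gene across 0/12/24 h time points in
triplicate (true folds 1, 2 and 8 relative to 0 h), recovers the folds,
and tests each stressed time point against the 0 h control.
"""

from flakit.expression import ddct, group_tests
from flakit.synthetic import make_ct_table

true_folds = {"fla2": {"0h": 1.0, "12h": 2.0, "24h": 8.0}}
table, truth = make_ct_table(
    ["fla2"], ["0h", "12h", "24h"], true_folds, noise_sd=0.1, seed=4
)

folds = ddct(table, "fla2", calibrator="0h").set_index("sample")
print(f"{'sample':<8}{'dCt':>7}{'fold':>8}   (true)")
for sample, true in true_folds["fla2"].items():
    row = folds.loc[sample]
    print(f"{sample:<8}{row['dct']:>7.2f}{row['fold']:>8.2f}   ({true})")

# per-time-point t-test vs the 0 h control, on replicate-level dCt
data = table.data
ref = data[data["gene"] == "actin"].set_index(["sample", "replicate"])["ct"]
tgt = data[data["gene"] == "fla2"].set_index(["sample", "replicate"])["ct"]
dct = (tgt - ref).reset_index()
control = list(dct[dct["sample"] == "0h"]["ct"])
for sample in ("12h", "24h"):
    res = group_tests(
        {"0h": control, sample: list(dct[dct["sample"] == sample]["ct"])},
        design="t_test",
    )
    star = res["stars"] or "ns"
    print(f"{sample} vs 0h: t = {res['t']:.2f}, p = {res['p']:.2g}  [{star}]")
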