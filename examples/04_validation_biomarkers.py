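"""Validation-cohort biomarker evaluation on the bundled fixture.

The synthetic validation cohort (56 patients, 25 responders) reproduces
the published confusion arithmetic: dichotomizing CYTIP promoter
methylation at 40% and TNFSF8 at 50% (value at or below the cutoff
predicts response), their AND-combination, and the PD-L1 >= 1% comparator.
"""

from methylresponse.biomarker import (
    combine_markers,
    evaluate_cutoff,
    pdl1_classifier,
    roc_auc,
    sweep_cutoffs,
    wilcoxon_rank_sum,
)
from methylresponse.simulate import make_validation_fixture

table = make_validation_fixture()
df = table.data

for marker in ("CYTIP", "TNFSF8"):
    keep = df[marker].notna()
    r = df.loc[keep & (df["response"] == "R"), marker]
    nr = df.loc[keep & (df["response"] == "NR"), marker]
    _, p = wilcoxon_rank_sum(r, nr, alternative="less")
    auc, _ = roc_auc(df.loc[keep, marker], df.loc[keep, "response"])
    best, _ = sweep_cutoffs(df[marker], df["response"], 5.0, marker=marker)
    print(f"{marker}: n={int(keep.sum())}  one-sided Wilcoxon p={p:.4f}  "
          f"AUC={auc:.3f}  sweep-chosen cutoff={best.cutoff:.0f}%")

cytip = evaluate_cutoff(df["CYTIP"], df["response"], 40, "CYTIP")
tnfsf8 = evaluate_cutoff(df["TNFSF8"], df["response"], 50, "TNFSF8")
combined = combine_markers(table, {"CYTIP": 40, "TNFSF8": 50})
pdl1 = pdl1_classifier(table, 1.0)

print("\nclassifier          PPV              NPV")
for clf in (cytip, tnfsf8, pdl1, combined):
    print(
        f"{clf.marker:<18}  {clf.ppv:.1%} ({clf.tp}/{clf.tp+clf.fp})   "
        f"{clf.npv:.1%} ({clf.tn}/{clf.tn+clf.fn})"
    )
# PPV = fraction of predicted responders who truly responded; the combined
# rule trades NPV for the highest PPV, and both markers beat PD-L1.
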