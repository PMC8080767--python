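"""Marker-stratified survival analysis on the validation fixture.

Kaplan-Meier curves and the log-rank test compare progression-free
survival between patients below and above the CYTIP methylation cutoff;
a Cox proportional-hazards model adjusts the marker effect for sex, age,
smoking and PD-L1 positivity.
"""

import numpy as np
import pandas as pd

from methylresponse.simulate import make_validation_fixture
from methylresponse.survival import cox_fit, km_estimate, logrank_test

df = make_validation_fixture().data
low = df["CYTIP"].notna() & (df["CYTIP"] <= 40)

t = df["pfs_months"].to_numpy(float)
e = df["pfs_event"].to_numpy(int)
groups = np.where(low, "low", "high")

km_low = km_estimate(t[groups == "low"], e[groups == "low"])
km_high = km_estimate(t[groups == "high"], e[groups == "high"])
chi2, p = logrank_test(t, e, groups)

fmt = lambda m: f"{m:.1f} months" if m is not None else "not reached"
print(f"median PFS, CYTIP <= 40%: {fmt(km_low.median)} (n={km_low.n})")
print(f"median PFS, CYTIP  > 40%: {fmt(km_high.median)} (n={km_high.n})")
print(f"log-rank: chi2={chi2:.2f}, p={p:.4f}")

covariates = pd.DataFrame(
    {
        "cytip_low": low.astype(float),
        "sex": df["sex"].astype(float),
        "age": df["age"].astype(float),
        "smoking": df["smoking"].astype(float),
        "pdl1_positive": (df["pdl1_percent"] >= 1).astype(float),
    }
)
fit = cox_fit(t, e, covariates)
row = fit.summary.loc["cytip_low"]
print(
    f"adjusted Cox HR for hypomethylation: {row['hr']:.3f} "
    f"(95% CI {row['hr_lo']:.3f}-{row['hr_hi']:.3f}, p={row['p']:.4f})"
)
# an HR below 1 means hypomethylated patients progress later even after
# adjusting for the clinical covariates.
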