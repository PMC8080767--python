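"""Validation-stage biomarker evaluation.

A methylation marker is dichotomized at a percent-methylation cutoff:
patients at or below the cutoff are predicted responders (hypomethylation
predicts response).  This module provides the group comparison (Wilcoxon
rank-sum), ROC/AUC, confusion-matrix evaluation with PPV/NPV, a 5%-grid
cutoff sweep, the two-marker AND-combination, and the PD-L1 (>= threshold
percent positive) comparator classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "MarkerClassifier",
    "ClinicalTable",
    "wilcoxon_rank_sum",
    "roc_auc",
    "evaluate_cutoff",
    "sweep_cutoffs",
    "combine_markers",
    "pdl1_classifier",
]


@dataclass
class ClinicalTable:
    """Per-patient clinical data.

    ``data`` holds one row per patient with columns: ``response`` ("R" or
    "NR"), optional marker columns of percent methylation in [0, 100]
    (NaN = not evaluable), ``pdl1_percent``, survival columns
    ``pfs_months, pfs_event, os_months, os_event``, and covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.data["response"].dropna()) <= {"R", "NR"}:
            raise ValueError("response labels must be 'R' or 'NR'")
        for col in ("pfs_event", "os_event"):
            if col in self.data:
                ev = self.data[col].dropna()
                if not set(ev.unique()) <= {0, 1}:
                    raise ValueError(f"{col} must be binary")

    @property
    def response(self) -> pd.Series:
        return self.data["response"]

    def marker(self, name: str) -> pd.Series:
        return self.data[name]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="patient_id")

    @classmethod
    def from_csv(cls, path) -> "ClinicalTable":
        return cls(pd.read_csv(path, index_col="patient_id"))


@dataclass(frozen=True)
class MarkerClassifier:
    """A dichotomization rule with its confusion counts and PPV/NPV.

    ``ppv``/``npv`` are None when their denominator is zero.  ``n_excluded``
    counts patients dropped for a missing marker value.
    """

    marker: str
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def npv(self) -> float | None:
        d = self.tn + self.fn
        return self.tn / d if d else None


def wilcoxon_rank_sum(values_a, values_b, alternative: str = "two-sided"):
    """Wilcoxon rank-sum (Mann-Whitney) test between two samples.

    Exact p by enumeration when the combined sample size is <= 12 and free
    of ties; otherwise the normal approximation with tie and continuity
    corrections.  ``alternative`` is "two-sided", "less" (a tends below b)
    or "greater".  Returns ``(U statistic of sample a, p)``; if every value
    in both samples is identical the test is degenerate and p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if not len(a) or not len(b):
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(len(a) * len(b) / 2.0), 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def roc_auc(values, labels) -> tuple[float, pd.DataFrame]:
    """ROC analysis with lower methylation scored toward response.

    ``labels`` are "R"/"NR"; the classifier score is the negated marker
    value, so AUC equals the probability (ties half-weighted) that a
    random responder has lower methylation than a random non-responder.
    Returns ``(auc, curve)`` with curve columns ``fpr, tpr, threshold``.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray([1 if l == "R" else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    score = -values
    auc = float(roc_auc_score(y, score))
    fpr, tpr, thr = roc_curve(y, score)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, curve


def evaluate_cutoff(
    values: pd.Series, labels: pd.Series, cutoff: float, marker: str = "marker"
) -> MarkerClassifier:
    """Confusion counts for the rule *value <= cutoff => predicted responder*.

    Patients with a missing marker value are excluded and counted in
    ``n_excluded``.  A value exactly at the cutoff predicts response.
    """
    values = pd.Series(values)
    labels = pd.Series(labels)
    keep = values.notna()
    v = values[keep].to_numpy(dtype=float)
    r = (labels[keep] == "R").to_numpy()
    predicted = v <= cutoff
    return MarkerClassifier(
        marker=marker,
        cutoff=float(cutoff),
        tp=int((predicted & r).sum()),
        fp=int((predicted & ~r).sum()),
        tn=int((~predicted & ~r).sum()),
        fn=int((~predicted & r).sum()),
        n_excluded=int((~keep).sum()),
    )


def sweep_cutoffs(
    values: pd.Series,
    labels: pd.Series,
    step_percent: float = 5.0,
    marker: str = "marker",
) -> tuple[MarkerClassifier, pd.DataFrame]:
    """Grid search of the cutoff over {0, step, ..., 100} maximizing PPV + NPV.

    Undefined PPV or NPV terms count as 0 in the objective; ties are broken
    toward the larger cutoff.  Returns the winning classifier and the full
    sweep table (one row per grid point) for audit.
    """
    if step_percent <= 0 or (100.0 / step_percent) % 1 != 0:
        raise ValueError("step must divide 100")
    grid = np.arange(0.0, 100.0 + step_percent / 2, step_percent)
    rows = []
    best = None
    best_obj = -np.inf
    for c in grid:
        clf = evaluate_cutoff(values, labels, c, marker=marker)
        obj = (clf.ppv or 0.0) + (clf.npv or 0.0)
        rows.append(
            {
                "cutoff": c,
                "tp": clf.tp,
                "fp": clf.fp,
                "tn": clf.tn,
                "fn": clf.fn,
                "ppv": clf.ppv,
                "npv": clf.npv,
                "objective": obj,
            }
        )
        if obj >= best_obj:  # >= keeps the larger tied cutoff
            best, best_obj = clf, obj
    return best, pd.DataFrame(rows)


def combine_markers(
    table: ClinicalTable, cutoffs: dict[str, float]
) -> MarkerClassifier:
    """AND-combination: predicted responder iff every marker is at or below
    its cutoff.  Only patients with all marker values present are evaluated.
    """
    df = table.data
    present = np.ones(len(df), dtype=bool)
    for m in cutoffs:
        present &= df[m].notna().to_numpy()
    sub = df.loc[present]
    predicted = np.ones(len(sub), dtype=bool)
    for m, c in cutoffs.items():
        predicted &= sub[m].to_numpy(dtype=float) <= c
    r = (sub["response"] == "R").to_numpy()
    name = "+".join(sorted(cutoffs))
    return MarkerClassifier(
        marker=name,
        cutoff=float("nan"),
        tp=int((predicted & r).sum()),
        fp=int((predicted & ~r).sum()),
        tn=int((~predicted & ~r).sum()),
        fn=int((~predicted & r).sum()),
        n_excluded=int((~present).sum()),
    )


def pdl1_classifier(
    table: ClinicalTable, threshold_percent: float = 1.0
) -> MarkerClassifier:
    """PD-L1 comparator: predicted responder iff PD-L1 percent >= threshold."""
    df = table.data
    keep = df["pdl1_percent"].notna()
    sub = df.loc[keep]
    predicted = sub["pdl1_percent"].to_numpy(dtype=float) >= threshold_percent
    r = (sub["response"] == "R").to_numpy()
    return MarkerClassifier(
        marker="PD-L1",
        cutoff=float(threshold_percent),
        tp=int((predicted & r).sum()),
        fp=int((predicted & ~r).sum()),
        tn=int((~predicted & ~r).sum()),
        fn=int((~predicted & r).sum()),
        n_excluded=int((~keep).sum()),
    )
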