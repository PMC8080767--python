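"""Differential expression and methylation-expression integration.

The differential-expression layer is a deliberately simple negative-binomial
Wald test: median-of-ratios size factors, per-gene method-of-moments
dispersion pooled within groups, and a Wald statistic on the log ratio of
normalized group means referred to a Welch-Satterthwaite t distribution.
It is not an empirical-Bayes method — no dispersion shrinkage — which is
adequate at simulated scale and keeps every step explicit.

The biomarker-selection rule marks a promoter DMR "functional" when its
methylation change is large (|meanbetaFC| > 0.15 by default), its gene's
expression moves at least two-fold in the opposite direction at q < 0.01,
and per-sample DMR methylation and expression are significantly
anti-aligned (Pearson p < 0.05 with sign opposite to the methylation
change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "differential_expression",
    "dmr_expression_correlation",
    "FunctionalDmr",
    "select_functional_dmrs",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample (column).

    Factors are medians of per-gene ratios to the geometric mean across
    samples, over genes with nonzero counts in every sample.  If no such
    gene exists the method degrades to total-count ratios (flagged by a
    warning in the returned series' attrs).
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    out_attrs = {}
    if all_nonzero.any():
        sub = mat[all_nonzero]
        log_geo = np.log(sub).mean(axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    else:
        totals = mat.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
        out_attrs["fallback"] = "total-count ratio (no all-nonzero gene)"
    s = pd.Series(factors, index=counts.columns, name="size_factor")
    s.attrs.update(out_attrs)
    return s


def differential_expression(
    counts: pd.DataFrame,
    groups: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """NB Wald test per gene, responder vs non-responder.

    Genes with zero counts everywhere are excluded (their ids are listed in
    ``result.attrs['all_zero']``).  Returns a frame indexed by gene with
    ``base_mean``, ``log2fc`` (positive = higher in responders), ``p``,
    ``q`` (BH over tested genes) and the dispersion estimate.
    """
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    pos = "R" if "R" in set(labels) else sorted(labels)[0]
    neg = [l for l in labels if l != pos][0]
    a_cols = groups.index[groups == pos]
    b_cols = groups.index[groups == neg]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 samples per group")

    nonzero = counts.sum(axis=1) > 0
    all_zero = counts.index[~nonzero]
    counts = counts.loc[nonzero]
    sf = size_factors(counts)
    norm = counts / sf

    ya = norm[a_cols].to_numpy(dtype=float)
    yb = norm[b_cols].to_numpy(dtype=float)
    na, nb = ya.shape[1], yb.shape[1]
    ma, mb = ya.mean(axis=1), yb.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()

    # method-of-moments dispersion pooled within groups:
    # Var(y) = mu + alpha * mu^2  =>  alpha = (s2 - mu) / mu^2
    va = ya.var(axis=1, ddof=1)
    vb = yb.var(axis=1, ddof=1)
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    mu = np.maximum(base_mean, 1e-8)
    alpha = np.maximum((pooled_var - mu) / mu**2, 0.0)

    log2fc = np.log2((ma + pseudocount) / (mb + pseudocount))
    # Wald on the log scale; delta method gives Var(ln mean_g) = Var(y)/ (n mu_g^2)
    va_nb = ma + alpha * ma**2
    vb_nb = mb + alpha * mb**2
    ta = va_nb / (na * np.maximum(ma, pseudocount) ** 2)
    tb = vb_nb / (nb * np.maximum(mb, pseudocount) ** 2)
    se = np.sqrt(np.maximum(ta + tb, 1e-12))
    wald = np.log((ma + pseudocount) / (mb + pseudocount)) / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    q = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "dispersion": alpha,
            "p": p,
            "q": q,
        },
        index=counts.index,
    )
    out.attrs["all_zero"] = list(all_zero)
    out.attrs["groups"] = {"positive": pos, "negative": neg}
    return out


def dmr_expression_correlation(
    dmr_beta: pd.Series, expression: pd.Series
) -> tuple[float, float]:
    """Pearson correlation between per-sample DMR methylation and expression.

    Both series are aligned on their (sample) index intersection; at least
    three paired samples are required.  Expression is expected on a log2
    normalized scale.  Returns ``(r, two-sided p)``; ``(nan, nan)`` when
    either vector is constant.
    """
    common = dmr_beta.index.intersection(expression.index)
    if len(common) < 3:
        raise ValueError("need >= 3 paired samples")
    x = dmr_beta.loc[common].to_numpy(dtype=float)
    y = expression.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class FunctionalDmr:
    """A promoter DMR with its expression evidence and the selection verdict."""

    dmr_index: int
    gene: str
    meanbetafc: float
    log2fc: float
    q: float
    pearson_r: float
    pearson_p: float
    selected: bool


def select_functional_dmrs(
    candidates: pd.DataFrame,
    de: pd.DataFrame,
    correlations: dict[str, tuple[float, float]],
    meanbetafc_min: float = 0.15,
    de_q_max: float = 0.01,
    corr_p_max: float = 0.05,
) -> list[FunctionalDmr]:
    """Apply the functional-DMR rule to promoter-DMR candidates.

    ``candidates`` needs columns ``dmr_index``, ``gene`` and ``meanbetafc``
    (signed responder minus non-responder).  Selected iff:

    * |meanbetafc| > ``meanbetafc_min``;
    * expression moves inversely at least two-fold with q < ``de_q_max``
      (hypermethylated => log2fc < -1; hypomethylated => log2fc > +1);
    * Pearson r is negative with p < ``corr_p_max`` — inverse coupling
      gives a negative methylation-expression correlation across samples
      whichever direction the methylation shifted.

    Candidates missing a DE or correlation record are dropped (ids in
    the returned list's ``attrs`` equivalent is not kept; they simply do
    not appear, and the caller's logger can compare lengths).
    """
    out: list[FunctionalDmr] = []
    for row in candidates.itertuples(index=False):
        gene = str(row.gene)
        if gene not in de.index or gene not in correlations:
            continue
        log2fc = float(de.loc[gene, "log2fc"])
        q = float(de.loc[gene, "q"])
        r, rp = correlations[gene]
        mfc = float(row.meanbetafc)
        effect_ok = abs(mfc) > meanbetafc_min
        if mfc > 0:
            de_ok = (log2fc < -1.0) and (q < de_q_max)
        else:
            de_ok = (log2fc > 1.0) and (q < de_q_max)
        corr_ok = np.isfinite(r) and np.isfinite(rp) and rp < corr_p_max and r < 0
        out.append(
            FunctionalDmr(
                dmr_index=int(row.dmr_index),
                gene=gene,
                meanbetafc=mfc,
                log2fc=log2fc,
                q=q,
                pearson_r=float(r),
                pearson_p=float(rp),
                selected=bool(effect_ok and de_ok and corr_ok),
            )
        )
    return out
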