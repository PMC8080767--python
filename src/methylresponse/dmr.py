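"""Kernel-smoothed differentially-methylated-region calling.

The caller works in three layers, in the spirit of agglomerative
kernel-smoothing DMR methods:

1. per-CpG Welch t-statistics on M-values (responder vs non-responder),
   with BH-adjusted p-values and per-CpG beta-scale effect sizes;
2. Gaussian-kernel smoothing of the squared t-statistic along each
   chromosome, with a Satterthwaite chi-square reference whose effective
   degrees of freedom come from the kernel weights;
3. merging of significant CpGs (smoothed FDR below threshold) into regions
   separated by at most ``gap_bp``.

A region's ``min_fdr`` is the minimum smoothed per-CpG FDR inside it and its
``meanbetafc`` is the unweighted mean of per-CpG group differences in beta
(responder minus non-responder); downstream filters use the magnitude, the
sign is kept as the region's direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Dmr",
    "per_cpg_stats",
    "smooth_stats",
    "call_dmrs",
    "recover_planted",
    "dmrs_to_bed",
]

_VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class Dmr:
    """A contiguous region of coherently differentially methylated CpGs.

    Coordinates are 0-based half-open; ``meanbetafc`` is signed
    responder-minus-non-responder.
    """

    chrom: str
    start: int
    end: int
    n_cpgs: int
    min_fdr: float
    meanbetafc: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.meanbetafc))

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("DMR requires start < end")
        if self.n_cpgs < 2:
            raise ValueError("DMR requires >= 2 CpGs")


def per_cpg_stats(
    m_values: pd.DataFrame,
    beta: pd.DataFrame,
    groups: pd.Series,
) -> pd.DataFrame:
    """Welch t-test per CpG on M-values, effect size on the beta scale.

    Parameters
    ----------
    m_values, beta
        CpG x sample matrices on the M and beta scales, identically indexed.
    groups
        Sample -> label series with exactly two levels; the label ``"R"``
        (responder) is the positive group if present, otherwise the
        lexicographically smaller label.

    Returns a DataFrame indexed by CpG id with columns ``t``, ``p``, ``fdr``
    (BH over all tested CpGs), ``delta_beta`` and ``var_floored``.
    Group variances are floored at 1e-8 so degenerate (zero-variance)
    inputs yield a finite statistic; such CpGs are flagged.
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

    ma = m_values[a_cols].to_numpy(dtype=float)
    mb = m_values[b_cols].to_numpy(dtype=float)
    na, nb = ma.shape[1], mb.shape[1]
    mean_a, mean_b = ma.mean(axis=1), mb.mean(axis=1)
    var_a = ma.var(axis=1, ddof=1)
    var_b = mb.var(axis=1, ddof=1)
    floored = (var_a < _VAR_FLOOR) | (var_b < _VAR_FLOOR)
    var_a = np.maximum(var_a, _VAR_FLOOR)
    var_b = np.maximum(var_b, _VAR_FLOOR)

    se2 = var_a / na + var_b / nb
    t = (mean_a - mean_b) / np.sqrt(se2)
    # Welch-Satterthwaite degrees of freedom
    df = se2**2 / ((var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    fdr = multipletests(p, method="fdr_bh")[1]

    delta = beta[a_cols].mean(axis=1) - beta[b_cols].mean(axis=1)
    return pd.DataFrame(
        {
            "t": t,
            "df": df,
            "p": p,
            "fdr": fdr,
            "delta_beta": delta.to_numpy(),
            "var_floored": floored,
        },
        index=m_values.index,
    )


def smooth_stats(
    stats_df: pd.DataFrame,
    positions: pd.DataFrame,
    bandwidth_bp: float = 1000.0,
) -> pd.DataFrame:
    """Gaussian-kernel smoothing of squared t along each chromosome.

    ``stats_df`` must be position-sorted within chromosomes (joint sort on
    ``(chrom, pos)``); an unsorted input raises.  Each per-CpG t statistic
    is first probit-standardized through its own p-value
    (``z = qnorm(1 - p/2)``), which is exactly standard normal under the
    null whatever the Welch degrees of freedom, so the squared statistic is
    an exact 1-df chi-square.  The smoothed statistic is the kernel-weighted
    average of squared z over neighbours within +/- 3 bandwidths (itself
    included), and its p-value comes from a scaled chi-square whose
    effective degrees of freedom are ``1 / sum(w_norm^2)`` (Satterthwaite
    moment match for a weighted sum of 1-df chi-squares).  A CpG with no
    neighbours keeps its own squared statistic and a 1-df reference.
    Smoothed FDR is BH over all CpGs.
    """
    pos_df = positions.loc[stats_df.index]
    chrom = pos_df["chrom"].to_numpy()
    pos = pos_df["pos"].to_numpy(dtype=float)
    order_ok = True
    for c in pd.unique(chrom):
        pc = pos[chrom == c]
        if np.any(np.diff(pc) < 0):
            order_ok = False
            break
    if not order_ok:
        raise ValueError("stats must be sorted by (chrom, pos)")

    # exact N(0,1) under the null regardless of the per-CpG df
    z = stats.norm.isf(np.minimum(stats_df["p"].to_numpy(dtype=float), 1.0) / 2.0)
    t2 = np.minimum(z, 40.0) ** 2  # cap guards p-underflow
    smoothed = np.empty_like(t2)
    eff_df = np.empty_like(t2)
    window = 3.0 * bandwidth_bp
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pc = pos[idx]
        tc = t2[idx]
        lo = np.searchsorted(pc, pc - window, side="left")
        hi = np.searchsorted(pc, pc + window, side="right")
        for k in range(len(idx)):
            sl = slice(lo[k], hi[k])
            w = np.exp(-((pc[sl] - pc[k]) ** 2) / (2.0 * bandwidth_bp**2))
            w = w / w.sum()
            smoothed[idx[k]] = float(w @ tc[sl])
            eff_df[idx[k]] = 1.0 / float(np.sum(w**2))

    # smoothed stat ~ (1/k) * chi2_k under the null (moment-matched)
    p = stats.chi2.sf(smoothed * eff_df, eff_df)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = stats_df.copy()
    out["smoothed_stat"] = smoothed
    out["eff_df"] = eff_df
    out["smoothed_p"] = p
    out["smoothed_fdr"] = fdr
    return out


def call_dmrs(
    smoothed: pd.DataFrame,
    positions: pd.DataFrame,
    min_fdr_threshold: float = 0.01,
    gap_bp: float = 1000.0,
    min_cpgs: int = 2,
    anchor_p: float | None = None,
) -> list[Dmr]:
    """Merge significant CpGs into regions.

    CpGs with smoothed FDR below ``min_fdr_threshold`` are merged into one
    region while consecutive significant CpGs lie within ``gap_bp`` of each
    other on the same chromosome; regions with fewer than ``min_cpgs`` CpGs
    are dropped.  The region interval spans the first to one past the last
    member CpG.

    A region must additionally contain at least ``min_cpgs`` *anchor* CpGs
    whose raw (unsmoothed) p-value is below ``anchor_p`` (defaults to
    ``min_fdr_threshold``).  Kernel smoothing borrows strength across
    neighbours, so a single extreme CpG — or the tail of a strong region up
    to three bandwidths away — can drag CpGs with no evidence of their own
    past the smoothed threshold; anchoring keeps called regions consistent
    with runs of individually supported CpGs.
    """
    if anchor_p is None:
        anchor_p = min_fdr_threshold
    pos_df = positions.loc[smoothed.index]
    sig = smoothed["smoothed_fdr"].to_numpy() < min_fdr_threshold
    chrom = pos_df["chrom"].to_numpy()
    pos = pos_df["pos"].to_numpy()
    delta = smoothed["delta_beta"].to_numpy(dtype=float)
    fdr = smoothed["smoothed_fdr"].to_numpy(dtype=float)
    raw_p = smoothed["p"].to_numpy(dtype=float)

    dmrs: list[Dmr] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= min_cpgs and int((raw_p[run] < anchor_p).sum()) >= min_cpgs:
            region_fdr = float(fdr[run].min())
            if region_fdr < min_fdr_threshold:
                dmrs.append(
                    Dmr(
                        chrom=str(chrom[run[0]]),
                        start=int(pos[run[0]]),
                        end=int(pos[run[-1]]) + 1,
                        n_cpgs=len(run),
                        min_fdr=region_fdr,
                        meanbetafc=float(np.mean(delta[run])),
                    )
                )
        run.clear()

    for i in np.flatnonzero(sig):
        if run and (chrom[i] != chrom[run[-1]] or pos[i] - pos[run[-1]] > gap_bp):
            flush()
        run.append(int(i))
    flush()
    return dmrs


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def recover_planted(dmrs: list[Dmr], truth_intervals) -> dict:
    """Interval-level recall/precision of called DMRs against planted truth.

    ``truth_intervals`` is an iterable of ``(chrom, start, end)`` (extra
    fields ignored).  A planted interval is recovered when some called DMR
    covers >= 50% of it; a called DMR is a true positive when it overlaps
    any planted interval at all.  Precision is ``None`` when nothing was
    called.
    """
    truth = [(str(t[0]), int(t[1]), int(t[2])) for t in truth_intervals]
    recovered = 0
    for chrom, start, end in truth:
        need = 0.5 * (end - start)
        if any(
            d.chrom == chrom and _overlap(start, end, d.start, d.end) >= need
            for d in dmrs
        ):
            recovered += 1
    recall = recovered / len(truth) if truth else None
    if dmrs:
        tp = sum(
            any(
                d.chrom == c and _overlap(s, e, d.start, d.end) > 0
                for (c, s, e) in truth
            )
            for d in dmrs
        )
        precision = tp / len(dmrs)
    else:
        precision = None
    return {"recall": recall, "precision": precision, "n_called": len(dmrs)}


def dmrs_to_bed(dmrs: list[Dmr]) -> pd.DataFrame:
    """BED6+3 table: name, score = -log10(min_fdr), strand '.', then
    n_cpgs / min_fdr / meanbetafc."""
    rows = [
        {
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "name": f"dmr_{i}",
            "score": float(-np.log10(max(d.min_fdr, 1e-300))),
            "strand": ".",
            "n_cpgs": d.n_cpgs,
            "min_fdr": d.min_fdr,
            "meanbetafc": d.meanbetafc,
        }
        for i, d in enumerate(dmrs)
    ]
    cols = ["chrom", "start", "end", "name", "score", "strand", "n_cpgs", "min_fdr", "meanbetafc"]
    return pd.DataFrame(rows, columns=cols)
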