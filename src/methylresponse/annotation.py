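"""Assignment of DMRs to promoters/enhancers and target-gene mapping.

Promoters carry gene ids directly; enhancers reach their target genes
through an enhancer-promoter interaction (EPI) network supplied as edges
``enhancer_id -> gene_id``.  All coordinates are 0-based half-open and
assignment means any-base sequence overlap.  Target genes are intersected
with a coding-gene set (a CCDS analogue) before reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RegulatoryAnnotation",
    "AnnotatedDmrSet",
    "filter_covered_elements",
    "assign_elements",
    "map_targets",
    "flag_super_enhancers",
    "chromosome_proportions",
    "overlap_any",
]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def _check_intervals(df: pd.DataFrame, what: str) -> pd.DataFrame:
    df = df.reset_index(drop=True)
    if len(df) and (df["start"] >= df["end"]).any():
        raise ValueError(f"{what}: intervals need start < end")
    return df


@dataclass
class RegulatoryAnnotation:
    """Promoters, enhancers, super-enhancers and the EPI edge map.

    ``promoters`` and ``enhancers`` are BED-like frames with columns
    ``chrom, start, end, name`` (+ optional score/strand); a promoter's
    ``name`` is its gene id, an enhancer's its enhancer id.
    ``epi_edges`` maps enhancer id -> set of target gene ids.
    """

    promoters: pd.DataFrame
    enhancers: pd.DataFrame
    epi_edges: dict[str, set[str]]
    super_enhancers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_BED_COLS[:4])
    )
    coding_gene_set: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.promoters = _check_intervals(self.promoters, "promoters")
        self.enhancers = _check_intervals(self.enhancers, "enhancers")
        self.super_enhancers = _check_intervals(self.super_enhancers, "super_enhancers")
        # edge genes must be known genes; the coding set is included so a
        # coverage-filtered view (promoters without profiled CpGs removed)
        # remains valid
        known_genes = set(self.promoters["name"]) | set(self.coding_gene_set)
        edge_genes = set().union(*self.epi_edges.values()) if self.epi_edges else set()
        if not edge_genes <= known_genes:
            raise ValueError("EPI edge genes must appear among promoter genes")

    def write_bed(self, promoters_path, enhancers_path, super_path, epi_path) -> None:
        for df, path in (
            (self.promoters, promoters_path),
            (self.enhancers, enhancers_path),
            (self.super_enhancers, super_path),
        ):
            out = df.copy()
            if "score" not in out:
                out["score"] = 0
            if "strand" not in out:
                out["strand"] = "."
            out[_BED_COLS].to_csv(path, sep="\t", header=False, index=False)
        rows = [
            {"enhancer_id": e, "gene_id": g}
            for e in sorted(self.epi_edges)
            for g in sorted(self.epi_edges[e])
        ]
        pd.DataFrame(rows, columns=["enhancer_id", "gene_id"]).to_csv(
            epi_path, sep="\t", index=False
        )


@dataclass
class AnnotatedDmrSet:
    """DMR indices split by element class, with their element links.

    ``pdmrs`` maps DMR index -> set of promoter gene ids it overlaps;
    ``edmrs`` maps DMR index -> set of enhancer ids.  A DMR overlapping
    both a promoter and an enhancer appears in both maps, so the class
    counts may sum to more than the number of distinct DMRs.
    """

    dmrs: pd.DataFrame
    pdmrs: dict[int, set[str]]
    edmrs: dict[int, set[str]]
    pdmr_targets: frozenset = frozenset()
    edmr_targets: frozenset = frozenset()


def overlap_any(
    query: pd.DataFrame, subject: pd.DataFrame
) -> list[tuple[int, int]]:
    """All (query_row, subject_row) index pairs with >= 1 bp overlap.

    Half-open interval intersection per chromosome via a vectorized scan;
    sizes here are small (thousands), so an O(n*m) masked comparison per
    chromosome is both clear and fast enough.
    """
    pairs: list[tuple[int, int]] = []
    if not len(query) or not len(subject):
        return pairs
    for chrom in pd.unique(query["chrom"]):
        qi = np.flatnonzero((query["chrom"] == chrom).to_numpy())
        si = np.flatnonzero((subject["chrom"] == chrom).to_numpy())
        if not len(si):
            continue
        qs = query["start"].to_numpy()[qi][:, None]
        qe = query["end"].to_numpy()[qi][:, None]
        ss = subject["start"].to_numpy()[si][None, :]
        se = subject["end"].to_numpy()[si][None, :]
        hit = (qs < se) & (ss < qe)
        for a, b in zip(*np.nonzero(hit)):
            pairs.append((int(qi[a]), int(si[b])))
    return sorted(pairs)


def filter_covered_elements(
    annotation: RegulatoryAnnotation, positions: pd.DataFrame
) -> tuple[RegulatoryAnnotation, dict]:
    """Restrict promoters/enhancers to those containing >= 1 profiled CpG.

    Containment is half-open: ``start <= pos < end``.  Returns the filtered
    annotation and a report of retained/removed counts per element class.
    """
    report = {}

    def covered(df: pd.DataFrame, what: str) -> pd.DataFrame:
        if not len(df):
            report[what] = {"input": 0, "retained": 0}
            return df
        keep = np.zeros(len(df), dtype=bool)
        for chrom, grp in positions.groupby("chrom", sort=False):
            mask = (df["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            pos = np.sort(grp["pos"].to_numpy())
            starts = df["start"].to_numpy()[mask]
            ends = df["end"].to_numpy()[mask]
            n_inside = np.searchsorted(pos, ends - 1, side="right") - np.searchsorted(
                pos, starts, side="left"
            )
            keep[mask] = n_inside > 0
        report[what] = {"input": int(len(df)), "retained": int(keep.sum())}
        return df.loc[keep].reset_index(drop=True)

    filtered = replace(
        annotation,
        promoters=covered(annotation.promoters, "promoters"),
        enhancers=covered(annotation.enhancers, "enhancers"),
    )
    return filtered, report


def assign_elements(
    dmrs: pd.DataFrame, annotation: RegulatoryAnnotation
) -> AnnotatedDmrSet:
    """Classify DMRs as pDMRs/eDMRs by any-base overlap with elements.

    ``dmrs`` is a frame with ``chrom, start, end`` (e.g. from
    :func:`methylresponse.dmr.dmrs_to_bed`); row order defines DMR indices.
    """
    dmrs = dmrs.reset_index(drop=True)
    pdmrs: dict[int, set[str]] = {}
    for qi, si in overlap_any(dmrs, annotation.promoters):
        pdmrs.setdefault(qi, set()).add(str(annotation.promoters.loc[si, "name"]))
    edmrs: dict[int, set[str]] = {}
    for qi, si in overlap_any(dmrs, annotation.enhancers):
        edmrs.setdefault(qi, set()).add(str(annotation.enhancers.loc[si, "name"]))
    return AnnotatedDmrSet(dmrs=dmrs, pdmrs=pdmrs, edmrs=edmrs)


def map_targets(
    annotated: AnnotatedDmrSet, annotation: RegulatoryAnnotation
) -> tuple[AnnotatedDmrSet, dict]:
    """Map pDMR/eDMR target gene sets through promoters and EPI edges.

    pDMR targets are the genes of overlapped promoters; eDMR targets the
    union of EPI edge genes of overlapped enhancers; both intersected with
    the coding gene set.  Enhancers without edges contribute nothing (they
    are counted in the report).  The summary reports set sizes, the overlap
    and its fraction of each set.
    """
    coding = set(annotation.coding_gene_set)
    pdmr_targets = set().union(*annotated.pdmrs.values()) if annotated.pdmrs else set()
    pdmr_targets &= coding
    edmr_targets: set[str] = set()
    edgeless: set[str] = set()
    for enh_ids in annotated.edmrs.values():
        for e in enh_ids:
            genes = annotation.epi_edges.get(e)
            if not genes:
                edgeless.add(e)
            else:
                edmr_targets |= genes
    edmr_targets &= coding
    inter = pdmr_targets & edmr_targets
    summary = {
        "n_pdmrs": len(annotated.pdmrs),
        "n_edmrs": len(annotated.edmrs),
        "n_pdmr_targets": len(pdmr_targets),
        "n_edmr_targets": len(edmr_targets),
        "n_shared_targets": len(inter),
        "shared_frac_of_pdmr": len(inter) / len(pdmr_targets) if pdmr_targets else None,
        "shared_frac_of_edmr": len(inter) / len(edmr_targets) if edmr_targets else None,
        "edgeless_enhancers": sorted(edgeless),
    }
    out = replace(
        annotated,
        pdmr_targets=frozenset(pdmr_targets),
        edmr_targets=frozenset(edmr_targets),
    )
    return out, summary


def flag_super_enhancers(
    annotated: AnnotatedDmrSet, annotation: RegulatoryAnnotation
) -> pd.Series:
    """Boolean per eDMR index: does the DMR overlap any super-enhancer?"""
    idx = sorted(annotated.edmrs)
    flags = pd.Series(False, index=idx, dtype=bool)
    if len(annotation.super_enhancers) and idx:
        sub = annotated.dmrs.loc[idx].reset_index()
        for qi, _ in overlap_any(sub, annotation.super_enhancers):
            flags.loc[int(sub.loc[qi, "index"])] = True
    return flags


def chromosome_proportions(
    annotated: AnnotatedDmrSet, annotation: RegulatoryAnnotation
) -> pd.DataFrame:
    """Per-chromosome fraction of promoters/enhancers hit by DMRs.

    ``NaN`` where a chromosome carries no elements of a class.
    """
    hit_prom: set[int] = set()
    for _, si in overlap_any(annotated.dmrs, annotation.promoters):
        hit_prom.add(si)
    hit_enh: set[int] = set()
    for _, si in overlap_any(annotated.dmrs, annotation.enhancers):
        hit_enh.add(si)

    chroms = sorted(
        set(annotation.promoters["chrom"]) | set(annotation.enhancers["chrom"])
    )
    rows = []
    for c in chroms:
        pm = (annotation.promoters["chrom"] == c).to_numpy()
        em = (annotation.enhancers["chrom"] == c).to_numpy()
        n_p, n_e = int(pm.sum()), int(em.sum())
        p_hit = sum(1 for i in hit_prom if pm[i])
        e_hit = sum(1 for i in hit_enh if em[i])
        rows.append(
            {
                "chrom": c,
                "n_promoters": n_p,
                "promoter_fraction": p_hit / n_p if n_p else np.nan,
                "n_enhancers": n_e,
                "enhancer_fraction": e_hit / n_e if n_e else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("chrom")
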