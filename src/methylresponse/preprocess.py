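"""CpG-site filtering and beta/M-value conversion.

The upstream contract is a matrix of *normalized* beta values (methylation
fractions) as produced by array preprocessing; normalization itself is not
reimplemented here.  This module applies the site-level exclusion rules that
precede region calling — detection-p failures, sex chromosomes, polymorphic
probes, cross-reactive probes, probe-context exclusions — and the standard
logit transform from beta values to M-values used for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BetaMatrix", "FilterSpec", "filter_sites", "beta_to_m"]


@dataclass
class BetaMatrix:
    """CpG-by-sample methylation fractions with a genomic position map.

    Parameters
    ----------
    values
        DataFrame of beta values in [0, 1] (or NaN), indexed by CpG id,
        one column per sample.
    positions
        DataFrame indexed by CpG id with columns ``chrom`` and ``pos``
        (0-based), covering every CpG in ``values``.
    """

    values: pd.DataFrame
    positions: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated CpG ids in beta matrix")
        missing = self.values.index.difference(self.positions.index)
        if len(missing):
            raise ValueError(f"{len(missing)} CpG ids lack positions")
        finite = self.values.to_numpy(dtype=float)
        finite = finite[np.isfinite(finite)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values outside [0, 1]")
        # keep the map aligned and ordered with the matrix
        self.positions = self.positions.loc[self.values.index, ["chrom", "pos"]]
        self.values.index.name = "cpg_id"
        self.positions.index.name = "cpg_id"

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, cpg_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[cpg_ids], self.positions.loc[cpg_ids])

    def sort_by_position(self) -> "BetaMatrix":
        order = self.positions.sort_values(["chrom", "pos"]).index
        return self.subset(order)

    def to_tsv(self, beta_path, map_path) -> None:
        self.values.to_csv(beta_path, sep="\t", index_label="cpg_id")
        self.positions.to_csv(map_path, sep="\t", index_label="cpg_id")

    @classmethod
    def from_tsv(cls, beta_path, map_path) -> "BetaMatrix":
        values = pd.read_csv(beta_path, sep="\t", index_col="cpg_id")
        positions = pd.read_csv(map_path, sep="\t", index_col="cpg_id")
        return cls(values, positions)


@dataclass
class FilterSpec:
    """Site-exclusion rules applied before region calling.

    ``snp_mask`` maps CpG id -> minor allele frequency of an overlapping
    variant; sites with MAF strictly above ``maf_threshold`` are removed.
    """

    detection_p_threshold: float = 0.01
    maf_threshold: float = 0.01
    sex_chromosomes: tuple[str, ...] = ("chrX", "chrY")
    snp_mask: dict[str, float] = field(default_factory=dict)
    cross_reactive_mask: frozenset = frozenset()
    context_exclusions: dict[str, frozenset] = field(default_factory=dict)
    # context_exclusions maps context label -> CpG ids in that context

    def __post_init__(self) -> None:
        if not (0 < self.detection_p_threshold < 1):
            raise ValueError("detection_p_threshold must be in (0, 1)")
        if not (0 < self.maf_threshold < 1):
            raise ValueError("maf_threshold must be in (0, 1)")


def filter_sites(
    beta: BetaMatrix,
    detection_p: pd.DataFrame | None,
    spec: FilterSpec,
) -> tuple[BetaMatrix, dict]:
    """Remove non-informative CpG sites; return the retained matrix and a report.

    A site is removed if any of the following hold:

    * its detection p-value exceeds ``spec.detection_p_threshold`` in *any*
      sample (per-site removal, the conservative reading);
    * it lies on a listed sex chromosome;
    * it carries a masked SNP with MAF > ``spec.maf_threshold``;
    * it is in the cross-reactive mask;
    * it belongs to an excluded probe context.

    The report counts removals per rule (a site may trip several rules) and
    the totals retained/removed.
    """
    ids = beta.cpg_ids
    remove = pd.Series(False, index=ids)
    report: dict = {"input_sites": int(len(ids)), "removed_by_rule": {}}

    def apply(rule: str, mask: pd.Series) -> None:
        report["removed_by_rule"][rule] = int(mask.sum())
        nonlocal remove
        remove = remove | mask

    if detection_p is not None:
        if not detection_p.index.equals(ids) or not detection_p.columns.equals(
            beta.sample_ids
        ):
            raise ValueError("detection-p matrix is not aligned with the beta matrix")
        apply(
            "detection_p",
            (detection_p > spec.detection_p_threshold).any(axis=1),
        )
    apply("sex_chromosome", beta.positions["chrom"].isin(spec.sex_chromosomes))
    snp_bad = {c for c, maf in spec.snp_mask.items() if maf > spec.maf_threshold}
    apply("snp", pd.Series(ids.isin(snp_bad), index=ids))
    apply("cross_reactive", pd.Series(ids.isin(spec.cross_reactive_mask), index=ids))
    context_ids: set = set()
    for label_ids in spec.context_exclusions.values():
        context_ids |= set(label_ids)
    apply("context", pd.Series(ids.isin(context_ids), index=ids))

    retained = ids[~remove.to_numpy()]
    report["removed_total"] = int(remove.sum())
    report["retained"] = int(len(retained))
    return beta.subset(retained), report


def beta_to_m(beta, offset: float = 0.01):
    """Logit transform of beta values: ``M = log2((b + offset) / (1 - b + offset))``.

    The offset (default 0.01) keeps boundary values finite.  Accepts an array
    or DataFrame and returns the same shape; monotone increasing in beta for
    any fixed non-negative offset.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    arr = beta.values.to_numpy(dtype=float) if isinstance(beta, BetaMatrix) else np.asarray(beta, dtype=float)
    with np.errstate(divide="ignore"):
        m = np.log2((arr + offset) / (1.0 - arr + offset))
    if isinstance(beta, BetaMatrix):
        return pd.DataFrame(m, index=beta.cpg_ids, columns=beta.sample_ids)
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m
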