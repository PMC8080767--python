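"""Synthetic cohort generator with planted ground truth.

Everything the discovery pipeline consumes can be simulated here: a
regulatory annotation (promoters, enhancers, super-enhancers, an
enhancer-promoter interaction network) with an array-like CpG position
map, a beta-value matrix with planted differentially methylated regions,
negative-binomial RNA counts coupled to the planted methylation for
designated genes, and a clinical table with marker methylation, PD-L1 and
exponential survival.  A separate deterministic fixture emulates the
validation cohort at the group level.

The stated world: a discovery cohort of 6 responders and 12 non-responders,
tens of thousands of CpGs clustered x5 inside regulatory elements,
Beta-distributed per-sample noise (SD ~0.08 on the beta scale), and
administratively censored exponential survival.

Determinism: every operation draws from ``numpy.random.default_rng`` seeded
from ``config.seed`` plus a fixed per-operation offset, so identical
configs give byte-identical outputs and the operations stay independent of
call order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import RegulatoryAnnotation
from .biomarker import ClinicalTable
from .preprocess import BetaMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_annotation",
    "simulate_methylation",
    "simulate_expression",
    "simulate_clinical",
    "make_validation_fixture",
]

# fixed per-operation seed offsets (keeps streams independent of call order)
_SEED_ANNOT, _SEED_METH, _SEED_EXPR, _SEED_CLIN = 11, 13, 17, 19


@dataclass
class SimulationConfig:
    """Parameters of the simulated world.

    ``planted_dmrs`` is a list of ``(n_cpgs, delta_beta, kind)`` with kind
    in {"promoter", "enhancer", "none"}; ``delta_beta`` is the responder
    minus non-responder difference in mean beta.  ``coupling_strength`` is
    the |log2 fold-change| imposed on functional genes' expression, in the
    direction opposite to their promoter's methylation change.
    """

    n_responders: int = 6
    n_nonresponders: int = 12
    n_cpgs: int = 20_000
    n_chromosomes: int = 4
    n_genes: int = 200
    n_enhancers: int = 100
    planted_dmrs: list = field(default_factory=list)
    beta_noise_sd: float = 0.08
    nb_dispersion: float = 0.1
    coupling_strength: float = 0.0
    seed: int = 0
    # layout parameters
    element_length: int = 1000
    background_spacing: int = 500
    element_densify: int = 5
    epi_fanout: int = 2
    superenhancer_fraction: float = 0.1
    # clinical parameters
    hazard_ratio: float = 0.45
    baseline_median_months: float = 4.0
    censor_horizon_months: float = 24.0
    censoring_fraction: float | None = None  # None = administrative only

    def __post_init__(self) -> None:
        for name in (
            "n_responders",
            "n_nonresponders",
            "n_cpgs",
            "n_chromosomes",
            "n_genes",
            "n_enhancers",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for _, db, kind in self.planted_dmrs:
            if abs(db) > 1:
                raise ValueError("|delta_beta| must be <= 1")
            if kind not in ("promoter", "enhancer", "none"):
                raise ValueError(f"unknown planted-DMR kind: {kind}")

    @property
    def n_samples(self) -> int:
        return self.n_responders + self.n_nonresponders

    @property
    def sample_ids(self) -> list[str]:
        return [f"R{i+1:02d}" for i in range(self.n_responders)] + [
            f"N{i+1:02d}" for i in range(self.n_nonresponders)
        ]

    @property
    def groups(self) -> pd.Series:
        labels = ["R"] * self.n_responders + ["NR"] * self.n_nonresponders
        return pd.Series(labels, index=self.sample_ids, name="response")


@dataclass
class GroundTruth:
    """Planted truth: DMR intervals, coupled genes, marker cutoffs."""

    true_dmr_intervals: list  # dicts: chrom/start/end/delta_beta/kind/gene
    functional_genes: list  # (gene_id, expression_direction +1/-1)
    marker_cutoffs: dict = field(default_factory=dict)


def _chrom_layout(config: SimulationConfig):
    """Round-robin assignment of genes/enhancers to chromosomes and sizing."""
    chroms = [f"chr{i+1}" for i in range(config.n_chromosomes)]
    genes = [f"G{i+1:04d}" for i in range(config.n_genes)]
    enhancers = [f"E{i+1:04d}" for i in range(config.n_enhancers)]
    gene_chrom = {g: chroms[i % len(chroms)] for i, g in enumerate(genes)}
    enh_chrom = {e: chroms[i % len(chroms)] for i, e in enumerate(enhancers)}
    cpgs_per_chrom = config.n_cpgs // config.n_chromosomes
    chrom_len = max(cpgs_per_chrom, 10) * config.background_spacing
    return chroms, genes, enhancers, gene_chrom, enh_chrom, chrom_len


def generate_annotation(
    config: SimulationConfig,
) -> tuple[RegulatoryAnnotation, pd.DataFrame]:
    """Build the regulatory annotation and the CpG position map.

    Promoters (one per gene) and enhancers are laid out non-overlapping in
    randomized slots along each chromosome; CpGs follow a homogeneous
    Poisson process densified x``element_densify`` inside elements, and
    every element is guaranteed at least one CpG.  Elements hosting planted
    DMRs (the first promoters/enhancers in id order, one per planted spec
    of that kind) are topped up to the planted CpG count.  Each enhancer is
    linked to its ``epi_fanout`` nearest promoters on the same chromosome;
    a random ``superenhancer_fraction`` of enhancers is flagged as
    super-enhancers (interval padded by 500 bp).
    """
    rng = np.random.default_rng(config.seed + _SEED_ANNOT)
    chroms, genes, enhancers, gene_chrom, enh_chrom, chrom_len = _chrom_layout(config)

    # slot layout per chromosome: promoters then enhancers, shuffled order
    prom_rows, enh_rows = [], []
    for chrom in chroms:
        elems = [("promoter", g) for g in genes if gene_chrom[g] == chrom] + [
            ("enhancer", e) for e in enhancers if enh_chrom[e] == chrom
        ]
        if not elems:
            continue
        order = rng.permutation(len(elems))
        slot_len = chrom_len // len(elems)
        if slot_len < 2 * config.element_length:
            raise ValueError(
                f"element count infeasible: {len(elems)} elements of "
                f"{config.element_length} bp do not fit in {chrom_len} bp"
            )
        for slot, k in enumerate(order):
            kind, name = elems[k]
            lo = slot * slot_len
            start = int(lo + rng.integers(0, slot_len - config.element_length))
            row = {
                "chrom": chrom,
                "start": start,
                "end": start + config.element_length,
                "name": name,
            }
            (prom_rows if kind == "promoter" else enh_rows).append(row)
    promoters = pd.DataFrame(prom_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    enhancers_df = pd.DataFrame(enh_rows).sort_values(["chrom", "start"]).reset_index(drop=True)

    # CpG placement: piecewise-constant Poisson intensity
    pos_rows = []
    for chrom in chroms:
        pieces = []  # (start, end, density)
        bounds = sorted(
            [
                (int(r.start), int(r.end))
                for df in (promoters, enhancers_df)
                for r in df[df["chrom"] == chrom].itertuples()
            ]
        )
        cursor = 0
        for s, e in bounds:
            if s > cursor:
                pieces.append((cursor, s, 1.0))
            pieces.append((s, e, float(config.element_densify)))
            cursor = max(cursor, e)
        if cursor < chrom_len:
            pieces.append((cursor, chrom_len, 1.0))
        weights = np.array([(e - s) * d for s, e, d in pieces], dtype=float)
        n_chrom = config.n_cpgs // config.n_chromosomes
        counts = rng.multinomial(n_chrom, weights / weights.sum())
        positions = []
        for (s, e, _), c in zip(pieces, counts):
            if c:
                positions.append(rng.integers(s, e, size=c))
        pos = np.unique(np.concatenate(positions)) if positions else np.array([], int)
        pos_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    positions = pd.concat(pos_rows, ignore_index=True)

    # guarantee >= 1 CpG per element; top up planted hosts
    need: dict[tuple[str, int, int], int] = {}
    for df in (promoters, enhancers_df):
        for r in df.itertuples():
            need[(r.chrom, int(r.start), int(r.end))] = 1
    for kind, names_df in (("promoter", promoters), ("enhancer", enhancers_df)):
        specs = [p for p in config.planted_dmrs if p[2] == kind]
        hosts = names_df.set_index("name")
        host_names = sorted(hosts.index)[: len(specs)]
        if len(host_names) < len(specs):
            raise ValueError(f"not enough {kind}s to host planted DMRs")
        for (n_cpg, _, _), name in zip(specs, host_names):
            r = hosts.loc[name]
            need[(str(r["chrom"]), int(r["start"]), int(r["end"]))] = int(n_cpg)
    extra = []
    for (chrom, s, e), n_req in need.items():
        sub = positions[(positions["chrom"] == chrom)]
        inside = sub[(sub["pos"] >= s) & (sub["pos"] < e)]
        if len(inside) < n_req:
            add = np.linspace(s, e - 1, n_req).astype(int)
            add = np.setdiff1d(add, inside["pos"].to_numpy())[: n_req - len(inside)]
            extra.append(pd.DataFrame({"chrom": chrom, "pos": add}))
    if extra:
        positions = pd.concat([positions] + extra, ignore_index=True)
    positions = positions.drop_duplicates().sort_values(["chrom", "pos"]).reset_index(drop=True)
    positions.index = [f"cg{i+1:07d}" for i in range(len(positions))]
    positions.index.name = "cpg_id"

    # EPI edges: nearest promoters on the same chromosome
    epi_edges: dict[str, set[str]] = {}
    prom_mid = promoters.assign(mid=(promoters["start"] + promoters["end"]) // 2)
    for r in enhancers_df.itertuples():
        same = prom_mid[prom_mid["chrom"] == r.chrom]
        if not len(same):
            same = prom_mid
        mid = (r.start + r.end) // 2
        nearest = (same["mid"] - mid).abs().nsmallest(config.epi_fanout).index
        epi_edges[str(r.name)] = {str(same.loc[i, "name"]) for i in nearest}

    n_se = int(round(config.superenhancer_fraction * len(enhancers_df)))
    se_idx = sorted(rng.choice(len(enhancers_df), size=n_se, replace=False)) if n_se else []
    super_df = enhancers_df.loc[se_idx].copy()
    super_df["start"] = np.maximum(super_df["start"] - 500, 0)
    super_df["end"] = super_df["end"] + 500
    super_df["name"] = ["SE_" + n for n in super_df["name"]]

    annotation = RegulatoryAnnotation(
        promoters=promoters,
        enhancers=enhancers_df,
        epi_edges=epi_edges,
        super_enhancers=super_df.reset_index(drop=True),
        coding_gene_set=frozenset(genes),
    )
    return annotation, positions


def _planted_hosts(config: SimulationConfig, annotation: RegulatoryAnnotation):
    """Deterministic planted-spec -> host-element mapping (id order)."""
    out = []
    for kind in ("promoter", "enhancer"):
        df = annotation.promoters if kind == "promoter" else annotation.enhancers
        specs = [(i, p) for i, p in enumerate(config.planted_dmrs) if p[2] == kind]
        hosts = df.set_index("name")
        for (spec_i, spec), name in zip(specs, sorted(hosts.index)):
            r = hosts.loc[name]
            out.append((spec_i, spec, str(r["chrom"]), int(r["start"]), int(r["end"]), name))
    return out


def simulate_methylation(
    config: SimulationConfig, annotation: RegulatoryAnnotation, positions: pd.DataFrame
) -> tuple[BetaMatrix, GroundTruth]:
    """Beta matrix with planted group differences and logit-scale noise.

    Background CpGs share one group mean drawn from a bimodal methylome-
    like mixture; inside each planted DMR the responder mean is shifted by
    ``delta_beta`` (baselines are drawn so the shift stays inside [0, 1];
    means that would still escape are clipped with a warning).  Per-sample
    values are Beta-distributed with mean exactly the group mean and SD
    ``beta_noise_sd`` (shrunk near the boundaries where a Beta cannot reach
    that SD), so values stay inside (0, 1) without boundary mass and the
    planted group-mean difference is reproduced without attenuation;
    ``beta_noise_sd = 0`` reproduces the group means exactly.
    """
    rng = np.random.default_rng(config.seed + _SEED_METH)
    n_cpg = len(positions)
    chrom_arr = positions["chrom"].to_numpy()
    pos_arr = positions["pos"].to_numpy()

    # bimodal baseline typical of methylomes
    comp = rng.choice(3, size=n_cpg, p=[0.4, 0.4, 0.2])
    base = np.where(
        comp == 0,
        rng.beta(2, 10, size=n_cpg),
        np.where(comp == 1, rng.beta(10, 2, size=n_cpg), rng.beta(5, 5, size=n_cpg)),
    )
    delta = np.zeros(n_cpg)

    truth_intervals = []
    functional = []
    margin = 0.05
    for spec_i, (n_req, db, kind), chrom, s, e, name in _planted_hosts(config, annotation):
        inside = np.flatnonzero((chrom_arr == chrom) & (pos_arr >= s) & (pos_arr < e))
        idx = inside[: int(n_req)]
        lo = max(margin, margin - db)
        hi = max(min(1 - margin, 1 - margin - db), lo)  # empty window when |db|~1
        base[idx] = rng.uniform(lo, hi, size=len(idx))
        delta[idx] = db
        truth_intervals.append(
            {
                "chrom": chrom,
                "start": int(pos_arr[idx].min()),
                "end": int(pos_arr[idx].max()) + 1,
                "delta_beta": float(db),
                "kind": kind,
                "element": name,
                "gene": name if kind == "promoter" else None,
            }
        )
        if kind == "promoter":
            functional.append((name, int(-np.sign(db))))
    # background ("none") planted DMRs: runs of CpGs outside all elements
    none_specs = [(i, p) for i, p in enumerate(config.planted_dmrs) if p[2] == "none"]
    if none_specs:
        in_element = np.zeros(n_cpg, dtype=bool)
        for df in (annotation.promoters, annotation.enhancers):
            for r in df.itertuples():
                in_element |= (
                    (chrom_arr == r.chrom) & (pos_arr >= r.start) & (pos_arr < r.end)
                )
        bg = np.flatnonzero(~in_element)
        stride = len(bg) // (len(none_specs) + 1)
        for j, (spec_i, (n_req, db, kind)) in enumerate(none_specs):
            idx = bg[(j + 1) * stride : (j + 1) * stride + int(n_req)]
            idx = idx[chrom_arr[idx] == chrom_arr[idx[0]]]
            lo = max(margin, margin - db)
            hi = max(min(1 - margin, 1 - margin - db), lo)  # empty window when |db|~1
            base[idx] = rng.uniform(lo, hi, size=len(idx))
            delta[idx] = db
            truth_intervals.append(
                {
                    "chrom": str(chrom_arr[idx[0]]),
                    "start": int(pos_arr[idx].min()),
                    "end": int(pos_arr[idx].max()) + 1,
                    "delta_beta": float(db),
                    "kind": "none",
                    "element": None,
                    "gene": None,
                }
            )

    mean_nr = base
    mean_r = base + delta
    if (mean_r < 0).any() or (mean_r > 1).any():
        warnings.warn("planted delta_beta pushed group means outside [0,1]; clipped")
        mean_r = np.clip(mean_r, 0.0, 1.0)

    eps = 1e-3
    values = np.empty((n_cpg, config.n_samples))
    group_means = [mean_r] * config.n_responders + [mean_nr] * config.n_nonresponders
    for j, m in enumerate(group_means):
        m = np.clip(m, eps, 1 - eps)
        if config.beta_noise_sd > 0:
            # Beta(m*nu, (1-m)*nu) has mean m and var m(1-m)/(nu+1); the SD
            # is capped at 80% of the boundary-feasible maximum
            sd = np.minimum(config.beta_noise_sd, 0.8 * np.sqrt(m * (1 - m)))
            nu = m * (1 - m) / sd**2 - 1.0
            values[:, j] = rng.beta(m * nu, (1 - m) * nu)
        else:
            values[:, j] = m

    beta = BetaMatrix(
        values=pd.DataFrame(values, index=positions.index, columns=config.sample_ids),
        positions=positions,
    )
    truth = GroundTruth(
        true_dmr_intervals=truth_intervals,
        functional_genes=functional,
        marker_cutoffs={},
    )
    return beta, truth


def simulate_expression(
    config: SimulationConfig, annotation: RegulatoryAnnotation, truth: GroundTruth
) -> pd.DataFrame:
    """Negative-binomial gene counts coupled to the planted methylation.

    Each functional gene's responder mean is shifted by
    ``direction * coupling_strength`` in log2; library sizes span a 2-fold
    range.  Dispersion is ``nb_dispersion`` (gamma-Poisson mixture).
    """
    rng = np.random.default_rng(config.seed + _SEED_EXPR)
    genes = sorted(annotation.coding_gene_set | set(annotation.promoters["name"]))
    mu = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=len(genes))
    lib = 2.0 ** np.linspace(-0.5, 0.5, config.n_samples)
    lib = lib[rng.permutation(config.n_samples)]

    direction = dict(truth.functional_genes)
    log2fc = np.array([direction.get(g, 0) * config.coupling_strength for g in genes])
    is_resp = np.array([1] * config.n_responders + [0] * config.n_nonresponders)

    mean_mat = np.outer(mu, lib) * np.where(
        is_resp[None, :] == 1, 2.0 ** log2fc[:, None], 1.0
    )
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mean_mat / shape)
    else:
        lam = mean_mat
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=genes, columns=config.sample_ids)


def simulate_clinical(
    config: SimulationConfig, truth: GroundTruth
) -> ClinicalTable:
    """Clinical table with marker methylation, PD-L1 and exponential survival.

    Marker percent methylation is centred 15 points below the cutoff for
    responders and 15 above for non-responders (SD 10, clipped to [0,100]).
    Survival is exponential with the marker-low group's hazard scaled by
    ``hazard_ratio`` (the first marker defines the stratum; with no markers
    the response group does), administratively censored at
    ``censor_horizon_months``; ``censoring_fraction = 0`` disables
    censoring entirely.  PD-L1 positivity is more frequent in responders.
    """
    rng = np.random.default_rng(config.seed + _SEED_CLIN)
    n = config.n_samples
    df = pd.DataFrame(index=pd.Index(config.sample_ids, name="patient_id"))
    df["response"] = config.groups.to_numpy()
    is_r = (df["response"] == "R").to_numpy()

    for marker, cutoff in truth.marker_cutoffs.items():
        vals = np.where(
            is_r,
            rng.normal(cutoff - 15.0, 10.0, size=n),
            rng.normal(cutoff + 15.0, 10.0, size=n),
        )
        df[marker] = np.clip(vals, 0.0, 100.0)

    p_pos = np.where(is_r, 0.84, 0.74)
    positive = rng.random(n) < p_pos
    df["pdl1_percent"] = np.where(positive, rng.uniform(1.0, 80.0, n), rng.uniform(0.0, 0.99, n))

    if truth.marker_cutoffs:
        marker, cutoff = next(iter(truth.marker_cutoffs.items()))
        low = df[marker].to_numpy() <= cutoff
    else:
        low = is_r
    h_high = np.log(2.0) / config.baseline_median_months
    hazard = np.where(low, h_high * config.hazard_ratio, h_high)
    for prefix in ("pfs", "os"):
        latent = rng.exponential(1.0 / hazard)
        if config.censoring_fraction == 0:
            df[f"{prefix}_months"] = latent
            df[f"{prefix}_event"] = 1
        else:
            horizon = config.censor_horizon_months
            df[f"{prefix}_months"] = np.minimum(latent, horizon)
            df[f"{prefix}_event"] = (latent <= horizon).astype(int)

    df["sex"] = rng.integers(0, 2, n)
    df["age"] = rng.integers(39, 82, n)
    df["smoking"] = rng.integers(0, 2, n)
    return ClinicalTable(df)


def make_validation_fixture() -> ClinicalTable:
    """Deterministic synthetic validation cohort (56 patients, 25 R / 31 NR).

    Per-patient methylation is not published for the validation cohort, so
    this synthetic stand-in stores group-level values whose dichotomization
    at 40% (CYTIP) and 50% (TNFSF8) reproduces the published predicted-
    group sizes and responder counts:

    ========================  ====  =====  ====  =====
    cell (C<=40, T<=50, resp)  n    cell   n     notes
    ========================  ====  =====  ====  =====
    (+, +, R)                  14   (-, +, R)  5   C- value 60
    (+, +, NR)                  6   (-, +, NR) 6   C- value 45
    (+, -, R)                   3   (-, -, R)  1
    (+, -, NR)                  3   (-, -, NR) 11
    ========================  ====  =====  ====  =====

    plus 2 CYTIP-only NR patients (TNFSF8 missing), 3 TNFSF8-only patients
    (2 R, 1 NR; CYTIP missing) and 2 patients missing both markers (NR).
    Marker values sit exactly at the cutoffs for predicted positives and
    just above (45 / 55) for selected predicted negatives so that the 5%
    cutoff sweep uniquely selects 40% and 50%.  PD-L1 splits 44 positive
    (21 R) / 12 negative (4 R).  Survival times are synthetic, drawn from
    exponentials whose hazards favour the hypomethylated stratum, with a
    fixed internal seed.
    """
    rows: list[dict] = []

    def add(n, cytip, tnfsf8, response):
        for _ in range(n):
            rows.append({"CYTIP": cytip, "TNFSF8": tnfsf8, "response": response})

    add(14, 40.0, 50.0, "R")   # C+ T+ R
    add(6, 40.0, 50.0, "NR")   # C+ T+ NR
    add(3, 40.0, 70.0, "R")    # C+ T- R
    add(3, 40.0, 55.0, "NR")   # C+ T- NR (just above the TNFSF8 cutoff)
    add(5, 60.0, 50.0, "R")    # C- T+ R
    add(6, 45.0, 50.0, "NR")   # C- T+ NR (just above the CYTIP cutoff)
    add(1, 60.0, 70.0, "R")    # C- T- R
    add(11, 60.0, 70.0, "NR")  # C- T- NR
    add(2, 40.0, np.nan, "NR")  # CYTIP evaluable only
    add(2, np.nan, 50.0, "R")   # TNFSF8 evaluable only
    add(1, np.nan, 50.0, "NR")
    add(2, np.nan, np.nan, "NR")  # neither marker evaluable

    df = pd.DataFrame(rows)
    df.index = pd.Index([f"V{i+1:02d}" for i in range(len(df))], name="patient_id")

    # PD-L1: 44 positive (21 of 25 R, 23 of 31 NR), 12 negative
    rng = np.random.default_rng(2019)
    is_r = (df["response"] == "R").to_numpy()
    pdl1 = np.empty(len(df))
    r_idx = np.flatnonzero(is_r)
    nr_idx = np.flatnonzero(~is_r)
    pdl1[r_idx[:21]] = np.round(rng.uniform(1.0, 80.0, 21), 1)
    pdl1[r_idx[21:]] = 0.0
    pdl1[nr_idx[:23]] = np.round(rng.uniform(1.0, 80.0, 23), 1)
    pdl1[nr_idx[23:]] = 0.0
    df["pdl1_percent"] = pdl1

    # synthetic survival: hypomethylated (marker-low) patients live longer
    low = (df["CYTIP"].fillna(100) <= 40) & (df["TNFSF8"].fillna(100) <= 50)
    h = np.where(low, np.log(2) / 12.0, np.log(2) / 3.0)
    for prefix in ("pfs", "os"):
        latent = rng.exponential(1.0 / h) * (1.5 if prefix == "os" else 1.0)
        df[f"{prefix}_months"] = np.round(np.minimum(latent, 24.0), 2)
        df[f"{prefix}_event"] = (latent <= 24.0).astype(int)

    df["sex"] = rng.integers(0, 2, len(df))
    df["age"] = rng.integers(39, 82, len(df))
    df["smoking"] = rng.integers(0, 2, len(df))
    return ClinicalTable(df)
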