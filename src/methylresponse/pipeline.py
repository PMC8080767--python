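"""End-to-end discovery and validation pipelines.

``run_discovery`` chains preprocessing, DMR calling, regulatory
annotation, expression integration and gene-set enrichment on simulated
inputs, writing every intermediate table plus a run manifest.
``run_validation`` evaluates the marker classifiers (group tests, ROC,
cutoff sweep, PPV/NPV, two-marker combination, PD-L1 comparator) and the
marker-stratified survival analyses on a clinical table.

Both are plain functions over a :class:`PipelineConfig`; every threshold
defaults to the value the analysis is defined with (minFDR 0.01,
|meanbetaFC| > 0.15, DE q < 0.01, Pearson p < 0.05, enrichment q < 0.01,
5% cutoff grid, PD-L1 at 1%).
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as annot_mod
from . import biomarker as bm
from . import dmr as dmr_mod
from . import enrichment as enr_mod
from . import expression as expr_mod
from . import survival as surv_mod
from .biomarker import ClinicalTable
from .enrichment import GeneSetCollection
from .preprocess import FilterSpec, beta_to_m, filter_sites
from .simulate import (
    SimulationConfig,
    generate_annotation,
    make_validation_fixture,
    simulate_clinical,
    simulate_expression,
    simulate_methylation,
)

__all__ = ["PipelineConfig", "StageError", "run_discovery", "run_validation"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Thresholds, seed and output directory for both pipelines."""

    outdir: str = "results"
    seed: int = 0
    min_fdr: float = 0.01
    meanbetafc_min: float = 0.15
    de_q: float = 0.01
    corr_p: float = 0.05
    enrich_q: float = 0.01
    cutoff_step: float = 5.0
    pdl1_threshold: float = 1.0
    bandwidth_bp: float = 1000.0
    gap_bp: float = 1000.0
    min_cpgs: int = 2
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        for name in ("min_fdr", "de_q", "corr_p", "enrich_q"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if not (0 < self.meanbetafc_min < 1):
            raise ValueError("meanbetafc_min must be in (0, 1)")


def _manifest(config: PipelineConfig, stages: list[dict], path: Path) -> None:
    payload = {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "simulation"
        },
        "simulation": asdict(config.simulation),
        "stages": stages,
    }
    path.write_text(json.dumps(payload, indent=2, default=str))


def _default_discovery_sim(seed: int) -> SimulationConfig:
    """The stated discovery world: 6 R vs 12 NR, planted promoter DMRs with
    methylation-expression coupling for three genes."""
    return SimulationConfig(
        seed=seed,
        planted_dmrs=[(20, -0.25, "promoter")] * 3 + [(20, 0.25, "enhancer")] * 2,
        coupling_strength=2.0,
    )


def run_discovery(config: PipelineConfig | None = None) -> dict:
    """Run the discovery pipeline; returns a dict of in-memory results and
    writes all tables under ``config.outdir``."""
    if config is None:
        config = PipelineConfig()
    if not config.simulation.planted_dmrs:
        config.simulation = _default_discovery_sim(config.seed)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    sim = config.simulation

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - report stage and re-raise
                raise StageError(name, exc) from exc
            stages.append({"stage": name, **result[1]})
            return result[0]

        return deco

    # ---- inputs (simulated) -------------------------------------------
    annotation, positions = generate_annotation(sim)
    beta_raw, truth = simulate_methylation(sim, annotation, positions)
    counts = simulate_expression(sim, annotation, truth)
    groups = sim.groups
    annotation.write_bed(
        out / "promoters.bed", out / "enhancers.bed",
        out / "super_enhancers.bed", out / "epi_edges.tsv",
    )
    beta_raw.to_tsv(out / "beta.tsv", out / "cpg_map.tsv")
    counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
    pd.DataFrame(truth.true_dmr_intervals).to_csv(
        out / "truth_dmrs.tsv", sep="\t", index=False
    )

    @stage("preprocess")
    def _preprocess():
        detection_p = pd.DataFrame(
            0.0, index=beta_raw.cpg_ids, columns=beta_raw.sample_ids
        )
        beta, report = filter_sites(beta_raw, detection_p, FilterSpec())
        beta = beta.sort_by_position()
        return (beta, {"retained_sites": report["retained"]})

    beta = _preprocess

    @stage("dmr_calling")
    def _dmrs():
        m = beta_to_m(beta)
        stats = dmr_mod.per_cpg_stats(m, beta.values, groups)
        smoothed = dmr_mod.smooth_stats(stats, beta.positions, config.bandwidth_bp)
        called = dmr_mod.call_dmrs(
            smoothed, beta.positions, config.min_fdr, config.gap_bp, config.min_cpgs
        )
        bed = dmr_mod.dmrs_to_bed(called)
        bed.to_csv(out / "dmrs.bed", sep="\t", header=False, index=False)
        smoothed.to_csv(out / "cpg_stats.tsv", sep="\t", index_label="cpg_id")
        return ((called, bed, smoothed), {"n_dmrs": len(called)})

    called_dmrs, dmr_bed, smoothed = _dmrs

    @stage("regulatory_annotation")
    def _annotate():
        covered, cov_report = annot_mod.filter_covered_elements(
            annotation, beta.positions
        )
        annotated = annot_mod.assign_elements(dmr_bed, covered)
        annotated, summary = annot_mod.map_targets(annotated, covered)
        se_flags = annot_mod.flag_super_enhancers(annotated, covered)
        props = annot_mod.chromosome_proportions(annotated, covered)
        props.to_csv(out / "chromosome_proportions.tsv", sep="\t")
        pd.Series(sorted(annotated.pdmr_targets)).to_csv(
            out / "pdmr_targets.txt", index=False, header=False
        )
        pd.Series(sorted(annotated.edmr_targets)).to_csv(
            out / "edmr_targets.txt", index=False, header=False
        )
        return ((annotated, se_flags, summary), {**cov_report, **{
            k: v for k, v in summary.items() if isinstance(v, (int, float))
        }})

    annotated, se_flags, target_summary = _annotate

    @stage("expression_integration")
    def _integrate():
        de = expr_mod.differential_expression(counts, groups)
        de.to_csv(out / "de_results.tsv", sep="\t", index_label="gene_id")
        # promoter-DMR candidates with their genes and effect sizes
        rows = []
        for i, genes in annotated.pdmrs.items():
            for g in genes:
                rows.append(
                    {
                        "dmr_index": i,
                        "gene": g,
                        "meanbetafc": float(dmr_bed.loc[i, "meanbetafc"]),
                    }
                )
        candidates = pd.DataFrame(rows, columns=["dmr_index", "gene", "meanbetafc"])
        sf = expr_mod.size_factors(counts)
        log_expr = np.log2(counts / sf + 1.0)
        correlations = {}
        for row in candidates.itertuples(index=False):
            d = called_dmrs[int(row.dmr_index)]
            in_dmr = (
                (beta.positions["chrom"] == d.chrom)
                & (beta.positions["pos"] >= d.start)
                & (beta.positions["pos"] < d.end)
            )
            dmr_beta = beta.values.loc[in_dmr.to_numpy()].mean(axis=0)
            correlations[row.gene] = expr_mod.dmr_expression_correlation(
                dmr_beta, log_expr.loc[row.gene]
            )
        functional = expr_mod.select_functional_dmrs(
            candidates,
            de,
            correlations,
            meanbetafc_min=config.meanbetafc_min,
            de_q_max=config.de_q,
            corr_p_max=config.corr_p,
        )
        func_df = pd.DataFrame([vars(f) for f in functional])
        func_df.to_csv(out / "functional_dmrs.tsv", sep="\t", index=False)
        selected = [f.gene for f in functional if f.selected]
        return (
            (functional, selected, de),
            {"n_candidates": len(candidates), "n_selected": len(selected)},
        )

    functional, selected_genes, de = _integrate

    @stage("enrichment")
    def _enrich():
        collection = _synthetic_gene_sets(annotation, annotated, config.seed)
        universe = sorted(annotation.coding_gene_set)
        res_p = enr_mod.enrich(annotated.pdmr_targets, collection, universe)
        res_e = enr_mod.enrich(annotated.edmr_targets, collection, universe)
        res_p.to_csv(out / "enrichment_pdmr.tsv", sep="\t")
        res_e.to_csv(out / "enrichment_edmr.tsv", sep="\t")
        comparison = enr_mod.compare_target_classes(res_p, res_e, config.enrich_q)
        return (
            (res_p, res_e, comparison),
            {
                "pdmr_significant": len(comparison["pdmr_significant"]),
                "edmr_significant": len(comparison["edmr_significant"]),
            },
        )

    enrich_p, enrich_e, enrich_cmp = _enrich

    _manifest(config, stages, out / "manifest.json")
    return {
        "annotation": annotation,
        "positions": positions,
        "truth": truth,
        "beta": beta,
        "dmrs": called_dmrs,
        "dmr_bed": dmr_bed,
        "annotated": annotated,
        "super_enhancer_flags": se_flags,
        "target_summary": target_summary,
        "de": de,
        "functional": functional,
        "candidate_biomarkers": selected_genes,
        "enrichment": {"pdmr": enrich_p, "edmr": enrich_e, "compare": enrich_cmp},
        "stages": stages,
    }


def _synthetic_gene_sets(annotation, annotated, seed: int) -> GeneSetCollection:
    """Gene sets for the enrichment stage: a few seeded with DMR targets
    (so something is enriched) plus random background sets."""
    rng = np.random.default_rng(seed + 29)
    genes = sorted(annotation.coding_gene_set)
    sets: dict[str, frozenset] = {}
    cats: dict[str, str] = {}
    targets = sorted(annotated.pdmr_targets | annotated.edmr_targets)
    if targets:
        pad = rng.choice(genes, size=min(10, len(genes)), replace=False)
        sets["TARGET_SET"] = frozenset(targets) | frozenset(pad)
        cats["TARGET_SET"] = "immune"
    for i in range(10):
        members = rng.choice(genes, size=min(15, len(genes)), replace=False)
        sets[f"RANDOM_{i:02d}"] = frozenset(members)
        cats[f"RANDOM_{i:02d}"] = "other"
    return GeneSetCollection(sets=sets, categories=cats)


def run_validation(
    config: PipelineConfig | None = None, table: ClinicalTable | None = None
) -> dict:
    """Run the validation pipeline on ``table`` (defaults to the bundled
    synthetic validation fixture); writes a summary report."""
    if config is None:
        config = PipelineConfig()
    if table is None:
        table = make_validation_fixture()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    df = table.data
    markers = [c for c in ("CYTIP", "TNFSF8") if c in df.columns]
    if not markers:
        raise StageError("biomarker", KeyError("no marker columns found"))

    summary: dict = {"n_patients": int(len(df))}
    classifiers: dict[str, bm.MarkerClassifier] = {}
    try:
        for m in markers:
            vals, resp = df[m], df["response"]
            keep = vals.notna()
            r_vals = vals[keep & (resp == "R")]
            nr_vals = vals[keep & (resp == "NR")]
            stat, p = bm.wilcoxon_rank_sum(r_vals, nr_vals, alternative="less")
            auc, _ = bm.roc_auc(vals[keep], resp[keep])
            best, sweep = bm.sweep_cutoffs(vals, resp, config.cutoff_step, marker=m)
            sweep.to_csv(out / f"sweep_{m}.tsv", sep="\t", index=False)
            classifiers[m] = best
            summary[m] = {
                "n_evaluable": int(keep.sum()),
                "wilcoxon_p_one_sided": p,
                "auc": auc,
                "chosen_cutoff": best.cutoff,
                "ppv": best.ppv,
                "npv": best.npv,
                "confusion": {"tp": best.tp, "fp": best.fp, "tn": best.tn, "fn": best.fn},
            }
        combined = bm.combine_markers(
            table, {m: classifiers[m].cutoff for m in markers}
        )
        summary["combined"] = {
            "ppv": combined.ppv,
            "npv": combined.npv,
            "confusion": {
                "tp": combined.tp, "fp": combined.fp,
                "tn": combined.tn, "fn": combined.fn,
            },
        }
        classifiers["combined"] = combined
        pdl1 = bm.pdl1_classifier(table, config.pdl1_threshold)
        summary["pdl1"] = {
            "ppv": pdl1.ppv,
            "npv": pdl1.npv,
            "confusion": {"tp": pdl1.tp, "fp": pdl1.fp, "tn": pdl1.tn, "fn": pdl1.fn},
        }
        classifiers["pdl1"] = pdl1
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("biomarker", exc) from exc

    try:
        strata = {
            m: df[m].notna() & (df[m] <= classifiers[m].cutoff) for m in markers
        }
        strata["combined"] = np.logical_and.reduce(
            [df[m].notna() & (df[m] <= classifiers[m].cutoff) for m in markers]
        )
        strata["pdl1"] = df["pdl1_percent"] >= config.pdl1_threshold
        survival_summary = {}
        for name, low in strata.items():
            low = pd.Series(low, index=df.index)
            per_endpoint = {}
            for endpoint in ("pfs", "os"):
                t = df[f"{endpoint}_months"].to_numpy(dtype=float)
                e = df[f"{endpoint}_event"].to_numpy(dtype=int)
                grp = np.where(low.to_numpy(), "low", "high")
                km_low = surv_mod.km_estimate(t[grp == "low"], e[grp == "low"])
                km_high = surv_mod.km_estimate(t[grp == "high"], e[grp == "high"])
                chi2, p = surv_mod.logrank_test(t, e, grp)
                cov = pd.DataFrame(
                    {
                        "marker_low": low.astype(float).to_numpy(),
                        "sex": df["sex"].to_numpy(dtype=float),
                        "age": df["age"].to_numpy(dtype=float),
                        "smoking": df["smoking"].to_numpy(dtype=float),
                        "pdl1_positive": (
                            df["pdl1_percent"] >= config.pdl1_threshold
                        ).to_numpy(dtype=float),
                    },
                    index=df.index,
                )
                fit = surv_mod.cox_fit(t, e, cov)
                per_endpoint[endpoint] = {
                    "median_low": km_low.median,
                    "median_high": km_high.median,
                    "logrank_chi2": chi2,
                    "logrank_p": p,
                    "cox_hr_marker": float(fit.summary.loc["marker_low", "hr"])
                    if fit.converged
                    else None,
                    "cox_converged": fit.converged,
                }
            survival_summary[name] = per_endpoint
        summary["survival"] = survival_summary
    except Exception as exc:  # noqa: BLE001
        raise StageError("survival", exc) from exc

    (out / "validation_summary.json").write_text(
        json.dumps(summary, indent=2, default=float)
    )
    return {"summary": summary, "classifiers": classifiers, "table": table}
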