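import numpy as np
import pandas as pd
import pytest

from methylresponse.annotation import (
    AnnotatedDmrSet,
    RegulatoryAnnotation,
    assign_elements,
    chromosome_proportions,
    filter_covered_elements,
    flag_super_enhancers,
    map_targets,
    overlap_any,
)
from conftest import brute_force_overlaps


def _annotation(**kwargs):
    defaults = dict(
        promoters=pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [100, 500, 100],
                "end": [200, 600, 200],
                "name": ["G1", "G2", "G3"],
            }
        ),
        enhancers=pd.DataFrame(
            {
                "chrom": ["chr1", "chr2"],
                "start": [300, 300],
                "end": [400, 400],
                "name": ["E1", "E2"],
            }
        ),
        epi_edges={"E1": {"G1", "G2"}, "E2": {"G3"}},
        coding_gene_set=frozenset({"G1", "G2", "G3"}),
    )
    defaults.update(kwargs)
    return RegulatoryAnnotation(**defaults)


class TestOverlapAny:
    def test_matches_brute_force(self, toy_intervals):
        query, subject = toy_intervals
        assert overlap_any(query, subject) == brute_force_overlaps(query, subject)

    def test_matches_brute_force_random(self, rng):
        for _ in range(5):
            q = pd.DataFrame(
                {
                    "chrom": rng.choice(["chr1", "chr2"], 30),
                    "start": (s := rng.integers(0, 1000, 30)),
                    "end": s + rng.integers(1, 200, 30),
                }
            )
            s2 = pd.DataFrame(
                {
                    "chrom": rng.choice(["chr1", "chr2"], 20),
                    "start": (t := rng.integers(0, 1000, 20)),
                    "end": t + rng.integers(1, 200, 20),
                }
            )
            assert overlap_any(q, s2) == brute_force_overlaps(q, s2)

    def test_half_open_boundary(self):
        q = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [250]})
        s = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        assert overlap_any(q, s) == []  # touching endpoints do not overlap


class TestFilterCoveredElements:
    def test_uncovered_element_removed(self):
        ann = _annotation()
        positions = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [150, 350]}, index=["a", "b"]
        )
        out, report = filter_covered_elements(ann, positions)
        assert list(out.promoters["name"]) == ["G1"]
        assert list(out.enhancers["name"]) == ["E1"]
        assert report["promoters"] == {"input": 3, "retained": 1}

    def test_cpg_at_start_counts_inside(self):
        ann = _annotation()
        positions = pd.DataFrame({"chrom": ["chr1"], "pos": [100]}, index=["a"])
        out, _ = filter_covered_elements(ann, positions)
        assert "G1" in set(out.promoters["name"])  # pos == start is inside

    def test_cpg_at_end_is_outside(self):
        ann = _annotation()
        positions = pd.DataFrame({"chrom": ["chr1"], "pos": [200]}, index=["a"])
        out, _ = filter_covered_elements(ann, positions)
        assert "G1" not in set(out.promoters["name"])  # half-open end

    def test_identity_when_all_covered(self, small_world):
        out, report = filter_covered_elements(
            small_world["annotation"], small_world["positions"]
        )
        assert report["promoters"]["input"] == report["promoters"]["retained"]
        assert report["enhancers"]["input"] == report["enhancers"]["retained"]


class TestAssignElements:
    def test_promoter_overlap_50bp(self):
        ann = _annotation()
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [250]})
        out = assign_elements(dmrs, ann)
        assert out.pdmrs == {0: {"G1"}}
        assert out.edmrs == {}

    def test_half_open_no_overlap(self):
        ann = _annotation()
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [250]})
        out = assign_elements(dmrs, ann)
        assert out.pdmrs == {}

    def test_dual_membership_inflates_class_sum(self):
        ann = _annotation()
        # spans promoter G2 and enhancer E1
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [350], "end": [550]})
        out = assign_elements(dmrs, ann)
        assert 0 in out.pdmrs and 0 in out.edmrs
        assert len(out.pdmrs) + len(out.edmrs) == 2 > len(dmrs)

    def test_input_order_invariance(self, small_world, rng):
        from methylresponse.dmr import dmrs_to_bed

        dmrs = pd.DataFrame(
            {
                "chrom": ["chr1", "chr2", "chr1"],
                "start": [100, 100, 500],
                "end": [250, 250, 650],
            }
        )
        ann = _annotation()
        base = assign_elements(dmrs, ann)
        perm = [2, 0, 1]
        shuffled = assign_elements(dmrs.iloc[perm].reset_index(drop=True), ann)
        remap = {new: old for new, old in enumerate(perm)}
        assert {remap[k]: v for k, v in shuffled.pdmrs.items()} == base.pdmrs


class TestMapTargets:
    def test_edmr_targets_via_edges(self):
        ann = _annotation()
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [350], "end": [360]})
        out, summary = map_targets(assign_elements(dmrs, ann), ann)
        assert out.edmr_targets == frozenset({"G1", "G2"})
        assert summary["n_edmr_targets"] == 2

    def test_non_coding_gene_excluded(self):
        ann = _annotation(coding_gene_set=frozenset({"G1", "G3"}))
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [350], "end": [360]})
        out, _ = map_targets(assign_elements(dmrs, ann), ann)
        assert out.edmr_targets == frozenset({"G1"})  # G2 not coding

    def test_overlap_fractions(self):
        annotated = AnnotatedDmrSet(
            dmrs=pd.DataFrame({"chrom": [], "start": [], "end": []}),
            pdmrs={0: {"A", "B", "C"}},
            edmrs={1: {"E1"}},
        )
        ann = _annotation(
            promoters=pd.DataFrame(
                {
                    "chrom": ["chr1"] * 4,
                    "start": [0, 100, 200, 300],
                    "end": [50, 150, 250, 350],
                    "name": ["A", "B", "C", "D"],
                }
            ),
            epi_edges={"E1": {"B", "C", "D"}},
            coding_gene_set=frozenset({"A", "B", "C", "D"}),
        )
        _, summary = map_targets(annotated, ann)
        assert summary["n_shared_targets"] == 2
        assert summary["shared_frac_of_pdmr"] == pytest.approx(2 / 3)
        assert summary["shared_frac_of_edmr"] == pytest.approx(2 / 3)

    def test_edgeless_enhancer_logged(self):
        ann = _annotation(epi_edges={"E1": set(), "E2": {"G3"}})
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [350], "end": [360]})
        out, summary = map_targets(assign_elements(dmrs, ann), ann)
        assert out.edmr_targets == frozenset()
        assert summary["edgeless_enhancers"] == ["E1"]

    def test_edmr_targets_have_edges(self, small_world):
        # every eDMR target is reachable through some overlapped enhancer
        from methylresponse.dmr import dmrs_to_bed

        ann = small_world["annotation"]
        dmrs = ann.enhancers[["chrom", "start", "end"]].head(5)
        out, _ = map_targets(assign_elements(dmrs, ann), ann)
        reachable = set()
        for enh_ids in out.edmrs.values():
            for e in enh_ids:
                reachable |= ann.epi_edges.get(e, set())
        assert out.edmr_targets <= reachable


class TestSuperEnhancers:
    def test_inside_flagged(self):
        ann = _annotation(
            super_enhancers=pd.DataFrame(
                {"chrom": ["chr1"], "start": [250], "end": [450], "name": ["SE1"]}
            )
        )
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [350], "end": [360]})
        flags = flag_super_enhancers(assign_elements(dmrs, ann), ann)
        assert flags.to_dict() == {0: True}

    def test_empty_set_all_false(self):
        ann = _annotation()
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [350], "end": [360]})
        flags = flag_super_enhancers(assign_elements(dmrs, ann), ann)
        assert not flags.any()

    def test_planted_two_of_five(self, small_world):
        ann = small_world["annotation"]
        enh = ann.enhancers.head(5).copy()
        se = enh.iloc[[1, 3]].copy()
        se["name"] = "SE_" + se["name"]
        import dataclasses

        ann2 = dataclasses.replace(ann, super_enhancers=se.reset_index(drop=True))
        dmrs = enh[["chrom", "start", "end"]].reset_index(drop=True)
        flags = flag_super_enhancers(assign_elements(dmrs, ann2), ann2)
        assert flags.sum() == 2
        assert set(flags[flags].index) == {1, 3}


class TestChromosomeProportions:
    def test_fraction_and_bounds(self):
        ann = _annotation()
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [250]})
        props = chromosome_proportions(assign_elements(dmrs, ann), ann)
        assert props.loc["chr1", "promoter_fraction"] == pytest.approx(0.5)
        assert props.loc["chr2", "promoter_fraction"] == 0.0
        assert (props["promoter_fraction"].dropna() <= 1).all()

    def test_no_dmrs_all_zero(self):
        ann = _annotation()
        empty = assign_elements(
            pd.DataFrame({"chrom": [], "start": [], "end": []}), ann
        )
        props = chromosome_proportions(empty, ann)
        assert (props["promoter_fraction"].dropna() == 0).all()
        assert (props["enhancer_fraction"].dropna() == 0).all()


class TestInvariants:
    def test_epi_edge_genes_must_be_promoter_genes(self):
        with pytest.raises(ValueError, match="promoter genes"):
            _annotation(epi_edges={"E1": {"NOT_A_GENE"}})
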