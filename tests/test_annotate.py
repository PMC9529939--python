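"""Gene annotation, burden sums, profiles, and gene-set score comparison."""

import math

import numpy as np
import pandas as pd
import pytest

import cnvburden as cb
from cnvburden.annotate import PROFILE_COLUMNS, SetSums
from cnvburden.errors import ConfigError, InsufficientDataError

from conftest import make_call, make_gene


@pytest.fixture()
def toy_genes():
    return [
        make_gene("A", "1", 10, 20, loeuf=0.5, ds=0.3, sets={"circadian"}),
        make_gene("B", "1", 30, 50, loeuf=2.0, ds=0.9, sets={"insomnia"}),
        make_gene("C", "1", 90, 110, loeuf=1.0, ds=0.5),
        make_gene("D", "1", 200, 240, loeuf=0.25, ds=0.2, sets={"circadian", "insomnia"}),
        make_gene("E", "2", 10, 20, loeuf=1.0, ds=0.4),
    ]


class TestGenesInCnv:
    def test_contained_gene_included_under_both_rules(self, toy_genes):
        cnv = make_call("1", 0, 100)
        assert "A" in cb.genes_in_cnv(cnv, toy_genes, "contained")
        assert "A" in cb.genes_in_cnv(cnv, toy_genes, "any_overlap")

    def test_boundary_gene_depends_on_rule(self, toy_genes):
        cnv = make_call("1", 0, 100)  # gene C spans [90,110)
        assert "C" not in cb.genes_in_cnv(cnv, toy_genes, "contained")
        assert "C" in cb.genes_in_cnv(cnv, toy_genes, "any_overlap")

    def test_unknown_rule_rejected(self, toy_genes):
        with pytest.raises(ConfigError):
            cb.genes_in_cnv(make_call("1", 0, 100), toy_genes, "touching")

    def test_membership_matches_per_base_bitmap(self, toy_genes):
        cnvs = [make_call("1", 0, 100), make_call("1", 25, 250)]
        for cnv in cnvs:
            bases = set(range(cnv.interval.start, cnv.interval.end))
            for rule in ("contained", "any_overlap"):
                got = set(cb.genes_in_cnv(cnv, toy_genes, rule))
                expect = set()
                for g in toy_genes:
                    if g.interval.chrom != cnv.interval.chrom:
                        continue
                    gb = set(range(g.interval.start, g.interval.end))
                    if rule == "contained" and gb <= bases:
                        expect.add(g.gene_id)
                    if rule == "any_overlap" and gb & bases:
                        expect.add(g.gene_id)
                assert got == expect


class TestAnnotate:
    def test_inv_loeuf_sum(self, toy_genes):
        cnv = make_call("1", 0, 60)  # contains A (0.5) and B (2.0), both sleep genes
        ann = cb.annotate(cnv, toy_genes, target_set="union")
        assert ann.target.inv_loeuf == pytest.approx(1 / 0.5 + 1 / 2.0)
        assert ann.target.n_genes == 2 and ann.other.n_genes == 0

    def test_empty_cnv_all_zero(self, toy_genes):
        ann = cb.annotate(make_call("3", 0, 1000), toy_genes)
        assert ann.target == SetSums()
        assert ann.total_genes == 0

    def test_ds_sums_split_by_set(self, toy_genes):
        cnv = make_call("1", 0, 120)  # A (target, ds 0.3) under any_overlap also C
        ann = cb.annotate(cnv, toy_genes, target_set="circadian", rule="any_overlap")
        assert ann.target.ds == pytest.approx(0.3)
        assert ann.other.ds == pytest.approx(0.9 + 0.5)  # B counts as other here

    def test_dual_membership_counts_once_under_union(self, toy_genes):
        cnv = make_call("1", 150, 300)  # gene D in both sets
        ann = cb.annotate(cnv, toy_genes, target_set="union")
        assert ann.target.n_genes == 1
        assert ann.target.inv_loeuf == pytest.approx(4.0)

    def test_missing_loeuf_counted_but_unscored(self):
        genes = [
            make_gene("N", "1", 10, 20, loeuf=float("nan"), ds=0.5, sets={"circadian"}),
            make_gene("M", "1", 30, 40, loeuf=0.5, ds=float("nan"), sets={"circadian"}),
        ]
        ann = cb.annotate(make_call("1", 0, 100), genes, target_set="circadian")
        assert ann.target.n_genes == 2
        assert ann.target.inv_loeuf == pytest.approx(2.0)
        assert ann.target.ds == pytest.approx(0.5)

    def test_conservation_target_plus_other_equals_setless_total(self, genome, gene_index):
        cfg = cb.SimulationConfig(n_cases=60, n_controls=60, seed=11)
        calls, _ = cb.simulate_cohort(genome, cfg)
        for target in ("circadian", "insomnia", "union"):
            for call in calls[:40]:
                ann = cb.annotate(call, gene_index, target_set=target)
                total = cb.annotate(call, gene_index, target_set="union")
                assert ann.target.n_genes + ann.other.n_genes == len(ann.gene_ids)
                assert ann.target.inv_loeuf + ann.other.inv_loeuf == pytest.approx(
                    total.target.inv_loeuf + total.other.inv_loeuf
                )

    def test_doubling_loeuf_halves_inv_sums(self, toy_genes):
        doubled = [
            cb.GeneRecord(g.gene_id, g.interval, g.loeuf * 2, g.ds_score, g.sets)
            for g in toy_genes
        ]
        cnv = make_call("1", 0, 300)
        a = cb.annotate(cnv, toy_genes)
        b = cb.annotate(cnv, doubled)
        assert b.target.inv_loeuf == pytest.approx(a.target.inv_loeuf / 2)
        assert b.other.inv_loeuf == pytest.approx(a.other.inv_loeuf / 2)


class TestProfiles:
    def test_additivity_over_cnvs(self, toy_genes):
        calls = [
            make_call("1", 0, 30, sample="P", dosage="DEL"),   # gene A
            make_call("1", 0, 60, sample="P", dosage="DEL"),   # genes A, B
        ]
        ann = cb.annotate_cnvs(calls, toy_genes, target_set="union")
        prof = cb.build_profiles(ann, ["P", "Q"])
        assert prof.loc["P", "DEL_target_n_genes"] == 3  # 1 + 2
        assert prof.loc["Q"].sum() == 0

    def test_cohort_without_cnvs_gets_zero_profiles(self):
        prof = cb.build_profiles([], [f"S{i}" for i in range(10)])
        assert prof.shape == (10, len(PROFILE_COLUMNS))
        assert (prof.to_numpy() == 0).all()

    def test_orphan_sample_rejected(self, toy_genes):
        ann = cb.annotate_cnvs([make_call("1", 0, 30, sample="ghost")], toy_genes)
        with pytest.raises(ConfigError):
            cb.build_profiles(ann, ["S1"])

    def test_profiles_match_brute_force_rescan(self, genome, gene_index):
        cfg = cb.SimulationConfig(n_cases=40, n_controls=40, seed=3)
        calls, ph = cb.simulate_cohort(genome, cfg)
        ann = cb.annotate_cnvs(calls, gene_index, target_set="union")
        prof = cb.build_profiles(ann, ph["sample_id"].tolist())
        # independent per-sample loop
        for sid in ph["sample_id"]:
            mine = {c: 0.0 for c in PROFILE_COLUMNS}
            for a in ann:
                if a.call.sample_id != sid:
                    continue
                for side, sums in (("target", a.target), ("other", a.other)):
                    mine[f"{a.call.dosage}_{side}_n_genes"] += sums.n_genes
                    mine[f"{a.call.dosage}_{side}_inv_loeuf"] += sums.inv_loeuf
                    mine[f"{a.call.dosage}_{side}_ds"] += sums.ds
            for col, v in mine.items():
                assert prof.loc[sid, col] == pytest.approx(v)

    def test_union_equals_circadian_plus_insomnia_minus_overlap(self):
        genes = [
            make_gene("C1", "1", 0, 10, loeuf=0.5, sets={"circadian"}),
            make_gene("I1", "1", 20, 30, loeuf=1.0, sets={"insomnia"}),
            make_gene("CI", "1", 40, 50, loeuf=0.25, sets={"circadian", "insomnia"}),
            make_gene("O1", "1", 60, 70, loeuf=2.0),
        ]
        call = make_call("1", 0, 100, sample="P", dosage="DUP")
        by_target = {
            t: cb.build_profiles(cb.annotate_cnvs([call], genes, target_set=t), ["P"])
            for t in ("circadian", "insomnia", "union")
        }
        overlap_contrib = 1 / 0.25  # gene CI counted in both single-set targets
        u = by_target["union"].loc["P", "DUP_target_inv_loeuf"]
        c = by_target["circadian"].loc["P", "DUP_target_inv_loeuf"]
        i = by_target["insomnia"].loc["P", "DUP_target_inv_loeuf"]
        assert u == pytest.approx(c + i - overlap_contrib)


class TestCompareGeneSetScores:
    def test_identical_sets_give_p_one(self, toy_genes):
        u, p = cb.compare_gene_set_scores(toy_genes * 2, "circadian", "circadian")
        assert p == pytest.approx(1.0)

    def test_complete_separation_gives_zero_u(self):
        genes = [
            make_gene(f"A{i}", "1", 100 * i + 10, 100 * i + 20, loeuf=v, sets={"circadian"})
            for i, v in enumerate((1.0, 2.0, 3.0))
        ] + [
            make_gene(f"B{i}", "2", 100 * i + 10, 100 * i + 20, loeuf=v, sets={"insomnia"})
            for i, v in enumerate((10.0, 20.0, 30.0))
        ]
        # scale to valid LOEUF range: use ds instead for raw values
        u, _ = cb.compare_gene_set_scores(genes, "circadian", "insomnia", metric="loeuf")
        assert u == 0.0

    def test_shifted_sets_detected(self, genome):
        _, p = cb.compare_gene_set_scores(genome.genes, "insomnia", "other", metric="loeuf")
        assert p < 0.01  # sleep genes simulated as more intolerant

    def test_small_set_rejected(self):
        genes = [make_gene("A", "1", 10, 20, sets={"circadian"})]
        with pytest.raises(InsufficientDataError):
            cb.compare_gene_set_scores(genes, "circadian", "insomnia")
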