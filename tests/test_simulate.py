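"""Synthetic-data generators: determinism, plan fidelity, no-leak."""

import numpy as np
import pandas as pd
import pytest

from dwdfam import (
    CodonPairPlan,
    ExpressionPlan,
    GenomePlan,
    ProteomePlan,
    evolve_codon_pair,
    generate_expression,
    generate_gene_map,
    generate_proteome,
    rank_loci,
    scan_proteome,
)
from dwdfam.errors import InvalidPlanError, PlanInfeasibleError
from dwdfam.kaks import STOP_CODONS


class TestProteome:
    def test_truth_table_counts_forced_by_plan(self):
        plan = ProteomePlan(n_proteins=4, motif_counts={0: 1, 1: 2}, seed=7)
        _, _, truth = generate_proteome(plan)
        assert len(truth) == 3
        per = truth.groupby("protein_id").size()
        assert per["P0001"] == 1 and per["P0002"] == 2

    def test_planted_motifs_lie_inside_wd40_intervals(self):
        plan = ProteomePlan(n_proteins=6, motif_counts={i: 2 for i in range(6)}, seed=1)
        _, domains, truth = generate_proteome(plan)
        for row in truth.itertuples():
            wd = domains[
                (domains["protein_id"] == row.protein_id)
                & (domains["domain_name"] == "WD40")
            ]
            assert ((wd["start"] <= row.start) & (row.end <= wd["end"])).any()

    def test_zero_motif_proteomes_yield_zero_hits_over_many_seeds(self):
        """No-leak: rejection sampling removes every accidental in-repeat match."""
        for seed in range(40):
            proteins, domains, truth = generate_proteome(
                ProteomePlan(n_proteins=6, seed=seed)
            )
            assert truth.empty
            assert scan_proteome(proteins, domains).empty

    def test_byte_identical_under_same_seed(self):
        plan = ProteomePlan(n_proteins=8, motif_counts={0: 1, 5: 3}, seed=99)
        p1, d1, t1 = generate_proteome(plan)
        p2, d2, t2 = generate_proteome(plan)
        assert p1 == p2
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_motif_count_exceeding_guaranteed_repeats_infeasible(self):
        with pytest.raises(PlanInfeasibleError):
            ProteomePlan(motif_counts={0: 3}, wd40_repeats_per_protein=(2, 6)).validate()

    def test_protein_too_short_for_repeats_infeasible(self):
        plan = ProteomePlan(
            n_proteins=2, wd40_repeats_per_protein=(8, 8), protein_length=(100, 150)
        )
        with pytest.raises(PlanInfeasibleError):
            generate_proteome(plan)

    def test_motif_count_out_of_range_invalid(self):
        with pytest.raises(InvalidPlanError):
            ProteomePlan(motif_counts={0: 4}).validate()


class TestGeneMap:
    def test_tandem_pair_occupies_expected_ranks(self):
        plan = GenomePlan(tandem_pairs=[("chr01", 2)], seed=5)
        loci, truth, _ = generate_gene_map(plan)
        ranked = rank_loci(loci).set_index("gene_id")
        a, b = truth.iloc[0][["gene_a", "gene_b"]]
        assert ranked.loc[b, "rank"] - ranked.loc[a, "rank"] == 3

    def test_block_table_lists_each_segmental_pair_once(self):
        plan = GenomePlan(
            segmental_pairs=[("B1", "chr01", "chr02"), ("B2", "chr02", "chr03")],
            seed=2,
        )
        _, truth, blocks = generate_gene_map(plan)
        assert len(blocks) == 2 and blocks["block_id"].is_unique
        seg = truth[truth["class"] == "segmental"]
        assert set(map(frozenset, zip(seg["gene_a"], seg["gene_b"]))) == set(
            map(frozenset, zip(blocks["gene_a"], blocks["gene_b"]))
        )

    def test_empty_plan_yields_empty_truth(self):
        loci, truth, blocks = generate_gene_map(GenomePlan(seed=0))
        assert truth.empty and blocks.empty and len(loci) == 4 * 40

    def test_loci_non_overlapping_and_increasing(self):
        loci, _, _ = generate_gene_map(GenomePlan(seed=3))
        for _, grp in loci.groupby("chromosome"):
            srt = grp.sort_values("start")
            assert (srt["end"] >= srt["start"]).all()
            assert (srt["start"].values[1:] > srt["end"].values[:-1]).all()

    def test_capacity_exceeded_is_infeasible(self):
        plan = GenomePlan(
            n_chromosomes=1,
            genes_per_chromosome=4,
            tandem_pairs=[("chr01", 3), ("chr01", 3)],
        )
        with pytest.raises(PlanInfeasibleError):
            generate_gene_map(plan)

    def test_invalid_intervening_counts_rejected(self):
        with pytest.raises(InvalidPlanError):
            GenomePlan(tandem_pairs=[("chr01", 5)]).validate()
        with pytest.raises(InvalidPlanError):
            GenomePlan(distractor_pairs=[("chr01", 4)]).validate()

    def test_deterministic_under_seed(self):
        plan = GenomePlan(tandem_pairs=[("chr01", 1)], seed=10)
        out1 = generate_gene_map(plan)
        out2 = generate_gene_map(plan)
        for a, b in zip(out1, out2):
            pd.testing.assert_frame_equal(a, b)


class TestCodonPairs:
    def test_zero_rates_give_identical_pair_and_empty_log(self):
        anc, der, log = evolve_codon_pair(CodonPairPlan(n_codons=50, p_syn=0, p_nonsyn=0))
        assert anc == der and log.empty

    def test_pure_synonymous_regime(self):
        _, _, log = evolve_codon_pair(
            CodonPairPlan(n_codons=200, p_syn=0.3, p_nonsyn=0.0, seed=1)
        )
        assert len(log) > 0 and (log["kind"] == "synonymous").all()

    def test_no_internal_stops_and_equal_length(self):
        anc, der, _ = evolve_codon_pair(
            CodonPairPlan(n_codons=150, p_syn=0.3, p_nonsyn=0.3, seed=6)
        )
        assert len(anc) == len(der) == 450
        for cds in (anc, der):
            codons = {cds[i : i + 3] for i in range(0, len(cds), 3)}
            assert not codons & STOP_CODONS

    def test_log_matches_realized_differences(self):
        anc, der, log = evolve_codon_pair(
            CodonPairPlan(n_codons=300, p_syn=0.2, p_nonsyn=0.05, seed=2)
        )
        diffs = sum(a != b for a, b in zip(anc, der))
        assert diffs == len(log)  # each site substituted at most once

    def test_rate_bounds_validated(self):
        with pytest.raises(InvalidPlanError):
            CodonPairPlan(p_syn=0.75).validate()

    def test_deterministic_under_seed(self):
        plan = CodonPairPlan(n_codons=100, seed=3)
        assert evolve_codon_pair(plan)[:2] == evolve_codon_pair(plan)[:2]


class TestExpression:
    def test_noiseless_fold_is_exact(self):
        matrix, truth = generate_expression(
            ExpressionPlan(n_genes=6, specific_genes={5: ("nodule", 50.0)}, noise_cv=0)
        )
        row = matrix.loc["EG0006"]
        assert row["nodule"] / row.drop("nodule").max() == pytest.approx(50.0)
        assert truth.iloc[0].tolist() == ["EG0006", "nodule", 50.0]

    def test_noiseless_baseline_rows_are_flat(self):
        matrix, _ = generate_expression(ExpressionPlan(n_genes=5, noise_cv=0))
        assert (matrix.max(axis=1) / matrix.min(axis=1) == 1.0).all()

    def test_all_values_non_negative(self):
        matrix, _ = generate_expression(ExpressionPlan(n_genes=40, noise_cv=0.8, seed=5))
        assert (matrix.values >= 0).all()

    def test_duplicate_tissues_invalid(self):
        with pytest.raises(InvalidPlanError):
            ExpressionPlan(tissues=("root", "root")).validate()

    def test_deterministic_under_seed(self):
        plan = ExpressionPlan(n_genes=10, noise_cv=0.2, seed=11)
        m1, _ = generate_expression(plan)
        m2, _ = generate_expression(plan)
        pd.testing.assert_frame_equal(m1, m2)
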