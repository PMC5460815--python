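"""Locus ranking, tandem/segmental classification, and alignment identity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwdfam import (
    GenomePlan,
    classify_pairs,
    generate_gene_map,
    global_identity,
    rank_loci,
)
from dwdfam.alignment import nw_align
from dwdfam.errors import ConsistencyError, SequenceError


def loci_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])


class TestRanking:
    def test_ranks_follow_start_order(self):
        loci = loci_frame(
            [("g2", "chr1", 500, 600, "+"), ("g1", "chr1", 100, 200, "+"),
             ("g3", "chr1", 900, 950, "-")]
        )
        ranked = rank_loci(loci).set_index("gene_id")
        assert ranked.loc[["g1", "g2", "g3"], "rank"].tolist() == [1, 2, 3]

    def test_chromosomes_rank_independently(self):
        loci = loci_frame(
            [("a1", "chr1", 100, 200, "+"), ("b1", "chr2", 50, 80, "+"),
             ("a2", "chr1", 300, 400, "+")]
        )
        ranked = rank_loci(loci).set_index("gene_id")
        assert ranked.loc["b1", "rank"] == 1 and ranked.loc["a2", "rank"] == 2

    def test_input_order_is_irrelevant(self):
        rng = np.random.default_rng(0)
        rows = [(f"g{i}", f"chr{i % 3}", 100 * i + 1, 100 * i + 50, "+") for i in range(30)]
        a = rank_loci(loci_frame(rows))
        b = rank_loci(loci_frame([rows[i] for i in rng.permutation(30)]))
        pd.testing.assert_frame_equal(
            a.sort_values("gene_id").reset_index(drop=True),
            b.sort_values("gene_id").reset_index(drop=True),
        )

    def test_duplicate_gene_id_rejected(self):
        loci = loci_frame([("g1", "chr1", 1, 10, "+"), ("g1", "chr1", 20, 30, "+")])
        with pytest.raises(ConsistencyError):
            rank_loci(loci)


class TestClassification:
    @staticmethod
    def simple_genome(n=20):
        return rank_loci(loci_frame(
            [(f"g{i:02d}", "chr1", 100 * i + 1, 100 * i + 50, "+") for i in range(n)]
        ))

    @pytest.mark.parametrize(
        "gap,expected",
        [(0, "tandem"), (2, "tandem"), (4, "tandem"), (5, "unclassified"),
         (6, "unclassified")],
    )
    def test_tandem_rule_is_strictly_less_than_threshold(self, gap, expected):
        ranked = self.simple_genome()
        pairs = pd.DataFrame([("g00", f"g{gap + 1:02d}")], columns=["gene_a", "gene_b"])
        out = classify_pairs(pairs, ranked)
        assert out.loc[0, "class"] == expected
        assert out.loc[0, "intervening_loci"] == gap

    def test_block_pair_is_segmental(self):
        ranked = self.simple_genome()
        pairs = pd.DataFrame([("g00", "g15")], columns=["gene_a", "gene_b"])
        blocks = pd.DataFrame([("B1", "g15", "g00")], columns=["block_id", "gene_a", "gene_b"])
        out = classify_pairs(pairs, ranked, blocks)
        assert out.loc[0, "class"] == "segmental" and out.loc[0, "block_id"] == "B1"

    def test_pair_matching_both_rules_is_tandem_with_flag(self):
        ranked = self.simple_genome()
        pairs = pd.DataFrame([("g00", "g02")], columns=["gene_a", "gene_b"])
        blocks = pd.DataFrame([("B1", "g00", "g02")], columns=["block_id", "gene_a", "gene_b"])
        out = classify_pairs(pairs, ranked, blocks)
        assert out.loc[0, "class"] == "tandem" and bool(out.loc[0, "also_on_block"])

    def test_missing_gene_is_a_consistency_error(self):
        ranked = self.simple_genome()
        pairs = pd.DataFrame([("g00", "missing")], columns=["gene_a", "gene_b"])
        with pytest.raises(ConsistencyError):
            classify_pairs(pairs, ranked)

    def test_synthetic_genome_classified_to_truth(self):
        plan = GenomePlan(
            n_chromosomes=6,
            genes_per_chromosome=30,
            tandem_pairs=[("chr01", 0), ("chr02", 2), ("chr03", 4)],
            segmental_pairs=[
                (f"B{k}", f"chr{1 + k % 5:02d}", f"chr{1 + (k + 2) % 5:02d}")
                for k in range(10)
            ],
            distractor_pairs=[("chr06", 7), ("chr06", 10)],
            seed=11,
        )
        loci, truth, blocks = generate_gene_map(plan)
        out = classify_pairs(truth[["gene_a", "gene_b"]], rank_loci(loci), blocks)
        assert list(out["class"]) == list(truth["class"])


class TestIdentity:
    def test_identical_sequences_are_100_percent(self):
        ident, cols = global_identity("ACDEFGHIK", "ACDEFGHIK")
        assert ident == 100.0 and cols == 9

    def test_single_terminal_mismatch(self):
        assert global_identity("ACDE", "ACDF")[0] == 75.0

    def test_gap_columns_lower_identity_by_default(self):
        ident, cols = global_identity("ACDE", "ACDEFG")
        assert cols == 6 and ident == pytest.approx(100 * 4 / 6)
        ident_ungapped, _ = global_identity("ACDE", "ACDEFG", count_gap_columns=False)
        assert ident_ungapped == 100.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(SequenceError):
            global_identity("", "ACDE")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACDEFG", min_size=1, max_size=50),
        st.text(alphabet="ACDEFG", min_size=1, max_size=50),
    )
    def test_symmetry_and_bounds(self, a, b):
        ia, ca = global_identity(a, b)
        ib, cb = global_identity(b, a)
        assert ia == ib and ca == cb
        assert 0.0 <= ia <= 100.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACDEF", min_size=1, max_size=50),
        st.text(alphabet="ACDEF", min_size=1, max_size=50),
    )
    def test_alignment_equals_reference_dp(self, a, b):
        """Independent O(nm) reference DP with the documented tie-break."""
        ali_a, ali_b, score = nw_align(a, b)
        ref_a, ref_b, ref_score = _reference_dp(a.upper(), b.upper())
        assert score == pytest.approx(ref_score)
        assert (ali_a, ali_b) == (ref_a, ref_b)


def _reference_dp(a, b, match=1.0, mismatch=0.0, gap=1.0):
    """Plain dictionary-based global alignment DP (no numpy), tie-break
    diagonal > gap-in-b > gap-in-a, written independently of the package."""
    table = {(0, 0): 0.0}
    for i in range(1, len(a) + 1):
        table[(i, 0)] = -gap * i
    for j in range(1, len(b) + 1):
        table[(0, j)] = -gap * j
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            diag = table[(i - 1, j - 1)] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = table[(i - 1, j)] - gap
            left = table[(i, j - 1)] - gap
            table[(i, j)] = max(diag, up, left)
    i, j = len(a), len(b)
    ra, rb = [], []
    while i > 0 or j > 0:
        score = table[(i, j)]
        diag = (
            table[(i - 1, j - 1)] + (match if a[i - 1] == b[j - 1] else mismatch)
            if i and j
            else None
        )
        if i and j and abs(score - diag) < 1e-9:
            ra.append(a[i - 1]); rb.append(b[j - 1]); i, j = i - 1, j - 1
        elif i and abs(score - (table[(i - 1, j)] - gap)) < 1e-9:
            ra.append(a[i - 1]); rb.append("-"); i -= 1
        else:
            ra.append("-"); rb.append(b[j - 1]); j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb)), table[(len(a), len(b))]
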