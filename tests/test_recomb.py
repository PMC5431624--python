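"""Clonality statistics: mismatch distances, I_A/rbar_d, permutation nulls,
phylogenetic compatibility (vs a brute-force marked-box oracle), clone
correction, and sites-as-loci conversion."""

from collections import Counter, defaultdict

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitohet.recomb import (
    clone_correct,
    compatibility_matrix,
    ia_rbard,
    ia_test,
    incompatibility_test,
    mismatch_distance,
    pairwise_compatible,
    pcp,
    permute_matrix,
    recomb_report,
    sites_to_loci,
)
from mitohet.simulate import LocusSpec, SimConfig, simulate_genotype_matrix

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracle: the marked-box path search
# ---------------------------------------------------------------------------

def marked_box_incompatible(combos):
    """Brute-force version of the printed-matrix rule: mark every observed
    allele combination in a rectangular table; two loci are incompatible iff
    one can leave a marked box and return to it by alternating horizontal and
    vertical moves through marked boxes (never re-entering the box just left,
    which alternation enforces automatically)."""
    boxes = sorted(set(combos))
    by_row, by_col = defaultdict(list), defaultdict(list)
    for box in boxes:
        by_row[box[0]].append(box)
        by_col[box[1]].append(box)
    for start in boxes:
        for first_dir in ("h", "v"):
            seen = set()
            stack = [(start, first_dir)]
            while stack:
                box, direction = stack.pop()
                pool = by_row[box[0]] if direction == "h" else by_col[box[1]]
                for nxt in pool:
                    if nxt == box:
                        continue
                    if nxt == start:
                        return True
                    state = (nxt, "v" if direction == "h" else "h")
                    if state not in seen:
                        seen.add(state)
                        stack.append(state)
    return False


def random_two_locus_matrix(rng, max_alleles=5, max_isolates=30):
    n = int(rng.integers(2, max_isolates + 1))
    a_labels = [f"a{i}" for i in range(int(rng.integers(1, max_alleles + 1)))]
    b_labels = [f"b{i}" for i in range(int(rng.integers(1, max_alleles + 1)))]
    rows = [(a_labels[rng.integers(len(a_labels))], b_labels[rng.integers(len(b_labels))])
            for _ in range(n)]
    return make_matrix(rows, ["L1", "L2"]), rows


class TestMismatchDistance:
    def test_identical_rows(self):
        assert mismatch_distance(("A", "B"), ("A", "B")) == 0

    def test_fully_different_rows(self):
        assert mismatch_distance(("A", "B"), ("a", "b")) == 2

    def test_partial_difference_and_missing(self):
        assert mismatch_distance(("A", "B"), ("a", "B")) == 1
        assert mismatch_distance(("A", None), ("a", "B")) == 1

    def test_disjoint_coverage_is_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="no typed locus"):
            assert mismatch_distance(("A", None), (None, "B")) is None


class TestIaRbard:
    def test_two_founder_hand_computation(self, two_founder_matrix):
        result = ia_rbard(two_founder_matrix)
        assert result.v_o == pytest.approx(8 / 9)
        assert result.v_e == pytest.approx(4 / 9)
        assert result.ia == pytest.approx(1.0)
        assert result.rbard == pytest.approx(1.0)

    def test_single_locus_ia_is_zero(self):
        matrix = make_matrix([("A",), ("A",), ("a",), ("a",)], ["L1"])
        result = ia_rbard(matrix)
        assert result.ia == pytest.approx(0.0)

    def test_monomorphic_matrix_is_flagged_undefined(self):
        matrix = make_matrix([("A", "B")] * 4, ["L1", "L2"])
        assert not ia_rbard(matrix).defined

    def test_invariant_to_allele_relabeling_and_row_order(self, two_founder_matrix):
        relabeled = make_matrix(
            [("x", "y"), ("x", "y"), ("q", "r"), ("q", "r")], ["L1", "L2"]
        )
        shuffled = make_matrix(
            [("a", "b"), ("A", "B"), ("a", "b"), ("A", "B")], ["L1", "L2"]
        )
        base = ia_rbard(two_founder_matrix)
        for other in (relabeled, shuffled):
            result = ia_rbard(other)
            assert result.ia == pytest.approx(base.ia)
            assert result.rbard == pytest.approx(base.rbard)

    def test_single_isolate_is_an_error(self):
        with pytest.raises(ValueError, match="two isolates"):
            ia_rbard(make_matrix([("A", "B")], ["L1", "L2"]))

    @given(data=st.data())
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_rbard_bounded_on_random_matrices(self, data):
        n = data.draw(st.integers(3, 12))
        n_loci = data.draw(st.integers(2, 4))
        rows = data.draw(
            st.lists(
                st.tuples(*[st.sampled_from("abc") for _ in range(n_loci)]),
                min_size=n, max_size=n,
            )
        )
        result = ia_rbard(make_matrix(rows, [f"L{j}" for j in range(n_loci)]))
        if result.defined and not np.isnan(result.rbard):
            assert -1.0 - 1e-9 <= result.rbard <= 1.0 + 1e-9


class TestPermutation:
    def test_columns_keep_their_allele_multisets(self, two_founder_matrix):
        permuted = permute_matrix(two_founder_matrix, seed=3)
        for locus in two_founder_matrix.loci:
            assert Counter(permuted.data[locus]) == Counter(two_founder_matrix.data[locus])

    def test_missing_cells_stay_in_place(self):
        matrix = make_matrix([("A", None), ("a", "B"), ("A", "b")], ["L1", "L2"])
        permuted = permute_matrix(matrix, seed=0)
        assert permuted.data.at["i1", "L2"] is None

    def test_single_isolate_matrix_is_unchanged(self):
        matrix = make_matrix([("A", "B")], ["L1", "L2"])
        assert permute_matrix(matrix, seed=1).data.equals(matrix.data)

    def test_clonal_matrix_has_extreme_observed_ia(self):
        rows = [("A", "B", "C")] * 10 + [("a", "b", "c")] * 10
        matrix = make_matrix(rows, ["L1", "L2", "L3"])
        test = ia_test(matrix, n_perm=500, seed=7)
        assert test.p_value <= 0.01
        assert abs(test.null_mean) < 0.2  # permuted datasets look recombining

    def test_zero_permutations_is_an_error(self, two_founder_matrix):
        with pytest.raises(ValueError, match="n_perm"):
            ia_test(two_founder_matrix, n_perm=0)


class TestCompatibility:
    def test_three_gametes_are_compatible(self):
        matrix = make_matrix([("A", "B"), ("A", "b"), ("a", "B")], ["L1", "L2"])
        assert pairwise_compatible(matrix, "L1", "L2")

    def test_four_gametes_are_incompatible(self):
        matrix = make_matrix(
            [("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")], ["L1", "L2"]
        )
        assert not pairwise_compatible(matrix, "L1", "L2")

    def test_multiallelic_six_cycle_matches_oracle(self):
        combos = [("1", "x"), ("2", "x"), ("2", "y"), ("3", "y"), ("3", "z"), ("1", "z")]
        matrix = make_matrix(combos, ["L1", "L2"])
        assert marked_box_incompatible(combos)
        assert not pairwise_compatible(matrix, "L1", "L2")

    def test_forest_test_agrees_with_marked_box_oracle(self):
        rng = np.random.default_rng(12345)
        for _ in range(400):
            matrix, rows = random_two_locus_matrix(rng)
            assert pairwise_compatible(matrix, "L1", "L2") == (
                not marked_box_incompatible(rows)
            )

    def test_pcp_trivial_cases(self):
        mono = make_matrix([("A", "B")] * 3, ["L1", "L2"])
        assert pcp(mono) == 1.0
        four = make_matrix([("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")], ["L1", "L2"])
        assert pcp(four) == 0.0

    def test_pcp_on_fully_compatible_site_matrix(self):
        # tree-like alignment: every site pair compatible, as seen intra-genically
        alignment = {
            "s1": "AAAA", "s2": "GAAA", "s3": "GTAA", "s4": "GTCA", "s5": "GTCT",
        }
        matrix = sites_to_loci(alignment)
        assert matrix.n_loci == 4
        assert pcp(matrix) == 1.0


class TestIncompatibilityTest:
    def test_clonal_data_show_fewer_incompatibilities_than_null(self):
        cfg = SimConfig(
            n_isolates=40,
            loci=[LocusSpec(f"L{j}", ("a", "b", "c"), (0.4, 0.35, 0.25)) for j in range(4)],
            mode="clonal", n_founders=3, seed=41,
        )
        matrix = simulate_genotype_matrix(cfg)
        result = incompatibility_test(matrix, n_perm=200, seed=42)
        assert result.observed_count == 0  # three clones cannot cycle
        assert result.p_value < 0.05
        assert result.null_mean > result.observed_count

    def test_panmictic_data_are_not_flagged(self):
        cfg = SimConfig(
            n_isolates=60,
            loci=[LocusSpec(f"L{j}", ("a", "b"), (0.5, 0.5)) for j in range(3)],
            mode="panmictic", seed=43,
        )
        result = incompatibility_test(simulate_genotype_matrix(cfg), n_perm=200, seed=44)
        assert result.p_value > 0.05

    def test_zero_permutations_is_an_error(self, two_founder_matrix):
        with pytest.raises(ValueError, match="n_perm"):
            incompatibility_test(two_founder_matrix, n_perm=0)


class TestCloneCorrection:
    def test_unique_rows_unchanged(self, two_founder_matrix):
        pass_through = clone_correct(
            make_matrix([("A", "B"), ("a", "b"), ("A", "b")], ["L1", "L2"])
        )
        assert pass_through.n_isolates == 3

    def test_replicated_genotype_collapses_to_one_row(self):
        matrix = make_matrix([("A", "B")] * 10, ["L1", "L2"])
        corrected = clone_correct(matrix)
        assert corrected.n_isolates == 1
        assert corrected.isolates == ["i1"]

    def test_sample_collapses_to_distinct_genotype_count(self):
        # 299 isolates carrying 32 distinct multilocus genotypes
        rng = np.random.default_rng(99)
        distinct = [(f"a{k}", f"b{k % 8}") for k in range(32)]
        rows = [distinct[k] for k in range(32)]
        rows += [distinct[rng.integers(32)] for _ in range(299 - 32)]
        corrected = clone_correct(make_matrix(rows, ["L1", "L2"]))
        assert corrected.n_isolates == 32

    def test_idempotent(self):
        matrix = make_matrix([("A", "B")] * 5 + [("a", "b")] * 5, ["L1", "L2"])
        once = clone_correct(matrix)
        twice = clone_correct(once)
        assert once.data.equals(twice.data)


class TestSitesToLoci:
    def test_polymorphic_sites_become_loci(self):
        # five sequence types over four polymorphic sites
        alignment = {
            "s1": "AACGTA", "s2": "AACGTA", "s3": "ATCGTA",
            "s4": "ATCGAA", "s5": "ATCCAA", "s6": "TTCCAA",
        }
        matrix = sites_to_loci(alignment)
        assert matrix.n_loci == 4
        assert matrix.loci == ["site1", "site2", "site4", "site5"]

    def test_monomorphic_alignment_is_empty(self):
        assert sites_to_loci({"a": "ACGT", "b": "ACGT"}).n_loci == 0

    def test_column_allele_counts_match_base_counts(self):
        alignment = {"a": "AG", "b": "AG", "c": "TG", "d": "TC"}
        matrix = sites_to_loci(alignment)
        assert Counter(matrix.data["site1"]) == Counter({"A": 2, "T": 2})
        assert Counter(matrix.data["site2"]) == Counter({"G": 3, "C": 1})

    def test_ambiguity_codes_are_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            sites_to_loci({"a": "ARGT", "b": "AAGT"})


class TestRecombReport:
    def test_power_grows_with_clonal_fraction(self):
        """Mean permutation p-value of I_A falls as clonality rises."""
        loci = [LocusSpec(f"L{j}", ("a", "b"), (0.5, 0.5)) for j in range(3)]
        mean_p = []
        for fraction in (0.0, 0.25, 1.0):
            ps = []
            for rep in range(10):
                cfg = SimConfig(
                    n_isolates=40, loci=loci, mode="mixed",
                    clonal_fraction=fraction, n_founders=2, seed=1000 + rep,
                    founders=[("a", "a", "a"), ("b", "b", "b")],
                )
                matrix = simulate_genotype_matrix(cfg)
                ps.append(ia_test(matrix, n_perm=100, seed=rep).p_value)
            mean_p.append(float(np.mean(ps)))
        assert mean_p[0] > mean_p[2]
        assert mean_p[0] >= mean_p[1] >= mean_p[2]

    def test_full_report_fields(self, two_founder_matrix):
        report = recomb_report(two_founder_matrix, n_perm=100, seed=1)
        payload = report.to_dict()
        assert payload["IA"] == pytest.approx(1.0)
        assert payload["PcP"] == 1.0  # only 3 of 4 gametes observed
        assert 0 < payload["p_IA"] <= 1
        assert compatibility_matrix(two_founder_matrix).all().all()
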