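"""Ortholog set algebra: Venn/core/pangenome partitions, expansions, features."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cosymbio.display import (
    floor_percent,
    percent_half_up,
    percent_one_decimal_capped,
)
from cosymbio.errors import EmptyInputError, UsageError, ValidationError
from cosymbio.ortholog_sets import (
    MembershipMatrix,
    TaxonMeta,
    build_membership,
    core_sets,
    expansion_profile,
    functional_breakdown,
    genome_feature_table,
    merged_interval_length,
    pangenome_overlap,
    pathway_completeness,
    venn_trio,
)
from cosymbio.types import ClusterTable, GeneRecord, GenomeBundle

TAXA5 = ["t1", "t2", "t3", "t4", "t5"]


def matrix_from_counts(rows, taxa=None, sizes=None):
    """Build a MembershipMatrix from a list of per-taxon count tuples."""
    import pandas as pd

    taxa = taxa or TAXA5[: len(rows[0])]
    frame = pd.DataFrame(rows, columns=taxa, index=[f"c{i}" for i in range(len(rows))])
    meta = {
        t: TaxonMeta(genome_size_bp=(sizes or {}).get(t, 1_000_000)) for t in taxa
    }
    return MembershipMatrix(counts=frame, taxa_meta=meta)


# ---------------------------------------------------------------------------
# Membership


class TestBuildMembership:
    def test_counts_exact(self):
        table = ClusterTable([("c1", {"A": ["g1", "g2"], "B": ["g3"]})]).validate()
        m = build_membership(table, {"A": TaxonMeta(1), "B": TaxonMeta(1)})
        assert m.counts.loc["c1", "A"] == 2 and m.counts.loc["c1", "B"] == 1

    def test_unknown_taxon_error(self):
        table = ClusterTable([("c1", {"A": ["g1"]})]).validate()
        with pytest.raises(ValidationError):
            build_membership(table, {"B": TaxonMeta(1)})

    def test_ignore_mode_drops_empty_clusters(self):
        table = ClusterTable([("c1", {"A": ["g1"]})]).validate()
        m = build_membership(table, {"B": TaxonMeta(1)}, on_unknown="ignore")
        assert m.counts.empty

    def test_column_sums_match_brute_force_recount(self):
        rng = np.random.default_rng(0)
        clusters = []
        gene_id = itertools.count()
        for i in range(10):
            members = {}
            for t in ("A", "B", "C"):
                n = int(rng.integers(0, 4))
                if n:
                    members[t] = [f"g{next(gene_id)}" for _ in range(n)]
            if members:
                clusters.append((f"c{i}", members))
        table = ClusterTable(clusters).validate()
        m = build_membership(table, {t: TaxonMeta(1) for t in "ABC"})
        for t in "ABC":
            brute = sum(len(members.get(t, [])) for _, members in clusters)
            assert int(m.counts[t].sum()) == brute


# ---------------------------------------------------------------------------
# Venn


class TestVenn:
    def test_hand_enumerated_example(self):
        m = matrix_from_counts(
            [(1, 1, 1)] * 2 + [(1, 1, 0)] * 3 + [(0, 0, 1)], taxa=["A", "B", "C"]
        )
        v = venn_trio(m, "A", "B", "C")
        assert (v.only_c, v.ab, v.abc) == (1, 3, 2)
        assert v.only_a == v.only_b == v.ac == v.bc == 0

    def test_all_shared(self):
        m = matrix_from_counts([(2, 1, 3)] * 4, taxa=["A", "B", "C"])
        v = venn_trio(m, "A", "B", "C")
        assert v.abc == 4 and v.total == 4

    def test_disjoint_singletons(self):
        m = matrix_from_counts([(1, 0, 0), (0, 1, 0), (0, 0, 1)], taxa=["A", "B", "C"])
        v = venn_trio(m, "A", "B", "C")
        assert (v.only_a, v.only_b, v.only_c, v.abc) == (1, 1, 1, 0)

    def test_duplicate_taxon_rejected(self):
        m = matrix_from_counts([(1, 1, 1)], taxa=["A", "B", "C"])
        with pytest.raises(UsageError):
            venn_trio(m, "A", "A", "B")

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        rows=st.lists(
            st.tuples(*[st.integers(0, 3)] * 5).filter(lambda r: sum(r) > 0),
            min_size=1, max_size=20,
        )
    )
    def test_cells_sum_to_touching_clusters(self, rows):
        m = matrix_from_counts(rows)
        v = venn_trio(m, "t1", "t2", "t3")
        touching = sum(1 for r in rows if r[0] or r[1] or r[2])
        assert v.total == touching


# ---------------------------------------------------------------------------
# Core sets & pangenome


class TestCoreSets:
    def test_planted_universal_and_ingroup_core(self):
        rows = (
            [(1, 1, 1, 1, 1)] * 5      # universal
            + [(1, 1, 1, 0, 0)] * 2    # ingroup-specific core
            + [(1, 0, 0, 0, 1)] * 3    # neither
        )
        m = matrix_from_counts(rows)
        rep = core_sets(m, ["t1", "t2", "t3"], ["t4", "t5"])
        assert (rep.n_universal, rep.n_ingroup) == (5, 2)

    def test_partial_outgroup_presence_default_vs_strict(self):
        # present in all ingroup, one of two outgroups
        m = matrix_from_counts([(1, 1, 1, 1, 0)])
        default = core_sets(m, ["t1", "t2", "t3"], ["t4", "t5"])
        strict = core_sets(m, ["t1", "t2", "t3"], ["t4", "t5"], strict=True)
        assert default.n_ingroup == 1  # absent from >= 1 outgroup
        assert strict.n_ingroup == 0   # not absent from all

    def test_overlapping_groups_rejected(self):
        m = matrix_from_counts([(1, 1, 1, 1, 1)])
        with pytest.raises(UsageError):
            core_sets(m, ["t1"], ["t1", "t2"])

    def test_empty_outgroup_rejected(self):
        m = matrix_from_counts([(1, 1, 1, 1, 1)])
        with pytest.raises(UsageError):
            core_sets(m, ["t1"], [])

    def test_outgroup_everywhere_gives_zero_ingroup_core(self):
        m = matrix_from_counts([(1, 1, 1, 1, 1)] * 4)
        rep = core_sets(m, ["t1", "t2", "t3"], ["t4", "t5"])
        assert rep.n_ingroup == 0 and rep.n_universal == 4

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        rows=st.lists(
            st.tuples(*[st.integers(0, 2)] * 5).filter(lambda r: sum(r) > 0),
            min_size=1, max_size=25,
        )
    )
    def test_brute_force_equivalence_random_matrices(self, rows):
        m = matrix_from_counts(rows)
        ingroup, outgroups = ["t1", "t2", "t3"], ["t4", "t5"]
        rep = core_sets(m, ingroup, outgroups)
        pan = pangenome_overlap(m, ingroup, outgroups)
        # independent brute-force recount straight off the tuples
        uni = sum(1 for r in rows if all(r[i] for i in range(5)))
        ing = sum(
            1 for r in rows if all(r[i] for i in range(3)) and not (r[3] and r[4])
        )
        g1 = sum(1 for r in rows if any(r[:3]) and not any(r[3:]))
        g2 = sum(1 for r in rows if not any(r[:3]) and any(r[3:]))
        both = sum(1 for r in rows if any(r[:3]) and any(r[3:]))
        assert (rep.n_universal, rep.n_ingroup) == (uni, ing)
        assert (pan.n_group1_only, pan.n_group2_only, pan.n_both) == (g1, g2, both)


# ---------------------------------------------------------------------------
# Percent display conventions


class TestPercentDisplay:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(123, 127, 96), (62, 127, 48), (0, 10, 0), (10, 10, 100)],
    )
    def test_floor_percent(self, num, den, expected):
        assert floor_percent(num, den) == expected

    @pytest.mark.parametrize(
        "num,den,expected",
        [(178, 7175, 2.5), (41, 52, 78.8), (350, 361, 96.9), (11, 361, 3.0),
         (1, 1, 100.0)],
    )
    def test_one_decimal_capped(self, num, den, expected):
        assert percent_one_decimal_capped(num, den) == expected

    @pytest.mark.parametrize(
        "num,den,decimals,expected",
        [(40, 154, 0, 26), (23, 154, 1, 14.9), (7, 154, 1, 4.5)],
    )
    def test_half_up(self, num, den, decimals, expected):
        assert percent_half_up(num, den, decimals) == expected


class TestPangenomePercents:
    def test_small_overlap(self):
        m = matrix_from_counts(
            [(1, 0, 0, 0, 0)] * 2 + [(0, 0, 0, 0, 1)] * 5 + [(1, 0, 0, 0, 1)] * 3
        )
        pan = pangenome_overlap(m, ["t1", "t2", "t3"], ["t4", "t5"])
        assert (pan.n_group1_only, pan.n_group2_only, pan.n_both) == (2, 5, 3)
        assert pan.percent_group1_only == 20.0

    def test_no_exclusive_clusters(self):
        m = matrix_from_counts([(1, 0, 0, 0, 1)] * 4)
        pan = pangenome_overlap(m, ["t1", "t2", "t3"], ["t4", "t5"])
        assert pan.percent_group1_only == 0.0 and pan.percent_group2_only == 0.0


# ---------------------------------------------------------------------------
# Functional breakdown


def breakdown_fixture(counts):
    """counts: {category: n_clusters}; single-gene clusters in taxon A."""
    clusters, categories = [], {}
    i = 0
    for cat, n in counts.items():
        for _ in range(n):
            gid = f"g{i}"
            clusters.append((f"c{i}", {"A": [gid]}))
            categories[("A", gid)] = cat
            i += 1
    return ClusterTable(clusters).validate(), categories


class TestFunctionalBreakdown:
    def test_printed_core_set_percents(self):
        table, cats = breakdown_fixture(
            {
                "unknown_function": 40,
                "general_prediction_only": 23,
                "transposase": 7,
                "known_function": 84,
            }
        )
        out = functional_breakdown(table.cluster_ids, table, cats)
        assert out.n_total == 154
        assert out.percents["unknown_function"] == 26
        assert out.percents["general_prediction_only"] == 14.9
        assert out.percents["transposase"] == 4.5

    def test_single_category(self):
        table, cats = breakdown_fixture({"transposase": 3})
        out = functional_breakdown(table.cluster_ids, table, cats)
        assert out.percents == {"transposase": 100}

    def test_majority_vote_and_tie(self):
        table = ClusterTable(
            [("c1", {"A": ["g1", "g2", "g3"]}), ("c2", {"A": ["g4"], "B": ["g5"]})]
        ).validate()
        cats = {
            ("A", "g1"): "transposase",
            ("A", "g2"): "transposase",
            ("A", "g3"): "known_function",
            ("A", "g4"): "known_function",
            ("B", "g5"): "transposase",  # tie in c2
        }
        out = functional_breakdown(["c1", "c2"], table, cats)
        assert out.counts == {"transposase": 1, "unknown_function": 1}

    def test_empty_input(self):
        table, cats = breakdown_fixture({"transposase": 1})
        with pytest.raises(EmptyInputError):
            functional_breakdown([], table, cats)


# ---------------------------------------------------------------------------
# Expansion profile


class TestExpansion:
    def test_min_copies_filter_and_normalisation(self):
        m = matrix_from_counts(
            [(24, 1, 1), (2, 1, 0), (10, 0, 0)],
            taxa=["A", "B", "C"],
            sizes={"A": 2_000_000, "B": 1_000_000, "C": 1_000_000},
        )
        table = expansion_profile(m, min_copies=3)
        assert list(table.included.index) == ["c0", "c2"]
        assert table.frame.loc["c2", "per_mbp:A"] == pytest.approx(5.0)
        # normalisation inverts exactly
        assert (
            table.frame.loc["c0", "per_mbp:A"] * 2_000_000 / 1e6
        ) == pytest.approx(24)

    def test_sorted_by_descending_max_copies(self):
        m = matrix_from_counts([(3, 0, 0), (7, 0, 0), (5, 0, 0)], taxa=["A", "B", "C"])
        table = expansion_profile(m)
        assert list(table.frame["max_copies"]) == [7, 5, 3]

    def test_input_order_invariance(self):
        rows = [(4, 1, 0), (1, 6, 1), (2, 2, 2)]
        a = expansion_profile(matrix_from_counts(rows, taxa=["A", "B", "C"]))
        b = expansion_profile(matrix_from_counts(rows[::-1], taxa=["A", "B", "C"]))
        assert sorted(a.frame["max_copies"]) == sorted(b.frame["max_copies"])

    def test_bad_min_copies(self):
        m = matrix_from_counts([(1, 1, 1)], taxa=["A", "B", "C"])
        with pytest.raises(UsageError):
            expansion_profile(m, min_copies=0)


# ---------------------------------------------------------------------------
# Pathways


class TestPathways:
    def test_partial_and_complete(self):
        out = pathway_completeness(
            {"A": {"metB"}, "B": {"metA", "metB", "metC"}},
            {"met": {"metA", "metB", "metC"}},
        )
        frame = out.frame.set_index("taxon")
        assert frame.loc["A", "completeness"] == pytest.approx(1 / 3)
        assert frame.loc["A", "status"] == "partial"
        assert frame.loc["B", "status"] == "complete"

    def test_brute_force_recount(self):
        rng = np.random.default_rng(1)
        genes = [f"k{i}" for i in range(20)]
        presence = {
            t: {g for g in genes if rng.random() < 0.5} for t in ("A", "B", "C")
        }
        defs = {"p1": set(genes[:7]), "p2": set(genes[5:17])}
        out = pathway_completeness(presence, defs)
        for _, row in out.frame.iterrows():
            expect = len(defs[row.pathway_id] & presence[row.taxon])
            assert row.n_present == expect

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValidationError):
            pathway_completeness({"A": set()}, {"p": set()})


# ---------------------------------------------------------------------------
# Genome features


class TestGenomeFeatures:
    def test_single_gene_full_coverage(self):
        bundle = GenomeBundle(
            "T", [("s1", "ATGC")], [GeneRecord("g1", "s1", 1, 4)]
        ).validate()
        frame = genome_feature_table([bundle], {"T": ["g1"]})
        assert frame.loc["T", "gc_percent"] == pytest.approx(50.0)
        assert frame.loc["T", "coding_fraction"] == pytest.approx(1.0)
        assert frame.loc["T", "ortholog_length_sum"] == 4

    def test_overlapping_genes_merged(self):
        bundle = GenomeBundle(
            "T",
            [("s1", "A" * 100)],
            [GeneRecord("g1", "s1", 10, 20), GeneRecord("g2", "s1", 15, 30)],
        ).validate()
        frame = genome_feature_table([bundle], {})
        assert frame.loc["T", "coding_fraction"] == pytest.approx(0.21)

    def test_no_genes(self):
        bundle = GenomeBundle("T", [("s1", "ACGT" * 10)], []).validate()
        frame = genome_feature_table([bundle], {})
        assert frame.loc["T", "coding_fraction"] == 0.0

    def test_ambiguity_codes_excluded_from_gc(self):
        bundle = GenomeBundle("T", [("s1", "GCNNNN")], []).validate()
        frame = genome_feature_table([bundle], {})
        assert frame.loc["T", "gc_percent"] == pytest.approx(100.0)

    def test_missing_designated_gene(self):
        bundle = GenomeBundle("T", [("s1", "ACGT")], []).validate()
        with pytest.raises(ValidationError):
            genome_feature_table([bundle], {"T": ["absent"]})

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        intervals=st.lists(
            st.tuples(st.integers(1, 50), st.integers(0, 20)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            min_size=1, max_size=10,
        )
    )
    def test_interval_union_against_set_oracle(self, intervals):
        covered = set()
        for start, end in intervals:
            covered.update(range(start, end + 1))
        assert merged_interval_length(intervals) == len(covered)
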