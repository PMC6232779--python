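"""HGT candidate identification, rule-based classification, box statistics."""

import numpy as np
import pytest

from conftest import tiny_pangenome_config
from cosymbio.errors import UsageError, ValidationError
from cosymbio.hgt_classifier import (
    ClassifierOptions,
    ExpectedLineage,
    HgtCandidate,
    box_stats,
    classify_candidate,
    drop_self_hits,
    evaluate_tree_concordance,
    identify_candidates,
    run_hgt_analysis,
)
from cosymbio.ortholog_sets import TaxonMeta, build_membership
from cosymbio.synthetic_data import SELF_LINEAGE, generate
from cosymbio.types import ClusterTable, GeneRecord, HitRecord, Lineage

BACTEROIDETES = Lineage("Bacteria", "Bacteroidetes", "Cytophagia", "Cytophagales",
                        "Cytophagaceae", "Cytophaga")
CARDINIUM = SELF_LINEAGE
GAMMA = Lineage("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                "Enterobacterales", "Yersiniaceae", "Regiella")
NEMATODA = Lineage("Eukaryota", "Nematoda", "Chromadorea", "Rhabditida",
                   "Pratylenchidae", "Pratylenchus")

EXPECTED = ExpectedLineage(lineage=CARDINIUM)


def hit(subject, lineage, score, query="gene1"):
    return HitRecord(query, subject, 50.0, 200, float(score), 1e-20, lineage)


def candidate(gene_id="gene1", flanks=("f1", "f2")):
    return HgtCandidate(gene_id, "foc", list(flanks), "no_outgroup_ortholog")


def self_flanks(score=150):
    return {
        "f1": [hit("Cyt_1", BACTEROIDETES, score, query="f1")],
        "f2": [hit("Cyt_2", BACTEROIDETES, score - 5, query="f2")],
    }


# ---------------------------------------------------------------------------
# Candidate identification


class TestIdentifyCandidates:
    def setup_method(self):
        self.table = ClusterTable(
            [
                ("c1", {"foc": ["g1"], "out": ["o1"]}),   # shared with outgroup
                ("c2", {"foc": ["g2"], "inA": ["i1"]}),   # ingroup-only
            ]
        ).validate()
        self.matrix = build_membership(
            self.table, {t: TaxonMeta(1) for t in ("foc", "inA", "out")}
        )
        self.genes = [
            GeneRecord(f"g{i}", "sc1", i * 1000, i * 1000 + 500) for i in range(1, 6)
        ]
        self.g2c = {"g1": "c1", "g2": "c2"}

    def test_outgroup_ortholog_not_candidate(self):
        cands = identify_candidates(
            self.matrix, self.genes, "foc", ["out"], gene_to_cluster=self.g2c
        )
        ids = {c.gene_id for c in cands}
        assert "g1" not in ids

    def test_singletons_and_ingroup_only_are_candidates(self):
        cands = identify_candidates(
            self.matrix, self.genes, "foc", ["out"], gene_to_cluster=self.g2c
        )
        by_id = {c.gene_id: c for c in cands}
        assert by_id["g2"].reason == "no_outgroup_ortholog"
        assert by_id["g3"].reason == "singleton"

    def test_scaffold_edge_truncates_flanks(self):
        cands = identify_candidates(
            self.matrix, self.genes, "foc", ["out"],
            flank_size=2, gene_to_cluster=self.g2c,
        )
        by_id = {c.gene_id: c for c in cands}
        assert by_id["g2"].flanking_gene_ids == ["g1", "g3", "g4"]  # one upstream only

    def test_unknown_focal_taxon(self):
        with pytest.raises(UsageError):
            identify_candidates(self.matrix, self.genes, "nope", ["out"])

    def test_drop_self_hits(self):
        hits = [hit("foc_g9", CARDINIUM, 500), hit("Cyt_1", BACTEROIDETES, 100)]
        assert [h.subject_id for h in drop_self_hits(hits, "foc")] == ["Cyt_1"]


# ---------------------------------------------------------------------------
# Classification rules


class TestClassifyRules:
    def test_all_self_phylum_is_non_hgt(self):
        gene_hits = [hit(f"Cyt_{i}", BACTEROIDETES, 150 - i) for i in range(10)]
        call = classify_candidate(candidate(), gene_hits, self_flanks(), EXPECTED)
        assert call.category == "non_hgt"

    def test_donor_top_with_self_flanks_is_recent(self):
        gene_hits = [hit(f"Reg_{i}", GAMMA, 250 - i) for i in range(5)] + [
            hit("Cyt_9", BACTEROIDETES, 140)
        ]
        call = classify_candidate(candidate(), gene_hits, self_flanks(), EXPECTED)
        assert call.category == "recent_hgt"
        assert call.donor_guess is not None and call.donor_guess[1] == "Regiella"
        assert call.bitscore_ratio == pytest.approx(250 / 147.5)

    def test_self_genus_top_then_donor_hits_is_older(self):
        gene_hits = [hit("Card_1", CARDINIUM, 300)] + [
            hit(f"Nem_{i}", NEMATODA, 250 - i) for i in range(8)
        ]
        call = classify_candidate(candidate(), gene_hits, self_flanks(), EXPECTED)
        assert call.category == "older_hgt"
        assert call.donor_guess[0] == "genus" and call.donor_guess[1] == "Pratylenchus"

    def test_donor_flanks_suggest_contamination(self):
        gene_hits = [hit(f"Reg_{i}", GAMMA, 250 - i) for i in range(5)]
        flanks = {
            "f1": [hit("Reg_x", GAMMA, 240, query="f1")],
            "f2": [hit("Reg_y", GAMMA, 230, query="f2")],
        }
        call = classify_candidate(candidate(), gene_hits, flanks, EXPECTED)
        assert call.category == "ambiguous"
        assert "contamination" in call.reason

    def test_no_hits_is_ambiguous(self):
        call = classify_candidate(candidate(), [], self_flanks(), EXPECTED)
        assert (call.category, call.reason) == ("ambiguous", "no_evidence")

    def test_tied_top_disagreeing_phyla_is_ambiguous(self):
        gene_hits = [hit("a", GAMMA, 200), hit("b", BACTEROIDETES, 200)]
        call = classify_candidate(candidate(), gene_hits, self_flanks(), EXPECTED)
        assert (call.category, call.reason) == ("ambiguous", "tied_top")

    def test_self_genus_top_with_self_phylum_next_is_not_older(self):
        gene_hits = [hit("Card_1", CARDINIUM, 300)] + [
            hit(f"Cyt_{i}", BACTEROIDETES, 250 - i) for i in range(8)
        ]
        call = classify_candidate(candidate(), gene_hits, self_flanks(), EXPECTED)
        assert call.category == "non_hgt"

    def test_raising_k_never_flips_uniform_phylum_to_recent(self):
        gene_hits = [hit(f"Cyt_{i}", BACTEROIDETES, 300 - i) for i in range(30)]
        for k in (1, 3, 10, 30):
            call = classify_candidate(
                candidate(), gene_hits, self_flanks(), EXPECTED,
                ClassifierOptions(k=k),
            )
            assert call.category == "non_hgt"

    def test_row_order_invariance(self):
        gene_hits = [hit(f"Reg_{i}", GAMMA, 250 - i) for i in range(5)] + [
            hit("Cyt_9", BACTEROIDETES, 140)
        ]
        a = classify_candidate(candidate(), gene_hits, self_flanks(), EXPECTED)
        b = classify_candidate(candidate(), gene_hits[::-1], self_flanks(), EXPECTED)
        assert a == b


# ---------------------------------------------------------------------------
# Tree concordance


class TestTreeConcordance:
    def lineages(self):
        return {
            "card1": CARDINIUM,
            "bact1": BACTEROIDETES,
            "gamma1": GAMMA,
            "out1": NEMATODA,
        }

    def test_self_phylum_sister_is_concordant(self):
        tree = "((query:1,card1:1):1,(bact1:1,out1:1):1);"
        assert evaluate_tree_concordance(tree, EXPECTED, "query", self.lineages()) is True

    def test_foreign_sister_is_discordant(self):
        tree = "((query:1,gamma1:1):1,(bact1:1,out1:1):1);"
        assert evaluate_tree_concordance(tree, EXPECTED, "query", self.lineages()) is False

    def test_three_tip_tree_not_evaluated(self):
        tree = "(query:1,card1:1,bact1:1);"
        assert evaluate_tree_concordance(tree, EXPECTED, "query", self.lineages()) \
            == "not_evaluated"

    def test_missing_query_tip(self):
        tree = "((a:1,card1:1):1,(bact1:1,out1:1):1);"
        with pytest.raises(ValidationError):
            evaluate_tree_concordance(tree, EXPECTED, "query", self.lineages())


# ---------------------------------------------------------------------------
# Box statistics


def quartile_oracle(values, q):
    """Sorted-rank linear interpolation, independent of numpy."""
    s = sorted(values)
    pos = (len(s) - 1) * q
    lo, hi = int(pos), min(int(pos) + 1, len(s) - 1)
    frac = pos - int(pos)
    return s[lo] * (1 - frac) + s[hi] * frac


class TestBoxStats:
    def test_odd_length_quartiles(self):
        b = box_stats([1, 2, 3, 4, 5])
        assert (b.q1, b.median, b.q3) == (2, 3, 4)

    def test_all_equal_zero_width_box(self):
        b = box_stats([7.0] * 6)
        assert b.q1 == b.q3 == b.median == 7.0
        assert b.outliers == []

    def test_outlier_beyond_fence(self):
        b = box_stats([1, 2, 3, 4, 100])
        assert 100.0 in b.outliers
        assert b.whisker_high <= 4

    def test_random_scores_match_rank_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = rng.normal(100, 25, size=int(rng.integers(4, 40))).tolist()
            b = box_stats(values)
            assert b.q1 == pytest.approx(quartile_oracle(values, 0.25))
            assert b.median == pytest.approx(quartile_oracle(values, 0.50))
            assert b.q3 == pytest.approx(quartile_oracle(values, 0.75))


# ---------------------------------------------------------------------------
# End-to-end planted recovery (small)


class TestPlantedRecovery:
    def test_tiny_simulation_recovers_planted_categories(self):
        config = tiny_pangenome_config(seed=11)
        result = generate(config)
        pg = result.pangenome
        taxa = {t.name: TaxonMeta(t.genome_size_bp) for t in config.taxa}
        matrix = build_membership(pg.cluster_table, taxa)
        g2c = {
            g: cid for (t, g), cid in pg.cluster_table.gene_to_cluster().items()
            if t == config.focal
        }
        _, calls, summary = run_hgt_analysis(
            matrix, pg.bundles[config.focal].genes, pg.hit_tables,
            config.focal, config.outgroups,
            ExpectedLineage(lineage=pg.expected_lineage), gene_to_cluster=g2c,
        )
        truth = result.truth.hgt_categories
        planted = {c.gene_id: c.category for c in calls if c.gene_id in truth}
        assert len(planted) == len(truth)
        n_correct = sum(planted[g] == truth[g] for g in truth)
        assert n_correct == len(truth)
        assert "self_phylum" in summary.flank_groups

    def test_no_planted_means_no_transfer_calls(self):
        config = tiny_pangenome_config(
            seed=5, hgt=tiny_pangenome_config().hgt.__class__(
                n_recent=0, n_older=0, n_non=10
            ),
        )
        result = generate(config)
        pg = result.pangenome
        taxa = {t.name: TaxonMeta(t.genome_size_bp) for t in config.taxa}
        matrix = build_membership(pg.cluster_table, taxa)
        g2c = {
            g: cid for (t, g), cid in pg.cluster_table.gene_to_cluster().items()
            if t == config.focal
        }
        _, calls, _ = run_hgt_analysis(
            matrix, pg.bundles[config.focal].genes, pg.hit_tables,
            config.focal, config.outgroups,
            ExpectedLineage(lineage=pg.expected_lineage), gene_to_cluster=g2c,
        )
        assert all(c.category not in ("recent_hgt", "older_hgt") for c in calls)
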