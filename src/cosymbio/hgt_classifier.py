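"""Rule-based horizontal-gene-transfer classification from blast-hit taxonomy.

Candidate HGT genes are the focal genome's genes whose ortholog cluster has
no member in any outgroup (including singletons with no cluster at all).
Each candidate is then classified from the ranked taxonomic lineages of its
blast hits and the hits of its flanking genes, which stand in for the
genomic background's expected taxonomy:

* **non_hgt** — the top hit and the majority of the top-k hits lie in the
  host genome's own phylum, and the flanking genes agree (and the gene tree
  is concordant with the species tree when one is supplied).  The gene is
  probably vertically inherited and merely unsampled in the outgroups.
* **recent_hgt** — the top hit is outside the host phylum while the
  flanking genes match it: the gene arrived recently enough that its closest
  relatives are still in the donor lineage.
* **older_hgt** — the top hit is within the host's own self-clade (genus by
  default: the transferred copy has since diversified within the recipient
  clade) but, once self-clade hits are removed, every remaining hit up to k
  is outside the host phylum.
* **ambiguous** — anything else (no hits; top-hit ties that disagree at the
  phylum rank; donor-like flanking context suggesting contamination...).
  The reason is recorded on the call.

As supporting (never gating) evidence, each call records the ratio of the
gene's best bit score to the median bit score of its flanking genes'
self-phylum hits: transferred genes typically score *higher* against their
donor lineage than the background scores against its own phylum.
"""

from __future__ import annotations

import io
import logging
import statistics
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np

from .errors import UsageError, ValidationError
from .types import GeneRecord, HitRecord, Lineage, RANKS, hit_sort_key
from .ortholog_sets import MembershipMatrix

logger = logging.getLogger("cosymbio.hgt")

CATEGORIES = ("non_hgt", "recent_hgt", "older_hgt", "ambiguous")


@dataclass(frozen=True)
class ClassifierOptions:
    """Tunable knobs of the rule set."""

    k: int = 10                  # how many top hits constitute "the closest matches"
    self_rank: str = "genus"     # rank defining the self-clade
    mismatch_rank: str = "phylum"  # rank at which a mismatch suggests transfer

    def validate(self) -> "ClassifierOptions":
        if self.k < 1:
            raise UsageError("k must be >= 1")
        for r in (self.self_rank, self.mismatch_rank):
            if r not in RANKS:
                raise UsageError(f"unknown rank {r!r}")
        return self


@dataclass(frozen=True)
class ExpectedLineage:
    """The host genome's own lineage plus the ranks used by the rules."""

    lineage: Lineage
    self_rank: str = "genus"
    mismatch_rank: str = "phylum"

    def validate(self) -> "ExpectedLineage":
        self.lineage.validate()
        if self.self_rank not in RANKS or self.mismatch_rank not in RANKS:
            raise UsageError("self_rank and mismatch_rank must be valid ranks")
        depth = RANKS.index(self.self_rank)
        for rank in RANKS[: depth + 1]:
            if self.lineage.get(rank) is None:
                raise ValidationError(
                    f"expected lineage must be filled down to {self.self_rank}; "
                    f"missing {rank}"
                )
        return self


@dataclass
class HgtCandidate:
    gene_id: str
    taxon: str
    flanking_gene_ids: List[str]  # upstream (nearest last) then downstream
    reason: str


@dataclass
class HgtCall:
    gene_id: str
    category: str
    reason: str
    top_hit_lineage: Optional[Lineage]
    closest_nonself_lineage: Optional[Lineage]
    gene_best_bitscore: Optional[float]
    flanking_median_bitscore_selfphylum: Optional[float]
    bitscore_ratio: Optional[float]
    donor_guess: Optional[Tuple[str, str]]  # (rank, name)
    tree_concordant: str = "not_evaluated"  # "true" | "false" | "not_evaluated"


@dataclass
class BoxStats:
    """Box-plot statistics: quartiles by linear interpolation, 1.5xIQR whiskers."""

    n: int
    q1: float
    median: float
    q3: float
    mean: float
    whisker_low: float
    whisker_high: float
    outliers: List[float]

    def validate(self) -> "BoxStats":
        if not (self.q1 <= self.median <= self.q3):
            raise ValidationError("quartiles out of order")
        return self


@dataclass
class BitscoreSummary:
    """Per hit-clade group box statistics, for genes and their flanks."""

    gene_groups: Dict[str, BoxStats]
    flank_groups: Dict[str, BoxStats]


# ---------------------------------------------------------------------------
# Candidate identification


def identify_candidates(
    matrix: MembershipMatrix,
    gene_records: Sequence[GeneRecord],
    focal_taxon: str,
    outgroups: Sequence[str],
    flank_size: int = 2,
    gene_to_cluster: Optional[Mapping[str, str]] = None,
) -> List[HgtCandidate]:
    """Genes of ``focal_taxon`` whose cluster has zero outgroup members.

    ``gene_to_cluster`` maps the focal taxon's gene ids to cluster ids; genes
    absent from it are singletons and automatically candidates.  Flanking
    genes are the up-to-``flank_size`` nearest genes on each side by
    coordinate on the same scaffold.
    """
    if focal_taxon not in matrix.taxa:
        raise UsageError(f"focal taxon {focal_taxon!r} not in matrix")
    for t in outgroups:
        if t not in matrix.taxa:
            raise UsageError(f"outgroup taxon {t!r} not in matrix")
    if flank_size < 1:
        raise UsageError("flank_size must be >= 1")
    gene_to_cluster = dict(gene_to_cluster or {})
    pres = matrix.presence()
    outgroup_present = (
        pres[list(outgroups)].any(axis=1) if len(outgroups) else pres.iloc[:, :0].any(axis=1)
    )
    ordered = sorted(gene_records, key=lambda g: (g.scaffold_id, g.start, g.gene_id))
    by_scaffold: Dict[str, List[GeneRecord]] = {}
    for g in ordered:
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    candidates: List[HgtCandidate] = []
    for scaffold, genes in by_scaffold.items():
        for i, g in enumerate(genes):
            cid = gene_to_cluster.get(g.gene_id)
            if cid is None:
                reason = "singleton"
            elif cid in outgroup_present.index and bool(outgroup_present.loc[cid]):
                continue
            else:
                reason = "no_outgroup_ortholog"
            upstream = [x.gene_id for x in genes[max(0, i - flank_size) : i]]
            downstream = [x.gene_id for x in genes[i + 1 : i + 1 + flank_size]]
            if len(upstream) < flank_size or len(downstream) < flank_size:
                logger.info(
                    "%s: only %d/%d flanking genes (scaffold edge)",
                    g.gene_id, len(upstream) + len(downstream), 2 * flank_size,
                )
            candidates.append(
                HgtCandidate(
                    gene_id=g.gene_id,
                    taxon=focal_taxon,
                    flanking_gene_ids=upstream + downstream,
                    reason=reason,
                )
            )
    return candidates


def drop_self_hits(
    hits: Sequence[HitRecord], self_subject_prefix: str
) -> List[HitRecord]:
    """Remove hits to the query's own strain (else every gene is trivially non-HGT)."""
    return [h for h in hits if not h.subject_id.startswith(self_subject_prefix)]


# ---------------------------------------------------------------------------
# Classification


def _matches(lineage: Lineage, expected: ExpectedLineage, rank: str) -> bool:
    name = lineage.get(rank)
    return name is not None and name == expected.lineage.get(rank)


def _majority_matches(
    hits: Sequence[HitRecord], expected: ExpectedLineage, rank: str
) -> bool:
    if not hits:
        return True  # vacuous: no evidence against the background
    n = sum(_matches(h.lineage, expected, rank) for h in hits)
    return 2 * n > len(hits)


def _flank_top_hits(flanking_hits: Mapping[str, Sequence[HitRecord]]) -> List[HitRecord]:
    """Best hit of each flanking gene (the flank's taxonomic signal)."""
    best: List[HitRecord] = []
    for gene_id in flanking_hits:
        hs = sorted(flanking_hits[gene_id], key=hit_sort_key)
        if hs:
            best.append(hs[0])
    return best


def _donor_guess(
    hits: Sequence[HitRecord],
) -> Optional[Tuple[str, str]]:
    """Deepest rank at which all hits agree, as (rank, name)."""
    if not hits:
        return None
    guess: Optional[Tuple[str, str]] = None
    for rank in RANKS:
        names = {h.lineage.get(rank) for h in hits}
        if len(names) == 1 and None not in names:
            guess = (rank, names.pop())
        else:
            break
    return guess


def classify_candidate(
    candidate: HgtCandidate,
    gene_hits: Sequence[HitRecord],
    flanking_hits: Mapping[str, Sequence[HitRecord]],
    expected: ExpectedLineage,
    options: ClassifierOptions = ClassifierOptions(),
    gene_tree: Optional["dendropy.Tree"] = None,
    tree_tip_lineages: Optional[Mapping[str, Lineage]] = None,
    query_tip: Optional[str] = None,
) -> HgtCall:
    """Apply the three-category rule set to one candidate gene.

    ``gene_hits`` must already have self-strain hits removed; they are
    re-sorted canonically here so row order never matters.
    """
    options.validate()
    expected.validate()
    srank, mrank = options.self_rank, options.mismatch_rank
    hits = sorted(gene_hits, key=hit_sort_key)
    flank_best = _flank_top_hits(flanking_hits)
    if not flanking_hits:
        logger.warning("%s: no flanking hits supplied", candidate.gene_id)

    # flanking self-phylum median bit score and evidence ratio
    flank_self_scores = [
        h.bit_score
        for gene_id in flanking_hits
        for h in flanking_hits[gene_id]
        if _matches(h.lineage, expected, mrank)
    ]
    flank_median = statistics.median(flank_self_scores) if flank_self_scores else None
    best_score = hits[0].bit_score if hits else None
    ratio = (
        best_score / flank_median
        if best_score is not None and flank_median
        else None
    )

    def call(category: str, reason: str, tree_state: str = "not_evaluated") -> HgtCall:
        nonself = [h for h in hits if not _matches(h.lineage, expected, srank)]
        # donor pool: hits outside the expected phylum (self-phylum non-genus
        # hits carry no signal about a donor lineage)
        donor_pool = [h for h in hits if not _matches(h.lineage, expected, mrank)]
        result = HgtCall(
            gene_id=candidate.gene_id,
            category=category,
            reason=reason,
            top_hit_lineage=hits[0].lineage if hits else None,
            closest_nonself_lineage=nonself[0].lineage if nonself else None,
            gene_best_bitscore=best_score,
            flanking_median_bitscore_selfphylum=flank_median,
            bitscore_ratio=ratio,
            donor_guess=_donor_guess(donor_pool[: options.k]),
            tree_concordant=tree_state,
        )
        _assert_call_invariants(result, hits, expected, options)
        return result

    # (a) no evidence at all
    if not hits:
        return call("ambiguous", "no_evidence")

    top = hits[0]
    tied = [h for h in hits if h.bit_score == top.bit_score]
    if len(tied) > 1 and len({h.lineage.get(mrank) for h in tied}) > 1:
        return call("ambiguous", "tied_top")

    top_k = hits[: options.k]
    nonself = [h for h in hits if not _matches(h.lineage, expected, srank)]
    next_k = nonself[: options.k]

    top_matches_phylum = _matches(top.lineage, expected, mrank)
    flank_matches = _majority_matches(flank_best, expected, mrank)

    # (c) non-HGT: gene and flanks both look like the host phylum
    if top_matches_phylum and _majority_matches(top_k, expected, mrank) and flank_matches:
        tree_state = "not_evaluated"
        if gene_tree is not None:
            concordant = evaluate_tree_concordance(
                gene_tree, expected, query_tip=query_tip, tip_lineages=tree_tip_lineages
            )
            tree_state = concordant if isinstance(concordant, str) else (
                "true" if concordant else "false"
            )
            if tree_state == "false":
                return call("ambiguous", "tree_discordant", tree_state)
        return call("non_hgt", "top_and_flanks_match_phylum", tree_state)

    # (d) recent HGT: gene points away from the host phylum, flanks do not
    if not top_matches_phylum and flank_best and flank_matches:
        return call("recent_hgt", "top_outside_phylum_flanks_match")

    # (e) older HGT: top within self-clade, all next-closest outside the phylum
    if (
        _matches(top.lineage, expected, srank)
        and next_k
        and all(not _matches(h.lineage, expected, mrank) for h in next_k)
    ):
        return call("older_hgt", "self_clade_top_nonself_outside_phylum")

    # (f) fall-through
    if not top_matches_phylum and not flank_matches:
        return call("ambiguous", "flanks_also_outside_phylum_possible_contamination")
    return call("ambiguous", "mixed_signal")


def _assert_call_invariants(
    result: HgtCall,
    hits: Sequence[HitRecord],
    expected: ExpectedLineage,
    options: ClassifierOptions,
) -> None:
    if result.category == "recent_hgt":
        assert hits and not _matches(hits[0].lineage, expected, options.mismatch_rank)
    if result.category == "older_hgt":
        assert hits and _matches(hits[0].lineage, expected, options.self_rank)
        nonself = [
            h for h in hits if not _matches(h.lineage, expected, options.self_rank)
        ]
        assert all(
            not _matches(h.lineage, expected, options.mismatch_rank)
            for h in nonself[: options.k]
        )


# ---------------------------------------------------------------------------
# Gene-tree concordance


def evaluate_tree_concordance(
    tree: Union[str, "dendropy.Tree"],
    expected: ExpectedLineage,
    query_tip: Optional[str] = None,
    tip_lineages: Optional[Mapping[str, Lineage]] = None,
) -> Union[bool, str]:
    """Does the query's sister group match the expected phylum?

    The tree (newick string or dendropy Tree) must have >= 4 tips, exactly
    one of which is the query (named ``query_tip``, default ``"query"``).
    Unrooted trees are midpoint-rooted first.  Returns True iff the majority
    lineage of the query's sister group (the other leaves under its parent)
    matches the expected phylum; ``"not_evaluated"`` for trees under 4 tips.
    """
    expected.validate()
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    query_tip = query_tip or "query"
    tip_lineages = tip_lineages or {}
    leaves = tree.leaf_nodes()
    if len(leaves) < 4:
        return "not_evaluated"
    if not tree.is_rooted:
        tree.reroot_at_midpoint(update_bipartitions=False)
    query_nodes = [
        lf for lf in tree.leaf_nodes() if lf.taxon and lf.taxon.label == query_tip
    ]
    if len(query_nodes) != 1:
        raise ValidationError(
            f"tree must contain exactly one query tip {query_tip!r}, "
            f"found {len(query_nodes)}"
        )
    node = query_nodes[0]
    parent = node.parent_node
    sister_leaves = [
        lf for lf in parent.leaf_iter() if lf is not node
    ] if parent is not None else []
    if not sister_leaves:
        return "not_evaluated"
    mrank = expected.mismatch_rank
    n_match = 0
    for lf in sister_leaves:
        label = lf.taxon.label if lf.taxon else ""
        lineage = tip_lineages.get(label)
        if lineage is None:
            # convention: tip labels may embed the lineage after the last '@',
            # with '|' standing in for ';' (illegal inside newick labels)
            if "@" in label:
                lineage = Lineage.from_string(
                    label.rsplit("@", 1)[1].replace("|", ";")
                )
            else:
                lineage = Lineage()
        if _matches(lineage, expected, mrank):
            n_match += 1
    return 2 * n_match > len(sister_leaves)


# ---------------------------------------------------------------------------
# Bit-score divergence summaries


def default_hit_grouping(lineage: Lineage, expected: ExpectedLineage) -> str:
    """Fig-style hit-clade grouping: self phylum / Rickettsiales / eukaryotes /
    other bacterial phyla / other."""
    if _matches(lineage, expected, expected.mismatch_rank):
        return "self_phylum"
    if lineage.order == "Rickettsiales":
        return "wolbachia_rickettsiales"
    if lineage.superkingdom == "Eukaryota":
        return "eukaryotes"
    if lineage.superkingdom == "Bacteria":
        return "other_bacterial_phyla"
    return "other"


def box_stats(scores: Sequence[float]) -> BoxStats:
    """Quartiles by linear interpolation, whiskers at the most extreme points
    within 1.5xIQR of the box, outliers beyond."""
    arr = np.asarray(sorted(scores), dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    return BoxStats(
        n=len(arr),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        mean=float(arr.mean()),
        whisker_low=float(inside.min()) if len(inside) else float(q1),
        whisker_high=float(inside.max()) if len(inside) else float(q3),
        outliers=[float(x) for x in outliers],
    ).validate()


def run_hgt_analysis(
    matrix: MembershipMatrix,
    gene_records: Sequence[GeneRecord],
    hits: Mapping[str, Sequence[HitRecord]],
    focal_taxon: str,
    outgroups: Sequence[str],
    expected: ExpectedLineage,
    options: ClassifierOptions = ClassifierOptions(),
    flank_size: int = 2,
    gene_to_cluster: Optional[Mapping[str, str]] = None,
    trees: Optional[Mapping[str, str]] = None,
    tree_tip_lineages: Optional[Mapping[str, Lineage]] = None,
) -> Tuple[List[HgtCandidate], List[HgtCall], "BitscoreSummary"]:
    """Identify candidates, classify each, and summarise bit-score divergence.

    ``hits`` maps every focal gene id (candidates and their flanks) to its
    blast hits, self-strain hits already removed; ``trees`` optionally maps
    gene ids to newick strings.
    """
    candidates = identify_candidates(
        matrix, gene_records, focal_taxon, outgroups,
        flank_size=flank_size, gene_to_cluster=gene_to_cluster,
    )
    calls: List[HgtCall] = []
    flank_map: Dict[str, Dict[str, List[HitRecord]]] = {}
    for cand in candidates:
        flanking = {
            g: list(hits.get(g, [])) for g in cand.flanking_gene_ids if hits.get(g)
        }
        flank_map[cand.gene_id] = flanking
        tree = (trees or {}).get(cand.gene_id)
        calls.append(
            classify_candidate(
                cand,
                hits.get(cand.gene_id, []),
                flanking,
                expected,
                options,
                gene_tree=tree,
                tree_tip_lineages=tree_tip_lineages,
                query_tip="query",
            )
        )
    summary = bitscore_divergence(calls, hits, flank_map, expected) if calls else (
        BitscoreSummary(gene_groups={}, flank_groups={})
    )
    return candidates, calls, summary


def bitscore_divergence(
    calls: Sequence[HgtCall],
    gene_hits: Mapping[str, Sequence[HitRecord]],
    flanking_hits: Mapping[str, Mapping[str, Sequence[HitRecord]]],
    expected: ExpectedLineage,
    grouping=default_hit_grouping,
) -> BitscoreSummary:
    """Box statistics of best-hit bit scores by hit-clade group.

    For each candidate gene (and, separately, each of its flanking genes) and
    each group, the best bit score among that gene's hits in the group
    contributes one observation.  Empty groups are omitted with a warning.
    """
    if not calls:
        raise UsageError("bitscore_divergence needs at least one call")

    def collect(hit_map: Mapping[str, Sequence[HitRecord]]) -> Dict[str, List[float]]:
        groups: Dict[str, List[float]] = {}
        for gene_id in hit_map:
            best: Dict[str, float] = {}
            for h in hit_map[gene_id]:
                g = grouping(h.lineage, expected)
                if g not in best or h.bit_score > best[g]:
                    best[g] = h.bit_score
            for g, score in best.items():
                groups.setdefault(g, []).append(score)
        return groups

    gene_map = {c.gene_id: gene_hits.get(c.gene_id, []) for c in calls}
    flank_map: Dict[str, List[HitRecord]] = {}
    for c in calls:
        for gene_id, hs in (flanking_hits.get(c.gene_id) or {}).items():
            flank_map.setdefault(gene_id, []).extend(hs)

    out_gene: Dict[str, BoxStats] = {}
    for g, scores in sorted(collect(gene_map).items()):
        out_gene[g] = box_stats(scores)
    out_flank: Dict[str, BoxStats] = {}
    for g, scores in sorted(collect(flank_map).items()):
        out_flank[g] = box_stats(scores)
    if not out_gene:
        logger.warning("no hit groups with data among candidate genes")
    return BitscoreSummary(gene_groups=out_gene, flank_groups=out_flank)
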