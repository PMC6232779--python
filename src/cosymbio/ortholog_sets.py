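"""Set algebra over ortholog clusters.

Everything here operates on a :class:`MembershipMatrix`: a clusters-by-taxa
table of gene copy counts built from an ortholog clustering (OrthoMCL-style
groups), plus per-taxon metadata (genome size, plasmid flag).  "Presence"
always means copy count >= 1; copy number only matters to
:func:`expansion_profile`.

Operations: three-way Venn partitions, universal vs ingroup-specific core
sets, pangenome overlap between two taxon groups, functional-category
breakdowns of a cluster set, gene-family expansion profiling normalised per
Mbp of genome, biosynthetic-pathway completeness, and genome feature
comparison (GC%, coding fraction, designated-ortholog length sums).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .display import percent_half_up, percent_one_decimal_capped
from .errors import EmptyInputError, UsageError, ValidationError
from .types import ClusterTable, GeneRecord, GenomeBundle

logger = logging.getLogger("cosymbio.sets")


@dataclass(frozen=True)
class TaxonMeta:
    genome_size_bp: int
    is_plasmid: bool = False


@dataclass
class MembershipMatrix:
    """Cluster x taxon copy-count matrix with taxon metadata."""

    counts: pd.DataFrame  # index: cluster ids, columns: taxa, int copy counts
    taxa_meta: Dict[str, TaxonMeta]

    @property
    def taxa(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def cluster_ids(self) -> List[str]:
        return list(self.counts.index)

    def presence(self) -> pd.DataFrame:
        return self.counts >= 1


@dataclass
class VennCounts:
    """Cluster counts in the seven cells of a three-taxon Venn diagram."""

    a: str
    b: str
    c: str
    only_a: int
    only_b: int
    only_c: int
    ab: int
    ac: int
    bc: int
    abc: int

    @property
    def total(self) -> int:
        return (
            self.only_a + self.only_b + self.only_c
            + self.ab + self.ac + self.bc + self.abc
        )


@dataclass
class CoreSetReport:
    universal_core: List[str]
    ingroup_core: List[str]
    absence_criterion: str  # "any_outgroup" | "all_outgroups"

    @property
    def n_universal(self) -> int:
        return len(self.universal_core)

    @property
    def n_ingroup(self) -> int:
        return len(self.ingroup_core)


@dataclass
class PangenomeReport:
    n_group1_only: int
    n_group2_only: int
    n_both: int
    n_total: int  # clusters touching either group
    percent_group1_only: float
    percent_group2_only: float
    percent_both: float


@dataclass
class CategoryFractions:
    """Per-category cluster counts and display percents."""

    counts: Dict[str, int]
    percents: Dict[str, float]
    n_total: int


@dataclass
class ExpansionTable:
    """Copy-number table restricted/flagged by the min-copies filter.

    ``frame`` columns: one copy-count column per taxon, ``max_copies``, one
    ``per_mbp:<taxon>`` column per taxon, and an ``included`` flag; sorted by
    descending ``max_copies``.
    """

    frame: pd.DataFrame
    min_copies: int

    @property
    def included(self) -> pd.DataFrame:
        return self.frame[self.frame["included"]]


@dataclass
class PathwayMatrix:
    """Long-form pathway completeness per (pathway, taxon)."""

    frame: pd.DataFrame  # columns: pathway_id, taxon, n_present, n_required,
    #                      completeness, status


# ---------------------------------------------------------------------------


def build_membership(
    cluster_table: ClusterTable,
    taxa: Mapping[str, TaxonMeta],
    on_unknown: str = "error",
) -> MembershipMatrix:
    """Count gene copies per (cluster, taxon).

    ``on_unknown`` controls members whose taxon is absent from ``taxa``:
    ``"error"`` raises; ``"ignore"`` drops them (clusters left with no member
    are dropped with a logged count).
    """
    if on_unknown not in ("error", "ignore"):
        raise UsageError(f"on_unknown must be 'error' or 'ignore', got {on_unknown!r}")
    cluster_table.validate()
    taxon_list = list(taxa)
    rows: List[List[int]] = []
    index: List[str] = []
    n_dropped = 0
    for cid, members in cluster_table.clusters:
        unknown = [t for t in members if t not in taxa]
        if unknown and on_unknown == "error":
            raise ValidationError(
                f"cluster {cid!r} references unknown taxon {unknown[0]!r}"
            )
        counts = [len(members.get(t, [])) for t in taxon_list]
        if sum(counts) == 0:
            n_dropped += 1
            continue
        rows.append(counts)
        index.append(cid)
    if n_dropped:
        logger.warning("dropped %d clusters with no member among selected taxa", n_dropped)
    frame = pd.DataFrame(rows, index=index, columns=taxon_list, dtype=int)
    if frame.empty:
        frame = pd.DataFrame(columns=taxon_list, dtype=int)
    return MembershipMatrix(counts=frame, taxa_meta=dict(taxa))


def venn_trio(matrix: MembershipMatrix, a: str, b: str, c: str) -> VennCounts:
    """Counts of clusters present in each exclusive region of the (a,b,c) Venn."""
    if len({a, b, c}) != 3:
        raise UsageError("venn_trio requires three distinct taxa")
    for t in (a, b, c):
        if t not in matrix.taxa:
            raise UsageError(f"taxon {t!r} not in matrix")
    pres = matrix.presence()
    pa, pb, pc = pres[a], pres[b], pres[c]
    return VennCounts(
        a=a, b=b, c=c,
        only_a=int((pa & ~pb & ~pc).sum()),
        only_b=int((~pa & pb & ~pc).sum()),
        only_c=int((~pa & ~pb & pc).sum()),
        ab=int((pa & pb & ~pc).sum()),
        ac=int((pa & ~pb & pc).sum()),
        bc=int((~pa & pb & pc).sum()),
        abc=int((pa & pb & pc).sum()),
    )


def _check_groups(matrix: MembershipMatrix, group1: Sequence[str], group2: Sequence[str]) -> None:
    if not group1 or not group2:
        raise UsageError("both taxon groups must be non-empty")
    overlap = set(group1) & set(group2)
    if overlap:
        raise UsageError(f"taxon groups overlap: {sorted(overlap)}")
    for t in list(group1) + list(group2):
        if t not in matrix.taxa:
            raise UsageError(f"taxon {t!r} not in matrix")


def core_sets(
    matrix: MembershipMatrix,
    ingroup: Sequence[str],
    outgroups: Sequence[str],
    strict: bool = False,
) -> CoreSetReport:
    """Universal vs ingroup-specific core clusters.

    * universal core: present in every ingroup AND every outgroup taxon;
    * ingroup-specific core: present in every ingroup taxon but absent from
      at least one outgroup taxon (default), or from all outgroup taxa when
      ``strict`` is set.
    """
    _check_groups(matrix, ingroup, outgroups)
    pres = matrix.presence()
    in_all_ingroup = pres[list(ingroup)].all(axis=1)
    in_all_outgroup = pres[list(outgroups)].all(axis=1)
    in_any_outgroup = pres[list(outgroups)].any(axis=1)
    universal = matrix.counts.index[in_all_ingroup & in_all_outgroup]
    if strict:
        ingroup_core = matrix.counts.index[in_all_ingroup & ~in_any_outgroup]
        criterion = "all_outgroups"
    else:
        ingroup_core = matrix.counts.index[in_all_ingroup & ~in_all_outgroup]
        criterion = "any_outgroup"
    return CoreSetReport(
        universal_core=list(universal),
        ingroup_core=list(ingroup_core),
        absence_criterion=criterion,
    )


def pangenome_overlap(
    matrix: MembershipMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
) -> PangenomeReport:
    """Clusters touching only group1, only group2, or both.

    Percents are of the clusters touching either group, shown to one decimal
    with the capped half-up convention of :mod:`cosymbio.display`.
    """
    _check_groups(matrix, group1, group2)
    pres = matrix.presence()
    in1 = pres[list(group1)].any(axis=1)
    in2 = pres[list(group2)].any(axis=1)
    n1 = int((in1 & ~in2).sum())
    n2 = int((~in1 & in2).sum())
    nb = int((in1 & in2).sum())
    total = n1 + n2 + nb
    if total == 0:
        return PangenomeReport(0, 0, 0, 0, 0.0, 0.0, 0.0)
    return PangenomeReport(
        n_group1_only=n1,
        n_group2_only=n2,
        n_both=nb,
        n_total=total,
        percent_group1_only=percent_one_decimal_capped(n1, total),
        percent_group2_only=percent_one_decimal_capped(n2, total),
        percent_both=percent_one_decimal_capped(nb, total),
    )


def cluster_category(
    cid: str,
    cluster_table: ClusterTable,
    gene_categories: Mapping[Tuple[str, str], str],
) -> str:
    """Representative functional category: majority vote, tie -> unknown_function."""
    members = dict(cluster_table.clusters)[cid]
    votes: Dict[str, int] = {}
    for taxon, genes in members.items():
        for gene in genes:
            cat = gene_categories.get((taxon, gene), "unknown_function")
            votes[cat] = votes.get(cat, 0) + 1
    best = max(votes.values())
    winners = [cat for cat, v in votes.items() if v == best]
    return winners[0] if len(winners) == 1 else "unknown_function"


def functional_breakdown(
    cluster_ids: Sequence[str],
    cluster_table: ClusterTable,
    gene_categories: Mapping[Tuple[str, str], str],
) -> CategoryFractions:
    """Category counts/percents over a set of clusters.

    Display percents are half-up: whole percent at or above 20%, one decimal
    below (40/154 shows as 26%, 7/154 as 4.5%).
    """
    if not cluster_ids:
        raise EmptyInputError("functional_breakdown needs at least one cluster")
    known = set(cluster_table.cluster_ids)
    missing = [c for c in cluster_ids if c not in known]
    if missing:
        raise ValidationError(f"unknown cluster id {missing[0]!r}")
    counts: Dict[str, int] = {}
    for cid in cluster_ids:
        cat = cluster_category(cid, cluster_table, gene_categories)
        counts[cat] = counts.get(cat, 0) + 1
    total = len(cluster_ids)
    percents: Dict[str, float] = {}
    for cat, n in counts.items():
        if 100 * n >= 20 * total:
            percents[cat] = float(percent_half_up(n, total, decimals=0))
        else:
            percents[cat] = percent_half_up(n, total, decimals=1)
    return CategoryFractions(counts=counts, percents=percents, n_total=total)


def expansion_profile(matrix: MembershipMatrix, min_copies: int = 3) -> ExpansionTable:
    """Copy-number expansion table with per-Mbp normalisation.

    A cluster is ``included`` iff its maximum per-taxon copy count reaches
    ``min_copies`` (gene-family expansion analyses conventionally ignore
    families below three copies).  ``per_mbp:<taxon>`` = copies divided by
    genome size in Mbp.
    """
    if min_copies < 1:
        raise UsageError("min_copies must be >= 1")
    for t in matrix.taxa:
        if matrix.taxa_meta[t].genome_size_bp <= 0:
            raise ValidationError(f"taxon {t!r} has non-positive genome size")
    frame = matrix.counts.copy()
    frame["max_copies"] = frame[matrix.taxa].max(axis=1) if len(frame) else 0
    for t in matrix.taxa:
        mbp = matrix.taxa_meta[t].genome_size_bp / 1e6
        frame[f"per_mbp:{t}"] = frame[t] / mbp
    frame["included"] = frame["max_copies"] >= min_copies
    frame = frame.loc[
        sorted(frame.index, key=lambda cid: (-frame.at[cid, "max_copies"], cid))
    ]
    return ExpansionTable(frame=frame, min_copies=min_copies)


def pathway_completeness(
    gene_presence: Mapping[str, Set[str]],
    pathway_defs: Mapping[str, Set[str]],
) -> PathwayMatrix:
    """Completeness of each pathway (gene-symbol set) in each taxon.

    Status: absent (0), partial (0 < c < 1), complete (1).
    """
    if not pathway_defs:
        raise EmptyInputError("no pathway definitions supplied")
    rows = []
    for pid in pathway_defs:
        required = set(pathway_defs[pid])
        if not required:
            raise ValidationError(f"pathway {pid!r} has an empty gene set")
        for taxon in gene_presence:
            present = len(required & set(gene_presence[taxon]))
            completeness = present / len(required)
            status = (
                "complete" if completeness == 1
                else "absent" if completeness == 0
                else "partial"
            )
            rows.append(
                {
                    "pathway_id": pid,
                    "taxon": taxon,
                    "n_present": present,
                    "n_required": len(required),
                    "completeness": completeness,
                    "status": status,
                }
            )
    return PathwayMatrix(frame=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Genome feature comparison


def gc_percent(sequences: Iterable[str]) -> float:
    """GC% over unambiguous bases only (N and other ambiguity codes excluded)."""
    gc = acgt = 0
    for seq in sequences:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        acgt += s.count("A") + s.count("C") + s.count("G") + s.count("T")
    return 100.0 * gc / acgt if acgt else 0.0


def merged_interval_length(intervals: Iterable[Tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    ordered = sorted(intervals)
    total = 0
    cur_start: Optional[int] = None
    cur_end = 0
    for start, end in ordered:
        if cur_start is None or start > cur_end + 1:
            if cur_start is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_start is not None:
        total += cur_end - cur_start + 1
    return total


def coding_fraction(bundle: GenomeBundle) -> float:
    """Union length of gene intervals / total scaffold length (overlaps merged)."""
    total = bundle.total_length
    if total == 0:
        return 0.0
    by_scaffold: Dict[str, List[Tuple[int, int]]] = {}
    for g in bundle.genes:
        by_scaffold.setdefault(g.scaffold_id, []).append((g.start, g.end))
    covered = sum(merged_interval_length(iv) for iv in by_scaffold.values())
    return covered / total


def genome_feature_table(
    bundles: Sequence[GenomeBundle],
    designated_gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-taxon genome features, indexed by taxon.

    Columns: genome_size_bp, n_proteins, gc_percent, coding_fraction,
    ortholog_length_sum (total length of a designated gene set, e.g. the
    single-copy phylogenomic markers).
    """
    if not bundles:
        raise EmptyInputError("no genome bundles supplied")
    rows = {}
    for bundle in bundles:
        bundle.validate()
        by_id = {g.gene_id: g for g in bundle.genes}
        designated = designated_gene_sets.get(bundle.taxon_id, [])
        missing = [g for g in designated if g not in by_id]
        if missing:
            raise ValidationError(
                f"{bundle.taxon_id}: designated gene {missing[0]!r} absent from bundle"
            )
        rows[bundle.taxon_id] = {
            "genome_size_bp": bundle.total_length,
            "n_proteins": len(bundle.genes),
            "gc_percent": gc_percent(seq for _, seq in bundle.scaffolds),
            "coding_fraction": coding_fraction(bundle),
            "ortholog_length_sum": sum(by_id[g].length for g in designated),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
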