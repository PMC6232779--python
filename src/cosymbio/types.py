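"""Domain types shared across the pipeline.

The in-memory containers are deliberately small dataclasses: a genome is a
set of scaffolds plus a gene table, ortholog clusters are an ordered list of
``(cluster_id, {taxon: [gene, ...]})`` entries, and a blast hit carries the
subject's ranked taxonomic lineage alongside the usual tabular columns.
Validation lives on the types themselves (``validate()``) so every reader in
:mod:`cosymbio.io_formats` and every generator in
:mod:`cosymbio.synthetic_data` enforces the same invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .errors import ValidationError

#: Taxonomic ranks, most inclusive first.  Lineages must be filled
#: contiguously from the left (no gaps).
RANKS: Tuple[str, ...] = ("superkingdom", "phylum", "class", "order", "family", "genus")

FUNCTIONAL_CATEGORIES = (
    "known_function",
    "general_prediction_only",
    "unknown_function",
    "transposase",
)

PCR_VALUES = ("pos", "neg", "na")
SEX_VALUES = ("F", "M", "unknown")


@dataclass(frozen=True)
class Lineage:
    """Ranked taxonomic lineage of a blast subject (or of a host genome).

    Ranks are filled contiguously from superkingdom down; an entirely empty
    lineage is allowed and means "unranked".
    """

    superkingdom: Optional[str] = None
    phylum: Optional[str] = None
    class_: Optional[str] = None
    order: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None

    _ATTRS = ("superkingdom", "phylum", "class_", "order", "family", "genus")

    def get(self, rank: str) -> Optional[str]:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        return getattr(self, self._ATTRS[RANKS.index(rank)])

    def as_tuple(self) -> Tuple[Optional[str], ...]:
        return tuple(getattr(self, a) for a in self._ATTRS)

    @property
    def is_empty(self) -> bool:
        return all(v is None for v in self.as_tuple())

    def validate(self) -> "Lineage":
        seen_gap = False
        for name in self.as_tuple():
            if name is None:
                seen_gap = True
            elif seen_gap:
                raise ValidationError(
                    f"lineage ranks must be contiguous from superkingdom down: {self}"
                )
        return self

    def to_string(self) -> str:
        """Semicolon-delimited, fixed rank order, empty string for absent ranks."""
        return ";".join(v if v is not None else "" for v in self.as_tuple())

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        parts = text.split(";")
        if len(parts) > len(RANKS):
            raise ValidationError(f"lineage has more than {len(RANKS)} ranks: {text!r}")
        parts += [""] * (len(RANKS) - len(parts))
        values = [p.strip() or None for p in parts]
        return cls(*values).validate()


@dataclass
class GeneRecord:
    """One annotated gene: 1-based inclusive coordinates on a scaffold."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    functional_category: str = "unknown_function"

    def validate(self) -> "GeneRecord":
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.functional_category not in FUNCTIONAL_CATEGORIES:
            raise ValidationError(
                f"gene {self.gene_id}: bad functional_category "
                f"{self.functional_category!r}"
            )
        return self

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeBundle:
    """Sequences + gene annotations + metadata for one taxon."""

    taxon_id: str
    scaffolds: List[Tuple[str, str]] = field(default_factory=list)
    genes: List[GeneRecord] = field(default_factory=list)
    is_plasmid: bool = False
    metadata: Dict[str, str] = field(default_factory=dict)

    def validate(self) -> "GenomeBundle":
        ids = [sid for sid, _ in self.scaffolds]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"{self.taxon_id}: duplicate scaffold ids")
        lengths = {sid: len(seq) for sid, seq in self.scaffolds}
        for g in self.genes:
            g.validate()
            if g.scaffold_id not in lengths:
                raise ValidationError(
                    f"gene {g.gene_id} references unknown scaffold {g.scaffold_id}"
                )
            if g.end > lengths[g.scaffold_id]:
                raise ValidationError(
                    f"gene {g.gene_id} end {g.end} exceeds scaffold "
                    f"{g.scaffold_id} length {lengths[g.scaffold_id]}"
                )
        return self

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.scaffolds)


@dataclass
class ClusterTable:
    """Ortholog cluster membership: ordered ``(cluster_id, {taxon: [genes]})``."""

    clusters: List[Tuple[str, Dict[str, List[str]]]] = field(default_factory=list)

    def validate(self) -> "ClusterTable":
        seen_clusters = set()
        seen_genes: Dict[Tuple[str, str], str] = {}
        for cid, members in self.clusters:
            if cid in seen_clusters:
                raise ValidationError(f"duplicate cluster id {cid!r}")
            seen_clusters.add(cid)
            if not members or all(len(v) == 0 for v in members.values()):
                raise ValidationError(f"cluster {cid!r} has no members")
            for taxon, genes in members.items():
                if not genes:
                    raise ValidationError(f"cluster {cid!r}: empty member list for {taxon!r}")
                for gene in genes:
                    key = (taxon, gene)
                    if key in seen_genes:
                        raise ValidationError(
                            f"gene {taxon}|{gene} assigned to both cluster "
                            f"{seen_genes[key]!r} and {cid!r}"
                        )
                    seen_genes[key] = cid
        return self

    def gene_to_cluster(self) -> Dict[Tuple[str, str], str]:
        """Map ``(taxon, gene_id)`` to its cluster id."""
        out: Dict[Tuple[str, str], str] = {}
        for cid, members in self.clusters:
            for taxon, genes in members.items():
                for gene in genes:
                    out[(taxon, gene)] = cid
        return out

    @property
    def cluster_ids(self) -> List[str]:
        return [cid for cid, _ in self.clusters]


@dataclass(frozen=True)
class HitRecord:
    """One taxonomy-annotated blast hit for a query gene."""

    query_gene_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    bit_score: float
    e_value: float
    lineage: Lineage = field(default_factory=Lineage)

    def validate(self) -> "HitRecord":
        import math

        if not math.isfinite(self.bit_score) or self.bit_score < 0:
            raise ValidationError(
                f"hit {self.query_gene_id}->{self.subject_id}: bad bit score "
                f"{self.bit_score}"
            )
        if self.e_value < 0:
            raise ValidationError(
                f"hit {self.query_gene_id}->{self.subject_id}: negative e-value"
            )
        if not (0 <= self.percent_identity <= 100):
            raise ValidationError(
                f"hit {self.query_gene_id}->{self.subject_id}: percent identity "
                f"{self.percent_identity} outside [0, 100]"
            )
        self.lineage.validate()
        if self.lineage.phylum is None and not self.lineage.is_empty:
            raise ValidationError(
                f"hit {self.query_gene_id}->{self.subject_id}: lineage must have "
                "a phylum or be fully unranked"
            )
        return self


def hit_sort_key(hit: HitRecord) -> Tuple[float, float, str]:
    """Total order on hits: descending bit score, ascending e-value, subject id."""
    return (-hit.bit_score, hit.e_value, hit.subject_id)


@dataclass(frozen=True)
class PanelRow:
    """One individual's PCR assay results (two symbiont assays + host control)."""

    individual_id: str
    sex: str = "unknown"
    cardinium_pcr: str = "na"
    wolbachia_pcr: str = "na"
    host_18s_pcr: str = "na"

    def validate(self) -> "PanelRow":
        if not self.individual_id:
            raise ValidationError("individual_id must be non-empty")
        if self.sex not in SEX_VALUES:
            raise ValidationError(f"{self.individual_id}: bad sex {self.sex!r}")
        for name in ("cardinium_pcr", "wolbachia_pcr", "host_18s_pcr"):
            if getattr(self, name) not in PCR_VALUES:
                raise ValidationError(
                    f"{self.individual_id}: bad {name} value {getattr(self, name)!r}"
                )
        return self


@dataclass
class PcrPanel:
    """Per-individual PCR panel; individual ids unique, at least one row."""

    rows: List[PanelRow] = field(default_factory=list)

    def validate(self) -> "PcrPanel":
        if not self.rows:
            raise ValidationError("PCR panel must have at least one row")
        ids = [r.individual_id for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate individual_id in PCR panel")
        for r in self.rows:
            r.validate()
        return self

    def __len__(self) -> int:
        return len(self.rows)
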