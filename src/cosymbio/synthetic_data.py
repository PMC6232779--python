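"""Planted-truth simulator for every input the pipeline consumes.

The generator emulates the study design the package analyses: a focal
endosymbiont genome plus two ingroup relatives and outgroup taxa sharing a
universal core, an ingroup-specific core, taxon-unique genes, copy-number
expansions, and planted HGT genes with known donor lineages; a
per-individual PCR panel with configurable prevalence and (optionally
nested) coinfection; and a coverage profile algebraically consistent with a
chosen cells-per-host count.

Defaults mirror the study conditions: 127 assayed individuals with
prevalences 123/127 and 62/127 (coinfection nested within the first
symbiont), host read depth 32.97X with 1,000 cells per host, and a planted
HGT panel of 50 recent / 25 older / 125 non-HGT genes.

Everything is drawn from one seeded :class:`numpy.random.Generator`, so a
given (seed, config) pair yields byte-identical output files.

Bit-score model: self-phylum hits are Normal(mu_flank, sd) truncated at 0;
planted donor hits are placed strictly above the gene's self-phylum scores
(offset |Normal((ratio-1)*mu_flank, sd)|), echoing the observation that
transferred genes score higher against their donor lineage than the
background does against its own phylum.  Gene lengths are uniform on
300-1500 bp with 50-200 bp intergenic gaps; both are recorded in the config
echo written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import io_formats
from .errors import UsageError, ValidationError
from .infection_stats import CoverageProfile
from .types import (
    ClusterTable,
    GeneRecord,
    GenomeBundle,
    HitRecord,
    Lineage,
    PanelRow,
    PcrPanel,
    hit_sort_key,
)

logger = logging.getLogger("cosymbio.synth")

#: Lineage of the focal clade (an intracellular Bacteroidetes of the
#: Amoebophilaceae, genus *Cardinium*).
SELF_LINEAGE = Lineage(
    "Bacteria", "Bacteroidetes", "Cytophagia", "Cytophagales",
    "Amoebophilaceae", "Cardinium",
)

#: Self-phylum but non-self-genus lineages (other Cytophagales families).
SELF_PHYLUM_LINEAGES = (
    Lineage("Bacteria", "Bacteroidetes", "Cytophagia", "Cytophagales",
            "Cytophagaceae", "Cytophaga"),
    Lineage("Bacteria", "Bacteroidetes", "Cytophagia", "Cytophagales",
            "Cyclobacteriaceae", "Cyclobacterium"),
    Lineage("Bacteria", "Bacteroidetes", "Cytophagia", "Cytophagales",
            "Flammeovirgaceae", "Flammeovirga"),
)

#: Default donor lineages for planted transfers: a gammaproteobacterial
#: insect symbiont, the Rickettsiales, a nematode, and a firmicute.
DEFAULT_DONOR_LINEAGES = (
    Lineage("Bacteria", "Proteobacteria", "Gammaproteobacteria",
            "Enterobacterales", "Yersiniaceae", "Regiella"),
    Lineage("Bacteria", "Proteobacteria", "Alphaproteobacteria",
            "Rickettsiales", "Anaplasmataceae", "Wolbachia"),
    Lineage("Eukaryota", "Nematoda", "Chromadorea", "Rhabditida",
            "Pratylenchidae", "Pratylenchus"),
    Lineage("Bacteria", "Firmicutes", "Bacilli", "Bacillales",
            "Bacillaceae", "Bacillus"),
)

FUNCTIONAL_CATEGORY_WEIGHTS = {
    "known_function": 0.40,
    "general_prediction_only": 0.14,
    "unknown_function": 0.41,
    "transposase": 0.05,
}

PRODUCTS = {
    "known_function": "conserved metabolic enzyme",
    "general_prediction_only": "putative membrane protein",
    "unknown_function": "hypothetical protein",
    "transposase": "IS66 family transposase",
}


@dataclass(frozen=True)
class TaxonSpec:
    name: str
    genome_size_bp: int
    role: str  # focal | ingroup | outgroup


@dataclass(frozen=True)
class ExpansionSpec:
    n_clusters: int = 5
    copy_range: Tuple[int, int] = (3, 8)  # inclusive, focal-taxon copies


@dataclass(frozen=True)
class HgtSpec:
    n_recent: int = 50
    n_older: int = 25
    n_non: int = 125
    donor_lineages: Tuple[Lineage, ...] = DEFAULT_DONOR_LINEAGES
    flank_bitscore_mean: float = 150.0
    bitscore_sd: float = 20.0
    bitscore_ratio: float = 1.5  # donor hits sit above flank scores by ~this factor
    n_hits: int = 12
    emit_trees: bool = False


@dataclass(frozen=True)
class CoverageSpec:
    cells_per_host: int = 1000
    cells: Mapping[str, float] = field(
        default_factory=lambda: {"cardinium": 437.0, "wolbachia": 243.0}
    )
    host_depth: float = 32.97


def _default_taxa() -> Tuple[TaxonSpec, ...]:
    return (
        TaxonSpec("cPpe", 1_358_214, "focal"),
        TaxonSpec("cEper1", 887_000, "ingroup"),
        TaxonSpec("cBtQ1", 1_013_000, "ingroup"),
        TaxonSpec("Aasi", 1_884_000, "outgroup"),
        TaxonSpec("Chut", 4_433_000, "outgroup"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # PCR panel
    n_individuals: int = 127
    true_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"cardinium": 123 / 127, "wolbachia": 62 / 127}
    )
    nested_coinfection: bool = True
    control_failure_rate: float = 0.0
    female_fraction: float = 100 / 127
    # pangenome structure
    taxa: Tuple[TaxonSpec, ...] = field(default_factory=_default_taxa)
    n_core_universal: int = 60
    n_ingroup_core: int = 20
    n_taxon_unique: Mapping[str, int] = field(
        default_factory=lambda: {"cPpe": 15, "cEper1": 10, "cBtQ1": 10,
                                 "Aasi": 10, "Chut": 10}
    )
    expansion: ExpansionSpec = ExpansionSpec()
    hgt: HgtSpec = HgtSpec()
    coverage: CoverageSpec = CoverageSpec()
    # layout
    gene_length_range: Tuple[int, int] = (300, 1500)
    intergenic_gap_range: Tuple[int, int] = (50, 200)
    scaffold_capacity: int = 400  # genes per scaffold
    gc_content: float = 0.358
    flank_pad: int = 2  # guaranteed background genes between planted candidates

    def validate(self) -> "SimulationConfig":
        for name, p in self.true_prevalence.items():
            if not (0 <= p <= 1):
                raise ValidationError(f"prevalence {name}={p} outside [0, 1]")
        if not (0 <= self.control_failure_rate <= 1):
            raise ValidationError("control_failure_rate outside [0, 1]")
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        roles = [t.role for t in self.taxa]
        if roles.count("focal") != 1:
            raise ValidationError("exactly one focal taxon required")
        for t in self.taxa:
            if t.role not in ("focal", "ingroup", "outgroup"):
                raise ValidationError(f"bad role {t.role!r} for taxon {t.name}")
            if t.genome_size_bp < 1:
                raise ValidationError(f"{t.name}: genome size must be positive")
        if self.hgt.n_recent < 0 or self.hgt.n_older < 0 or self.hgt.n_non < 0:
            raise ValidationError("hgt counts must be >= 0")
        return self

    @property
    def focal(self) -> str:
        return next(t.name for t in self.taxa if t.role == "focal")

    @property
    def ingroup(self) -> List[str]:
        return [t.name for t in self.taxa if t.role in ("focal", "ingroup")]

    @property
    def outgroups(self) -> List[str]:
        return [t.name for t in self.taxa if t.role == "outgroup"]


@dataclass
class TruthBundle:
    """Ground truth implied by a simulation, sufficient to check every stage."""

    infection_states: Dict[str, Dict[str, bool]]  # individual -> symbiont -> infected
    true_prevalence: Dict[str, float]
    true_cells: Dict[str, float]
    hgt_categories: Dict[str, str]          # planted focal gene -> category
    hgt_donor_phylum: Dict[str, Optional[str]]
    cluster_labels: Dict[str, str]          # cluster -> partition label
    expansion_copies: Dict[str, Dict[str, int]]

    def to_json_dict(self) -> dict:
        return {
            "infection_states": self.infection_states,
            "true_prevalence": self.true_prevalence,
            "true_cells": self.true_cells,
            "hgt_categories": self.hgt_categories,
            "hgt_donor_phylum": self.hgt_donor_phylum,
            "cluster_labels": self.cluster_labels,
            "expansion_copies": self.expansion_copies,
        }


@dataclass
class SyntheticPangenome:
    bundles: Dict[str, GenomeBundle]
    cluster_table: ClusterTable
    hit_tables: Dict[str, List[HitRecord]]  # focal query gene -> hits
    trees: Dict[str, str]                   # focal gene -> newick
    expected_lineage: Lineage


@dataclass
class SimulationResult:
    config: SimulationConfig
    panel: PcrPanel
    profile: CoverageProfile
    pangenome: SyntheticPangenome
    truth: TruthBundle


# ---------------------------------------------------------------------------
# PCR panel


def gen_pcr_panel(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[PcrPanel, Dict[str, Dict[str, bool]]]:
    """Bernoulli panel draw; returns the panel and per-individual truth.

    With nested coinfection the second symbiont is drawn only among carriers
    of the first, at rate p2/p1 so the marginal prevalence stays p2.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p1 = config.true_prevalence.get("cardinium", 0.0)
    p2 = config.true_prevalence.get("wolbachia", 0.0)
    if config.nested_coinfection and p2 > p1:
        raise ValidationError("nested coinfection requires p(wolbachia) <= p(cardinium)")
    rows: List[PanelRow] = []
    truth: Dict[str, Dict[str, bool]] = {}
    for i in range(config.n_individuals):
        ind = f"ind{i + 1:05d}"
        sex = "F" if rng.random() < config.female_fraction else "M"
        c_inf = rng.random() < p1
        if config.nested_coinfection:
            w_inf = c_inf and (p1 > 0) and (rng.random() < p2 / p1)
        else:
            w_inf = rng.random() < p2
        control_ok = rng.random() >= config.control_failure_rate
        rows.append(
            PanelRow(
                individual_id=ind,
                sex=sex,
                cardinium_pcr="pos" if c_inf else "neg",
                wolbachia_pcr="pos" if w_inf else "neg",
                host_18s_pcr="pos" if control_ok else "neg",
            )
        )
        truth[ind] = {"cardinium": bool(c_inf), "wolbachia": bool(w_inf)}
    return PcrPanel(rows).validate(), truth


# ---------------------------------------------------------------------------
# Coverage profile


def gen_coverage_profile(config: SimulationConfig) -> CoverageProfile:
    """Deterministic inversion of the titer formula.

    Emits symbiont coverages such that the as-printed intensity estimator
    recovers the configured cells-per-infected-host exactly:
    ``coverage = cells * (host_depth / cells_per_host) / prevalence``.
    """
    config.validate()
    spec = config.coverage
    per_cell = spec.host_depth / spec.cells_per_host
    coverage: Dict[str, float] = {}
    for name in spec.cells:
        cells = float(spec.cells[name])
        prev = config.true_prevalence.get(name, 0.0)
        if cells == 0:
            coverage[name] = 0.0
        elif prev <= 0:
            raise ValidationError(
                f"{name}: positive cell count with zero prevalence is inconsistent"
            )
        else:
            coverage[name] = cells * per_cell / prev
    return CoverageProfile(
        symbiont_coverage=coverage,
        host_single_copy_coverage=spec.host_depth,
        prevalence={name: config.true_prevalence.get(name, 0.0) for name in spec.cells},
        cells_per_host=spec.cells_per_host,
    ).validate()


# ---------------------------------------------------------------------------
# Pangenome, hit tables, trees


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=length, p=probs))


def _truncnorm_positive(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    draws = rng.normal(mean, sd, size=size)
    while (draws <= 0).any():
        bad = draws <= 0
        draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return draws


class _GeneFactory:
    """Allocates deterministic per-taxon gene ids."""

    def __init__(self) -> None:
        self.counters: Dict[str, int] = {}

    def new(self, taxon: str) -> str:
        n = self.counters.get(taxon, 0) + 1
        self.counters[taxon] = n
        return f"{taxon}_g{n:05d}"


def gen_pangenome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[SyntheticPangenome, TruthBundle]:
    """Generate genomes, clusters, hit tables and (optionally) gene trees.

    Planted HGT genes are focal-taxon singletons (no cluster membership), so
    candidate identification finds them; their hit tables follow the
    category's taxonomy pattern.  Focal genes are laid out so that every
    planted candidate has at least ``flank_pad`` non-planted neighbours on
    each side, guaranteeing the flanking-gene taxonomy control reflects the
    genomic background.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    focal = config.focal
    ingroup = config.ingroup            # includes focal
    outgroups = config.outgroups
    all_taxa = [t.name for t in config.taxa]
    factory = _GeneFactory()

    clusters: List[Tuple[str, Dict[str, List[str]]]] = []
    cluster_labels: Dict[str, str] = {}
    expansion_copies: Dict[str, Dict[str, int]] = {}
    gene_category: Dict[Tuple[str, str], str] = {}

    cats = list(FUNCTIONAL_CATEGORY_WEIGHTS)
    cat_p = np.array([FUNCTIONAL_CATEGORY_WEIGHTS[c] for c in cats])

    def draw_category() -> str:
        return cats[int(rng.choice(len(cats), p=cat_p))]

    def add_cluster(cid: str, members: Dict[str, List[str]], label: str,
                    category: Optional[str] = None) -> None:
        clusters.append((cid, members))
        cluster_labels[cid] = label
        cat = category or draw_category()
        for taxon, genes in members.items():
            for g in genes:
                gene_category[(taxon, g)] = cat

    for i in range(config.n_core_universal):
        add_cluster(
            f"OG_U{i:04d}",
            {t: [factory.new(t)] for t in all_taxa},
            "universal_core",
        )
    for i in range(config.n_ingroup_core):
        add_cluster(
            f"OG_I{i:04d}",
            {t: [factory.new(t)] for t in ingroup},
            "ingroup_core",
        )
    for taxon in all_taxa:
        for i in range(config.n_taxon_unique.get(taxon, 0)):
            add_cluster(
                f"OG_Q_{taxon}_{i:03d}",
                {taxon: [factory.new(taxon)]},
                f"unique:{taxon}",
            )
    lo, hi = config.expansion.copy_range
    anchor_out = outgroups[0] if outgroups else None
    for i in range(config.expansion.n_clusters):
        n_copies = int(rng.integers(lo, hi + 1))
        members = {focal: [factory.new(focal) for _ in range(n_copies)]}
        for t in ingroup:
            if t != focal:
                members[t] = [factory.new(t)]
        if anchor_out is not None:
            members[anchor_out] = [factory.new(anchor_out)]
        cid = f"OG_E{i:04d}"
        add_cluster(cid, members, "expansion", category="known_function")
        expansion_copies[cid] = {t: len(g) for t, g in members.items()}

    # planted HGT genes: focal singletons, no cluster membership
    hgt_genes: List[Tuple[str, str]] = []  # (gene_id, category)
    hgt_categories: Dict[str, str] = {}
    hgt_donor_phylum: Dict[str, Optional[str]] = {}
    for category, count in (
        ("recent_hgt", config.hgt.n_recent),
        ("older_hgt", config.hgt.n_older),
        ("non_hgt", config.hgt.n_non),
    ):
        for _ in range(count):
            gid = factory.new(focal)
            hgt_genes.append((gid, category))
            hgt_categories[gid] = category
            gene_category[(focal, gid)] = draw_category()

    # spacer budget: every planted candidate needs flank_pad non-planted
    # neighbours on each side in the interleaved layout below
    per_taxon_genes: Dict[str, List[str]] = {t: [] for t in all_taxa}
    for cid, members in clusters:
        for taxon, genes in members.items():
            per_taxon_genes[taxon].extend(genes)
    n_planted = len(hgt_genes)
    pool = list(per_taxon_genes[focal])
    needed = config.flank_pad * n_planted + (config.flank_pad if n_planted else 0)
    n_background = max(0, needed - len(pool))
    for i in range(n_background):
        gid = factory.new(focal)
        members = {focal: [gid]}
        if anchor_out is not None:
            members[anchor_out] = [factory.new(anchor_out)]
        add_cluster(f"OG_B{i:04d}", members, "background")
    per_taxon_genes = {t: [] for t in all_taxa}
    for cid, members in clusters:
        for taxon, genes in members.items():
            per_taxon_genes[taxon].extend(genes)

    cluster_table = ClusterTable(clusters).validate()

    # ---- layout: interleave planted genes among shuffled non-planted genes
    layouts: Dict[str, List[str]] = {}
    for taxon in all_taxa:
        genes = list(per_taxon_genes[taxon])
        if taxon == focal:
            planted = [g for g, _ in hgt_genes]
            rng.shuffle(planted)
            spacers = genes  # focal cluster genes (planted are not in clusters)
            rng.shuffle(spacers)
            order: List[str] = []
            si = 0
            for g in planted:
                order.extend(spacers[si : si + config.flank_pad])
                si += config.flank_pad
                order.append(g)
            order.extend(spacers[si:])
            if n_planted and len(spacers) - si < config.flank_pad:
                raise ValidationError("insufficient spacer genes for flanking layout")
            layouts[taxon] = order
        else:
            rng.shuffle(genes)
            layouts[taxon] = genes

    glo, ghi = config.gene_length_range
    ilo, ihi = config.intergenic_gap_range
    bundles: Dict[str, GenomeBundle] = {}
    gene_records: Dict[str, List[GeneRecord]] = {}
    for spec in config.taxa:
        taxon = spec.name
        order = layouts[taxon]
        records: List[GeneRecord] = []
        scaffolds: List[Tuple[str, str]] = []
        for chunk_idx in range(0, max(1, len(order)), config.scaffold_capacity):
            chunk = order[chunk_idx : chunk_idx + config.scaffold_capacity]
            sid = f"{taxon}_sc{chunk_idx // config.scaffold_capacity + 1}"
            pos = 0
            for gid in chunk:
                gap = int(rng.integers(ilo, ihi + 1))
                length = int(rng.integers(glo, ghi + 1))
                start = pos + gap + 1
                end = start + length - 1
                strand = "+" if rng.random() < 0.5 else "-"
                cat = gene_category.get((taxon, gid), "unknown_function")
                records.append(
                    GeneRecord(
                        gene_id=gid,
                        scaffold_id=sid,
                        start=start,
                        end=end,
                        strand=strand,
                        product=PRODUCTS[cat],
                        functional_category=cat,
                    )
                )
                pos = end
            tail = int(rng.integers(ilo, ihi + 1))
            scaffolds.append((sid, _random_sequence(rng, pos + tail, config.gc_content)))
        bundles[taxon] = GenomeBundle(
            taxon_id=taxon,
            scaffolds=scaffolds,
            genes=records,
            metadata={"source": "cosymbio.synthetic_data", "role": spec.role},
        ).validate()
        gene_records[taxon] = records

    # ---- hit tables for every focal gene
    hit_tables: Dict[str, List[HitRecord]] = {}
    trees: Dict[str, str] = {}
    subject_counter = [0]
    other_strains = [t for t in ingroup if t != focal] or ["relative"]

    def subject(genus: str) -> str:
        subject_counter[0] += 1
        return f"{genus}_s{subject_counter[0]:06d}"

    def make_hits(gid: str, entries: List[Tuple[Lineage, float, str]]) -> None:
        recs = []
        for lineage, score, genus in entries:
            score = round(float(score), 1)
            recs.append(
                HitRecord(
                    query_gene_id=gid,
                    subject_id=subject(genus),
                    percent_identity=round(float(rng.uniform(30, 95)), 1),
                    alignment_length=int(rng.integers(100, 500)),
                    bit_score=score,
                    e_value=float(f"{10 ** (-score / 10):.3e}") if score < 1000 else 0.0,
                    lineage=lineage,
                ).validate()
            )
        hit_tables[gid] = sorted(recs, key=hit_sort_key)

    def self_pattern(gid: str) -> None:
        n = config.hgt.n_hits
        scores = np.sort(
            _truncnorm_positive(rng, config.hgt.flank_bitscore_mean,
                                config.hgt.bitscore_sd, n)
        )[::-1]
        entries: List[Tuple[Lineage, float, str]] = []
        for j, score in enumerate(scores):
            if j < 2:
                strain = other_strains[j % len(other_strains)]
                entries.append((SELF_LINEAGE, score, strain))
            else:
                lin = SELF_PHYLUM_LINEAGES[int(rng.integers(len(SELF_PHYLUM_LINEAGES)))]
                entries.append((lin, score, lin.genus))
        make_hits(gid, entries)

    donors = list(config.hgt.donor_lineages)
    mu_gap = (config.hgt.bitscore_ratio - 1.0) * config.hgt.flank_bitscore_mean

    def recent_pattern(gid: str) -> Lineage:
        donor = donors[int(rng.integers(len(donors)))]
        n_self = max(2, config.hgt.n_hits // 3)
        n_donor = config.hgt.n_hits - n_self
        self_scores = _truncnorm_positive(
            rng, config.hgt.flank_bitscore_mean, config.hgt.bitscore_sd, n_self
        )
        top = float(self_scores.max())
        donor_scores = top + 1.0 + np.abs(rng.normal(mu_gap, config.hgt.bitscore_sd, n_donor))
        entries = [(donor, s, donor.genus) for s in donor_scores]
        for s in self_scores:
            lin = SELF_PHYLUM_LINEAGES[int(rng.integers(len(SELF_PHYLUM_LINEAGES)))]
            entries.append((lin, s, lin.genus))
        make_hits(gid, entries)
        return donor

    def older_pattern(gid: str) -> Lineage:
        donor = donors[int(rng.integers(len(donors)))]
        n_genus = 2
        n_donor = config.hgt.n_hits - n_genus
        donor_scores = _truncnorm_positive(
            rng,
            config.hgt.bitscore_ratio * config.hgt.flank_bitscore_mean,
            config.hgt.bitscore_sd,
            n_donor,
        )
        top = float(donor_scores.max())
        genus_scores = top + 1.0 + np.abs(rng.normal(20.0, 10.0, n_genus))
        entries = [
            (SELF_LINEAGE, s, other_strains[j % len(other_strains)])
            for j, s in enumerate(genus_scores)
        ]
        entries.extend((donor, s, donor.genus) for s in donor_scores)
        make_hits(gid, entries)
        return donor

    planted_set = set(hgt_categories)
    for g in gene_records[focal]:
        gid = g.gene_id
        if gid not in planted_set:
            self_pattern(gid)
    for gid, category in hgt_genes:
        if category == "non_hgt":
            self_pattern(gid)
            hgt_donor_phylum[gid] = None
        elif category == "recent_hgt":
            hgt_donor_phylum[gid] = recent_pattern(gid).phylum
        else:
            hgt_donor_phylum[gid] = older_pattern(gid).phylum

    if config.hgt.emit_trees:
        for gid, category in hgt_genes:
            if category == "recent_hgt":
                sister = f"hit_{gid}@" + hit_tables[gid][0].lineage.to_string().replace(";", "|")
            else:
                sister = f"hit_{gid}@" + SELF_LINEAGE.to_string().replace(";", "|")
            bact = "bg1@" + SELF_PHYLUM_LINEAGES[0].to_string().replace(";", "|")
            out = "out1@" + DEFAULT_DONOR_LINEAGES[3].to_string().replace(";", "|")
            trees[gid] = f"((query:1,{sister}:1):1,({bact}:1,{out}:1):1);"

    pangenome = SyntheticPangenome(
        bundles=bundles,
        cluster_table=cluster_table,
        hit_tables=hit_tables,
        trees=trees,
        expected_lineage=SELF_LINEAGE,
    )
    truth = TruthBundle(
        infection_states={},
        true_prevalence=dict(config.true_prevalence),
        true_cells={k: float(v) for k, v in config.coverage.cells.items()},
        hgt_categories=hgt_categories,
        hgt_donor_phylum=hgt_donor_phylum,
        cluster_labels=cluster_labels,
        expansion_copies=expansion_copies,
    )
    return pangenome, truth


# ---------------------------------------------------------------------------
# Orchestration


def generate(config: SimulationConfig) -> SimulationResult:
    """Run every generator off one seeded stream (panel, coverage, pangenome)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel, infection_truth = gen_pcr_panel(config, rng)
    profile = gen_coverage_profile(config)
    pangenome, truth = gen_pangenome(config, rng)
    truth.infection_states = infection_truth
    return SimulationResult(
        config=config, panel=panel, profile=profile, pangenome=pangenome, truth=truth
    )


def config_to_dict(config: SimulationConfig) -> dict:
    def convert(obj):
        if isinstance(obj, Lineage):
            return obj.to_string()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                f.name: convert(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            }
        if isinstance(obj, Mapping):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    out = {}
    for f in dataclasses.fields(config):
        out[f.name] = convert(getattr(config, f.name))
    return out


def config_from_dict(data: Optional[Mapping]) -> SimulationConfig:
    """Build a config from a (possibly partial) plain mapping, e.g. YAML.

    Unknown keys are rejected; nested sections (``taxa``, ``expansion``,
    ``hgt``, ``coverage``) override whole sub-specs.  Donor lineages are
    given as semicolon-delimited rank strings.
    """
    if not data:
        return SimulationConfig()
    data = dict(data)
    kwargs: Dict[str, object] = {}
    if "taxa" in data:
        kwargs["taxa"] = tuple(
            TaxonSpec(t["name"], int(t["genome_size_bp"]), t["role"])
            for t in data.pop("taxa")
        )
    if "expansion" in data:
        sub = dict(data.pop("expansion"))
        if "copy_range" in sub:
            sub["copy_range"] = tuple(sub["copy_range"])
        kwargs["expansion"] = ExpansionSpec(**sub)
    if "hgt" in data:
        sub = dict(data.pop("hgt"))
        if "donor_lineages" in sub:
            sub["donor_lineages"] = tuple(
                Lineage.from_string(s) for s in sub["donor_lineages"]
            )
        kwargs["hgt"] = HgtSpec(**sub)
    if "coverage" in data:
        kwargs["coverage"] = CoverageSpec(**dict(data.pop("coverage")))
    allowed = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise UsageError(f"unknown simulation config keys: {sorted(unknown)}")
    for key, value in data.items():
        if key in ("gene_length_range", "intergenic_gap_range"):
            value = tuple(value)
        kwargs[key] = value
    return SimulationConfig(**kwargs).validate()


def write_simulation(result: SimulationResult, out_dir) -> None:
    """Write the full input file set plus ``truth.json`` and a config echo."""
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "hits").mkdir(exist_ok=True)
    io_formats.write_pcr_panel(out / "panel.tsv", result.panel)
    io_formats.write_coverage_profile(out / "coverage.yaml", result.profile)
    io_formats.write_cluster_groups(out / "clusters.txt", result.pangenome.cluster_table)
    for taxon in sorted(result.pangenome.bundles):
        bundle = result.pangenome.bundles[taxon]
        io_formats.write_fasta(out / "genomes" / f"{taxon}.fasta", bundle.scaffolds)
        io_formats.write_gene_table(
            out / "genomes" / f"{taxon}.genes.tsv", bundle.genes, dialect="tsv"
        )
    focal = result.config.focal
    io_formats.write_hit_table(out / "hits" / f"{focal}.tsv", result.pangenome.hit_tables)
    if result.pangenome.trees:
        (out / "trees").mkdir(exist_ok=True)
        for gid in sorted(result.pangenome.trees):
            with open(out / "trees" / f"{gid}.nwk", "w", encoding="utf-8",
                      newline="\n") as handle:
                handle.write(result.pangenome.trees[gid] + "\n")
    with open(out / "truth.json", "w", encoding="utf-8", newline="\n") as handle:
        json.dump(result.truth.to_json_dict(), handle, indent=1, sort_keys=True)
        handle.write("\n")
    with open(out / "config.json", "w", encoding="utf-8", newline="\n") as handle:
        json.dump(config_to_dict(result.config), handle, indent=1, sort_keys=True)
        handle.write("\n")
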