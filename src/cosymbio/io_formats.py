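"""Readers and writers for every external representation the pipeline touches.

Formats are all plain text, UTF-8, LF newlines:

* FASTA (plain; wrapped or unwrapped on read, wrapped at 70 columns on write)
* gene tables as GFF3 (``gene``/``CDS`` rows only) or a simple TSV dialect
* ortholog clusters in the OrthoMCL "groups" dialect
  (``clusterId: taxon|gene taxon|gene ...``)
* tabular blast hits: the 12 standard columns plus a semicolon-delimited
  ranked-lineage column
* PCR panel TSV, coverage-profile YAML

Readers validate on the way in and raise the exceptions in
:mod:`cosymbio.errors`; each ``write_*`` is the exact inverse of its
``read_*`` (round-trip property-tested).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import FormatError, ParseError, UsageError, ValidationError
from .types import (
    ClusterTable,
    GeneRecord,
    HitRecord,
    Lineage,
    PanelRow,
    PcrPanel,
    hit_sort_key,
)

logger = logging.getLogger("cosymbio.io")

PathLike = Union[str, Path]

HIT_COLUMNS = (
    "query",
    "subject",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "lineage",
)

GENE_TSV_COLUMNS = (
    "gene_id",
    "scaffold_id",
    "start",
    "end",
    "strand",
    "product",
    "functional_category",
)

PANEL_COLUMNS = ("individual_id", "sex", "cardinium_pcr", "wolbachia_pcr", "host_18s_pcr")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> List[Tuple[str, str]]:
    """Read FASTA records as ``(id, SEQUENCE)`` tuples, in file order.

    Ids are the first whitespace-delimited header token; sequences are
    uppercased.  Empty files and duplicate ids are rejected.
    """
    records: List[Tuple[str, str]] = []
    seen = set()
    with open(path, encoding="utf-8") as handle:
        for header, seq in SimpleFastaParser(handle):
            rec_id = header.split()[0] if header.split() else ""
            if not rec_id:
                raise ParseError(f"{path}: FASTA header with no id")
            if rec_id in seen:
                raise ValidationError(f"{path}: duplicate FASTA id {rec_id!r}")
            seen.add(rec_id)
            records.append((rec_id, seq.upper()))
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(path: PathLike, records: Sequence[Tuple[str, str]], width: int = 70) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for rec_id, seq in records:
            handle.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
            if not seq:
                handle.write("\n")


# ---------------------------------------------------------------------------
# Gene tables


def _parse_gff3_attributes(text: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, value = chunk.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_gene_table(path: PathLike, dialect: str = "gff3") -> List[GeneRecord]:
    """Read gene annotations; returns records sorted by ``(scaffold_id, start)``.

    ``dialect`` is ``"gff3"`` (only ``gene``/``CDS`` rows consumed, 1-based
    inclusive coordinates) or ``"tsv"`` (columns as written by
    :func:`write_gene_table`).  Strand ``"."`` is mapped to ``"+"`` with a
    logged warning.
    """
    if dialect not in ("gff3", "tsv"):
        raise UsageError(f"unknown gene-table dialect {dialect!r}")
    records: List[GeneRecord] = []
    seen = set()
    with open(path, encoding="utf-8") as handle:
        if dialect == "gff3":
            for lineno, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
                seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
                if ftype not in ("gene", "CDS"):
                    continue
                attributes = _parse_gff3_attributes(attrs)
                gene_id = attributes.get("ID") or attributes.get("Parent")
                if not gene_id:
                    raise ParseError(f"{path}:{lineno}: row has no ID attribute")
                if gene_id in seen:
                    continue  # gene row and its CDS row share an ID
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
                if strand == ".":
                    logger.warning("%s:%d: strand '.' mapped to '+'", path, lineno)
                    strand = "+"
                rec = GeneRecord(
                    gene_id=gene_id,
                    scaffold_id=seqid,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    product=attributes.get("product", ""),
                    functional_category=attributes.get(
                        "functional_category", "unknown_function"
                    ),
                ).validate()
                seen.add(gene_id)
                records.append(rec)
        else:
            header = handle.readline().rstrip("\n").split("\t")
            if tuple(header) != GENE_TSV_COLUMNS:
                raise FormatError(f"{path}: bad gene-table header {header}")
            for lineno, line in enumerate(handle, 2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != len(GENE_TSV_COLUMNS):
                    raise ParseError(f"{path}:{lineno}: wrong number of columns")
                gene_id, scaffold_id, start, end, strand, product, category = fields
                if strand == ".":
                    logger.warning("%s:%d: strand '.' mapped to '+'", path, lineno)
                    strand = "+"
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
                records.append(
                    GeneRecord(
                        gene_id=gene_id,
                        scaffold_id=scaffold_id,
                        start=start_i,
                        end=end_i,
                        strand=strand,
                        product=product,
                        functional_category=category,
                    ).validate()
                )
    records.sort(key=lambda g: (g.scaffold_id, g.start, g.gene_id))
    return records


def write_gene_table(path: PathLike, genes: Sequence[GeneRecord], dialect: str = "tsv") -> None:
    if dialect not in ("gff3", "tsv"):
        raise UsageError(f"unknown gene-table dialect {dialect!r}")
    ordered = sorted(genes, key=lambda g: (g.scaffold_id, g.start, g.gene_id))
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        if dialect == "tsv":
            handle.write("\t".join(GENE_TSV_COLUMNS) + "\n")
            for g in ordered:
                handle.write(
                    "\t".join(
                        [
                            g.gene_id,
                            g.scaffold_id,
                            str(g.start),
                            str(g.end),
                            g.strand,
                            g.product,
                            g.functional_category,
                        ]
                    )
                    + "\n"
                )
        else:
            handle.write("##gff-version 3\n")
            for g in ordered:
                attrs = f"ID={g.gene_id}"
                if g.product:
                    attrs += f";product={g.product}"
                attrs += f";functional_category={g.functional_category}"
                handle.write(
                    "\t".join(
                        [
                            g.scaffold_id,
                            "cosymbio",
                            "gene",
                            str(g.start),
                            str(g.end),
                            ".",
                            g.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# OrthoMCL groups


def read_cluster_groups(path: PathLike) -> ClusterTable:
    """Read an OrthoMCL-style groups file into a :class:`ClusterTable`."""
    clusters: List[Tuple[str, Dict[str, List[str]]]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise ParseError(f"{path}:{lineno}: missing ':' after cluster id")
            cid, rest = line.split(":", 1)
            cid = cid.strip()
            if not cid:
                raise ParseError(f"{path}:{lineno}: empty cluster id")
            members: Dict[str, List[str]] = {}
            for token in rest.split():
                if "|" not in token:
                    raise ParseError(
                        f"{path}:{lineno}: malformed member token {token!r} "
                        "(expected taxon|gene)"
                    )
                taxon, gene = token.split("|", 1)
                if not taxon or not gene:
                    raise ParseError(
                        f"{path}:{lineno}: malformed member token {token!r}"
                    )
                members.setdefault(taxon, []).append(gene)
            if not members:
                raise ParseError(f"{path}:{lineno}: cluster {cid!r} has no members")
            clusters.append((cid, members))
    return ClusterTable(clusters).validate()


def write_cluster_groups(path: PathLike, table: ClusterTable) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for cid, members in table.clusters:
            tokens = [
                f"{taxon}|{gene}" for taxon in members for gene in members[taxon]
            ]
            handle.write(f"{cid}: " + " ".join(tokens) + "\n")


# ---------------------------------------------------------------------------
# Blast hit tables


def _format_float(x: float) -> str:
    return repr(float(x))


def read_hit_table(path: PathLike) -> Dict[str, List[HitRecord]]:
    """Read a 13-column tabular blast file into ``{query: [hits...]}``.

    Hits per query are sorted by descending bit score; ties broken by
    ascending e-value, then lexicographic subject id.
    """
    hits: Dict[str, List[HitRecord]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(HIT_COLUMNS):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(HIT_COLUMNS)} columns "
                    f"(12 blast columns + lineage), got {len(fields)}"
                )
            query, subject = fields[0], fields[1]
            try:
                pident = float(fields[2])
                length = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric blast field") from exc
            lineage = Lineage.from_string(fields[12])
            rec = HitRecord(
                query_gene_id=query,
                subject_id=subject,
                percent_identity=pident,
                alignment_length=length,
                bit_score=bitscore,
                e_value=evalue,
                lineage=lineage,
            ).validate()
            hits.setdefault(query, []).append(rec)
    for query in hits:
        hits[query].sort(key=hit_sort_key)
    return hits


def write_hit_table(path: PathLike, hits: Mapping[str, Sequence[HitRecord]]) -> None:
    """Write hits in the 13-column dialect; unused blast columns are zeroed."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for query in hits:
            for h in sorted(hits[query], key=hit_sort_key):
                handle.write(
                    "\t".join(
                        [
                            h.query_gene_id,
                            h.subject_id,
                            _format_float(h.percent_identity),
                            str(h.alignment_length),
                            "0",
                            "0",
                            "1",
                            str(h.alignment_length),
                            "1",
                            str(h.alignment_length),
                            _format_float(h.e_value),
                            _format_float(h.bit_score),
                            h.lineage.to_string(),
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# PCR panel


def read_pcr_panel(path: PathLike) -> PcrPanel:
    rows: List[PanelRow] = []
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != PANEL_COLUMNS:
            raise FormatError(f"{path}: bad PCR panel header {header}")
        for lineno, line in enumerate(handle, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(PANEL_COLUMNS):
                raise ParseError(f"{path}:{lineno}: wrong number of columns")
            rows.append(PanelRow(*fields).validate())
    return PcrPanel(rows).validate()


def write_pcr_panel(path: PathLike, panel: PcrPanel) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\t".join(PANEL_COLUMNS) + "\n")
        for r in panel.rows:
            handle.write(
                "\t".join(
                    [r.individual_id, r.sex, r.cardinium_pcr, r.wolbachia_pcr, r.host_18s_pcr]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Coverage profile YAML


def read_coverage_profile(path: PathLike):
    """Read a coverage-profile YAML into a CoverageProfile.

    Schema::

        symbionts:
          cardinium: {coverage: 15.01, prevalence: 0.96}
          wolbachia: {coverage: 16.70, prevalence: 0.48}
        host_gene_coverage: 32.97
        cells_per_host: 1000
    """
    from .infection_stats import CoverageProfile

    with open(path, encoding="utf-8") as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict) or "symbionts" not in data:
        raise FormatError(f"{path}: coverage profile must have a 'symbionts' map")
    symbionts = data["symbionts"]
    coverage = {name: float(entry["coverage"]) for name, entry in symbionts.items()}
    prevalence = {name: float(entry["prevalence"]) for name, entry in symbionts.items()}
    return CoverageProfile(
        symbiont_coverage=coverage,
        host_single_copy_coverage=float(data["host_gene_coverage"]),
        prevalence=prevalence,
        cells_per_host=int(data.get("cells_per_host", 1000)),
    ).validate()


def write_coverage_profile(path: PathLike, profile) -> None:
    data = {
        "symbionts": {
            name: {
                "coverage": float(profile.symbiont_coverage[name]),
                "prevalence": float(profile.prevalence[name]),
            }
            for name in sorted(profile.symbiont_coverage)
        },
        "host_gene_coverage": float(profile.host_single_copy_coverage),
        "cells_per_host": int(profile.cells_per_host),
    }
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        yaml.safe_dump(data, handle, sort_keys=True)
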