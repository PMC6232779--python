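"""Scaffold-level assembly statistics.

N50 follows the usual convention: sort scaffold lengths descending and take
the length at which the running sum first reaches half the assembly total.
GC% excludes ambiguity codes from both numerator and denominator; runs of N
(gap fill) still count toward total length.  rRNA/tRNA genes are counted by
matching gene products against configurable regular expressions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .errors import EmptyInputError
from .ortholog_sets import coding_fraction, gc_percent
from .types import GenomeBundle

DEFAULT_RRNA_PATTERN = r"(ribosomal RNA|\brRNA\b|[0-9]+S rRNA)"
DEFAULT_TRNA_PATTERN = r"\btRNA\b"


@dataclass
class AssemblyStats:
    n_scaffolds: int
    total_length_bp: int
    n50_bp: int
    gc_percent: float
    n_genes: int
    coding_fraction: float
    n_rrna: int
    n_trna: int


def n50(lengths: Sequence[int]) -> int:
    """Length of the scaffold at which the descending cumulative sum first
    reaches half the total."""
    if not lengths:
        raise EmptyInputError("n50 of an empty assembly")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    running = 0
    for length in ordered:
        running += length
        if running >= half:
            return length
    return ordered[-1]  # unreachable


def compute_assembly_stats(
    bundle: GenomeBundle,
    rrna_pattern: str = DEFAULT_RRNA_PATTERN,
    trna_pattern: str = DEFAULT_TRNA_PATTERN,
) -> AssemblyStats:
    bundle.validate()
    if not bundle.scaffolds:
        raise EmptyInputError(f"{bundle.taxon_id}: no scaffolds")
    lengths = [len(seq) for _, seq in bundle.scaffolds]
    rrna_re = re.compile(rrna_pattern, re.IGNORECASE)
    trna_re = re.compile(trna_pattern, re.IGNORECASE)
    n_rrna = sum(bool(rrna_re.search(g.product)) for g in bundle.genes)
    n_trna = sum(bool(trna_re.search(g.product)) for g in bundle.genes)
    return AssemblyStats(
        n_scaffolds=len(lengths),
        total_length_bp=sum(lengths),
        n50_bp=n50(lengths),
        gc_percent=gc_percent(seq for _, seq in bundle.scaffolds),
        n_genes=len(bundle.genes),
        coding_fraction=coding_fraction(bundle),
        n_rrna=n_rrna,
        n_trna=n_trna,
    )
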