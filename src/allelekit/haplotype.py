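"""Anchor-gene haplotype analysis.

A gene heterozygous in the subject (e.g. IGHJ6 carrying alleles *02 and *03)
splits the repertoire into two chromosomal haplotypes: every V(D)J
rearrangement uses the J of its own chromosome, so the anchor allele a read
carries identifies the haplotype its V allele sits on.  A novel V allele
found exclusively with one anchor allele behaves like a real germline gene
on one chromosome — strong supporting evidence that it is not a
hypermutation artifact, which would scatter across both haplotypes.

Anchor detection runs on unmutated reads only (hypermutation distorts
allele-call ratios); the haplotype split itself counts all assigned reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .germline import ReferenceSet
from .genotype import is_unmutated
from .rearrangements import Rearrangement, primary_call

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL = 100
DEFAULT_MIN_MINOR_FRACTION = 0.2
DEFAULT_MIN_READS = 10


@dataclass(frozen=True)
class AnchorCandidate:
    gene: str
    alleles: tuple[str, str]
    total: int


@dataclass
class HaplotypeReport:
    """Per-allele read counts split by anchor allele.

    ``per_gene_counts[gene][allele]`` is a ``(count_anchor1, count_anchor2)``
    pair; ``exclusivity[allele]`` is ``(flag, ratio)`` per
    :func:`exclusivity_score`.
    """

    anchor_gene: str
    anchor_alleles: tuple[str, str]
    per_gene_counts: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    exclusivity: dict[str, tuple[bool, float]] = field(default_factory=dict)

    def counts(self, allele: str) -> tuple[int, int]:
        gene = allele.split("*")[0]
        return self.per_gene_counts.get(gene, {}).get(allele, (0, 0))


def allele_usage_by_gene(
    reads: Sequence[Rearrangement],
    segment: str = "J",
    refset: ReferenceSet | None = None,
    studied_segment: str | None = None,
) -> dict[str, dict[str, int]]:
    """Per-gene allele usage counts for ``segment``, unambiguous calls only.

    When ``refset`` and ``studied_segment`` are given, counting is
    restricted to reads unmutated in their (unambiguously called)
    studied-segment allele, which keeps hypermutation from distorting the
    ratios used for heterozygosity detection.  Genes and alleles are ordered
    by name.
    """
    usage: dict[str, dict[str, int]] = {}
    for read in reads:
        call = read.call_for(segment)
        if not call.strip():
            continue
        name, ambiguous = primary_call(call)
        if ambiguous:
            continue
        if refset is not None and studied_segment is not None:
            sc = read.call_for(studied_segment)
            if not sc.strip():
                continue
            s_name, s_amb = primary_call(sc)
            if s_amb or s_name not in refset or not is_unmutated(read, refset[s_name]):
                continue
        gene = name.split("*")[0]
        usage.setdefault(gene, {})[name] = usage.setdefault(gene, {}).get(name, 0) + 1
    return {
        g: dict(sorted(usage[g].items())) for g in sorted(usage)
    }


def detect_anchor(
    usage: dict[str, dict[str, int]],
    min_total: int = DEFAULT_MIN_TOTAL,
    min_minor_fraction: float = DEFAULT_MIN_MINOR_FRACTION,
) -> list[AnchorCandidate]:
    """Genes usable as haplotype anchors.

    A gene qualifies iff exactly two of its alleles each hold at least
    ``min_minor_fraction`` of the gene's reads and the gene total is at
    least ``min_total``.  Candidates are sorted by total, descending; an
    empty list means haplotyping is not possible.
    """
    candidates: list[AnchorCandidate] = []
    for gene, alleles in usage.items():
        total = sum(alleles.values())
        if total < min_total:
            continue
        major = [a for a, n in alleles.items() if n / total >= min_minor_fraction]
        if len(major) == 2:
            candidates.append(AnchorCandidate(gene, (major[0], major[1]), total))
    return sorted(candidates, key=lambda c: (-c.total, c.gene))


def exclusivity_score(
    count1: int, count2: int, min_reads: int = DEFAULT_MIN_READS
) -> tuple[bool, float]:
    """Exclusive-association evidence for one allele across the two anchors.

    The flag is true iff the allele is seen at least ``min_reads`` times on
    one haplotype and never on the other.  The ratio min/max (0 when both
    counts are 0) measures how far from exclusive the split is.
    """
    if count1 < 0 or count2 < 0:
        raise ValueError("counts must be non-negative")
    hi, lo = max(count1, count2), min(count1, count2)
    if hi == 0:
        return False, 0.0
    return (hi >= min_reads and lo == 0), lo / hi


def haplotype_counts(
    reads: Sequence[Rearrangement],
    anchor_gene: str,
    anchor_alleles: tuple[str, str],
    segment_under_study: str = "V",
    refset: ReferenceSet | None = None,
    min_reads: int = DEFAULT_MIN_READS,
) -> HaplotypeReport:
    """Split studied-segment allele usage by anchor allele.

    Each read with an unambiguous anchor-segment call equal to one of the
    two anchor alleles contributes to that anchor's column for the read's
    studied-segment allele; reads calling other alleles of the anchor gene,
    or other genes of the anchor segment, are excluded from the split.
    Alleles with zero reads under both anchors do not appear.

    Exclusivity is scored for every allele in the report; when ``refset``
    is given the novel alleles are the ones of interest, but the scores are
    reported for all so reference alleles show the expected non-exclusive
    pattern.
    """
    anchor_segment = anchor_gene[3] if len(anchor_gene) > 3 and anchor_gene[3] in "VDJ" else "J"
    a1, a2 = anchor_alleles
    per_gene: dict[str, dict[str, list[int]]] = {}
    seen_anchor = {a1: 0, a2: 0}
    for read in reads:
        a_call = read.call_for(anchor_segment)
        if not a_call.strip():
            continue
        a_name, a_amb = primary_call(a_call)
        if a_amb or a_name not in (a1, a2):
            continue
        s_call = read.call_for(segment_under_study)
        if not s_call.strip():
            continue
        s_name, _ = primary_call(s_call)
        gene = s_name.split("*")[0]
        cell = per_gene.setdefault(gene, {}).setdefault(s_name, [0, 0])
        cell[0 if a_name == a1 else 1] += 1
        seen_anchor[a_name] += 1
    if seen_anchor[a1] == 0 and seen_anchor[a2] == 0:
        raise ValueError(
            f"anchor alleles {a1!r}/{a2!r} not found in any read"
        )
    report = HaplotypeReport(anchor_gene=anchor_gene, anchor_alleles=(a1, a2))
    for gene in sorted(per_gene):
        report.per_gene_counts[gene] = {
            allele: (c[0], c[1]) for allele, c in sorted(per_gene[gene].items())
        }
        for allele, (c1, c2) in report.per_gene_counts[gene].items():
            report.exclusivity[allele] = exclusivity_score(c1, c2, min_reads)
    return report


def haplotyping_gene_label(anchors: Sequence[AnchorCandidate]) -> str:
    """Comma-joined anchor gene names for the genotype report field."""
    return ",".join(a.gene for a in anchors)
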