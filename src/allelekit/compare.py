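"""Closest-reference search and substitution annotation for novel alleles.

Novel V inferences are routinely shorter than reference alleles at the 3'
end, because junction trimming makes the final germline nucleotides hard to
infer from rearranged reads.  All comparisons therefore run over the
overlapping 5' extent only; the unmatched tail is ignored and logged.

Substitution positions use IMGT (gapped-frame) numbering for V genes and
1-based ungapped coding positions for D/J genes, e.g. ``G112A`` for a
nucleotide change and ``A96N`` for the corresponding amino-acid change at
codon 96.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .germline import GAP, GermlineAllele

logger = logging.getLogger(__name__)


@dataclass
class AlleleDiff:
    """Difference annotation of a novel allele against its closest references."""

    closest_reference: str = ""
    closest_host: str = ""
    nt_diff: int | None = None
    nt_diff_host: int | None = None
    nt_substitutions: list[str] = field(default_factory=list)
    aa_diff: int | None = None
    aa_substitutions: list[str] = field(default_factory=list)


def gapped_hamming(a: str, b: str) -> int:
    """Count differing aligned positions over the shorter 3' extent.

    Positions where one sequence has a gap ('.') and the other a base count
    as differences; columns gapped in both do not.  The tail beyond the
    shorter sequence (junction-trimmed) is ignored.
    """
    n = min(len(a), len(b))
    return sum(1 for i in range(n) if a[i] != b[i] and not (a[i] == GAP and b[i] == GAP))


def closest_allele(
    novel: GermlineAllele, candidates: list[GermlineAllele]
) -> tuple[str, int]:
    """Candidate with minimal gapped Hamming distance to ``novel``.

    Ties break to the lexicographically smallest allele name, so the result
    is deterministic.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    best = min(
        candidates,
        key=lambda c: (gapped_hamming(novel.gapped_seq, c.gapped_seq), c.name),
    )
    return best.name, gapped_hamming(novel.gapped_seq, best.gapped_seq)


def _codon_number(gapped_pos: int) -> int:
    return (gapped_pos + 2) // 3


def _translate_codon(codon: str) -> str:
    if len(codon) < 3 or GAP in codon or "N" in codon:
        return "X"
    return str(Seq(codon).translate())


def substitution_strings(
    novel: GermlineAllele, ref: GermlineAllele
) -> tuple[list[str], list[str]]:
    """Nucleotide and amino-acid substitution lists between two alleles.

    Nucleotide entries are ``<refBase><position><novelBase>``; gap-vs-base
    columns are marked with ``ins``/``del`` instead of a base.  Amino-acid
    entries compare the reading-frame-1 translation codon by codon on the
    shared frame; codons containing '.' or N translate to 'X' and are
    excluded (no amino-acid differences are fabricated at gap columns).
    D genes lack a fixed reading frame, so their amino-acid list is empty.
    """
    if novel.segment != ref.segment:
        raise ValueError(
            f"segment mismatch: {novel.name} is {novel.segment}, {ref.name} is {ref.segment}"
        )
    a, b = ref.gapped_seq, novel.gapped_seq
    n = min(len(a), len(b))
    if len(a) != len(b):
        logger.info(
            "comparing %s vs %s over shared extent of %d columns "
            "(unmatched tail ignored)", novel.name, ref.name, n,
        )
    is_v = novel.segment == "V"
    nt_subs: list[str] = []
    ungapped_pos = 0
    for i in range(n):
        ra, nb = a[i], b[i]
        if ra != GAP:
            ungapped_pos += 1
        pos = (i + 1) if is_v else ungapped_pos
        if ra == nb or (ra == GAP and nb == GAP):
            continue
        if ra == GAP:
            nt_subs.append(f"ins{pos}{nb}")
            logger.warning("%s vs %s: insertion at position %d", novel.name, ref.name, pos)
        elif nb == GAP:
            nt_subs.append(f"{ra}{pos}del")
            logger.warning("%s vs %s: deletion at position %d", novel.name, ref.name, pos)
        else:
            nt_subs.append(f"{ra}{pos}{nb}")

    aa_subs: list[str] = []
    if novel.segment != "D":
        for start in range(0, n - n % 3, 3):
            ra = _translate_codon(a[start : start + 3])
            na = _translate_codon(b[start : start + 3])
            if ra == na or "X" in (ra, na):
                continue
            codon = _codon_number(start + 1) if is_v else (
                len(a[: start + 3].replace(GAP, "")) + 2
            ) // 3
            aa_subs.append(f"{ra}{codon}{na}")
    return nt_subs, aa_subs


def annotate_novel(
    novel: GermlineAllele,
    reference_alleles: list[GermlineAllele],
    host_alleles: list[GermlineAllele],
) -> AlleleDiff:
    """Full difference annotation of one novel allele.

    ``reference_alleles`` is the full reference set for the segment;
    ``host_alleles`` the subset present in the subject's genotype, so
    ``nt_diff_host >= nt_diff`` always holds.
    """
    diff = AlleleDiff()
    same_seg = [c for c in reference_alleles if c.segment == novel.segment]
    if same_seg:
        diff.closest_reference, diff.nt_diff = closest_allele(novel, same_seg)
        ref = next(c for c in same_seg if c.name == diff.closest_reference)
        diff.nt_substitutions, diff.aa_substitutions = substitution_strings(novel, ref)
        diff.aa_diff = len(diff.aa_substitutions)
    host_seg = [c for c in host_alleles if c.segment == novel.segment]
    if host_seg:
        diff.closest_host, diff.nt_diff_host = closest_allele(novel, host_seg)
    return diff
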