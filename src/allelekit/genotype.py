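"""The standardized genotype report: one row of usage statistics per allele.

A subject's genotype is the set of germline alleles that lead to expressed
productive rearrangements in their repertoire.  For each allele the report
gives assignment counts, exact-match (unmutated) counts and frequencies,
diversity of co-occurring segments and CDR3s, and — for novel alleles —
difference annotations against the closest reference and host alleles.

Definitions used throughout:

* a read is *assigned* to the first allele of its call string; reads with
  ambiguous (multi-valued) calls count toward ``sequences`` but are excluded
  from exact-match statistics, so exact matches are never double-counted;
* a read is *unmutated* (an exact match) when its aligned segment region
  equals the germline allele over the read's covered extent — gap columns
  are ignored, the junction-trimmed tail is ignored, and N counts as a
  mismatch.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

from .compare import AlleleDiff, annotate_novel, gapped_hamming
from .germline import GermlineAllele, ReferenceSet
from .rearrangements import Rearrangement, filter_productive, primary_call

logger = logging.getLogger(__name__)

GENOTYPE_COLUMNS = (
    "sequence_id",
    "sequences",
    "closest_reference",
    "closest_host",
    "nt_diff",
    "nt_diff_host",
    "nt_substitutions",
    "aa_diff",
    "aa_substitutions",
    "unmutated_sequences",
    "assigned_unmutated_frequency",
    "unmutated_umis",
    "allelic_percentage",
    "unmutated_frequency",
    "unique_vs",
    "unique_ds",
    "unique_js",
    "unique_cdr3s",
    "unique_vs_unmutated",
    "unique_ds_unmutated",
    "unique_js_unmutated",
    "unique_cdr3s_unmutated",
    "haplotyping_gene",
)


class EmptyRepertoireError(ValueError):
    pass


def segment_diff_count(read: Rearrangement, allele: GermlineAllele) -> int | None:
    """Nucleotide differences between a read's segment region and the germline.

    The comparison covers the read's covered extent only: for V (and D) the
    shared 5' prefix, for J the shared 3' suffix (J reads are trimmed at the
    5' end by the recombination junction).  Columns gapped in both are
    skipped; gap-vs-base and N-vs-base count as differences.  Returns None
    when the read carries no alignment.
    """
    region = read.segment_region(allele.segment)
    if not region:
        return None
    germ = allele.gapped_seq
    if allele.segment == "J" and len(region) < len(germ):
        germ = germ[len(germ) - len(region):]
    return gapped_hamming(region, germ)


def is_unmutated(read: Rearrangement, allele: GermlineAllele) -> bool:
    """True iff the read exactly matches the germline allele over its
    covered segment extent (see :func:`segment_diff_count`)."""
    d = segment_diff_count(read, allele)
    if d is None:
        logger.warning("read %s lacks sequence_alignment; excluded", read.read_id)
        return False
    return d == 0


@dataclass
class GenotypeRow:
    sequence_id: str
    sequences: int = 0
    diff: AlleleDiff = field(default_factory=AlleleDiff)
    unmutated_sequences: int = 0
    assigned_unmutated_frequency: float | None = None
    unmutated_umis: int | None = None
    allelic_percentage: float | None = None
    unmutated_frequency: float | None = None
    unique_vs: int = 0
    unique_ds: int = 0
    unique_js: int = 0
    unique_cdr3s: int = 0
    unique_vs_unmutated: int = 0
    unique_ds_unmutated: int = 0
    unique_js_unmutated: int = 0
    unique_cdr3s_unmutated: int = 0
    haplotyping_gene: str = ""


@dataclass
class Genotype:
    rows: list[GenotypeRow]
    locus: str
    subject: str
    segment: str
    total_assigned: int
    total_unmutated: int
    cdr3_field: str  # "junction_aa" or "cdr3_nt"
    unknown_alleles: list[str] = field(default_factory=list)

    def row(self, sequence_id: str) -> GenotypeRow:
        for r in self.rows:
            if r.sequence_id == sequence_id:
                return r
        raise KeyError(sequence_id)


def _gene_of(name: str) -> str:
    return name.split("*")[0]


def _cdr3_key(read: Rearrangement, cdr3_field: str) -> str:
    return read.junction_aa if cdr3_field == "junction_aa" else read.cdr3_nt


def compute_genotype(
    reads: Sequence[Rearrangement],
    refset: ReferenceSet,
    segment: str = "V",
    subject: str = "subject",
) -> Genotype:
    """Build the standardized genotype for the studied segment.

    ``reads`` should be productive-filtered; the filter is re-applied here
    (it is idempotent) so the genotype can never include non-productive
    sequences.  Alleles called in the reads but absent from ``refset`` get a
    row with difference fields empty and a logged discrepancy; their reads
    cannot be checked for exact germline match and count as mutated.
    """
    if segment not in "VDJ":
        raise ValueError(f"segment must be V, D or J, got {segment!r}")
    reads = filter_productive(reads)
    if not reads:
        raise EmptyRepertoireError("empty repertoire: no productive reads")

    umi_present = any(r.umi for r in reads)
    cdr3_field = "junction_aa" if any(r.junction_aa for r in reads) else "cdr3_nt"

    assigned: dict[str, list[tuple[Rearrangement, bool]]] = {}
    for read in reads:
        call = read.call_for(segment)
        if not call.strip():
            continue
        name, ambiguous = primary_call(call)
        assigned.setdefault(name, []).append((read, ambiguous))

    unknown = sorted(name for name in assigned if name not in refset)
    for name in unknown:
        logger.warning(
            "allele %r has %d assigned reads but is absent from the reference "
            "set; difference fields left empty", name, len(assigned[name]),
        )

    # per-allele unmutated read lists (unambiguous calls only)
    unmutated: dict[str, list[Rearrangement]] = {}
    for name, items in assigned.items():
        allele = refset[name] if name in refset else None
        unmutated[name] = [
            read
            for read, ambiguous in items
            if not ambiguous and allele is not None and is_unmutated(read, allele)
        ]

    total_unmutated = sum(len(v) for v in unmutated.values())
    gene_unmutated: dict[str, int] = {}
    for name in assigned:
        gene_unmutated[_gene_of(name)] = gene_unmutated.get(_gene_of(name), 0) + len(
            unmutated[name]
        )

    rows: list[GenotypeRow] = []
    for name in sorted(assigned, key=lambda n: (_gene_of(n), n)):
        items = assigned[name]
        reads_here = [r for r, _ in items]
        unmut_here = unmutated[name]
        n_seq = len(items)
        n_unmut = len(unmut_here)

        def uniq(sub_reads: Sequence[Rearrangement], seg: str) -> int:
            calls = set()
            for r in sub_reads:
                c = r.call_for(seg)
                if c.strip():
                    calls.add(primary_call(c)[0])
            return len(calls)

        def uniq_cdr3(sub_reads: Sequence[Rearrangement]) -> int:
            return len({_cdr3_key(r, cdr3_field) for r in sub_reads if _cdr3_key(r, cdr3_field)})

        row = GenotypeRow(
            sequence_id=name,
            sequences=n_seq,
            unmutated_sequences=n_unmut,
            assigned_unmutated_frequency=100.0 * n_unmut / n_seq,
            unique_vs=uniq(reads_here, "V"),
            unique_ds=uniq(reads_here, "D"),
            unique_js=uniq(reads_here, "J"),
            unique_cdr3s=uniq_cdr3(reads_here),
            unique_vs_unmutated=uniq(unmut_here, "V"),
            unique_ds_unmutated=uniq(unmut_here, "D"),
            unique_js_unmutated=uniq(unmut_here, "J"),
            unique_cdr3s_unmutated=uniq_cdr3(unmut_here),
        )
        if umi_present:
            row.unmutated_umis = len({r.umi for r in unmut_here if r.umi})
        denom = gene_unmutated[_gene_of(name)]
        if denom > 0:
            row.allelic_percentage = 100.0 * n_unmut / denom
        if total_unmutated > 0:
            row.unmutated_frequency = 100.0 * n_unmut / total_unmutated
        rows.append(row)

    # difference annotation for novel alleles, against the full reference and
    # against the host genotype (reference alleles present in the rows)
    host = [
        refset[r.sequence_id]
        for r in rows
        if r.sequence_id in refset and not refset[r.sequence_id].is_novel
    ]
    for row in rows:
        if row.sequence_id in refset and refset[row.sequence_id].is_novel:
            row.diff = annotate_novel(
                refset[row.sequence_id],
                [a for a in refset.reference_proper() if a.segment == segment],
                host,
            )

    return Genotype(
        rows=rows,
        locus=refset.locus,
        subject=subject,
        segment=segment,
        total_assigned=sum(r.sequences for r in rows),
        total_unmutated=total_unmutated,
        cdr3_field=cdr3_field,
        unknown_alleles=unknown,
    )


def _fmt_percent(value: float | None) -> str:
    if value is None:
        return ""
    return str(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _fmt_opt(value) -> str:
    return "" if value is None else str(value)


def genotype_row_record(row: GenotypeRow) -> dict[str, str]:
    """One genotype row serialized to the standard column set."""
    d = row.diff
    return {
        "sequence_id": row.sequence_id,
        "sequences": str(row.sequences),
        "closest_reference": d.closest_reference,
        "closest_host": d.closest_host,
        "nt_diff": _fmt_opt(d.nt_diff),
        "nt_diff_host": _fmt_opt(d.nt_diff_host),
        "nt_substitutions": ",".join(d.nt_substitutions),
        "aa_diff": _fmt_opt(d.aa_diff),
        "aa_substitutions": ",".join(d.aa_substitutions),
        "unmutated_sequences": str(row.unmutated_sequences),
        "assigned_unmutated_frequency": _fmt_percent(row.assigned_unmutated_frequency),
        "unmutated_umis": _fmt_opt(row.unmutated_umis),
        "allelic_percentage": _fmt_percent(row.allelic_percentage),
        "unmutated_frequency": _fmt_percent(row.unmutated_frequency),
        "unique_vs": str(row.unique_vs),
        "unique_ds": str(row.unique_ds),
        "unique_js": str(row.unique_js),
        "unique_cdr3s": str(row.unique_cdr3s),
        "unique_vs_unmutated": str(row.unique_vs_unmutated),
        "unique_ds_unmutated": str(row.unique_ds_unmutated),
        "unique_js_unmutated": str(row.unique_js_unmutated),
        "unique_cdr3s_unmutated": str(row.unique_cdr3s_unmutated),
        "haplotyping_gene": row.haplotyping_gene,
    }


def write_genotype_csv(genotype: Genotype, path: str | Path) -> None:
    """Write the genotype report as CSV with the standard header order.

    Percentages carry 2 decimals (half-up); undefined fields are rendered
    empty, never 0.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=GENOTYPE_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for row in genotype.rows:
            writer.writerow(genotype_row_record(row))
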