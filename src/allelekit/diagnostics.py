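"""Diagnostic panels for assessing novel-allele inferences.

Five views of the evidence behind an inference:

A. IMGT alignment of all reads assigned to the allele (gaps '.', low-
   confidence base calls '-');
B. a zoom of that alignment on the terminal nucleotides — the 3' end for V
   genes (default 8 positions), where junction trimming makes the final
   germline nucleotide hard to infer, and the 5' end for J genes;
C. a histogram of reads by nucleotide distance to the (possibly inferred)
   germline sequence — a clean inference shows a large unmutated peak at 0;
D. allele usage within each gene of the partner segment, which exposes
   heterozygous genes usable as haplotype anchors;
E. studied-segment usage split by anchor allele, where exclusive
   association of a novel allele with one haplotype supports the inference.

Each panel is computed as a plain table (tested directly) and rendered to an
image with deterministic layout.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .germline import GAP, GermlineAllele
from .genotype import segment_diff_count
from .haplotype import HaplotypeReport
from .rearrangements import Rearrangement, primary_call

logger = logging.getLogger(__name__)

LOW_CONFIDENCE = "-"
DEFAULT_QUAL_THRESHOLD = 20
DEFAULT_ZOOM = 8


@dataclass
class AlignmentPanel:
    """Reads projected onto a germline allele's gapped coordinate frame."""

    allele_name: str
    germline: str  # gapped germline row
    positions: list[int]  # 1-based frame column labels
    read_ids: list[str] = field(default_factory=list)
    rows: list[str] = field(default_factory=list)

    @property
    def consensus(self) -> str:
        """Majority base per column over {A,C,G,T,N}; '.' where no base."""
        out = []
        for i in range(len(self.germline)):
            counts = Counter(
                row[i] for row in self.rows if row[i] not in (GAP, LOW_CONFIDENCE)
            )
            out.append(counts.most_common(1)[0][0] if counts else GAP)
        return "".join(out)

    def to_frame(self) -> pd.DataFrame:
        data = {rid: list(row) for rid, row in zip(self.read_ids, self.rows)}
        df = pd.DataFrame.from_dict(data, orient="index", columns=self.positions)
        df.index.name = "read_id"
        return df


@dataclass
class MutationHistogram:
    """Reads assigned to an allele, binned by nucleotide distance to it."""

    allele_name: str
    bins: dict[int, int] = field(default_factory=dict)
    skipped: int = 0

    @property
    def n_reads(self) -> int:
        return sum(self.bins.values())


def alignment_panel(
    reads: list[Rearrangement],
    allele: GermlineAllele,
    qual_threshold: int = DEFAULT_QUAL_THRESHOLD,
) -> AlignmentPanel:
    """Project reads assigned to ``allele`` onto its gapped frame.

    Bases whose Phred quality is below ``qual_threshold`` are shown as '-';
    reads without quality data are rendered as-is.  Positions beyond a
    read's covered extent are shown as '.'.  Reads whose gapped region is
    longer than the allele frame cannot be projected and are skipped.
    """
    frame_len = len(allele.gapped_seq)
    panel = AlignmentPanel(
        allele_name=allele.name,
        germline=allele.gapped_seq,
        positions=list(range(1, frame_len + 1)),
    )
    for read in reads:
        region = read.segment_region(allele.segment)
        if len(region) > frame_len:
            logger.warning(
                "read %s: gapped region (%d) exceeds frame (%d); skipped",
                read.read_id, len(region), frame_len,
            )
            continue
        chars = list(region)
        if read.quals:
            base_idx = 0
            for i, c in enumerate(chars):
                if c == GAP:
                    continue
                if base_idx < len(read.quals) and read.quals[base_idx] < qual_threshold:
                    chars[i] = LOW_CONFIDENCE
                base_idx += 1
        row = "".join(chars).ljust(frame_len, GAP)
        panel.read_ids.append(read.read_id)
        panel.rows.append(row)
    return panel


def end_zoom(
    panel: AlignmentPanel, segment: str = "V", n: int = DEFAULT_ZOOM
) -> AlignmentPanel:
    """Restrict a panel to its terminal columns.

    V genes: the last ``n`` non-gap columns of the germline frame (the 3'
    terminus, where inference is hardest).  J genes: the first ``n``
    columns (the 5' end).
    """
    nongap = [i for i, c in enumerate(panel.germline) if c != GAP]
    if segment == "V":
        cols = nongap[-n:] if n > 0 else []
    else:
        cols = list(range(min(n, len(panel.germline))))
    if n > len(panel.germline):
        logger.warning("zoom width %d exceeds panel width %d; full panel returned",
                       n, len(panel.germline))
        cols = list(range(len(panel.germline))) if segment != "V" else nongap
    return AlignmentPanel(
        allele_name=panel.allele_name,
        germline="".join(panel.germline[i] for i in cols),
        positions=[panel.positions[i] for i in cols],
        read_ids=list(panel.read_ids),
        rows=["".join(row[i] for i in cols) for row in panel.rows],
    )


def mutation_histogram(
    reads: list[Rearrangement], allele: GermlineAllele
) -> MutationHistogram:
    """Distance-to-germline histogram for reads assigned to ``allele``.

    Distances use the same covered-extent comparison as the unmutated
    statistics, so bin 0 equals ``unmutated_sequences`` for the allele.
    Ambiguously called reads and reads without alignments are skipped (they
    are excluded from exact-match statistics for the same reason).
    """
    hist = MutationHistogram(allele_name=allele.name)
    for read in reads:
        call = read.call_for(allele.segment)
        if call.strip() and primary_call(call)[1]:
            hist.skipped += 1
            continue
        d = segment_diff_count(read, allele)
        if d is None:
            hist.skipped += 1
            continue
        hist.bins[d] = hist.bins.get(d, 0) + 1
    hist.bins = dict(sorted(hist.bins.items()))
    return hist


# ---------------------------------------------------------------- tables

def panel_table(panel: AlignmentPanel) -> pd.DataFrame:
    df = panel.to_frame()
    germ = pd.DataFrame(
        [list(panel.germline)], index=["germline"], columns=panel.positions
    )
    cons = pd.DataFrame(
        [list(panel.consensus)], index=["consensus"], columns=panel.positions
    )
    out = pd.concat([germ, cons, df])
    out.index.name = "read_id"
    return out


def histogram_table(hist: MutationHistogram) -> pd.DataFrame:
    return pd.DataFrame(
        {"nt_differences": list(hist.bins), "reads": list(hist.bins.values())}
    )


def usage_table(usage: dict[str, dict[str, int]]) -> pd.DataFrame:
    records = [
        {"gene": gene, "allele": allele, "reads": n}
        for gene, alleles in usage.items()
        for allele, n in alleles.items()
    ]
    return pd.DataFrame(records, columns=["gene", "allele", "reads"])


def haplotype_table(report: HaplotypeReport) -> pd.DataFrame:
    a1, a2 = report.anchor_alleles
    records = []
    for gene, alleles in report.per_gene_counts.items():
        for allele, (c1, c2) in alleles.items():
            flag, ratio = report.exclusivity[allele]
            records.append(
                {
                    "gene": gene,
                    "allele": allele,
                    f"count_{a1}": c1,
                    f"count_{a2}": c2,
                    "exclusive": flag,
                    "ratio": round(ratio, 4),
                }
            )
    return pd.DataFrame(
        records,
        columns=["gene", "allele", f"count_{a1}", f"count_{a2}", "exclusive", "ratio"],
    )


# --------------------------------------------------------------- rendering

_BASE_COLORS = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, GAP: 5, LOW_CONFIDENCE: 6}


def render_alignment(panel: AlignmentPanel, path: str | Path) -> None:
    rows = [panel.germline] + panel.rows
    labels = ["germline"] + panel.read_ids
    if not panel.rows:
        rows, labels = [panel.germline], ["germline"]
    mat = np.array([[_BASE_COLORS.get(c, 4) for c in row] for row in rows])
    fig, ax = plt.subplots(
        figsize=(max(4, len(panel.positions) * 0.06), max(2, len(rows) * 0.12))
    )
    ax.imshow(mat, aspect="auto", cmap="tab10", vmin=0, vmax=9, interpolation="nearest")
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=4)
    step = max(1, len(panel.positions) // 20)
    ax.set_xticks(range(0, len(panel.positions), step))
    ax.set_xticklabels(panel.positions[::step], fontsize=5, rotation=90)
    ax.set_title(f"Alignment of reads assigned to {panel.allele_name}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_histogram(hist: MutationHistogram, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = sorted(hist.bins)
    ax.bar(xs, [hist.bins[x] for x in xs], color="#4878a8")
    ax.set_xlabel("nucleotide differences to germline")
    ax.set_ylabel("reads")
    ax.set_title(f"Reads assigned to {hist.allele_name} by distance to germline")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_usage(usage: dict[str, dict[str, int]], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    labels, values, colors = [], [], []
    palette = plt.get_cmap("tab10")
    for gi, gene in enumerate(sorted(usage)):
        for allele, n in sorted(usage[gene].items()):
            labels.append(allele)
            values.append(n)
            colors.append(palette(gi % 10))
    ax.bar(range(len(values)), values, color=colors)
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("unmutated reads")
    ax.set_title("Allele usage by gene")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_haplotype(report: HaplotypeReport, path: str | Path) -> None:
    a1, a2 = report.anchor_alleles
    alleles, c1s, c2s = [], [], []
    for gene in sorted(report.per_gene_counts):
        for allele, (c1, c2) in sorted(report.per_gene_counts[gene].items()):
            alleles.append(allele)
            c1s.append(c1)
            c2s.append(c2)
    x = np.arange(len(alleles))
    width = 0.4
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(x - width / 2, c1s, width, label=a1, color="#4878a8")
    ax.bar(x + width / 2, c2s, width, label=a2, color="#d1605e")
    ax.set_xticks(x)
    ax.set_xticklabels(alleles, rotation=90, fontsize=7)
    ax.set_ylabel("reads")
    ax.set_title(f"Usage split by {report.anchor_gene} anchor allele")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render(obj, path: str | Path) -> None:
    """Render any computed panel object to an image file (dispatch on type)."""
    if isinstance(obj, AlignmentPanel):
        render_alignment(obj, path)
    elif isinstance(obj, MutationHistogram):
        render_histogram(obj, path)
    elif isinstance(obj, HaplotypeReport):
        render_haplotype(obj, path)
    elif isinstance(obj, dict):
        render_usage(obj, path)
    else:
        raise TypeError(f"cannot render object of type {type(obj).__name__}")
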