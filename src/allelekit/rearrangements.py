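"""AIRR rearrangement TSV input, productivity filtering and call normalization.

The genotype is the set of germline alleles that lead to expressed
*productive* rearrangements, so the productive filter here defines genotype
membership for everything downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sequence_id", "v_call", "j_call", "sequence_alignment", "productive")
OPTIONAL_COLUMNS = (
    "d_call",
    "junction_aa",
    "cdr3",
    "umi",
    "quality_alignment",
    "v_germline_end",
)

_TRUE_STRINGS = {"T", "TRUE", "1"}
_FALSE_STRINGS = {"F", "FALSE", "0", ""}


@dataclass
class Rearrangement:
    """One annotated read.

    ``sequence_alignment`` holds the read's nucleotides on the germline
    IMGT-gapped frame over the V region and beyond; ``v_germline_end`` (when
    set) is the 1-based gapped column of the V 3' end, delimiting the V
    region within the alignment.  ``quals`` are Phred scores for the non-gap
    positions of ``sequence_alignment``, in order.
    """

    read_id: str
    v_call: str
    j_call: str
    sequence_alignment: str
    productive: bool
    d_call: str = ""
    junction_aa: str = ""
    cdr3_nt: str = ""
    umi: str = ""
    quals: list[int] = field(default_factory=list)
    v_germline_end: int | None = None

    def call_for(self, segment: str) -> str:
        return {"V": self.v_call, "D": self.d_call, "J": self.j_call}[segment]

    def segment_region(self, segment: str) -> str:
        """The gapped sub-alignment covering ``segment``.

        For V this is the alignment up to ``v_germline_end`` (the whole
        alignment when unset); for D and J the whole alignment is taken,
        i.e. the file is expected to carry the studied segment's alignment.
        """
        if segment == "V" and self.v_germline_end is not None:
            return self.sequence_alignment[: self.v_germline_end]
        return self.sequence_alignment


def parse_productive(value: str) -> bool:
    """Normalize a productivity flag; unrecognized spellings are treated as
    non-productive (the genotype is built only from expressed productive
    sequences, so the conservative reading is exclusion)."""
    v = str(value).strip().upper()
    if v in _TRUE_STRINGS:
        return True
    if v not in _FALSE_STRINGS:
        logger.warning("unrecognized productive value %r treated as false", value)
    return False


def parse_quals(value: str) -> list[int]:
    """Parse a per-base quality string (ASCII Phred+33, FASTQ convention)."""
    return [ord(c) - 33 for c in str(value)]


def read_airr_tsv(
    path: str | Path, colmap: Mapping[str, str] | None = None
) -> list[Rearrangement]:
    """Read an AIRR rearrangement TSV.

    ``colmap`` maps file header names to AIRR schema names (e.g.
    ``{"seq_id": "sequence_id"}``) so exports from other annotation tools
    can be read without conversion scripts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if colmap:
        df = df.rename(columns=dict(colmap))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"required column {missing[0]!r} not found in {path}")
    reads: list[Rearrangement] = []
    skipped = 0
    for row in df.itertuples(index=False):
        r = row._asdict()
        try:
            alignment = r["sequence_alignment"].strip().upper()
            quals = parse_quals(r["quality_alignment"]) if r.get("quality_alignment") else []
            if quals and len(quals) != len(alignment.replace(".", "")):
                logger.warning(
                    "read %s: quality length %d != non-gap alignment length %d; "
                    "qualities dropped",
                    r["sequence_id"], len(quals), len(alignment.replace(".", "")),
                )
                quals = []
            vge = r.get("v_germline_end", "")
            reads.append(
                Rearrangement(
                    read_id=r["sequence_id"].strip(),
                    v_call=r["v_call"].strip(),
                    j_call=r["j_call"].strip(),
                    d_call=r.get("d_call", "").strip(),
                    sequence_alignment=alignment,
                    productive=parse_productive(r["productive"]),
                    junction_aa=r.get("junction_aa", "").strip(),
                    cdr3_nt=r.get("cdr3", "").strip().upper(),
                    umi=r.get("umi", "").strip(),
                    quals=quals,
                    v_germline_end=int(vge) if str(vge).strip() else None,
                )
            )
        except (KeyError, ValueError, AttributeError) as exc:
            skipped += 1
            logger.warning("skipping unreadable row (%s)", exc)
    logger.info("read %d rearrangements from %s (%d skipped)", len(reads), path, skipped)
    return reads


def filter_productive(reads: Sequence[Rearrangement]) -> list[Rearrangement]:
    """Keep productive reads only. Idempotent."""
    kept = [r for r in reads if r.productive]
    logger.info("productive filter: %d kept, %d removed", len(kept), len(reads) - len(kept))
    return kept


def primary_call(call: str) -> tuple[str, bool]:
    """First allele of a (possibly multi-valued) call string, plus an
    ambiguity flag set when more than one allele is listed."""
    if not call or not call.strip():
        raise ValueError("empty allele call")
    parts = [p.strip() for p in call.split(",") if p.strip()]
    if not parts:
        raise ValueError(f"no allele names in call {call!r}")
    return parts[0], len(parts) > 1
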