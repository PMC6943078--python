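"""Germline reference sets: gapped FASTA I/O, IMGT coordinate maps, discrepancy checks.

V genes are carried on the IMGT-gapped frame, a fixed coordinate system in
which gap columns ('.') make positions comparable across genes.  D and J
genes are ungapped and numbered from the start of the coding sequence.
All coordinates in this package are 1-based and inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GAP = "."
_VALID_CHARS = frozenset("ACGTN.")


class GermlineError(ValueError):
    """Raised for malformed germline input."""


@dataclass(frozen=True)
class GermlineAllele:
    """One germline allele sequence.

    ``name`` follows the ``gene*allele`` convention (e.g. ``IGHJ6*03``) for
    reference alleles; candidate novel alleles carry a submitter name without
    an allele designator (e.g. ``IGHV_S1``).  ``gapped_seq`` may contain '.'
    gap characters (V genes only); ``ungapped_seq`` is derived from it.
    """

    name: str
    gapped_seq: str
    is_novel: bool = False

    def __post_init__(self) -> None:
        bad = [i for i, c in enumerate(self.gapped_seq) if c not in _VALID_CHARS]
        if bad:
            raise GermlineError(
                f"allele {self.name!r}: illegal character "
                f"{self.gapped_seq[bad[0]]!r} at position {bad[0] + 1}"
            )

    @property
    def gene(self) -> str:
        return self.name.split("*")[0]

    @property
    def segment(self) -> str:
        """Segment letter (V, D or J), the fourth character of the name."""
        if len(self.name) < 4 or self.name[3] not in "VDJ":
            raise GermlineError(
                f"cannot derive segment from allele name {self.name!r}"
            )
        return self.name[3]

    @property
    def ungapped_seq(self) -> str:
        return self.gapped_seq.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.gapped_seq)


@dataclass
class ReferenceSet:
    """A collection of germline alleles for one locus, keyed by name."""

    alleles: dict[str, GermlineAllele] = field(default_factory=dict)
    locus: str = "IGH"

    def add(self, allele: GermlineAllele) -> None:
        if allele.name in self.alleles:
            raise GermlineError(f"duplicate allele name {allele.name!r}")
        self.alleles[allele.name] = allele
        self._check_v_frame()

    def _check_v_frame(self) -> None:
        v_lengths = [len(a) for a in self.alleles.values() if a.segment == "V"]
        if v_lengths:
            frame = max(v_lengths)
            # all V alleles must fit the common frame; longer ones would
            # silently shift IMGT coordinates
            over = [
                a.name
                for a in self.alleles.values()
                if a.segment == "V" and len(a) > frame
            ]
            if over:  # pragma: no cover - max() makes this unreachable
                raise GermlineError(f"V alleles exceed the frame: {over}")

    def __contains__(self, name: str) -> bool:
        return name in self.alleles

    def __getitem__(self, name: str) -> GermlineAllele:
        return self.alleles[name]

    def __len__(self) -> int:
        return len(self.alleles)

    def by_segment(self, segment: str) -> list[GermlineAllele]:
        return [a for a in self.alleles.values() if a.segment == segment]

    def novel(self) -> list[GermlineAllele]:
        return [a for a in self.alleles.values() if a.is_novel]

    def reference_proper(self) -> list[GermlineAllele]:
        return [a for a in self.alleles.values() if not a.is_novel]

    @property
    def v_frame_length(self) -> int:
        """Length of the shared gapped V coordinate frame (0 if no V alleles)."""
        return max((len(a) for a in self.by_segment("V")), default=0)


def read_gapped_fasta(
    path: str | Path,
    novel_names: Iterable[str] | None = None,
    locus: str = "IGH",
) -> ReferenceSet:
    """Read a (possibly gapped) germline FASTA into a :class:`ReferenceSet`.

    '-' gap characters are accepted and normalized to '.'.  An allele is
    flagged novel when its name appears in ``novel_names``, or — when
    ``novel_names`` is None — when the name lacks a '*' allele designator
    (the submitter-name convention, e.g. ``IGHV_S1``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    novel_set = set(novel_names) if novel_names is not None else None
    refset = ReferenceSet(locus=locus)
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        name = record.id.strip()
        seq = str(record.seq).upper()
        if "-" in seq:
            logger.info("allele %s: normalizing '-' gaps to '.'", name)
            seq = seq.replace("-", GAP)
        if novel_set is not None:
            is_novel = name in novel_set
        else:
            is_novel = "*" not in name
        try:
            allele = GermlineAllele(name=name, gapped_seq=seq, is_novel=is_novel)
        except GermlineError as exc:
            raise GermlineError(f"record {name!r}: {exc}") from exc
        refset.add(allele)
    if n == 0:
        logger.warning("no records in %s: empty reference set", path)
    return refset


def write_fasta(alleles: Iterable[GermlineAllele], path: str | Path) -> None:
    """Write alleles as gapped FASTA (gap character '.')."""
    records = [
        SeqRecord(Seq(a.gapped_seq), id=a.name, description="") for a in alleles
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def imgt_position_map(allele: GermlineAllele) -> dict[int, int]:
    """Map 1-based ungapped indices to 1-based gapped (IMGT) positions.

    Only defined for V alleles; D and J genes are numbered from the start of
    the coding sequence, i.e. the identity map, and calling this for them is
    an error.
    """
    if allele.segment != "V":
        raise GermlineError(
            f"IMGT position map requested for {allele.segment} allele "
            f"{allele.name!r}; D/J genes use ungapped coding coordinates"
        )
    mapping: dict[int, int] = {}
    ungapped = 0
    for col, char in enumerate(allele.gapped_seq, start=1):
        if char != GAP:
            ungapped += 1
            mapping[ungapped] = col
    return mapping


@dataclass(frozen=True)
class Discrepancy:
    name: str
    kind: str  # "missing" | "sequence_mismatch"
    detail: str


def check_against_reference(
    genotype_alleles: Mapping[str, str], reference: ReferenceSet
) -> list[Discrepancy]:
    """Check named sequences against a reference set.

    Returns one :class:`Discrepancy` per allele whose name is absent from the
    reference, or whose ungapped sequence differs from the same-named
    reference entry.  Discrepancies are data, not errors.
    """
    out: list[Discrepancy] = []
    for name in sorted(genotype_alleles):
        seq = genotype_alleles[name].replace(GAP, "").replace("-", "").upper()
        if name not in reference:
            out.append(Discrepancy(name, "missing", "not in reference set"))
            continue
        ref_seq = reference[name].ungapped_seq
        if seq != ref_seq:
            positions = [
                i + 1
                for i, (a, b) in enumerate(zip(seq, ref_seq))
                if a != b
            ]
            if len(seq) != len(ref_seq):
                detail = (
                    f"length {len(seq)} vs reference {len(ref_seq)}"
                    + (f"; differs at {positions}" if positions else "")
                )
            else:
                detail = f"differs at ungapped position(s) {positions}"
            out.append(Discrepancy(name, "sequence_mismatch", detail))
    return out
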