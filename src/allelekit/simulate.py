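"""Seedable synthetic AIRR repertoires with exact ground truth.

The generator emulates the statistical structure that the genotype evidence
statistics assume: a subject genotype drawn from a germline reference set
plus at least one novel allele, per-read somatic hypermutation at a stated
rate, 3' V-end trimming at the junction, UMI duplication, CDR3 diversity,
and a heterozygous anchor J gene with haplotype-linked novel-allele usage.

Annotation is taken as oracle-correct: the emitted allele calls are the
true alleles each read was generated from, so the fixtures test the
statistics, not an annotator.  Mutations are never placed in gap columns.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .germline import GAP, GermlineAllele, ReferenceSet, write_fasta

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_AA = list("ARNDCQEGHILKMFPSTYV")  # junction residues sampled between C...W

# shared gapped V frame: 312 columns, two codon-aligned gap blocks
# (columns 79-90 and 172-183), giving 288 coding nucleotides
V_FRAME_LEN = 312
V_GAP_BLOCKS = ((79, 90), (172, 183))


@dataclass
class SimConfig:
    """Study conditions for one simulated repertoire.

    ``v_usage``/``j_usage`` are allele-name → weight maps defining the
    subject genotype; ``novel`` lists candidate novel alleles as
    ``(name, base_allele, substitutions)`` built by applying substitutions
    (e.g. ``"G112A"``, gapped coordinates for V) to a reference base;
    ``linkage`` forces a V allele onto one anchor J allele, emulating a
    novel allele that sits on a single chromosome; ``umi_dup_rate`` is the
    probability a molecule is read twice (duplicates share UMI and mutation
    pattern), or None to disable UMIs entirely.
    """

    seed: int = 1
    n_reads: int = 10000
    v_usage: dict[str, float] = field(default_factory=dict)
    j_usage: dict[str, float] = field(default_factory=dict)
    d_alleles: list[str] = field(default_factory=list)
    novel: list[tuple[str, str, list[str]]] = field(default_factory=list)
    mutation_rate: float = 0.01
    trim_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.4, 1: 0.3, 2: 0.2, 3: 0.1}
    )
    umi_dup_rate: float | None = 0.2
    anchor_gene: str = "IGHJ6"
    anchor_alleles: tuple[str, str] = ("IGHJ6*02", "IGHJ6*03")
    linkage: dict[str, str] = field(default_factory=dict)
    low_quality_fraction: float = 0.02
    nonproductive_fraction: float = 0.05

    def validate(self, refset: ReferenceSet) -> None:
        for name in list(self.v_usage) + list(self.j_usage) + self.d_alleles:
            if name not in refset:
                raise ValueError(f"config references unknown allele {name!r}")
        for v_name, j_name in self.linkage.items():
            if v_name not in self.v_usage:
                raise ValueError(f"linkage references allele {v_name!r} not in genotype")
            if j_name not in refset:
                raise ValueError(f"linkage target {j_name!r} not in reference set")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation rate must be in [0, 1)")
        if any(w <= 0 for w in self.v_usage.values()):
            raise ValueError("usage weights must be positive")


@dataclass
class GroundTruth:
    """Exact per-read records and per-allele tallies of every count field."""

    per_read: list[dict] = field(default_factory=list)
    tallies: dict[str, dict] = field(default_factory=dict)
    cross_tab: dict[str, dict[str, int]] = field(default_factory=dict)
    umi_used: bool = True

    def to_dict(self) -> dict:
        return {
            "tallies": self.tallies,
            "cross_tab": self.cross_tab,
            "umi_used": self.umi_used,
            "n_reads": len(self.per_read),
        }


_SUB_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")


def apply_substitutions(base: GermlineAllele, name: str, subs: list[str]) -> GermlineAllele:
    """Build a novel allele by applying substitutions to a reference base.

    Positions are gapped (IMGT) for V and ungapped coding positions for
    D/J, matching the notation of the genotype report (e.g. ``G112A``).
    """
    seq = list(base.gapped_seq)
    for sub in subs:
        m = _SUB_RE.match(sub)
        if not m:
            raise ValueError(f"cannot parse substitution {sub!r}")
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        idx = pos - 1
        if base.segment != "V":
            # ungapped coding position; base D/J sequences carry no gaps
            pass
        if idx >= len(seq) or seq[idx] == GAP:
            raise ValueError(f"substitution {sub!r} falls outside {base.name} or in a gap column")
        if seq[idx] != ref:
            raise ValueError(
                f"substitution {sub!r}: {base.name} has {seq[idx]} at position {pos}, not {ref}"
            )
        seq[idx] = alt
    return GermlineAllele(name=name, gapped_seq="".join(seq), is_novel=True)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _variant(rng: np.random.Generator, seq: str, n_diffs: int, avoid: set[int]) -> str:
    """Copy of ``seq`` with ``n_diffs`` substitutions at non-gap positions
    outside ``avoid`` (0-based)."""
    chars = list(seq)
    eligible = [i for i, c in enumerate(chars) if c != GAP and i not in avoid]
    for i in rng.choice(eligible, size=n_diffs, replace=False):
        old = chars[i]
        choices = [b for b in "ACGT" if b != old]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def build_reference_set(seed: int = 20) -> ReferenceSet:
    """A small deterministic germline reference for simulation and tests.

    Three V genes with two alleles each on the shared gapped frame, two J
    genes (IGHJ6 with the *02/*03 allele pair usable as a heterozygous
    anchor), and two D genes.  IGHV1-69*01 carries G at IMGT position 112
    so the stock novel allele ``IGHV_S1`` (G112A) can be derived from it.
    """
    rng = np.random.default_rng(seed)
    gap_cols = set()
    for lo, hi in V_GAP_BLOCKS:
        gap_cols.update(range(lo - 1, hi))

    def gapped_v(core: str) -> str:
        out, it = [], iter(core)
        for i in range(V_FRAME_LEN):
            out.append(GAP if i in gap_cols else next(it))
        return "".join(out)

    refset = ReferenceSet(locus="IGH")
    v_genes = ("IGHV1-69", "IGHV3-23", "IGHV4-34")
    for gene in v_genes:
        core = _random_seq(rng, V_FRAME_LEN - len(gap_cols))
        a1 = gapped_v(core)
        if gene == "IGHV1-69":
            a1 = a1[:111] + "G" + a1[112:]  # fixed base at IMGT position 112
        a2 = _variant(rng, a1, n_diffs=3, avoid={111})
        refset.add(GermlineAllele(name=f"{gene}*01", gapped_seq=a1))
        second = "*04" if gene == "IGHV3-23" else "*02"
        refset.add(GermlineAllele(name=f"{gene}{second}", gapped_seq=a2))
    j6 = _random_seq(rng, 50)
    refset.add(GermlineAllele(name="IGHJ6*02", gapped_seq=j6))
    refset.add(GermlineAllele(name="IGHJ6*03", gapped_seq=_variant(rng, j6, 2, set())))
    refset.add(GermlineAllele(name="IGHJ4*02", gapped_seq=_random_seq(rng, 48)))
    refset.add(GermlineAllele(name="IGHD3-10*01", gapped_seq=_random_seq(rng, 28)))
    refset.add(GermlineAllele(name="IGHD3-22*01", gapped_seq=_random_seq(rng, 26)))
    return refset


def default_config(seed: int = 1) -> SimConfig:
    """The stock study conditions: a two-allele-per-gene genotype with one
    novel allele (IGHV_S1 = IGHV1-69*01 + G112A) linked exclusively to the
    IGHJ6*03 haplotype of a 50/50 heterozygous IGHJ6 anchor."""
    return SimConfig(
        seed=seed,
        v_usage={
            "IGHV1-69*01": 0.20,
            "IGHV1-69*02": 0.15,
            "IGHV3-23*01": 0.15,
            "IGHV3-23*04": 0.12,
            "IGHV4-34*01": 0.14,
            "IGHV4-34*02": 0.14,
            "IGHV_S1": 0.10,
        },
        j_usage={"IGHJ6*02": 0.35, "IGHJ6*03": 0.35, "IGHJ4*02": 0.30},
        d_alleles=["IGHD3-10*01", "IGHD3-22*01"],
        novel=[("IGHV_S1", "IGHV1-69*01", ["G112A"])],
        linkage={"IGHV_S1": "IGHJ6*03"},
    )


def homozygous_config(seed: int = 1) -> SimConfig:
    """Same genotype but a homozygous J locus: no anchor should be found."""
    cfg = default_config(seed)
    cfg.j_usage = {"IGHJ6*02": 0.7, "IGHJ4*02": 0.3}
    cfg.linkage = {}
    return cfg


def augment_with_novel(refset: ReferenceSet, config: SimConfig) -> ReferenceSet:
    """Reference set plus the config's novel alleles (built from their bases)."""
    out = ReferenceSet(locus=refset.locus)
    for allele in refset.alleles.values():
        out.add(allele)
    for name, base_name, subs in config.novel:
        if name in out:
            continue
        if base_name not in refset:
            raise ValueError(f"novel allele {name!r}: unknown base {base_name!r}")
        out.add(apply_substitutions(refset[base_name], name, subs))
    return out


def _truncate_after_trim(gapped: str, trim: int) -> str:
    """Remove the last ``trim`` non-gap bases (and any trailing gaps)."""
    if trim <= 0:
        return gapped
    kept = len(gapped.replace(GAP, "")) - trim
    out, n = [], 0
    for c in gapped:
        if c != GAP:
            if n >= kept:
                break
            n += 1
        out.append(c)
    while out and out[-1] == GAP:
        out.pop()
    return "".join(out)


def simulate_repertoire(
    config: SimConfig, refset: ReferenceSet
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an AIRR rearrangement table with exact ground truth.

    ``refset`` must already include the config's novel alleles (see
    :func:`augment_with_novel`).  The returned frame uses AIRR column names
    and can be written with ``to_csv(sep="\\t")`` and re-read by
    :mod:`allelekit.rearrangements`.
    """
    config.validate(refset)
    rng = np.random.default_rng(config.seed)
    use_umi = config.umi_dup_rate is not None

    v_names = sorted(config.v_usage)
    v_w = np.array([config.v_usage[n] for n in v_names], dtype=float)
    v_w /= v_w.sum()
    j_names = sorted(config.j_usage)
    j_w = np.array([config.j_usage[n] for n in j_names], dtype=float)
    j_w /= j_w.sum()
    trims = sorted(config.trim_probs)
    trim_w = np.array([config.trim_probs[t] for t in trims], dtype=float)
    trim_w /= trim_w.sum()

    records: list[dict] = []
    truth = GroundTruth(umi_used=use_umi)

    def emit(read_id: str, mol: dict) -> None:
        region = mol["region"]
        alignment = region + mol["cdr3_nt"]
        n_bases = len(alignment.replace(GAP, ""))
        lowq = rng.random(n_bases) < config.low_quality_fraction
        quals = "".join(chr(33 + (2 if lq else 40)) for lq in lowq)
        rec = {
            "sequence_id": read_id,
            "v_call": mol["v"],
            "d_call": mol["d"],
            "j_call": mol["j"],
            "sequence_alignment": alignment,
            "junction_aa": mol["junction_aa"],
            "cdr3": mol["cdr3_nt"],
            "productive": "T" if mol["productive"] else "F",
            "v_germline_end": len(region),
            "quality_alignment": quals,
        }
        if use_umi:
            rec["umi"] = mol["umi"]
        records.append(rec)
        truth.per_read.append(
            {
                "read_id": read_id,
                "v": mol["v"],
                "d": mol["d"],
                "j": mol["j"],
                "mutations": mol["mutations"],
                "umi": mol["umi"] if use_umi else "",
                "junction_aa": mol["junction_aa"],
                "productive": mol["productive"],
            }
        )

    i = 0
    while len(records) < config.n_reads:
        i += 1
        v_name = v_names[rng.choice(len(v_names), p=v_w)]
        if v_name in config.linkage:
            j_name = config.linkage[v_name]
        else:
            j_name = j_names[rng.choice(len(j_names), p=j_w)]
        d_name = (
            config.d_alleles[rng.integers(len(config.d_alleles))]
            if config.d_alleles
            else ""
        )
        trim = trims[rng.choice(len(trims), p=trim_w)]
        region = _truncate_after_trim(refset[v_name].gapped_seq, trim)
        # hypermutation: uniform over covered non-gap positions, never in gaps
        chars = list(region)
        nongap_idx = np.array([k for k, c in enumerate(chars) if c != GAP])
        hits = nongap_idx[rng.random(len(nongap_idx)) < config.mutation_rate]
        for k in hits:
            alts = [b for b in "ACGT" if b != chars[k]]
            chars[k] = alts[rng.integers(3)]
        region = "".join(chars)

        jlen = int(rng.integers(8, 15))
        junction_aa = "C" + "".join(rng.choice(_AA, size=jlen)) + "W"
        cdr3_nt = _random_seq(rng, 3 * (jlen + 2))
        mol = {
            "v": v_name,
            "d": d_name,
            "j": j_name,
            "region": region,
            "mutations": len(hits),
            "junction_aa": junction_aa,
            "cdr3_nt": cdr3_nt,
            "umi": _random_seq(rng, 12) if use_umi else "",
            "productive": bool(rng.random() >= config.nonproductive_fraction),
        }
        emit(f"R{i:06d}_1", mol)
        if (
            use_umi
            and len(records) < config.n_reads
            and rng.random() < config.umi_dup_rate
        ):
            emit(f"R{i:06d}_2", mol)  # PCR duplicate: same UMI, same mutations

    _tally(truth, config)
    columns = [
        "sequence_id", "v_call", "d_call", "j_call", "sequence_alignment",
        "junction_aa", "cdr3", "productive", "v_germline_end", "quality_alignment",
    ] + (["umi"] if use_umi else [])
    frame = pd.DataFrame.from_records(records, columns=columns)
    logger.info("simulated %d reads (%d molecules)", len(frame), i)
    return frame, truth


def _tally(truth: GroundTruth, config: SimConfig) -> None:
    """Aggregate per-read records into per-allele count-field tallies.

    Uses the generator's knowledge of true mutation counts (a read is
    unmutated iff zero mutations were placed), not sequence comparison, so
    the tallies are an independent target for the genotype pipeline.
    Non-productive reads never count: the genotype covers expressed
    productive sequences only.
    """
    productive = [r for r in truth.per_read if r["productive"]]
    by_v: dict[str, list[dict]] = {}
    for r in productive:
        by_v.setdefault(r["v"], []).append(r)
    a1, a2 = config.anchor_alleles
    for v_name in sorted(by_v):
        rs = by_v[v_name]
        unmut = [r for r in rs if r["mutations"] == 0]
        t = {
            "sequences": len(rs),
            "unmutated_sequences": len(unmut),
            "unique_vs": len({r["v"] for r in rs}),
            "unique_ds": len({r["d"] for r in rs if r["d"]}),
            "unique_js": len({r["j"] for r in rs}),
            "unique_cdr3s": len({r["junction_aa"] for r in rs}),
            "unique_vs_unmutated": len({r["v"] for r in unmut}),
            "unique_ds_unmutated": len({r["d"] for r in unmut if r["d"]}),
            "unique_js_unmutated": len({r["j"] for r in unmut}),
            "unique_cdr3s_unmutated": len({r["junction_aa"] for r in unmut}),
        }
        if truth.umi_used:
            t["unmutated_umis"] = len({r["umi"] for r in unmut if r["umi"]})
        truth.tallies[v_name] = t
        truth.cross_tab[v_name] = {
            a1: sum(1 for r in rs if r["j"] == a1),
            a2: sum(1 for r in rs if r["j"] == a2),
        }


def write_fixture(
    config: SimConfig, refset: ReferenceSet, outdir: str | Path
) -> dict[str, Path]:
    """Simulate and write reads.tsv, germline.fasta, novel.fasta, truth.json.

    Re-running with the same config (same seed) reproduces byte-identical
    files.  ``refset`` is the reference proper; the config's novel alleles
    are built and written to novel.fasta.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    full = augment_with_novel(refset, config)
    frame, truth = simulate_repertoire(config, full)
    paths = {
        "reads": outdir / "reads.tsv",
        "germline": outdir / "germline.fasta",
        "novel": outdir / "novel.fasta",
        "truth": outdir / "truth.json",
    }
    frame.to_csv(paths["reads"], sep="\t", index=False, lineterminator="\n")
    write_fasta(full.reference_proper(), paths["germline"])
    write_fasta(full.novel(), paths["novel"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def load_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a flat YAML mapping."""
    with open(path) as fh:
        raw: Mapping = yaml.safe_load(fh) or {}
    cfg = SimConfig()
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        if key == "novel":
            value = [(n, b, list(s)) for n, b, s in value]
        if key == "anchor_alleles":
            value = tuple(value)
        if key == "trim_probs":
            value = {int(k): float(v) for k, v in value.items()}
        setattr(cfg, key, value)
    return cfg
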