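"""Shared fixtures: toy germline sets, a session-scoped simulated repertoire,
and an independent brute-force genotype recount used as an oracle."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import pytest

import allelekit as ak
from allelekit.simulate import augment_with_novel


# ------------------------------------------------------- brute-force oracle

def brute_force_genotype(tsv_path: Path, germline: dict[str, str]) -> dict[str, dict]:
    """Recount every genotype field for V-gene study from the raw TSV.

    Deliberately independent of the package's computation path: plain csv
    module, explicit loops, and its own exact-match comparison.  Returns
    allele -> field dict including the percentage fields at full precision.
    """
    rows = []
    with open(tsv_path) as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            rows.append(rec)

    def productive(rec):
        return rec["productive"].strip().upper() in ("T", "TRUE", "1")

    def primary(call):
        return call.split(",")[0].strip()

    def ambiguous(call):
        return "," in call

    def exact(rec):
        v = primary(rec["v_call"])
        if v not in germline:
            return False
        end = rec.get("v_germline_end", "").strip()
        region = rec["sequence_alignment"]
        if end:
            region = region[: int(end)]
        germ = germline[v]
        n = min(len(region), len(germ))
        for i in range(n):
            a, b = region[i], germ[i]
            if a == "." and b == ".":
                continue
            if a != b:
                return False
        return True

    prod = [r for r in rows if productive(r)]
    per_v: dict[str, list] = {}
    for r in prod:
        per_v.setdefault(primary(r["v_call"]), []).append(r)
    unmut = {
        v: [r for r in rs if not ambiguous(r["v_call"]) and exact(r)]
        for v, rs in per_v.items()
    }
    total_unmut = sum(len(v) for v in unmut.values())
    gene_unmut: dict[str, int] = {}
    for v, rs in unmut.items():
        gene = v.split("*")[0]
        gene_unmut[gene] = gene_unmut.get(gene, 0) + len(rs)

    has_umi = any(r.get("umi", "").strip() for r in prod)
    out = {}
    for v, rs in per_v.items():
        um = unmut[v]
        gene = v.split("*")[0]
        fields = {
            "sequences": len(rs),
            "unmutated_sequences": len(um),
            "assigned_unmutated_frequency": 100.0 * len(um) / len(rs),
            "allelic_percentage": (
                100.0 * len(um) / gene_unmut[gene] if gene_unmut[gene] else None
            ),
            "unmutated_frequency": (
                100.0 * len(um) / total_unmut if total_unmut else None
            ),
            "unique_vs": len({primary(r["v_call"]) for r in rs}),
            "unique_ds": len({primary(r["d_call"]) for r in rs if r["d_call"].strip()}),
            "unique_js": len({primary(r["j_call"]) for r in rs}),
            "unique_cdr3s": len({r["junction_aa"] for r in rs if r["junction_aa"]}),
            "unique_vs_unmutated": len({primary(r["v_call"]) for r in um}),
            "unique_ds_unmutated": len(
                {primary(r["d_call"]) for r in um if r["d_call"].strip()}
            ),
            "unique_js_unmutated": len({primary(r["j_call"]) for r in um}),
            "unique_cdr3s_unmutated": len(
                {r["junction_aa"] for r in um if r["junction_aa"]}
            ),
            "unmutated_umis": (
                len({r["umi"] for r in um if r.get("umi", "").strip()})
                if has_umi
                else None
            ),
        }
        out[v] = fields
    return out


@pytest.fixture(scope="session")
def oracle():
    return brute_force_genotype


# ----------------------------------------------------------- toy germline

TOY_V1 = "ACGTAC...GGGTACGTACGT"  # 21 columns, 3-column gap block
TOY_V2 = "ACGTAC...GGGTACGAACGT"  # differs from V1 at column 17 (T->A)


def make_read(
    read_id="r1",
    v_call="TSTV1-1*01",
    j_call="TSTJ1*01",
    alignment=TOY_V1,
    productive=True,
    d_call="",
    junction_aa="CARW",
    umi="",
    quals=None,
    v_germline_end=None,
):
    return ak.Rearrangement(
        read_id=read_id,
        v_call=v_call,
        j_call=j_call,
        d_call=d_call,
        sequence_alignment=alignment,
        productive=productive,
        junction_aa=junction_aa,
        umi=umi,
        quals=quals or [],
        v_germline_end=v_germline_end,
    )


@pytest.fixture()
def toy_refset():
    rs = ak.ReferenceSet(locus="TST")
    rs.add(ak.GermlineAllele(name="TSTV1-1*01", gapped_seq=TOY_V1))
    rs.add(ak.GermlineAllele(name="TSTV1-1*02", gapped_seq=TOY_V2))
    rs.add(ak.GermlineAllele(name="TSTJ1*01", gapped_seq="ATTACTAC"))
    rs.add(ak.GermlineAllele(name="TSTJ1*02", gapped_seq="ATTACTAA"))
    return rs


# ------------------------------------------------ session-scoped simulation

@dataclass
class SimBundle:
    config: ak.SimConfig
    refset: ak.ReferenceSet  # reference + novel alleles
    paths: dict[str, Path]
    truth: ak.GroundTruth
    reads: list  # all reads as parsed back from the TSV
    genotype: ak.Genotype


def _simulate(tmp_root: Path, config: ak.SimConfig) -> SimBundle:
    base = ak.build_reference_set()
    full = augment_with_novel(base, config)
    paths = ak.write_fixture(config, base, tmp_root)
    _, truth = ak.simulate_repertoire(config, full)
    reads = ak.read_airr_tsv(paths["reads"])
    genotype = ak.compute_genotype(ak.filter_productive(reads), full, "V")
    return SimBundle(config, full, paths, truth, reads, genotype)


@pytest.fixture(scope="session")
def sim(tmp_path_factory) -> SimBundle:
    """The stock study conditions: 10,000 reads, 1% mutation rate, two
    alleles per gene, one novel allele linked to the IGHJ6*03 haplotype."""
    return _simulate(tmp_path_factory.mktemp("sim"), ak.default_config(seed=7))


@pytest.fixture(scope="session")
def sim_homozygous(tmp_path_factory) -> SimBundle:
    cfg = ak.homozygous_config(seed=7)
    cfg.n_reads = 4000
    return _simulate(tmp_path_factory.mktemp("sim_hom"), cfg)
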