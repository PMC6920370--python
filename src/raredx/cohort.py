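"""The in-memory cohort bundle and its on-disk layout.

A cohort directory holds everything one analysis run consumes:

* ``cohort.vcf`` — multi-sample genotypes
* ``cohort.ped`` — pedigrees with label-confidence column
* ``annotations.tsv`` — per-variant annotation table
* ``cnv.tsv`` / ``genes.tsv`` — CNV segments and gene intervals
* ``genome.tsv`` — chromosome lengths
* ``manifest.json`` — the simulator's truth manifest (synthetic cohorts only)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .annotation import AnnotationFrame
from .genome import CHROM_LENGTHS
from .pedigree import Pedigree, mark_sequenced, parse_ped, write_ped
from .variants import (
    CNVSegment,
    GeneInterval,
    VariantKey,
    VariantTable,
    sample_family_map,
)
from . import io as cio


@dataclass
class TruthManifest:
    """Ground truth recorded by the synthetic-cohort generator."""

    scenario: str
    target_family: str
    causal_keys: list[list] = field(default_factory=list)  # [chrom,pos,ref,alt]
    causal_gene: str | None = None
    hidden_locus: tuple[str, int] | None = None
    cnv_segment: tuple[str, int, int, str] | None = None
    label_flips: list[tuple[str, str]] = field(default_factory=list)  # (family, individual)
    seed: int | None = None

    @property
    def causal_variant_keys(self) -> list[VariantKey]:
        return [(c, int(p), r, a) for c, p, r, a in self.causal_keys]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        d["hidden_locus"] = tuple(d["hidden_locus"]) if d.get("hidden_locus") else None
        d["cnv_segment"] = tuple(d["cnv_segment"]) if d.get("cnv_segment") else None
        d["label_flips"] = [tuple(x) for x in d.get("label_flips", [])]
        return cls(**d)


@dataclass
class Cohort:
    pedigrees: list[Pedigree]
    table: VariantTable
    annotations: AnnotationFrame
    cnv_segments: list[CNVSegment] = field(default_factory=list)
    genes: list[GeneInterval] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(CHROM_LENGTHS))
    manifest: TruthManifest | None = None

    def __post_init__(self) -> None:
        self.sample_family = sample_family_map(self.pedigrees)

    def pedigree(self, family_id: str) -> Pedigree:
        for ped in self.pedigrees:
            if ped.family_id == family_id:
                return ped
        raise KeyError(f"no family {family_id!r} in cohort")

    @property
    def family_ids(self) -> list[str]:
        return [p.family_id for p in self.pedigrees]


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_vcf(out / "cohort.vcf", cohort.table.samples, cohort.table.to_records())
    (out / "cohort.ped").write_text(write_ped(cohort.pedigrees))
    cio.write_annotations(out / "annotations.tsv", cohort.annotations.to_records())
    cio.write_cnv_table(out / "cnv.tsv", cohort.cnv_segments)
    cio.write_gene_table(out / "genes.tsv", cohort.genes)
    with open(out / "genome.tsv", "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in cohort.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    if cohort.manifest is not None:
        (out / "manifest.json").write_text(cohort.manifest.to_json())
    return out


def load_cohort(in_dir: str | Path) -> Cohort:
    d = Path(in_dir)
    samples, table = cio.read_vcf_table(d / "cohort.vcf")
    pedigrees = parse_ped((d / "cohort.ped").read_text())
    mark_sequenced(pedigrees, samples)
    ann_records = cio.read_annotations(d / "annotations.tsv")
    annotations = AnnotationFrame.from_records(table.keys(), ann_records)
    cnv = cio.read_cnv_table(d / "cnv.tsv") if (d / "cnv.tsv").exists() else []
    genes = cio.read_gene_table(d / "genes.tsv") if (d / "genes.tsv").exists() else []
    chrom_lengths: dict[str, int] = {}
    if (d / "genome.tsv").exists():
        for line in (d / "genome.tsv").read_text().splitlines()[1:]:
            if line.strip():
                chrom, length = line.split("\t")
                chrom_lengths[chrom] = int(length)
    else:
        chrom_lengths = dict(CHROM_LENGTHS)
    manifest = None
    if (d / "manifest.json").exists():
        manifest = TruthManifest.from_json((d / "manifest.json").read_text())
    return Cohort(
        pedigrees=pedigrees,
        table=table,
        annotations=annotations,
        cnv_segments=cnv,
        genes=genes,
        chrom_lengths=chrom_lengths,
        manifest=manifest,
    )
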