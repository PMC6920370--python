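"""Readers and writers for the cohort file formats.

Formats: multi-sample VCF 4.2 (GT, optional GQ) via pysam, PED (see
:mod:`raredx.pedigree`), and three tab-separated tables — per-variant
annotations, CNV segments and gene intervals (the latter two BED-like,
0-based half-open).  Multiallelic VCF sites are normalized to biallelic
records at ingest because every downstream filter reasons per alt allele.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import (
    PREDICTORS,
    AnnotationRecord,
    FuncClass,
    PredictorCall,
    POPULATIONS,
)
from .variants import (
    CNVSegment,
    CNVState,
    GeneInterval,
    GenotypeCall,
    VariantKey,
    VariantRecord,
    VariantTable,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _split_genotype(
    gt: tuple[int | None, ...] | None, alt_index: int
) -> tuple[int | None, int | None] | None:
    """Remap one sample's multiallelic GT onto the biallelic record for
    ``alt_index`` (1-based).  Other alt alleles become missing slots so the
    per-sample multiset of non-reference alleles is conserved across splits."""
    if gt is None or len(gt) == 0 or all(a is None for a in gt):
        return None
    if len(gt) == 1:  # haploid call: pad with a missing slot
        gt = (gt[0], None)
    a, b = gt[0], gt[1]

    def remap(x: int | None) -> int | None:
        if x is None:
            return None
        if x == 0:
            return 0
        return 1 if x == alt_index else None

    return (remap(a), remap(b))


def read_vcf(path: str | Path) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF into biallelic :class:`VariantRecord` objects in file order."""
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        if "GT" not in vf.header.formats:
            raise FormatError(f"{path}: GT missing from FORMAT header")
        samples = list(vf.header.samples)
        records: list[VariantRecord] = []
        for rec in vf:
            if rec.alts is None:
                continue
            gts = {}
            for s in samples:
                sd = rec.samples[s]
                gts[s] = (sd["GT"], sd.get("GQ"))
            for j, alt in enumerate(rec.alts, start=1):
                calls = {}
                for s, (gt, gq) in gts.items():
                    alleles = _split_genotype(gt, j)
                    calls[s] = GenotypeCall(alleles, None if gq is None else float(gq))
                records.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alt, calls))
    return samples, records


def read_vcf_table(path: str | Path) -> tuple[list[str], VariantTable]:
    samples, records = read_vcf(path)
    return samples, VariantTable.from_records(samples, records)


def write_vcf(
    path: str | Path,
    samples: Sequence[str],
    records: Iterable[VariantRecord],
) -> None:
    """Write biallelic records as VCF 4.2 with GT (and GQ where present)."""
    import pysam

    records = list(records)
    header = pysam.VariantHeader()
    contigs: list[str] = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    for c in contigs:
        header.contigs.add(c)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype Quality")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            vrec = out.new_record(
                contig=rec.chrom, start=rec.pos - 1, alleles=(rec.ref, rec.alt)
            )
            for s in samples:
                call = rec.call(s)
                vrec.samples[s]["GT"] = call.alleles if call.alleles is not None else (None, None)
                if call.quality is not None:
                    vrec.samples[s]["GQ"] = int(call.quality)
            out.write(vrec)


# ---------------------------------------------------------------------------
# annotation table
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS: tuple[str, ...] = (
    ("chrom", "pos", "ref", "alt", "gene", "func_class")
    + POPULATIONS
    + ("dbsnp", "esp", "esp_freq")
    + PREDICTORS
)

_PREDICTOR_IN = {"D": PredictorCall.DAMAGING, "T": PredictorCall.TOLERATED,
                 ".": PredictorCall.MISSING, "": PredictorCall.MISSING}


def read_annotations(path: str | Path) -> dict[VariantKey, AnnotationRecord]:
    """Read the tab-separated annotation table keyed by (chrom,pos,ref,alt).

    Variants absent from the table are novel: callers should fall back to an
    empty :class:`AnnotationRecord`.  Duplicate keys: last row wins (warning
    logged).  Malformed numeric fields raise with the offending line number.
    """
    out: dict[VariantKey, AnnotationRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty annotation file") from None
        if tuple(header) != ANNOTATION_COLUMNS:
            raise FormatError(
                f"{path}: unexpected annotation header {header[:6]}..., "
                f"expected columns {ANNOTATION_COLUMNS[:6]}..."
            )
        col = {name: i for i, name in enumerate(header)}
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            try:
                key: VariantKey = (
                    row[col["chrom"]],
                    int(row[col["pos"]]),
                    row[col["ref"]],
                    row[col["alt"]],
                )
                pop_freq = {}
                for pop in POPULATIONS:
                    cell = row[col[pop]].strip()
                    if cell not in ("", "."):
                        pop_freq[pop] = float(cell)
                esp_cell = row[col["esp_freq"]].strip()
                gene = row[col["gene"]].strip()
                cls = row[col["func_class"]].strip()
                rec = AnnotationRecord(
                    gene=gene if gene not in ("", ".") else None,
                    func_class=FuncClass(cls) if cls not in ("", ".") else None,
                    pop_freq=pop_freq,
                    in_dbsnp=row[col["dbsnp"]].strip() in ("1", "true", "True"),
                    in_esp=row[col["esp"]].strip() in ("1", "true", "True"),
                    esp_freq=float(esp_cell) if esp_cell not in ("", ".") else None,
                    predictor_calls={
                        tool: _PREDICTOR_IN[row[col[tool]].strip()] for tool in PREDICTORS
                    },
                )
            except (ValueError, KeyError, IndexError) as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
            if key in out:
                logger.warning("duplicate annotation for %s:%d %s>%s (line %d); last row wins",
                               key[0], key[1], key[2], key[3], lineno)
            out[key] = rec
    return out


def write_annotations(
    path: str | Path, records: Mapping[VariantKey, AnnotationRecord]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for (chrom, pos, ref, alt), rec in records.items():
            row = [chrom, pos, ref, alt,
                   rec.gene or ".",
                   rec.func_class.value if rec.func_class else "."]
            for pop in POPULATIONS:
                row.append(f"{rec.pop_freq[pop]:.6g}" if pop in rec.pop_freq else ".")
            row.append("1" if rec.in_dbsnp else "0")
            row.append("1" if rec.in_esp else "0")
            row.append(f"{rec.esp_freq:.6g}" if rec.esp_freq is not None else ".")
            for tool in PREDICTORS:
                row.append(rec.predictor_calls[tool].value)
            writer.writerow(row)


# ---------------------------------------------------------------------------
# BED-like tables: CNV segments and gene intervals
# ---------------------------------------------------------------------------

def _bed_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if lineno == 1 and line.split("\t")[0].lower() == "chrom":
                continue  # optional header row
            yield lineno, line.split("\t")


def read_cnv_table(path: str | Path) -> list[CNVSegment]:
    """Read chrom/start/end/state/sample rows, sorted by (chrom, start)."""
    segs = []
    for lineno, row in _bed_rows(path):
        if len(row) < 5:
            raise FormatError(f"{path} line {lineno}: expected 5 columns, got {len(row)}")
        try:
            segs.append(
                CNVSegment(row[0], int(row[1]), int(row[2]), CNVState(row[3]), row[4])
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {lineno}: {exc}") from exc
    segs.sort(key=lambda s: (s.chrom, s.start, s.end, s.sample_id))
    return segs


def write_cnv_table(path: str | Path, segments: Iterable[CNVSegment]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstate\tsample\n")
        for seg in sorted(segments, key=lambda s: (s.chrom, s.start, s.end, s.sample_id)):
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.state.value}\t{seg.sample_id}\n")


def _parse_exons(cell: str) -> tuple[tuple[int, int], ...]:
    if cell in ("", "."):
        return ()
    out = []
    for part in cell.split(","):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def read_gene_table(path: str | Path) -> list[GeneInterval]:
    """Read chrom/start/end/symbol/strand/exons/cds_start/cds_end rows."""
    genes = []
    for lineno, row in _bed_rows(path):
        if len(row) < 8:
            raise FormatError(f"{path} line {lineno}: expected 8 columns, got {len(row)}")
        try:
            genes.append(
                GeneInterval(
                    chrom=row[0],
                    start=int(row[1]),
                    end=int(row[2]),
                    symbol=row[3],
                    strand=row[4],
                    exons=_parse_exons(row[5]),
                    cds_start=None if row[6] in ("", ".") else int(row[6]),
                    cds_end=None if row[7] in ("", ".") else int(row[7]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {lineno}: {exc}") from exc
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


def write_gene_table(path: str | Path, genes: Iterable[GeneInterval]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsymbol\tstrand\texons\tcds_start\tcds_end\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end)):
            exons = ",".join(f"{s}-{e}" for s, e in g.exons) or "."
            cs = "." if g.cds_start is None else g.cds_start
            ce = "." if g.cds_end is None else g.cds_end
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\t{g.strand}\t{exons}\t{cs}\t{ce}\n")


def read_reference(path: str | Path) -> dict[str, str]:
    """Read a (toy) reference FASTA into a chrom -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# preflight validation
# ---------------------------------------------------------------------------

def _chrom_style(chroms: Iterable[str]) -> set[str]:
    return {"chr" if c.startswith("chr") else "bare" for c in chroms}


def validate_cohort(
    vcf_samples: Sequence[str],
    pedigrees: Sequence,
    vcf_chroms: Iterable[str] = (),
    table_chroms: Iterable[str] = (),
) -> list[str]:
    """Return a list of human-readable consistency problems (empty = clean).

    Checks: VCF samples are known pedigree members, every family has a
    sequenced affected member, and chromosome naming ("chr" prefix or bare)
    is internally consistent across files.
    """
    problems = []
    ped_ids = {m.id for ped in pedigrees for m in ped.members}
    for s in vcf_samples:
        if s not in ped_ids:
            problems.append(f"VCF sample {s!r} not present in any pedigree")
    for ped in pedigrees:
        if not any(m.sequenced and m.affection.value == "affected" for m in ped.members):
            problems.append(f"family {ped.family_id} has no sequenced affected member")
    styles = _chrom_style(vcf_chroms) | _chrom_style(table_chroms)
    if len(styles) > 1:
        problems.append("inconsistent chromosome naming across files (chr-prefixed and bare)")
    return problems
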