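"""Functional annotation and the frequency / database / predictor filters.

A candidate causal variant for a rare Mendelian disease must be (a) rare in
reference populations, (b) not a well-characterized common polymorphism, and
(c) predicted to damage the protein.  This module implements those three
filters:

* a multi-condition population-frequency rule over the 1000 Genomes
  super-populations (remove when >=1 population reaches 0.05, or >=2 reach
  0.03, or >=3 reach 0.025, or >=4 reach 0.02);
* a polymorphism-database filter over dbSNP / ESP membership, with a
  default policy (frequency-evidence based) and a strict policy (any dbSNP
  membership removes);
* a consensus vote over eight in-silico effect predictors (SIFT, PolyPhen,
  LRT, MutationTaster, MutationAssessor, FATHMM, MetaSVM, MetaLR) in which
  damaging calls must outnumber tolerated calls for a missense variant,
  while protein-truncating classes (nonsense, frameshift, canonical splice)
  count as deleterious outright since the predictors only score non-silent
  amino-acid substitutions.

Functional classification against a toy gene model (exons + coding span on a
supplied reference sequence) is provided for self-contained cohorts; it is a
minimal stand-in for transcript-aware annotators, not a reimplementation of
them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .variants import GeneInterval, VariantKey, VariantRecord

POPULATIONS: tuple[str, ...] = ("AFR", "AMR", "EAS", "EUR", "SAS")

PREDICTORS: tuple[str, ...] = (
    "SIFT",
    "PolyPhen",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "MetaSVM",
    "MetaLR",
)


class FuncClass(enum.Enum):
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"


#: classes treated as deleterious without consulting the predictors
TRUNCATING_CLASSES = frozenset(
    {FuncClass.NONSENSE, FuncClass.FRAMESHIFT_INDEL, FuncClass.SPLICING}
)


class PredictorCall(enum.Enum):
    DAMAGING = "D"
    TOLERATED = "T"
    MISSING = "."


@dataclass
class AnnotationRecord:
    """Annotation for one variant. An all-defaults record is a novel variant."""

    gene: str | None = None
    func_class: FuncClass | None = None
    pop_freq: dict[str, float] = field(default_factory=dict)
    in_dbsnp: bool = False
    in_esp: bool = False
    esp_freq: float | None = None
    predictor_calls: dict[str, PredictorCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, f in self.pop_freq.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"frequency {f} for {pop} outside [0, 1]")
        for tool in self.predictor_calls:
            if tool not in PREDICTORS:
                raise ValueError(f"unknown predictor {tool!r}")
        # exactly eight entries: absent tools are explicit MISSING
        for tool in PREDICTORS:
            self.predictor_calls.setdefault(tool, PredictorCall.MISSING)

    @property
    def n_damaging(self) -> int:
        return sum(1 for c in self.predictor_calls.values() if c is PredictorCall.DAMAGING)

    @property
    def n_tolerated(self) -> int:
        return sum(1 for c in self.predictor_calls.values() if c is PredictorCall.TOLERATED)


@dataclass(frozen=True)
class FrequencyRule:
    """Remove a variant when any (min_populations, threshold) clause fires.

    A clause (k, t) fires when at least k populations have frequency >= t.
    Thresholds must be strictly decreasing as k increases: a variant common
    in one population, or moderately frequent in several, is too common to
    cause a rare disease.
    """

    conditions: tuple[tuple[int, float], ...] = ((1, 0.05), (2, 0.03), (3, 0.025), (4, 0.02))

    def __post_init__(self) -> None:
        ks = [k for k, _ in self.conditions]
        ts = [t for _, t in self.conditions]
        if any(k2 <= k1 for k1, k2 in zip(ks, ks[1:])):
            raise ValueError("min_populations must be strictly increasing")
        if any(t2 >= t1 for t1, t2 in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly decreasing")
        if any(k < 1 or not (0 < t <= 1) for k, t in self.conditions):
            raise ValueError("conditions must have k >= 1 and 0 < t <= 1")

    @classmethod
    def parse(cls, text: str) -> "FrequencyRule":
        """Parse "k:t,k:t,..." (the --freq-rule CLI syntax)."""
        conds = []
        for part in text.split(","):
            k, t = part.split(":")
            conds.append((int(k), float(t)))
        return cls(tuple(conds))


DEFAULT_FREQUENCY_RULE = FrequencyRule()


def frequency_filter(rec: AnnotationRecord, rule: FrequencyRule = DEFAULT_FREQUENCY_RULE) -> bool:
    """True = keep. Absent populations count as unobserved (frequency ~ 0)."""
    freqs = list(rec.pop_freq.values())
    for k, t in rule.conditions:
        if sum(1 for f in freqs if f >= t) >= k:
            return False
    return True


class DatabasePolicy(enum.Enum):
    DEFAULT = "default"
    STRICT = "strict"


def database_filter(
    rec: AnnotationRecord,
    rule: FrequencyRule = DEFAULT_FREQUENCY_RULE,
    policy: DatabasePolicy | str = DatabasePolicy.DEFAULT,
) -> bool:
    """True = keep.

    Default policy: remove iff the frequency rule removes, or the variant is
    in ESP with a recorded frequency at or above the single-population
    threshold.  Bare dbSNP membership without frequency evidence does not
    remove (known pathogenic alleles have rs ids too).  Strict policy:
    additionally remove on any dbSNP membership.
    """
    if isinstance(policy, str):
        try:
            policy = DatabasePolicy(policy)
        except ValueError:
            raise ValueError(f"unknown database policy {policy!r}") from None
    if not frequency_filter(rec, rule):
        return False
    single_pop_threshold = rule.conditions[0][1]
    if rec.in_esp and rec.esp_freq is not None and rec.esp_freq >= single_pop_threshold:
        return False
    if policy is DatabasePolicy.STRICT and rec.in_dbsnp:
        return False
    return True


def deleterious_vote(rec: AnnotationRecord, min_margin: int = 1) -> bool:
    """Consensus call over the eight predictors.

    Truncating/splice classes are deleterious unconditionally.  Missense
    needs damaging calls to exceed tolerated calls by at least ``min_margin``
    among non-missing calls (ties and all-missing are not deleterious).
    Non-frameshift indels need at least one damaging call.  Synonymous and
    noncoding variants are never deleterious.
    """
    if rec.func_class in TRUNCATING_CLASSES:
        return True
    if rec.func_class is FuncClass.MISSENSE:
        return rec.n_damaging - rec.n_tolerated >= min_margin
    if rec.func_class is FuncClass.NONFRAMESHIFT_INDEL:
        return rec.n_damaging >= 1
    return False


# ---------------------------------------------------------------------------
# functional classification against a toy gene model
# ---------------------------------------------------------------------------

SPLICE_FLANK = 2  # canonical donor/acceptor dinucleotide


def _coding_segments(gene: GeneInterval) -> list[tuple[int, int]]:
    if gene.cds_start is None or gene.cds_end is None:
        return []
    segs = []
    for s, e in gene.exons:
        cs, ce = max(s, gene.cds_start), min(e, gene.cds_end)
        if cs < ce:
            segs.append((cs, ce))
    return segs


def _splice_sites(gene: GeneInterval) -> set[int]:
    """0-based positions of the +/-2 intronic bases flanking coding exons."""
    sites: set[int] = set()
    segs = _coding_segments(gene)
    exon_spans = gene.exons
    for i, (s, e) in enumerate(exon_spans):
        if not any(cs < e and s < ce for cs, ce in segs):
            continue  # exon fully non-coding
        if i > 0:  # acceptor side: intron precedes this exon
            sites.update(range(s - SPLICE_FLANK, s))
        if i < len(exon_spans) - 1:  # donor side: intron follows
            sites.update(range(e, e + SPLICE_FLANK))
    return sites


def _coding_sequence(gene: GeneInterval, chrom_seq: str) -> tuple[str, dict[int, int]]:
    """CDS sequence (5'->3' of the mRNA) and genomic-pos -> cds-index map."""
    segs = _coding_segments(gene)
    seq_parts = []
    index: dict[int, int] = {}
    offset = 0
    for s, e in segs:
        seq_parts.append(chrom_seq[s:e])
        for g in range(s, e):
            index[g] = offset + (g - s)
        offset += e - s
    cds = "".join(seq_parts)
    if gene.strand == "-":
        n = len(cds)
        cds = str(Seq(cds).reverse_complement())
        index = {g: n - 1 - i for g, i in index.items()}
    return cds, index


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def classify_functional(
    v: VariantRecord,
    genes: Iterable[GeneInterval],
    reference: Mapping[str, str],
) -> list[tuple[str | None, FuncClass]]:
    """Classify a variant's effect against every gene it overlaps.

    Returns one (gene symbol, class) pair per overlapped gene; a variant
    outside all genes yields a single ``(None, noncoding)`` entry.  Splice
    assignment (within the 2 intronic bases flanking a coding exon) takes
    precedence over everything else; inside the CDS an indel is frameshift
    iff its net length is not a multiple of 3, and an SNV is classified by
    codon translation of the toy reference.
    """
    pos0 = v.pos - 1
    # genomic footprint of the change (VCF-style anchored alleles share base 0)
    if v.is_snv:
        span = (pos0, pos0 + 1)
    elif len(v.ref) > len(v.alt):  # deletion: affected bases follow the anchor
        span = (pos0 + 1, pos0 + len(v.ref))
    else:  # insertion: the junction between anchor base and the next
        span = (pos0, pos0 + 2)
    out: list[tuple[str | None, FuncClass]] = []
    for gene in genes:
        if not gene.overlaps(v.chrom, span[0], span[1]):
            continue
        out.append((gene.symbol, _classify_in_gene(v, gene, reference, pos0, span)))
    if not out:
        return [(None, FuncClass.NONCODING)]
    return out


def _classify_in_gene(
    v: VariantRecord,
    gene: GeneInterval,
    reference: Mapping[str, str],
    pos0: int,
    span: tuple[int, int],
) -> FuncClass:
    splice = _splice_sites(gene)
    if any(p in splice for p in range(span[0], span[1])):
        return FuncClass.SPLICING
    segs = _coding_segments(gene)
    in_cds = any(s < span[1] and span[0] < e for s, e in segs)
    if not v.is_snv:
        if not in_cds:
            return FuncClass.NONCODING
        if v.indel_length % 3 != 0:
            return FuncClass.FRAMESHIFT_INDEL
        return FuncClass.NONFRAMESHIFT_INDEL
    if not any(s <= pos0 < e for s, e in segs):
        return FuncClass.NONCODING
    chrom_seq = reference[v.chrom]
    cds, index = _coding_sequence(gene, chrom_seq)
    ci = index[pos0]
    codon_start = ci - ci % 3
    codon = cds[codon_start : codon_start + 3]
    if len(codon) < 3:
        return FuncClass.NONCODING  # truncated terminal codon in toy model
    alt_base = v.alt if gene.strand == "+" else v.alt.translate(_COMPLEMENT)
    mutated = list(codon)
    mutated[ci - codon_start] = alt_base
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq("".join(mutated)).translate())
    if aa_alt == aa_ref:
        return FuncClass.SYNONYMOUS
    if aa_alt == "*":
        return FuncClass.NONSENSE
    return FuncClass.MISSENSE


# ---------------------------------------------------------------------------
# vectorized annotation frame for whole-cohort filtering
# ---------------------------------------------------------------------------

_CLASS_CODES = {c: i for i, c in enumerate(FuncClass)}
_TRUNCATING_CODES = np.array([_CLASS_CODES[c] for c in TRUNCATING_CLASSES])
_MISSENSE_CODE = _CLASS_CODES[FuncClass.MISSENSE]
_NONFS_CODE = _CLASS_CODES[FuncClass.NONFRAMESHIFT_INDEL]


# predictor-call codes in the (n_variants, 8) matrix
PRED_MISSING, PRED_DAMAGING, PRED_TOLERATED = 0, 1, 2
_PRED_CODE = {
    PredictorCall.MISSING: PRED_MISSING,
    PredictorCall.DAMAGING: PRED_DAMAGING,
    PredictorCall.TOLERATED: PRED_TOLERATED,
}
_CODE_PRED = {v: k for k, v in _PRED_CODE.items()}
_CODE_CLASS = {i: c for c, i in _CLASS_CODES.items()}


class AnnotationFrame:
    """Column-wise annotation store aligned to a list of variant keys.

    Mirrors the scalar filters above as array operations; equivalence with
    the record-level functions is asserted by a property test.  ``pred`` is
    an (n_variants, 8) int8 matrix of per-tool calls in ``PREDICTORS``
    order, coded missing/damaging/tolerated = 0/1/2.
    """

    def __init__(
        self,
        keys: Sequence[VariantKey],
        gene: np.ndarray,
        freq: np.ndarray,
        in_dbsnp: np.ndarray,
        in_esp: np.ndarray,
        esp_freq: np.ndarray,
        class_code: np.ndarray,
        pred: np.ndarray,
    ) -> None:
        n = len(keys)
        self.keys = list(keys)
        self.gene = np.asarray(gene, dtype=object)
        self.freq = np.asarray(freq, dtype=float)
        self.in_dbsnp = np.asarray(in_dbsnp, dtype=bool)
        self.in_esp = np.asarray(in_esp, dtype=bool)
        self.esp_freq = np.asarray(esp_freq, dtype=float)
        self.class_code = np.asarray(class_code, dtype=np.int8)
        self.pred = np.asarray(pred, dtype=np.int8)
        if self.freq.shape != (n, len(POPULATIONS)) or self.pred.shape != (n, len(PREDICTORS)):
            raise ValueError("annotation column shapes do not match key count")

    @classmethod
    def from_records(
        cls,
        keys: Sequence[VariantKey],
        records: Mapping[VariantKey, AnnotationRecord],
    ) -> "AnnotationFrame":
        """Build the frame for ``keys``; unlisted keys get a novel (empty)
        annotation."""
        n = len(keys)
        gene = np.empty(n, dtype=object)
        freq = np.full((n, len(POPULATIONS)), np.nan)
        in_dbsnp = np.zeros(n, dtype=bool)
        in_esp = np.zeros(n, dtype=bool)
        esp_freq = np.full(n, np.nan)
        class_code = np.full(n, -1, dtype=np.int8)
        pred = np.zeros((n, len(PREDICTORS)), dtype=np.int8)
        empty = AnnotationRecord()
        for i, key in enumerate(keys):
            rec = records.get(key, empty)
            gene[i] = rec.gene
            for j, pop in enumerate(POPULATIONS):
                if pop in rec.pop_freq:
                    freq[i, j] = rec.pop_freq[pop]
            in_dbsnp[i] = rec.in_dbsnp
            in_esp[i] = rec.in_esp
            if rec.esp_freq is not None:
                esp_freq[i] = rec.esp_freq
            if rec.func_class is not None:
                class_code[i] = _CLASS_CODES[rec.func_class]
            for j, tool in enumerate(PREDICTORS):
                pred[i, j] = _PRED_CODE[rec.predictor_calls[tool]]
        return cls(keys, gene, freq, in_dbsnp, in_esp, esp_freq, class_code, pred)

    def record(self, i: int) -> AnnotationRecord:
        return AnnotationRecord(
            gene=self.gene[i],
            func_class=_CODE_CLASS.get(int(self.class_code[i])),
            pop_freq={
                pop: float(self.freq[i, j])
                for j, pop in enumerate(POPULATIONS)
                if not np.isnan(self.freq[i, j])
            },
            in_dbsnp=bool(self.in_dbsnp[i]),
            in_esp=bool(self.in_esp[i]),
            esp_freq=None if np.isnan(self.esp_freq[i]) else float(self.esp_freq[i]),
            predictor_calls={
                tool: _CODE_PRED[int(self.pred[i, j])] for j, tool in enumerate(PREDICTORS)
            },
        )

    def to_records(self) -> dict[VariantKey, AnnotationRecord]:
        return {key: self.record(i) for i, key in enumerate(self.keys)}

    @property
    def n_damaging(self) -> np.ndarray:
        return (self.pred == PRED_DAMAGING).sum(axis=1)

    @property
    def n_tolerated(self) -> np.ndarray:
        return (self.pred == PRED_TOLERATED).sum(axis=1)

    def __len__(self) -> int:
        return len(self.keys)

    def frequency_keep(self, rule: FrequencyRule = DEFAULT_FREQUENCY_RULE) -> np.ndarray:
        remove = np.zeros(len(self), dtype=bool)
        with np.errstate(invalid="ignore"):
            for k, t in rule.conditions:
                remove |= (self.freq >= t).sum(axis=1) >= k
        return ~remove

    def database_keep(
        self,
        rule: FrequencyRule = DEFAULT_FREQUENCY_RULE,
        policy: DatabasePolicy | str = DatabasePolicy.DEFAULT,
    ) -> np.ndarray:
        if isinstance(policy, str):
            policy = DatabasePolicy(policy)
        keep = self.frequency_keep(rule)
        with np.errstate(invalid="ignore"):
            keep &= ~(self.in_esp & (self.esp_freq >= rule.conditions[0][1]))
        if policy is DatabasePolicy.STRICT:
            keep &= ~self.in_dbsnp
        return keep

    def deleterious(self, min_margin: int = 1) -> np.ndarray:
        out = np.isin(self.class_code, _TRUNCATING_CODES)
        out |= (self.class_code == _MISSENSE_CODE) & (
            self.n_damaging.astype(int) - self.n_tolerated >= min_margin
        )
        out |= (self.class_code == _NONFS_CODE) & (self.n_damaging >= 1)
        return out
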