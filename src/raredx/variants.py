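"""In-memory containers for variant calls, CNV segments and gene models.

Two views of the same genotype data coexist:

* record level — :class:`VariantRecord` with per-sample :class:`GenotypeCall`
  objects, the unit the segregation predicates are defined on;
* matrix level — :class:`VariantTable`, a dense ``(n_variants, n_samples, 2)``
  ``int8`` allele array (-1 = missing allele) used by the vectorized filter
  engine so whole-cohort scans stay cheap.

Allele slots are individually optional: after a multiallelic site is split
into biallelic records, an allele belonging to one of the *other* alternate
alleles is represented as missing in the current record, so the per-sample
multiset of non-reference alleles is conserved across the split.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

VariantKey = tuple[str, int, str, str]  # (chrom, pos, ref, alt)


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid call at one biallelic site.

    ``alleles`` is None for a fully missing call; otherwise a pair where each
    slot is 0 (ref), 1 (alt) or None (missing / other-alt allele).
    """

    alleles: tuple[int | None, int | None] | None = None
    quality: float | None = None

    # -- predicates used by the segregation filters ---------------------
    @property
    def is_missing(self) -> bool:
        return self.alleles is None or all(a is None for a in self.alleles)

    @property
    def alt_count(self) -> int:
        if self.alleles is None:
            return 0
        return sum(1 for a in self.alleles if a == 1)

    @property
    def carries_alt(self) -> bool:
        return self.alt_count >= 1

    @property
    def is_hom_alt(self) -> bool:
        return self.alleles is not None and self.alleles[0] == 1 and self.alleles[1] == 1

    @property
    def is_hom_ref(self) -> bool:
        return self.alleles is not None and self.alleles[0] == 0 and self.alleles[1] == 0

    @property
    def is_het(self) -> bool:
        if self.alleles is None:
            return False
        return sorted(a for a in self.alleles if a is not None) == [0, 1] and None not in self.alleles

    @property
    def has_ref_allele(self) -> bool:
        return self.alleles is not None and any(a == 0 for a in self.alleles)

    def __str__(self) -> str:
        if self.alleles is None:
            return "./."
        return "/".join("." if a is None else str(a) for a in self.alleles)


MISSING_CALL = GenotypeCall(None, None)


@dataclass
class VariantRecord:
    """One biallelic site with per-sample genotype calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        """Signed net length change (insertions positive)."""
        return len(self.alt) - len(self.ref)

    def call(self, sample: str) -> GenotypeCall:
        return self.calls.get(sample, MISSING_CALL)


class CNVState(enum.Enum):
    LOSS = "loss"
    GAIN = "gain"


@dataclass(frozen=True)
class CNVSegment:
    """A copy-number segment in BED convention (0-based half-open)."""

    chrom: str
    start: int
    end: int
    state: CNVState
    sample_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad CNV span [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "CNVSegment") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneInterval:
    """Minimal gene model: span, strand, exons and coding span (BED coords)."""

    chrom: str
    start: int
    end: int
    symbol: str
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene span for {self.symbol}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.symbol}")
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise ValueError(f"exons of {self.symbol} not sorted/disjoint within gene span")
            prev_end = e

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


class VariantTable:
    """Dense genotype matrix over a fixed sample order.

    ``geno`` has shape (n_variants, n_samples, 2) with values in {-1, 0, 1}
    where -1 marks a missing allele slot.
    """

    def __init__(
        self,
        samples: Sequence[str],
        chrom: Sequence[str],
        pos: np.ndarray,
        ref: Sequence[str],
        alt: Sequence[str],
        geno: np.ndarray,
        qual: np.ndarray | None = None,
    ) -> None:
        self.samples = list(samples)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.geno = np.asarray(geno, dtype=np.int8)
        self.qual = qual
        n = len(self.pos)
        if self.geno.shape != (n, len(self.samples), 2):
            raise ValueError(f"genotype matrix shape {self.geno.shape} does not match "
                             f"{n} variants x {len(self.samples)} samples")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    def __len__(self) -> int:
        return len(self.pos)

    def sample_index(self, sample: str) -> int:
        return self._sample_index[sample]

    def key(self, i: int) -> VariantKey:
        return (self.chrom[i], int(self.pos[i]), self.ref[i], self.alt[i])

    def keys(self) -> list[VariantKey]:
        return [self.key(i) for i in range(len(self))]

    # -- vectorized genotype summaries ----------------------------------
    def carries_alt(self) -> np.ndarray:
        """(n, s) bool: at least one called alt allele."""
        return (self.geno == 1).any(axis=2)

    def hom_alt(self) -> np.ndarray:
        return (self.geno == 1).all(axis=2)

    def has_ref_allele(self) -> np.ndarray:
        return (self.geno == 0).any(axis=2)

    def hom_ref(self) -> np.ndarray:
        return (self.geno == 0).all(axis=2)

    def strict_het(self) -> np.ndarray:
        return (self.geno == 1).any(axis=2) & (self.geno == 0).any(axis=2)

    # -- conversions -----------------------------------------------------
    @classmethod
    def from_records(
        cls, samples: Sequence[str], records: Iterable[VariantRecord]
    ) -> "VariantTable":
        recs = list(records)
        n, s = len(recs), len(samples)
        geno = np.full((n, s, 2), -1, dtype=np.int8)
        chrom, pos, ref, alt = [], [], [], []
        for i, rec in enumerate(recs):
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref)
            alt.append(rec.alt)
            for j, sample in enumerate(samples):
                call = rec.call(sample)
                if call.alleles is not None:
                    for k, a in enumerate(call.alleles):
                        geno[i, j, k] = -1 if a is None else a
        return cls(samples, chrom, np.array(pos, dtype=np.int64), ref, alt, geno)

    def record(self, i: int) -> VariantRecord:
        calls = {}
        for j, sample in enumerate(self.samples):
            a, b = int(self.geno[i, j, 0]), int(self.geno[i, j, 1])
            if a < 0 and b < 0:
                calls[sample] = MISSING_CALL
            else:
                calls[sample] = GenotypeCall(
                    (None if a < 0 else a, None if b < 0 else b)
                )
        return VariantRecord(self.chrom[i], int(self.pos[i]), self.ref[i], self.alt[i], calls)

    def to_records(self) -> list[VariantRecord]:
        return [self.record(i) for i in range(len(self))]

    def subset(self, mask_or_index: np.ndarray) -> "VariantTable":
        idx = np.asarray(mask_or_index)
        return VariantTable(
            self.samples,
            self.chrom[idx],
            self.pos[idx],
            self.ref[idx],
            self.alt[idx],
            self.geno[idx],
            None if self.qual is None else self.qual[idx],
        )


def sample_family_map(pedigrees: Iterable) -> dict[str, str]:
    """Map individual id -> family id over a pedigree collection."""
    out: dict[str, str] = {}
    for ped in pedigrees:
        for m in ped.members:
            out[m.id] = ped.family_id
    return out
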