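"""Shared builders: tiny pedigrees, random small cohorts for oracle checks."""

from __future__ import annotations

import numpy as np
import pytest

from raredx.pedigree import (
    Affection,
    Individual,
    LabelConfidence,
    Pedigree,
    Sex,
)
from raredx.variants import GenotypeCall, VariantRecord


def ind(
    i: str,
    fam: str = "F1",
    father: str | None = None,
    mother: str | None = None,
    sex: Sex = Sex.MALE,
    aff: Affection = Affection.UNAFFECTED,
    sequenced: bool = True,
    confidence: LabelConfidence = LabelConfidence.SOFT,
) -> Individual:
    return Individual(
        id=i, family_id=fam, father_id=father, mother_id=mother,
        sex=sex, affection=aff, label_confidence=confidence, sequenced=sequenced,
    )


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        "F1",
        [
            ind("f", sex=Sex.MALE),
            ind("m", sex=Sex.FEMALE),
            ind("c", father="f", mother="m", sex=Sex.MALE, aff=Affection.AFFECTED),
        ],
    )


@pytest.fixture
def quartet() -> Pedigree:
    return Pedigree(
        "F1",
        [
            ind("f", sex=Sex.MALE),
            ind("m", sex=Sex.FEMALE),
            ind("c1", father="f", mother="m", sex=Sex.MALE, aff=Affection.AFFECTED),
            ind("c2", father="f", mother="m", sex=Sex.FEMALE),
        ],
    )


def variant(
    genotypes: dict[str, tuple | None],
    chrom: str = "chr1",
    pos: int = 100,
    ref: str = "A",
    alt: str = "G",
) -> VariantRecord:
    calls = {s: GenotypeCall(g) for s, g in genotypes.items()}
    return VariantRecord(chrom, pos, ref, alt, calls)


# ---------------------------------------------------------------------------
# random small cohorts for oracle comparisons
# ---------------------------------------------------------------------------

_GT_CHOICES: list[tuple | None] = [
    (0, 0), (0, 1), (1, 1), None, (0, None), (1, None),
]
_GT_WEIGHTS = np.array([0.45, 0.25, 0.12, 0.08, 0.05, 0.05])

_AFF_CHOICES = [Affection.AFFECTED, Affection.UNAFFECTED, Affection.UNKNOWN]


def random_pedigree(rng: np.random.Generator, fam: str = "F1") -> Pedigree:
    """A random family of 3-8 members: a founder couple, 1-4 children,
    optionally a married-in spouse + grandchild, random sexes/labels, with
    at least one sequenced affected member."""
    members = [
        ind("f", fam, sex=Sex.MALE),
        ind("m", fam, sex=Sex.FEMALE),
    ]
    n_children = int(rng.integers(1, 5))
    for k in range(n_children):
        members.append(
            ind(f"c{k}", fam, father="f", mother="m",
                sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE)
        )
    if rng.random() < 0.4 and n_children >= 1:
        spouse_sex = Sex.FEMALE if members[2].sex is Sex.MALE else Sex.MALE
        members.append(ind("s0", fam, sex=spouse_sex))
        father_id = "c0" if members[2].sex is Sex.MALE else "s0"
        mother_id = "s0" if members[2].sex is Sex.MALE else "c0"
        members.append(
            ind("g0", fam, father=father_id, mother=mother_id,
                sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE)
        )
    for m in members:
        m.affection = _AFF_CHOICES[int(rng.choice(3, p=[0.4, 0.45, 0.15]))]
        m.sequenced = bool(rng.random() < 0.85)
    # guarantee one sequenced affected
    pick = members[int(rng.integers(0, len(members)))]
    pick.affection = Affection.AFFECTED
    pick.sequenced = True
    return Pedigree(fam, members)


def random_variants(
    rng: np.random.Generator,
    samples: list[str],
    n: int,
    n_genes: int = 4,
) -> list[VariantRecord]:
    """Random biallelic records over ``samples``, some on chrX, clustered
    into a few genes via position buckets."""
    out = []
    for i in range(n):
        chrom = "chrX" if rng.random() < 0.3 else "chr1"
        pos = int(rng.integers(1, n_genes * 1000))
        genotypes = {
            s: _GT_CHOICES[int(rng.choice(len(_GT_CHOICES), p=_GT_WEIGHTS))]
            for s in samples
        }
        out.append(variant(genotypes, chrom=chrom, pos=pos + i * 10_000))
    return out
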