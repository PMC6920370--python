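"""Pedigree parsing, validation and affection-label relabeling.

Pedigrees are the backbone of every segregation filter: each filter is a
predicate over the genotypes of a family's sequenced members given their
affection labels.  Because clinical affection labels can be wrong (mild or
late-onset phenotypes, self-report bias), labels carry a confidence flag and
the :func:`enumerate_relabelings` generator enumerates bounded sets of
affected<->unaffected flips for the misclassification-tolerant search.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class LabelConfidence(enum.Enum):
    FIRM = "firm"
    SOFT = "soft"


class PedigreeError(ValueError):
    """Raised on malformed or inconsistent pedigree input."""


# PLINK PED dialect codes
_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_AFF_CODES = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED, "0": Affection.UNKNOWN}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_OUT = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}


@dataclass
class Individual:
    id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    label_confidence: LabelConfidence = LabelConfidence.SOFT
    sequenced: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """One family: an ordered collection of :class:`Individual`.

    Validation enforces that parent references resolve, that the parent
    relation is acyclic, that referenced fathers/mothers are male/female
    (unknown sex is inferred and fixed), and that at least one member is
    affected.
    """

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookup helpers -------------------------------------------------
    def __iter__(self) -> Iterator[Individual]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def get(self, ind_id: str) -> Individual:
        try:
            return self._index[ind_id]
        except KeyError:
            raise PedigreeError(f"no individual {ind_id!r} in family {self.family_id}")

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._index

    def validate(self) -> None:
        self._index: dict[str, Individual] = {}
        for ind in self.members:
            if ind.family_id != self.family_id:
                raise PedigreeError(
                    f"member {ind.id} has family {ind.family_id!r}, expected {self.family_id!r}"
                )
            if ind.id in self._index:
                raise PedigreeError(f"duplicate individual id {ind.id!r} in family {self.family_id}")
            self._index[ind.id] = ind
        for ind in self.members:
            for pid, want_sex in ((ind.father_id, Sex.MALE), (ind.mother_id, Sex.FEMALE)):
                if pid is None:
                    continue
                if pid not in self._index:
                    raise PedigreeError(
                        f"individual {ind.id} references undefined parent {pid!r} "
                        f"in family {self.family_id}"
                    )
                parent = self._index[pid]
                if parent.sex is Sex.UNKNOWN:
                    parent.sex = want_sex  # infer from parental role
                elif parent.sex is not want_sex:
                    raise PedigreeError(
                        f"parent {pid} of {ind.id} has sex {parent.sex.value}, "
                        f"expected {want_sex.value}"
                    )
        self._check_acyclic()
        if not any(m.affection is Affection.AFFECTED for m in self.members):
            raise PedigreeError(f"family {self.family_id} has no affected member")

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 = visiting, 1 = done

        def visit(ind_id: str, chain: list[str]) -> None:
            if state.get(ind_id) == 1:
                return
            if state.get(ind_id) == 0:
                raise PedigreeError(
                    f"pedigree cycle in family {self.family_id}: {' -> '.join(chain + [ind_id])}"
                )
            state[ind_id] = 0
            ind = self._index[ind_id]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid, chain + [ind_id])
            state[ind_id] = 1

        for ind in self.members:
            visit(ind.id, [])

    # -- derived views ---------------------------------------------------
    def affected(self) -> list[Individual]:
        return [m for m in self.members if m.affection is Affection.AFFECTED]

    def unaffected(self) -> list[Individual]:
        return [m for m in self.members if m.affection is Affection.UNAFFECTED]

    def sequenced_members(self) -> list[Individual]:
        return [m for m in self.members if m.sequenced]

    def parents_of(self, ind_id: str) -> tuple[Individual | None, Individual | None]:
        ind = self.get(ind_id)
        father = self._index.get(ind.father_id) if ind.father_id else None
        mother = self._index.get(ind.mother_id) if ind.mother_id else None
        return father, mother

    def topological_order(self) -> list[Individual]:
        """Members ordered founders-first (parents precede children)."""
        done: set[str] = set()
        out: list[Individual] = []

        def visit(ind: Individual) -> None:
            if ind.id in done:
                return
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(self._index[pid])
            done.add(ind.id)
            out.append(ind)

        for ind in self.members:
            visit(ind)
        return out

    def with_labels(self, labels: Mapping[str, Affection]) -> "Pedigree":
        """Copy of the pedigree with affection labels overridden."""
        members = [
            replace(m, affection=labels.get(m.id, m.affection)) for m in self.members
        ]
        return Pedigree(self.family_id, members)


@dataclass(frozen=True)
class LabelAssignment:
    """A full affection-label map obtained by flipping a set of soft labels."""

    labels: Mapping[str, Affection]
    flipped_ids: frozenset[str]

    @property
    def flip_count(self) -> int:
        return len(self.flipped_ids)


def parse_ped(text: str) -> list[Pedigree]:
    """Parse whitespace-delimited PED content into one Pedigree per family.

    Columns: family, id, father, mother, sex (1/2/0), affection (2/1/0),
    optional 7th column ``firm``/``soft`` (default soft).  Parent code "0"
    means founder.  Families are returned in first-seen order.
    """
    families: dict[str, list[Individual]] = {}
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) not in (6, 7):
            raise PedigreeError(f"PED line {lineno}: expected 6 or 7 columns, got {len(fields)}")
        fam, ind_id, father, mother, sex_code, aff_code = fields[:6]
        if (fam, ind_id) in seen:
            raise PedigreeError(f"PED line {lineno}: duplicate individual ({fam}, {ind_id})")
        seen.add((fam, ind_id))
        if sex_code not in _SEX_CODES:
            raise PedigreeError(f"PED line {lineno}: bad sex code {sex_code!r}")
        if aff_code not in _AFF_CODES:
            raise PedigreeError(f"PED line {lineno}: bad affection code {aff_code!r}")
        confidence = LabelConfidence.SOFT
        if len(fields) == 7:
            try:
                confidence = LabelConfidence(fields[6].lower())
            except ValueError:
                raise PedigreeError(f"PED line {lineno}: bad confidence {fields[6]!r}") from None
        families.setdefault(fam, []).append(
            Individual(
                id=ind_id,
                family_id=fam,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_SEX_CODES[sex_code],
                affection=_AFF_CODES[aff_code],
                label_confidence=confidence,
            )
        )
    return [Pedigree(fam, members) for fam, members in families.items()]


def write_ped(pedigrees: Iterable[Pedigree]) -> str:
    """Serialize pedigrees back to 7-column PED text (round-trips parse_ped)."""
    lines = []
    for ped in pedigrees:
        for m in ped.members:
            lines.append(
                "\t".join(
                    [
                        ped.family_id,
                        m.id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _SEX_OUT[m.sex],
                        _AFF_OUT[m.affection],
                        m.label_confidence.value,
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def mark_sequenced(pedigrees: Iterable[Pedigree], sample_ids: Iterable[str]) -> None:
    """Set each member's ``sequenced`` flag from a VCF sample-id list.

    Unsequenced members are retained: they contribute pedigree structure
    (parent inference) but never constrain genotype-based filters.
    """
    samples = set(sample_ids)
    for ped in pedigrees:
        for m in ped.members:
            m.sequenced = m.id in samples


_FLIP = {
    Affection.AFFECTED: Affection.UNAFFECTED,
    Affection.UNAFFECTED: Affection.AFFECTED,
}


def flippable_members(ped: Pedigree) -> list[Individual]:
    """Members whose label the misclassification search may flip: sequenced,
    soft-confidence, with a known (affected/unaffected) label."""
    return [
        m
        for m in ped.members
        if m.sequenced
        and m.label_confidence is LabelConfidence.SOFT
        and m.affection in _FLIP
    ]


def enumerate_relabelings(ped: Pedigree, max_flips: int) -> Iterator[LabelAssignment]:
    """Yield label assignments with 0..max_flips flips of soft sequenced labels.

    Ordered by ascending flip count; within a flip count, lexicographically by
    the sorted tuple of flipped ids.  Unknown labels are never flipped (they
    are unconstrained in every filter).  The first assignment is always the
    identity.
    """
    if max_flips < 0:
        raise ValueError("max_flips must be nonnegative")
    base = {m.id: m.affection for m in ped.members}
    soft_ids = sorted(m.id for m in flippable_members(ped))
    for k in range(0, max_flips + 1):
        if k > len(soft_ids):
            break
        for combo in itertools.combinations(soft_ids, k):
            labels = dict(base)
            for ind_id in combo:
                labels[ind_id] = _FLIP[labels[ind_id]]
            yield LabelAssignment(labels=labels, flipped_ids=frozenset(combo))


def count_relabelings(n_soft: int, max_flips: int) -> int:
    """Closed-form count of assignments: sum_{k<=max_flips} C(n_soft, k)."""
    from math import comb

    return sum(comb(n_soft, k) for k in range(0, min(max_flips, n_soft) + 1))
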