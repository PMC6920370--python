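"""Inheritance-mode segregation filters and the misclassification search.

Under the "rare disease, rare variant" assumption, a causal variant must
track the affection labels of a family under one of five transmission
models: dominant, recessive (homozygous), compound heterozygous, X-linked
recessive, or de novo.  All sequenced individuals outside the analyzed
family additionally serve as healthy controls (cross-family exclusion).

Missing-genotype semantics: a missing call can never *violate* a predicate
(WGS at ~30x has dropout), but a variant must still be positively supported
by at least one affected individual's observed genotype.  A partially
missing call like 0/. can hide an alt allele and therefore does not violate
a carrier requirement, while any observed alt allele in a control does
violate a non-carrier requirement.

Because clinical affection labels may be wrong, every predicate takes an
optional label override, and :func:`misclassification_search` re-runs the
filters under all bounded relabelings of soft-confidence labels, reporting
each surviving candidate at the minimal number of flips that rescues it.

Two implementations coexist: per-record predicates (``fits_*``, the
reference semantics) and :class:`FamilyGenotypeEngine`, a genotype-matrix
version used for whole-cohort scans; a property test asserts equivalence.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .pedigree import (
    Affection,
    Individual,
    LabelAssignment,
    Pedigree,
    Sex,
    count_relabelings,
    enumerate_relabelings,
    flippable_members,
)
from .variants import GenotypeCall, VariantKey, VariantRecord, VariantTable

DEFAULT_X_CHROM = "chrX"


class InheritanceModel(enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE_HOM = "recessive_hom"
    COMPOUND_HET = "compound_het"
    X_LINKED = "x_linked"
    DE_NOVO = "de_novo"


ALL_MODELS: tuple[InheritanceModel, ...] = tuple(InheritanceModel)


class ConfigurationError(ValueError):
    """Model/pedigree combination that can never be evaluated."""


@dataclass(frozen=True)
class SegregationResult:
    key: VariantKey
    model: InheritanceModel
    partner: VariantKey | None = None
    phase_unknown: bool = False
    assignment: LabelAssignment | None = None

    def __post_init__(self) -> None:
        if (self.partner is not None) != (self.model is InheritanceModel.COMPOUND_HET):
            raise ValueError("partner present iff model is compound_het")


# ---------------------------------------------------------------------------
# per-call predicate helpers (missing never violates)
# ---------------------------------------------------------------------------

def _violates_must_carry(c: GenotypeCall) -> bool:
    return c.is_hom_ref


def _violates_must_not_carry(c: GenotypeCall) -> bool:
    return c.carries_alt


def _violates_must_be_hom_alt(c: GenotypeCall) -> bool:
    return c.has_ref_allele


def _violates_must_not_be_hom_alt(c: GenotypeCall) -> bool:
    return c.is_hom_alt


def _violates_must_be_het(c: GenotypeCall) -> bool:
    return c.is_hom_ref or c.is_hom_alt


def _label(ind: Individual, labels: Mapping[str, Affection] | None) -> Affection:
    if labels is None:
        return ind.affection
    return labels.get(ind.id, ind.affection)


def _groups(
    ped: Pedigree, labels: Mapping[str, Affection] | None
) -> tuple[list[Individual], list[Individual]]:
    aff, unaff = [], []
    for m in ped.sequenced_members():
        lab = _label(m, labels)
        if lab is Affection.AFFECTED:
            aff.append(m)
        elif lab is Affection.UNAFFECTED:
            unaff.append(m)
    return aff, unaff


# ---------------------------------------------------------------------------
# the five model predicates
# ---------------------------------------------------------------------------

def fits_dominant(
    v: VariantRecord, ped: Pedigree, labels: Mapping[str, Affection] | None = None
) -> bool:
    """Every sequenced affected carries an alt allele; no sequenced
    unaffected does; unknown labels are unconstrained."""
    aff, unaff = _groups(ped, labels)
    if any(_violates_must_carry(v.call(m.id)) for m in aff):
        return False
    if any(_violates_must_not_carry(v.call(m.id)) for m in unaff):
        return False
    return any(v.call(m.id).carries_alt for m in aff)


def fits_recessive_hom(
    v: VariantRecord, ped: Pedigree, labels: Mapping[str, Affection] | None = None
) -> bool:
    """Affecteds homozygous alt, unaffecteds not, and every sequenced parent
    of an affected is a carrier (excludes apparent de novo homozygotes)."""
    aff, unaff = _groups(ped, labels)
    if any(_violates_must_be_hom_alt(v.call(m.id)) for m in aff):
        return False
    if any(_violates_must_not_be_hom_alt(v.call(m.id)) for m in unaff):
        return False
    for m in aff:
        for parent in ped.parents_of(m.id):
            if parent is not None and parent.sequenced:
                if _violates_must_carry(v.call(parent.id)):
                    return False
    return any(v.call(m.id).is_hom_alt for m in aff)


def fits_x_linked(
    v: VariantRecord,
    ped: Pedigree,
    labels: Mapping[str, Affection] | None = None,
    x_chrom: str = DEFAULT_X_CHROM,
) -> bool:
    """X-linked recessive: affected males carry (hemizygotes may be coded
    0/1 or 1/1 by diploid callers), affected females are hom-alt, unaffected
    males carry nothing, unaffected females are not hom-alt.  Unknown-sex
    individuals are unconstrained."""
    if v.chrom != x_chrom:
        return False
    aff, unaff = _groups(ped, labels)
    for m in aff:
        c = v.call(m.id)
        if m.sex is Sex.MALE and _violates_must_carry(c):
            return False
        if m.sex is Sex.FEMALE and _violates_must_be_hom_alt(c):
            return False
    for m in unaff:
        c = v.call(m.id)
        if m.sex is Sex.MALE and _violates_must_not_carry(c):
            return False
        if m.sex is Sex.FEMALE and _violates_must_not_be_hom_alt(c):
            return False
    return any(
        (m.sex is Sex.MALE and v.call(m.id).carries_alt)
        or (m.sex is Sex.FEMALE and v.call(m.id).is_hom_alt)
        for m in aff
    )


def _trio_affecteds(ped: Pedigree, aff: Iterable[Individual]) -> list[Individual]:
    out = []
    for m in aff:
        father, mother = ped.parents_of(m.id)
        if father is not None and father.sequenced and mother is not None and mother.sequenced:
            out.append(m)
    return out


def fits_de_novo(
    v: VariantRecord, ped: Pedigree, labels: Mapping[str, Affection] | None = None
) -> bool:
    """Affecteds carry, their sequenced parent pairs do not, and — stricter
    than minimal trio logic — no sequenced unaffected in the family carries
    either (the extended family serves as controls)."""
    aff, unaff = _groups(ped, labels)
    trio_aff = _trio_affecteds(ped, aff)
    if not trio_aff:
        return False
    if any(_violates_must_carry(v.call(m.id)) for m in aff):
        return False
    for m in trio_aff:
        for parent in ped.parents_of(m.id):
            if _violates_must_not_carry(v.call(parent.id)):
                return False
    if any(_violates_must_not_carry(v.call(m.id)) for m in unaff):
        return False
    return any(v.call(m.id).carries_alt for m in trio_aff)


@dataclass(frozen=True)
class CompoundHetPair:
    a: VariantKey
    b: VariantKey
    phase_unknown: bool


def _parental_origin(
    v: VariantRecord, father: Individual, mother: Individual
) -> str:
    f, m = v.call(father.id), v.call(mother.id)
    if f.carries_alt and not m.carries_alt:
        return "father"
    if m.carries_alt and not f.carries_alt:
        return "mother"
    return "ambiguous"


def fits_compound_het(
    gene: str,
    variants: Sequence[VariantRecord],
    ped: Pedigree,
    labels: Mapping[str, Affection] | None = None,
) -> list[CompoundHetPair]:
    """Qualifying trans pairs of heterozygous variants within one gene.

    A pair qualifies when every sequenced affected is het for both variants,
    no sequenced unaffected carries both, and — where an affected has both
    parents sequenced — the two variants come from different parents.  Pairs
    whose phase cannot be resolved from parental genotypes are returned
    flagged ``phase_unknown`` rather than discarded.
    """
    aff, unaff = _groups(ped, labels)
    candidates = []
    for v in variants:
        if any(_violates_must_be_het(v.call(m.id)) for m in aff):
            continue
        if not any(v.call(m.id).is_het for m in aff):
            continue
        candidates.append(v)
    trio_aff = _trio_affecteds(ped, aff)
    pairs: list[CompoundHetPair] = []
    for va, vb in itertools.combinations(sorted(candidates, key=lambda v: v.key), 2):
        if any(
            va.call(m.id).carries_alt and vb.call(m.id).carries_alt for m in unaff
        ):
            continue
        phase_known_trans = False
        cis = False
        for m in trio_aff:
            father, mother = ped.parents_of(m.id)
            oa = _parental_origin(va, father, mother)
            ob = _parental_origin(vb, father, mother)
            if "ambiguous" in (oa, ob):
                continue
            if oa == ob:
                cis = True
                break
            phase_known_trans = True
        if cis:
            continue
        pairs.append(CompoundHetPair(va.key, vb.key, phase_unknown=not phase_known_trans))
    return pairs


# ---------------------------------------------------------------------------
# cross-family controls and the per-family run
# ---------------------------------------------------------------------------

def cross_family_exclude(
    v: VariantRecord, sample_family: Mapping[str, str], target_family: str
) -> bool:
    """True = keep.  Remove when any sequenced individual outside the target
    family carries an alt allele; missing calls never trigger removal."""
    for sample, call in v.calls.items():
        if sample_family.get(sample) != target_family and call.carries_alt:
            return False
    return True


def check_model_feasibility(
    ped: Pedigree, models: Iterable[InheritanceModel]
) -> None:
    if InheritanceModel.DE_NOVO in set(models):
        aff = [m for m in ped.sequenced_members() if m.affection is Affection.AFFECTED]
        if not _trio_affecteds(ped, aff):
            raise ConfigurationError(
                f"de_novo requested for family {ped.family_id} but no sequenced "
                "affected has both parents sequenced"
            )


def run_segregation(
    ped: Pedigree,
    variants: Sequence[VariantRecord],
    models: Sequence[InheritanceModel],
    labels: Mapping[str, Affection] | None = None,
    sample_family: Mapping[str, str] | None = None,
    gene_of: Mapping[VariantKey, str | None] | None = None,
    x_chrom: str = DEFAULT_X_CHROM,
    assignment: LabelAssignment | None = None,
) -> dict[InheritanceModel, list[SegregationResult]]:
    """Apply cross-family exclusion then each requested model filter.

    ``gene_of`` (variant key -> gene symbol) is required to evaluate the
    compound-het model; variants without a gene are skipped for that model.
    """
    check_model_feasibility(ped, models)
    if sample_family is not None:
        variants = [v for v in variants if cross_family_exclude(v, sample_family, ped.family_id)]
    out: dict[InheritanceModel, list[SegregationResult]] = {m: [] for m in models}
    simple = {
        InheritanceModel.DOMINANT: fits_dominant,
        InheritanceModel.RECESSIVE_HOM: fits_recessive_hom,
        InheritanceModel.DE_NOVO: fits_de_novo,
    }
    for model in models:
        if model in simple:
            fn = simple[model]
            out[model] = [
                SegregationResult(v.key, model, assignment=assignment)
                for v in variants
                if fn(v, ped, labels)
            ]
        elif model is InheritanceModel.X_LINKED:
            out[model] = [
                SegregationResult(v.key, model, assignment=assignment)
                for v in variants
                if fits_x_linked(v, ped, labels, x_chrom)
            ]
        elif model is InheritanceModel.COMPOUND_HET:
            if gene_of is None:
                continue
            by_gene: dict[str, list[VariantRecord]] = {}
            for v in variants:
                gene = gene_of.get(v.key)
                if gene:
                    by_gene.setdefault(gene, []).append(v)
            for gene in sorted(by_gene):
                for pair in fits_compound_het(gene, by_gene[gene], ped, labels):
                    out[model].append(
                        SegregationResult(
                            pair.a, model, partner=pair.b,
                            phase_unknown=pair.phase_unknown, assignment=assignment,
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# misclassification-tolerant search
# ---------------------------------------------------------------------------

@dataclass
class SearchHit:
    """One candidate surviving the cascade at its minimal flip count."""

    key: VariantKey
    model: InheritanceModel
    min_flips: int
    flip_sets: list[frozenset[str]] = field(default_factory=list)
    partner: VariantKey | None = None
    phase_unknown: bool = False


def misclassification_search(
    ped: Pedigree,
    variants: Sequence[VariantRecord],
    models: Sequence[InheritanceModel],
    max_flips: int,
    labels: Mapping[str, Affection] | None = None,
    sample_family: Mapping[str, str] | None = None,
    gene_of: Mapping[VariantKey, str | None] | None = None,
    x_chrom: str = DEFAULT_X_CHROM,
    post_filter: Callable[[VariantKey], bool] | None = None,
    max_assignments: int = 100_000,
) -> list[SearchHit]:
    """Run the segregation cascade under every soft-label relabeling with at
    most ``max_flips`` flips; report each surviving candidate once, at the
    minimal flip count where it first appears, with all rescuing flip sets
    of that size.  ``post_filter`` (the downstream annotation filters) is
    applied before a candidate is reported.

    Hits are ranked by (minimal flip count, number of distinct flip sets,
    genomic coordinate).
    """
    if max_flips < 0:
        raise ValueError("max_flips must be nonnegative")
    n_soft = len(flippable_members(ped))
    if count_relabelings(n_soft, max_flips) > max_assignments:
        raise ConfigurationError(
            f"{count_relabelings(n_soft, max_flips)} relabelings exceed the cap "
            f"of {max_assignments}; lower max_flips or firm up labels"
        )
    base = ped.with_labels(labels) if labels else ped
    hits: dict[tuple, SearchHit] = {}
    for assignment in enumerate_relabelings(base, max_flips):
        results = run_segregation(
            base, variants, models,
            labels=assignment.labels, sample_family=sample_family,
            gene_of=gene_of, x_chrom=x_chrom, assignment=assignment,
        )
        for model, res_list in results.items():
            for res in res_list:
                if post_filter is not None and not post_filter(res.key):
                    continue
                if res.partner is not None and post_filter is not None and not post_filter(res.partner):
                    continue
                ident = (res.key, model, res.partner)
                hit = hits.get(ident)
                if hit is None:
                    hits[ident] = SearchHit(
                        key=res.key, model=model, min_flips=assignment.flip_count,
                        flip_sets=[assignment.flipped_ids], partner=res.partner,
                        phase_unknown=res.phase_unknown,
                    )
                elif assignment.flip_count == hit.min_flips:
                    if assignment.flipped_ids not in hit.flip_sets:
                        hit.flip_sets.append(assignment.flipped_ids)
    ranked = sorted(
        hits.values(),
        key=lambda h: (h.min_flips, len(h.flip_sets), h.key[0], h.key[1], h.key[2], h.key[3]),
    )
    return ranked


# ---------------------------------------------------------------------------
# vectorized engine over a genotype matrix
# ---------------------------------------------------------------------------

class FamilyGenotypeEngine:
    """Matrix formulation of the model predicates for one family.

    Precomputes per-sample boolean genotype summaries over a
    :class:`VariantTable` once; each label assignment then costs a handful
    of boolean reductions, which keeps the relabeling search cheap on
    cohort-scale variant sets.
    """

    def __init__(
        self,
        table: VariantTable,
        ped: Pedigree,
        sample_family: Mapping[str, str] | None = None,
        x_chrom: str = DEFAULT_X_CHROM,
    ) -> None:
        self.table = table
        self.ped = ped
        self.x_chrom = x_chrom
        self.carries = table.carries_alt()
        self.hom_alt = table.hom_alt()
        self.hom_ref = table.hom_ref()
        self.has_ref = table.has_ref_allele()
        self.het = table.strict_het()
        self.on_x = np.asarray([c == x_chrom for c in table.chrom], dtype=bool)
        self._col = {s: i for i, s in enumerate(table.samples)}
        self.members = [m for m in ped.sequenced_members() if m.id in self._col]
        if sample_family is None:
            self.cross_family_keep = np.ones(len(table), dtype=bool)
        else:
            outside = [
                self._col[s]
                for s in table.samples
                if sample_family.get(s) != ped.family_id
            ]
            self.cross_family_keep = ~self.carries[:, outside].any(axis=1)

    def _cols(self, members: Iterable[Individual]) -> list[int]:
        return [self._col[m.id] for m in members]

    def _split(
        self, labels: Mapping[str, Affection] | None
    ) -> tuple[list[Individual], list[Individual]]:
        aff, unaff = [], []
        for m in self.members:
            lab = _label(m, labels)
            if lab is Affection.AFFECTED:
                aff.append(m)
            elif lab is Affection.UNAFFECTED:
                unaff.append(m)
        return aff, unaff

    def model_mask(
        self,
        model: InheritanceModel,
        labels: Mapping[str, Affection] | None = None,
        apply_cross_family: bool = True,
    ) -> np.ndarray:
        """Boolean mask over the variant table for one simple model.

        compound_het is pairwise, not per-variant; use
        :meth:`compound_het_pairs`.
        """
        aff, unaff = self._split(labels)
        a, u = self._cols(aff), self._cols(unaff)
        if model is InheritanceModel.DOMINANT:
            ok = (
                ~self.hom_ref[:, a].any(axis=1)
                & ~self.carries[:, u].any(axis=1)
                & self.carries[:, a].any(axis=1)
            )
        elif model is InheritanceModel.RECESSIVE_HOM:
            parent_cols = sorted(
                {
                    self._col[p.id]
                    for m in aff
                    for p in self.ped.parents_of(m.id)
                    if p is not None and p.sequenced and p.id in self._col
                }
            )
            ok = (
                ~self.has_ref[:, a].any(axis=1)
                & ~self.hom_alt[:, u].any(axis=1)
                & ~self.hom_ref[:, parent_cols].any(axis=1)
                & self.hom_alt[:, a].any(axis=1)
            )
        elif model is InheritanceModel.X_LINKED:
            am = self._cols([m for m in aff if m.sex is Sex.MALE])
            af = self._cols([m for m in aff if m.sex is Sex.FEMALE])
            um = self._cols([m for m in unaff if m.sex is Sex.MALE])
            uf = self._cols([m for m in unaff if m.sex is Sex.FEMALE])
            ok = (
                self.on_x
                & ~self.hom_ref[:, am].any(axis=1)
                & ~self.has_ref[:, af].any(axis=1)
                & ~self.carries[:, um].any(axis=1)
                & ~self.hom_alt[:, uf].any(axis=1)
                & (self.carries[:, am].any(axis=1) | self.hom_alt[:, af].any(axis=1))
            )
        elif model is InheritanceModel.DE_NOVO:
            trio_aff = _trio_affecteds(self.ped, aff)
            trio_aff = [m for m in trio_aff if m.id in self._col]
            if not trio_aff:
                return np.zeros(len(self.table), dtype=bool)
            parent_cols = sorted(
                {
                    self._col[p.id]
                    for m in trio_aff
                    for p in self.ped.parents_of(m.id)
                    if p.id in self._col
                }
            )
            t = self._cols(trio_aff)
            ok = (
                ~self.hom_ref[:, a].any(axis=1)
                & ~self.carries[:, parent_cols].any(axis=1)
                & ~self.carries[:, u].any(axis=1)
                & self.carries[:, t].any(axis=1)
            )
        else:
            raise ValueError(f"model_mask does not handle {model}")
        if apply_cross_family:
            ok = ok & self.cross_family_keep
        return ok

    def compound_het_pairs(
        self,
        gene: np.ndarray,
        labels: Mapping[str, Affection] | None = None,
        apply_cross_family: bool = True,
        extra_mask: np.ndarray | None = None,
    ) -> list[tuple[int, int, bool]]:
        """(index_a, index_b, phase_unknown) trans pairs grouped by ``gene``
        (an object array aligned to the variant table; None = intergenic)."""
        aff, unaff = self._split(labels)
        a, u = self._cols(aff), self._cols(unaff)
        cand = (
            ~(self.hom_ref | self.hom_alt)[:, a].any(axis=1)
            & self.het[:, a].any(axis=1)
        )
        if apply_cross_family:
            cand &= self.cross_family_keep
        if extra_mask is not None:
            cand &= extra_mask
        trio_aff = [m for m in _trio_affecteds(self.ped, aff) if m.id in self._col]
        by_gene: dict[str, list[int]] = {}
        for i in np.flatnonzero(cand):
            g = gene[i]
            if g:
                by_gene.setdefault(g, []).append(int(i))
        pairs: list[tuple[int, int, bool]] = []
        for g in sorted(by_gene):
            idx = by_gene[g]
            for ia, ib in itertools.combinations(idx, 2):
                if any(
                    self.carries[ia, c] and self.carries[ib, c] for c in u
                ):
                    continue
                cis = False
                trans = False
                for m in trio_aff:
                    father, mother = self.ped.parents_of(m.id)
                    fc, mc = self._col.get(father.id), self._col.get(mother.id)
                    if fc is None or mc is None:
                        continue
                    origins = []
                    for i in (ia, ib):
                        if self.carries[i, fc] and not self.carries[i, mc]:
                            origins.append("father")
                        elif self.carries[i, mc] and not self.carries[i, fc]:
                            origins.append("mother")
                        else:
                            origins.append("ambiguous")
                    if "ambiguous" in origins:
                        continue
                    if origins[0] == origins[1]:
                        cis = True
                        break
                    trans = True
                if cis:
                    continue
                pairs.append((ia, ib, not trans))
        return pairs
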