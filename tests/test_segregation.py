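"""Segregation filters: worked examples, a brute-force oracle over random
small cohorts, matrix-engine equivalence, and the relabeling search."""

import itertools

import numpy as np
import pytest

from raredx.pedigree import Affection, Pedigree, Sex
from raredx.segregation import (
    ConfigurationError,
    FamilyGenotypeEngine,
    InheritanceModel,
    cross_family_exclude,
    fits_compound_het,
    fits_de_novo,
    fits_dominant,
    fits_recessive_hom,
    fits_x_linked,
    misclassification_search,
    run_segregation,
)
from raredx.variants import VariantTable
from conftest import ind, random_pedigree, random_variants, variant

A, U = Affection.AFFECTED, Affection.UNAFFECTED


class TestDominant:
    def test_affected_het_controls_clear(self, trio):
        assert fits_dominant(variant({"c": (0, 1), "f": (0, 0), "m": (0, 0)}), trio)

    def test_unaffected_carrier_fails(self, trio):
        assert not fits_dominant(variant({"c": (0, 1), "f": (0, 1), "m": (0, 0)}), trio)

    def test_affected_noncarrier_fails(self, trio):
        assert not fits_dominant(variant({"c": (0, 0), "f": (0, 0), "m": (0, 0)}), trio)

    def test_missing_call_does_not_violate_but_support_required(self, quartet):
        # second affected-compatible member missing: still passes on c1's call
        ped = quartet
        assert fits_dominant(variant({"c1": (0, 1), "f": None, "m": (0, 0), "c2": (0, 0)}), ped)
        # all affected calls missing: no positive support
        assert not fits_dominant(variant({"c1": None, "f": (0, 0), "m": (0, 0), "c2": (0, 0)}), ped)

    def test_splice_carrier_pattern_needs_relabeling(self):
        """Six carriers but only the twins labeled affected: dominant fails
        with the recorded labels (the carrier 'controls' violate it)."""
        ped = _eight_member_family()
        v = _eight_member_splice_variant()
        assert not fits_dominant(v, ped)


class TestRecessiveHom:
    def test_two_affected_sons_hom_parents_het(self):
        ped = Pedigree("F1", [
            ind("f"), ind("m", sex=Sex.FEMALE),
            ind("c1", father="f", mother="m", aff=A),
            ind("c2", father="f", mother="m", aff=A),
        ])
        v = variant({"f": (0, 1), "m": (0, 1), "c1": (1, 1), "c2": (1, 1)})
        assert fits_recessive_hom(v, ped)

    def test_hom_unaffected_sibling_fails(self, quartet):
        v = variant({"f": (0, 1), "m": (0, 1), "c1": (1, 1), "c2": (1, 1)})
        assert not fits_recessive_hom(v, quartet)

    def test_het_affected_fails(self, trio):
        assert not fits_recessive_hom(variant({"c": (0, 1), "f": (0, 1), "m": (0, 1)}), trio)

    def test_noncarrier_parent_fails(self, trio):
        # apparent hom-alt child with a hom-ref parent is not a recessive fit
        assert not fits_recessive_hom(variant({"c": (1, 1), "f": (0, 0), "m": (0, 1)}), trio)


class TestXLinked:
    def _ped(self):
        return Pedigree("F1", [
            ind("f"), ind("m", sex=Sex.FEMALE),
            ind("c1", father="f", mother="m", sex=Sex.MALE, aff=A),
            ind("c2", father="f", mother="m", sex=Sex.FEMALE),
        ])

    def test_hemizygous_affected_son_carrier_mother(self):
        v = variant({"c1": (0, 1), "m": (0, 1), "f": (0, 0), "c2": (0, 0)}, chrom="chrX")
        assert fits_x_linked(v, self._ped())

    def test_hom_coded_hemizygote_also_accepted(self):
        v = variant({"c1": (1, 1), "m": (0, 1), "f": (0, 0), "c2": (0, 0)}, chrom="chrX")
        assert fits_x_linked(v, self._ped())

    def test_unaffected_male_carrier_fails(self):
        v = variant({"c1": (0, 1), "m": (0, 1), "f": (0, 1), "c2": (0, 0)}, chrom="chrX")
        assert not fits_x_linked(v, self._ped())

    def test_het_affected_female_fails(self):
        ped = Pedigree("F1", [
            ind("f"), ind("m", sex=Sex.FEMALE),
            ind("c1", father="f", mother="m", sex=Sex.FEMALE, aff=A),
        ])
        v = variant({"c1": (0, 1), "m": (0, 1), "f": (0, 0)}, chrom="chrX")
        assert not fits_x_linked(v, ped)

    def test_autosomal_variant_never_fits(self):
        v = variant({"c1": (0, 1), "m": (0, 1), "f": (0, 0), "c2": (0, 0)}, chrom="chr5")
        assert not fits_x_linked(v, self._ped())


class TestDeNovo:
    def test_trio_child_het_parents_clear(self, trio):
        assert fits_de_novo(variant({"c": (0, 1), "f": (0, 0), "m": (0, 0)}), trio)

    def test_carrier_parent_fails(self, trio):
        assert not fits_de_novo(variant({"c": (0, 1), "f": (0, 1), "m": (0, 0)}), trio)

    def test_shared_apparent_de_novo_in_sibs_passes(self):
        ped = Pedigree("F1", [
            ind("f"), ind("m", sex=Sex.FEMALE),
            ind("c1", father="f", mother="m", aff=A),
            ind("c2", father="f", mother="m", aff=A),
        ])
        v = variant({"f": (0, 0), "m": (0, 0), "c1": (0, 1), "c2": (0, 1)})
        assert fits_de_novo(v, ped)

    def test_unaffected_carrier_sib_fails(self, quartet):
        v = variant({"f": (0, 0), "m": (0, 0), "c1": (0, 1), "c2": (0, 1)})
        assert not fits_de_novo(v, quartet)

    def test_no_sequenced_parent_pair_is_config_error(self):
        ped = Pedigree("F1", [ind("a", aff=A)])
        with pytest.raises(ConfigurationError):
            run_segregation(ped, [], [InheritanceModel.DE_NOVO])


class TestCompoundHet:
    def _quartet_cht(self):
        return Pedigree("F1", [
            ind("f"), ind("m", sex=Sex.FEMALE),
            ind("c1", father="f", mother="m", aff=A),
        ])

    def test_trans_pair_found(self):
        ped = self._quartet_cht()
        va = variant({"f": (0, 1), "m": (0, 0), "c1": (0, 1)}, pos=100)
        vb = variant({"f": (0, 0), "m": (0, 1), "c1": (0, 1)}, pos=200)
        (pair,) = fits_compound_het("G", [va, vb], ped)
        assert {pair.a, pair.b} == {va.key, vb.key}
        assert not pair.phase_unknown

    def test_cis_pair_excluded(self):
        ped = self._quartet_cht()
        va = variant({"f": (0, 1), "m": (0, 0), "c1": (0, 1)}, pos=100)
        vb = variant({"f": (0, 1), "m": (0, 0), "c1": (0, 1)}, pos=200)
        assert fits_compound_het("G", [va, vb], ped) == []

    def test_unaffected_with_both_excluded(self):
        ped = Pedigree("F1", [
            ind("f"), ind("m", sex=Sex.FEMALE),
            ind("c1", father="f", mother="m", aff=A),
            ind("c2", father="f", mother="m"),
        ])
        va = variant({"f": (0, 1), "m": (0, 0), "c1": (0, 1), "c2": (0, 1)}, pos=100)
        vb = variant({"f": (0, 0), "m": (0, 1), "c1": (0, 1), "c2": (0, 1)}, pos=200)
        assert fits_compound_het("G", [va, vb], ped) == []

    def test_no_parents_gives_all_pairs_phase_unknown(self):
        ped = Pedigree("F1", [ind("p", aff=A)])
        vs = [variant({"p": (0, 1)}, pos=100 * (i + 1)) for i in range(4)]
        pairs = fits_compound_het("G", vs, ped)
        assert len(pairs) == 6  # C(4, 2): exhaustive pair enumeration
        assert all(p.phase_unknown for p in pairs)


class TestCrossFamily:
    FAMS = {"a": "F1", "b": "F1", "x": "F2", "y": "F3"}

    def test_other_family_carrier_removes(self):
        v = variant({"a": (0, 1), "x": (0, 1), "y": (0, 0)})
        assert not cross_family_exclude(v, self.FAMS, "F1")

    def test_target_only_carrier_kept(self):
        v = variant({"a": (0, 1), "b": (1, 1), "x": (0, 0), "y": (0, 0)})
        assert cross_family_exclude(v, self.FAMS, "F1")

    def test_missing_elsewhere_does_not_remove_but_carrier_does(self):
        v = variant({"a": (0, 1), "x": None, "y": (0, 1)})
        assert not cross_family_exclude(v, self.FAMS, "F1")
        v2 = variant({"a": (0, 1), "x": None, "y": (0, 0)})
        assert cross_family_exclude(v2, self.FAMS, "F1")


# ---------------------------------------------------------------------------
# brute-force oracle over random small cohorts
# ---------------------------------------------------------------------------

def _alleles(call):
    return [] if call.alleles is None else [x for x in call.alleles if x is not None]


def _could_carry(call):
    al = _alleles(call)
    return 1 in al or len(al) < 2


def _could_be_hom(call):
    return 0 not in _alleles(call)


def oracle_model(model, v, ped, labels=None):
    """Literal restatement of each model predicate on the genotype table."""
    aff, unaff = [], []
    for m in ped.members:
        if not m.sequenced:
            continue
        lab = labels.get(m.id, m.affection) if labels else m.affection
        (aff if lab is A else unaff if lab is U else []).append(m)
    calls = {m.id: v.call(m.id) for m in ped.members}
    if model is InheritanceModel.DOMINANT:
        return (
            all(_could_carry(calls[m.id]) for m in aff)
            and not any(1 in _alleles(calls[m.id]) for m in unaff)
            and any(1 in _alleles(calls[m.id]) for m in aff)
        )
    if model is InheritanceModel.RECESSIVE_HOM:
        parents = set()
        for m in aff:
            for p in ped.parents_of(m.id):
                if p is not None and p.sequenced:
                    parents.add(p.id)
        return (
            all(_could_be_hom(calls[m.id]) for m in aff)
            and not any(_alleles(calls[m.id]) == [1, 1] for m in unaff)
            and all(_could_carry(calls[p]) for p in parents)
            and any(_alleles(calls[m.id]) == [1, 1] for m in aff)
        )
    if model is InheritanceModel.X_LINKED:
        if v.chrom != "chrX":
            return False
        for m in aff:
            if m.sex is Sex.MALE and not _could_carry(calls[m.id]):
                return False
            if m.sex is Sex.FEMALE and not _could_be_hom(calls[m.id]):
                return False
        for m in unaff:
            if m.sex is Sex.MALE and 1 in _alleles(calls[m.id]):
                return False
            if m.sex is Sex.FEMALE and _alleles(calls[m.id]) == [1, 1]:
                return False
        return any(
            (m.sex is Sex.MALE and 1 in _alleles(calls[m.id]))
            or (m.sex is Sex.FEMALE and _alleles(calls[m.id]) == [1, 1])
            for m in aff
        )
    if model is InheritanceModel.DE_NOVO:
        trio_aff = [
            m for m in aff
            if all(p is not None and p.sequenced for p in ped.parents_of(m.id))
        ]
        if not trio_aff:
            return False
        parent_ids = {p.id for m in trio_aff for p in ped.parents_of(m.id)}
        return (
            all(_could_carry(calls[m.id]) for m in aff)
            and not any(1 in _alleles(calls[p]) for p in parent_ids)
            and not any(1 in _alleles(calls[m.id]) for m in unaff)
            and any(1 in _alleles(calls[m.id]) for m in trio_aff)
        )
    raise AssertionError(model)


def oracle_compound_het(variants, ped, labels=None):
    aff, unaff = [], []
    for m in ped.members:
        if not m.sequenced:
            continue
        lab = labels.get(m.id, m.affection) if labels else m.affection
        (aff if lab is A else unaff if lab is U else []).append(m)

    def is_het(call):
        al = _alleles(call)
        return not (al == [0, 0] or al == [1, 1]) if len(al) == 2 else True

    cands = [
        v for v in variants
        if all(is_het(v.call(m.id)) for m in aff)
        and any(sorted(_alleles(v.call(m.id))) == [0, 1] for m in aff)
    ]
    trio_aff = [
        m for m in aff
        if all(p is not None and p.sequenced for p in ped.parents_of(m.id))
    ]
    pairs = set()
    for va, vb in itertools.combinations(sorted(cands, key=lambda v: v.key), 2):
        if any(
            1 in _alleles(va.call(m.id)) and 1 in _alleles(vb.call(m.id)) for m in unaff
        ):
            continue
        cis = False
        for m in trio_aff:
            f, mo = ped.parents_of(m.id)
            sides = []
            for v in (va, vb):
                fc, mc = 1 in _alleles(v.call(f.id)), 1 in _alleles(v.call(mo.id))
                sides.append("F" if fc and not mc else "M" if mc and not fc else "?")
            if "?" not in sides and sides[0] == sides[1]:
                cis = True
        if not cis:
            pairs.add(frozenset((va.key, vb.key)))
    return pairs


SIMPLE_MODELS = [
    InheritanceModel.DOMINANT,
    InheritanceModel.RECESSIVE_HOM,
    InheritanceModel.X_LINKED,
    InheritanceModel.DE_NOVO,
]


def _check_cohort_against_oracle(rng):
    ped = random_pedigree(rng)
    samples = [m.id for m in ped.sequenced_members()]
    variants = random_variants(rng, samples, n=int(rng.integers(5, 51)))
    for v in variants:
        for model, fn in zip(
            SIMPLE_MODELS,
            [fits_dominant, fits_recessive_hom,
             lambda v, p: fits_x_linked(v, p), fits_de_novo],
        ):
            assert fn(v, ped) == oracle_model(model, v, ped), (model, v.key)
    got = {
        frozenset((p.a, p.b)) for p in fits_compound_het("G", variants, ped)
    }
    assert got == oracle_compound_het(variants, ped)


def test_filters_match_bruteforce_oracle_sample():
    """Spot-check against the oracle (the full 1000-cohort sweep lives in
    the acceptance suite)."""
    rng = np.random.default_rng(123)
    for _ in range(60):
        _check_cohort_against_oracle(rng)


def test_matrix_engine_equals_scalar_predicates():
    """The vectorized engine and the per-record predicates are the same
    filter, including under relabelings and cross-family exclusion."""
    rng = np.random.default_rng(321)
    for _ in range(40):
        ped = random_pedigree(rng)
        samples = [m.id for m in ped.sequenced_members()]
        # a second family acts as cross-family controls
        other = [f"o{i}" for i in range(3)]
        all_samples = samples + other
        variants = random_variants(rng, all_samples, n=30)
        sample_family = {**{s: "F1" for s in samples}, **{s: "F2" for s in other}}
        table = VariantTable.from_records(all_samples, variants)
        engine = FamilyGenotypeEngine(table, ped, sample_family)
        kept = [v for v in variants if cross_family_exclude(v, sample_family, "F1")]
        for model, fn in zip(
            SIMPLE_MODELS,
            [fits_dominant, fits_recessive_hom,
             lambda v, p: fits_x_linked(v, p), fits_de_novo],
        ):
            mask = engine.model_mask(model)
            expected = {v.key for v in kept if fn(v, ped)}
            got = {table.key(i) for i in np.flatnonzero(mask)}
            assert got == expected, model
        gene = np.array(["G"] * len(variants), dtype=object)
        pairs = engine.compound_het_pairs(gene)
        got_pairs = {frozenset((table.key(a), table.key(b))) for a, b, _ in pairs}
        assert got_pairs == {
            frozenset((p.a, p.b)) for p in fits_compound_het("G", kept, ped)
        }


# ---------------------------------------------------------------------------
# misclassification-tolerant search
# ---------------------------------------------------------------------------

def _eight_member_family():
    """Couple, affected twin daughters, unaffected sister/brother, and an
    unaffected aunt and uncle (collateral founders)."""
    return Pedigree("F5", [
        ind("f", "F5"), ind("m", "F5", sex=Sex.FEMALE),
        ind("aunt", "F5", sex=Sex.FEMALE), ind("uncle", "F5", sex=Sex.MALE),
        ind("c1", "F5", father="f", mother="m", sex=Sex.FEMALE, aff=A),
        ind("c2", "F5", father="f", mother="m", sex=Sex.FEMALE, aff=A),
        ind("c3", "F5", father="f", mother="m", sex=Sex.FEMALE),
        ind("c4", "F5", father="f", mother="m", sex=Sex.MALE),
    ])


def _eight_member_splice_variant():
    # six carriers: twins + aunt + uncle + mother + sister; father and
    # brother are non-carriers
    return variant({
        "c1": (0, 1), "c2": (0, 1), "aunt": (0, 1), "uncle": (0, 1),
        "m": (0, 1), "c3": (0, 1), "f": (0, 0), "c4": (0, 0),
    })


class TestMisclassificationSearch:
    def test_zero_flips_equals_plain_run(self, quartet):
        vs = [
            variant({"c1": (0, 1), "f": (0, 0), "m": (0, 0), "c2": (0, 0)}, pos=100),
            variant({"c1": (0, 0), "f": (0, 1), "m": (0, 0), "c2": (0, 0)}, pos=200),
        ]
        hits = misclassification_search(quartet, vs, [InheritanceModel.DOMINANT], 0)
        plain = run_segregation(quartet, vs, [InheritanceModel.DOMINANT])
        assert {h.key for h in hits} == {r.key for r in plain[InheritanceModel.DOMINANT]}
        assert all(h.min_flips == 0 for h in hits)

    def test_single_mislabeled_carrier_found_at_k1(self):
        """One affected carrier recorded as unaffected: the causal variant
        is rescued at exactly one flip, naming that individual."""
        ped = Pedigree("F13", [
            ind("f", "F13"), ind("m", "F13", sex=Sex.FEMALE),
            ind("c1", "F13", father="f", mother="m", aff=A),
            ind("c2", "F13", father="f", mother="m", aff=U),  # wrongly recorded
            ind("m2", "F13", father="f", mother="m", aff=U),
        ])
        v = variant({"c1": (0, 1), "c2": (0, 1), "f": (0, 0), "m": (0, 0), "m2": (0, 0)})
        (hit,) = misclassification_search(ped, [v], [InheritanceModel.DOMINANT], 2)
        assert hit.min_flips == 1
        assert hit.flip_sets == [frozenset({"c2"})]

    def test_six_carrier_family_resolved_at_k4(self):
        """With only the twins labeled affected, the splice variant needs
        exactly four flips — aunt, uncle, mother, sister — verified against
        exhaustive relabeling of the six non-proband members."""
        ped = _eight_member_family()
        v = _eight_member_splice_variant()
        hits = misclassification_search(ped, [v], [InheritanceModel.DOMINANT], 6)
        (hit,) = [h for h in hits if h.key == v.key]
        assert hit.min_flips == 4
        assert hit.flip_sets == [frozenset({"aunt", "uncle", "m", "c3"})]
        # exhaustive oracle: no smaller flip set of non-twin members works
        non_twins = ["f", "m", "aunt", "uncle", "c3", "c4"]
        for r in range(0, 4):
            for combo in itertools.combinations(non_twins, r):
                labels = {m.id: m.affection for m in ped.members}
                for i in combo:
                    labels[i] = A if labels[i] is U else U
                assert not fits_dominant(v, ped, labels), combo

    def test_combinatorial_cap_enforced(self):
        ped = _eight_member_family()
        with pytest.raises(ConfigurationError):
            misclassification_search(ped, [], [InheritanceModel.DOMINANT], 8,
                                     max_assignments=10)
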