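import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from raredx.annotation import (
    AnnotationFrame,
    AnnotationRecord,
    DatabasePolicy,
    FrequencyRule,
    FuncClass,
    POPULATIONS,
    PREDICTORS,
    PredictorCall,
    classify_functional,
    database_filter,
    deleterious_vote,
    frequency_filter,
)
from raredx.variants import GeneInterval
from conftest import variant

D, T, M = PredictorCall.DAMAGING, PredictorCall.TOLERATED, PredictorCall.MISSING


def rec(**kw) -> AnnotationRecord:
    return AnnotationRecord(**kw)


class TestFrequencyRule:
    @pytest.mark.parametrize(
        "freqs, keep",
        [
            ({"EAS": 0.06}, False),            # one population >= 0.05
            ({"EAS": 0.03, "EUR": 0.03}, False),  # two >= 0.03
            ({"EAS": 0.04}, True),
            ({}, True),                        # novel variant
            ({"AFR": 0.025, "AMR": 0.025, "EAS": 0.025}, False),  # three >= 0.025
            ({"AFR": 0.025, "AMR": 0.025}, True),
            ({"AFR": 0.02, "AMR": 0.02, "EAS": 0.02, "EUR": 0.02}, False),  # four >= 0.02
        ],
    )
    def test_default_rule(self, freqs, keep):
        assert frequency_filter(rec(pop_freq=freqs)) is keep

    def test_rule_parse(self):
        rule = FrequencyRule.parse("1:0.05,2:0.03,3:0.025,4:0.02")
        assert rule == FrequencyRule()

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            FrequencyRule(((1, 0.05), (2, 0.05)))  # thresholds not decreasing
        with pytest.raises(ValueError):
            FrequencyRule(((2, 0.05), (1, 0.03)))  # k not increasing

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        freqs=st.dictionaries(
            st.sampled_from(POPULATIONS), st.floats(0, 0.2), max_size=5
        ),
        pop=st.sampled_from(POPULATIONS),
        bump=st.floats(0, 0.5),
    )
    def test_monotone_in_frequency(self, freqs, pop, bump):
        """Raising any population frequency never turns remove into keep."""
        before = frequency_filter(rec(pop_freq=dict(freqs)))
        raised = dict(freqs)
        raised[pop] = min(1.0, raised.get(pop, 0.0) + bump)
        after = frequency_filter(rec(pop_freq=raised))
        assert not (before is False and after is True)


class TestDatabaseFilter:
    def test_bare_dbsnp_membership_policies(self):
        r = rec(in_dbsnp=True)
        assert database_filter(r, policy="default") is True
        assert database_filter(r, policy="strict") is False

    def test_esp_with_high_frequency_removed(self):
        assert database_filter(rec(in_esp=True, esp_freq=0.08)) is False
        assert database_filter(rec(in_esp=True, esp_freq=0.01)) is True
        assert database_filter(rec(in_esp=True)) is True  # no frequency evidence

    def test_all_flags_clear_kept(self):
        assert database_filter(rec()) is True

    def test_frequency_removal_propagates(self):
        assert database_filter(rec(pop_freq={"EAS": 0.06})) is False

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            database_filter(rec(), policy="lenient")


class TestDeleteriousVote:
    def _pred(self, n_d, n_t, n_m=0):
        calls = {}
        tools = iter(PREDICTORS)
        for _ in range(n_d):
            calls[next(tools)] = D
        for _ in range(n_t):
            calls[next(tools)] = T
        for _ in range(n_m):
            calls[next(tools)] = M
        return calls

    def test_missense_strict_majority(self):
        r = rec(func_class=FuncClass.MISSENSE, predictor_calls=self._pred(5, 2, 1))
        assert deleterious_vote(r) is True

    def test_missense_tie_not_deleterious(self):
        r = rec(func_class=FuncClass.MISSENSE, predictor_calls=self._pred(4, 4))
        assert deleterious_vote(r) is False

    def test_truncating_classes_bypass_vote(self):
        for cls in (FuncClass.NONSENSE, FuncClass.FRAMESHIFT_INDEL, FuncClass.SPLICING):
            assert deleterious_vote(rec(func_class=cls)) is True

    def test_silent_classes_never_deleterious(self):
        for cls in (FuncClass.SYNONYMOUS, FuncClass.NONCODING):
            r = rec(func_class=cls, predictor_calls=self._pred(8, 0))
            assert deleterious_vote(r) is False

    def test_nonframeshift_needs_one_damaging(self):
        assert deleterious_vote(
            rec(func_class=FuncClass.NONFRAMESHIFT_INDEL, predictor_calls=self._pred(1, 7))
        ) is True
        assert deleterious_vote(
            rec(func_class=FuncClass.NONFRAMESHIFT_INDEL, predictor_calls=self._pred(0, 8))
        ) is False

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(perm=st.permutations(range(len(PREDICTORS))), n_d=st.integers(0, 8))
    def test_invariant_to_predictor_order(self, perm, n_d):
        calls = {t: (D if i < n_d else T) for i, t in enumerate(PREDICTORS)}
        shuffled = {PREDICTORS[j]: calls[PREDICTORS[j]] for j in perm}
        a = rec(func_class=FuncClass.MISSENSE, predictor_calls=calls)
        b = rec(func_class=FuncClass.MISSENSE, predictor_calls=shuffled)
        assert deleterious_vote(a) == deleterious_vote(b)


# ---------------------------------------------------------------------------
# functional classification
# ---------------------------------------------------------------------------

# single-exon fully coding plus-strand gene starting with ATG
TOY_SEQ = "ATGCAGGCTTGGAAACGTACGGATTACCTGTAA" + "GTAAGT" + "ACGT" * 40
TOY_GENE = GeneInterval("toy", 0, 33, "TG1", "+", ((0, 33),), 0, 33)
REF = {"toy": TOY_SEQ}


class TestClassifyFunctional:
    def test_stop_gain_is_nonsense(self):
        # codon 2 is CAG; C>T at pos 4 (1-based) gives TAG
        v = variant({}, chrom="toy", pos=4, ref="C", alt="T")
        assert classify_functional(v, [TOY_GENE], REF) == [("TG1", FuncClass.NONSENSE)]

    def test_synonymous_snv(self):
        # codon 2 CAG>CAA, both Gln
        v = variant({}, chrom="toy", pos=6, ref="G", alt="A")
        assert classify_functional(v, [TOY_GENE], REF) == [("TG1", FuncClass.SYNONYMOUS)]

    def test_missense_snv(self):
        # codon 2 CAG>CGG (Gln>Arg)
        v = variant({}, chrom="toy", pos=5, ref="A", alt="G")
        assert classify_functional(v, [TOY_GENE], REF) == [("TG1", FuncClass.MISSENSE)]

    def test_two_bp_deletion_is_frameshift(self):
        v = variant({}, chrom="toy", pos=7, ref="GCT", alt="G")
        assert classify_functional(v, [TOY_GENE], REF) == [("TG1", FuncClass.FRAMESHIFT_INDEL)]

    def test_three_bp_deletion_is_nonframeshift(self):
        v = variant({}, chrom="toy", pos=6, ref="GGCT", alt="G")
        assert classify_functional(v, [TOY_GENE], REF) == [("TG1", FuncClass.NONFRAMESHIFT_INDEL)]

    def test_outside_genes_noncoding(self):
        v = variant({}, chrom="toy", pos=150, ref="A", alt="G")
        assert classify_functional(v, [TOY_GENE], REF) == [(None, FuncClass.NONCODING)]

    def test_donor_site_snv_is_splicing(self):
        # two-exon gene: intron starts right after the first coding exon
        gene = GeneInterval("toy", 0, 60, "TG2", "+", ((0, 21), (39, 60)), 0, 60)
        for pos in (22, 23):  # +1/+2 intronic bases after exon 1 (1-based)
            v = variant({}, chrom="toy", pos=pos, ref=TOY_SEQ[pos - 1], alt="C"
                        if TOY_SEQ[pos - 1] != "C" else "G")
            assert classify_functional(v, [gene], REF) == [("TG2", FuncClass.SPLICING)]
        for pos in (38, 39):  # -2/-1 before exon 2
            v = variant({}, chrom="toy", pos=pos, ref=TOY_SEQ[pos - 1], alt="C"
                        if TOY_SEQ[pos - 1] != "C" else "G")
            assert classify_functional(v, [gene], REF) == [("TG2", FuncClass.SPLICING)]

    def test_variant_in_two_genes_reported_per_gene(self):
        g2 = GeneInterval("toy", 0, 40, "TG3", "+", ((0, 40),), None, None)
        v = variant({}, chrom="toy", pos=4, ref="C", alt="T")
        out = classify_functional(v, [TOY_GENE, g2], REF)
        assert ("TG1", FuncClass.NONSENSE) in out and ("TG3", FuncClass.NONCODING) in out

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_snv_agreement_with_full_translation_oracle(self, strand):
        """Every SNV in a 300-bp two-exon CDS matches a brute-force oracle
        that translates the entire coding sequence before and after."""
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        exons = ((50, 200), (260, 410))  # coding length 300
        gene = GeneInterval("chrZ", 40, 420, "ORA", strand, exons, 50, 410)
        ref = {"chrZ": seq}

        def oracle(pos0: int, alt: str) -> FuncClass:
            def cds_of(s: str) -> str:
                cds = "".join(s[a:b] for a, b in exons)
                return str(Seq(cds).reverse_complement()) if strand == "-" else cds

            mutated = seq[:pos0] + alt + seq[pos0 + 1:]
            p_ref = str(Seq(cds_of(seq)).translate())
            p_alt = str(Seq(cds_of(mutated)).translate())
            if p_ref == p_alt:
                return FuncClass.SYNONYMOUS
            diff = next(i for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b)
            return FuncClass.NONSENSE if p_alt[diff] == "*" else FuncClass.MISSENSE

        checked = 0
        for a, b in exons:
            for pos0 in range(a, b):
                for alt in "ACGT":
                    if alt == seq[pos0]:
                        continue
                    v = variant({}, chrom="chrZ", pos=pos0 + 1, ref=seq[pos0], alt=alt)
                    (got,) = classify_functional(v, [gene], ref)
                    assert got == ("ORA", oracle(pos0, alt)), (pos0, alt)
                    checked += 1
        assert checked == 900


class TestAnnotationFrame:
    def test_vectorized_filters_match_scalar(self):
        rng = np.random.default_rng(11)
        keys, records = [], {}
        for i in range(300):
            key = ("chr1", i + 1, "A", "G")
            keys.append(key)
            freqs = {
                p: float(rng.choice([0.0, 0.01, 0.02, 0.03, 0.05, 0.1]))
                for p in rng.choice(POPULATIONS, size=rng.integers(0, 6), replace=False)
            }
            calls = {
                t: [M, D, T][rng.integers(0, 3)] for t in PREDICTORS
            }
            records[key] = AnnotationRecord(
                gene=f"G{i % 7}",
                func_class=list(FuncClass)[rng.integers(0, len(FuncClass))],
                pop_freq={k: v for k, v in freqs.items() if v > 0},
                in_dbsnp=bool(rng.random() < 0.5),
                in_esp=bool(rng.random() < 0.3),
                esp_freq=float(rng.choice([0.001, 0.06])) if rng.random() < 0.5 else None,
                predictor_calls=calls,
            )
        frame = AnnotationFrame.from_records(keys, records)
        for policy in (DatabasePolicy.DEFAULT, DatabasePolicy.STRICT):
            vec = frame.database_keep(policy=policy)
            for i, key in enumerate(keys):
                assert vec[i] == database_filter(records[key], policy=policy), key
        vec_d = frame.deleterious()
        for i, key in enumerate(keys):
            assert vec_d[i] == deleterious_vote(records[key]), key

    def test_roundtrip_records(self):
        keys = [("chr1", 1, "A", "G")]
        r = AnnotationRecord(gene="X", func_class=FuncClass.MISSENSE,
                             pop_freq={"EAS": 0.01}, predictor_calls={"SIFT": D})
        frame = AnnotationFrame.from_records(keys, {keys[0]: r})
        assert frame.to_records()[keys[0]] == r
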