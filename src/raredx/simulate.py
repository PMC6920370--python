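"""Synthetic family-cohort generator with a machine-readable truth manifest.

Emulates the statistical structure a family-based rare-disease WGS analysis
assumes: ~16 families / ~79 sequenced individuals, decoy variants gene-dropped
independently per family from correlated super-population frequencies, one
planted causal scenario per cohort (dominant, recessive-homozygous, compound
het, X-linked, de novo, a co-segregating LD block around a hidden
repeat-expansion locus, or a de novo CNV), optional injected affection-label
errors, and low rates of genotype missingness and allele dropout.

The planted causal allele is absent from every other family's founders —
the generator makes the "rare disease, rare variant" assumption true by
construction — and everything planted is recorded in the
:class:`~raredx.cohort.TruthManifest`.  Output is fully deterministic given
the seed (per-purpose RNG substreams are spawned from one master
SeedSequence).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .annotation import AnnotationFrame, FuncClass, POPULATIONS, PREDICTORS
from .annotation import PRED_DAMAGING, PRED_MISSING, PRED_TOLERATED, _CLASS_CODES
from .cohort import Cohort, TruthManifest
from .genome import AUTOSOMES, CHROM_LENGTHS, CHROM_ORDER, X_CHROM
from .pedigree import (
    Affection,
    Individual,
    LabelConfidence,
    Pedigree,
    PedigreeError,
    Sex,
)
from .variants import CNVSegment, CNVState, GeneInterval, VariantTable

# ---------------------------------------------------------------------------
# pedigree templates
# ---------------------------------------------------------------------------

_A, _U = Affection.AFFECTED, Affection.UNAFFECTED
_M, _F = Sex.MALE, Sex.FEMALE

# (suffix, father, mother, sex, affection, sequenced)
_TEMPLATES: dict[str, list[tuple]] = {
    "trio": [
        ("f", None, None, _M, _U, True),
        ("m", None, None, _F, _U, True),
        ("c1", "f", "m", _M, _A, True),
    ],
    "quartet": [
        ("f", None, None, _M, _U, True),
        ("m", None, None, _F, _U, True),
        ("c1", "f", "m", _M, _A, True),
        ("c2", "f", "m", _F, _U, True),
    ],
    # two affected sons, carrier parents: the classic recessive sibship
    "quintet": [
        ("f", None, None, _M, _U, True),
        ("m", None, None, _F, _U, True),
        ("c1", "f", "m", _M, _A, True),
        ("c2", "f", "m", _M, _A, True),
        ("c3", "f", "m", _F, _U, True),
    ],
    # three generations with affecteds in each: a dominant-transmission shape
    "threegen6": [
        ("gf", None, None, _M, _A, True),
        ("gm", None, None, _F, _U, True),
        ("f", "gf", "gm", _M, _A, True),
        ("m", None, None, _F, _U, True),
        ("c1", "f", "m", _M, _A, True),
        ("c2", "f", "m", _F, _U, True),
    ],
    # eight sequenced members incl. collateral relatives
    "eight": [
        ("f", None, None, _M, _U, True),
        ("m", None, None, _F, _U, True),
        ("aunt", None, None, _F, _U, True),
        ("uncle", None, None, _M, _U, True),
        ("c1", "f", "m", _F, _A, True),
        ("c2", "f", "m", _F, _A, True),
        ("c3", "f", "m", _F, _U, True),
        ("c4", "f", "m", _M, _U, True),
    ],
    # ten sequenced (six affected, four healthy) across three generations,
    # plus one unsequenced married-in spouse
    "fam32": [
        ("gf", None, None, _M, _A, True),
        ("gm", None, None, _F, _U, True),
        ("a1", "gf", "gm", _M, _A, True),
        ("a2", "gf", "gm", _F, _A, True),
        ("u1", "gf", "gm", _F, _U, True),
        ("s1", None, None, _F, _U, True),
        ("s2", None, None, _M, _U, False),
        ("b1", "a1", "s1", _M, _A, True),
        ("b2", "a1", "s1", _F, _A, True),
        ("b3", "a1", "s1", _F, _U, True),
        ("c1", "s2", "a2", _M, _A, True),
    ],
}

#: 16 families totalling 79 sequenced individuals
DEFAULT_FAMILY_PLAN: tuple[str, ...] = (
    ("trio",) * 4 + ("quartet",) * 4 + ("quintet",) * 3 + ("threegen6",) * 3
    + ("eight",) + ("fam32",)
)

SCENARIOS: tuple[str, ...] = (
    "dominant", "recessive_hom", "compound_het", "x_linked", "de_novo",
    "ssr_ld_block", "denovo_cnv",
)

_SCENARIO_TEMPLATE = {
    "dominant": "threegen6",
    "recessive_hom": "quintet",
    "compound_het": "quartet",
    "x_linked": "quartet",
    "de_novo": "trio",
    "ssr_ld_block": "fam32",
    "denovo_cnv": "trio",
}

# decoy functional-class mix: mostly noncoding/synonymous, few truncating
_DECOY_CLASSES = (
    FuncClass.NONCODING, FuncClass.SYNONYMOUS, FuncClass.MISSENSE,
    FuncClass.NONFRAMESHIFT_INDEL, FuncClass.FRAMESHIFT_INDEL,
    FuncClass.NONSENSE, FuncClass.SPLICING,
)
_DECOY_CLASS_PROBS = (0.58, 0.12, 0.22, 0.03, 0.02, 0.015, 0.015)

_BASES = np.array(list("ACGT"))


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic cohort."""

    scenario: str = "dominant"
    seed: int = 0
    n_decoy_variants: int = 20_000
    family_plan: tuple[str, ...] = DEFAULT_FAMILY_PLAN
    # founder allele-frequency model: a common component and a rare tail
    p_common: float = 0.6
    # predictor calibration
    p_damaging_given_causal: float = 0.9
    p_damaging_given_benign: float = 0.1
    p_predictor_missing: float = 0.05
    # sequencing imperfections
    missing_rate: float = 0.01
    dropout_rate: float = 0.001  # alt-allele dropout per allele
    # misclassification injection: flip this many affected soft labels in
    # the target family (the designated proband is never flipped)
    n_label_flips: int = 0
    explicit_label_flips: tuple[tuple[str, str], ...] = ()
    # LD-block scenario geometry
    ssr_chrom: str = "chr14"
    ssr_n_variants: int = 100
    ssr_block_half_span: int = 8_000_000
    ssr_locus_jitter: int = 2_000_000
    x_chrom: str = X_CHROM

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_decoy_variants <= 0:
            raise ValueError("n_decoy_variants must be positive")
        for p in (self.p_common, self.p_damaging_given_causal,
                  self.p_damaging_given_benign, self.p_predictor_missing,
                  self.missing_rate, self.dropout_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# pedigree construction and gene dropping
# ---------------------------------------------------------------------------

def build_family(template: str, family_id: str) -> Pedigree:
    members = []
    for suffix, fa, mo, sex, aff, seq in _TEMPLATES[template]:
        members.append(
            Individual(
                id=f"{family_id}_{suffix}",
                family_id=family_id,
                father_id=f"{family_id}_{fa}" if fa else None,
                mother_id=f"{family_id}_{mo}" if mo else None,
                sex=sex,
                affection=aff,
                label_confidence=LabelConfidence.SOFT,
                sequenced=seq,
            )
        )
    return Pedigree(family_id, members)


def gene_drop(
    ped: Pedigree,
    founder_sampler: float | Callable[[np.random.Generator], tuple[int, int]],
    rng: np.random.Generator,
) -> dict[str, tuple[int, int]]:
    """Drop one biallelic site through a pedigree.

    Founders draw two alleles from Hardy-Weinberg at the site frequency
    (or from ``founder_sampler`` when callable); each non-founder receives
    one uniformly chosen allele from each parent.
    """
    geno: dict[str, tuple[int, int]] = {}
    for m in ped.topological_order():
        if m.is_founder and callable(founder_sampler):
            a, b = founder_sampler(rng)
            geno[m.id] = (int(a), int(b))
            continue
        alleles = []
        for parent_id in (m.father_id, m.mother_id):
            if parent_id is None:
                if callable(founder_sampler):
                    raise ValueError(
                        "callable founder sampler requires both parents absent or present"
                    )
                alleles.append(int(rng.random() < founder_sampler))
            else:
                pg = geno[parent_id]
                alleles.append(pg[int(rng.integers(0, 2))])
        geno[m.id] = (alleles[0], alleles[1])
    return geno


def _gene_drop_matrix(
    ped: Pedigree,
    freq: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorized gene drop of ``len(freq)`` independent sites; returns
    member id -> (n_sites, 2) int8 allele array."""
    n = len(freq)
    geno: dict[str, np.ndarray] = {}
    idx = np.arange(n)
    for m in ped.topological_order():
        g = np.empty((n, 2), dtype=np.int8)
        for slot, parent_id in enumerate((m.father_id, m.mother_id)):
            if parent_id is None:
                g[:, slot] = rng.random(n) < freq
            else:
                pick = rng.integers(0, 2, size=n)
                g[:, slot] = geno[parent_id][idx, pick]
        geno[m.id] = g
    return geno


def inject_label_noise(
    ped: Pedigree, flip_ids: Iterable[str]
) -> Pedigree:
    """Return a copy of the pedigree with the given affection labels flipped.

    Only sequenced soft-confidence members with a known label may be
    flipped; the result must still contain an affected member.
    """
    flip_set = set(flip_ids)
    new_members = []
    for m in ped.members:
        if m.id in flip_set:
            if m.label_confidence is LabelConfidence.FIRM:
                raise PedigreeError(f"cannot flip firm-labeled member {m.id}")
            if not m.sequenced or m.affection is Affection.UNKNOWN:
                raise PedigreeError(f"cannot flip {m.id}: not a sequenced labeled member")
            new_aff = _U if m.affection is _A else _A
            new_members.append(dataclasses.replace(m, affection=new_aff))
        else:
            new_members.append(dataclasses.replace(m))
    return Pedigree(ped.family_id, new_members)


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

@dataclass
class _Site:
    """One planted (non-decoy) site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, tuple[int, int]]  # member id -> alleles; others 0/0
    gene: str | None
    func_class: FuncClass
    causal: bool  # recorded in the manifest's causal_keys
    damaging_truth: bool


_EAS_COL = POPULATIONS.index("EAS")


def _decoy_sites(config: ScenarioConfig, rng: np.random.Generator):
    n = config.n_decoy_variants
    lengths = np.array([CHROM_LENGTHS[c] for c in CHROM_ORDER], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(CHROM_ORDER), size=n, p=probs)
    pos = 1 + (rng.random(n) * (lengths[chrom_idx] - 1)).astype(np.int64)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    order = np.lexsort((pos, chrom_idx))
    return chrom_idx[order], pos[order], _BASES[ref_idx[order]], _BASES[alt_idx[order]]


def _population_frequencies(config: ScenarioConfig, n: int, rng: np.random.Generator):
    """Per-variant base frequency and correlated per-population frequencies."""
    is_common = rng.random(n) < config.p_common
    base = np.where(
        is_common,
        rng.beta(0.8, 4.0, size=n),
        10.0 ** rng.uniform(-4, -2, size=n),
    )
    pop = np.clip(base[:, None] * np.exp(rng.normal(0.0, 0.4, size=(n, 5))), 0.0, 0.95)
    founder = pop[:, _EAS_COL].copy()
    pop[pop < 1e-4] = np.nan  # too rare to have been observed in the panel
    return is_common, base, pop, founder


def _random_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    r = int(rng.integers(0, 4))
    a = (r + int(rng.integers(1, 4))) % 4
    return str(_BASES[r]), str(_BASES[a])


def _planted_sites(
    config: ScenarioConfig, target: Pedigree, rng: np.random.Generator
) -> tuple[list[_Site], tuple[str, int] | None]:
    """Causal SNV/indel sites (and the hidden SSR locus, if any)."""
    fam = target.family_id
    ids = {suffix: f"{fam}_{suffix}" for suffix, *_ in _TEMPLATES[_SCENARIO_TEMPLATE[config.scenario]]}
    sites: list[_Site] = []
    hidden_locus = None
    scenario = config.scenario
    if scenario in ("dominant", "recessive_hom", "compound_het", "de_novo"):
        chrom = str(rng.choice(AUTOSOMES))
        pos = int(1 + rng.integers(0, CHROM_LENGTHS[chrom] - 1000))
    if scenario == "dominant":
        ref, alt = _random_snv_alleles(rng)
        geno = {ids["gf"]: (0, 1), ids["f"]: (0, 1), ids["c1"]: (0, 1)}
        sites.append(_Site(chrom, pos, ref, alt, geno, "CGENE1", FuncClass.MISSENSE, True, True))
    elif scenario == "recessive_hom":
        ref, alt = _random_snv_alleles(rng)
        geno = {
            ids["f"]: (0, 1), ids["m"]: (0, 1),
            ids["c1"]: (1, 1), ids["c2"]: (1, 1), ids["c3"]: (0, 1),
        }
        sites.append(_Site(chrom, pos, ref, alt, geno, "CGENE1", FuncClass.MISSENSE, True, True))
    elif scenario == "compound_het":
        ref, alt = _random_snv_alleles(rng)
        geno_a = {ids["f"]: (0, 1), ids["c1"]: (0, 1), ids["c2"]: (0, 1)}
        sites.append(_Site(chrom, pos, ref, alt, geno_a, "CGENE1", FuncClass.NONSENSE, True, True))
        geno_b = {ids["m"]: (0, 1), ids["c1"]: (0, 1)}
        sites.append(
            _Site(chrom, pos + 211, "TA", "T", geno_b, "CGENE1",
                  FuncClass.FRAMESHIFT_INDEL, True, True)
        )
    elif scenario == "x_linked":
        chrom = config.x_chrom
        pos = int(1 + rng.integers(0, CHROM_LENGTHS[chrom] - 1000))
        ref, alt = _random_snv_alleles(rng)
        geno = {ids["m"]: (0, 1), ids["c1"]: (0, 1), ids["c2"]: (0, 1)}
        sites.append(_Site(chrom, pos, ref, alt, geno, "CGENE1", FuncClass.MISSENSE, True, True))
    elif scenario == "de_novo":
        ref, alt = _random_snv_alleles(rng)
        geno = {ids["c1"]: (0, 1)}
        sites.append(_Site(chrom, pos, ref, alt, geno, "CGENE1", FuncClass.MISSENSE, True, True))
    elif scenario == "ssr_ld_block":
        chrom = config.ssr_chrom
        half = config.ssr_block_half_span
        center = int(rng.integers(half, CHROM_LENGTHS[chrom] - half))
        locus = int(center + rng.integers(-config.ssr_locus_jitter, config.ssr_locus_jitter + 1))
        hidden_locus = (chrom, locus)
        carriers = {m.id: (0, 1) for m in target.members if m.affection is _A}
        n_blk = config.ssr_n_variants
        near = rng.random(n_blk) < 0.5
        pos_arr = np.where(
            near,
            rng.normal(locus, 1_000_000, size=n_blk),
            rng.uniform(center - half, center + half, size=n_blk),
        )
        pos_arr = np.clip(pos_arr, center - half, center + half).astype(np.int64)
        for p in np.sort(pos_arr):
            ref, alt = _random_snv_alleles(rng)
            sites.append(
                _Site(chrom, int(p), ref, alt, dict(carriers), None,
                      FuncClass.NONCODING, False, False)
            )
    elif scenario == "denovo_cnv":
        pass  # handled by _cnv_tables
    return sites, hidden_locus


def _cnv_tables(
    config: ScenarioConfig, target: Pedigree, rng: np.random.Generator
) -> tuple[list[CNVSegment], CNVSegment | None]:
    if config.scenario != "denovo_cnv":
        return [], None
    fam = target.family_id
    child, father, mother = f"{fam}_c1", f"{fam}_f", f"{fam}_m"
    segs: list[CNVSegment] = []
    planted = CNVSegment("chr3", 0, 10_350_000, CNVState.LOSS, child)
    segs.append(planted)
    for parent in (father, mother):
        for _ in range(5):
            chrom = str(rng.choice(AUTOSOMES))
            length = int(rng.integers(50_000, 2_000_000))
            start = int(rng.integers(0, CHROM_LENGTHS[chrom] - length))
            state = CNVState.LOSS if rng.random() < 0.5 else CNVState.GAIN
            pseg = CNVSegment(chrom, start, start + length, state, parent)
            segs.append(pseg)
            # child inherits the parental segment with slightly jittered
            # breakpoints, as independent per-sample calling would produce
            j1, j2 = int(rng.integers(-2000, 2001)), int(rng.integers(-2000, 2001))
            cs = max(0, start + j1)
            ce = max(cs + 1000, start + length + j2)
            segs.append(CNVSegment(chrom, cs, ce, state, child))
    segs.sort(key=lambda s: (s.chrom, s.start, s.end, s.sample_id))
    return segs, planted


def _gene_table(
    config: ScenarioConfig, hidden_locus: tuple[str, int] | None, rng: np.random.Generator
) -> tuple[list[GeneInterval], str | None]:
    genes: list[GeneInterval] = [
        GeneInterval("chr1", 1_000_000, 1_050_000, "ANCHOR1", "+"),
        GeneInterval("chr1", 5_000_000, 5_080_000, "ANCHOR2", "-"),
    ]
    target_symbol = None
    if config.scenario == "denovo_cnv":
        for k, start in enumerate(range(500_000, 10_200_000, 1_600_000)):
            genes.append(GeneInterval("chr3", start, start + 120_000, f"D3G{k + 1}", "+"))
        for k, start in enumerate((100_292_000, 100_325_000, 100_361_000)):
            genes.append(GeneInterval("chr7", start, start + 15_000, f"D7G{k + 1}", "+"))
    if hidden_locus is not None:
        chrom, locus = hidden_locus
        target_symbol = "SSR_TARGET"
        genes.append(GeneInterval(chrom, max(0, locus - 75_000), locus + 75_000, target_symbol, "+"))
        half = config.ssr_block_half_span
        k = 0
        for start in range(locus - half, locus + half, 400_000):
            if start < 0 or start + 150_000 > CHROM_LENGTHS[chrom]:
                continue
            if abs(start + 75_000 - locus) < 200_000:
                continue  # leave the planted target as the nearest gene
            k += 1
            genes.append(GeneInterval(chrom, start, start + 150_000, f"TILE{k}", "+"))
    return genes, target_symbol


def simulate_cohort(config: ScenarioConfig) -> Cohort:
    """Generate one cohort under ``config``; deterministic given the seed."""
    ss = np.random.SeedSequence(config.seed)
    n_fam = len(config.family_plan)
    children = ss.spawn(6 + n_fam)
    rng_sites = np.random.default_rng(children[0])
    rng_freq = np.random.default_rng(children[1])
    rng_caus = np.random.default_rng(children[2])
    rng_noise = np.random.default_rng(children[3])
    rng_ann = np.random.default_rng(children[4])
    rng_cnv = np.random.default_rng(children[5])
    fam_rngs = [np.random.default_rng(c) for c in children[6:]]

    # pedigrees (truth labels)
    pedigrees = [
        build_family(tmpl, f"Fam{i + 1:02d}") for i, tmpl in enumerate(config.family_plan)
    ]
    wanted = _SCENARIO_TEMPLATE[config.scenario]
    try:
        target = next(p for p, t in zip(pedigrees, config.family_plan) if t == wanted)
    except StopIteration:
        raise ValueError(
            f"scenario {config.scenario!r} needs a {wanted!r} family in the plan"
        ) from None

    # decoy sites, frequencies, per-family gene drop
    chrom_idx, pos, ref, alt = _decoy_sites(config, rng_sites)
    n = len(pos)
    is_common, base_freq, pop_freq, founder_freq = _population_frequencies(config, n, rng_freq)
    member_geno: dict[str, np.ndarray] = {}
    for ped, rng in zip(pedigrees, fam_rngs):
        member_geno.update(_gene_drop_matrix(ped, founder_freq, rng))

    # planted causal sites
    planted, hidden_locus = _planted_sites(config, target, rng_caus)
    cnv_segments, planted_cnv = _cnv_tables(config, target, rng_cnv)
    genes, ssr_target_gene = _gene_table(config, hidden_locus, rng_cnv)

    # assemble full site arrays (decoys + planted), sorted by coordinate
    chrom_rank = {c: i for i, c in enumerate(CHROM_ORDER)}
    all_chrom = [CHROM_ORDER[i] for i in chrom_idx] + [s.chrom for s in planted]
    all_rank = np.array([chrom_rank[c] for c in all_chrom])
    all_pos = np.concatenate([pos, np.array([s.pos for s in planted], dtype=np.int64)])
    all_ref = np.concatenate([ref, np.array([s.ref for s in planted], dtype=object)])
    all_alt = np.concatenate([alt, np.array([s.alt for s in planted], dtype=object)])
    order = np.lexsort((all_pos, all_rank))

    samples = [m.id for ped in pedigrees for m in ped.members if m.sequenced]
    n_tot = n + len(planted)
    geno = np.zeros((n_tot, len(samples), 2), dtype=np.int8)
    for j, s in enumerate(samples):
        geno[:n, j, :] = member_geno[s]
    for i, site in enumerate(planted):
        for member_id, alleles in site.genotypes.items():
            j = samples.index(member_id)
            geno[n + i, j, :] = alleles

    # annotation columns
    freq_cols = np.vstack([pop_freq, np.full((len(planted), 5), np.nan)])
    class_code = np.empty(n_tot, dtype=np.int8)
    decoy_class = rng_ann.choice(len(_DECOY_CLASSES), size=n, p=_DECOY_CLASS_PROBS)
    class_code[:n] = [_CLASS_CODES[_DECOY_CLASSES[k]] for k in decoy_class]
    class_code[n:] = [_CLASS_CODES[s.func_class] for s in planted]
    gene_col = np.empty(n_tot, dtype=object)
    for i in range(n):
        if _DECOY_CLASSES[decoy_class[i]] is FuncClass.NONCODING:
            gene_col[i] = None
        else:
            gene_col[i] = f"G{chrom_idx[i]}_{pos[i] // 200_000}"
    for i, site in enumerate(planted):
        gene_col[n + i] = site.gene
    # predictors: benign-truth decoys vs damaging-truth planted causals;
    # tools only score protein-altering variants
    u_miss = rng_ann.random((n_tot, len(PREDICTORS))) < config.p_predictor_missing
    p_dam = np.full(n_tot, config.p_damaging_given_benign)
    p_dam[n:] = [
        config.p_damaging_given_causal if s.damaging_truth else config.p_damaging_given_benign
        for s in planted
    ]
    u_dam = rng_ann.random((n_tot, len(PREDICTORS))) < p_dam[:, None]
    pred = np.where(u_miss, PRED_MISSING, np.where(u_dam, PRED_DAMAGING, PRED_TOLERATED))
    scored = ~np.isin(
        class_code,
        [_CLASS_CODES[FuncClass.NONCODING], _CLASS_CODES[FuncClass.SYNONYMOUS]],
    )
    pred[~scored] = PRED_MISSING
    in_dbsnp = np.zeros(n_tot, dtype=bool)
    in_esp = np.zeros(n_tot, dtype=bool)
    esp_freq = np.full(n_tot, np.nan)
    in_dbsnp[:n] = rng_ann.random(n) < np.where(is_common, 0.9, 0.1)
    in_esp[:n] = rng_ann.random(n) < np.where(is_common, 0.7, 0.05)
    esp_vals = np.clip(base_freq * np.exp(rng_ann.normal(0, 0.3, n)), 0, 0.95)
    esp_freq[:n] = np.where(in_esp[:n], esp_vals, np.nan)

    # sequencing imperfections: alt-allele dropout, then whole-call missingness
    if config.dropout_rate > 0:
        drop = (rng_noise.random(geno.shape) < config.dropout_rate) & (geno == 1)
        geno[drop] = 0
    if config.missing_rate > 0:
        miss = rng_noise.random(geno.shape[:2]) < config.missing_rate
        geno[miss, :] = -1

    # apply the sort
    all_chrom_arr = np.array(all_chrom, dtype=object)[order]
    table = VariantTable(
        samples, all_chrom_arr, all_pos[order], all_ref[order], all_alt[order], geno[order]
    )
    annotations = AnnotationFrame(
        table.keys(),
        gene_col[order],
        freq_cols[order],
        in_dbsnp[order],
        in_esp[order],
        esp_freq[order],
        class_code[order],
        pred[order],
    )

    # injected affection-label errors (emitted PED only; truth in manifest)
    flips: list[tuple[str, str]] = [tuple(x) for x in config.explicit_label_flips]
    if config.n_label_flips > 0:
        affected = [
            m for m in target.members
            if m.affection is _A and m.sequenced
            and m.label_confidence is LabelConfidence.SOFT
        ]
        proband = affected[-1]  # youngest-generation affected stays labeled
        candidates = sorted(m.id for m in affected if m.id != proband.id)
        if config.n_label_flips > len(candidates):
            raise ValueError(
                f"cannot flip {config.n_label_flips} labels: only "
                f"{len(candidates)} flippable affected members"
            )
        chosen = rng_noise.choice(len(candidates), size=config.n_label_flips, replace=False)
        flips.extend((target.family_id, candidates[k]) for k in sorted(chosen))
    emitted_pedigrees = []
    for ped in pedigrees:
        fam_flips = [i for f, i in flips if f == ped.family_id]
        emitted_pedigrees.append(inject_label_noise(ped, fam_flips) if fam_flips else ped)

    causal_keys = [
        [s.chrom, int(s.pos), s.ref, s.alt] for s in planted if s.causal
    ]
    manifest = TruthManifest(
        scenario=config.scenario,
        target_family=target.family_id,
        causal_keys=causal_keys,
        causal_gene="CGENE1" if causal_keys else ssr_target_gene,
        hidden_locus=hidden_locus,
        cnv_segment=(
            (planted_cnv.chrom, planted_cnv.start, planted_cnv.end, planted_cnv.state.value)
            if planted_cnv else None
        ),
        label_flips=flips,
        seed=config.seed,
    )
    return Cohort(
        pedigrees=emitted_pedigrees,
        table=table,
        annotations=annotations,
        cnv_segments=cnv_segments,
        genes=genes,
        chrom_lengths=dict(CHROM_LENGTHS),
        manifest=manifest,
    )
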