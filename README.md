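# raredx

Pedigree-aware variant prioritization for family-based rare-disease
sequencing cohorts.

When each family in a cohort segregates its own rare Mendelian disorder, a
causal variant must pass three independent hurdles, and `raredx`
implements exactly that cascade for multi-sample VCFs plus PED pedigrees:

1. **Segregation** under an inheritance model — dominant, recessive
   (homozygous), compound heterozygous (trans pairs within a gene),
   X-linked recessive, or de novo — with every sequenced individual from
   *other* families treated as a healthy control (the rare-disease /
   rare-variant assumption).
2. **Rarity** — removal when, across the 1000 Genomes super-populations,
   ≥ 1 population has frequency ≥ 0.05, ≥ 2 have ≥ 0.03, ≥ 3 have ≥ 0.025,
   or ≥ 4 have ≥ 0.02; plus a configurable dbSNP/ESP database policy.
3. **Deleteriousness** — a consensus vote of eight effect predictors
   (SIFT, PolyPhen, LRT, MutationTaster, MutationAssessor, FATHMM,
   MetaSVM, MetaLR): damaging must outvote tolerated for missense, while
   truncating and canonical-splice variants pass outright.

Because rare-disease phenotyping is unreliable, the cascade can be wrapped
in a **misclassification-tolerant search**: affection labels flagged as
soft may be flipped, and each surviving candidate is reported at the
minimal number of flips k that rescues it, with the rescuing flip sets.
Two further detectors cover what SNV filtering cannot see: a
**variant-density scan** (per-chromosome binomial enrichment with BH
correction, then a 1 Mb sliding-window peak whose center ± 1 Mb is the
candidate interval) localizes hidden loci such as repeat expansions from
their co-segregating LD block, and a **de novo CNV** module classifies a
child's copy-number segments against parental calls by reciprocal overlap
(≥ 0.5 by default).

A synthetic-cohort generator (`raredx.simulate`) produces complete cohorts
— 16 families / 79 sequenced genomes, 20,000 decoy variants, one planted
causal scenario, optional injected label errors — with a machine-readable
truth manifest, so the entire pipeline is testable end to end without
access-restricted patient data. See `docs/methods.md` for the model
details and the generator's scope.

## Worked example

Generate a cohort in which a recessive missense variant is planted in a
five-member family (carrier parents, two homozygous affected sons, one
carrier daughter), then analyze that family:

```python
from raredx import ScenarioConfig, simulate_cohort, run_family_analysis

cohort = simulate_cohort(ScenarioConfig(scenario="recessive_hom", seed=1))
traces, report = run_family_analysis(cohort, cohort.manifest.target_family)

print(traces[0].counts)
for c in report.candidates:
    print(c.key, c.gene, c.func_class, c.models_passed, c.n_damaging, c.n_tolerated)
```

prints

```
{'dominant': (1, 1, 0), 'recessive_hom': (1, 1, 1), 'compound_het': (0, 0, 0),
 'x_linked': (0, 0, 0), 'de_novo': (1, 1, 0)}
('chr10', 31602174, 'A', 'C') CGENE1 missense ('recessive_hom',) 7 1
```

The trace is the per-model candidate count after each stage (segregation →
frequency/database → predictor vote): of 20,001 sites, cross-family
exclusion and segregation leave one candidate per compatible model, and
only the recessive one survives the predictor vote — the planted variant
(`cohort.manifest.causal_keys` confirms), a novel missense change with 7
of 8 predictors calling it damaging. Stage counts shrink monotonically by
construction; with `max_flips > 0` each candidate would also carry its
minimal flip count and flip sets.

The same runs from a shell:

```bash
raredx simulate --scenario recessive_hom --seed 1 --out cohort/
raredx validate cohort/
raredx run cohort/ --family Fam09 --max-flips 0 --out report.json
raredx report report.json
```

Other subcommands: `densityscan` (enrichment + peak localization TSV),
`cnv` (de novo segment calls for a trio), `annotate-filter` (per-variant
filter decisions), `segregate` (alias of `run`).

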