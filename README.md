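# pollenkiller

Modeling and analysis of *pollen-killer* genetic systems: gametophytic
killer loci whose action is gated by unlinked sporophytic partner loci
(activators or suppressors). The package computes expected and simulated
genotype frequencies across cross designs, estimates the male transmission
parameter *k* from progeny counts, predicts pollen-fertility phenotypes for
multilocus genotypes, and fine-maps causal loci from recombinant panels.

## Model in one paragraph

A killer locus heterozygote aborts pollen carrying the targeted allele with
survival probability *s*, so the opposite allele is transmitted through the
male side at frequency *k* = 1/(1+*s*) ≥ 0.5; female transmission stays
Mendelian, and homozygotes show no phenotype. Whether the killer fires is
decided by the diploid parent's genotype at a partner locus: an activator
needs at least one donor allele, a suppressor needs none (donor alleles are
fully dominant). Repeated selfing (single-seed descent) then fixes lines at
a *k* : 1−*k* ratio, and an active killer–activator pair on different
chromosomes produces pseudo-linkage (an excess of parental two-locus
classes) in recombinant inbreds.

## Layout

| module                       | contents                                                                 |
|------------------------------|--------------------------------------------------------------------------|
| `pollenkiller.model_core`    | domain types, activation rule, per-locus gamete distributions            |
| `pollenkiller.segregation`   | closed-form cross expectations, SSD recursion, *k* estimation, GOF tests |
| `pollenkiller.popsim`        | forward Monte-Carlo simulator (Haldane recombination, gamete rejection)  |
| `pollenkiller.phenotype`     | fertility prediction, class thresholds, staining observation model       |
| `pollenkiller.finemap`       | breakpoint logic: minimal candidate interval from recombinant panels     |
| `pollenkiller.synthetic_data`| seeded generators for testcross/selfed/panel fixtures                    |
| `pollenkiller.io` / `cli`    | TSV/YAML readers and writers, `pollenkiller` command line                |

A ready-made two-pathway network (activator INK→S35, suppressor EFS⊣S24)
ships as the default config (`pollenkiller/data/efs_s24_ink_s35.yaml`).

## Command line

```bash
# transmission parameter from testcross counts (with exact binomial CI)
pollenkiller estimate-k --design testcross --counts H=134,JJ=17

# analytic expectations and the RI fixation limit
pollenkiller expect --design ssd --k 0.89 --generations 10
pollenkiller ri-expect --k 0.89 --n 148

# goodness of fit (Pearson or exact multinomial)
pollenkiller gof --counts 17,134 --ratio 1,1 --method pearson

# phenotype prediction and classification
pollenkiller predict --genotype S24=H,EFS=JJ,S35=H,INK=H
pollenkiller classify --pct 77.3

# forward simulation and pseudo-linkage
pollenkiller simulate --design ssd --lines 300 --generations 8 --seed 1 --out ri.tsv
pollenkiller pseudolink --table ri.tsv --a S35 --b INK

# synthetic fixtures and fine mapping
pollenkiller gen panel --markers 10 --lines 20 --seed 5 --out panel.tsv
pollenkiller finemap --panel panel.tsv --map panel.map.tsv --carrier-rule dominant-donor
```

All randomness is controlled with `--seed`; results go to stdout or
`--out` as JSON/TSV; diagnostics go to stderr.

## File formats

- **Genotype table** — TSV, `sample_id` column plus one column per marker;
  codes `II`/`H`/`JJ`/`NA`; optional `phenotype`/`population` columns.
- **Marker map** — TSV with `marker`, `chrom`, `pos_bp` and optional `cM`.
- **Systems config** — YAML/JSON declaring loci (name, chrom, pos_bp, role),
  killer systems (killer, partner, partner_mode, targeted_allele,
  survival_s, collateral_c), and an optional `map` of cM positions.
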