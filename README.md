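# polyassoc

Case-control SNP association and polygenic risk stratification toolkit for
small candidate-gene panels. It covers:

- **Single-locus association**: Hardy–Weinberg χ² goodness of fit, 2×2 odds
  ratios with Woolf 95% CIs and uncorrected Pearson χ² p-values, allelic /
  codominant / dominant / recessive model encodings, and sex/age-adjusted
  odds ratios via an in-house IRLS unconditional logistic regression.
- **Three-way comparison design**: all cases vs controls, hereditary-background
  cases (cases^A) vs controls, cases^A vs non-hereditary cases (cases^B),
  plus subgroup stratification by sex, age band, tumour location and Lauren
  type.
- **Combined-genotype stratification**: cross-classify subjects by genotype
  tuples over a SNP subset, pick a reference stratum (lowest risk-allele
  dose by default) and compute per-stratum unadjusted ORs against one or
  more comparison groups, with a risk-ladder report.
- **Multiplicative polygenic risk model**: per-locus log-risk variance
  contributions `2·p·(1−p)·(ln rr)²`, fraction of the familial genetic risk
  explained (total variance `V = 2·ln λ`), log-normal risk-percentile
  ratios, and screening-benefit arithmetic for top-risk-fraction screening.
- **Synthetic cohorts**: a seeded generator drawing population genotypes under
  HWE and rejection-sampling cases/controls from a logistic disease model,
  plus a parameter-recovery harness for calibration experiments.

## Input format

The canonical input is a TSV with header
`id status sex age hereditary location lauren` followed by one two-letter
genotype column per rs id (`00`/`NN` = missing; allele order is
insignificant, `GA` ≡ `AG`). Field values: `status` case|control, `sex`
M|F, `hereditary` 1|0|NA, `location` cardia|noncardia|unknown|NA, `lauren`
intestinal|diffuse|mixed|unknown|NA. Optional `#snp` comment lines carry
SNP metadata (`rs_id gene allele_a allele_b risk_allele`); without them the
built-in six-SNP panel (rs4072037, rs9841504, rs2294008, rs2274223,
rs13361707, rs2790) supplies defaults. A PLINK-style `.ped`/`.map` pair is
accepted read-only (phenotype detail in a `<stem>.pheno.tsv` side-car).

Missing genotypes are handled by per-analysis complete-case deletion, and
every result carries its effective N.

## CLI

```bash
polyassoc assoc     --input cohort.tsv --snp rs4072037 --model allelic \
                    --design casesA-vs-controls --adjust sex,age --out results.tsv
polyassoc combine   --input cohort.tsv --snps rs4072037,rs9841504 \
                    --comparisons cases-vs-controls --out table.tsv
polyassoc subgroup  --input cohort.tsv --snp rs2294008 --factor lauren
polyassoc riskmodel --effects effects.tsv --lambda 2.0 --top 0.1 \
                    --reduction 0.4 --baseline 0.01
polyassoc simulate  --config sim.yaml --out cohort.tsv     # seed mandatory
polyassoc pipeline  --config analysis.yaml
```

`effects.tsv` has columns `rs_id  p_risk  rr`. The pipeline emits
publication-style TSV tables (ORs 2 dp, p-values 4 dp, percentages 1 dp,
significance markers `*`/`†`/`‡` for p < 0.05/0.01/0.001) plus an unrounded
JSON sidecar and a run log; rounded tables are a pure function of the
sidecar.

## Notes on conventions

- Woolf CI: `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`; Haldane–Anscombe 0.5
  correction is opt-in and never silent.
- Combination-table ORs are unadjusted cross-product ratios (matching the
  published tables); adjustment is available but off by default.
- `λ` (familial relative risk) is a required user input to the polygenic
  model; there is no default.
- Age enters adjusted models as a continuous covariate by default; a banded
  (≤40 / >40) coding is available via `age_coding="banded"`.
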