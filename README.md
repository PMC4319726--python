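# snpcc

Case-control SNP association analysis: Hardy–Weinberg equilibrium testing,
genetic-model odds ratios (crude and covariate-adjusted logistic
regression), combined risk-genotype profiling, stratified analysis with
Cochran-Q heterogeneity and interaction likelihood-ratio tests,
false-positive report probability (FPRP) with power calculation, and a
seeded synthetic-cohort simulator so the whole pipeline can be exercised
and validated without access to the original subject-level data.

The package bundles, as a fixture (`snpcc.datasets`), the printed count
tables of a published stomach-cancer case-control study (692 cases / 774
controls; *PSCA* rs2294008 and rs2976392, *PLCE1* rs2274223, *MUC1*
rs4072037) and reproduces that study's crude statistics exactly from those
counts.

## Library overview

| module | what it does |
| --- | --- |
| `snpcc.data_model` | `SnpDef`/`Subject`/`CohortTable` domain types, subject-TSV I/O, genotype tabulation, 2×2 genetic-model contrasts, percentage→count resolution |
| `snpcc.hwe` | HWE chi-square goodness-of-fit (and an optional exact test) |
| `snpcc.association` | Woolf/Wald crude ORs, Pearson 2×3 and 2×2 tests, Cochran–Armitage trend, adjusted logistic regression |
| `snpcc.risk_profile` | per-subject risk-genotype counts, high (≥2) vs low carrier contrast |
| `snpcc.stratification` | stratified estimates, Cochran's Q, genotype×covariate interaction LRT |
| `snpcc.fprp` | FPRP = α(1−π)/[α(1−π)+(1−β)π] over a prior grid, power to detect OR 1.50/0.67, noteworthiness |
| `snpcc.synthetic_data` | marginal (table-regenerating, optionally exact) and causal (logistic truth model) cohort simulation |
| `snpcc.datasets` | the bundled study's count tables, covariate margins, published power/FPRP values |

```python
from snpcc import datasets, hwe_chisq, crude_or, make_contrast

counts = datasets.genotype_counts()["rs2294008"]
hwe_chisq(counts.control).p          # 0.105
crude_or(make_contrast(counts, "het_vs_ref")).or_hat  # 1.31
```

## Command line

The `snpcc` entry point exposes `simulate`, `hwe`, `assoc`, `profile`,
`stratify`, `fprp` and `report` subcommands. All tables are TSV (or JSON
with `--json`); displayed ORs are rounded to 2 decimals and p/FPRP values
to 3 (p < 1e-4 renders as `<0.0001`), while every internal computation uses
full precision. Exit codes: 0 success, 2 invalid input, 1 computational
failure.

```sh
snpcc simulate --config sim.yaml --seed 17 --out subjects.tsv --truth truth.json
snpcc hwe --subjects subjects.tsv --snp-config snps.yaml
snpcc assoc --subjects subjects.tsv --snp-config snps.yaml \
    --models het,hom,dominant --adjust age,sex,bmi,smoking,drinking
snpcc profile --subjects subjects.tsv --snp-config snps.yaml
snpcc stratify --subjects subjects.tsv --snp-config snps.yaml \
    --by smoking --snp rs2274223 --model dominant
snpcc fprp --or 1.30 --ci 1.05,1.62
snpcc report --subjects subjects.tsv --snp-config snps.yaml --out-dir report/
```

The SNP config is a YAML list (`id`, `gene`, `alleles: "C>T"`,
`risk_genotypes`, `direction`); see `snpcc.data_model.load_snp_config`.
The subject table is one row per participant with the fixed header
`subject_id status age sex smoking pack_years_cat drinking bmi_cat site
stage` followed by one genotype column per SNP (`NA` for missing).

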