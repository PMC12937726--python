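# acemod

Blood-enzyme phenotyping and variant-screening toolkit: genotype-corrected
level classification for carriers of a damaging missense mutation, a
mutant-marker antibody binding ratio, a calibrated filtering cascade over
plasma-protein GWAS summary statistics, per-carrier phenotype-reliability
calls, and a case/control exclusive-variant screen with a carrier-recurrence
window. Every stage runs on synthetic cohorts generated by the package
itself or on the small printed-table fixtures shipped with it — no downloads
required.

## Modules

| module | what it does |
|---|---|
| `acemod.synth_cohort` | Simulates cohorts (Hardy–Weinberg I/D genotypes, allele-dosage mutation effect, log-normal assay noise), antibody assay panels, pQTL summary-stat tables with planted effects, and grouped genotype matrices with planted exclusive variants. |
| `acemod.phenotyping` | Percent-of-control normalization, multiplicative I/D genotype correction, five-class level binning, and the 5B3/1G12 mutant-marker ratio. |
| `acemod.pqtl_screen` | Candidate filter (nominal p, coding consequence, \|beta\| ≥ 0.350), exome-wide Bonferroni short list (p < 3×10⁻⁷), large-effect sublist (\|beta\| > 1), control-based refinement, gene summaries. |
| `acemod.carrier_screen` | Modifier-variant lookup per carrier, false-positive / false-negative reliability calls, carrier-per-100,000 arithmetic, APOE summaries. |
| `acemod.protective_screen` | Variant QC (call rate, MAF), allelic chi-square association, genomic inflation, Bonferroni adjustment, exclusivity screen and the [3,5]-carrier recurrence filter. |
| `acemod.io` / `acemod.cli` / `acemod.pipeline` | TSV/VCF readers and writers (typeset scientific notation tolerated on read), packaged fixtures, the `acemod` CLI and the end-to-end driver. |

## CLI

```sh
acemod simulate --n 1000 --seed 1 --out-dir out/            # synthetic inputs
acemod phenotype --phenotypes out/phenotypes.tsv \
    --controls out/phenotypes.tsv --out out/report.tsv
acemod pqtl-screen --stats out/summary_stats.tsv --out-dir out/pqtl
acemod carrier-screen --vcf out/genotypes.vcf \
    --phenotype-report out/report.tsv \
    --refined out/pqtl/refined_list.tsv --out-dir out/carriers
acemod protective-screen --vcf out/genotypes.vcf \
    --groups out/groups.tsv --out-dir out/screen
acemod run --out-dir out/full --seed 1                      # end to end
```

Reports are deterministic for a fixed seed (no timestamps in data files), so
`acemod run` with the same seed twice produces byte-identical output.

## Fixtures

`src/acemod/data/` ships three small TSV tables used by tests and the
acceptance report: the 17-row exome-wide significant pQTL short list, the
per-cohort carrier-frequency table (with rows that do not reproduce under
any single rounding convention flagged `reproducible=no`), and the 42 × 15
exclusive-variant recurrence grid.
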