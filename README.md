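# panelpipe

Targeted amplicon-panel simulation and calling plus clinical cohort
statistics, as one tested pipeline:

* **`panelpipe.sim`** — synthetic data: random reference segments
  (FASTA), an amplicon panel with 14–21 control amplicons on each of
  chromosomes 5/8/11/18 (BED), single-end panel reads with spike-in
  point mutations / fusion-junction reads / gene-level copy-number
  changes plus matched control bloods (FASTQ), and a clinical cohort
  table with configurable staining–covariate associations and a
  proportional-hazards survival model (TSV).
* **`panelpipe.align` / `panelpipe.variants`** — a k-mer seed-and-extend
  ungapped aligner (SAM import/export supported), per-site pileups, a
  background error model estimated as the mean alternate-allele fraction
  across control bloods, and the three-rule mutation filter: allele
  fraction ≥ 10%, ≥ 5 alternate reads, and allele fraction ≥ 20× the
  background rate (all thresholds configurable). Calls go to VCF v4.2
  with per-rule FILTER tags (`lowAF`, `lowDepth`, `bgRatio`).
* **`panelpipe.fusions`** — split-anchor rearrangement detection on the
  unaligned read pool: each read is split into two 30 bp end anchors,
  anchors are placed by exact 30-mer lookup (1-mismatch fallback),
  discordant pairs are grouped by position, and groups with ≥ 8
  supporting reads are flagged. BEDPE + JSON evidence output.
* **`panelpipe.cnv`** — copy-number calling from amplicon read counts:
  per-sample coverage correction by the median control-amplicon count,
  per-amplicon log2 ratios against a blood-derived baseline, gene-level
  median summaries and loss/neutral/gain calls at ±0.5.
* **`panelpipe.stats`** — Fisher's exact test for 2×2 tables, exact
  enumeration or Monte-Carlo estimation (default 2.5×10⁷ replicates,
  with standard errors) for r×c tables, Kaplan–Meier estimation, the
  two-group log-rank test, and Cox proportional-hazards regression by
  Newton maximization (Breslow/Efron ties) with forward stepwise
  covariate selection by likelihood-ratio testing.

Coordinates are 0-based half-open internally; SAM/VCF output follows
those formats' 1-based conventions.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` implements the acceptance criteria (one test
class per criterion). One parametrized sub-case
(`fgfr3_grade` under criterion 1) is expected to fail: the published
contingency table it checks against is internally inconsistent and its
printed p-value cannot be reproduced from the printed counts (the exact
p is 0.0125, printed as 0.013); see the test module docstring.

## CLI

```sh
# synthetic inputs
panelpipe simulate reads  --config cfg.yaml --seed 1 --out simdir/
panelpipe simulate cohort --config cohort.yaml --seed 1 --out cohort.tsv

# calling
panelpipe call-variants  --reads simdir/tumor.fastq --ref simdir/ref.fa \
    --panel simdir/panel.bed --controls controls/ \
    --min-af 0.10 --min-alt 5 --bg-factor 20 --out calls.vcf
panelpipe detect-fusions --unaligned simdir/tumor.fastq --ref simdir/ref.fa \
    --panel simdir/panel.bed --anchor-len 30 --min-support 8 --window 500 \
    --out fusions.bedpe
panelpipe call-cnv --tumor t.counts.tsv --baseline b.counts.tsv \
    --panel simdir/panel.bed --loss -0.5 --gain 0.5 --out cnv.tsv

# cohort statistics
panelpipe associate --cohort cohort.tsv \
    --pairs fgfr3:location,fgfr3:grade,fgfr1:location,fgfr1:grade,fgfr3:age16 \
    --mc-reps 1000000 --seed 7 --out assoc.tsv
panelpipe survive --cohort cohort.tsv --group fgfr3 --test logrank
panelpipe survive --cohort cohort.tsv \
    --cox location,grade,proliferation_group,fgfr_combined --stepwise
```

`simulate reads` expects a YAML config with `reference` (chromosome
lengths; must include the four control chromosomes), `panel`
(target genes, amplicon length/step, controls per chromosome),
`sample` (depth, read length, base error rate, number of control
bloods) and `lesions` (snvs/fusions/cnvs) sections; see
`tests/test_io_cli.py` for a complete example. `simulate cohort` takes
any subset of the `CohortConfig` fields (patient count, grade/location
marginals, staining odds ratios, hazard model, censoring horizon).

Derived cohort variables are available in `associate`/`survive` by
name: `fgfr1`, `fgfr3` (scores 0–1 → low, 2–3 → high), `fgfr_combined`
(both-low / one-high / both-high), `age16` (pediatric < 16 vs adult).
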