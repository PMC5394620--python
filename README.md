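# itckit

Intersect-then-combine (ITC) post-processing and benchmarking for
tumour-normal somatic variant call sets.

Somatic calls made by the same caller on two different alignment pipelines
disagree mostly on false positives, while callers disagree mostly on true
positives. `itckit` exploits this: per caller it **intersects** the call sets
from two aligners (dropping aligner-specific false positives), then
**unions** the per-caller intersections (recovering caller-specific true
positives). Around that core it provides:

- **Caller-dialect I/O** — Mutect2 (GATK 3.5 era) and Strelka v1 somatic
  VCFs (SNV and indel files with tiered counts), plus a generic provenance-
  tagged VCF for merged products.
- **Admission filtering** — the callers' default criteria and an optimized
  policy: Mutect2 calls failing only the internal alt-allele-in-normal
  filter are re-admitted when the normal VAF is ≤ 7% and the tumour/normal
  VAF ratio exceeds 5; Strelka thresholds are raised to QSS_NT > 25 /
  QSI_NT > 35 with tier-2 support accepted. An optional proximity filter
  removes clustered calls.
- **Variant normalization** — left-alignment and trimming against a
  reference FASTA so equivalent indel representations from different
  callers match; without a reference, matching degrades to exact
  coordinate+allele equality.
- **Benchmarking** — TP/FP/FN classification against a truth set restricted
  to confident reference regions, sensitivity `TP/(TP+FN)`, false positives
  per megabase `FP/n_ref x 1e6`, dilution-series evaluation (FPR reported
  only at the lowest purity), false-negative breakdown by coverage, and
  replicate-concordance summaries.
- **Synthetic data** — a call-level simulator (no reads or BAMs) generating
  a mini reference with low-complexity runs, truth sets, and four
  caller-dialect VCFs per purity point with binomial allele sampling,
  pipeline-specific vs shared false positives, and optional right-shifted
  indel representations, so the whole pipeline is testable offline.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (published-table
identities, normalization and filter oracles, multi-seed set-algebra
bounds); the rest of the suite is unit and property tests per module.

## CLI

```sh
# 1. generate a synthetic dilution-series study
itckit simulate --seed 1 --out-dir study/

# 2. filter one call set with the optimized policy
itckit filter --calls study/purity_1/mutect2_bwa.vcf --dialect mutect2 \
    --policy optimized --out filtered.vcf

# 3. full ITC: filter all four call sets, intersect per caller, union
itckit combine \
    --mutect2-bwa  study/purity_1/mutect2_bwa.vcf \
    --mutect2-novo study/purity_1/mutect2_novoalign.vcf \
    --strelka-bwa  study/purity_1/strelka_bwa_snv.vcf \
    --strelka-bwa  study/purity_1/strelka_bwa_indel.vcf \
    --strelka-novo study/purity_1/strelka_novoalign_snv.vcf \
    --strelka-novo study/purity_1/strelka_novoalign_indel.vcf \
    --reference study/reference.fasta \
    --out final.vcf --stats-out stats.tsv

# 4. benchmark against the truth set
itckit benchmark --calls final.vcf --truth study/truth.tsv \
    --confident-regions study/confident.bed --target-regions study/target.bed \
    --reference study/reference.fasta --pileup study/purity_1/pileup.tsv \
    --out report.json

# 5. overlap statistics between two call sets
itckit overlap --a final.vcf --b other.vcf
```

Filter thresholds and simulation parameters can be set in a YAML config
(`--config`); CLI flags override it. Every subcommand writes a JSON
provenance record beside its outputs.

## Package layout

| module | contents |
| --- | --- |
| `itckit.variant_model` | `Variant`, normalization/left-alignment, region algebra |
| `itckit.caller_io` | dialect readers/writers, `CallRecord`/`CallSet`, VAF |
| `itckit.filters` | `FilterPolicy`, admission rules, T/N ratio, proximity filter |
| `itckit.combine` | intersections, unions, `itc`, overlap statistics |
| `itckit.benchmark` | truth sets, classification, sensitivity/FPR-per-Mb, replicates |
| `itckit.synthetic` | reference/truth/call-set simulator, study writer |
| `itckit.cli` | `simulate` / `filter` / `combine` / `overlap` / `benchmark` |
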