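# somase

Allele-specific expression of somatic variants from matched tumor/normal
DNA and RNA read counts.

`somase` integrates per-site variant/reference read counts from four
matched sequencing datasets per sample — normal exome, normal
transcriptome, tumor exome, tumor transcriptome — to:

1. **Filter** (sample, site) pairs: minimum tumor DNA/RNA depth (default
   10), germline screen on the normal datasets, bi-allelic tumor DNA
   (`0 < VAF(tDNA) < 1`), exclusion of imprinted regions (BED) and
   copy-number-altered segments (SEG, `|seg_mean|` threshold), and
   cohort-level hypermutator-sample removal (> 3 sample SDs above the mean
   mutation burden).
2. **Quantify** the variant allele fraction `VAF = n(var) / (n(ref) +
   n(var))` per dataset and the RNA:DNA expression ratio
   `V_R:D = VAF(tRNA) / VAF(tDNA)`.
3. **Call** each retained site SOM-E (mono-allelic variant expression,
   `VAF(tRNA) ~ 1`), SOM-L (variant lost from the transcriptome,
   `VAF(tRNA) ~ 0`), or expressed-balanced, using an exact two-sided
   binomial test of the tumor-RNA counts against the site's own tumor-DNA
   VAF (or 0.5), with Benjamini-Hochberg FDR control across the batch and
   hard `VAF(tRNA)` thresholds (defaults 0.9 / 0.05).
4. **Summarize** cohorts: recurrence spectra (multiplicity histogram,
   singleton fraction), stratified V_R:D / call-class comparisons
   (Kruskal-Wallis, Fisher exact, chi-square with automatic Yates
   correction), and Spearman correlations of allelic expression with
   pathogenicity/conservation scores.
5. **Simulate** full cohorts with known ground truth: negative-binomial
   coverage, purity-diluted heterozygous tumor DNA, beta-binomial RNA
   overdispersion, sequencing error, germline contamination, CNA/imprinted
   intervals, and annotation scores with a controllable rank correlation
   to the true RNA variant fraction (Gaussian copula).

## Run the tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence of the exact binomial and Fisher tests, simulation-based
type-I/sensitivity/correlation-recovery checks, exhaustive filter
verification, and the published-cohort recurrence arithmetic).

## CLI

```sh
# generate a synthetic cohort (counts.tsv, imprinted.bed, cna.seg,
# annotations.tsv, truth.tsv, manifest.json)
somase simulate --out-dir cohort/ --seed 1 --n-samples 8 --sites-per-sample 200

# filter + call expression status
somase call --counts cohort/counts.tsv \
            --imprinted-bed cohort/imprinted.bed \
            --cna-seg cohort/cna.seg \
            --out-dir called/

# recurrence spectrum + stratified summaries
somase summarize --calls called/calls.tsv \
                 --annotations cohort/annotations.tsv --out-dir summary/

# correlations and group tests
somase stats --calls called/calls.tsv \
             --annotations cohort/annotations.tsv --out-dir stats/
```

Every threshold has a CLI flag and can also be set in a plain `key =
value` config file (`--config`); precedence is flag > config file >
default. Each run writes a `manifest.json` recording the exact
configuration used, so re-running from a manifest reproduces the outputs
bit-for-bit.

## Package layout

| module | contents |
| --- | --- |
| `somase.allele_model` | `SiteKey`, `AlleleCounts`, `QuadCounts`, `VariantRecord`, `vaf`, `v_rd` |
| `somase.io_formats` | counts TSV / VCF-AD, BED / SEG intervals, annotation TSV, calls TSV |
| `somase.site_filters` | coverage / germline / bi-allelic / interval / hypermutator rules |
| `somase.ase_calling` | exact binomial test, BH adjustment, SOM-E / SOM-L caller |
| `somase.cohort_stats` | recurrence spectrum, Spearman, Kruskal-Wallis, 2x2 tests, stratified summaries |
| `somase.synthetic_cohort` | seeded cohort generator, truth table, confusion/recovery metrics |
| `somase.cli` | `simulate` / `call` / `summarize` / `stats` subcommands |
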