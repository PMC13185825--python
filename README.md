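# repsv

Analysis pipeline for **repeat-mediated structural variants (rep-SVs)** in a
two-subspecies cattle-like cohort (humpless taurine, humped indicine, plus
hybrids). Long-read SV call sets frequently coincide with transposable
elements and other repeats; this package classifies SVs against repeat
annotation, stratifies them by evolutionary state, and asks how repeat-driven
variation is distributed along the genome and across individuals:

- **rep-SV definition** — an SV whose affected interval overlaps an annotated
  repeat by ≥ 1 bp and is < 100 kbp long. Insertions occupy
  `[start, start + insertion length)`.
- **Evolutionary states** from cohort genotype patterns: *shared* (carriers in
  both subspecies), *subspecies-private* (≥ 2 carriers in one subspecies, none
  in the other), *specific*/young (a single carrier).
- **Size spectrum** — modal length peaks (~140, ~280, ~1150, ~8400 bp) and the
  REP types over-represented inside each peak window (across-type regression
  with externally studentized residuals, Bonferroni-corrected).
- **X-vs-autosome bias** — density ratios
  `(count_X/len_X) / (Σcount_A/Σlen_A)` over size thresholds, Cook's-distance
  sweeps, and a Grubbs single-outlier test (Shapiro–Wilk pre-check) on
  per-chromosome large/small rep-SV ratios.
- **Community ecology** of REP-type composition — Shannon `H = −Σ pᵢ ln pᵢ`,
  Pielou `J = H/ln S`, Bray–Curtis `Σ|u−v|/Σ(u+v)`, PCoA, DCA gradient length
  (RDA if < 3), and redundancy analysis with a free-permutation test.
- **Model selection** — nine candidate curve models fitted by OLS /
  Levenberg–Marquardt, compared on `AIC = n·ln(SSres/n) + 2k` and
  `BIC = n·ln(SSres/n) + k·ln n`, with delta-method 95% confidence bands.
- **Population statistics** — Weir–Cockerham F_ST (variance components
  a, b, c; genome-wide ratio of sums), Wilcoxon rank-sum contrasts, one-way
  ANOVA for genotype–phenotype association.

Because real multi-genome cohorts are not desk-reproducible, a first-class
**synthetic cohort generator** (`repsv.simulate`) emits VCF/BED/RepeatMasker
`.out`/GFF3/TSV files with exact ground truth for every label the pipeline is
supposed to recover (state, repeat status, dominant REP type, X placement).

## Layout

```
src/repsv/       library: simulate, sv_io, annotate, chrom_bias,
                 size_spectrum, ecology, model_select, popstats
analysis/        numbered drivers; each prints what it finds and writes
                 tables under results/
scripts/         acceptance.py — end-to-end pipeline run
tests/           pytest suite (tests/test_acceptance.py holds the
                 headline property checks)
```

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/05_chromosome_bias.py
```

prints (seed 17, 5000 SVs, 30 individuals, 3× X placement bias for rep-SVs
over 8 kb):

```
X/A density ratio by minimum SV size:
 threshold  rep_ratio  nonrep_ratio
        50       0.98          0.87
      1000       1.20          0.86
      4000       1.72          0.68
      8000       2.12           NaN
Grubbs test on per-chromosome >8kb/<=8kb rep-SV ratios: G=4.02, outlier=X, p=3.5e-05
```

Small rep-SVs land on the X in proportion to its length (ratio ≈ 1), while
the relative density of large (> 8 kb) rep-SVs roughly doubles and the X is
the single Grubbs outlier among 30 chromosomes — the planted bias is
recovered. `analysis/07_model_selection.py` likewise reports per-model AIC
recovery rates (all ≥ 0.85 at n = 50, SNR = 10) and fits one noisy power-law
dataset, ranking `Power` first (R² ≈ 0.99) with its 95% confidence band.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch — simulates the cohort, merges call
sets, classifies rep-SVs, profiles the length spectrum and X bias, computes
diversity/RDA, the model-recovery study and Weir–Cockerham F_ST — printing a
summary and writing the results JSON to `--out`. All randomness derives from
`--seed`.
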