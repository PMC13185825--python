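# Methods

## Scope and units

All internal intervals are 0-based half-open; VCF (1-based, inclusive END),
RepeatMasker `.out` (1-based inclusive) and GFF3 are converted at the I/O
boundary, BED passes through. SV lengths are absolute base pairs; an
insertion's effective interval is `[pos−1, pos−1+svlen)` — its start plus the
insertion length — so insertions and deletions share one overlap arithmetic.
Diploid genotypes are alternate-allele counts (0/1/2, −1 missing); a carrier
is any individual with count ≥ 1.

## The synthetic cohort: what it emulates, what it does not

`repsv.simulate.simulate_cohort` produces the statistical structure the
downstream analyses assume, with exact truth labels:

- **Individuals.** Default 12 taurine + 12 indicine + 6 hybrids. Breeds are
  cosmetic labels; sex is drawn but unused downstream (no Y chromosome, and
  the X is treated as diploid for genotype purposes).
- **States.** Each SV draws a state from (shared 0.45, private-taurine 0.15,
  private-indicine 0.15, specific 0.25). Genotype patterns come from
  Beta-distributed subspecies allele frequencies conditioned on the state
  (shared: Beta(1.5, 1.5) per subspecies; private: Beta(2, 2) in the carrier
  subspecies, 0 in the other), Bernoulli presence per individual, then
  per-genotype missingness (default 0.02) — the whole draw is rejected and
  repeated until the pattern, recomputed from non-missing calls, still
  satisfies the state definition. Hybrids get the mean of the two subspecies
  frequencies for shared SVs and never carry private SVs, so state truth is
  exactly recoverable. The Beta parameters are tunable conventions, not
  estimates.
- **Sizes.** Repeat SVs mix a log-uniform background on [50, 20 000] bp
  (weight 0.55) with four uniform peak components — 125–158 (0.18, Bov-A2),
  252–316 (0.12, Bov-A2), 1018–1263 (0.09, LTR/ERVK), 7686–9689 bp
  (0.06, LTR/ERVK). Non-repeat SVs are log-uniform on [50, 5 000] bp; the
  smaller cap keeps repeat-free placement feasible on the desk-scale genome
  (real non-repeat SVs extend further — a documented realism trade-off).
- **Placement.** Chromosome choice is proportional to length; for repeat SVs
  longer than 8 000 bp the X weight is multiplied by `x_bias` (default 1;
  the analysis scripts use 3). Effective intervals are kept pairwise
  disjoint with a 150 bp free margin, large SVs placed first.
- **Repeat track.** Each repeat SV receives a co-placed repeat covering its
  entire effective interval, so its truth REP type always attains the
  maximal possible overlap and the dominant-type label is exact; decoy
  repeats (30/Mb) avoid every SV interval, so non-repeat SVs overlap
  nothing. Consequences worth knowing: repeat coverage is not genome-wide
  realistic, and the disjointness margin (150 bp < the 1 kb merge distance)
  means SURVIVOR-style merging may still chain a few neighbouring SVs —
  deliberately, since real merging does too.
- **Determinism.** One `numpy` Generator drives every draw in a fixed order;
  the same config yields byte-identical output files. No float reductions
  with order ambiguity enter the draw path.

A green test on this cohort therefore establishes that the *pipeline logic*
recovers planted structure; it says nothing about caller error models,
breakpoint uncertainty, reference bias, or sequence content, none of which
are simulated.

The default desk genome is 29 autosomes × 1 Mb + X × 1.5 Mb. Dense
simulations (10 000 SVs, or 5 000 with the analysis defaults) use a 3×
version to keep the disjoint-placement occupancy low; both satisfy the same
proportional-placement model.

## Merging and filters

Merging is single-linkage per chromosome (and per SV type): an edge joins
two records when both start and end are within 1 000 bp; clusters with
support from fewer than 2 distinct sources are dropped (configurable), and
merged lengths outside [50 bp, 100 kbp] are removed. The representative is
the member with the smallest `(chrom, pos, end, source)` tuple; the merged
length is the lower median of member lengths — deterministic choices made
where the cited tool's behaviour is unspecified. Chains may exceed the
pairwise distance (single-linkage property). Missingness filtering removes
SVs with strictly more than 50% missing genotypes; SVs absent in every
individual can be dropped with `drop_all_absent`. Novelty uses 50% reciprocal
overlap of effective intervals against any published SV type. Saturation
subsamples call-set orderings without replacement; identity is the SV id
(shared pan-SV namespace) or the coordinate tuple as a fallback.

## Classification

rep-SV ⇔ total repeat overlap ≥ 1 bp and svlen < 100 kbp (strict). Dominant
REP type: largest summed overlap, ties to the lexicographically smaller
label. Genomic context priority: exon > intron > intergenic. States follow
the carrier rules above; hybrids are ignored for the shared/private tests
and count only toward the single-carrier ("specific" ≡ young) total. Size
classes are half-open: [50, 200), [200, 500), [500, ∞).

## X-vs-autosome diagnostics

Density ratios pool autosomes length-weighted:
`(count_X/len_X) / (Σcount_A/Σlen_A)`. The Cook sweep's default "ratio" mode
measures each chromosome's influence on the *mean* rep/nonrep count ratio
(intercept-only model) — the regress-on-length alternative is degenerate on
the equal-length desk genome; "counts" mode regresses rep on nonrep counts
with full OLS influence measures. The Grubbs test is two-sided on the
maximum absolute deviation, p from the closed-form t relation
`G = (n−1)/√n · √(t²/(n−2+t²))`, with a Shapiro–Wilk warning below p = 0.05.
PCA centers (optionally scales) features, uses SVD, and fixes each
component's sign so its largest-|loading| entry is positive.

## Ecology

Natural logarithms throughout (J = H/ln S is base-invariant anyway).
Bray–Curtis operates on raw counts. PCoA double-centers squared distances;
negative eigenvalues are reported but excluded from variance fractions. The
DCA gradient length is the range of CA axis-1 site scores under Hill's
scaling (standard coordinates × √(λ/(1−λ))); nonlinear rescaling is omitted.
On short (noise) gradients this agrees closely with the detrended reference
implementation (≈ 0.1–0.2 SD on random matrices, vs 3.4 unscaled) and it
overestimates very long gradients — harmless, since only the "< 3 ⇒ linear
ordination" decision consumes the value. RDA column-centers the response
(Hellinger optional), dummy-codes the constraint drop-first, eigendecomposes
the fitted values, and tests significance by freely permuting response rows
with the pseudo-F statistic, `p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)`. The
implementation reproduces vegan's `rda` constrained proportion to 1e-12 on a
frozen fixture (tests/test_ecology.py).

## Model selection

Forms: Linear `a+bx`; Inverse `a+b/x`; Logarithmic `a+b·ln x`; Quadratic
`a+bx+cx²`; InverseAndLinear `a+b/x+cx`; ConstantAndLogarithmic and
InverseAndConstant are retained re-parameterisations of Logarithmic and
Inverse (the candidate list is kept verbatim; `equivalent_models` exposes the
alias classes and ties resolve AIC → BIC → k → name). Exponential
`a·e^{bx}` and Power `a·x^b` are fitted by `scipy.optimize.curve_fit`
started from log-linearised estimates using only y > 0 points; fits that
fail are flagged and excluded from selection. All models share the
RSS-based criteria `AIC = n·ln(SSres/n)+2k`, `BIC = n·ln(SSres/n)+k·ln n`,
with SSres floored at machine-ε × SStot so exact fits still rank first; a
constant response reports R² = 0. Confidence bands use the delta method
(`se² = Jᵀ Cov J`, t quantiles at n−k df) and refuse extrapolation beyond
the observed x-range. The recovery study (n = 50, SNR = 10, parameters in
`simulate.RECOVERY_PARAMS`) counts a selection as correct when the AIC-best
model can represent the generating curve exactly — this folds in the alias
pairs and the nesting of Linear/Inverse inside InverseAndLinear.

## Population statistics

Weir–Cockerham components per biallelic site (r groups, sitewise missing
exclusion): with per-group sizes nᵢ, frequencies pᵢ and het fractions hᵢ,
`a = n̄/n_c[s² − (p̄q̄ − s²(r−1)/r − h̄/4)/(n̄−1)]`,
`b = n̄/(n̄−1)[p̄q̄ − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]`, `c = h̄/2`,
θ̂ = a/(a+b+c); the genome-wide value is Σa/Σ(a+b+c). Monomorphic sites and
sites missing in a whole group are skipped and counted; negative θ̂ are kept.
Tests cross-check against an independently coded nested-ANOVA (mean-square)
formulation and a Balding–Nichols drift simulation. Rank-sum contrasts use
exact enumeration when both groups are ≤ 10 without ties, else the
tie-corrected normal approximation. ANOVA guards the degenerate corners:
equal class means ⇒ F = 0, p = 1; zero within-class variance with unequal
means ⇒ F = ∞, p = 0; singleton genotype classes are dropped with a warning.
The 2×2 chi-square is Pearson's without continuity correction.

## Known limitations

- No sequence content: alleles are symbolic; breakpoint-resolution effects
  and caller-specific error modes are out of scope.
- The repeat track guarantees classification truth rather than genome-wide
  repeat realism; overlap statistics on it should not be read as biological.
- Non-repeat SV sizes are capped at 5 kb in the generator, so nonrep density
  ratios above that threshold are undefined (reported as missing).
- DCA omits nonlinear rescaling (decision-rule fidelity only); CCA itself is
  not implemented — the recommendation is emitted.
- BND/multi-allelic records are skipped at VCF ingestion and counted.
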