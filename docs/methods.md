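# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `neutroqtl`, in the spirit of the methods documentation
of mature statistical-genetics packages.

## Association model and permutation calibration

The association engine fits ordinary least squares of (log2, quantile-
normalized) expression on allele count (0/1/2) per SNP–probe pair, restricted
to pairs whose SNP lies within ±250,000 bp of the probe midpoint (bounds
inclusive: "±250 kbp" is read as a closed interval). Samples with a missing
genotype call are excluded pairwise, per SNP. A pair is undefined — skipped
and logged, never imputed — when fewer than 3 complete samples or fewer than
2 genotype classes remain.

The nominal P value is the two-sided t test on the slope with `n_used − 2`
degrees of freedom, evaluated through the Student-t survival function so
extreme associations keep a positive, accurate tail value instead of
underflowing to zero; a floor of 1e−300 is applied for numerically perfect
fits. Variance explained is reported as r², the squared genotype–expression
Pearson correlation (equivalently t²/(t²+df)).

Per-probe significance uses Churchill/Stranger-style phenotype permutations.
One permutation = one label swap of the expression vector, shared by all cis
SNPs of the probe within that iteration so the LD among SNPs — and hence the
effective multiplicity — is preserved; permuting per SNP independently would
break the min-P null. Missing genotypes are handled under permutation exactly
as in the observed fit: labels are swapped first, then pairwise deletion per
SNP. The threshold is the k-th smallest of the `n_perm` min-P values with
k = ⌈α·n_perm⌉ and no interpolation (10th of 10,000 at α = 0.001); the
ceiling is computed with a 1e−9 guard so binary float products such as
0.001 × 10000 do not round up. Significance is the strict inequality
`p_nominal < p_threshold`. Two perfectly correlated cis SNPs produce exactly
the min-P distribution of one SNP — redundancy adds no multiplicity.

Each probe draws its permutations from a random stream derived
deterministically from `(seed, probe_id)` (BLAKE2 hash of the probe id
seeding a PCG64 generator), so serial and parallel traversals, or scans of
probe subsets, give identical thresholds.

At α = 1.0 the threshold equals the maximum of the permutation minima. This
makes every probe with at least one testable cis SNP significant at the
probe level with high probability, but *not* every pair: a pair's nominal P
can exceed the largest min-P when the probe has several cis SNPs.

## Synthetic cohort generator

The generator emulates the structure of an array-genotyped expression cohort
and is itself first-class, tested code; its defaults are the study conditions
the rest of the package is validated under.

**Genotypes.** A latent-Gaussian copula: per haplotype, a standard-normal
AR(1) chain within each LD block (adjacent-SNP latent correlation
`ld_decay`, default 0.9; blocks of `ld_block_size` = 10 SNPs are mutually
independent) is thresholded at Φ⁻¹(MAF) and the two haplotype indicators are
summed. This yields Hardy–Weinberg genotype frequencies per SNP and a
monotonically decaying genotypic r² within blocks; the realized genotypic r²
is attenuated relative to the latent correlation (tetrachoric-type
attenuation), which is acceptable because tests assert ordering and
calibration, not a specific r² value. MAFs are drawn uniformly in
`maf_range` (default (0.05, 0.5]) for flat coverage of the frequency
spectrum; no population-specific spectrum is claimed. Missing calls are
masked uniformly at random (MCAR, default 1%), matching the
pairwise-exclusion contract being tested. SNP positions are 1-based, evenly
spaced (5 kb) and strictly increasing on a single autosome.

**Expression.** The signal is additive on the log2 scale:
`baseline + β·g + N(0, noise_sd)` with per-probe baselines uniform in
[6, 10] (typical log2 array intensities) and unit noise by default. β is
calibrated against the *empirical* genotype variance so that
β²Var(g)/(β²Var(g)+noise_sd²) equals the requested variance explained;
realized r² therefore converges to the target as the cohort grows (verified
at n = 5,000 within 0.02). When a genotype call is masked, the signal uses
the per-SNP mean fill — the donor's phenotype exists regardless of whether
the array call succeeded. Exported intensities are `2^signal`, i.e.
log-normal raw values, so the quantile-normalize + log2 stage is exercised
end to end; `log2` of the raw matrix recovers the signal exactly. With
`noise_sd = 0` any planted effect fits with r² = 1 exactly.

**What the generator does not emulate:** haplotype phase, recombination
maps, population structure/admixture, batch effects, platform detection
p-values (detection calls are an external input; the generator fabricates
them by thresholding intensities), probe cross-hybridization. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under a clean additive model, not robustness to those real-data
complications.

**Default cohort size is 114 samples**, matching the emulated study, so
power and recovery figures are representative of that regime. Tests and the
acceptance script use 40–120 SNPs, 8–25 probes and 200–1,000 permutations —
sizes chosen so the full suite runs in minutes while keeping Monte-Carlo
error well inside the asserted tolerances.

## Quality control

Rules are applied in a fixed precedence order so report counts are
deterministic and each marker is counted once: for SNPs, non-autosome →
call rate → monomorphic; for probes, non-autosome → SNP-in-probe. A SNP is
kept when its call rate is ≥ 0.95 (the boundary is retained: "below 95%" is
removed) and at least two genotype classes are observed. "Monomorphic" means
one distinct observed genotype; no additional MAF filter is applied to
analysis SNPs. Probes detected in fewer than 5% of samples are flagged but
retained — selective loss of expression can be biologically meaningful.

Quantile normalization across samples replaces each sample's rank-k value by
the mean of the rank-k values over samples; tied values receive the mean of
the reference values at their tied ranks (the common convention; the
platform software's tie dialect is unspecified). Log2 follows. After the
transform every sample's sorted vector is identical by construction — the
defining property, tested on arbitrary random matrices.

Duplicate samples are detected as pairs with squared Pearson correlation
across probes **at or above** the threshold (default 0.98). The inclusive
comparison is this package's convention: it makes the boundary case
`r2_threshold = 1.0` mean "exactly the bit-identical pairs" instead of the
empty set, and differs from a strict comparison only on a measure-zero
boundary.

## LD, sharing and enrichment

LD is genotypic (composite) r² — the squared Pearson correlation of
allele-count vectors over pairwise-complete samples — the standard unphased
proxy when haplotype phase is unavailable; it is symmetric and invariant to
allele-label flips. A constant vector makes r² undefined (NaN), which
compares below any threshold. Proxy expansion is one hop only (a SNP joins
the set if it exceeds the threshold against at least one *seed* SNP; no
transitive closure), matching tagSNP practice. Two threshold conventions are
exposed because the use cases differ: expansion defaults to strict
(`r² > 0.8`, "exceeding"), sharing defaults to inclusive (`r² ≥ 0.8`,
"threshold of 0.8").

Cross-dataset sharing partitions our significant probes into four disjoint
classes (shared with both external datasets / with the first only / with the
second only / unique); a probe is shared with a dataset when the dataset has
an eQTL for the same matching key (gene symbol by default, probe id
optionally) whose SNP is identical to or in LD with one of the probe's
significant SNPs. Percentages are round-half-even to 2 decimals; the four
counts always sum to the total.

Overlap enrichment is the hypergeometric upper tail P(X ≥ k), computed via
the log survival function so values far below float underflow remain usable
(a `log10` variant is provided). The enrichment universe is a parameter —
total tested probes for the sharing analysis, distinct catalog SNPs for the
GWAS intersection, by default — because no universally correct choice
exists; reported P values should be read relative to the stated universe.
Homolog mapping is a strict two-column join: conflicting duplicate mappings
raise an error naming the symbol, unmapped genes are listed rather than
dropped silently.

## Stimulation-response statistics

qPCR arithmetic: ΔCt = Ct(gene) − Ct(control) (negative values allowed),
linear expression 2^(−ΔCt), and treated-vs-mock fold change
2^(ΔCt_mock − ΔCt_treated), invariant to adding a constant to both ΔCt
values.

Two genotype groups are compared with a two-sided Mann–Whitney U test. In
the small-sample regime (combined n ≤ 20, the size of typical validation
cohorts at 7–9 donors per genotype) the p value is exact by full enumeration
of all C(n₁+n₂, n₁) label assignments of the pooled mid-ranks, using the
symmetric-tail definition P(|U − n₁n₂/2| ≥ |u_obs − n₁n₂/2|). This handles
ties without approximation and gives p = 1 for identical groups; on tie-free
data it agrees with the classical exact distribution. Larger samples use the
tie-corrected normal approximation. Three genotypes use the Kruskal–Wallis
chi-square approximation with tie correction, followed by Dunn's pairwise
z-tests on the pooled mid-ranks with the usual tie-corrected variance;
p values are Bonferroni-adjusted by default (the adjustment choice is
exposed, since common software offers both adjusted and unadjusted output).
Group sizes are data, never constants.

## Pipeline

`run_pipeline` chains simulate → QC/normalize → cis scan → sharing → catalog
intersection from a single serializable config whose one seed reproduces the
entire run byte-for-byte (output tables contain no timestamps). Each stage
logs a record-count ledger (input = retained + removed) and a failure aborts
with the stage named. The external eQTL lists and the GWAS-style catalog
used by the overlap stages are deterministic fixtures subsampled from the
run's own significant eQTLs at sharing fractions of 0.42 (monocyte stand-in)
and 0.28 (B-cell stand-in), chosen to mirror the relative sharing of
myeloid- versus lymphoid-origin subsets; they are stand-ins whose purpose is
to exercise the partition logic, not to model any published dataset.

## Known limitations

- No covariate adjustment (principal components, sex, batch); the engine
  regresses expression on genotype alone.
- No trans-eQTL mapping and no beta-approximation of permutation p values;
  thresholds are purely empirical order statistics.
- Genotypic r² understates haplotype r² when phase matters; no imputation.
- The permutation threshold at very small α requires correspondingly many
  permutations (k = ⌈α·n_perm⌉ ≥ 1 enforces a floor at the minimum).
- The exact Mann–Whitney enumerates up to C(20,10) ≈ 1.8 × 10⁵ assignments;
  the cutoff is configurable but quadratic growth makes much larger exact
  settings impractical.
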