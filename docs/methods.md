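# Methods

## Posterior computation

For one region with Q variants and two traits, each causal configuration
assigns at most one causal variant per trait. With per-variant Bayes
factors BF1, BF2 (association vs. null) and per-SNP priors p1, p2, p12, the
unnormalised hypothesis weights are

    H0: 1
    H1: p1 · S1              S1  = Σᵢ BF1ᵢ
    H2: p2 · S2              S2  = Σⱼ BF2ⱼ
    H3: p1·p2 · (S1·S2 − S12)
    H4: p12 · S12            S12 = Σᵢ BF1ᵢ·BF2ᵢ

normalised to PP0..PP4. The hypothesis-level priors are induced from the
per-SNP ones by this construction; there is no separate hypothesis-prior
interface. `enumerate_posteriors_oracle` evaluates the same posterior by
explicit enumeration of all (Q+1)² configurations and exists purely as an
independent check (it is capped at Q ≤ 2000).

Numerical choices:

- Everything is aggregated in log space with log-sum-exp; per-variant log
  Bayes factors up to ~700 (z ≈ 37 with heavy shrinkage) cause no overflow.
- The H3 cross-term S1·S2 − S12 is *not* formed as a difference: when one
  shared signal dominates, S1·S2 and S12 agree to machine precision and
  the difference cancels catastrophically. It is instead computed exactly
  as LSEᵢ(log BF1ᵢ + LSE_{j≠i} log BF2ⱼ) using prefix/suffix log-sum-exp
  arrays — still O(Q), no clamping or special-casing needed. At Q = 1 the
  term is empty and PP3 = 0 identically.
- log(1 − r) in the Wakefield factor is formed as log V − log(V + W), which
  stays accurate when V ≪ W (where 1 − r itself loses precision).
- Ties for the top shared variant break by smallest input row index.
- p12 > min(p1, p2) is rejected outright rather than reordered: p12/p1 is
  the conditional probability that a trait-1 causal variant also drives
  trait 2 and cannot exceed one.

Posteriors are reported as probabilities in [0, 1]; the CLI additionally
prints percentages.

## Bayes factors

The prior effect SD (√W) defaults to 0.15 for quantitative traits on a
standardised scale and 0.20 for case-control traits (log-odds scale); both
are per-trait constants, configurable. For a quantitative trait reported on
an unstandardised scale, √W is multiplied by the phenotype SD. When sdY is
not supplied it is estimated by regressing 2Nf(1−f) on 1/varβ through the
origin (slope = sdY²), requiring ≥ 10 variants; when only p-values are
available sdY = 1 is assumed with a warning.

Two input routes per variant: (β̂, V) directly from regression output
(preferred, especially for imputed data, where the MAF approximation
understates V), or (p, MAF) with |z| = Φ⁻¹(1 − p/2) and V from the
MAF/sample-size approximation. Both routes may be mixed within a pair and
agree to rounding when describing the same data. p-values below 1e-300
cannot be inverted in double precision and raise an error asking for
β̂/V instead — silent clamping would bias the Bayes factors. Allele
frequencies above 0.5 are folded; only f(1−f) enters.

## Harmonisation

Variants are matched across the two tables on identifier alone (an optional
chrom:pos mode exists in the reader's column map); alleles are never used
because the statistic depends on z² only, so effect directions need no
alignment. Filters follow common eQTL practice: MAF < 0.001, monomorphic
sites, and imputation Rsq < 0.3 are dropped (the Rsq filter is skipped,
once, when no rsq column exists — typed data); known multi-allelic sites
can be excluded via a user-supplied id list, since no variant database is
bundled. Every dropped variant appears exactly once in the audit log with
one of: not_shared, low_maf, monomorphic, multi_allelic, low_rsq,
duplicate. Retained variants are ordered by position then id. Coordinates
are 1-based inclusive throughout.

## Simulation framework

The generator emulates a fine-mapping region: Q = 100 variants spaced 4 kb
apart (≈ 400 kb span), allele frequencies uniform on (0.05, 0.5),
haplotypes drawn by thresholding a latent stationary AR(1) Gaussian
(lag-one correlation `ld_decay`, default 0.9) at frequency-matched
cutoffs. This yields binary haplotypes whose r² decays with distance, from
a panel of 1,000 haplotypes per replicate. Cohorts for both traits are
drawn from the same panel, so allele frequencies and LD are identical in
the two study populations by construction.

Phenotypes have unit variance: a causal variant with frequency f and target
variance fraction v contributes b·g with b = √(v/(2f(1−f))) under additive
coding (g ∈ {0,1,2}); recessive inheritance uses the indicator of two
copies with b = √(v/(q(1−q))), q = f². Residual normal noise fills the
remaining variance. Scans are marginal trend tests (univariate OLS per
variant, normal approximation to the t statistic); conditional scans refit
every variant with the index dosage as covariate, the index defaulting to
the smallest marginal p-value (eligibility threshold for stepwise use:
marginal p < 1e-6, configurable). Sparse-panel modes keep a random half of
the variants, forcing the causal variants in or out, before the summary
statistics enter the pipeline.

Standard scenarios fix the expression-like trait at n = 1,000 (n = 966 in
the small-biomarker design) with the causal variant explaining 10% of
variance, and the biomarker-like trait at n = 10,000 (or 2,000) with 2% —
the regime where both single studies are well powered. The mixed-regulation
design splits the 10% expression variance equally between a shared and an
expression-only variant, placed at least 20 variants apart so the two
signals are nearly independent. Power experiments run 500 replicates per
design by default (200 in the faster test-suite checks); every replicate
draws a fresh panel and causal placement from a spawned seed, so results
are reproducible bit for bit from one integer seed.

### What the scaffold does not emulate

Thresholding a latent Gaussian with independently drawn per-variant
frequencies cannot produce near-perfect proxies: pairwise binary r²
saturates around 0.3–0.4 regardless of the latent correlation, whereas real
imputed data give a typical causal variant several r² > 0.8 tags. Two
consequences:

- Claims that depend only on signal strength and shared-vs-distinct
  placement (null behaviour, hypothesis recovery, power vs. sample size,
  loss of power under causal-variant masking) transfer well.
- The split of posterior mass between H3 and H4 when two near-equal signals
  compete is sensitive to LD multiplicity: many high-r² tags per signal
  inflate the H3 cross-sum by roughly log(number of tags) relative to the
  H4 diagonal. With ~1 effective tag per signal, this scaffold settles
  near-ties in favour of H4 more often than denser real data would — the
  mixed-regulation design yields PP4 > 0.9 in ≈ 0.65–0.70 of replicates
  here (insensitive to `ld_decay` over 0.8–0.98), where denser scaffolds
  sit nearer one half. The PP3 > 0.9 proportion (≈ 0.15–0.20) is much less
  affected.

Also not modelled: imputation uncertainty (no Rsq simulation), covariates
or population structure, binary-outcome cohorts (the case-control variance
approximation is validated against a logistic-regression Monte-Carlo
oracle instead), and coalescent-exact haplotype histories.

## Degenerate inputs and edge behaviour

Q = 1 forces PP3 = 0. Monomorphic scan columns and variants collinear with
the conditioning index are flagged and dropped before dataset construction,
as is the index variant itself. Scan p-values are floored at 1e-300 when
packaged into summary tables (the β̂/V route, which the pipeline prefers,
is unaffected by the floor). W = 0 gives log ABF = 0 for any z.

## Known limitations

One causal variant per trait per region is the core modelling assumption:
regions with multiple independent associations should be analysed
stepwise, re-running the test on conditional statistics (supported via
`conditional_scan`; approximate conditional analysis from summary
statistics alone is out of scope). Priors are shared across all SNPs —
no location- or annotation-specific weighting. Effect sizes across traits
are treated as independent under H4; correlated-effect extensions are not
implemented.
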