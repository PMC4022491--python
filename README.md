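# pycoloc

Bayesian colocalisation testing for pairs of genetic association signals
from single-SNP summary statistics.

## The problem

A GWAS hit and an eQTL in the same genomic region may reflect one shared
causal variant (the expression change mediates the trait association) or
two distinct variants that happen to sit in the same LD neighbourhood.
Overlapping significance, or lead SNPs being in LD, cannot distinguish
these situations. `pycoloc` computes, from nothing more than per-variant
summary statistics for each trait (p-value + minor allele frequency +
sample size, or effect estimate + its variance), posterior probabilities
for the five mutually exclusive hypotheses about a region with Q variants:

| hypothesis | meaning |
|---|---|
| H0 | neither trait has a causal variant in the region |
| H1 | only trait 1 does |
| H2 | only trait 2 does |
| H3 | both do, at two distinct variants |
| H4 | both do, at one shared variant |

It is aimed at statistical geneticists integrating GWAS with molecular QTL
catalogues, and anyone comparing two association scans over a region.

## The model

Assume at most one causal variant per trait per region. Every causal
"configuration" is then a pair (i, j), i, j ∈ {∅, 1..Q}, and the
(Q+1)² configurations partition into H0–H4. Evidence per variant and trait
is a Wakefield approximate Bayes factor: for effect estimate β̂ with
variance V, prior β ~ N(0, W),

    log ABF = ½ [ log(1 − r) + r z² ],    r = W/(V + W),    z = β̂/√V.

Only z² enters, so allele orientation is irrelevant. V may come from
regression output or be approximated as V = sdY²/(2Nf(1−f)) for a
quantitative trait (1/(2Nf(1−f)s(1−s)) on the log-odds scale for
case-control with case fraction s). Per-SNP priors p1, p2 (association with
one trait) and p12 (association with both; default 1e-4, 1e-4, 1e-5) weight
each configuration, and the hypothesis sums factorise into a single linear
pass per trait:

    PP_h ∝ { 1,  p1·S1,  p2·S2,  p1·p2·(S1·S2 − S12),  p12·S12 }

with S1 = Σᵢ BF1ᵢ, S2 = Σⱼ BF2ⱼ, S12 = Σᵢ BF1ᵢ·BF2ᵢ, all evaluated in log
space. Conditional on H4, the posterior that variant i is the shared causal
one is softmax(log BF1 + log BF2)ᵢ. A brute-force enumeration oracle over
all configurations is included and tested against the fast path.

The package also ships the surrounding workflow: summary-table reading and
harmonisation (MAF ≥ 0.001 and imputation Rsq ≥ 0.3 filters, with an audit
log of every dropped variant), prior-sensitivity scans over p12, conditional
single-SNP re-analysis for regions with multiple independent signals, and a
seeded LD-structured simulation framework for power experiments.

## Worked example

Generate the bundled 8-SNP toy region (a shared signal at rs3 in both
traits) and test it:

```sh
pycoloc make-fixture --out-dir .
pycoloc coloc --trait1 toy_trait1.tsv --trait2 toy_trait2.tsv \
    --n1 5000 --n2 8000 --sdy1 1 --sdy2 1 --out-dir results
```

prints

```
nsnps	8
PP0	2.22471e-23	0.00%
PP1	2.55379e-11	0.00%
PP2	8.71514e-16	0.00%
PP3	4.33583e-07	0.00%
PP4	1	100.00%
top_shared_variant	rs3
```

i.e. essentially all posterior mass on a shared causal variant (PP4 ≈ 1),
with rs3 the most probable shared variant — as constructed. The prior
sensitivity scan (`pycoloc sensitivity`, default grid 1e-6, 1e-5, 2e-5,
1e-4) shows PP4 > 0.9999 across two orders of magnitude of p12, so the
conclusion here is prior-robust.

A power experiment under a strong shared-variant design (expression trait:
n = 1,000, 10% of variance; biomarker: n = 10,000, 2% of variance):

```sh
pycoloc simulate --scenario h4 --n-reps 50 --seed 7 --out-dir sim
```

```
              q10        median           q90  prop_gt_0.9
PP0  6.810503e-73  5.036724e-62  9.712111e-51          0.0
...
PP4  1.000000e+00  1.000000e+00  1.000000e+00          1.0
```

every replicate confidently recovers the shared variant. Scenarios `h0`
through `h4`, tag-only panels (`tag-causal-absent`) and a two-signal
mixed-regulation design (`mixed-regulation`) are built in.

As a library:

```python
from pycoloc import combine_abf, ColocPriors
res = combine_abf(labf_trait1, labf_trait2, ColocPriors())
res.pp            # PP0..PP4
res.per_snp_h4    # per-variant shared-causal posterior
```

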