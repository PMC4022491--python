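"""LD-structured cohort simulation and power experiments.

Haplotypes are generated from a latent stationary AR(1) Gaussian process
thresholded at frequency-matched cutoffs, which yields binary haplotypes
whose pairwise correlation decays with distance — a seeded stand-in for a
real fine-mapping genotype scaffold with a matched MAF spectrum and a
tunable LD-decay knob.  Cohorts draw genotypes as random haplotype pairs
from one shared panel, so allele frequencies and LD patterns are identical
in both study populations.

Phenotypes are standardised to unit variance: a causal variant with
frequency f explaining a fraction ``v`` of trait variance gets additive
effect ``b = sqrt(v / (2 f (1-f)))`` per allele (or, under recessive
inheritance, ``b = sqrt(v / (q (1-q)))`` on the indicator of two copies,
``q = f**2``), with residual noise filling the remaining variance.

Scans are marginal linear trend tests (one univariate regression per
variant); conditional scans refit every variant with the index dosage as a
covariate.  Power experiments wire the simulated summary statistics through
the full I/O + Bayes-factor + posterior pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abf import TraitSpec
from .engine import HYPOTHESES, ColocPriors, coloc_summary_pair
from .summaries import SummaryDataset

__all__ = [
    "HaplotypePanel",
    "SimulatedStudy",
    "Scenario",
    "PowerTable",
    "simulate_haplotype_panel",
    "simulate_study",
    "single_snp_scan",
    "conditional_scan",
    "scan_to_dataset",
    "run_power_experiment",
    "standard_scenarios",
]

#: Marginal p-value below which a signal is considered worth conditioning on.
CONDITIONAL_P_THRESHOLD = 1e-6


@dataclass
class HaplotypePanel:
    """A set of binary haplotypes over Q ordered variants."""

    haplotypes: np.ndarray  # (n_hap, Q) 0/1
    positions: np.ndarray  # 1-based coordinates
    frequencies: np.ndarray  # realised allele-1 frequencies
    ld_decay: float
    seed: object = None

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def variant_ids(self) -> list[str]:
        return [f"snp{j + 1}" for j in range(self.n_variants)]

    def r_squared(self) -> np.ndarray:
        """Pairwise haplotype r^2 between variants."""
        c = np.corrcoef(self.haplotypes.T)
        return c**2


@dataclass
class SimulatedStudy:
    """One cohort: genotype dosages, a unit-variance phenotype, and truth."""

    genotypes: np.ndarray  # (N, Q) dosages 0/1/2
    phenotype: np.ndarray
    causal_indices: tuple[int, ...]
    variance_explained: tuple[float, ...]
    model: str
    panel: HaplotypePanel
    seed: object = None

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]


def simulate_haplotype_panel(
    n_variants: int,
    n_haplotypes: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_decay: float = 0.9,
    seed=None,
    spacing_bp: int = 4000,
) -> HaplotypePanel:
    """Draw binary haplotypes with distance-decaying LD.

    A latent AR(1) Gaussian with lag-1 correlation ``ld_decay`` is
    thresholded per variant at the quantile of a target frequency drawn
    uniformly from ``maf_range``.  Deterministic under ``seed``.
    """
    if n_variants < 2 or n_haplotypes < 100:
        raise ValueError("need n_variants >= 2 and n_haplotypes >= 100")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    if not 0.0 <= ld_decay < 1.0:
        raise ValueError("ld_decay must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    target = rng.uniform(lo, hi, n_variants)
    cut = stats.norm.ppf(target)

    innov_sd = np.sqrt(1.0 - ld_decay**2)
    for _ in range(10):
        z = np.empty((n_haplotypes, n_variants))
        z[:, 0] = rng.standard_normal(n_haplotypes)
        eps = rng.standard_normal((n_haplotypes, n_variants - 1)) * innov_sd
        for j in range(1, n_variants):
            z[:, j] = ld_decay * z[:, j - 1] + eps[:, j - 1]
        hap = (z < cut).astype(np.uint8)
        freq = hap.mean(axis=0)
        if np.all((freq > 0) & (freq < 1)):
            break
    else:
        raise RuntimeError("could not realise a polymorphic panel; widen maf_range")

    positions = 1 + spacing_bp * np.arange(n_variants)
    return HaplotypePanel(
        haplotypes=hap,
        positions=positions,
        frequencies=freq,
        ld_decay=ld_decay,
        seed=seed,
    )


def simulate_study(
    panel: HaplotypePanel,
    n_samples: int,
    causal_spec: dict[int, float] | None,
    model: str = "additive",
    seed=None,
) -> SimulatedStudy:
    """Draw a cohort from the panel with the given causal architecture.

    ``causal_spec`` maps variant index -> fraction of phenotype variance
    explained; the fractions must sum to < 1.  Genotypes are random
    haplotype pairs; the phenotype is the sum of scaled causal dosages plus
    normal noise, standardised to unit total variance.
    """
    if model not in ("additive", "recessive"):
        raise ValueError(f"unknown inheritance model {model!r}")
    causal = dict(causal_spec or {})
    for j in causal:
        if not 0 <= j < panel.n_variants:
            raise ValueError(f"causal index {j} outside panel")
    v_total = sum(causal.values())
    if v_total >= 1.0:
        raise ValueError(f"variance fractions sum to {v_total} >= 1")
    if any(v < 0 for v in causal.values()):
        raise ValueError("variance fractions must be nonnegative")

    rng = np.random.default_rng(seed)
    pick = rng.integers(0, panel.n_haplotypes, size=(n_samples, 2))
    x = (panel.haplotypes[pick[:, 0]] + panel.haplotypes[pick[:, 1]]).astype(float)

    genetic = np.zeros(n_samples)
    for j, v in causal.items():
        if v == 0:
            continue
        f = panel.frequencies[j]
        if model == "additive":
            b = np.sqrt(v / (2.0 * f * (1.0 - f)))
            genetic += b * x[:, j]
        else:
            q = f**2
            b = np.sqrt(v / (q * (1.0 - q)))
            genetic += b * (x[:, j] == 2)
    y = genetic + rng.normal(0.0, np.sqrt(1.0 - v_total), n_samples)

    return SimulatedStudy(
        genotypes=x,
        phenotype=y,
        causal_indices=tuple(causal),
        variance_explained=tuple(causal.values()),
        model=model,
        panel=panel,
        seed=seed,
    )


def _marginal_ols(x: np.ndarray, y: np.ndarray, df_resid: int):
    """Vectorised per-column univariate least squares of y on columns of x."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    syy = float((yc**2).sum())
    mono = sxx <= 0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = xc.T @ yc / sxx_safe
    rss = np.maximum(syy - beta**2 * sxx_safe, 0.0)
    varbeta = rss / df_resid / sxx_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / np.sqrt(varbeta)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    beta[mono] = np.nan
    varbeta[mono] = np.nan
    pval[mono] = np.nan
    return beta, varbeta, pval, mono


def single_snp_scan(study: SimulatedStudy) -> pd.DataFrame:
    """Marginal linear trend test of the phenotype on each variant's dosage.

    Returns one row per variant with ``beta``, ``varbeta`` and the normal
    approximation to the two-sided p-value.  Monomorphic columns get NaN
    statistics and ``flag = 'monomorphic'``.
    """
    beta, varbeta, pval, mono = _marginal_ols(
        study.genotypes, study.phenotype, study.n_samples - 2
    )
    return pd.DataFrame(
        {
            "variant_id": study.panel.variant_ids,
            "pos": study.panel.positions,
            "maf": np.minimum(study.panel.frequencies, 1 - study.panel.frequencies),
            "beta": beta,
            "varbeta": varbeta,
            "pval": pval,
            "flag": np.where(mono, "monomorphic", ""),
        }
    )


def conditional_scan(
    study: SimulatedStudy, index_variant: int | None = None
) -> pd.DataFrame:
    """Per-variant association statistics conditional on an index variant.

    Each variant other than the index is refit in a two-predictor regression
    with the index dosage as covariate (done by residualising both the
    variant and the phenotype on the index).  When ``index_variant`` is None
    the variant with the smallest marginal p-value is used (ties broken by
    lowest index).  Variants collinear with the index get NaN statistics and
    ``flag = 'collinear'``.
    """
    x = study.genotypes
    y = study.phenotype
    n = study.n_samples

    if index_variant is None:
        marg = single_snp_scan(study)
        p = marg["pval"].to_numpy()
        if np.all(np.isnan(p)):
            raise ValueError("no polymorphic variant to condition on")
        index_variant = int(np.nanargmin(p))
    g = x[:, index_variant]
    if np.var(g) == 0:
        raise ValueError("index variant is monomorphic")

    gc = g - g.mean()
    sgg = float((gc**2).sum())
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    # residualise on the index dosage
    xr = xc - np.outer(gc, xc.T @ gc / sgg)
    yr = yc - gc * float(yc @ gc) / sgg

    sxx = (xr**2).sum(axis=0)
    syy = float((yr**2).sum())
    collinear = sxx <= 1e-10 * (xc**2).sum(axis=0)
    collinear[index_variant] = True
    sxx_safe = np.where(collinear, 1.0, sxx)
    beta = xr.T @ yr / sxx_safe
    rss = np.maximum(syy - beta**2 * sxx_safe, 0.0)
    varbeta = rss / (n - 3) / sxx_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / np.sqrt(varbeta)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    beta[collinear] = np.nan
    varbeta[collinear] = np.nan
    pval[collinear] = np.nan

    flag = np.where(collinear, "collinear", "")
    flag[index_variant] = "index"
    return pd.DataFrame(
        {
            "variant_id": study.panel.variant_ids,
            "pos": study.panel.positions,
            "maf": np.minimum(study.panel.frequencies, 1 - study.panel.frequencies),
            "beta": beta,
            "varbeta": varbeta,
            "pval": pval,
            "flag": flag,
        }
    )


def scan_to_dataset(scan: pd.DataFrame, trait_spec: TraitSpec) -> SummaryDataset:
    """Package scan output as a summary-statistics dataset.

    Rows with missing statistics (monomorphic, collinear or index variants)
    are dropped; p-values are floored at the smallest value convertible to a
    Z-score in double precision.
    """
    ok = scan["beta"].notna() & scan["varbeta"].notna() & (scan["varbeta"] > 0)
    df = scan.loc[ok, ["variant_id", "pos", "maf", "beta", "varbeta", "pval"]].copy()
    df["pval"] = np.maximum(df["pval"], 1e-300)
    return SummaryDataset(frame=df.reset_index(drop=True), trait_spec=trait_spec)


@dataclass
class Scenario:
    """A paired-study simulation design.

    ``shared`` lists (v_trait1, v_trait2) pairs, one per causal variant
    affecting both traits; ``trait1_only``/``trait2_only`` list variance
    fractions for trait-specific causal variants.  ``density`` controls
    variant masking before the scan statistics are analysed:
    ``full`` keeps every variant; the ``tag_only_*`` modes keep a random
    ``tag_fraction`` of variants, forcing the causal variants in
    (``tag_only_causal_present``) or out (``tag_only_causal_absent``) —
    emulating a sparse genotyping panel where the causal site is typed or
    only tagged.
    """

    n1: int = 1000
    n2: int = 10000
    shared: tuple[tuple[float, float], ...] = ()
    trait1_only: tuple[float, ...] = ()
    trait2_only: tuple[float, ...] = ()
    density: str = "full"
    model: str = "additive"
    n_variants: int = 100
    n_haplotypes: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.9
    tag_fraction: float = 0.5
    min_causal_separation: int = 20

    def __post_init__(self) -> None:
        if self.density not in (
            "full",
            "tag_only_causal_present",
            "tag_only_causal_absent",
        ):
            raise ValueError(f"unknown density mode {self.density!r}")
        v1 = sum(v for v, _ in self.shared) + sum(self.trait1_only)
        v2 = sum(v for _, v in self.shared) + sum(self.trait2_only)
        if v1 >= 1 or v2 >= 1:
            raise ValueError("per-trait variance fractions must sum to < 1")

    @property
    def n_causal(self) -> int:
        return len(self.shared) + len(self.trait1_only) + len(self.trait2_only)


@dataclass
class PowerTable:
    """Per-replicate posterior probabilities and their summaries."""

    replicates: pd.DataFrame  # columns PP0..PP4, one row per replicate
    scenario: Scenario | None = None
    threshold: float = 0.9

    def quantiles(self) -> pd.DataFrame:
        q = self.replicates[list(HYPOTHESES)].quantile([0.1, 0.5, 0.9])
        q.index = ["q10", "median", "q90"]
        return q

    def proportions_above(self, threshold: float | None = None) -> pd.Series:
        t = self.threshold if threshold is None else threshold
        return (self.replicates[list(HYPOTHESES)] > t).mean()

    def summary(self) -> pd.DataFrame:
        out = self.quantiles().T
        out[f"prop_gt_{self.threshold:g}"] = self.proportions_above()
        return out


def _place_causals(scenario: Scenario, rng: np.random.Generator) -> list[int]:
    """Pick causal variant indices with a minimum pairwise separation."""
    k = scenario.n_causal
    if k == 0:
        return []
    q = scenario.n_variants
    sep = min(scenario.min_causal_separation, max(1, q // (k + 1)))
    # keep causal sites away from the edges so they always have tags nearby
    lo, hi = q // 10, q - q // 10
    for _ in range(200):
        idx = sorted(rng.choice(np.arange(lo, hi), size=k, replace=False))
        if all(b - a >= sep for a, b in zip(idx, idx[1:])):
            rng.shuffle(idx)
            return [int(i) for i in idx]
    raise RuntimeError("could not place causal variants with the requested separation")


def _mask_for_density(
    scenario: Scenario, causal: list[int], rng: np.random.Generator
) -> np.ndarray:
    """Boolean keep-mask over variants implementing the panel-density mode."""
    q = scenario.n_variants
    if scenario.density == "full":
        return np.ones(q, dtype=bool)
    keep = np.zeros(q, dtype=bool)
    n_keep = max(2, int(round(scenario.tag_fraction * q)))
    keep[rng.choice(q, size=n_keep, replace=False)] = True
    if scenario.density == "tag_only_causal_present":
        keep[causal] = True
    elif scenario.density == "tag_only_causal_absent":
        keep[causal] = False
        if keep.sum() < 2:
            keep[[i for i in range(q) if i not in causal][:2]] = True
    return keep


def simulate_pair(scenario: Scenario, seed=None):
    """One replicate: panel, causal placement, and both cohorts."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_panel, s_place, s1, s2, s_mask = ss.spawn(5)
    panel = simulate_haplotype_panel(
        scenario.n_variants,
        scenario.n_haplotypes,
        scenario.maf_range,
        scenario.ld_decay,
        seed=s_panel,
    )
    rng = np.random.default_rng(s_place)
    causal = _place_causals(scenario, rng)
    k_sh = len(scenario.shared)
    k_t1 = len(scenario.trait1_only)
    shared_idx = causal[:k_sh]
    t1_idx = causal[k_sh : k_sh + k_t1]
    t2_idx = causal[k_sh + k_t1 :]

    spec1 = {i: v for i, (v, _) in zip(shared_idx, scenario.shared)}
    spec1.update(dict(zip(t1_idx, scenario.trait1_only)))
    spec2 = {i: v for i, (_, v) in zip(shared_idx, scenario.shared)}
    spec2.update(dict(zip(t2_idx, scenario.trait2_only)))

    study1 = simulate_study(panel, scenario.n1, spec1, scenario.model, seed=s1)
    study2 = simulate_study(panel, scenario.n2, spec2, scenario.model, seed=s2)
    mask = _mask_for_density(scenario, causal, np.random.default_rng(s_mask))
    return panel, study1, study2, mask


def run_power_experiment(
    scenario: Scenario,
    n_reps: int,
    seed=None,
    priors: ColocPriors = ColocPriors(),
) -> PowerTable:
    """Monte-Carlo power experiment over independent replicate regions.

    Per replicate: fresh haplotype panel and causal placement, two cohorts,
    marginal scans, panel-density masking, and the full summary-statistics
    colocalisation pipeline; collects PP0..PP4.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    root = np.random.SeedSequence(seed)
    rows = []
    for child in root.spawn(n_reps):
        panel, study1, study2, mask = simulate_pair(scenario, seed=child)
        scan1 = single_snp_scan(study1).loc[mask].reset_index(drop=True)
        scan2 = single_snp_scan(study2).loc[mask].reset_index(drop=True)
        d1 = scan_to_dataset(scan1, TraitSpec("quantitative", scenario.n1, sdY=1.0))
        d2 = scan_to_dataset(scan2, TraitSpec("quantitative", scenario.n2, sdY=1.0))
        res = coloc_summary_pair(d1, d2, priors=priors)
        rows.append({h: res[h] for h in HYPOTHESES})
    return PowerTable(replicates=pd.DataFrame(rows), scenario=scenario)


def standard_scenarios() -> dict[str, Scenario]:
    """Named study designs used throughout the power analyses.

    The eQTL-like trait is trait 1 (the shared variant explains 10% of
    expression variance, cohort of ~1,000); the biomarker-like trait is
    trait 2 (2% of variance, large cohort).
    """
    base = dict(n_variants=100, n_haplotypes=1000)
    return {
        "h0": Scenario(n1=1000, n2=10000, **base),
        "h1": Scenario(n1=1000, n2=10000, trait1_only=(0.10,), **base),
        "h2": Scenario(n1=1000, n2=10000, trait2_only=(0.02,), **base),
        "h3": Scenario(
            n1=1000, n2=10000, trait1_only=(0.10,), trait2_only=(0.02,), **base
        ),
        "h4": Scenario(n1=1000, n2=10000, shared=((0.10, 0.02),), **base),
        "shared-small-biomarker": Scenario(
            n1=966, n2=2000, shared=((0.10, 0.02),), **base
        ),
        "mixed-regulation": Scenario(
            n1=1000,
            n2=10000,
            shared=((0.05, 0.02),),
            trait1_only=(0.05,),
            **base,
        ),
        "tag-causal-present": Scenario(
            n1=1000,
            n2=10000,
            shared=((0.10, 0.02),),
            density="tag_only_causal_present",
            **base,
        ),
        "tag-causal-absent": Scenario(
            n1=1000,
            n2=10000,
            shared=((0.10, 0.02),),
            density="tag_only_causal_absent",
            **base,
        ),
    }
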