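"""Wakefield approximate Bayes factors for single-SNP association.

For one variant with effect estimate ``beta`` and estimate variance ``V``,
the evidence for association against the null under a zero-centred normal
prior N(0, W) on the effect is summarised by the log approximate Bayes
factor

    log ABF = 0.5 * (log(1 - r) + r * z**2),    r = W / (V + W),

where ``z = beta / sqrt(V)`` and the shrinkage factor ``r`` is the fraction
of the total variance contributed by the prior.  Only ``z**2`` enters, so
allele orientation is irrelevant.  ``V`` may be taken directly from
regression output or approximated from the minor allele frequency and
sample size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TraitSpec",
    "ABFTable",
    "z_from_pvalue",
    "approx_var_beta",
    "estimate_sdY",
    "log_abf",
    "abf_table_from_dataset",
]

#: Smallest two-sided p-value that can be inverted in double precision.
#: Below this, callers must supply beta/varbeta instead.
P_FLOOR = 1e-300

#: Default prior effect SDs on a standardised trait scale.
DEFAULT_W_SQRT_QUANT = 0.15
DEFAULT_W_SQRT_CC = 0.20


@dataclass
class TraitSpec:
    """Per-trait metadata needed to turn summary statistics into Bayes factors.

    Parameters
    ----------
    trait_type :
        ``"quantitative"`` or ``"case_control"``.
    N :
        Total sample size of the study.
    s :
        Case fraction, required iff ``trait_type == "case_control"``.
    sdY :
        Phenotype standard deviation for quantitative traits.  If omitted it
        is assumed to be 1 (standardised trait) when working from p-values,
        or estimated from ``varbeta``/MAF/N when effect estimates are given.
    W_sqrt :
        Prior effect SD on the standardised scale; defaults to 0.15 for
        quantitative and 0.20 for case-control traits.
    """

    trait_type: str
    N: int
    s: float | None = None
    sdY: float | None = None
    W_sqrt: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(
                f"trait_type must be 'quantitative' or 'case_control', got {self.trait_type!r}"
            )
        if self.N is not None and self.N < 2:
            raise ValueError(f"sample size N must be >= 2, got {self.N}")
        if self.trait_type == "case_control":
            if self.s is None:
                raise ValueError("case_fraction s is required for case_control traits")
            if not 0.0 < self.s < 1.0:
                raise ValueError(f"case fraction s must be in (0,1), got {self.s}")
        elif self.s is not None:
            raise ValueError("case_fraction s is only meaningful for case_control traits")
        if self.sdY is not None and self.sdY <= 0:
            raise ValueError(f"sdY must be positive, got {self.sdY}")
        if self.W_sqrt is None:
            self.W_sqrt = (
                DEFAULT_W_SQRT_QUANT
                if self.trait_type == "quantitative"
                else DEFAULT_W_SQRT_CC
            )
        if self.W_sqrt < 0:
            raise ValueError(f"prior effect SD must be nonnegative, got {self.W_sqrt}")


@dataclass
class ABFTable:
    """Per-variant log approximate Bayes factors for one trait."""

    variant_ids: list[str]
    labf: np.ndarray

    def __post_init__(self) -> None:
        self.labf = np.asarray(self.labf, dtype=float)
        if len(self.variant_ids) != self.labf.shape[0]:
            raise ValueError("variant_ids and labf must have the same length")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant_ids must be unique")
        if not np.all(np.isfinite(self.labf)):
            raise ValueError("all log Bayes factors must be finite")

    def __len__(self) -> int:
        return len(self.variant_ids)


def z_from_pvalue(p):
    """Magnitude of the normal score corresponding to a two-sided p-value.

    ``|Z| = Phi^{-1}(1 - p/2)``; strictly decreasing in ``p``.  Vectorised.

    Raises for p outside (0, 1] and for p below :data:`P_FLOOR`, where the
    inversion is not representable in double precision — supply
    beta/varbeta for such variants instead.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(p < P_FLOOR):
        raise ValueError(
            f"p-value below {P_FLOOR:g} cannot be converted to a Z-score in "
            "double precision; supply beta and varbeta for this variant"
        )
    z = stats.norm.isf(p / 2.0)
    return float(z) if z.ndim == 0 else z


def approx_var_beta(maf, spec: TraitSpec):
    """Approximate the sampling variance of a single-SNP effect estimate.

    Quantitative traits:  ``V = sdY**2 / (2 N f (1-f))`` (sdY defaults to 1).
    Case-control traits (log-odds scale): ``V = 1 / (2 N f (1-f) s (1-s))``.

    ``maf`` must already be folded into (0, 0.5].  Vectorised over ``maf``.
    """
    f = np.asarray(maf, dtype=float)
    if np.any(f <= 0) or np.any(f > 0.5):
        raise ValueError("MAF must lie in (0, 0.5]; fold frequencies > 0.5 first")
    het = 2.0 * spec.N * f * (1.0 - f)
    if spec.trait_type == "quantitative":
        sdY = 1.0 if spec.sdY is None else spec.sdY
        v = sdY**2 / het
    else:
        v = 1.0 / (het * spec.s * (1.0 - spec.s))
    return float(v) if v.ndim == 0 else v


def estimate_sdY(varbeta, maf, N: int) -> float:
    """Estimate the phenotype SD from effect-estimate variances and MAFs.

    Under the single-SNP regression approximation,
    ``varbeta ~= sdY**2 / (2 N f (1-f))``, so ``2 N f (1-f)`` regressed on
    ``1/varbeta`` through the origin has slope ``sdY**2``.  Needed when
    quantitative summary statistics are reported on an unstandardised scale.
    """
    vb = np.asarray(varbeta, dtype=float)
    f = np.asarray(maf, dtype=float)
    if vb.shape != f.shape or vb.ndim != 1:
        raise ValueError("varbeta and maf must be 1-d vectors of equal length")
    if vb.shape[0] < 10:
        raise ValueError("at least 10 variants are required to estimate sdY")
    if np.any(vb <= 0):
        raise ValueError("all varbeta must be positive")
    if np.any(f <= 0) or np.any(f > 0.5):
        raise ValueError("all maf must lie in (0, 0.5]")
    oneover = 1.0 / vb
    nvx = 2.0 * N * f * (1.0 - f)
    sdY2 = float(np.dot(oneover, nvx) / np.dot(oneover, oneover))
    if sdY2 <= 0:
        raise ValueError("estimated sdY^2 is nonpositive; inputs are inconsistent")
    return math.sqrt(sdY2)


def log_abf(z, V, W):
    """Log approximate Bayes factor for association against the null.

    ``0.5 * (log(1-r) + r z**2)`` with shrinkage ``r = W/(V+W)``.  Equal to
    the log ratio of the two marginal likelihoods of the observed effect,
    ``N(beta; 0, V+W) / N(beta; 0, V)``.  Returns 0 when ``W == 0``.
    Vectorised over any broadcastable combination of arguments.
    """
    z = np.asarray(z, dtype=float)
    V = np.asarray(V, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(V <= 0):
        raise ValueError("V must be positive")
    if np.any(W < 0):
        raise ValueError("W must be nonnegative")
    r = W / (V + W)
    # log(1-r) formed as log(V) - log(V+W): stays exact when V << W,
    # where 1-r itself underflows in precision
    out = 0.5 * ((np.log(V) - np.log(V + W)) + r * z**2)
    return float(out) if out.ndim == 0 else out


def _effective_prior_sd(spec: TraitSpec, sdY: float | None) -> float:
    # The prior SD is specified on a standardised trait; for quantitative
    # traits on their native scale it is multiplied by sdY.
    if spec.trait_type == "quantitative":
        return spec.W_sqrt * (1.0 if sdY is None else sdY)
    return spec.W_sqrt


def abf_table_from_dataset(dataset, spec: TraitSpec | None = None) -> ABFTable:
    """Compute per-variant log ABFs for one trait's summary statistics.

    Each variant must carry either ``(beta, varbeta)`` — preferred,
    especially for imputed data — or ``(pval, maf)``, in which case the
    z-score comes from the p-value and ``V`` from the MAF/sample-size
    approximation.  Output order matches input order.
    """
    if spec is None:
        spec = dataset.trait_spec
    df = dataset.frame if hasattr(dataset, "frame") else dataset

    n = len(df)
    beta = df["beta"].to_numpy(dtype=float) if "beta" in df else np.full(n, np.nan)
    varbeta = df["varbeta"].to_numpy(dtype=float) if "varbeta" in df else np.full(n, np.nan)
    pval = df["pval"].to_numpy(dtype=float) if "pval" in df else np.full(n, np.nan)
    maf = df["maf"].to_numpy(dtype=float) if "maf" in df else np.full(n, np.nan)
    ids = list(df["variant_id"]) if "variant_id" in df else [str(i) for i in range(n)]

    has_bv = np.isfinite(beta) & np.isfinite(varbeta)
    has_pm = np.isfinite(pval) & np.isfinite(maf)
    bad = ~(has_bv | has_pm)
    if np.any(bad):
        first = ids[int(np.flatnonzero(bad)[0])]
        raise ValueError(
            f"variant {first!r} has neither (beta, varbeta) nor (pval, maf)"
        )

    sdY = spec.sdY
    if spec.trait_type == "quantitative" and sdY is None:
        if np.all(has_bv) and np.isfinite(maf).sum() >= 10 and spec.N is not None:
            ok = has_bv & np.isfinite(maf)
            sdY = estimate_sdY(varbeta[ok], maf[ok], spec.N)
        else:
            warnings.warn(
                "sdY not given for a quantitative trait; assuming a "
                "standardised phenotype (sdY = 1)",
                stacklevel=2,
            )
            sdY = 1.0

    W = _effective_prior_sd(spec, sdY) ** 2

    z = np.empty(n)
    V = np.empty(n)
    if np.any(has_bv):
        z[has_bv] = beta[has_bv] / np.sqrt(varbeta[has_bv])
        V[has_bv] = varbeta[has_bv]
    use_pm = ~has_bv
    if np.any(use_pm):
        if spec.N is None:
            raise ValueError("sample size N is required when only p-values are given")
        spec_for_v = spec if spec.sdY is not None or spec.trait_type != "quantitative" else (
            TraitSpec(spec.trait_type, spec.N, sdY=sdY, W_sqrt=spec.W_sqrt)
        )
        z[use_pm] = z_from_pvalue(pval[use_pm])
        V[use_pm] = approx_var_beta(maf[use_pm], spec_for_v)

    return ABFTable(variant_ids=ids, labf=log_abf(z, V, W))
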