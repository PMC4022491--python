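"""Posterior probabilities for shared vs. distinct causal variants.

Given per-variant log Bayes factors for two traits over the same Q variants
of a region, and assuming at most one causal variant per trait, every causal
"configuration" is a pair (i, j) with i, j in {none, 1..Q}.  The (Q+1)^2
configurations partition into five hypotheses:

    H0  neither trait associated
    H1  trait 1 only
    H2  trait 2 only
    H3  both traits, two distinct causal variants
    H4  both traits, one shared causal variant

Each configuration is weighted by prior * Bayes factor, with per-SNP priors
p1, p2 (single-trait association) and p12 (shared association).  Summing the
weights within each hypothesis class and normalising yields PP0..PP4.  The
sums factorise, so the whole computation is a single linear pass per trait
done in log space; a brute-force enumeration oracle is provided for
verification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

__all__ = [
    "ColocPriors",
    "ColocResult",
    "combine_abf",
    "enumerate_posteriors_oracle",
    "per_snp_h4",
    "sensitivity_p12",
    "coloc_summary_pair",
]

HYPOTHESES = ("PP0", "PP1", "PP2", "PP3", "PP4")


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of association.

    ``p1``/``p2``: probability that a given variant is associated with trait
    1/2 only; ``p12``: probability it is associated with both.  ``p12/p1``
    is the conditional probability that a trait-1-associated variant also
    drives trait 2, so ``p12`` may not exceed ``min(p1, p2)``.
    Defaults: p1 = p2 = 1e-4, p12 = 1e-5 (1 in 100 trait-1 variants shared).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError(
                f"p12 ({self.p12}) must not exceed min(p1, p2) "
                f"({min(self.p1, self.p2)}): it is the prior that a variant "
                "is causal for both traits"
            )
        if self.p1 + self.p2 + self.p12 >= 1.0:
            raise ValueError("p1 + p2 + p12 must be < 1")


@dataclass
class ColocResult:
    """Posterior summary of one colocalisation analysis."""

    nsnps: int
    pp: np.ndarray  # PP0..PP4
    per_snp_h4: np.ndarray
    priors_used: ColocPriors
    variant_ids: list[str] | None = None
    top_shared_variant: str | int | None = field(default=None)

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        self.per_snp_h4 = np.asarray(self.per_snp_h4, dtype=float)
        if self.pp.shape != (5,):
            raise ValueError("pp must contain exactly five probabilities")
        if self.per_snp_h4.shape != (self.nsnps,):
            raise ValueError("per_snp_h4 must have one entry per variant")
        if self.top_shared_variant is None:
            top = int(np.argmax(self.per_snp_h4))
            self.top_shared_variant = (
                self.variant_ids[top] if self.variant_ids is not None else top
            )

    def __getitem__(self, key: str) -> float:
        return float(self.pp[HYPOTHESES.index(key)])

    def to_dict(self) -> dict:
        d = {"nsnps": self.nsnps}
        d.update({h: float(p) for h, p in zip(HYPOTHESES, self.pp)})
        d.update(
            {
                "p1": self.priors_used.p1,
                "p2": self.priors_used.p2,
                "p12": self.priors_used.p12,
                "top_shared_variant": self.top_shared_variant,
            }
        )
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def per_snp_frame(self, labf1=None, labf2=None) -> pd.DataFrame:
        ids = self.variant_ids or list(range(self.nsnps))
        cols = {"variant_id": ids}
        if labf1 is not None:
            cols["labf1"] = np.asarray(labf1, dtype=float)
        if labf2 is not None:
            cols["labf2"] = np.asarray(labf2, dtype=float)
        cols["h4_posterior"] = self.per_snp_h4
        return pd.DataFrame(cols)


def _log_cross_sum(l1: np.ndarray, l2: np.ndarray) -> float:
    """log of sum_{i != j} BF1_i * BF2_j, computed without cancellation.

    Equals log(S1*S2 - S12) but is evaluated as
    LSE_i(l1_i + LSE_{j != i}(l2_j)) using prefix/suffix log-sum-exps, so it
    stays exact even when a single shared signal makes S1*S2 and S12 agree
    to machine precision.  Linear in Q; -inf when Q == 1.
    """
    q = l1.shape[0]
    if q == 1:
        return -np.inf
    acc_fwd = np.logaddexp.accumulate(l2)
    acc_bwd = np.logaddexp.accumulate(l2[::-1])[::-1]
    prefix = np.concatenate(([-np.inf], acc_fwd[:-1]))
    suffix = np.concatenate((acc_bwd[1:], [-np.inf]))
    loo = np.logaddexp(prefix, suffix)  # LSE of l2 excluding entry i
    return float(logsumexp(l1 + loo))


def _as_labf(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.shape[0] == 0:
        raise ValueError(f"{name} must be a nonempty 1-d vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def per_snp_h4(labf1, labf2) -> np.ndarray:
    """Posterior that each variant is the shared causal one, given H4.

    The softmax of ``labf1 + labf2``: the configuration posterior restricted
    to the diagonal (shared-variant) configurations, renormalised.
    """
    l1 = _as_labf(labf1, "labf1")
    l2 = _as_labf(labf2, "labf2")
    if l1.shape != l2.shape:
        raise ValueError("labf1 and labf2 must have the same length")
    return softmax(l1 + l2)


def combine_abf(labf1, labf2, priors: ColocPriors = ColocPriors()) -> ColocResult:
    """Aggregate two traits' log Bayes factors into PP0..PP4.

    With ``S1 = sum_i BF1_i``, ``S2 = sum_j BF2_j`` and
    ``S12 = sum_i BF1_i BF2_i``, the unnormalised hypothesis weights are::

        H0: 1
        H1: p1 * S1
        H2: p2 * S2
        H3: p1 * p2 * (S1 * S2 - S12)
        H4: p12 * S12

    computed in log space with log-sum-exp; H3's cross-term
    ``S1*S2 - S12`` is evaluated by a cancellation-free leave-one-out
    log-sum-exp (see :func:`_log_cross_sum`).  Runtime is linear in the
    number of variants.
    """
    l1 = _as_labf(labf1, "labf1")
    l2 = _as_labf(labf2, "labf2")
    if l1.shape != l2.shape:
        raise ValueError("labf1 and labf2 must have the same length")
    q = l1.shape[0]

    log_s1 = logsumexp(l1)
    log_s2 = logsumexp(l2)
    log_s12 = logsumexp(l1 + l2)

    # no configuration with two distinct variants exists at Q == 1
    log_cross = _log_cross_sum(l1, l2)

    logw = np.array(
        [
            0.0,
            np.log(priors.p1) + log_s1,
            np.log(priors.p2) + log_s2,
            np.log(priors.p1) + np.log(priors.p2) + log_cross,
            np.log(priors.p12) + log_s12,
        ]
    )
    pp = np.exp(logw - logsumexp(logw))

    return ColocResult(
        nsnps=q,
        pp=pp,
        per_snp_h4=per_snp_h4(l1, l2),
        priors_used=priors,
    )


def enumerate_posteriors_oracle(
    labf1, labf2, priors: ColocPriors = ColocPriors()
) -> np.ndarray:
    """PP0..PP4 by explicit enumeration of all (Q+1)^2 configurations.

    Quadratic in Q (capped at Q <= 2000); exists to verify
    :func:`combine_abf` and has no shortcuts in common with it.
    """
    l1 = _as_labf(labf1, "labf1")
    l2 = _as_labf(labf2, "labf2")
    if l1.shape != l2.shape:
        raise ValueError("labf1 and labf2 must have the same length")
    q = l1.shape[0]
    if q > 2000:
        raise ValueError("oracle enumeration is limited to Q <= 2000")

    logw = {h: [] for h in range(5)}
    logw[0].append(0.0)  # baseline configuration: no causal variant
    lp1, lp2, lp12 = np.log(priors.p1), np.log(priors.p2), np.log(priors.p12)
    for i in range(q):
        logw[1].append(lp1 + l1[i])
        logw[2].append(lp2 + l2[i])
    for i in range(q):
        for j in range(q):
            if i == j:
                logw[4].append(lp12 + l1[i] + l2[i])
            else:
                logw[3].append(lp1 + lp2 + l1[i] + l2[j])

    log_h = np.array(
        [logsumexp(logw[h]) if logw[h] else -np.inf for h in range(5)]
    )
    return np.exp(log_h - logsumexp(log_h))


def sensitivity_p12(
    labf1,
    labf2,
    p12_grid,
    p1: float = 1e-4,
    p2: float = 1e-4,
) -> pd.DataFrame:
    """Recompute PP0..PP4 across a grid of shared-association priors p12.

    Returns one row per grid value; PP4 is nondecreasing in p12 for fixed
    data.  Each grid value must satisfy the prior invariants (in particular
    ``p12 <= min(p1, p2)``).
    """
    rows = []
    for p12 in p12_grid:
        try:
            priors = ColocPriors(p1=p1, p2=p2, p12=float(p12))
        except ValueError as exc:
            raise ValueError(f"invalid p12 grid value {p12!r}: {exc}") from exc
        res = combine_abf(labf1, labf2, priors)
        rows.append({"p12": float(p12), **{h: res[h] for h in HYPOTHESES}})
    return pd.DataFrame(rows)


def coloc_summary_pair(
    d1,
    d2,
    priors: ColocPriors = ColocPriors(),
    min_maf: float = 0.001,
    min_rsq: float = 0.3,
    exclude_variants=None,
) -> ColocResult:
    """End-to-end colocalisation test for two summary-statistics datasets.

    Harmonises the pair (intersection of variant ids, MAF/Rsq filters),
    computes each trait's ABF table, and combines them.  Runtime is linear
    in the number of shared variants.
    """
    from .abf import abf_table_from_dataset
    from .summaries import harmonize_pair

    pair = harmonize_pair(
        d1, d2, min_maf=min_maf, min_rsq=min_rsq, exclude_variants=exclude_variants
    )
    t1 = abf_table_from_dataset(pair.dataset1)
    t2 = abf_table_from_dataset(pair.dataset2)
    res = combine_abf(t1.labf, t2.labf, priors)
    res.variant_ids = list(t1.variant_ids)
    res.top_shared_variant = res.variant_ids[int(np.argmax(res.per_snp_h4))]
    return res
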