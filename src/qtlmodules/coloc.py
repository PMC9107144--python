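"""Bayesian colocalization of two traits from per-variant summary statistics.

Under the single-causal-variant assumption, each variant's evidence for
association with a trait is a Wakefield approximate Bayes factor computed
from (beta, se) and a prior effect SD.  Region-level posteriors over the
five hypotheses

  H0 no causal variant; H1/H2 causal for one trait only;
  H3 two distinct causal variants; H4 one shared causal variant

follow from per-variant priors p1, p2 (one-trait causal) and p12 (shared).
All sums are accumulated in log space so |z| up to ~50 is safe.  A
brute-force causal-configuration enumerator is provided as an independent
oracle for small regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .containers import SummaryStatSet
from .errors import InputError

logger = logging.getLogger(__name__)

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class ColocPriors:
    """Per-variant prior probabilities of causality."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def validate(self, n_variants: int) -> None:
        if not (0 <= self.p12 and 0 < self.p1 < 1 and 0 < self.p2 < 1):
            raise InputError("priors must satisfy 0 < p1, p2 < 1 and p12 >= 0")
        if self.p12 > min(self.p1, self.p2):
            raise InputError("p12 must not exceed p1 or p2")
        if n_variants * (self.p1 + self.p2 + self.p12) > 1:
            raise InputError("per-region prior mass exceeds 1; shrink priors or region")


@dataclass
class ColocResult:
    """Posterior probabilities over H0..H4 for one region."""

    pp: np.ndarray  # length 5, sums to 1
    n_variants: int
    log_abf_1: np.ndarray = field(repr=False)
    log_abf_2: np.ndarray = field(repr=False)
    priors: ColocPriors = field(default_factory=ColocPriors)
    h4_threshold: float = 0.9

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])

    @property
    def h4_call(self) -> bool:
        """Decision flag: PP.H4 above the shared-causal-variant threshold."""
        return self.pp_h4 > self.h4_threshold

    def as_dict(self) -> dict[str, float]:
        return {f"pp_{h}": float(v) for h, v in zip(HYPOTHESES, self.pp)}


def log_abf(beta, se, prior_sd: float = 0.15):
    """Wakefield log approximate Bayes factor for association versus null.

    With V = se^2, W = prior_sd^2, r = W/(V+W) and z = beta/se:
    log ABF = 0.5*[log(1 - r) + z^2 * r].
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise InputError("standard errors must be positive")
    if prior_sd <= 0:
        raise InputError("prior effect SD must be positive")
    V = se**2
    W = prior_sd**2
    r = W / (V + W)
    z = beta / se
    return 0.5 * (np.log1p(-r) + z * z * r)


def _aligned_abfs(
    stats1: SummaryStatSet,
    stats2: SummaryStatSet,
    prior_sd1: float,
    prior_sd2: float,
):
    """Intersect on variant_id, align trait-2 effect alleles to trait 1 and
    return the two log-ABF vectors plus the shared variant list."""
    t1 = stats1.table.set_index("variant_id")
    t2 = stats2.table.set_index("variant_id")
    shared = [v for v in t1.index if v in t2.index]
    if not shared:
        raise InputError("no shared variants between the two traits")
    t1 = t1.loc[shared]
    t2 = t2.loc[shared]
    beta2 = t2["beta"].to_numpy(dtype=float).copy()
    has_alleles = {"effect_allele", "other_allele"} <= set(t1.columns) and {
        "effect_allele",
        "other_allele",
    } <= set(t2.columns)
    if has_alleles:
        keep = np.ones(len(shared), dtype=bool)
        for i, vid in enumerate(shared):
            e1, o1 = t1.loc[vid, "effect_allele"], t1.loc[vid, "other_allele"]
            e2, o2 = t2.loc[vid, "effect_allele"], t2.loc[vid, "other_allele"]
            if frozenset((e1, o1)) in AMBIGUOUS_PAIRS:
                keep[i] = False
                logger.warning("dropping strand-ambiguous variant %s", vid)
            elif (e1, o1) == (e2, o2):
                continue
            elif (e1, o1) == (o2, e2):
                beta2[i] = -beta2[i]
            else:
                raise InputError(f"unresolvable allele mismatch at {vid}")
        shared = [v for v, k in zip(shared, keep) if k]
        if not shared:
            raise InputError("no shared variants left after allele filtering")
        t1, t2, beta2 = t1.loc[shared], t2.loc[shared], beta2[keep]
    l1 = log_abf(t1["beta"].to_numpy(dtype=float), t1["se"].to_numpy(dtype=float), prior_sd1)
    l2 = log_abf(beta2, t2["se"].to_numpy(dtype=float), prior_sd2)
    return l1, l2, shared


def coloc_region(
    stats1: SummaryStatSet,
    stats2: SummaryStatSet,
    priors: ColocPriors | None = None,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
    h4_threshold: float = 0.9,
) -> ColocResult:
    """Posterior hypothesis probabilities for a region shared by two traits.

    Unnormalized hypothesis weights over shared variants i, j:
      S0 = 1
      S1 = p1 * sum_i exp(l1_i)
      S2 = p2 * sum_j exp(l2_j)
      S3 = p1*p2 * sum_{i != j} exp(l1_i + l2_j)
      S4 = p12 * sum_i exp(l1_i + l2_i)
    """
    priors = priors or ColocPriors()
    l1, l2, shared = _aligned_abfs(stats1, stats2, prior_sd1, prior_sd2)
    priors.validate(len(shared))
    log_s1 = np.log(priors.p1) + logsumexp(l1)
    log_s2 = np.log(priors.p2) + logsumexp(l2)
    log_s4 = (np.log(priors.p12) + logsumexp(l1 + l2)) if priors.p12 > 0 else -np.inf
    # sum_{i != j} = (sum_i)(sum_j) - sum_i(diagonal), all in log space
    log_cross = logsumexp(l1) + logsumexp(l2)
    log_diag = logsumexp(l1 + l2)
    n_shared = len(shared)
    if n_shared == 1:
        log_s3 = -np.inf
    elif n_shared <= 2048:
        # exact off-diagonal sum; the difference form log_cross +
        # log1p(-exp(log_diag - log_cross)) cancels catastrophically when a
        # single variant dominates both traits
        outer = l1[:, None] + l2[None, :]
        np.fill_diagonal(outer, -np.inf)
        log_s3 = np.log(priors.p1) + np.log(priors.p2) + logsumexp(outer)
    else:
        delta = min(log_diag - log_cross, -1e-16)  # <= 0 mathematically
        log_s3 = np.log(priors.p1) + np.log(priors.p2) + log_cross + np.log1p(-np.exp(delta))
    log_s = np.array([0.0, log_s1, log_s2, log_s3, log_s4])
    pp = np.exp(log_s - logsumexp(log_s))
    pp = pp / pp.sum()
    return ColocResult(
        pp=pp,
        n_variants=len(shared),
        log_abf_1=l1,
        log_abf_2=l2,
        priors=priors,
        h4_threshold=h4_threshold,
    )


def enumerate_oracle(
    stats1: SummaryStatSet,
    stats2: SummaryStatSet,
    priors: ColocPriors | None = None,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
    max_variants: int = 12,
) -> ColocResult:
    """Explicit enumeration of every causal configuration (validation path).

    Configurations: none; causal i for trait 1 only; causal j for trait 2
    only; ordered pairs (i, j), i != j; shared causal i.  Each contributes
    prior weight x likelihood ratio; posteriors are the normalized
    per-hypothesis totals.  Must agree with :func:`coloc_region`.
    """
    priors = priors or ColocPriors()
    l1, l2, shared = _aligned_abfs(stats1, stats2, prior_sd1, prior_sd2)
    n = len(shared)
    if n > max_variants:
        raise InputError(f"enumeration oracle limited to {max_variants} variants")
    priors.validate(n)
    logs: dict[str, list[float]] = {h: [] for h in HYPOTHESES}
    logs["H0"].append(0.0)
    for i in range(n):
        logs["H1"].append(np.log(priors.p1) + l1[i])
        logs["H2"].append(np.log(priors.p2) + l2[i])
        if priors.p12 > 0:
            logs["H4"].append(np.log(priors.p12) + l1[i] + l2[i])
        for j in range(n):
            if i != j:
                logs["H3"].append(np.log(priors.p1) + np.log(priors.p2) + l1[i] + l2[j])
    log_s = np.array(
        [logsumexp(logs[h]) if logs[h] else -np.inf for h in HYPOTHESES]
    )
    pp = np.exp(log_s - logsumexp(log_s))
    pp = pp / pp.sum()
    return ColocResult(
        pp=pp, n_variants=n, log_abf_1=l1, log_abf_2=l2, priors=priors
    )
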