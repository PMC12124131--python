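"""Stratified exact meta-analysis, genomic inflation, and power analysis.

Exact Cochran-Mantel-Haenszel (CMH) test
----------------------------------------
For K strata of 2x2 carrier-by-status tables, conditioning on every
stratum's margins makes each ``a_i`` cell an independent central
hypergeometric variable.  The test statistic is ``S = sum_i a_i`` and its
null distribution is the convolution of the K hypergeometric distributions,
computed here by dynamic programming in log space (supports are small for
rare carriers, so the convolution is cheap even at biobank scale).  The
two-sided p-value uses the same point-probability criterion as the Fisher
test: all values ``s`` with ``P(S = s) <= P(S = s_obs) * (1 + 1e-7)``
contribute.  The common odds ratio is the Mantel-Haenszel estimate with a
Robins-Breslow-Greenland (RBG) variance for its confidence interval.

Genomic inflation (lambda_GC)
-----------------------------
Observed and empirical-null p-values (the latter from a single "n-of-1"
permutation of case-control labels) are transformed to chi-square(1)
quantiles; lambda is the ratio of the medians.  A well-calibrated analysis
gives lambda close to 1.

Power analysis
--------------
Carrier status is modelled as one Bernoulli draw per person with control
carrier probability ``q0 = 2*CAF*(1-CAF)`` (Hardy-Weinberg for a rare
allele); the case carrier probability is obtained by scaling the odds by the
carrier odds ratio.  Power at a design point is the Monte-Carlo fraction of
replicates whose two-sided Fisher test reaches the significance level, and
the smallest cohort reaching a target power is found by bisection with
common random numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2

from .stats import ContingencyTable, fisher_two_sided, _log_support, _REL_TOL, _Z_95


@dataclass
class StratifiedTables:
    """A labelled collection of per-stratum 2x2 tables."""

    strata: list[tuple[str, ContingencyTable]]

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("at least one stratum is required")

    def labels(self) -> list[str]:
        return [lab for lab, _ in self.strata]

    def tables(self) -> list[ContingencyTable]:
        return [t for _, t in self.strata]


@dataclass
class LambdaEstimate:
    lambda_gc: float
    n_units: int
    seed: int | None = None


@dataclass
class PowerSpec:
    """Design point for the rare-variant Fisher power simulation."""

    caf: float
    or_: float
    alpha: float = 0.05
    power_target: float = 0.80
    case_control_ratio: float = 1.0
    reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.caf < 0.5:
            raise ValueError("caf must lie in (0, 0.5)")
        if self.or_ <= 0:
            raise ValueError("or_ must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power_target < 1:
            raise ValueError("power_target must lie in (0, 1)")
        if self.case_control_ratio <= 0 or self.reps < 1:
            raise ValueError("invalid case_control_ratio or reps")


def cmh_exact(
    s: StratifiedTables,
    conf: float = 0.95,
    two_sided: str = "point-probability",
) -> tuple[float, float, tuple[float, float]]:
    """Exact stratified CMH test with MH common odds ratio and RBG CI.

    Strata with an empty margin carry no conditional information and are
    dropped with a warning.  ``two_sided`` selects the two-sided rule:
    ``"point-probability"`` (default, consistent with the Fisher test here)
    or ``"double-tail"`` (twice the smaller tail, capped at 1).
    """
    if two_sided not in ("point-probability", "double-tail"):
        raise ValueError(f"unknown two-sided rule {two_sided!r}")
    kept: list[ContingencyTable] = []
    for label, t in s.strata:
        if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
            warnings.warn(f"stratum {label!r} has an empty margin; dropped")
            continue
        kept.append(t)
    if not kept:
        raise ValueError("no stratum with positive margins")

    # Convolve the conditional null distributions of the a-cells.
    offset = 0
    log_dist = np.array([0.0])
    for t in kept:
        support, logp = _log_support(t)
        offset += int(support[0])
        new = np.full(len(log_dist) + len(logp) - 1, -np.inf)
        for j, lp in enumerate(logp):
            seg = new[j : j + len(log_dist)]
            np.logaddexp(seg, log_dist + lp, out=seg)
        log_dist = new
    s_obs = sum(t.a for t in kept)
    idx = s_obs - offset
    if two_sided == "point-probability":
        keep = log_dist <= log_dist[idx] + np.log1p(_REL_TOL)
        p = float(min(1.0, np.exp(logsumexp(log_dist[keep]))))
    else:
        lower = float(np.exp(logsumexp(log_dist[: idx + 1])))
        upper = float(np.exp(logsumexp(log_dist[idx:])))
        p = float(min(1.0, 2.0 * min(lower, upper)))

    or_mh, ci = _mantel_haenszel_or(kept, conf)
    return p, or_mh, ci


def _mantel_haenszel_or(
    tables: list[ContingencyTable], conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """MH common odds ratio with the Robins-Breslow-Greenland variance."""
    R = sum(t.a * t.d / t.n for t in tables)
    S = sum(t.b * t.c / t.n for t in tables)
    if S == 0.0 or R == 0.0:
        # degenerate concordant-zero cells: estimate at the boundary
        or_mh = np.inf if S == 0.0 else 0.0
        return float(or_mh), (float("nan"), float("nan"))
    or_mh = R / S
    # RBG variance of log(OR_MH).
    num1 = sum((t.a + t.d) / t.n * (t.a * t.d / t.n) for t in tables)
    num2 = sum(
        ((t.a + t.d) / t.n * (t.b * t.c / t.n) + (t.b + t.c) / t.n * (t.a * t.d / t.n))
        for t in tables
    )
    num3 = sum((t.b + t.c) / t.n * (t.b * t.c / t.n) for t in tables)
    var = num1 / (2 * R * R) + num2 / (2 * R * S) + num3 / (2 * S * S)
    if conf == 0.95:
        z = _Z_95
    else:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + conf / 2.0))
    half = z * np.sqrt(var)
    log_or = np.log(or_mh)
    return float(or_mh), (float(np.exp(log_or - half)), float(np.exp(log_or + half)))


def estimate_lambda(
    p_observed, p_null, seed: int | None = None
) -> LambdaEstimate:
    """Genomic inflation factor against an empirical permutation null.

    Each p-value is mapped to the chi-square(1) quantile ``q = F^-1(1 - p)``
    (so p = 1 maps to q = 0) and lambda is ``median(q_obs)/median(q_null)``.
    """
    p_obs = np.asarray(p_observed, dtype=float)
    p_nul = np.asarray(p_null, dtype=float)
    if p_obs.size == 0 or p_nul.size == 0:
        raise ValueError("p-value lists must be non-empty")
    if p_obs.size != p_nul.size:
        raise ValueError("observed and null lists must have equal length")
    q_obs = chi2.isf(p_obs, df=1)
    q_nul = chi2.isf(p_nul, df=1)
    med_null = float(np.median(q_nul))
    if med_null == 0.0:
        raise ValueError("null median chi-square quantile is zero; lambda undefined")
    return LambdaEstimate(
        lambda_gc=float(np.median(q_obs)) / med_null,
        n_units=int(p_obs.size),
        seed=seed,
    )


def permute_and_refit(samples, analysis, seed: int):
    """Run an analysis once under a single permutation of case-control labels.

    ``samples`` is a DataFrame with a ``phenotype`` column ("case"/"control");
    ``analysis`` is a closure mapping a phenotype Series (indexed like
    ``samples``) to a Series of unit-level p-values.  The returned p-values
    form the empirical null of the n-of-1 permutation procedure.
    """
    rng = np.random.default_rng(seed)
    permuted = samples["phenotype"].to_numpy().copy()
    rng.shuffle(permuted)
    import pandas as pd

    return analysis(pd.Series(permuted, index=samples.index, name="phenotype"))


def power_fisher(
    spec: PowerSpec, n_total: int, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Monte-Carlo power of the two-sided Fisher test at a design point.

    Returns ``(power, mc_se)``.  Cohort sizes follow ``case_control_ratio``
    (cases:controls); carrier counts are binomial under the HWE diplotype
    model described in the module docstring.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_case = int(round(n_total / (1.0 + 1.0 / spec.case_control_ratio)))
    n_ctrl = n_total - n_case
    if n_case < 1 or n_ctrl < 1:
        raise ValueError("n_total too small for the requested ratio")
    q0 = 2.0 * spec.caf * (1.0 - spec.caf)
    odds1 = spec.or_ * q0 / (1.0 - q0)
    q1 = odds1 / (1.0 + odds1)
    a = rng.binomial(n_case, q1, size=spec.reps)
    c = rng.binomial(n_ctrl, q0, size=spec.reps)
    hits = 0
    for ai, ci in zip(a, c):
        if ai + ci == 0:
            continue  # no carriers at all: p = 1 by convention
        p = fisher_two_sided(ContingencyTable(int(ai), n_case - int(ai), int(ci), n_ctrl - int(ci)))
        if p <= spec.alpha:
            hits += 1
    power = hits / spec.reps
    mc_se = float(np.sqrt(power * (1.0 - power) / spec.reps))
    return power, mc_se


def required_n(
    spec: PowerSpec, n_low: int = 100, n_high: int = 2_000_000
) -> tuple[int, float]:
    """Smallest total cohort size reaching the target power, by bisection.

    Uses common random numbers (the generator is re-seeded identically at
    every candidate size) so the estimated power curve is near-monotone in
    ``n_total`` and bisection is well behaved.  Returns ``(n, power_at_n)``.
    """

    def power_at(n: int) -> float:
        return power_fisher(spec, n, rng=np.random.default_rng(spec.seed))[0]

    if power_at(n_high) < spec.power_target:
        raise RuntimeError(
            f"power target {spec.power_target} not reached by n_total={n_high}"
        )
    lo, hi = n_low, n_high
    while hi - lo > max(2, int(0.005 * hi)):
        mid = (lo + hi) // 2
        if power_at(mid) >= spec.power_target:
            hi = mid
        else:
            lo = mid
    return hi, power_at(hi)
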