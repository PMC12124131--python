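"""Exact 2x2 association statistics for carrier-by-status tables.

The gene-level collapsing framework reduces every gene x QV-model analysis to
a 2x2 contingency table of qualifying-variant carriers versus non-carriers in
cases and controls.  This module provides the exact statistics applied to
those tables:

* a two-sided Fisher exact test using the point-probability criterion (every
  table with the same margins whose hypergeometric probability does not
  exceed the observed one, up to a relative tolerance of 1e-7, contributes to
  the p-value -- the convention of R ``fisher.test``),
* the sample odds ratio with a Woolf (log-OR normal approximation) confidence
  interval, falling back to a Haldane-Anscombe correction (add 1 to all four
  cells) when any cell is zero,
* a leave-one-out influence analysis ranking qualifying sites by how much the
  association degrades when each is removed.

All probability sums are performed in log space so that cohort-scale counts
(hundreds of thousands of controls) do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

# Relative tolerance of the two-sided point-probability criterion, matching
# the convention of standard exact-test implementations.
_REL_TOL = 1e-7

#: z quantile for 95% Woolf confidence intervals.
_Z_95 = 1.95996


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier-by-status 2x2 counts.

    ``a`` case carriers, ``b`` case non-carriers, ``c`` control carriers,
    ``d`` control non-carriers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_case(self) -> int:
        return self.a + self.b

    @property
    def n_control(self) -> int:
        return self.c + self.d

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class AssociationResult:
    """Result of one unit-level (gene or variant) association test."""

    unit: str
    model: str
    p: float
    or_: float
    ci_low: float
    ci_high: float
    corrected: bool
    counts: ContingencyTable


def _log_support(t: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Support of the ``a`` cell under fixed margins, with log-probabilities.

    Conditioning on both margins, ``a`` follows a central hypergeometric
    distribution: drawing ``a + c`` carriers from ``n`` individuals of whom
    ``a + b`` are cases.
    """
    r1, c1, n = t.a + t.b, t.a + t.c, t.n
    lo = max(0, c1 - (t.c + t.d))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = hypergeom.logpmf(support, n, r1, c1)
    return support, logp


def fisher_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact test p-value by the point-probability rule.

    Sums hypergeometric point probabilities over all tables with the observed
    margins whose probability is at most the observed table's probability
    times ``1 + 1e-7``.

    Raises ``ValueError`` when a margin is empty (the conditional
    distribution, and hence the p-value, is undefined).
    """
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        raise ValueError("Fisher test undefined for a table with an empty margin")
    support, logp = _log_support(t)
    log_obs = logp[np.searchsorted(support, t.a)]
    keep = logp <= log_obs + np.log1p(_REL_TOL)
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def odds_ratio_ci(
    t: ContingencyTable, conf: float = 0.95
) -> tuple[float, float, float, bool]:
    """Sample odds ratio with a Woolf confidence interval.

    If any cell is zero the table is Haldane-Anscombe corrected (one added to
    every cell) before computing both the odds ratio and the interval, and
    the ``corrected`` flag is returned as True.  P-values are never computed
    on corrected tables; the correction affects effect-size reporting only.
    """
    corrected = 0 in t.as_tuple()
    u = (
        ContingencyTable(t.a + 1, t.b + 1, t.c + 1, t.d + 1) if corrected else t
    )
    or_ = (u.a * u.d) / (u.b * u.c)
    if conf == 0.95:
        z = _Z_95
    else:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + conf / 2.0))
    se = np.sqrt(1 / u.a + 1 / u.b + 1 / u.c + 1 / u.d)
    log_or = np.log(or_)
    return (
        float(or_),
        float(np.exp(log_or - z * se)),
        float(np.exp(log_or + z * se)),
        corrected,
    )


def carrier_frequency(k: int, n: int) -> float:
    """Carrier frequency as a percentage; summaries print it at 2 s.f."""
    if n <= 0:
        raise ValueError("total must be positive")
    if not 0 <= k <= n:
        raise ValueError("carrier count must lie in [0, total]")
    return 100.0 * k / n


def leave_one_out(
    site_carriers: Mapping[str, tuple[Iterable[str], Iterable[str]]],
    n_case: int,
    n_control: int,
) -> list[tuple[str, float]]:
    """Rank qualifying sites by influence on the gene-level association.

    ``site_carriers`` maps each qualifying variant key to the pair
    ``(case carrier ids, control carrier ids)`` it contributes.  For each
    site the carrier sets are rebuilt without it and the Fisher test is
    recomputed; the site whose removal weakens the association the most
    (largest p-value without it) ranks first.  Ties are broken by variant key
    for determinism.
    """
    if not site_carriers:
        raise ValueError("leave-one-out requires at least one qualifying site")
    keys = sorted(site_carriers)
    case_sets = {k: frozenset(site_carriers[k][0]) for k in keys}
    ctrl_sets = {k: frozenset(site_carriers[k][1]) for k in keys}
    out: list[tuple[str, float]] = []
    for drop in keys:
        cases: set[str] = set()
        ctrls: set[str] = set()
        for k in keys:
            if k != drop:
                cases |= case_sets[k]
                ctrls |= ctrl_sets[k]
        a, c = len(cases), len(ctrls)
        table = ContingencyTable(a, n_case - a, c, n_control - c)
        if min(a + c, table.b + table.d) == 0:
            p = 1.0
        else:
            p = fisher_two_sided(table)
        out.append((drop, p))
    out.sort(key=lambda kp: (-kp[1], kp[0]))
    return out


def format_p(p: float) -> str:
    """Scientific notation at 3 significant figures, report style."""
    return f"{p:.2e}"


def format_or_ci(or_: float, ci_low: float, ci_high: float) -> str:
    return f"{or_:.2f} [{ci_low:.2f}, {ci_high:.2f}]"
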