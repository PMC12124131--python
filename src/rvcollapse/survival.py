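"""Age-of-onset comparisons: log-rank tests and onset summaries.

The log-rank machinery comes from lifelines; this module adapts it to the
cohort tables used here (onset/censor times plus event flags per genetic
subset) and returns the chi-square statistic and p-value in the package's
``SurvivalResult`` form.  Kaplan-Meier curve coordinates are exposed for
plotting by the caller.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .firth import SurvivalResult


def logrank(groups: dict[str, tuple]) -> SurvivalResult:
    """Log-rank test across two or more groups.

    ``groups`` maps a label to ``(times, events)`` with boolean/0-1 event
    flags (True = diagnosed, False = censored).  Requires at least two
    groups and at least one event overall.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    times, events, labels = [], [], []
    for label, (t, e) in groups.items():
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        times.append(t)
        events.append(e)
        labels.extend([label] * len(t))
    times = np.concatenate(times)
    events = np.concatenate(events)
    if events.sum() == 0:
        raise ValueError("log-rank test undefined with no events")
    res = multivariate_logrank_test(times, labels, events)
    return SurvivalResult(
        hr=float("nan"),
        ci=(float("nan"), float("nan")),
        p=float(res.p_value),
        statistic=float(res.test_statistic),
        n_events=int(events.sum()),
    )


def onset_summary(ages) -> tuple[float, tuple[float, float]]:
    """Median and interquartile range (linear interpolation)."""
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("onset_summary requires at least one age")
    q25, med, q75 = np.percentile(ages, [25, 50, 75])
    return float(med), (float(q25), float(q75))


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier survival-curve coordinates (time, survival)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=bool))
    sf = kmf.survival_function_.reset_index()
    sf.columns = ["time", "survival"]
    return sf
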