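"""Cohort-construction procedures: sex rebalancing and carrier exclusion.

``rebalance_controls`` removes randomly chosen female controls until the
control male:female odds match the case odds, but only when a Fisher test
first finds a significant sex-by-status imbalance -- the step used to
prevent sex from confounding downstream carrier tests.

``exclude_flagged_carriers`` removes every participant carrying at least one
variant in any of the supplied per-criterion flag sets (e.g. ClinVar
pathogenic, marginal single-variant associations, and permissive collapsing
models for two established disease genes), so the remaining association can
be attributed to the gene under study alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import ContingencyTable, fisher_two_sided


def rebalance_controls(
    samples: pd.DataFrame, seed: int, alpha: float = 0.05
) -> pd.DataFrame:
    """Downsample female controls to match the case male:female odds.

    Returns the retained samples (all cases, all male controls, and the
    pseudo-randomly chosen female controls).  Identity when the sex-by-status
    Fisher test is not significant at ``alpha``.
    """
    cases = samples[samples["phenotype"] == "case"]
    ctrls = samples[samples["phenotype"] == "control"]
    cm = int((cases["sex"] == "male").sum())
    cf = int((cases["sex"] == "female").sum())
    km = int((ctrls["sex"] == "male").sum())
    kf = int((ctrls["sex"] == "female").sum())
    if cm > 0 and km == 0:
        raise ValueError("cannot match case sex odds: no male controls available")
    p = fisher_two_sided(ContingencyTable(cm, cf, km, kf))
    if p >= alpha:
        return samples
    if cm == 0:
        raise ValueError("cannot match sex odds: no male cases")
    target_f = int(round(km * cf / cm))
    if target_f >= kf:
        return samples
    rng = np.random.default_rng(seed)
    female_ids = ctrls.loc[ctrls["sex"] == "female", "sample_id"].to_numpy()
    keep_f = set(rng.choice(female_ids, size=target_f, replace=False))
    keep = (
        (samples["phenotype"] == "case")
        | (samples["sex"] == "male")
        | samples["sample_id"].isin(keep_f)
    )
    return samples[keep]


def exclude_flagged_carriers(
    samples: pd.DataFrame,
    calls: pd.DataFrame,
    flag_sets: dict[str, set[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove samples carrying any variant in the union of flag criteria.

    ``flag_sets`` maps a criterion name to a set of variant keys.  Returns
    ``(reduced samples, report)`` where the report counts removals per
    phenotype and per criterion.
    """
    flagged_keys = set().union(*flag_sets.values()) if flag_sets else set()
    if flagged_keys and len(calls):
        carriers = set(
            calls.loc[
                calls["variant_key"].isin(flagged_keys)
                & (calls["zygosity"] != "missing"),
                "sample_id",
            ]
        )
    else:
        carriers = set()
    removed = samples[samples["sample_id"].isin(carriers)]
    rows = []
    for crit, keys in flag_sets.items():
        crit_carriers = set(
            calls.loc[calls["variant_key"].isin(keys), "sample_id"]
        ) if len(calls) else set()
        sub = samples[samples["sample_id"].isin(crit_carriers)]
        rows.append(
            {
                "criterion": crit,
                "cases_removed": int((sub["phenotype"] == "case").sum()),
                "controls_removed": int((sub["phenotype"] == "control").sum()),
            }
        )
    rows.append(
        {
            "criterion": "any",
            "cases_removed": int((removed["phenotype"] == "case").sum()),
            "controls_removed": int((removed["phenotype"] == "control").sum()),
        }
    )
    report = pd.DataFrame(rows, columns=["criterion", "cases_removed", "controls_removed"])
    return samples[~samples["sample_id"].isin(carriers)], report
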