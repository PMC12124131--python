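"""Age-of-onset characterisation of effect-gene carriers.

On the simulated cohort from 02: onset summaries (median, IQR), a log-rank
comparison of carrier versus non-carrier cases, a Firth Cox model of sex,
and the Firth logistic sensitivity model with sex, age, principal components
and exome-wide PTV burden as covariates.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rvcollapse import io
from rvcollapse.firth import cox_firth, firth_logistic
from rvcollapse.survival import logrank, onset_summary

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORT = ROOT / "cohort"


def main() -> None:
    samples = io.read_samples_tsv(COHORT / "samples.tsv")
    sites = io.read_sites_tsv(COHORT / "sites.tsv")
    calls = io.read_calls_tsv(COHORT / "calls.tsv")
    ptv_keys = set(
        sites.loc[(sites["gene"] == "GENE0001") & (sites["class"] == "ptv"), "variant_key"]
    )
    carrier_ids = set(calls.loc[calls["variant_key"].isin(ptv_keys), "sample_id"])
    cases = samples[samples["phenotype"] == "case"]
    carrier = cases["sample_id"].isin(carrier_ids)

    med, (q25, q75) = onset_summary(cases["age_at_event"])
    print(f"median age at diagnosis (all cases): {med:.0f} (IQR {q25:.0f}-{q75:.0f})")
    if carrier.sum() >= 2:
        res = logrank({
            "carrier": (cases.loc[carrier, "age_at_event"],
                        cases.loc[carrier, "event"] == "diagnosed"),
            "non-carrier": (cases.loc[~carrier, "age_at_event"],
                            cases.loc[~carrier, "event"] == "diagnosed"),
        })
        print(f"log-rank carrier vs non-carrier cases: chi2={res.statistic:.2f}, p={res.p:.3f}")

    # sex as an age-of-onset predictor among carriers (cases + controls)
    carriers_all = samples[samples["sample_id"].isin(carrier_ids)]
    if len(carriers_all) >= 10 and (carriers_all["event"] == "diagnosed").any():
        x = (carriers_all["sex"] == "male").astype(float).to_numpy()
        fit, summary = cox_firth(
            carriers_all["age_at_event"].to_numpy(),
            (carriers_all["event"] == "diagnosed").to_numpy(),
            x[:, None],
        )
        print(f"Firth Cox, sex among {len(carriers_all)} carriers: "
              f"HR={summary.hr:.2f} [{summary.ci[0]:.2f}, {summary.ci[1]:.2f}], p={summary.p:.2f}")

    # Firth logistic sensitivity model for the carrier effect
    y = (samples["phenotype"] == "case").astype(int).to_numpy()
    X = pd.DataFrame({
        "carrier": samples["sample_id"].isin(carrier_ids).astype(float).to_numpy(),
        "sex_male": (samples["sex"] == "male").astype(float).to_numpy(),
        "age": samples["age_at_recruitment"].to_numpy(),
        "pc1": samples["pc1"], "pc2": samples["pc2"],
        "pc3": samples["pc3"], "pc4": samples["pc4"],
        "ptv_burden": samples["ptv_burden"].astype(float).to_numpy(),
    })
    fit = firth_logistic(y, X)
    or_ = float(np.exp(fit.coefficients["carrier"]))
    lo, hi = float(np.exp(fit.ci_low["carrier"])), float(np.exp(fit.ci_high["carrier"]))
    print(f"Firth logistic sensitivity: carrier OR={or_:.2f} [{lo:.2f}, {hi:.2f}], "
          f"p={fit.p['carrier']:.2e}")
    OUT = ROOT / "onset_summary.tsv"
    pd.DataFrame([{
        "median_onset": med, "iqr_low": q25, "iqr_high": q75,
        "carrier_or_firth": or_, "ci_low": lo, "ci_high": hi,
        "p_firth": fit.p["carrier"],
    }]).to_csv(OUT, sep="\t", index=False)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
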