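"""Generate the example synthetic cohort used by the downstream scripts.

One strong PTV effect gene (GENE0001, carrier OR 10) among null genes, with
QC-metric noise so every filter is exercised.  Writes samples/sites/calls/
reference TSVs plus a BED whitelist under ``results/cohort``.
"""

from pathlib import Path

from rvcollapse import io
from rvcollapse.simulate import SimulationConfig, generate_reference, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 2025


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(
        n_cases=1000,
        n_controls=10000,
        n_genes=40,
        cumulative_ptv_allele_freq=1e-3,
        gene_effects={"GENE0001": 10.0},
        seed=SEED,
    )
    samples, sites, calls = simulate_cohort(config)
    reference = generate_reference(sites, seed=SEED + 1)
    io.write_samples_tsv(samples, OUT / "samples.tsv")
    io.write_sites_tsv(sites, OUT / "sites.tsv")
    io.write_calls_tsv(calls, OUT / "calls.tsv")
    io.write_reference_tsv(reference, OUT / "reference.tsv")
    io.write_bed(sites, OUT / "regions.bed")
    n_case_carriers = len(
        set(calls[calls["variant_key"].isin(
            sites.loc[(sites["gene"] == "GENE0001") & (sites["class"] == "ptv"),
                      "variant_key"])]["sample_id"])
        & set(samples.loc[samples["phenotype"] == "case", "sample_id"])
    )
    print(f"cohort: {len(samples)} samples, {len(sites)} sites, {len(calls)} calls")
    print(f"effect gene GENE0001 has {n_case_carriers} case PTV carriers")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
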