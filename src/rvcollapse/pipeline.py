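"""End-to-end orchestration: discovery, replication, reporting.

``run_discovery`` performs the full gene-level collapsing battery (all
configured QV models, with the synonymous model as the empirical negative
control), the variant-level ExWAS, and the n-of-1 permutation inflation
estimate, writing deterministic TSVs plus a run-metadata sidecar.
``run_replication`` re-tests discovery hits in an independent cohort and
combines evidence with the exact stratified CMH test.

All randomness flows from a single root seed split per stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exwas import dosage_matrix, run_exwas
from .meta import StratifiedTables, cmh_exact, estimate_lambda
from .models import (
    DEFAULT_MODELS,
    QVModel,
    collect_gene_carriers,
    carrier_table,
    qualifying_sites,
)
from .qc import VariantSite, apply_genotype_qc, qc_external, qc_site
from .stats import ContingencyTable, fisher_two_sided, odds_ratio_ci


@dataclass
class RunConfig:
    """Run-level configuration; thresholds must be strictly descending."""

    models: tuple[str, ...] = ("ptv", "flexnonsynmtr", "flexdmg", "syn")
    p_study_wide: float = 1e-8
    p_suggestive: float = 1e-6
    p_replication: float = 0.05
    min_observed: int = 6
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.p_study_wide < self.p_suggestive:
            raise ValueError("study-wide threshold must be below suggestive")
        unknown = [m for m in self.models if m not in DEFAULT_MODELS]
        if unknown:
            raise ValueError(f"unknown QV models: {unknown}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def site_qc_mask(sites: pd.DataFrame, profile: str, reference: dict) -> pd.Series:
    """Boolean pass mask over a sites table for one profile."""
    flags = []
    for row in sites.itertuples(index=False):
        site = VariantSite(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene=row.gene,
            consequence=row.consequence,
            qual=_opt(row, "qual"),
            fs=_opt(row, "fs"),
            mq=_opt(row, "mq"),
            rprs=_opt(row, "rprs"),
            mqrs=_opt(row, "mqrs"),
            filter_status=getattr(row, "filter_status", "PASS"),
            missingness=float(getattr(row, "missingness", 0.0)),
            n_qc_fail=int(getattr(row, "n_qc_fail", 0)),
            internal_maf=float(getattr(row, "internal_maf", 0.0)),
        )
        ok = qc_site(site, profile).passed and qc_external(
            site, reference.get(row.variant_key), profile
        ).passed
        flags.append(ok)
    return pd.Series(flags, index=sites.index)


def _opt(row, attr):
    import math

    v = getattr(row, attr, None)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def collapse_genes(
    sites: pd.DataFrame,
    calls: pd.DataFrame,
    phenotype: pd.Series,
    model: QVModel,
    reference: dict,
) -> pd.DataFrame:
    """Gene-level collapsing association for one QV model.

    ``sites`` must already carry the collapsing QC restriction; ``calls``
    may carry a ``qc_pass`` column (failing calls are treated as missing).
    Returns one row per gene with the exact test and effect estimates.
    """
    n_case = int((phenotype == "case").sum())
    n_ctrl = int((phenotype == "control").sum())
    qsites = qualifying_sites(sites, reference, model)
    key_gene = qsites.set_index("variant_key")["gene"].to_dict()
    usable = calls
    if "qc_pass" in usable.columns:
        usable = usable[usable["qc_pass"]]
    usable = usable[usable["variant_key"].isin(key_gene)]
    pheno = phenotype.to_dict()

    rows = []
    gene_sites = {
        g: frozenset(ks) for g, ks in qsites.groupby("gene")["variant_key"]
    }
    n_qv_by_gene = {g: len(ks) for g, ks in gene_sites.items()}
    all_genes = sorted(sites["gene"].unique())

    # identical carrier counts give identical statistics; cache by (a, c)
    stat_cache: dict[tuple[int, int], tuple] = {}

    def stats_for(a: int, c: int):
        got = stat_cache.get((a, c))
        if got is None:
            t = ContingencyTable(a, n_case - a, c, n_ctrl - c)
            p = fisher_two_sided(t) if a + c > 0 else 1.0
            or_, lo, hi, corrected = odds_ratio_ci(t)
            got = (p, or_, lo, hi, corrected, t)
            stat_cache[(a, c)] = got
        return got

    if model.zygosity_mode == "dominant":
        # vectorised path: a carrier is any sample with >=1 qualifying call
        pairs = pd.DataFrame(
            {
                "gene": usable["variant_key"].map(key_gene),
                "sample_id": usable["sample_id"],
            }
        ).drop_duplicates()
        pairs["pheno"] = pairs["sample_id"].map(pheno)
        counts = (
            pairs.groupby(["gene", "pheno"], observed=True).size().unstack(fill_value=0)
        )
        a_by_gene = (
            counts["case"].to_dict() if "case" in counts else {}
        )
        c_by_gene = (
            counts["control"].to_dict() if "control" in counts else {}
        )
        for gene in all_genes:
            a = int(a_by_gene.get(gene, 0))
            c = int(c_by_gene.get(gene, 0))
            p, or_, lo, hi, corrected, t = stats_for(a, c)
            rows.append(
                {
                    "gene": gene, "model": model.name, "p": p, "or": or_,
                    "ci_low": lo, "ci_high": hi, "corrected": corrected,
                    "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                    "n_qv_sites": n_qv_by_gene.get(gene, 0),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "gene", "model", "p", "or", "ci_low", "ci_high",
                "corrected", "a", "b", "c", "d", "n_qv_sites",
            ],
        )

    grouped = dict(tuple(usable.groupby(usable["variant_key"].map(key_gene))))
    empty = usable.iloc[0:0]
    for gene in all_genes:
        gene_qv = gene_sites.get(gene, frozenset())
        gcalls = grouped.get(gene, empty)
        carriers = collect_gene_carriers(gene, gcalls, model, gene_qv, pheno)
        t = carrier_table(carriers, n_case, n_ctrl)
        p, or_, lo, hi, corrected, t = stats_for(t.a, t.c)
        rows.append(
            {
                "gene": gene,
                "model": model.name,
                "p": p,
                "or": or_,
                "ci_low": lo,
                "ci_high": hi,
                "corrected": corrected,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "n_qv_sites": len(gene_qv),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "model", "p", "or", "ci_low", "ci_high",
            "corrected", "a", "b", "c", "d", "n_qv_sites",
        ],
    )


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_discovery(
    samples: pd.DataFrame,
    sites: pd.DataFrame,
    calls: pd.DataFrame,
    reference: dict,
    config: RunConfig,
) -> dict:
    """Discovery battery: collapsing per model, ExWAS, inflation, ranked hits.

    Returns a bundle of DataFrames; writes TSVs (stable column order, header,
    metadata sidecar) when ``config.outdir`` is set.  Deterministic given the
    config seed.
    """
    phenotype = pd.Series(
        samples["phenotype"].to_numpy(), index=samples["sample_id"].to_numpy()
    )

    col_mask = site_qc_mask(sites, "collapsing", reference)
    col_sites = sites[col_mask]
    col_calls = apply_genotype_qc(calls, "collapsing")

    gene_results = []
    null_results = []
    perm_seed = _stage_seed(config.seed, "n-of-1-permutation")
    rng = np.random.default_rng(perm_seed)
    perm = samples["phenotype"].to_numpy().copy()
    rng.shuffle(perm)
    perm_pheno = pd.Series(perm, index=samples["sample_id"].to_numpy())

    for name in config.models:
        model = DEFAULT_MODELS[name]
        res = collapse_genes(col_sites, col_calls, phenotype, model, reference)
        gene_results.append(res)
        nres = collapse_genes(col_sites, col_calls, perm_pheno, model, reference)
        nres["model"] = name
        null_results.append(nres)
    gene_df = pd.concat(gene_results, ignore_index=True)
    null_df = pd.concat(null_results, ignore_index=True)

    lam_rows = []
    for name in config.models:
        obs = gene_df.loc[gene_df["model"] == name, "p"].to_numpy()
        nul = null_df.loc[null_df["model"] == name, "p"].to_numpy()
        try:
            lam = estimate_lambda(obs, nul, seed=perm_seed).lambda_gc
        except ValueError:
            lam = float("nan")
        lam_rows.append({"model": name, "lambda_gc": lam, "n_genes": len(obs)})
    lambda_df = pd.DataFrame(lam_rows, columns=["model", "lambda_gc", "n_genes"])

    ex_mask = site_qc_mask(sites, "exwas", reference)
    ex_calls = apply_genotype_qc(calls, "exwas")
    exwas_df = run_exwas(ex_calls, phenotype, sites[ex_mask], config.min_observed)

    hits = gene_df[gene_df["model"] != "syn"].copy()
    hits["tier"] = np.where(
        hits["p"] <= config.p_study_wide,
        "study-wide",
        np.where(hits["p"] <= config.p_suggestive, "suggestive", "ns"),
    )
    hits = hits.sort_values(["p", "gene", "model"], kind="mergesort").reset_index(drop=True)

    bundle = {
        "genes": gene_df,
        "genes_null": null_df,
        "lambda": lambda_df,
        "exwas": exwas_df,
        "hits": hits,
    }
    if config.outdir:
        _write_bundle(bundle, config)
    return bundle


def run_replication(
    config: RunConfig,
    hits: pd.DataFrame,
    repl_samples: pd.DataFrame,
    repl_sites: pd.DataFrame,
    repl_calls: pd.DataFrame,
    repl_reference: dict,
    p_select: float = 1e-4,
) -> pd.DataFrame:
    """Replicate top-ranking discovery hits in an independent cohort.

    Hits with discovery p below ``p_select`` are re-tested with a Fisher
    test in the replication cohort, then combined with the discovery table
    by the exact CMH test.  A hit replicates when its replication p is below
    the replication threshold with a concordant direction of effect.  Hits
    whose gene is absent from the replication data are reported untestable.
    """
    selected = hits[(hits["p"] < p_select) & (hits["model"] != "syn")]
    if selected.empty:
        return pd.DataFrame(
            columns=[
                "gene", "model", "p_discovery", "p_replication", "or_replication",
                "p_combined", "or_combined", "replicates", "status",
            ]
        )
    phenotype = pd.Series(
        repl_samples["phenotype"].to_numpy(), index=repl_samples["sample_id"].to_numpy()
    )
    col_mask = site_qc_mask(repl_sites, "collapsing", repl_reference)
    col_sites = repl_sites[col_mask]
    col_calls = apply_genotype_qc(repl_calls, "collapsing")

    rows = []
    for _, hit in selected.iterrows():
        model = DEFAULT_MODELS[hit["model"]]
        gene_sites = col_sites[col_sites["gene"] == hit["gene"]]
        if gene_sites.empty:
            rows.append(
                {
                    "gene": hit["gene"], "model": hit["model"], "p_discovery": hit["p"],
                    "p_replication": float("nan"), "or_replication": float("nan"),
                    "p_combined": float("nan"), "or_combined": float("nan"),
                    "replicates": False, "status": "untestable",
                }
            )
            continue
        res = collapse_genes(gene_sites, col_calls, phenotype, model, repl_reference)
        row = res.iloc[0]
        t_disc = ContingencyTable(int(hit["a"]), int(hit["b"]), int(hit["c"]), int(hit["d"]))
        t_repl = ContingencyTable(int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"]))
        try:
            p_comb, or_comb, _ = cmh_exact(
                StratifiedTables([("discovery", t_disc), ("replication", t_repl)])
            )
        except ValueError:
            p_comb, or_comb = float("nan"), float("nan")
        concordant = (hit["or"] > 1) == (row["or"] > 1)
        replicates = bool(row["p"] < config.p_replication and concordant)
        rows.append(
            {
                "gene": hit["gene"], "model": hit["model"], "p_discovery": hit["p"],
                "p_replication": float(row["p"]), "or_replication": float(row["or"]),
                "p_combined": p_comb, "or_combined": or_comb,
                "replicates": replicates,
                "status": "replicates" if replicates else "non-replicating",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "model", "p_discovery", "p_replication", "or_replication",
            "p_combined", "or_combined", "replicates", "status",
        ],
    )


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
    sidecar = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "config": asdict(config),
    }
    (outdir / "run_metadata.json").write_text(json.dumps(sidecar, indent=2, default=str))
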