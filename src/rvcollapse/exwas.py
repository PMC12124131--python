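"""Variant-level exome-wide association tests and LD clumping.

Each QC-passing site is tested under three genetic models derived from its
genotype counts (A = alternate allele, B = reference):

* allelic  -- A versus B allele counts,
* dominant -- carriers (hom-alt + het) versus hom-ref individuals,
* recessive -- hom-alt versus the rest.

Only sites observed in at least ``min_observed`` participants (carriers of
the alternate allele) are tested.  Significant results are grouped into
independent loci by greedy clumping: the smallest-p unassigned variant
becomes a locus index and absorbs every unassigned variant on the same
chromosome within a window whose genotype-dosage correlation with it reaches
``r2_min``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ContingencyTable, fisher_two_sided, odds_ratio_ci

GENETIC_MODELS = ("allelic", "dominant", "recessive")


@dataclass(frozen=True)
class GenotypeCountTable:
    """Genotype counts per phenotype; AA = hom alt, AB = het, BB = hom ref."""

    case_aa: int
    case_ab: int
    case_bb: int
    ctrl_aa: int
    ctrl_ab: int
    ctrl_bb: int

    @property
    def n_case(self) -> int:
        return self.case_aa + self.case_ab + self.case_bb

    @property
    def n_ctrl(self) -> int:
        return self.ctrl_aa + self.ctrl_ab + self.ctrl_bb

    @property
    def n_observed(self) -> int:
        """Participants carrying the alternate allele."""
        return self.case_aa + self.case_ab + self.ctrl_aa + self.ctrl_ab


def model_table(counts: GenotypeCountTable, model: str) -> ContingencyTable:
    """2x2 table for one genetic model."""
    if model == "allelic":
        return ContingencyTable(
            2 * counts.case_aa + counts.case_ab,
            counts.case_ab + 2 * counts.case_bb,
            2 * counts.ctrl_aa + counts.ctrl_ab,
            counts.ctrl_ab + 2 * counts.ctrl_bb,
        )
    if model == "dominant":
        return ContingencyTable(
            counts.case_aa + counts.case_ab,
            counts.case_bb,
            counts.ctrl_aa + counts.ctrl_ab,
            counts.ctrl_bb,
        )
    if model == "recessive":
        return ContingencyTable(
            counts.case_aa,
            counts.case_ab + counts.case_bb,
            counts.ctrl_aa,
            counts.ctrl_ab + counts.ctrl_bb,
        )
    raise ValueError(f"unknown genetic model {model!r}; expected one of {GENETIC_MODELS}")


def genotype_counts(
    calls: pd.DataFrame, phenotype: pd.Series, variant_key: str
) -> GenotypeCountTable:
    """Genotype counts at one site from a non-reference calls table.

    Samples absent from the calls at this site are hom-ref; calls flagged
    ``qc_pass == False`` (if the column exists) count as missing and are
    excluded from both margins.
    """
    sub = calls[calls["variant_key"] == variant_key]
    if "qc_pass" in sub.columns:
        missing_ids = set(sub.loc[~sub["qc_pass"], "sample_id"])
        sub = sub[sub["qc_pass"]]
    else:
        missing_ids = set()
    zyg = dict(zip(sub["sample_id"], sub["zygosity"]))
    n = {"case": {"aa": 0, "ab": 0, "bb": 0}, "control": {"aa": 0, "ab": 0, "bb": 0}}
    for sid, pheno in phenotype.items():
        if sid in missing_ids or pheno not in n:
            continue
        z = zyg.get(sid)
        if z in ("hom_alt", "hemi"):
            n[pheno]["aa"] += 1
        elif z == "het":
            n[pheno]["ab"] += 1
        else:
            n[pheno]["bb"] += 1
    return GenotypeCountTable(
        n["case"]["aa"], n["case"]["ab"], n["case"]["bb"],
        n["control"]["aa"], n["control"]["ab"], n["control"]["bb"],
    )


def run_exwas(
    calls: pd.DataFrame,
    phenotype: pd.Series,
    sites: pd.DataFrame,
    min_observed: int = 6,
) -> pd.DataFrame:
    """Fisher tests per site under all three genetic models.

    ``phenotype`` maps sample_id -> "case"/"control" for the analysed cohort;
    ``sites`` must already be restricted to the exwas QC-passing set.
    "Observed in at least ``min_observed`` participants" is counted as
    participants carrying the allele (not allele copies).
    Returns one row per site x model.
    """
    n_case = int((phenotype == "case").sum())
    n_ctrl = int((phenotype == "control").sum())
    rows = []
    for site in sites.itertuples(index=False):
        counts = genotype_counts(calls, phenotype, site.variant_key)
        if counts.n_observed < min_observed:
            continue
        for model in GENETIC_MODELS:
            t = model_table(counts, model)
            if t.a + t.c == 0 or t.b + t.d == 0:
                p = 1.0  # uninformative margin (e.g. recessive with no hom-alt)
            else:
                p = fisher_two_sided(t)
            or_, lo, hi, corrected = odds_ratio_ci(t)
            rows.append(
                {
                    "variant_key": site.variant_key,
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "gene": site.gene,
                    "model": model,
                    "p": p,
                    "or": or_,
                    "ci_low": lo,
                    "ci_high": hi,
                    "corrected": corrected,
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "maf": (2 * counts.case_aa + counts.case_ab + 2 * counts.ctrl_aa + counts.ctrl_ab)
                    / max(2 * (n_case + n_ctrl), 1),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_key", "chrom", "pos", "gene", "model",
            "p", "or", "ci_low", "ci_high", "corrected",
            "a", "b", "c", "d", "maf",
        ],
    )


def dosage_matrix(calls: pd.DataFrame, sample_ids, variant_keys) -> np.ndarray:
    """0/1/2 alternate-allele dosage matrix (samples x sites).

    QC-failing calls (``qc_pass == False``) become NaN (missing).
    """
    sid_idx = {s: i for i, s in enumerate(sample_ids)}
    key_idx = {k: j for j, k in enumerate(variant_keys)}
    dm = np.zeros((len(sid_idx), len(key_idx)))
    dose = {"het": 1.0, "hom_alt": 2.0, "hemi": 2.0}
    for row in calls.itertuples(index=False):
        i = sid_idx.get(row.sample_id)
        j = key_idx.get(row.variant_key)
        if i is None or j is None:
            continue
        if getattr(row, "qc_pass", True):
            dm[i, j] = dose.get(row.zygosity, 0.0)
        else:
            dm[i, j] = np.nan
    return dm


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over jointly non-missing samples."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def clump(
    results: pd.DataFrame,
    dosages: np.ndarray,
    variant_keys,
    r2_min: float = 0.5,
    window_kb: float = 250.0,
    p_max: float = 1e-4,
    maf_min: float = 0.001,
) -> list[dict]:
    """Greedy clumping of significant variants into independent loci.

    ``results`` needs variant_key / chrom / pos / p / maf columns (one row
    per variant; collapse multiple genetic models to the best p before
    calling).  ``dosages`` columns align with ``variant_keys``.  Ties in p
    break by (chrom, pos).  Returns a list of loci, each with its index
    variant and members; the loci partition the significant set.
    """
    key_col = {k: j for j, k in enumerate(variant_keys)}
    sig = results[(results["p"] < p_max) & (results["maf"] >= maf_min)].copy()
    sig = sig.sort_values(["p", "chrom", "pos"], kind="mergesort")
    unassigned = {row.variant_key: row for row in sig.itertuples(index=False)}
    loci = []
    for row in sig.itertuples(index=False):
        if row.variant_key not in unassigned:
            continue
        members = [row.variant_key]
        del unassigned[row.variant_key]
        xi = dosages[:, key_col[row.variant_key]]
        for other_key in list(unassigned):
            other = unassigned[other_key]
            if str(other.chrom) != str(row.chrom):
                continue
            if abs(other.pos - row.pos) > window_kb * 1000:
                continue
            if _r2(xi, dosages[:, key_col[other_key]]) >= r2_min:
                members.append(other_key)
                del unassigned[other_key]
        loci.append(
            {
                "index_variant": row.variant_key,
                "chrom": row.chrom,
                "pos": row.pos,
                "p": row.p,
                "members": members,
            }
        )
    return loci
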