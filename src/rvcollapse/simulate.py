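"""Synthetic case-control cohorts with rare-variant architecture.

The generator emulates the statistical structure a rare-variant collapsing
analysis assumes, so that every downstream stage (QC, qualifying-variant
aggregation, exact tests, meta-analysis, survival models) is testable
without access-controlled biobank data:

* genes carry independent rare sites with protein-truncating, missense, and
  synonymous consequences; per-gene cumulative allele frequencies (CAF) are
  split across sites by a Dirichlet draw;
* genotypes are drawn under Hardy-Weinberg equilibrium by scattering
  binomially-drawn allele counts over the ``2M`` chromosomes of a synthetic
  population;
* disease status follows a logistic model: a baseline log-odds set by the
  population prevalence plus ``log(OR)`` for every effect gene in which the
  person carries a protein-truncating allele.  Cases and controls are then
  sampled from the population (rejection sampling), which preserves the
  carrier odds ratio in the case-control sample;
* sex, age, ancestry strata, principal-component covariates, exome-wide PTV
  burden, Weibull ages of onset with right-censoring, and per-site/per-call
  sequencing QC metrics are attached, with configurable fractions of records
  built to fail each QC filter.

Sites are independent (no linkage disequilibrium) and the site frequency
spectrum is schematic; both are deliberate -- see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import binom

from .stats import ContingencyTable
from .meta import StratifiedTables


def gene_name(i: int) -> str:
    return f"GENE{i + 1:04d}"


@dataclass(frozen=True)
class QCNoise:
    """Parameters of the synthetic sequencing-metric distributions.

    ``site_fail_frac`` / ``call_fail_frac`` set the probability that each
    site-level metric / genotype-call metric is drawn from its failing range
    (independently per metric; the filters only need exercising, so no
    metric covariance is modelled).
    """

    mean_dp: float = 30.0
    mean_gq: float = 80.0
    site_fail_frac: float = 0.02
    call_fail_frac: float = 0.02

    def __post_init__(self) -> None:
        for name in ("site_fail_frac", "call_fail_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"qc_noise.{name} must lie in [0, 1]")


@dataclass(frozen=True)
class OnsetModel:
    """Weibull age-of-onset model with administrative censoring."""

    shape: float = 5.0
    scale: float = 75.0
    censor_age: float = 80.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0 or self.censor_age <= 0:
            raise ValueError("onset_model parameters must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one synthetic cohort.

    ``cumulative_ptv_allele_freq`` is the per-gene cumulative allele
    frequency summed over the gene's PTV sites; ``gene_effects`` maps gene
    names to carrier odds ratios (genes not listed are null).  Disease
    prevalence in the source population defaults to 1% (configurable; the
    case-control design conditions on it only through sampling).
    """

    n_cases: int = 1000
    n_controls: int = 10000
    n_genes: int = 20
    variants_per_gene_mean: float = 8.0
    cumulative_ptv_allele_freq: float = 3e-4
    cumulative_missense_allele_freq: float = 1e-3
    cumulative_synonymous_allele_freq: float = 1e-2
    gene_effects: Mapping[str, float] = field(default_factory=dict)
    consequence_mix: Mapping[str, float] = field(
        default_factory=lambda: {"ptv": 0.25, "missense": 0.45, "synonymous": 0.30}
    )
    mtr_intolerant_fraction: float = 0.35
    ancestry_strata: tuple[tuple[str, float], ...] = (("EUR", 0.92), ("SAS", 0.04), ("AFR", 0.03), ("EAS", 0.01))
    sex_ratio_cases: float = 0.63
    prevalence: float = 0.01
    qc_noise: QCNoise = field(default_factory=QCNoise)
    onset_model: OnsetModel = field(default_factory=OnsetModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.variants_per_gene_mean < 1:
            raise ValueError("variants_per_gene_mean must be >= 1")
        for name in (
            "cumulative_ptv_allele_freq",
            "cumulative_missense_allele_freq",
            "cumulative_synonymous_allele_freq",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5)")
        for g, orr in self.gene_effects.items():
            if orr <= 0:
                raise ValueError(f"gene_effects[{g!r}] must be a positive odds ratio")
        mix_sum = sum(self.consequence_mix.values())
        if abs(mix_sum - 1.0) > 1e-6 or any(v < 0 for v in self.consequence_mix.values()):
            raise ValueError("consequence_mix fractions must be non-negative and sum to 1")
        if not 0.0 <= self.mtr_intolerant_fraction <= 1.0:
            raise ValueError("mtr_intolerant_fraction must lie in [0, 1]")
        if not 0.0 < self.sex_ratio_cases < 1.0:
            raise ValueError("sex_ratio_cases must lie in (0, 1)")
        if not 0.0 < self.prevalence < 0.5:
            raise ValueError("prevalence must lie in (0, 0.5)")
        w = [wt for _, wt in self.ancestry_strata]
        if not w or abs(sum(w) - 1.0) > 1e-6 or any(x < 0 for x in w):
            raise ValueError("ancestry_strata weights must be non-negative and sum to 1")


_BASES = np.array(list("ACGT"))


def _build_sites(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    classes = list(config.consequence_mix)
    weights = np.array([config.consequence_mix[c] for c in classes], dtype=float)
    caf_by_class = {
        "ptv": config.cumulative_ptv_allele_freq,
        "missense": config.cumulative_missense_allele_freq,
        "synonymous": config.cumulative_synonymous_allele_freq,
    }
    term_by_class = {
        "ptv": "stop_gained",
        "missense": "missense_variant",
        "synonymous": "synonymous_variant",
    }
    # per-site frequency scale: classes with a large cumulative frequency get
    # proportionally more sites, keeping individual sites in the rare regime
    per_site_af = 4e-4
    rows = []
    for gi in range(config.n_genes):
        gene = gene_name(gi)
        cls: list[str] = []
        af_list: list[float] = []
        for c in classes:
            frac = config.consequence_mix[c]
            if frac == 0:
                continue
            caf_c = caf_by_class.get(c, 1e-5)
            k = max(
                1,
                int(rng.poisson(config.variants_per_gene_mean * frac)),
                int(np.ceil(caf_c / per_site_af)),
            )
            share = rng.dirichlet(np.ones(k))
            cls.extend([c] * k)
            af_list.extend(share * caf_c)
        n_var = len(cls)
        afs = np.asarray(af_list)
        base = 1_000_000 * (gi + 1)
        chrom = str(1 + gi % 22)
        for vi in range(n_var):
            is_indel = rng.random() < 0.10
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            if is_indel:
                ref = ref + alt
            rows.append(
                {
                    "chrom": chrom,
                    "pos": base + 100 * vi,
                    "ref": ref,
                    "alt": alt,
                    "gene": gene,
                    "transcript": f"TX{gi + 1:04d}",
                    "consequence": term_by_class[cls[vi]],
                    "class": cls[vi],
                    "mtr_intolerant": bool(
                        cls[vi] == "missense"
                        and rng.random() < config.mtr_intolerant_fraction
                    ),
                    "true_af": float(afs[vi]),
                    "is_indel": is_indel,
                }
            )
    sites = pd.DataFrame(rows)
    sites["variant_key"] = (
        sites["chrom"].astype(str)
        + "-"
        + sites["pos"].astype(str)
        + "-"
        + sites["ref"]
        + "-"
        + sites["alt"]
    )
    return sites


def _site_metrics(sites: pd.DataFrame, noise: QCNoise, rng: np.random.Generator) -> pd.DataFrame:
    n = len(sites)
    f = noise.site_fail_frac

    def mix(passing, failing):
        bad = rng.random(n) < f
        return np.where(bad, failing, passing)

    sites = sites.copy()
    sites["qual"] = mix(rng.normal(200, 40, n).clip(35), rng.uniform(5, 29, n)).round(2)
    fs_cap = np.where(sites["is_indel"], 200.0, 60.0)
    sites["fs"] = mix(rng.uniform(0, 0.5, n) * fs_cap, fs_cap * rng.uniform(1.01, 2.0, n)).round(3)
    sites["mq"] = mix(rng.normal(58, 3, n).clip(41), rng.uniform(20, 39, n)).round(2)
    sites["rprs"] = mix(rng.normal(0, 0.6, n).clip(-1.9, 3), rng.uniform(-6, -2.1, n)).round(3)
    sites["mqrs"] = mix(rng.normal(0, 1.5, n).clip(-7.5, 7.5), rng.uniform(-20, -8.1, n)).round(3)
    sites["filter_status"] = np.where(rng.random(n) < f, "LowQual", "PASS")
    sites["missingness"] = np.where(
        rng.random(n) < f, rng.uniform(0.101, 0.4, n), rng.uniform(0, 0.05, n)
    ).round(4)
    # scatter a few missing annotations: missing values pass QC by design
    for col in ("fs", "mq", "rprs", "mqrs"):
        miss = rng.random(n) < 0.01
        sites.loc[miss, col] = np.nan
    return sites


def _binom_two_sided_half(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Exact two-sided binomial p at p0=0.5, vectorised.

    The Binomial(n, 1/2) pmf is symmetric, so the two-sided p-value is the
    probability of being at least as far from n/2 as observed.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    lo = np.minimum(k, n - k)
    hi = np.maximum(k, n - k)
    p = binom.cdf(lo, n, 0.5) + binom.sf(hi - 1, n, 0.5)
    return np.minimum(p, 1.0)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (samples, variant_sites, genotype_calls) tables.

    Deterministic for a given config (byte-identical on repeat calls).
    Raises ``RuntimeError`` if the population does not yield enough cases at
    the configured prevalence (the population is grown twice before giving
    up).
    """
    rng = np.random.default_rng(config.seed)
    sites = _build_sites(config, rng)
    effects = dict(config.gene_effects)
    unknown = set(effects) - set(sites["gene"])
    if unknown:
        raise ValueError(f"gene_effects names unknown genes: {sorted(unknown)}")

    n_samp = config.n_cases + config.n_controls
    afs = sites["true_af"].to_numpy()
    # disease risk flows through PTV carriers of the effect genes only; all
    # other sites are independent of phenotype and can be drawn directly for
    # the sampled cohort (distributionally identical, far cheaper)
    eff_mask = (
        sites["gene"].isin(effects).to_numpy() & (sites["class"] == "ptv").to_numpy()
        if effects
        else np.zeros(len(sites), dtype=bool)
    )

    eff_site_idx: list[int] = []
    eff_sample_pos: list[np.ndarray] = []
    eff_copies: list[np.ndarray] = []
    if effects:
        margin = 1.4
        M = int(np.ceil(config.n_cases / config.prevalence * margin)) + config.n_controls
        for _attempt in range(3):
            out = _draw_population(config, sites, effects, eff_mask, M, rng)
            if out is not None:
                case_idx, ctrl_idx, eff_chroms = out
                break
            M *= 2
        else:
            raise RuntimeError(
                "population exhausted before filling case/control quotas; "
                "check prevalence and cohort sizes"
            )
        # map population individual -> sampled cohort position
        pos_arr = np.full(M, -1, dtype=np.int64)
        pos_arr[case_idx] = np.arange(len(case_idx))
        pos_arr[ctrl_idx] = len(case_idx) + np.arange(len(ctrl_idx))
        for si, chroms in zip(np.flatnonzero(eff_mask), eff_chroms):
            if chroms.size == 0:
                continue
            inds, copies = np.unique(chroms // 2, return_counts=True)
            pos = pos_arr[inds]
            keep = pos >= 0
            if keep.any():
                eff_site_idx.append(si)
                eff_sample_pos.append(pos[keep])
                eff_copies.append(copies[keep])
    # null sites: HWE draws over the sampled cohort's 2n chromosomes.
    # Per-site sampling without replacement is realised as iid chromosome
    # draws with rejection of within-site duplicates (the conditional law of
    # iid draws given distinctness IS sampling without replacement).
    null_idx = np.flatnonzero(~eff_mask)
    null_ac = rng.binomial(2 * n_samp, afs[null_idx])
    site_rep = np.repeat(null_idx, null_ac)
    if site_rep.size:
        chrom_pos = rng.integers(0, 2 * n_samp, size=site_rep.size)
        for _ in range(100):
            ckey = site_rep * np.int64(2 * n_samp) + chrom_pos
            order = np.argsort(ckey, kind="stable")
            sorted_key = ckey[order]
            dup_sorted = np.zeros(len(ckey), dtype=bool)
            dup_sorted[1:] = sorted_key[1:] == sorted_key[:-1]
            dup = np.zeros(len(ckey), dtype=bool)
            dup[order] = dup_sorted
            if not dup.any():
                break
            chrom_pos[dup] = rng.integers(0, 2 * n_samp, size=int(dup.sum()))
        else:
            raise RuntimeError("duplicate-rejection sampling failed to converge")
        key = site_rep * np.int64(n_samp) + chrom_pos // 2
        uniq, counts = np.unique(key, return_counts=True)
        null_site = (uniq // n_samp).astype(np.int64)
        null_sample = (uniq % n_samp).astype(np.int64)
    else:
        null_site = np.array([], dtype=np.int64)
        null_sample = np.array([], dtype=np.int64)
        counts = np.array([], dtype=np.int64)

    call_site = np.concatenate(
        [null_site]
        + [np.full(len(p), si, dtype=np.int64) for si, p in zip(eff_site_idx, eff_sample_pos)]
    ) if (null_site.size or eff_site_idx) else np.array([], dtype=np.int64)
    call_sample = np.concatenate(
        [null_sample] + eff_sample_pos
    ) if (null_sample.size or eff_sample_pos) else np.array([], dtype=np.int64)
    call_copies = np.concatenate(
        [np.minimum(counts, 2)] + [np.minimum(c, 2) for c in eff_copies]
    ) if (counts.size or eff_copies) else np.array([], dtype=np.int64)

    phenotype = np.array(
        ["case"] * config.n_cases + ["control"] * config.n_controls
    )
    sample_ids = np.array([f"S{i + 1:06d}" for i in range(n_samp)])

    calls = pd.DataFrame(
        {
            "sample_id": sample_ids[call_sample],
            "variant_key": sites["variant_key"].to_numpy()[call_site],
            "copies": call_copies.astype(int),
        }
    )
    calls["zygosity"] = np.where(calls["copies"] >= 2, "hom_alt", "het")

    # per-call sequencing metrics
    noise = config.qc_noise
    ncall = len(calls)
    bad = rng.random(ncall) < noise.call_fail_frac
    dp = np.where(
        bad, rng.integers(0, 10, ncall), rng.poisson(noise.mean_dp, ncall).clip(10)
    ).astype(int)
    gq = np.where(
        rng.random(ncall) < noise.call_fail_frac,
        rng.integers(0, 20, ncall),
        rng.normal(noise.mean_gq, 10, ncall).clip(20, 99).astype(int),
    ).astype(int)
    het = calls["zygosity"].to_numpy() == "het"
    ab_bad = rng.random(ncall) < noise.call_fail_frac
    ab = np.where(
        het,
        np.where(ab_bad, rng.beta(2, 14, ncall), rng.beta(30, 30, ncall)),
        np.where(ab_bad, rng.beta(10, 4, ncall), rng.beta(80, 1, ncall)),
    )
    alt_reads = np.round(ab * dp).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        ab_obs = np.where(dp > 0, alt_reads / np.maximum(dp, 1), np.nan)
    ab_p = np.full(ncall, np.nan)
    if het.any():
        ab_p[het] = _binom_two_sided_half(alt_reads[het], dp[het])
    calls["dp"] = dp
    calls["gq"] = gq
    calls["ab"] = np.round(ab_obs, 4)
    calls["ab_binom_p"] = ab_p
    calls = calls.sort_values(["variant_key", "sample_id"], kind="mergesort").reset_index(drop=True)

    # internal frequencies from the analysed cohort
    mac = calls.groupby("variant_key")["copies"].sum()
    sites = sites.set_index("variant_key", drop=False)
    sites["internal_mac"] = mac.reindex(sites.index).fillna(0).astype(int)
    sites["internal_maf"] = (sites["internal_mac"] / (2 * n_samp)).clip(upper=0.5)
    sites["n_qc_fail"] = rng.poisson(2, len(sites))
    sites = _site_metrics(sites.reset_index(drop=True), noise, rng)

    # exome-wide PTV burden: genes with >=1 PTV allele, per sample
    ptv_keys = set(sites.loc[sites["class"] == "ptv", "variant_key"])
    ptv_calls = calls[calls["variant_key"].isin(ptv_keys)]
    key_gene = sites.set_index("variant_key")["gene"]
    burden = (
        ptv_calls.assign(gene=ptv_calls["variant_key"].map(key_gene))
        .groupby("sample_id")["gene"]
        .nunique()
    )

    samples = _build_samples(
        config, rng, sample_ids, phenotype, burden
    )
    return samples, sites, calls


def _draw_population(config, sites, effects, eff_mask, M, rng):
    """Population-level draws for the effect sites; samples the cohort.

    Returns ``(case_idx, ctrl_idx, eff_chroms)`` or None when the population
    cannot fill the quotas.
    """
    afs = sites["true_af"].to_numpy()
    eff_idx = np.flatnonzero(eff_mask)
    eff_chroms: list[np.ndarray] = []
    for si in eff_idx:
        ac = rng.binomial(2 * M, afs[si])
        eff_chroms.append(
            rng.choice(2 * M, size=ac, replace=False, shuffle=False)
            if ac
            else np.array([], dtype=np.int64)
        )
    # disease model: baseline prevalence log-odds + per-gene carrier effects
    logit0 = np.log(config.prevalence / (1.0 - config.prevalence))
    eta = np.full(M, logit0)
    genes = sites["gene"].to_numpy()
    for gene, orr in effects.items():
        carrier = np.zeros(M, dtype=bool)
        for j, si in enumerate(eff_idx):
            if genes[si] == gene:
                carrier[eff_chroms[j] // 2] = True
        eta[carrier] += np.log(orr)
    p_case = 1.0 / (1.0 + np.exp(-eta))
    is_case = rng.random(M) < p_case
    case_pool = np.flatnonzero(is_case)
    ctrl_pool = np.flatnonzero(~is_case)
    if len(case_pool) < config.n_cases or len(ctrl_pool) < config.n_controls:
        return None
    case_idx = rng.choice(case_pool, size=config.n_cases, replace=False)
    ctrl_idx = rng.choice(ctrl_pool, size=config.n_controls, replace=False)
    return np.sort(case_idx), np.sort(ctrl_idx), eff_chroms


def _build_samples(config, rng, sample_ids, phenotype, burden) -> pd.DataFrame:
    n = len(sample_ids)
    is_case = phenotype == "case"
    sex = np.where(rng.random(n) < config.sex_ratio_cases, "male", "female")
    age = rng.normal(57, 8, n).clip(40, 70).round(1)
    labels = [lab for lab, _ in config.ancestry_strata]
    weights = np.array([w for _, w in config.ancestry_strata])
    ancestry = rng.choice(labels, size=n, p=weights)
    shift = {lab: i * 1.5 for i, lab in enumerate(labels)}
    pcs = rng.normal(0, 1, size=(n, 4))
    pcs[:, 0] += np.array([shift[a] for a in ancestry])

    om = config.onset_model
    # onset conditioned on diagnosis by the censor age (inverse-CDF draw)
    f_censor = 1.0 - np.exp(-((om.censor_age / om.scale) ** om.shape))
    u = rng.random(n) * f_censor
    onset = om.scale * (-np.log(1.0 - u)) ** (1.0 / om.shape)
    age_at_event = np.where(is_case, onset.round(1), float(om.censor_age))
    event = np.where(is_case, "diagnosed", "censored")

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "phenotype": phenotype,
            "sex": sex,
            "age_at_recruitment": age,
            "ancestry": ancestry,
            "age_at_event": age_at_event,
            "event": event,
            "pc1": pcs[:, 0].round(4),
            "pc2": pcs[:, 1].round(4),
            "pc3": pcs[:, 2].round(4),
            "pc4": pcs[:, 3].round(4),
        }
    )
    samples["ptv_burden"] = (
        samples["sample_id"].map(burden).fillna(0).astype(int)
    )
    return samples


def generate_reference(
    sites: pd.DataFrame, seed: int, n_ref: int = 125_000, presence_prob: float = 0.9
) -> pd.DataFrame:
    """Synthetic external-reference (gnomAD-style) frequency table.

    Reference allele frequencies jitter around each site's true frequency;
    a configurable fraction of sites are absent from the reference, and the
    coverage / allele-count / RPRS / MQ columns exercise the out-of-sample
    QC filters.
    """
    rng = np.random.default_rng(seed)
    n = len(sites)
    present = rng.random(n) < presence_prob
    ac_raw = rng.poisson(np.maximum(sites["true_af"].to_numpy() * 2 * n_ref, 0.1))
    ac_raw = np.where(present, np.maximum(ac_raw, 1), 0)
    ac = np.round(ac_raw * rng.uniform(0.6, 1.0, n)).astype(int)
    af = ac_raw / (2 * n_ref)
    cov = rng.beta(30, 4, n).round(4)
    low_cov = rng.random(n) < 0.03
    cov = np.where(low_cov, rng.uniform(0.05, 0.24, n).round(4), cov)
    return pd.DataFrame(
        {
            "variant_key": sites["variant_key"].to_numpy(),
            "present": present,
            "af": np.where(present, af, np.nan).round(8),
            "ac_raw": ac_raw,
            "ac": np.where(present, ac, 0),
            "coverage10x_fraction": cov,
            "rprs": rng.normal(0, 0.8, n).round(3),
            "mq": rng.normal(55, 6, n).round(2),
        }
    )


# ---------------------------------------------------------------------------
# Printed worked-example tables (carrier counts as published)
# ---------------------------------------------------------------------------

#: Named carrier-by-status tables transcribed from the published analysis:
#: discovery (UKB European), replication (AMP-PD cases vs AoU controls;
#: deCODE), and the pathogenic-carrier exclusion reruns.
PRINTED_TABLES: dict[str, ContingencyTable] = {
    "GBA1-UKB": ContingencyTable(33, 3669, 591, 232787),
    "ITSN1-UKB": ContingencyTable(9, 3693, 54, 233324),
    "ADH5-UKB": ContingencyTable(26, 3676, 640, 232738),
    "MERTK-UKB": ContingencyTable(21, 3681, 469, 232909),
    "PLEKHB2-UKB": ContingencyTable(7, 3695, 54, 233324),
    "ATP6V1B2-UKB": ContingencyTable(0, 3702, 671, 232707),
    "NEK11-UKB": ContingencyTable(42, 3660, 1338, 232040),
    "ZNF554-UKB": ContingencyTable(5, 3697, 1311, 232067),
    "ITSN1-AMP-AoU": ContingencyTable(4, 3142, 9, 50745),
    "ITSN1-deCODE": ContingencyTable(5, 4663, 36, 355240),
    "ITSN1-UKB-noGBA1LRRK2": ContingencyTable(9, 3292, 49, 217507),
    "ITSN1-AMP-AoU-noGBA1LRRK2": ContingencyTable(4, 2441, 9, 49185),
}


def fixture_tables() -> StratifiedTables:
    """All printed worked-example tables, as labelled strata."""
    return StratifiedTables(strata=[(k, t) for k, t in PRINTED_TABLES.items()])


def itsn1_strata() -> StratifiedTables:
    """The three printed ITSN1 PTV strata usable for stratified meta-analysis."""
    keys = ("ITSN1-UKB", "ITSN1-AMP-AoU", "ITSN1-deCODE")
    return StratifiedTables(strata=[(k, PRINTED_TABLES[k]) for k in keys])
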