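"""Variant-site, genotype-call, and out-of-sample reference QC filters.

Two filtering profiles are supported, mirroring the two association
frameworks they feed:

* ``exwas`` -- variant-level exome-wide association tests,
* ``collapsing`` -- gene-level qualifying-variant collapsing tests.

The profiles share most thresholds (DP >= 10, GQ >= 20, het allele-balance
binomial p >= 1e-6, FS <= 200 for indels / <= 60 for SNVs, MQ >= 40,
QUAL >= 30, RPRS >= -2, MQRS >= -8, caller FILTER = PASS, site missingness
<= 10%) and differ where the source protocols differ: the het allele-balance
bound is AB >= 0.20 for exwas but 0.25 <= AB <= 0.80 for collapsing (which
also requires AB >= 0.8 for homozygous-alt calls), the external-reference
coverage requirement is >= 10x in >= 30% of reference exomes for exwas
versus >= 25% for collapsing, and only exwas drops sites failing genotype QC
in more than 20,000 people.

A metric that is missing (None/NaN) passes that check; a record is only
rejected by thresholds it measurably violates.  Failing records report every
violated rule, not just the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROFILES = ("exwas", "collapsing")


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass
class VariantSite:
    """One biallelic chrom-pos-ref-alt site with its annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    transcript: str = ""
    consequence: str = ""
    qual: float | None = None
    fs: float | None = None
    mq: float | None = None
    rprs: float | None = None
    mqrs: float | None = None
    filter_status: str = "PASS"
    missingness: float = 0.0
    n_qc_fail: int = 0
    internal_maf: float = 0.0
    internal_mac: int | None = None
    mtr_intolerant: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError("missingness must lie in [0, 1]")
        if not 0.0 <= self.internal_maf <= 0.5:
            raise ValueError("internal_maf must lie in [0, 0.5]")

    @property
    def variant_key(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class GenotypeCall:
    sample_id: str
    variant_key: str
    zygosity: str  # hom_ref | het | hom_alt | hemi | missing
    dp: float | None = None
    gq: float | None = None
    ab: float | None = None
    ab_binom_p: float | None = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("hom_ref", "het", "hom_alt", "hemi", "missing"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.ab is not None and not (0.0 <= self.ab <= 1.0):
            raise ValueError("ab must lie in [0, 1]")


@dataclass
class ExternalReferenceEntry:
    """Out-of-sample reference (gnomAD-style) summary for one site."""

    variant_key: str
    present: bool
    af: float | None = None
    ac_raw: int | None = None
    ac: int | None = None
    coverage10x_fraction: float | None = None
    rprs: float | None = None
    mq: float | None = None

    def __post_init__(self) -> None:
        if (
            self.ac is not None
            and self.ac_raw is not None
            and self.ac > self.ac_raw
        ):
            raise ValueError("ac cannot exceed ac_raw")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _check_profile(profile: str) -> None:
    if profile not in PROFILES:
        raise ValueError(f"unknown QC profile {profile!r}; expected one of {PROFILES}")


def qc_genotype(call: GenotypeCall, profile: str) -> QCResult:
    """Apply genotype-call filters; returns every violated rule by name."""
    _check_profile(profile)
    if call.zygosity == "missing":
        raise ValueError("cannot QC a missing genotype call")
    reasons: list[str] = []
    if not _missing(call.dp) and call.dp < 10:
        reasons.append("coverage")
    if not _missing(call.gq) and call.gq < 20:
        reasons.append("GQ")
    if not _missing(call.ab):
        if call.zygosity == "het":
            if profile == "exwas":
                if call.ab < 0.20:
                    reasons.append("AB")
            else:
                if not (0.25 <= call.ab <= 0.80):
                    reasons.append("AB")
        elif call.zygosity in ("hom_alt", "hemi"):
            # hemizygous calls are held to the homozygous-alt rule
            if profile == "collapsing" and call.ab < 0.8:
                reasons.append("AB")
    if (
        call.zygosity == "het"
        and not _missing(call.ab_binom_p)
        and call.ab_binom_p < 1e-6
    ):
        reasons.append("AB_binom")
    return QCResult(not reasons, tuple(reasons))


def qc_site(site: VariantSite, profile: str) -> QCResult:
    """Apply site-level filters for the given profile."""
    _check_profile(profile)
    reasons: list[str] = []
    fs_max = 200.0 if site.is_indel else 60.0
    if not _missing(site.fs) and site.fs > fs_max:
        reasons.append("FS")
    if not _missing(site.mq) and site.mq < 40:
        reasons.append("MQ")
    if not _missing(site.qual) and site.qual < 30:
        reasons.append("QUAL")
    if not _missing(site.rprs) and site.rprs < -2:
        reasons.append("RPRS")
    if not _missing(site.mqrs) and site.mqrs < -8:
        reasons.append("MQRS")
    if site.filter_status != "PASS":
        reasons.append("FILTER")
    if site.missingness > 0.10:
        reasons.append("missingness")
    if profile == "exwas" and site.n_qc_fail > 20_000:
        reasons.append("qc_fail_count")
    return QCResult(not reasons, tuple(reasons))


def qc_external(
    site: VariantSite, ref: ExternalReferenceEntry | None, profile: str
) -> QCResult:
    """Out-of-sample reference filters (coverage, frequency-table QC)."""
    _check_profile(profile)
    reasons: list[str] = []
    if ref is None:
        return QCResult(True, ())
    cov_min = 0.30 if profile == "exwas" else 0.25
    if not _missing(ref.coverage10x_fraction) and ref.coverage10x_fraction < cov_min:
        reasons.append("ref_coverage")
    if ref.present:
        if profile == "exwas":
            if (
                not _missing(ref.ac)
                and not _missing(ref.ac_raw)
                and ref.ac_raw > 0
                and ref.ac < 0.5 * ref.ac_raw
            ):
                reasons.append("ref_ac_ratio")
        else:
            if not _missing(ref.rprs) and ref.rprs < -2:
                reasons.append("ref_RPRS")
            if not _missing(ref.mq) and ref.mq < 30:
                reasons.append("ref_MQ")
    return QCResult(not reasons, tuple(reasons))


def read_bed(path) -> pd.DataFrame:
    """Read a BED whitelist (0-based half-open) with per-line validation."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {i}: fewer than 3 fields")
            chrom, start, end = parts[0], parts[1], parts[2]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"malformed BED line {i}: non-integer bounds") from exc
            if s < 0 or e < s:
                raise ValueError(f"malformed BED line {i}: invalid interval [{s}, {e})")
            rows.append((chrom, s, e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def restrict_to_regions(
    sites: Sequence[VariantSite] | pd.DataFrame, whitelist: pd.DataFrame
):
    """Keep sites inside the coding-region whitelist.

    ``whitelist`` holds BED intervals as read from disk (0-based half-open);
    a site with 1-based position ``pos`` is kept when some interval on its
    chromosome satisfies ``start <= pos <= end``.
    """
    if isinstance(sites, pd.DataFrame):
        if whitelist.empty:
            return sites.iloc[0:0]
        keep = np.zeros(len(sites), dtype=bool)
        for chrom, grp in whitelist.groupby("chrom"):
            on = sites["chrom"].astype(str) == str(chrom)
            if not on.any():
                continue
            pos = sites.loc[on, "pos"].to_numpy()
            ok = np.zeros(len(pos), dtype=bool)
            for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
                ok |= (pos >= s) & (pos <= e)
            keep[np.flatnonzero(on.to_numpy())] = ok
        return sites.loc[keep]
    if whitelist.empty:
        return []
    by_chrom = {c: g[["start", "end"]].to_numpy() for c, g in whitelist.groupby("chrom")}
    kept = []
    for site in sites:
        ivals = by_chrom.get(site.chrom)
        if ivals is None:
            continue
        if any(s <= site.pos <= e for s, e in ivals):
            kept.append(site)
    return kept


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a minimal VCF 4.2 into site and genotype-call tables.

    Uses cyvcf2; expects biallelic records (multi-allelic ALTs are rejected
    -- the QC ledger is defined per alternate allele) with GT:DP:GQ:AD
    genotype fields and FS/MQ/RPRS/MQRS INFO keys where available.  The het
    allele balance is ``AD_alt / (AD_ref + AD_alt)``; its binomial test
    against 0.5 is computed on the spot.
    """
    from cyvcf2 import VCF
    from scipy.stats import binomtest

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    site_rows = []
    call_rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; decompose first"
            )
        key = f"{rec.CHROM}-{rec.POS}-{rec.REF}-{rec.ALT[0]}"
        info = dict(rec.INFO)
        site_rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "gene": info.get("GENE", ""),
                "consequence": info.get("CSQ", ""),
                "variant_key": key,
                "qual": rec.QUAL,
                "fs": info.get("FS"),
                "mq": info.get("MQ"),
                "rprs": info.get("RPRS"),
                "mqrs": info.get("MQRS"),
                "filter_status": rec.FILTER or "PASS",
            }
        )
        gts = rec.genotype.array()
        depths = rec.format("DP")
        quals = rec.format("GQ")
        ads = rec.format("AD")
        for si, sid in enumerate(sample_ids):
            alleles = [a for a in gts[si][:-1] if a >= 0]
            if not alleles:
                continue
            n_alt = sum(1 for a in alleles if a > 0)
            if n_alt == 0:
                continue
            if len(alleles) == 1:
                zyg = "hemi"
            else:
                zyg = "hom_alt" if n_alt == 2 else "het"
            ad_ref = int(ads[si][0]) if ads is not None else None
            ad_alt = int(ads[si][1]) if ads is not None else None
            ab = None
            ab_p = None
            if ad_ref is not None and ad_alt is not None and ad_ref + ad_alt > 0:
                ab = ad_alt / (ad_ref + ad_alt)
                if zyg == "het":
                    ab_p = binomtest(ad_alt, ad_ref + ad_alt, 0.5).pvalue
            call_rows.append(
                {
                    "sample_id": sid,
                    "variant_key": key,
                    "zygosity": zyg,
                    "dp": float(depths[si][0]) if depths is not None else None,
                    "gq": float(quals[si][0]) if quals is not None else None,
                    "ab": ab,
                    "ab_binom_p": ab_p,
                }
            )
    sites = pd.DataFrame(site_rows)
    calls = pd.DataFrame(
        call_rows,
        columns=["sample_id", "variant_key", "zygosity", "dp", "gq", "ab", "ab_binom_p"],
    )
    return sites, calls


def qc_report(
    sites: Iterable[VariantSite],
    profile: str,
    reference: dict[str, ExternalReferenceEntry] | None = None,
) -> pd.DataFrame:
    """Per-site QC report: pass flag plus semicolon-joined failure reasons."""
    reference = reference or {}
    rows = []
    for site in sites:
        res_site = qc_site(site, profile)
        res_ext = qc_external(site, reference.get(site.variant_key), profile)
        reasons = res_site.reasons + res_ext.reasons
        rows.append(
            {
                "variant_key": site.variant_key,
                "gene": site.gene,
                "pass": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows, columns=["variant_key", "gene", "pass", "reasons"])


def apply_genotype_qc(calls: pd.DataFrame, profile: str) -> pd.DataFrame:
    """Vectorised genotype QC over a calls table.

    Returns a copy with ``qc_pass`` and ``qc_reasons`` columns.  A failing
    genotype is treated as missing downstream (it still counts toward site
    missingness and the per-site QC-failure tally); it is not dropped here.
    """
    _check_profile(profile)
    df = calls.copy()
    n = len(df)
    dp = df["dp"].to_numpy(dtype=float)
    gq = df["gq"].to_numpy(dtype=float)
    ab = df["ab"].to_numpy(dtype=float)
    abp = df["ab_binom_p"].to_numpy(dtype=float)
    zyg = df["zygosity"].to_numpy()
    het = zyg == "het"
    homlike = (zyg == "hom_alt") | (zyg == "hemi")
    fail_dp = ~np.isnan(dp) & (dp < 10)
    fail_gq = ~np.isnan(gq) & (gq < 20)
    if profile == "exwas":
        fail_ab = het & ~np.isnan(ab) & (ab < 0.20)
    else:
        fail_ab = (het & ~np.isnan(ab) & ((ab < 0.25) | (ab > 0.80))) | (
            homlike & ~np.isnan(ab) & (ab < 0.8)
        )
    fail_binom = het & ~np.isnan(abp) & (abp < 1e-6)
    any_fail = fail_dp | fail_gq | fail_ab | fail_binom
    reasons = np.full(n, "", dtype=object)
    # reason strings are assembled only for the failing minority
    for i in np.flatnonzero(any_fail):
        r = []
        if fail_dp[i]:
            r.append("coverage")
        if fail_gq[i]:
            r.append("GQ")
        if fail_ab[i]:
            r.append("AB")
        if fail_binom[i]:
            r.append("AB_binom")
        reasons[i] = ";".join(r)
    df["qc_pass"] = ~any_fail
    df["qc_reasons"] = reasons
    return df
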