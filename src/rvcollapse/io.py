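"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: a minimal VCF 4.2 for genotypes, tab-separated
tables for samples / sites / external reference frequencies, and BED for the
coding-region whitelist.  The VCF writer emits GT:DP:GQ:AD per call plus the
site QC annotations (QUAL, FILTER and INFO keys FS, MQ, RPRS, MQRS, GENE,
CSQ) consumed by :func:`rvcollapse.qc.read_vcf`.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .qc import ExternalReferenceEntry


def _fmt(x, nd=4) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "."
    return f"{x:.{nd}g}" if isinstance(x, float) else str(x)


def write_vcf(sites: pd.DataFrame, calls: pd.DataFrame, samples: pd.DataFrame, path) -> None:
    """Write a minimal biallelic VCF 4.2 with all cohort samples as columns."""
    sample_ids = list(samples["sample_id"])
    col = {s: i for i, s in enumerate(sample_ids)}
    by_site: dict[str, list] = {}
    for row in calls.itertuples(index=False):
        by_site.setdefault(row.variant_key, []).append(row)
    ordered = sites.sort_values(["chrom", "pos"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(ordered["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        for key, desc in (
            ("FS", "Fisher strand bias"),
            ("MQ", "RMS mapping quality"),
            ("RPRS", "Read position rank sum"),
            ("MQRS", "Mapping quality rank sum"),
        ):
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for site in ordered.itertuples(index=False):
            info_parts = [f"GENE={site.gene}", f"CSQ={site.consequence}"]
            for key, attr in (("FS", "fs"), ("MQ", "mq"), ("RPRS", "rprs"), ("MQRS", "mqrs")):
                v = getattr(site, attr, None)
                if v is not None and not (isinstance(v, float) and math.isnan(v)):
                    info_parts.append(f"{key}={v:g}")
            gts = ["0/0:30:80:30,0"] * len(sample_ids)
            for row in by_site.get(site.variant_key, ()):
                dp = int(row.dp)
                alt = int(round((row.ab if not math.isnan(row.ab) else 0.0) * dp))
                ref_reads = max(dp - alt, 0)
                gt = {"het": "0/1", "hom_alt": "1/1", "hemi": "1"}[row.zygosity]
                gts[col[row.sample_id]] = f"{gt}:{dp}:{int(row.gq)}:{ref_reads},{alt}"
            fh.write(
                "\t".join(
                    [
                        str(site.chrom),
                        str(site.pos),
                        ".",
                        site.ref,
                        site.alt,
                        _fmt(float(site.qual), 6),
                        site.filter_status if site.filter_status == "PASS" else site.filter_status,
                        ";".join(info_parts),
                        "GT:DP:GQ:AD",
                    ]
                    + gts
                )
                + "\n"
            )


def write_samples_tsv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_sites_tsv(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "variant_key": str})


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "variant_key": str})


def write_reference_tsv(reference: pd.DataFrame, path) -> None:
    reference.to_csv(path, sep="\t", index=False)


def read_reference_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"variant_key": str})


def reference_dict(reference: pd.DataFrame) -> dict[str, ExternalReferenceEntry]:
    """External-reference table as a variant_key -> entry mapping."""
    out: dict[str, ExternalReferenceEntry] = {}
    for row in reference.itertuples(index=False):
        af = getattr(row, "af", None)
        out[row.variant_key] = ExternalReferenceEntry(
            variant_key=row.variant_key,
            present=bool(row.present),
            af=None if af is None or (isinstance(af, float) and math.isnan(af)) else float(af),
            ac_raw=int(row.ac_raw) if not _isnan(getattr(row, "ac_raw", None)) else None,
            ac=int(row.ac) if not _isnan(getattr(row, "ac", None)) else None,
            coverage10x_fraction=_optf(getattr(row, "coverage10x_fraction", None)),
            rprs=_optf(getattr(row, "rprs", None)),
            mq=_optf(getattr(row, "mq", None)),
        )
    return out


def _isnan(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _optf(x):
    return None if _isnan(x) else float(x)


def write_bed(sites_or_regions: pd.DataFrame, path, pad: int = 50) -> None:
    """Write a BED whitelist.

    Accepts either an explicit region table (chrom, start, end; 0-based
    half-open) or a sites table, in which case each site becomes a padded
    interval around its position.
    """
    df = sites_or_regions
    if {"start", "end"}.issubset(df.columns):
        regions = df[["chrom", "start", "end"]]
    else:
        raw = pd.DataFrame(
            {
                "chrom": df["chrom"].astype(str),
                "start": (df["pos"] - 1 - pad).clip(lower=0),
                "end": df["pos"] + pad,
            }
        )
        rows = []
        for chrom, grp in raw.groupby("chrom", sort=False):
            merged: list[list[int]] = []
            for s, e in sorted(zip(grp["start"], grp["end"])):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([int(s), int(e)])
            rows.extend((chrom, s, e) for s, e in merged)
        regions = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    regions.to_csv(path, sep="\t", header=False, index=False)
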