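"""Qualifying-variant (QV) models and per-gene carrier aggregation.

A QV model is a declarative rule set deciding which QC-passing variants
count toward a gene's carrier burden: internal and external minor-allele
frequency caps, an allowed consequence set, an optional requirement that
missense variants fall in missense-intolerant (MTR-flagged) regions, and a
zygosity mode.  Under the dominant mode a person carrying at least one QV in
a gene is a carrier; under the recessive mode carriers need two QV copies --
homozygous-alt at a qualifying site, hemizygous on X, or heterozygous at two
or more distinct qualifying sites (putative compound heterozygote, phase
unknown).

The shipped model registry reconstructs a conventional 10-model panel (one
strict PTV model, progressively looser damaging-missense models with and
without the intolerance requirement, an ultra-rare model, a recessive model,
and a synonymous negative control).  Every default is editable: models load
from and save to YAML, and the exact caps are configuration, not assertions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .qc import ExternalReferenceEntry, VariantSite
from .stats import ContingencyTable

#: Consequence terms classified as protein-truncating.
PTV_TERMS = frozenset(
    {
        "exon_loss_variant",
        "frameshift_variant",
        "start_lost",
        "stop_gained",
        "stop_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "gene_fusion",
        "bidirectional_gene_fusion",
        "rare_amino_acid_variant",
        "transcript_ablation",
    }
)

_MISSENSE_TERMS = frozenset({"missense_variant"})
_SYNONYMOUS_TERMS = frozenset({"synonymous_variant"})

CONSEQUENCE_CLASSES = ("ptv", "missense", "synonymous", "other")


def classify_consequence(term: str) -> str:
    """Map an SO-style annotation term to {ptv, missense, synonymous, other}."""
    if not term:
        raise ValueError("empty consequence term")
    if term in PTV_TERMS:
        return "ptv"
    if term in _MISSENSE_TERMS:
        return "missense"
    if term in _SYNONYMOUS_TERMS:
        return "synonymous"
    return "other"


@dataclass(frozen=True)
class QVModel:
    """A named qualifying-variant rule set."""

    name: str
    internal_maf_max: float
    external_maf_max: float
    allowed_consequences: frozenset[str]
    require_mtr_intolerant: bool = False
    zygosity_mode: str = "dominant"
    # Ultra-rare style extras: cap on internal allele count, and a
    # requirement that the variant be absent from the external reference.
    internal_ac_max: int | None = None
    require_absent_external: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.internal_maf_max <= 0.5:
            raise ValueError("internal_maf_max must lie in (0, 0.5]")
        if not 0 < self.external_maf_max <= 0.5:
            raise ValueError("external_maf_max must lie in (0, 0.5]")
        if not self.allowed_consequences:
            raise ValueError("allowed_consequences must be non-empty")
        if self.zygosity_mode not in ("dominant", "recessive"):
            raise ValueError(f"unknown zygosity_mode {self.zygosity_mode!r}")
        object.__setattr__(
            self, "allowed_consequences", frozenset(self.allowed_consequences)
        )


def _model(name, imaf, emaf, cons, mtr=False, zyg="dominant", ac=None, absent=False):
    return QVModel(
        name=name,
        internal_maf_max=imaf,
        external_maf_max=emaf,
        allowed_consequences=frozenset(cons),
        require_mtr_intolerant=mtr,
        zygosity_mode=zyg,
        internal_ac_max=ac,
        require_absent_external=absent,
    )


#: Reconstructed default model panel (editable; exact caps are configuration).
DEFAULT_MODELS: dict[str, QVModel] = {
    m.name: m
    for m in (
        _model("ptv", 0.001, 0.001, {"ptv"}),
        _model("raredmg", 0.001, 0.001, {"missense"}),
        _model("raredmgmtr", 0.001, 0.001, {"missense"}, mtr=True),
        _model("flexdmg", 0.005, 0.005, {"ptv", "missense"}),
        _model("flexnonsynmtr", 0.005, 0.005, {"ptv", "missense"}, mtr=True),
        _model("ptvraredmg", 0.001, 0.001, {"ptv", "missense"}),
        _model("UR", 0.001, 0.001, {"ptv", "missense"}, ac=1, absent=True),
        _model("rec", 0.01, 0.01, {"ptv", "missense"}, zyg="recessive"),
        _model("flexnonsyn", 0.005, 0.005, {"ptv", "missense"}),
        _model("syn", 0.001, 0.001, {"synonymous"}),
    )
}

NONSYNONYMOUS_MODELS = tuple(n for n in DEFAULT_MODELS if n != "syn")


def load_models(path) -> dict[str, QVModel]:
    """Load QV models from a YAML file (one mapping per model)."""
    with open(path) as fh:
        docs = yaml.safe_load(fh)
    models = {}
    for entry in docs:
        models[entry["name"]] = QVModel(
            name=entry["name"],
            internal_maf_max=float(entry["internal_maf_max"]),
            external_maf_max=float(entry["external_maf_max"]),
            allowed_consequences=frozenset(entry["allowed_consequences"]),
            require_mtr_intolerant=bool(entry.get("require_mtr_intolerant", False)),
            zygosity_mode=entry.get("zygosity_mode", "dominant"),
            internal_ac_max=entry.get("internal_ac_max"),
            require_absent_external=bool(entry.get("require_absent_external", False)),
        )
    return models


def save_models(models: Mapping[str, QVModel], path) -> None:
    docs = []
    for m in models.values():
        docs.append(
            {
                "name": m.name,
                "internal_maf_max": m.internal_maf_max,
                "external_maf_max": m.external_maf_max,
                "allowed_consequences": sorted(m.allowed_consequences),
                "require_mtr_intolerant": m.require_mtr_intolerant,
                "zygosity_mode": m.zygosity_mode,
                "internal_ac_max": m.internal_ac_max,
                "require_absent_external": m.require_absent_external,
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump(docs, fh, sort_keys=False)


def is_qualifying(
    site: VariantSite,
    ref: ExternalReferenceEntry | None,
    model: QVModel,
) -> bool:
    """Does a QC-passing site qualify under the model?

    Internal frequency is capped at ``internal_maf_max``; the external
    (reference) frequency is capped at ``external_maf_max`` when the variant
    is present in the reference (absent variants pass the frequency test).
    The consequence class must be in the allowed set, and when the model
    requires missense intolerance, missense sites qualify only if flagged.
    """
    if site.internal_maf > model.internal_maf_max:
        return False
    if model.internal_ac_max is not None:
        if site.internal_mac is not None and site.internal_mac > model.internal_ac_max:
            return False
    present = ref is not None and ref.present
    if model.require_absent_external and present:
        return False
    if present and ref.af is not None and ref.af > model.external_maf_max:
        return False
    cls = classify_consequence(site.consequence)
    if cls not in model.allowed_consequences:
        return False
    if cls == "missense" and model.require_mtr_intolerant and not site.mtr_intolerant:
        return False
    return True


@dataclass
class GeneCarrierSet:
    gene: str
    model: str
    case_carriers: frozenset[str]
    control_carriers: frozenset[str]
    qv_sites: frozenset[str]


def collect_gene_carriers(
    gene: str,
    calls: pd.DataFrame,
    model: QVModel,
    qv_sites: Iterable[str],
    phenotype: Mapping[str, str],
) -> GeneCarrierSet:
    """Aggregate per-gene carrier status from QC'd genotype calls.

    ``calls`` holds non-reference calls (sample_id, variant_key, zygosity);
    ``qv_sites`` are the gene's qualifying variant keys; ``phenotype`` maps
    sample id to "case"/"control" (samples without a phenotype are ignored).
    A gene with no qualifying sites yields empty carrier sets.
    """
    qv = frozenset(qv_sites)
    if len(calls) and len(qv):
        sub = calls[calls["variant_key"].isin(qv)]
    else:
        sub = calls.iloc[0:0]
    if model.zygosity_mode == "dominant":
        carriers = set(sub.loc[sub["zygosity"] != "missing", "sample_id"])
    else:
        two_copy = sub[sub["zygosity"].isin(("hom_alt", "hemi"))]
        carriers = set(two_copy["sample_id"])
        hets = sub[sub["zygosity"] == "het"]
        het_counts = hets.groupby("sample_id")["variant_key"].nunique()
        carriers |= set(het_counts[het_counts >= 2].index)
    cases = frozenset(s for s in carriers if phenotype.get(s) == "case")
    ctrls = frozenset(s for s in carriers if phenotype.get(s) == "control")
    return GeneCarrierSet(
        gene=gene,
        model=model.name,
        case_carriers=cases,
        control_carriers=ctrls,
        qv_sites=qv,
    )


def carrier_table(
    carriers: GeneCarrierSet, n_case: int, n_control: int
) -> ContingencyTable:
    """Carrier-by-status 2x2 table for one gene under one model."""
    a = len(carriers.case_carriers)
    c = len(carriers.control_carriers)
    if a > n_case or c > n_control:
        raise ValueError(
            f"carrier counts ({a}, {c}) exceed cohort sizes ({n_case}, {n_control})"
        )
    return ContingencyTable(a, n_case - a, c, n_control - c)


def qualifying_sites(
    sites: pd.DataFrame,
    reference: Mapping[str, ExternalReferenceEntry],
    model: QVModel,
) -> pd.DataFrame:
    """Vectorised qualifying-site selection over a sites table.

    Expects columns: variant_key, gene, consequence, internal_maf and
    optionally internal_mac, mtr_intolerant.  External frequencies come from
    ``reference``.  Returns the qualifying subset.
    """
    cls = sites["consequence"].map(classify_consequence)
    keep = cls.isin(model.allowed_consequences)
    keep &= sites["internal_maf"] <= model.internal_maf_max
    if model.internal_ac_max is not None and "internal_mac" in sites:
        keep &= sites["internal_mac"].fillna(0) <= model.internal_ac_max
    if model.require_mtr_intolerant:
        mtr = (
            sites["mtr_intolerant"]
            if "mtr_intolerant" in sites
            else pd.Series(False, index=sites.index)
        )
        keep &= (cls != "missense") | mtr.fillna(False).astype(bool)
    ext_af = sites["variant_key"].map(
        lambda k: (
            reference[k].af
            if k in reference and reference[k].present and reference[k].af is not None
            else None
        )
    )
    present = sites["variant_key"].map(
        lambda k: k in reference and reference[k].present
    )
    if model.require_absent_external:
        keep &= ~present
    keep &= ext_af.isna() | (ext_af.astype(float) <= model.external_maf_max)
    return sites[keep]
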