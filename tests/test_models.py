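"""Qualifying-variant models and per-gene carrier aggregation."""

import numpy as np
import pandas as pd
import pytest

from rvcollapse.models import (
    DEFAULT_MODELS,
    PTV_TERMS,
    QVModel,
    carrier_table,
    classify_consequence,
    collect_gene_carriers,
    is_qualifying,
    load_models,
    qualifying_sites,
    save_models,
)
from rvcollapse.qc import ExternalReferenceEntry, VariantSite
from rvcollapse.stats import ContingencyTable


def _site(consequence="stop_gained", maf=5e-5, mtr=False, **kw):
    return VariantSite(
        chrom="21", pos=33782101, ref="C", alt="T", gene="GENE0001",
        consequence=consequence, internal_maf=maf, mtr_intolerant=mtr, **kw
    )


class TestConsequences:
    @pytest.mark.parametrize("term", sorted(PTV_TERMS))
    def test_all_ptv_terms(self, term):
        assert classify_consequence(term) == "ptv"

    @pytest.mark.parametrize(
        "term,cls",
        [
            ("missense_variant", "missense"),
            ("synonymous_variant", "synonymous"),
            ("intron_variant", "other"),
            ("5_prime_UTR_variant", "other"),
        ],
    )
    def test_non_ptv_terms(self, term, cls):
        assert classify_consequence(term) == cls

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            classify_consequence("")


class TestQualifying:
    def test_rare_ptv_absent_from_reference(self):
        assert is_qualifying(_site(), None, DEFAULT_MODELS["ptv"])

    def test_intolerant_missense_model_dependence(self):
        site = _site(consequence="missense_variant", maf=5e-4, mtr=True)
        assert is_qualifying(site, None, DEFAULT_MODELS["flexnonsynmtr"])
        assert not is_qualifying(site, None, DEFAULT_MODELS["ptv"])
        # same site without the intolerance flag fails the mtr-requiring model
        tolerant = _site(consequence="missense_variant", maf=5e-4, mtr=False)
        assert not is_qualifying(tolerant, None, DEFAULT_MODELS["flexnonsynmtr"])

    def test_synonymous_never_qualifies_under_ptv(self):
        assert not is_qualifying(_site(consequence="synonymous_variant"), None, DEFAULT_MODELS["ptv"])

    def test_external_frequency_cap(self):
        common = ExternalReferenceEntry("k", present=True, af=0.01)
        assert not is_qualifying(_site(), common, DEFAULT_MODELS["ptv"])
        rare = ExternalReferenceEntry("k", present=True, af=1e-5)
        assert is_qualifying(_site(), rare, DEFAULT_MODELS["ptv"])

    def test_ultra_rare_requires_absence(self):
        present = ExternalReferenceEntry("k", present=True, af=1e-6)
        site = _site(internal_mac=1)
        assert not is_qualifying(site, present, DEFAULT_MODELS["UR"])
        assert is_qualifying(site, None, DEFAULT_MODELS["UR"])
        assert not is_qualifying(_site(internal_mac=3), None, DEFAULT_MODELS["UR"])

    def test_model_nesting(self):
        """Everything qualifying under ptv qualifies under any model with a
        superset consequence set and caps at least as large."""
        rng = np.random.default_rng(5)
        wider = DEFAULT_MODELS["flexnonsyn"]  # {ptv, missense}, caps 0.5%
        for _ in range(100):
            site = _site(
                consequence=rng.choice(
                    ["stop_gained", "missense_variant", "synonymous_variant"]
                ),
                maf=round(float(rng.uniform(0, 2e-3)), 6) or 1e-6,
                mtr=bool(rng.random() < 0.5),
            )
            ref = (
                None
                if rng.random() < 0.5
                else ExternalReferenceEntry("k", present=True, af=float(rng.uniform(0, 2e-3)))
            )
            if is_qualifying(site, ref, DEFAULT_MODELS["ptv"]):
                assert is_qualifying(site, ref, wider)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            QVModel("bad", 0.0, 0.001, frozenset({"ptv"}))
        with pytest.raises(ValueError):
            QVModel("bad", 0.001, 0.001, frozenset())
        with pytest.raises(ValueError):
            QVModel("bad", 0.001, 0.001, frozenset({"ptv"}), zygosity_mode="codominant")


def _calls(rows):
    return pd.DataFrame(rows, columns=["sample_id", "variant_key", "zygosity"])


PHENO = {"c1": "case", "c2": "case", "k1": "control", "k2": "control", "x": None}


class TestCarrierAggregation:
    def test_dominant_single_call(self):
        calls = _calls([("c1", "v1", "het"), ("k1", "v1", "hom_alt")])
        cs = collect_gene_carriers("g", calls, DEFAULT_MODELS["ptv"], {"v1"}, PHENO)
        assert cs.case_carriers == {"c1"} and cs.control_carriers == {"k1"}

    def test_recessive_compound_het(self):
        calls = _calls([("c1", "v1", "het"), ("c1", "v2", "het"), ("c2", "v1", "het")])
        cs = collect_gene_carriers("g", calls, DEFAULT_MODELS["rec"], {"v1", "v2"}, PHENO)
        assert cs.case_carriers == {"c1"}  # two distinct sites; c2 has one
        assert cs.control_carriers == set()

    def test_recessive_hom_and_hemi(self):
        calls = _calls([("c1", "v1", "hom_alt"), ("k1", "v1", "hemi")])
        cs = collect_gene_carriers("g", calls, DEFAULT_MODELS["rec"], {"v1"}, PHENO)
        assert cs.case_carriers == {"c1"} and cs.control_carriers == {"k1"}

    def test_no_qualifying_sites_empty(self):
        cs = collect_gene_carriers("g", _calls([]), DEFAULT_MODELS["ptv"], set(), PHENO)
        assert not cs.case_carriers and not cs.control_carriers

    def test_unphenotyped_samples_excluded(self):
        calls = _calls([("x", "v1", "het")])
        cs = collect_gene_carriers("g", calls, DEFAULT_MODELS["ptv"], {"v1"}, PHENO)
        assert not cs.case_carriers and not cs.control_carriers

    def test_carrier_monotonicity(self):
        """Shrinking the qualifying-site set never adds carriers."""
        rng = np.random.default_rng(11)
        rows = [
            (f"s{rng.integers(20)}", f"v{rng.integers(6)}", "het") for _ in range(60)
        ]
        pheno = {f"s{i}": ("case" if i < 10 else "control") for i in range(20)}
        calls = _calls(rows).drop_duplicates()
        full = {f"v{i}" for i in range(6)}
        for model in (DEFAULT_MODELS["ptv"], DEFAULT_MODELS["rec"]):
            big = collect_gene_carriers("g", calls, model, full, pheno)
            small = collect_gene_carriers("g", calls, model, set(list(full)[:3]), pheno)
            assert small.case_carriers <= big.case_carriers
            assert small.control_carriers <= big.control_carriers


class TestCarrierTable:
    def test_published_structure(self):
        cs = collect_gene_carriers(
            "g",
            _calls([(f"c{i}", "v1", "het") for i in range(9)]
                   + [(f"k{i}", "v1", "het") for i in range(54)]),
            DEFAULT_MODELS["ptv"],
            {"v1"},
            {**{f"c{i}": "case" for i in range(9)}, **{f"k{i}": "control" for i in range(54)}},
        )
        t = carrier_table(cs, 3702, 233378)
        assert (t.a, t.b, t.c, t.d) == (9, 3693, 54, 233324)
        assert t.a + t.b == 3702

    def test_zero_carriers(self):
        cs = collect_gene_carriers("g", _calls([]), DEFAULT_MODELS["ptv"], set(), PHENO)
        t = carrier_table(cs, 100, 1000)
        assert (t.a, t.b, t.c, t.d) == (0, 100, 0, 1000)

    def test_overflow_rejected(self):
        cs = collect_gene_carriers(
            "g",
            _calls([("c1", "v1", "het"), ("c2", "v1", "het")]),
            DEFAULT_MODELS["ptv"],
            {"v1"},
            PHENO,
        )
        with pytest.raises(ValueError):
            carrier_table(cs, 1, 1000)


def test_yaml_round_trip(tmp_path):
    path = tmp_path / "models.yaml"
    save_models(DEFAULT_MODELS, path)
    loaded = load_models(path)
    assert loaded == DEFAULT_MODELS


def test_qualifying_sites_vector_agrees_with_scalar(small_cohort):
    """The vectorised site selection matches per-site is_qualifying."""
    sites = small_cohort["sites"]
    ref = small_cohort["reference"]
    for name in ("ptv", "flexnonsynmtr", "syn", "UR"):
        model = DEFAULT_MODELS[name]
        chosen = set(qualifying_sites(sites, ref, model)["variant_key"])
        for row in sites.itertuples(index=False):
            site = VariantSite(
                chrom=str(row.chrom), pos=int(row.pos), ref=row.ref, alt=row.alt,
                gene=row.gene, consequence=row.consequence,
                internal_maf=float(row.internal_maf),
                internal_mac=int(row.internal_mac),
                mtr_intolerant=bool(row.mtr_intolerant),
            )
            assert (row.variant_key in chosen) == is_qualifying(
                site, ref.get(row.variant_key), model
            )
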