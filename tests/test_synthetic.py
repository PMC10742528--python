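import json

import pytest

from hippo import io_formats, synthetic
from hippo.cascade import max_population_af, passes_variant_type, run_hippo
from hippo.inheritance import build_trio, classify_single, find_comp_het
from hippo.synthetic import CohortSpec, PlantSpec


def test_same_seed_byte_identical(tmp_path):
    spec = CohortSpec(seed=3, n_families=2, variants_per_family=40,
                      planted=[PlantSpec("de_novo", "PG1", True)])
    a = synthetic.generate(spec, tmp_path / "a")
    b = synthetic.generate(spec, tmp_path / "b")
    assert (tmp_path / "a/cohort.vcf").read_bytes() == (tmp_path / "b/cohort.vcf").read_bytes()
    assert (tmp_path / "a/cohort.ped").read_bytes() == (tmp_path / "b/cohort.ped").read_bytes()
    assert a["manifest"] == b["manifest"]


def test_different_seed_differs(tmp_path):
    s1 = CohortSpec(seed=3, n_families=2, variants_per_family=40)
    s2 = CohortSpec(seed=4, n_families=2, variants_per_family=40)
    synthetic.generate(s1, tmp_path / "a")
    synthetic.generate(s2, tmp_path / "b")
    assert (tmp_path / "a/cohort.vcf").read_bytes() != (tmp_path / "b/cohort.vcf").read_bytes()


def test_x_linked_plant_in_female_proband_family_is_fatal(tmp_path):
    spec = CohortSpec(
        seed=1, n_families=2, variants_per_family=10,
        planted=[PlantSpec("de_novo", "PG1", True), PlantSpec("x_linked", "PGX", True)],
    )
    with pytest.raises(ValueError, match="female"):
        synthetic.generate(spec, tmp_path)


def test_manifest_predicates_hold_on_emitted_vcf(random_cohort):
    """Every predicate the truth manifest claims is recomputable from the
    emitted VCF and agrees."""
    variants = {v.key: v for v in random_cohort["variants"]}
    peds = {p.family_id: p for p in random_cohort["pedigrees"]}
    for m in random_cohort["out"]["manifest"]["planted"]:
        v = variants[m["key"]]
        ped = peds[m["family_id"]]
        pro = ped.member(m["proband_id"])
        pred = m["predicates"]
        dominant = m["model"] in ("de_novo", "clinvar_inherited")
        af_cap = 0.001 if dominant else 0.05
        assert pred["af_population_ok"] == (max_population_af(v) < af_cap)
        assert pred["af_cohort_ok"] == (v.cohort_af < 0.01)
        assert pred["variant_type_ok"] == passes_variant_type(v, 20)
        assert pred["cadd_ok"] == (v.cadd is None or v.cadd > 15)
        assert pred["clinvar_ok"] == (v.clinvar not in ("B", "LB"))
        call = v.calls[pro.sample_id]
        assert pred["genotype_quality_ok"] == (call.gq > 40)
        if call.gt == "het":
            r, a = call.allele_depths
            assert pred["allele_balance_ok"] == (a / (r + a) > 0.2)
        # inheritance claim
        trio = build_trio(v, ped, pro)
        model = classify_single(trio, 40).model
        if m["model"] == "de_novo":
            got = model == "de_novo"
        elif m["model"] == "hom_recessive":
            got = model == "hom_recessive"
        elif m["model"] == "x_linked":
            got = model == "x_linked_recessive"
        elif m["model"] == "clinvar_inherited":
            got = model in ("de_novo", "dominant_inherited") or (
                trio.proband.gt == "het" and model == "none" and v.clinvar in ("P", "LP")
            )
        else:  # comp_het: partner in trans
            partner = variants[m["partner_key"]]
            pairs = find_comp_het(
                [(v, trio), (partner, build_trio(partner, ped, pro))]
            )
            got = len(pairs) == 1
        assert got == pred["inheritance_ok"], m


def test_cis_comp_het_plant_absent_from_pair_search(tmp_path):
    spec = CohortSpec(
        seed=9, n_families=1, variants_per_family=5,
        planted=[PlantSpec("comp_het", "CISG", False, violation="inheritance")],
    )
    out = synthetic.generate(spec, tmp_path)
    peds = io_formats.read_ped(out["ped"])
    variants = io_formats.read_cohort_vcf(out["vcf"], peds)
    ped = peds[0]
    pro = ped.affected_probands()[0]
    gene_vs = [v for v in variants if v.gene == "CISG"]
    assert len(gene_vs) == 2
    items = [(v, build_trio(v, ped, pro)) for v in gene_vs]
    assert find_comp_het(items) == []


def test_background_rarely_passes(random_cohort):
    """Under the default background distributions fewer than 5% of
    non-planted variants survive the cascade."""
    cands = run_hippo(random_cohort["variants"], random_cohort["pedigrees"])
    bg = set(random_cohort["out"]["manifest"]["background_keys"])
    n_bg_pass = len({c.variant.key for c in cands if c.variant.key in bg})
    assert n_bg_pass / len(bg) < 0.05


# --- published-table fixtures ------------------------------------------------


def test_table4_has_14_expected_candidates(table4):
    manifest = table4["fx"]["manifest"]
    assert manifest["n_expected_candidates"] == 14
    assert len(manifest["variants"]) == 14
    # one VCF record per unique site/alt; the twin variant is shared
    assert len(table4["variants"]) == 13


def test_table4_printed_annotations(table4):
    by_gene = {}
    for v in table4["variants"]:
        by_gene.setdefault(v.gene, []).append(v)
    ppp1cb = by_gene["PPP1CB"][0]
    assert ppp1cb.cadd == 26.7
    assert ppp1cb.key == "2:28776944:C:G"
    abcc8 = by_gene["ABCC8"][0]
    assert abcc8.cadd == 43.0
    assert "stop_gained" in abcc8.consequence_terms
    carriers = [s for s, c in abcc8.calls.items() if c.carries_alt()]
    assert sorted(carriers) == ["FAM_5_14", "FAM_5_16"]  # proband + one parent
    hmgb1 = by_gene["HMGB1"][0]
    assert "frameshift" in hmgb1.consequence_terms
    assert hmgb1.calls["FAM_1_2"].gt == "hom_ref"
    assert hmgb1.calls["FAM_1_3"].gt == "hom_ref"


def test_table3_column_sums_match_published_totals():
    counts = synthetic.table3_fixture()
    assert sum(fc.n_assessed_hippo for fc in counts) == 109
    assert sum(fc.n_assessed_hippo_gencc for fc in counts) == 38
    assert sum(fc.n_assessed_gms for fc in counts) == 77
    fam4 = next(fc for fc in counts if fc.family_id == "FAM_4")
    assert fam4.n_assessed_hippo == 68
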