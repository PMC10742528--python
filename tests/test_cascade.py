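import dataclasses

import numpy as np
import pytest

from hippo import io_formats, synthetic
from hippo.cascade import (
    RULES,
    allele_balance,
    apply_exclusion_criteria,
    clinvar_gate,
    max_population_af,
    passes_insilico,
    passes_variant_type,
    restrict_to_gencc,
    run_hippo,
)
from hippo.models import (
    CandidateVariant,
    EvidenceFlags,
    GenCCRecord,
    HiPPoConfig,
    InheritanceCall,
)
from hippo.synthetic import CohortSpec, PlantSpec

from conftest import make_call, make_variant
import oracle


def test_max_population_af():
    v = make_variant(pop_afs={"gnomad_exomes": 1e-3, "topmed": 2e-3})
    assert max_population_af(v) == 2e-3
    assert max_population_af(make_variant(pop_afs={})) == 0.0
    assert max_population_af(v, exclude=("topmed",)) == 1e-3


def test_allele_balance():
    assert allele_balance(make_call(ad=(10, 10))) == 0.5
    assert allele_balance(make_call(ad=(18, 2))) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        allele_balance(make_call(ad=(0, 0)))
    with pytest.raises(ValueError):
        allele_balance(make_call(ad=None))


def test_variant_type_window_boundary():
    cfg = HiPPoConfig()
    assert passes_variant_type(make_variant(terms=("stop_gained",), dist=0), 20)
    assert not passes_variant_type(make_variant(terms=("synonymous",)), 20)
    near = make_variant(terms=("intron",), dist=20)
    far = make_variant(terms=("intron",), dist=21)
    assert passes_variant_type(near, cfg.coding_window_bp)
    assert not passes_variant_type(far, cfg.coding_window_bp)


def test_cadd_threshold_is_strict():
    cfg = HiPPoConfig()
    ok, trace = passes_insilico(make_variant(cadd=15.0), cfg)
    assert not ok and dict(trace)["cadd"] == "fail"
    ok, _ = passes_insilico(make_variant(cadd=15.01), cfg)
    assert ok


def test_spliceai_applies_only_to_splicing_variants():
    cfg = HiPPoConfig()
    splice = make_variant(terms=("splice_region",), dist=5, spliceai=0.1, cadd=20)
    ok, trace = passes_insilico(splice, cfg)
    assert not ok and dict(trace)["spliceai"] == "fail"
    coding = make_variant(terms=("missense",), spliceai=0.1, cadd=20)
    ok, trace = passes_insilico(coding, cfg)
    assert ok and dict(trace)["spliceai"] == "skipped"


def test_missing_scores_follow_policy():
    retain = HiPPoConfig()
    drop = HiPPoConfig(missing_score_policy="drop")
    v = make_variant(cadd=None)
    assert passes_insilico(v, retain)[0]
    assert not passes_insilico(v, drop)[0]


def test_clinvar_gate():
    assert clinvar_gate(make_variant(clinvar="B")) == "fail"
    assert clinvar_gate(make_variant(clinvar="LB")) == "fail"
    assert clinvar_gate(make_variant(clinvar="P")) == "override"
    assert clinvar_gate(make_variant(clinvar="none")) == "neutral"
    assert clinvar_gate(make_variant(clinvar="VUS")) == "neutral"


def test_clinvar_override_rescues_insilico_but_never_af():
    cfg = HiPPoConfig()
    rescued = make_variant(clinvar="P", cadd=5.0)
    ok, trace = passes_insilico(rescued, cfg)
    assert ok and dict(trace)["cadd"] == "overridden"
    # the AF cap stays unconditional: checked end to end below
    assert max_population_af(make_variant(pop_afs={"exac": 0.02})) > cfg.af_dominant


# --- end-to-end cascade ------------------------------------------------------


def test_curated_fixture_all_pass(table4):
    cands = run_hippo(table4["variants"], table4["pedigrees"])
    got = {(c.family_id, c.proband_id, c.variant.key, c.inheritance.model)
           for c in cands}
    want = {
        (m["family_id"], m["proband_id"], m["key"], m["model"])
        for m in table4["fx"]["manifest"]["variants"]
    }
    assert got == want


def test_pathogenic_variant_from_unaffected_parent_retained(table4):
    """The inherited stop-gain with a ClinVar LP assertion survives via the
    override even though the carrier parent is unaffected."""
    cands = run_hippo(table4["variants"], table4["pedigrees"])
    abcc8 = next(c for c in cands if c.variant.gene == "ABCC8")
    assert dict(c for c in abcc8.rule_trace)["inheritance"] == "overridden"
    assert not abcc8.inheritance.confirmed_de_novo


def test_planted_benign_common_variant_excluded(table4):
    """A common missense with a benign assertion never survives the
    dominant arm."""
    v = make_variant(
        key="5:1000:A:G",
        gene="NOISE1",
        pop_afs={"gnomad_exomes": 0.01},
        clinvar="B",
        calls={
            "FAM_1_1": make_call("FAM_1_1"),
            "FAM_1_2": make_call("FAM_1_2", "hom_ref", ad=(30, 0)),
            "FAM_1_3": make_call("FAM_1_3", "hom_ref", ad=(30, 0)),
        },
    )
    cands = run_hippo(table4["variants"] + [v], table4["pedigrees"])
    assert all(c.variant.key != v.key for c in cands)


def test_rule_trace_contains_every_rule_exactly_once(table4):
    for c in run_hippo(table4["variants"], table4["pedigrees"]):
        assert [r for r, _ in c.rule_trace] == list(RULES)


def test_candidate_constructor_rejects_failing_trace():
    v = make_variant(calls={"pro": make_call()})
    with pytest.raises(ValueError):
        CandidateVariant(
            variant=v,
            family_id="F",
            proband_id="pro",
            inheritance=InheritanceCall(model="de_novo"),
            rule_trace=[("cadd", "fail")],
        )


def test_matches_straightline_oracle_on_random_cohort(random_cohort):
    cands = run_hippo(random_cohort["variants"], random_cohort["pedigrees"])
    got = {(c.family_id, c.proband_id, c.variant.key) for c in cands}
    want = oracle.oracle_hippo(random_cohort["variants"], random_cohort["pedigrees"])
    assert got == want


TIGHTER = {
    "af_dominant": 1e-5,
    "af_recessive": 1e-4,
    "cohort_af_max": 1e-5,
    "coding_window_bp": 0,
    "spliceai_min": 0.9,
    "cadd_min": 35.0,
    "allele_balance_min": 0.45,
    "gq_min": 90,
    "missing_score_policy": "drop",
}


@pytest.mark.parametrize("field", sorted(TIGHTER))
def test_threshold_monotonicity(random_cohort, field):
    """Tightening any single threshold never increases the candidate count."""
    base = len(run_hippo(random_cohort["variants"], random_cohort["pedigrees"]))
    cfg = HiPPoConfig(**{field: TIGHTER[field]})
    tight = len(run_hippo(random_cohort["variants"], random_cohort["pedigrees"], cfg))
    assert tight <= base


def test_gencc_restriction_is_a_subset(random_cohort):
    cands = run_hippo(random_cohort["variants"], random_cohort["pedigrees"])
    sub = restrict_to_gencc(cands, random_cohort["gencc"])
    ids = lambda cs: {(c.family_id, c.proband_id, c.variant.key) for c in cs}
    assert ids(sub) <= ids(cands)
    assert all(c.strategy == "hippo_gencc" for c in sub)
    trusted = {
        r.gene_symbol
        for r in random_cohort["gencc"]
        if r.validity in ("definitive", "strong")
    }
    assert all(c.variant.gene in trusted for c in sub)


def test_gencc_validity_levels():
    cands = []
    for i, gene in enumerate(("GDEF", "GSTRONG", "GMOD")):
        v = make_variant(key=f"1:{100 + i}:A:T", gene=gene,
                         calls={"pro": make_call()})
        cands.append(
            CandidateVariant(
                variant=v, family_id="F", proband_id="pro",
                inheritance=InheritanceCall(model="de_novo"),
            )
        )
    gencc = [
        GenCCRecord("GDEF", "definitive"),
        GenCCRecord("GSTRONG", "strong"),
        GenCCRecord("GMOD", "moderate"),
    ]
    kept = {c.variant.gene for c in restrict_to_gencc(cands, gencc)}
    assert kept == {"GDEF", "GSTRONG"}


# --- reportability engine ----------------------------------------------------


def _cand(v, model="de_novo", proband="pro", partner=None):
    inh = InheritanceCall(
        model=model, partner_key=partner if model == "comp_het_member" else None
    )
    return CandidateVariant(
        variant=v, family_id="F", proband_id=proband, inheritance=inh
    )


def test_exclusion_defaults_open():
    v = make_variant(calls={"pro": make_call()})
    out = apply_exclusion_criteria([_cand(v)], [], [])
    assert out[0].reportable is True


def test_exclusion_clause_matrix():
    gencc = [GenCCRecord("KNOWN", "definitive")]
    known_het = make_variant(key="1:10:A:T", gene="KNOWN", calls={"pro": make_call()})
    novel = make_variant(key="1:20:A:T", gene="NOVEL", calls={"pro": make_call()})
    plof = make_variant(key="1:30:A:T", gene="NOVEL", terms=("stop_gained",),
                        calls={"pro": make_call()})

    def verdict(v, flags, **kw):
        return apply_exclusion_criteria([_cand(v, **kw)], [flags], gencc)[0].reportable

    # (1) single het in a recessive disease gene without a second hit
    assert verdict(known_het, EvidenceFlags("1:10:A:T", second_hit_found=False)) is False
    # ...but a comp-het member with the same flag stays
    assert verdict(known_het, EvidenceFlags("1:10:A:T", second_hit_found=False),
                   model="comp_het_member", partner="1:99:A:T") is True
    # (2) phenotype mismatch in a known gene
    assert verdict(known_het, EvidenceFlags("1:10:A:T", phenotype_match=False)) is False
    # (3) poor tissue expression of a known gene
    assert verdict(known_het, EvidenceFlags("1:10:A:T", tissue_expression_ok=False)) is False
    # (4) novel gene, implausible pathway
    assert verdict(novel, EvidenceFlags("1:20:A:T", pathway_plausible=False)) is False
    # (5) pLoF curated away
    assert verdict(plof, EvidenceFlags("1:30:A:T", lof_curation="not_LoF")) is False
    assert verdict(plof, EvidenceFlags("1:30:A:T", lof_curation="likely_LoF")) is True
    # (6) alignment artefact
    assert verdict(novel, EvidenceFlags("1:20:A:T", igv_artefact=True)) is False


def test_phenotype_mismatch_clinvar_carveout():
    """In a comp-het pair with a phenotype mismatch, the ClinVar pathogenic
    member survives clause 2 while the uncertain member is excluded."""
    gencc = [GenCCRecord("SDCCAG8", "definitive")]
    vp = make_variant(key="1:243341070:TG:T", gene="SDCCAG8", terms=("frameshift",),
                      clinvar="P", calls={"pro": make_call()})
    vv = make_variant(key="1:243378799:A:G", gene="SDCCAG8", clinvar="VUS",
                      calls={"pro": make_call()})
    cands = [
        _cand(vp, model="comp_het_member", partner=vv.key),
        _cand(vv, model="comp_het_member", partner=vp.key),
    ]
    evidence = [
        EvidenceFlags(vp.key, phenotype_match=False),
        EvidenceFlags(vv.key, phenotype_match=False),
    ]
    out = apply_exclusion_criteria(cands, evidence, gencc)
    verdicts = {c.variant.key: c.reportable for c in out}
    assert verdicts[vp.key] is True
    assert verdicts[vv.key] is False


def test_unmatched_evidence_warns():
    v = make_variant(calls={"pro": make_call()})
    with pytest.warns(UserWarning, match="no candidate"):
        apply_exclusion_criteria([_cand(v)], [EvidenceFlags("9:9:A:T")], [])


# --- planted-variant recovery ------------------------------------------------


def test_planted_recovery_single_de_novo(tmp_path):
    spec = CohortSpec(seed=5, n_families=2, variants_per_family=30,
                      planted=[PlantSpec("de_novo", "TARGET", True)])
    out = synthetic.generate(spec, tmp_path)
    peds = io_formats.read_ped(out["ped"])
    variants = io_formats.read_cohort_vcf(out["vcf"], peds)
    cands = run_hippo(variants, peds)
    plant = out["manifest"]["planted"][0]
    assert {(c.family_id, c.variant.key) for c in cands} >= {
        (plant["family_id"], plant["key"])
    }


@pytest.mark.parametrize("seed", range(20))
def test_planted_recovery_across_seeds(tmp_path, seed):
    """Plants constructed to satisfy the cascade are always recovered;
    plants constructed to violate one predicate never are."""
    plants = [
        PlantSpec("de_novo", "P_DN", True),
        PlantSpec("comp_het", "P_CH", True),
        PlantSpec("x_linked", "P_XL", True),
        PlantSpec("hom_recessive", "P_HR", True),
        PlantSpec("clinvar_inherited", "P_CI", True),
        PlantSpec("de_novo", "B_DN", False),
        PlantSpec("comp_het", "B_CH", False),
        PlantSpec("clinvar_inherited", "B_CI", False),
    ]
    spec = CohortSpec(seed=1000 + seed, n_families=3, variants_per_family=25,
                      planted=plants)
    out = synthetic.generate(spec, tmp_path / str(seed))
    peds = io_formats.read_ped(out["ped"])
    variants = io_formats.read_cohort_vcf(out["vcf"], peds)
    hits = {(c.family_id, c.variant.key) for c in run_hippo(variants, peds)}
    for m in out["manifest"]["planted"]:
        recovered = (m["family_id"], m["key"]) in hits
        assert recovered == m["satisfies_hippo"], m
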