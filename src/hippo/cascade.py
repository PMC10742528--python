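"""The panel-agnostic HiPPo filter cascade, GenCC restriction and the
reportability (exclusion-criteria) engine.

The cascade keeps a variant only when every rule is non-failing; each
candidate carries a full ordered rule trace with one entry per rule
(``pass`` / ``fail`` / ``overridden`` / ``skipped``).  A ClinVar P/LP
assertion overrides inheritance-model failures (a pathogenic variant is
retained even when carried by an unaffected parent) and in-silico score
failures, but never the allele-frequency caps: AF is an unconditional row
of the cascade and the cap is what keeps recurrent benign ClinVar
submissions out of the output.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

from .inheritance import build_trio, classify_single, find_comp_het
from .models import (
    AnnotatedVariant,
    CandidateVariant,
    EvidenceFlags,
    GenCCRecord,
    HiPPoConfig,
    InheritanceCall,
    Pedigree,
    SampleCall,
    TrioContext,
    variant_sort_key,
)

__all__ = [
    "RULES",
    "max_population_af",
    "allele_balance",
    "passes_variant_type",
    "passes_insilico",
    "clinvar_gate",
    "run_hippo",
    "restrict_to_gencc",
    "apply_exclusion_criteria",
]

# rule names, in cascade order; every candidate trace holds each exactly once
RULES = (
    "inheritance",
    "af_population",
    "af_cohort",
    "variant_type",
    "spliceai",
    "cadd",
    "clinvar",
    "genotype_quality",
    "allele_balance",
)

# canonical short-form SO terms regarded as coding
CODING_TERMS = frozenset(
    {
        "missense",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift",
        "inframe_deletion",
        "inframe_insertion",
        "protein_altering",
        "synonymous",
        "stop_retained",
        "start_retained",
        "coding_sequence",
        "transcript_ablation",
    }
)
SYNONYMOUS_TERMS = frozenset({"synonymous", "stop_retained", "start_retained"})
# "splicing variants" for the SpliceAI rule: variants whose qualifying
# consequences are all splice-region/intronic
SPLICE_TERMS = frozenset({"splice_donor", "splice_acceptor", "splice_region", "intron"})

PLOF_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift",
        "splice_donor",
        "splice_acceptor",
        "start_lost",
        "stop_lost",
        "transcript_ablation",
    }
)


def max_population_af(v: AnnotatedVariant, exclude: tuple[str, ...] = ()) -> float:
    """Maximum allele frequency across the present population sources.

    Returns 0.0 when no source is present (an unobserved allele).  ``exclude``
    drops sources from the maximisation (the panel-based emulation does not
    use TOPMED).
    """
    afs = [af for src, af in v.pop_afs.items() if src not in exclude]
    return max(afs) if afs else 0.0


def allele_balance(call: SampleCall) -> float:
    """Alt-read fraction of a call; undefined without usable depths."""
    if call.allele_depths is None:
        raise ValueError("allele depths absent")
    ref_reads, alt_reads = call.allele_depths
    total = ref_reads + alt_reads
    if total <= 0:
        raise ValueError("zero total reads")
    return alt_reads / total


def _qualifying_terms(v: AnnotatedVariant, window_bp: int) -> frozenset[str]:
    """Consequence terms that place the variant in scope: coding terms, or
    any term when the variant lies within ``window_bp`` of a coding exon."""
    if v.coding_distance_bp <= window_bp:
        return v.consequence_terms
    return frozenset(t for t in v.consequence_terms if t in CODING_TERMS)


def passes_variant_type(v: AnnotatedVariant, window_bp: int) -> bool:
    """Coding +/- window, excluding variants that are synonymous-only."""
    qual = _qualifying_terms(v, window_bp)
    if not qual:
        return False
    if qual <= SYNONYMOUS_TERMS:
        return False
    return True


def is_splicing_variant(v: AnnotatedVariant, window_bp: int) -> bool:
    qual = _qualifying_terms(v, window_bp)
    return bool(qual) and qual <= SPLICE_TERMS


def clinvar_gate(v: AnnotatedVariant) -> str:
    """ClinVar cascade outcome: 'fail' (B/LB), 'override' (P/LP) or 'neutral'."""
    if v.clinvar in ("B", "LB"):
        return "fail"
    if v.clinvar in ("P", "LP"):
        return "override"
    return "neutral"


def passes_insilico(
    v: AnnotatedVariant, cfg: HiPPoConfig
) -> tuple[bool, list[tuple[str, str]]]:
    """Apply the SpliceAI and CADD rules, honouring the missing-score policy
    and the ClinVar P/LP override.  Returns (ok, [(rule, outcome), ...])."""
    override = clinvar_gate(v) == "override"
    trace: list[tuple[str, str]] = []

    if is_splicing_variant(v, cfg.coding_window_bp):
        if v.spliceai is None:
            trace.append(("spliceai", "skipped" if cfg.missing_score_policy == "retain" else "fail"))
        elif v.spliceai > cfg.spliceai_min:
            trace.append(("spliceai", "pass"))
        else:
            trace.append(("spliceai", "overridden" if override else "fail"))
    else:
        trace.append(("spliceai", "skipped"))

    if v.cadd is None:
        trace.append(("cadd", "skipped" if cfg.missing_score_policy == "retain" else "fail"))
    elif v.cadd > cfg.cadd_min:
        trace.append(("cadd", "pass"))
    else:
        trace.append(("cadd", "overridden" if override else "fail"))

    ok = all(outcome != "fail" for _, outcome in trace)
    return ok, trace


def resolve_cohort_af(v: AnnotatedVariant, pedigrees: list[Pedigree]) -> float | None:
    """COHORT_AF when annotated; otherwise the founder allele frequency
    computed from the input calls."""
    if v.cohort_af is not None:
        return v.cohort_af
    n_alleles = 0
    n_alt = 0
    for ped in pedigrees:
        for f in ped.founders():
            call = v.calls.get(f.sample_id)
            if call is None or call.gt == "missing":
                continue
            ploidy = 1 if call.gt == "hemi" else 2
            n_alleles += ploidy
            n_alt += {"hom_ref": 0, "het": 1, "hom_alt": 2, "hemi": 1}[call.gt]
    if n_alleles == 0:
        return None
    return n_alt / n_alleles


def _evaluate_shared(
    v: AnnotatedVariant,
    call: SampleCall,
    cfg: HiPPoConfig,
    cohort_af: float | None,
    arm_af_cap: float,
) -> list[tuple[str, str]]:
    """The rules common to both arms, in cascade order (without inheritance)."""
    retain = cfg.missing_score_policy == "retain"
    trace: list[tuple[str, str]] = []

    trace.append(
        ("af_population", "pass" if max_population_af(v) < arm_af_cap else "fail")
    )
    if cohort_af is None:
        trace.append(("af_cohort", "skipped" if retain else "fail"))
    else:
        trace.append(("af_cohort", "pass" if cohort_af < cfg.cohort_af_max else "fail"))

    if passes_variant_type(v, cfg.coding_window_bp):
        trace.append(("variant_type", "pass"))
    elif (
        _qualifying_terms(v, cfg.coding_window_bp) <= SYNONYMOUS_TERMS
        and v.spliceai is not None
        and v.spliceai > cfg.spliceai_min
    ):
        # deviation from the strict coding rule: a synonymous variant with a
        # strong splice-disruption prediction is retained, flagged in trace
        trace.append(("variant_type", "overridden"))
    else:
        trace.append(("variant_type", "fail"))

    _, insilico_trace = passes_insilico(v, cfg)
    trace.extend(insilico_trace)

    gate = clinvar_gate(v)
    trace.append(("clinvar", "fail" if gate == "fail" else "pass"))

    if call.gq is None:
        trace.append(("genotype_quality", "skipped" if retain else "fail"))
    else:
        trace.append(("genotype_quality", "pass" if call.gq > cfg.gq_min else "fail"))

    if call.gt == "het":
        try:
            ab = allele_balance(call)
        except ValueError:
            trace.append(("allele_balance", "skipped" if retain else "fail"))
        else:
            trace.append(
                ("allele_balance", "pass" if ab > cfg.allele_balance_min else "fail")
            )
    else:
        trace.append(("allele_balance", "skipped"))
    return trace


def _ordered_trace(inh_outcome: str, shared: list[tuple[str, str]]) -> list[tuple[str, str]]:
    by_rule = dict(shared)
    by_rule["inheritance"] = inh_outcome
    return [(r, by_rule[r]) for r in RULES]


def _no_fail(trace: list[tuple[str, str]]) -> bool:
    return all(outcome != "fail" for _, outcome in trace)


def run_hippo(
    variants: list[AnnotatedVariant],
    pedigrees: list[Pedigree],
    cfg: HiPPoConfig | None = None,
) -> list[CandidateVariant]:
    """Run the full cascade over a cohort.

    Dominant arm: de novo / dominant calls under the stringent AF cap.
    Recessive arm: homozygous recessive, X-linked recessive and per-gene
    compound-het pairs under the relaxed AF cap.  All arms share the variant
    type, in-silico, ClinVar, call-quality and allele-balance rules.  Output
    is deterministic, ordered by (chrom, pos, ref, alt) then proband.
    """
    cfg = cfg or HiPPoConfig()
    cands: dict[tuple[str, str, str], CandidateVariant] = {}

    cohort_afs = {v.key: resolve_cohort_af(v, pedigrees) for v in variants}

    for ped in pedigrees:
        for proband in ped.affected_probands():
            # per-gene pool of comp-het-eligible variants for this proband
            eligible_pairs: dict[str, list[tuple[AnnotatedVariant, TrioContext, list]]] = {}
            for v in variants:
                call = v.calls.get(proband.sample_id)
                if call is None or not call.carries_alt():
                    continue
                trio = build_trio(v, ped, proband)
                inh = classify_single(trio, cfg.gq_min)
                gate = clinvar_gate(v)

                if inh.model in ("de_novo", "dominant_inherited") or (
                    call.gt == "het" and inh.model == "none" and gate == "override"
                ):
                    inh_outcome = "pass"
                    if inh.model == "none":
                        # pathogenic variant carried by an unaffected parent
                        inh = InheritanceCall(model="dominant_inherited")
                        inh_outcome = "overridden"
                    shared = _evaluate_shared(
                        v, call, cfg, cohort_afs[v.key], cfg.af_dominant
                    )
                    trace = _ordered_trace(inh_outcome, shared)
                    if _no_fail(trace):
                        cands[(ped.family_id, proband.sample_id, v.key)] = CandidateVariant(
                            variant=v,
                            family_id=ped.family_id,
                            proband_id=proband.sample_id,
                            inheritance=inh,
                            rule_trace=trace,
                            strategy="hippo",
                        )
                elif inh.model in ("hom_recessive", "x_linked_recessive"):
                    shared = _evaluate_shared(
                        v, call, cfg, cohort_afs[v.key], cfg.af_recessive
                    )
                    trace = _ordered_trace("pass", shared)
                    if _no_fail(trace):
                        cands[(ped.family_id, proband.sample_id, v.key)] = CandidateVariant(
                            variant=v,
                            family_id=ped.family_id,
                            proband_id=proband.sample_id,
                            inheritance=inh,
                            rule_trace=trace,
                            strategy="hippo",
                        )

                # comp-het eligibility: proband-het variant passing the shared
                # rules under the recessive AF cap, regardless of single-variant
                # model
                if call.gt == "het" and v.gene:
                    shared_rec = _evaluate_shared(
                        v, call, cfg, cohort_afs[v.key], cfg.af_recessive
                    )
                    if _no_fail(shared_rec):
                        eligible_pairs.setdefault(v.gene, []).append((v, trio, shared_rec))

            for gene, items in eligible_pairs.items():
                pairs = find_comp_het([(v, trio) for v, trio, _ in items])
                shared_by_key = {v.key: shared for v, _, shared in items}
                for v1, v2, phase_unknown in pairs:
                    for member, partner in ((v1, v2), (v2, v1)):
                        k = (ped.family_id, proband.sample_id, member.key)
                        if k in cands:
                            continue  # dominant/recessive single call takes precedence
                        inh = InheritanceCall(
                            model="comp_het_member",
                            partner_key=partner.key,
                            phase_unknown=phase_unknown,
                        )
                        cands[k] = CandidateVariant(
                            variant=member,
                            family_id=ped.family_id,
                            proband_id=proband.sample_id,
                            inheritance=inh,
                            rule_trace=_ordered_trace("pass", shared_by_key[member.key]),
                            strategy="hippo",
                        )

    out = list(cands.values())
    out.sort(key=lambda c: (variant_sort_key(c.variant.key), c.family_id, c.proband_id))
    return out


def restrict_to_gencc(
    cands: list[CandidateVariant], gencc: list[GenCCRecord]
) -> list[CandidateVariant]:
    """Subset to genes with definitive or strong disease-gene validity."""
    trusted = {r.gene_symbol for r in gencc if r.validity in ("definitive", "strong")}
    return [c.relabel("hippo_gencc") for c in cands if c.variant.gene in trusted]


def _is_plof(v: AnnotatedVariant) -> bool:
    return bool(v.consequence_terms & PLOF_TERMS)


def apply_exclusion_criteria(
    cands: list[CandidateVariant],
    evidence: list[EvidenceFlags],
    gencc: list[GenCCRecord],
) -> list[CandidateVariant]:
    """Set ``reportable`` on each candidate from curator evidence flags.

    A candidate is excluded when any rule fires; an unknown flag never fires
    a rule (the engine defaults open).  Rules: (1) het single hit in a
    recessive disease gene with no second hit found; (2) known disease gene,
    phenotype mismatch, and not ClinVar P/LP; (3) known disease gene poorly
    expressed in the relevant tissue; (4) novel gene poorly expressed or
    biologically implausible; (5) predicted LoF manually curated as (likely)
    not LoF; (6) an alignment artefact on read inspection.
    """
    by_key = {e.variant_key: e for e in evidence}
    cand_keys = {c.variant.key for c in cands}
    for k in by_key:
        if k not in cand_keys:
            warnings.warn(f"evidence for {k} matches no candidate")
    known_genes = {r.gene_symbol for r in gencc}

    out = []
    for c in cands:
        e = by_key.get(c.variant.key, EvidenceFlags(variant_key=c.variant.key))
        known = c.variant.gene in known_genes
        het_single = (
            c.variant.calls.get(c.proband_id, SampleCall(c.proband_id, "missing")).gt
            == "het"
            and c.inheritance.model != "comp_het_member"
        )
        fired = []
        if known and het_single and e.second_hit_found is False:
            fired.append(1)
        if known and e.phenotype_match is False and c.variant.clinvar not in ("P", "LP"):
            fired.append(2)
        if known and e.tissue_expression_ok is False:
            fired.append(3)
        if not known and (
            e.tissue_expression_ok is False or e.pathway_plausible is False
        ):
            fired.append(4)
        if _is_plof(c.variant) and e.lof_curation in ("likely_not_LoF", "not_LoF"):
            fired.append(5)
        if e.igv_artefact is True:
            fired.append(6)

        c2 = replace(c)
        c2.rule_trace = list(c.rule_trace)
        c2.reportable = not fired
        out.append(c2)
    return out
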