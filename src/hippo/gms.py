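"""Emulation of the panel-based clinical tiering strategy.

Variants are prefiltered on mode of inheritance, call quality, PASS status
and allele frequency, then tiered against the green genes of the applied
panels: Tier 1 for predicted loss-of-function or confirmed de novo variants
in a green gene, Tier 2 for other coding +/- 8 bp non-synonymous variants in
a green gene.  A complementary gene-agnostic branch assesses any coding
de novo (not filtered on quality) and the top-three Exomiser-ranked coding
variants with score >= 0.95.  Precedence when a variant qualifies twice:
tier1 > tier2 > ga_denovo > ga_exomiser.  Synonymous variants never tier.
No ClinVar, cohort-AF or in-silico rules exist in this strategy, and the
TOPMED frequency source is not consulted.
"""

from __future__ import annotations

from .cascade import PLOF_TERMS, max_population_af, passes_variant_type
from .inheritance import build_trio, classify_single, find_comp_het
from .models import (
    AnnotatedVariant,
    CandidateVariant,
    GMSConfig,
    InheritanceCall,
    PanelGene,
    Pedigree,
    TierAssignment,
    TrioContext,
    variant_sort_key,
)

__all__ = ["is_plof", "green_genes", "assign_tier", "run_gms"]

# population AF sources ignored by the panel-based strategy
GMS_EXCLUDED_AF_SOURCES = ("topmed",)


def is_plof(v: AnnotatedVariant) -> bool:
    """Predicted loss-of-function on any transcript."""
    return bool(v.consequence_terms & PLOF_TERMS)


def green_genes(panels: list[PanelGene]) -> dict[str, list[str]]:
    """gene -> sorted panel ids on which it is rated green (panels union)."""
    out: dict[str, set[str]] = {}
    for p in panels:
        if p.rating == "green":
            out.setdefault(p.gene_symbol, set()).add(p.panel_id)
    return {g: sorted(ids) for g, ids in out.items()}


def _af_ok(v: AnnotatedVariant, cap: float) -> bool:
    return max_population_af(v, exclude=GMS_EXCLUDED_AF_SOURCES) < cap


def assign_tier(
    v: AnnotatedVariant,
    trio: TrioContext,
    panels: list[PanelGene],
    cfg: GMSConfig | None = None,
    *,
    prefilter_ok: bool = True,
    comp_het_ok: bool = False,
) -> TierAssignment:
    """Assign the tier label for one variant call.

    ``prefilter_ok`` states whether the inheritance/quality/AF/PASS
    prefilters passed (panel tiers require them; the gene-agnostic branch
    does not).  ``comp_het_ok`` marks membership of a valid comp-het pair as
    an accepted recessive mode.
    """
    cfg = cfg or GMSConfig()
    green = green_genes(panels)
    coding_ok = passes_variant_type(v, cfg.coding_window_bp)
    panels_hit = tuple(green.get(v.gene, ()))

    inh = classify_single(trio, cfg.gq_min)
    arm_ok = (
        (inh.model in ("de_novo", "dominant_inherited") and _af_ok(v, cfg.af_dominant))
        or (
            inh.model in ("hom_recessive", "x_linked_recessive")
            and _af_ok(v, cfg.af_recessive)
        )
        or (comp_het_ok and _af_ok(v, cfg.af_recessive))
    )

    if prefilter_ok and arm_ok and coding_ok and panels_hit:
        if is_plof(v) or (inh.model == "de_novo" and inh.confirmed_de_novo):
            return TierAssignment(v.key, "tier1", panels_hit)
        return TierAssignment(v.key, "tier2", panels_hit)

    # gene-agnostic branch: any coding de novo, not filtered on quality
    inh_any_quality = classify_single(trio, 0)
    if (
        inh_any_quality.model == "de_novo"
        and coding_ok
        and _af_ok(v, cfg.af_dominant)
    ):
        return TierAssignment(v.key, "ga_denovo")

    if (
        v.exomiser_rank is not None
        and v.exomiser_rank <= cfg.exomiser_top_rank
        and v.exomiser_score is not None
        and v.exomiser_score >= cfg.exomiser_min_score
        and coding_ok
    ):
        return TierAssignment(v.key, "ga_exomiser")

    return TierAssignment(v.key, "untiered")


def run_gms(
    variants: list[AnnotatedVariant],
    pedigrees: list[Pedigree],
    panels: list[PanelGene],
    cfg: GMSConfig | None = None,
) -> list[CandidateVariant]:
    """Run the panel-based strategy; returns assessed variants only."""
    cfg = cfg or GMSConfig()
    out: list[CandidateVariant] = []

    for ped in pedigrees:
        for proband in ped.affected_probands():
            trios: dict[str, TrioContext] = {}
            carried: list[AnnotatedVariant] = []
            for v in variants:
                call = v.calls.get(proband.sample_id)
                if call is None or not call.carries_alt():
                    continue
                trios[v.key] = build_trio(v, ped, proband)
                carried.append(v)

            # comp-het pairs among prefilter-grade het variants per gene
            comp_het_keys: set[str] = set()
            by_gene: dict[str, list[tuple[AnnotatedVariant, TrioContext]]] = {}
            for v in carried:
                trio = trios[v.key]
                if (
                    trio.proband.gt == "het"
                    and v.gene
                    and _prefilter(v, trio, cfg)
                    and _af_ok(v, cfg.af_recessive)
                    and passes_variant_type(v, cfg.coding_window_bp)
                ):
                    by_gene.setdefault(v.gene, []).append((v, trio))
            for gene, items in by_gene.items():
                for v1, v2, _ in find_comp_het(items):
                    comp_het_keys.update((v1.key, v2.key))

            for v in carried:
                trio = trios[v.key]
                tier = assign_tier(
                    v,
                    trio,
                    panels,
                    cfg,
                    prefilter_ok=_prefilter(v, trio, cfg),
                    comp_het_ok=v.key in comp_het_keys,
                )
                if not tier.assessed:
                    continue
                inh = classify_single(trio, cfg.gq_min if tier.tier != "ga_denovo" else 0)
                trace = [
                    ("prefilter", "pass" if _prefilter(v, trio, cfg) else "skipped"),
                    ("tier", "pass"),
                ]
                out.append(
                    CandidateVariant(
                        variant=v,
                        family_id=ped.family_id,
                        proband_id=proband.sample_id,
                        inheritance=inh,
                        rule_trace=trace,
                        strategy="gms",
                        tier=tier,
                    )
                )

    out.sort(key=lambda c: (variant_sort_key(c.variant.key), c.family_id, c.proband_id))
    return out


def _prefilter(v: AnnotatedVariant, trio: TrioContext, cfg: GMSConfig) -> bool:
    """Quality/PASS prefilter shared by the panel tiers."""
    if cfg.require_pass_filter and not v.filter_pass:
        return False
    gq = trio.proband.gq
    return gq is not None and gq > cfg.gq_min
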