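"""Trio inheritance-model classification.

``classify_single`` is a pure function of the trio genotypes at one site.
A parent with a missing genotype is treated as absent at that site: a no-call
can neither confirm a transmission nor a de novo event.  Mitochondrial and
chrY variants are out of scope and classify as ``none``.

Compound heterozygotes are detected per gene from parental origin: a valid
pair has one allele attributable to the mother only and the other to the
father only (in trans), and no unaffected trio member carrying both.  With
an unsequenced parent, pairs whose phase cannot exclude cis are retained and
flagged ``phase_unknown`` (an incomplete trio should widen, not silence, the
recessive search).
"""

from __future__ import annotations

from .models import (
    AnnotatedVariant,
    InheritanceCall,
    Pedigree,
    PedigreeMember,
    SampleCall,
    TrioContext,
)

__all__ = ["build_trio", "classify_single", "find_comp_het"]

_NONE = InheritanceCall(model="none")


def build_trio(variant: AnnotatedVariant, pedigree: Pedigree,
               proband: PedigreeMember) -> TrioContext:
    """Assemble the trio context for one affected member at one site."""

    def usable(sample_id: str | None) -> SampleCall | None:
        if sample_id is None:
            return None
        call = variant.calls.get(sample_id)
        if call is None or call.gt == "missing":
            return None
        return call

    father = usable(proband.father_id)
    mother = usable(proband.mother_id)
    pcall = variant.calls.get(proband.sample_id)
    if pcall is None:
        pcall = SampleCall(sample_id=proband.sample_id, gt="missing")

    def status(pid: str | None) -> str:
        if pid is None:
            return "unknown"
        try:
            return pedigree.member(pid).affected
        except KeyError:
            return "unknown"

    return TrioContext(
        proband=pcall,
        father=father,
        mother=mother,
        proband_sex=proband.sex,
        chrom_class=variant.chrom_class,
        father_affected=status(proband.father_id),
        mother_affected=status(proband.mother_id),
    )


def _meets_gq(call: SampleCall | None, min_gq: int) -> bool:
    if call is None:
        return False
    if min_gq <= 0:
        return True
    return call.gq is not None and call.gq > min_gq


def classify_single(trio: TrioContext, min_gq: int = 40) -> InheritanceCall:
    """Classify one variant call under the trio inheritance models.

    Order of precedence: confirmed de novo, homozygous recessive, X-linked
    recessive, dominant/inherited.  ``dominant_inherited`` requires that no
    *unaffected* sequenced parent carries the allele; a carrier parent who is
    affected or of unknown status, or an absent parent, keeps the dominant
    reading open.  The ClinVar pathogenic override for variants carried by
    unaffected parents is applied downstream, never here.
    """
    p = trio.proband
    if p.gt in ("missing", "hom_ref"):
        return _NONE
    if trio.chrom_class in ("chrY", "MT"):
        return _NONE

    father, mother = trio.father, trio.mother
    male_x = trio.chrom_class == "chrX" and trio.proband_sex == "male"
    het_like = p.gt == "het" or (male_x and p.gt == "hemi")

    def carrier(call: SampleCall | None) -> bool:
        return call is not None and call.carries_alt()

    # de novo: both parents present, called hom_ref, all three calls confident
    if (
        het_like
        and father is not None
        and mother is not None
        and father.gt == "hom_ref"
        and mother.gt == "hom_ref"
        and _meets_gq(p, min_gq)
        and _meets_gq(father, min_gq)
        and _meets_gq(mother, min_gq)
    ):
        return InheritanceCall(model="de_novo", confirmed_de_novo=True)

    # homozygous recessive: each *present* parent must be a het carrier
    if p.gt == "hom_alt" and not male_x:
        ok = all(c is None or c.gt == "het" for c in (father, mother))
        if ok:
            return InheritanceCall(model="hom_recessive")
        return _NONE

    # X-linked recessive: hemizygous male, het carrier mother, father non-carrier
    if male_x and p.gt in ("hemi", "hom_alt"):
        if mother is not None and mother.gt == "het" and not carrier(father):
            return InheritanceCall(model="x_linked_recessive")
        # fall through: an apparent de novo hemizygous call without a
        # carrier mother is handled by the dominant/de-novo path above

    if p.gt == "het" or (male_x and p.gt == "hemi"):
        carriers = [
            (c, status)
            for c, status in ((father, trio.father_affected), (mother, trio.mother_affected))
            if carrier(c)
        ]
        if any(status == "no" for _, status in carriers):
            return _NONE
        return InheritanceCall(model="dominant_inherited")

    return _NONE


def _origin(variant: AnnotatedVariant, trio: TrioContext) -> str:
    """Parental origin of a proband-het allele: maternal / paternal /
    both / neither / unknown (a parent unsequenced)."""
    f, m = trio.father, trio.mother
    f_car = f is not None and f.carries_alt()
    m_car = m is not None and m.carries_alt()
    if f is None or m is None:
        if f_car:
            return "paternal"
        if m_car:
            return "maternal"
        return "unknown"
    if f_car and m_car:
        return "both"
    if f_car:
        return "paternal"
    if m_car:
        return "maternal"
    return "neither"


def find_comp_het(
    variants_in_gene: list[tuple[AnnotatedVariant, TrioContext]]
) -> list[tuple[AnnotatedVariant, AnnotatedVariant, bool]]:
    """Return candidate compound-het pairs (v1, v2, phase_unknown).

    All variants must share one gene.  Only proband-het variants pair.  A
    pair is excluded when it is provably cis (both alleles attributable to
    the same single parent) or when an unaffected sequenced parent carries
    both members.  ``phase_unknown`` is True unless one allele is maternal-
    only and the other paternal-only with both parents sequenced.
    """
    genes = {v.gene for v, _ in variants_in_gene}
    if len(genes) > 1:
        raise ValueError(f"variants from multiple genes: {sorted(genes)}")

    items = [
        (v, trio, _origin(v, trio))
        for v, trio in variants_in_gene
        if trio.proband.gt == "het"
    ]
    pairs: list[tuple[AnnotatedVariant, AnnotatedVariant, bool]] = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            v1, t1, o1 = items[i]
            v2, t2, o2 = items[j]
            if o1 == o2 and o1 in ("maternal", "paternal"):
                both_parents = (
                    t1.father is not None and t1.mother is not None
                    and t2.father is not None and t2.mother is not None
                )
                if both_parents:
                    continue  # provably cis
            # an unaffected sequenced parent carrying both alleles rules the
            # pair out (that parent would be a compound het themselves)
            excluded = False
            for role, status in (("father", t1.father_affected), ("mother", t1.mother_affected)):
                c1 = getattr(t1, role)
                c2 = getattr(t2, role)
                if (
                    status == "no"
                    and c1 is not None and c1.carries_alt()
                    and c2 is not None and c2.carries_alt()
                ):
                    excluded = True
            if excluded:
                continue
            phased = {o1, o2} == {"maternal", "paternal"}
            pairs.append((v1, v2, not phased))
    return pairs
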