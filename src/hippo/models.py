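"""Core domain types shared across the package.

Coordinates follow the VCF convention (1-based, inclusive) and every variant
is identified by the key ``chrom:pos:ref:alt`` after multi-allelic
decomposition.  Consequence terms are stored in a canonical short form with
the Sequence Ontology ``_variant`` suffix stripped (``missense``,
``stop_gained``, ``splice_donor`` ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "SampleCall",
    "PedigreeMember",
    "Pedigree",
    "GenCCRecord",
    "PanelGene",
    "EvidenceFlags",
    "AnnotatedVariant",
    "TrioContext",
    "InheritanceCall",
    "HiPPoConfig",
    "GMSConfig",
    "TierAssignment",
    "CandidateVariant",
    "FamilyCounts",
    "ComparisonReport",
    "CHROM_ORDER",
    "chrom_class",
    "variant_sort_key",
]

# chromosome ordering used for deterministic output
CHROM_ORDER = {str(i): i for i in range(1, 23)}
CHROM_ORDER.update({"X": 23, "Y": 24, "MT": 25, "M": 25})

GENCC_VALIDITIES = frozenset(
    {"definitive", "strong", "moderate", "limited", "disputed", "refuted", "other"}
)
PANEL_RATINGS = frozenset({"green", "amber", "red"})
CLINVAR_LEVELS = frozenset({"P", "LP", "VUS", "LB", "B", "none"})
LOF_CURATIONS = frozenset(
    {"LoF", "likely_LoF", "likely_not_LoF", "not_LoF", "unknown"}
)


def normalize_chrom(chrom: str) -> str:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return "MT" if c == "M" else c


def chrom_class(chrom: str) -> str:
    """Classify a chromosome name as autosome / chrX / chrY / MT."""
    c = normalize_chrom(chrom)
    if c == "X":
        return "chrX"
    if c == "Y":
        return "chrY"
    if c == "MT":
        return "MT"
    return "autosome"


def variant_sort_key(key: str) -> tuple:
    chrom, pos, ref, alt = key.split(":", 3)
    return (CHROM_ORDER.get(normalize_chrom(chrom), 99), int(pos), ref, alt, key)


@dataclass(frozen=True)
class SampleCall:
    """One sample's genotype call at one decomposed alt allele."""

    sample_id: str
    gt: str  # hom_ref | het | hom_alt | hemi | missing
    allele_depths: tuple[int, int] | None = None  # (ref_reads, alt_reads)
    gq: int | None = None
    filter_pass: bool = True

    def carries_alt(self) -> bool:
        return self.gt in ("het", "hom_alt", "hemi")


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # male | female | unknown
    affected: str  # yes | no | unknown


@dataclass
class Pedigree:
    """One family: members with resolved parent links.

    Invariants checked at construction: parent references resolve (or are
    None), at least one member is affected, and no member is its own
    ancestor.
    """

    family_id: str
    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        ids = {m.sample_id for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise ValueError(
                        f"{self.family_id}: parent {pid!r} of {m.sample_id!r} "
                        "is not a member of the family"
                    )
        if not any(m.affected == "yes" for m in self.members):
            raise ValueError(f"{self.family_id}: no affected member")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        by_id = {m.sample_id: m for m in self.members}
        for start in self.members:
            # walk the ancestor graph; revisiting the start means a cycle
            seen: set[str] = set()
            stack = [p for p in (start.father_id, start.mother_id) if p]
            while stack:
                sid = stack.pop()
                if sid == start.sample_id:
                    raise ValueError(
                        f"{self.family_id}: {start.sample_id!r} is its own ancestor"
                    )
                if sid in seen:
                    continue
                seen.add(sid)
                mem = by_id.get(sid)
                if mem is not None:
                    stack.extend(p for p in (mem.father_id, mem.mother_id) if p)

    def member(self, sample_id: str) -> PedigreeMember:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    def affected_probands(self) -> list[PedigreeMember]:
        """Affected members analysed as trio-unit probands."""
        return [m for m in self.members if m.affected == "yes"]

    def founders(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.father_id is None and m.mother_id is None]


@dataclass(frozen=True)
class GenCCRecord:
    gene_symbol: str
    validity: str

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("empty gene symbol")
        if self.validity not in GENCC_VALIDITIES:
            raise ValueError(f"unrecognised GenCC validity {self.validity!r}")


@dataclass(frozen=True)
class PanelGene:
    panel_id: str
    gene_symbol: str
    rating: str

    def __post_init__(self) -> None:
        if self.rating not in PANEL_RATINGS:
            raise ValueError(f"unrecognised panel rating {self.rating!r}")


@dataclass(frozen=True)
class EvidenceFlags:
    """Curator-supplied evidence for the reportability exclusion rules.

    ``None`` means unknown, the default for every field; unknown evidence
    never fires an exclusion rule.
    """

    variant_key: str
    second_hit_found: bool | None = None
    phenotype_match: bool | None = None
    tissue_expression_ok: bool | None = None
    pathway_plausible: bool | None = None
    lof_curation: str = "unknown"
    igv_artefact: bool | None = None

    def __post_init__(self) -> None:
        if self.lof_curation not in LOF_CURATIONS:
            raise ValueError(f"unrecognised LoF curation {self.lof_curation!r}")


@dataclass
class AnnotatedVariant:
    """One alt allele at one site with annotations and per-sample calls.

    Missing annotations are ``None`` (absent), never a numeric default.
    ``pop_afs`` maps source name (``gnomad_exomes``, ``gnomad_genomes``,
    ``topmed``, ``exac``, ``kg``) to the allele frequency in that population.
    """

    key: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence_terms: frozenset[str]
    coding_distance_bp: int = 0
    pop_afs: dict[str, float] = field(default_factory=dict)
    cohort_af: float | None = None
    cadd: float | None = None
    revel: float | None = None
    spliceai: float | None = None
    clinvar: str = "none"
    exomiser_rank: int | None = None
    exomiser_score: float | None = None
    calls: dict[str, SampleCall] = field(default_factory=dict)
    filter_pass: bool = True

    def __post_init__(self) -> None:
        if self.clinvar not in CLINVAR_LEVELS:
            raise ValueError(f"unrecognised ClinVar level {self.clinvar!r}")

    @property
    def chrom_class(self) -> str:
        return chrom_class(self.chrom)


@dataclass(frozen=True)
class TrioContext:
    """Pedigree roles and usable calls for one proband at one site.

    A parent whose genotype is missing at the site is represented as absent
    (transmission cannot be confirmed from a no-call).
    """

    proband: SampleCall
    father: SampleCall | None
    mother: SampleCall | None
    proband_sex: str
    chrom_class: str
    father_affected: str = "no"
    mother_affected: str = "no"


@dataclass(frozen=True)
class InheritanceCall:
    model: str  # de_novo | dominant_inherited | hom_recessive | x_linked_recessive | comp_het_member | none
    partner_key: str | None = None
    confirmed_de_novo: bool = False
    phase_unknown: bool = False

    def __post_init__(self) -> None:
        if (self.partner_key is not None) != (self.model == "comp_het_member"):
            raise ValueError("partner_key present iff model is comp_het_member")


@dataclass(frozen=True)
class HiPPoConfig:
    """Thresholds of the panel-agnostic cascade (research-exome defaults).

    All comparisons are strict in the documented direction: population AF
    < af_dominant / af_recessive, cohort AF < cohort_af_max, CADD > cadd_min,
    SpliceAI > spliceai_min, GQ > gq_min, allele balance > allele_balance_min.
    ``missing_score_policy`` controls variants lacking CADD/SpliceAI/AD/GQ:
    ``retain`` fails open (a pathogenicity filter should not discard a
    variant for absent evidence), ``drop`` fails closed.
    """

    af_dominant: float = 0.001
    af_recessive: float = 0.05
    cohort_af_max: float = 0.01
    coding_window_bp: int = 20
    spliceai_min: float = 0.2
    cadd_min: float = 15.0
    allele_balance_min: float = 0.2
    gq_min: int = 40
    missing_score_policy: str = "retain"  # retain | drop

    def __post_init__(self) -> None:
        if self.missing_score_policy not in ("retain", "drop"):
            raise ValueError("missing_score_policy must be 'retain' or 'drop'")
        for name in ("af_dominant", "af_recessive", "cohort_af_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} out of [0, 1]")


@dataclass(frozen=True)
class GMSConfig:
    """Thresholds of the panel-based tiering emulation (NHS genome column)."""

    af_dominant: float = 0.001
    af_recessive: float = 0.01
    coding_window_bp: int = 8
    gq_min: int = 30
    exomiser_top_rank: int = 3
    exomiser_min_score: float = 0.95
    require_pass_filter: bool = True


@dataclass(frozen=True)
class TierAssignment:
    variant_key: str
    tier: str  # tier1 | tier2 | ga_denovo | ga_exomiser | untiered
    panels_hit: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tier in ("tier1", "tier2") and not self.panels_hit:
            raise ValueError(f"{self.tier} requires at least one panel hit")

    @property
    def assessed(self) -> bool:
        return self.tier != "untiered"


@dataclass
class CandidateVariant:
    """A variant that survived a strategy, with per-rule provenance."""

    variant: AnnotatedVariant
    family_id: str
    proband_id: str
    inheritance: InheritanceCall
    rule_trace: list[tuple[str, str]] = field(default_factory=list)
    strategy: str = "hippo"  # hippo | hippo_gencc | gms
    reportable: bool | None = None  # None = undetermined
    diagnostic: bool = False
    tier: TierAssignment | None = None

    def __post_init__(self) -> None:
        if any(outcome == "fail" for _, outcome in self.rule_trace):
            raise ValueError("candidate constructed with a failing rule")

    def relabel(self, strategy: str) -> "CandidateVariant":
        c = replace(self)
        c.strategy = strategy
        c.rule_trace = list(self.rule_trace)
        return c


@dataclass
class FamilyCounts:
    """Per-family assessed / diagnostic / reportable counts and HPO tallies."""

    family_id: str
    n_assessed_hippo: int = 0
    n_assessed_hippo_gencc: int = 0
    n_assessed_gms: int = 0
    n_diagnostic_hippo: int = 0
    n_diagnostic_hippo_gencc: int = 0
    n_diagnostic_gms: int = 0
    n_reportable_hippo: int = 0
    n_reportable_hippo_gencc: int = 0
    n_reportable_gms: int = 0
    n_hpo_research: int = 0
    n_hpo_clinical: int = 0

    def __post_init__(self) -> None:
        for strat in ("hippo", "gms"):
            d = getattr(self, f"n_diagnostic_{strat}")
            r = getattr(self, f"n_reportable_{strat}")
            a = getattr(self, f"n_assessed_{strat}")
            if not 0 <= d <= r <= a:
                raise ValueError(
                    f"{self.family_id}/{strat}: need diagnostic <= reportable <= assessed"
                )


@dataclass
class ComparisonReport:
    per_family: list[FamilyCounts]
    excluded_families: list[str]
    rates: dict
    wilcoxon: dict
    fisher: dict

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "per_family": [asdict(fc) for fc in self.per_family],
            "excluded_families": list(self.excluded_families),
            "rates": self.rates,
            "wilcoxon": self.wilcoxon,
            "fisher": self.fisher,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        return cls(
            per_family=[FamilyCounts(**fc) for fc in d["per_family"]],
            excluded_families=list(d["excluded_families"]),
            rates=d["rates"],
            wilcoxon=d["wilcoxon"],
            fisher=d["fisher"],
        )
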