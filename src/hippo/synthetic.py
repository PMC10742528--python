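"""Synthetic trio cohorts and the published-table fixtures.

The generator emulates a joint-called rare-disease trio cohort: a handful of
families, a background of mostly common, mostly benign coding and
near-coding variants drawn with Mendelian transmission from founder
genotypes, and a small set of *planted* variants constructed to satisfy — or
deliberately violate — the filter cascade under a named inheritance model.
Every run emits a truth manifest recording, per planted variant, the
intended model and whether each cascade predicate holds by construction, so
recovery is checkable without re-deriving intent from the data.

It emulates allele frequencies, annotation scores, call quality and simple
genotyping noise (occasional false de novo calls).  It does not emulate
linkage, haplotype structure, mosaicism or read-level artefacts; a clean
pass on synthetic data therefore validates the filter logic, not robustness
to upstream calling errors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .models import CHROM_ORDER, FamilyCounts

__all__ = [
    "PlantSpec",
    "CohortSpec",
    "generate",
    "table4_fixture",
    "table3_fixture",
    "TABLE3_DIAGNOSTIC_KEYS",
]

PLANT_MODELS = (
    "de_novo",
    "comp_het",
    "hom_recessive",
    "x_linked",
    "clinvar_inherited",
)

VIOLATIONS = (
    "af_population",
    "cadd",
    "variant_type_synonymous",
    "allele_balance",
    "genotype_quality",
    "clinvar_benign",
    "inheritance",
)


@dataclass(frozen=True)
class PlantSpec:
    model: str
    gene: str
    satisfies_hippo: bool = True
    on_panel: bool = False
    violation: str | None = None  # auto-chosen when not satisfying

    def __post_init__(self) -> None:
        if self.model not in PLANT_MODELS:
            raise ValueError(f"unknown plant model {self.model!r}")
        if self.violation is not None and self.violation not in VIOLATIONS:
            raise ValueError(f"unknown violation {self.violation!r}")


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort (seed is mandatory)."""

    seed: int
    n_families: int = 8
    variants_per_family: int = 150
    planted: list[PlantSpec] = field(default_factory=list)
    af_distribution: str = "rare_disease_background"
    score_distribution: str = "default"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.planted) > self.variants_per_family:
            raise ValueError("more plants than variants per family")


VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=GNOMAD_EX_AF,Number=A,Type=Float,Description="gnomAD exomes AF">',
    '##INFO=<ID=GNOMAD_WG_AF,Number=A,Type=Float,Description="gnomAD genomes AF">',
    '##INFO=<ID=TOPMED_AF,Number=A,Type=Float,Description="TOPMed AF">',
    '##INFO=<ID=EXAC_AF,Number=A,Type=Float,Description="ExAC AF">',
    '##INFO=<ID=KG_AF,Number=A,Type=Float,Description="1000 Genomes AF">',
    '##INFO=<ID=COHORT_AF,Number=A,Type=Float,Description="joint-call cohort AF">',
    '##INFO=<ID=CADD_PHRED,Number=A,Type=Float,Description="CADD PHRED score">',
    '##INFO=<ID=REVEL,Number=A,Type=Float,Description="REVEL score">',
    '##INFO=<ID=SPLICEAI_DS,Number=A,Type=Float,Description="SpliceAI max delta score">',
    '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar significance (P/LP/VUS/LB/B)">',
    '##INFO=<ID=EXOMISER_RANK,Number=1,Type=Integer,Description="Exomiser rank">',
    '##INFO=<ID=EXOMISER_SCORE,Number=1,Type=Float,Description="Exomiser score">',
    '##INFO=<ID=CSQ_GENE,Number=1,Type=String,Description="gene symbol">',
    '##INFO=<ID=CSQ_TERMS,Number=1,Type=String,Description="comma list of SO consequence terms">',
    '##INFO=<ID=CSQ_DIST,Number=1,Type=Integer,Description="bp to nearest coding exon (0 if coding)">',
    '##FILTER=<ID=lowq,Description="low call quality">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
]
_CONTIGS = [str(i) for i in range(1, 23)] + ["X"]


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _info_str(d: dict) -> str:
    parts = []
    for k, v in d.items():
        if v is None:
            continue
        parts.append(f"{k}={v}")
    return ";".join(parts) if parts else "."


def _write_vcf(path: Path, samples: list[str], rows: list[dict]) -> None:
    rows = sorted(rows, key=lambda r: (CHROM_ORDER[r["chrom"]], r["pos"], r["ref"], r["alt"]))
    with open(path, "w") as fh:
        for line in VCF_HEADER_LINES:
            fh.write(line + "\n")
        for c in _CONTIGS:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for r in rows:
            gts = []
            for s in samples:
                gt, ad, gq = r["calls"].get(s, ("0/0", (30, 0), 60))
                gts.append(f"{gt}:{ad[0]},{ad[1]}:{gq}")
            fh.write(
                "\t".join(
                    [
                        r["chrom"],
                        str(r["pos"]),
                        ".",
                        r["ref"],
                        r["alt"],
                        "100",
                        r.get("filter", "PASS"),
                        _info_str(r["info"]),
                        "GT:AD:GQ",
                    ]
                    + gts
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# random cohorts with planted variants


def _family_layout(n_families: int) -> list[dict]:
    """Deterministic family structures: odd-numbered families have a male
    proband, even-numbered a female one."""
    fams = []
    for k in range(1, n_families + 1):
        fam = f"FAM_{k}"
        fams.append(
            {
                "family_id": fam,
                "proband": f"{fam}_p",
                "father": f"{fam}_f",
                "mother": f"{fam}_m",
                "proband_sex": "male" if k % 2 == 1 else "female",
            }
        )
    return fams


def _ped_lines(families: list[dict]) -> str:
    lines = []
    for f in families:
        sex = "1" if f["proband_sex"] == "male" else "2"
        lines.append(
            f"{f['family_id']}\t{f['proband']}\t{f['father']}\t{f['mother']}\t{sex}\t2"
        )
        lines.append(f"{f['family_id']}\t{f['father']}\t0\t0\t1\t1")
        lines.append(f"{f['family_id']}\t{f['mother']}\t0\t0\t2\t1")
    return "\n".join(lines) + "\n"


def _draw_background(rng: np.random.Generator):
    u = rng.random()
    if u < 0.55:
        af = rng.uniform(0.01, 0.5)
    elif u < 0.80:
        af = rng.uniform(0.001, 0.01)
    else:
        af = rng.uniform(1e-6, 0.001)
    cons_terms = ["missense", "synonymous", "intron", "splice_region",
                  "stop_gained", "frameshift", "5_prime_UTR"]
    cons = cons_terms[rng.choice(7, p=[0.40, 0.20, 0.15, 0.07, 0.05, 0.05, 0.08])]
    if cons in ("missense", "synonymous", "stop_gained", "frameshift"):
        dist = 0
    elif cons == "splice_region":
        dist = int(rng.integers(1, 9))
    else:
        dist = int(rng.integers(1, 101))
    cadd = float(rng.gamma(2.0, 4.0)) if rng.random() < 0.92 else None
    spliceai = (
        float(rng.beta(0.4, 8.0))
        if cons in ("intron", "splice_region") and rng.random() < 0.8
        else None
    )
    u = rng.random()
    clinvar = "B" if u < 0.03 else "LB" if u < 0.05 else "P" if u < 0.055 else "none"
    return af, cons, dist, cadd, spliceai, clinvar


def _het_ad(rng: np.random.Generator) -> tuple[int, int]:
    depth = int(rng.poisson(30)) + 6
    frac = 0.12 if rng.random() < 0.03 else 0.5
    alt = int(rng.binomial(depth, frac))
    return depth - alt, alt


def _gq(rng: np.random.Generator) -> int:
    return int(rng.integers(41, 100)) if rng.random() < 0.95 else int(rng.integers(10, 41))


def _transmit(rng: np.random.Generator, af: float) -> tuple[int, int, int]:
    """Founder allele counts and the transmitted proband count."""
    fa = int(rng.binomial(2, af))
    mo = int(rng.binomial(2, af))
    pa = int(rng.random() < fa / 2) + int(rng.random() < mo / 2)
    return fa, mo, pa


def _gt_str(n_alt: int, ploidy: int = 2) -> str:
    if ploidy == 1:
        return str(n_alt)
    return ("0/0", "0/1", "1/1")[n_alt]


def _call(rng, n_alt: int, ploidy: int = 2, gq: int | None = None):
    if ploidy == 1:
        ad = (0, 20) if n_alt else (20, 0)
    elif n_alt == 1:
        ad = _het_ad(rng)
    elif n_alt == 2:
        ad = (0, int(rng.poisson(30)) + 6)
    else:
        ad = (int(rng.poisson(30)) + 6, 0)
    return (_gt_str(n_alt, ploidy), ad, gq if gq is not None else _gq(rng))


def _plant_predicates(attrs: dict, arm: str) -> dict:
    """Cascade predicates recorded in the truth manifest, by construction."""
    af_cap = 0.001 if arm == "dominant" else 0.05
    qual_syn = attrs["consequence"] == "synonymous"
    return {
        "inheritance_ok": attrs["inheritance_ok"],
        "af_population_ok": attrs["af"] < af_cap,
        "af_cohort_ok": attrs["cohort_af"] < 0.01,
        "variant_type_ok": not qual_syn,
        "cadd_ok": attrs["cadd"] is None or attrs["cadd"] > 15,
        "spliceai_ok": True,
        "clinvar_ok": attrs["clinvar"] not in ("B", "LB"),
        "genotype_quality_ok": attrs["proband_gq"] > 40,
        "allele_balance_ok": attrs["ab_ok"],
    }


def generate(spec: CohortSpec, out_dir) -> dict:
    """Generate VCF + PED + GenCC/panel/evidence tables + truth manifest.

    Deterministic given ``spec.seed``: one RNG stream per family for
    genotype draws plus one cohort-level stream for annotations.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    families = _family_layout(spec.n_families)
    samples = [s for f in families for s in (f["proband"], f["father"], f["mother"])]
    fam_rngs = [np.random.default_rng([spec.seed, k]) for k in range(spec.n_families)]
    ann_rng = np.random.default_rng([spec.seed, 1_000_003])

    # gene loci: background pool plus one dedicated locus per plant gene
    genes: dict[str, tuple[str, int]] = {}
    for i in range(300):
        chrom = _CONTIGS[i % len(_CONTIGS)]
        genes[f"GENE{i:03d}"] = (chrom, 1_000_000 + (i // len(_CONTIGS)) * 2_000_000)
    next_plant_locus = 0
    gene_cursor: dict[str, int] = {}

    def next_pos(gene: str) -> tuple[str, int]:
        chrom, base = genes[gene]
        off = gene_cursor.get(gene, 0)
        gene_cursor[gene] = off + 1
        return chrom, base + 61 * off

    rows: list[dict] = []
    manifest_plants: list[dict] = []

    # --- planted variants -------------------------------------------------
    violation_cycle = 0
    for i, plant in enumerate(spec.planted):
        fam = families[i % spec.n_families]
        frng = fam_rngs[i % spec.n_families]
        if plant.model == "x_linked" and fam["proband_sex"] != "male":
            raise ValueError(
                f"cannot plant an X-linked recessive variant in {fam['family_id']}: "
                "the proband is female (hemizygosity requires a male proband)"
            )
        if plant.gene not in genes:
            chrom = "X" if plant.model == "x_linked" else _CONTIGS[next_plant_locus % 22]
            genes[plant.gene] = (chrom, 120_000_000 + next_plant_locus * 3_000_000)
            next_plant_locus += 1

        violation = None
        if not plant.satisfies_hippo:
            violation = plant.violation or VIOLATIONS[violation_cycle % len(VIOLATIONS)]
            violation_cycle += 1
            # the allele-balance rule only applies to heterozygous calls
            if violation == "allele_balance" and plant.model in (
                "hom_recessive",
                "x_linked",
            ):
                violation = "cadd"

        arm = "dominant" if plant.model in ("de_novo", "clinvar_inherited") else "recessive"
        n_members = 2 if plant.model == "comp_het" else 1
        member_keys = []
        for j in range(n_members):
            af = 1e-4 if arm == "dominant" else 5e-3
            cohort_af = 3.3e-5
            cadd = 28.0
            consequence = "missense"
            clinvar = "P" if plant.model == "clinvar_inherited" else "none"
            proband_gq = 60
            ab_ok = True
            proband_ad = (14, 13)
            inheritance_ok = True

            # genotype pattern per model (counts: proband, father, mother)
            hemi = plant.model == "x_linked"
            if plant.model == "de_novo":
                pat = (1, 0, 0)
            elif plant.model == "clinvar_inherited":
                pat = (1, 1, 0)
            elif plant.model == "hom_recessive":
                pat = (2, 1, 1)
                proband_ad = (0, 27)
            elif plant.model == "x_linked":
                pat = (1, 0, 1)
                proband_ad = (0, 22)
            else:  # comp_het: one paternal, one maternal
                pat = (1, 1, 0) if j == 0 else (1, 0, 1)

            if violation == "af_population":
                af = 0.05 if arm == "dominant" else 0.08
                inheritance_ok = True
            elif violation == "cadd":
                cadd = 5.0
            elif violation == "variant_type_synonymous":
                consequence = "synonymous"
            elif violation == "allele_balance":
                proband_ad = (26, 4) if pat[0] == 1 and not hemi else proband_ad
                ab_ok = not (pat[0] == 1 and not hemi)
            elif violation == "genotype_quality":
                proband_gq = 20
            elif violation == "clinvar_benign":
                clinvar = "B"
            elif violation == "inheritance":
                inheritance_ok = False
                if plant.model in ("de_novo", "clinvar_inherited"):
                    pat = (1, 1, 0)
                    clinvar = "none"  # unaffected carrier father, no rescue
                elif plant.model == "hom_recessive":
                    pat = (2, 0, 1)
                elif plant.model == "x_linked":
                    pat = (1, 1, 0)  # carrier father, mother non-carrier
                else:
                    pat = (1, 0, 1) if j == 0 else (1, 0, 1)  # both maternal: cis

            chrom, pos = next_pos(plant.gene)
            if hemi and chrom != "X":
                raise ValueError(f"x_linked plant gene {plant.gene} not on chrX")
            p_ploidy = 1 if hemi else 2
            f_ploidy = 1 if hemi else 2
            calls = {
                fam["proband"]: (
                    _gt_str(pat[0], p_ploidy),
                    proband_ad,
                    proband_gq,
                ),
                fam["father"]: _call(frng, pat[1], f_ploidy),
                fam["mother"]: _call(frng, pat[2]),
            }
            info = {
                "GNOMAD_EX_AF": _fmt(af),
                "GNOMAD_WG_AF": _fmt(af),
                "COHORT_AF": _fmt(cohort_af),
                "CADD_PHRED": _fmt(cadd) if cadd is not None else None,
                "CLNSIG": None if clinvar == "none" else clinvar,
                "CSQ_GENE": plant.gene,
                "CSQ_TERMS": consequence,
                "CSQ_DIST": 0,
            }
            key = f"{chrom}:{pos}:C:T"
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": "C",
                    "alt": "T",
                    "info": info,
                    "calls": calls,
                    "filter": "PASS",
                }
            )
            member_keys.append(key)
            attrs = {
                "af": af,
                "cohort_af": cohort_af,
                "cadd": cadd,
                "consequence": consequence,
                "clinvar": clinvar,
                "proband_gq": proband_gq,
                "ab_ok": ab_ok,
                "inheritance_ok": inheritance_ok,
            }
            predicates = _plant_predicates(attrs, arm)
            if plant.satisfies_hippo != all(predicates.values()):
                raise AssertionError(
                    f"plant construction inconsistent for {plant.gene}: "
                    f"{predicates}"
                )
            manifest_plants.append(
                {
                    "key": key,
                    "gene": plant.gene,
                    "family_id": fam["family_id"],
                    "proband_id": fam["proband"],
                    "model": plant.model,
                    "satisfies_hippo": plant.satisfies_hippo,
                    "on_panel": plant.on_panel,
                    "violation": violation,
                    "predicates": predicates,
                }
            )
        if n_members == 2:
            for mk, other in zip(member_keys, reversed(member_keys)):
                for mp in manifest_plants:
                    if mp["key"] == mk and mp["family_id"] == fam["family_id"]:
                        mp["partner_key"] = other

    # --- background variants ---------------------------------------------
    n_background = spec.n_families * spec.variants_per_family - len(
        [m for m in manifest_plants]
    )
    bg_genes = [f"GENE{i:03d}" for i in range(300)]
    background_keys = []
    for _ in range(max(0, n_background)):
        gene = bg_genes[int(ann_rng.integers(0, 300))]
        chrom, pos = next_pos(gene)
        af, cons, dist, cadd, spliceai, clinvar = _draw_background(ann_rng)
        calls = {}
        for f, frng in zip(families, fam_rngs):
            fa, mo, pa = _transmit(frng, af)
            if frng.random() < 0.003:  # genotyping noise: false de novo call
                pa, fa, mo = 1, 0, 0
            calls[f["proband"]] = _call(frng, pa)
            calls[f["father"]] = _call(frng, fa)
            calls[f["mother"]] = _call(frng, mo)
        info = {
            "GNOMAD_EX_AF": _fmt(af),
            "GNOMAD_WG_AF": _fmt(max(0.0, af * float(ann_rng.uniform(0.8, 1.2)))),
            "TOPMED_AF": _fmt(af) if ann_rng.random() < 0.7 else None,
            "COHORT_AF": _fmt(af),
            "CADD_PHRED": _fmt(cadd) if cadd is not None else None,
            "SPLICEAI_DS": _fmt(spliceai) if spliceai is not None else None,
            "CLNSIG": None if clinvar == "none" else clinvar,
            "CSQ_GENE": gene,
            "CSQ_TERMS": cons,
            "CSQ_DIST": dist,
        }
        if ann_rng.random() < 0.02:
            info["EXOMISER_RANK"] = int(ann_rng.integers(1, 50))
            info["EXOMISER_SCORE"] = _fmt(float(ann_rng.beta(5, 1)))
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": "G",
                "alt": "A",
                "info": info,
                "calls": calls,
                "filter": "PASS" if ann_rng.random() < 0.97 else "lowq",
            }
        )
        background_keys.append(f"{chrom}:{pos}:G:A")

    vcf_path = out_dir / "cohort.vcf"
    ped_path = out_dir / "cohort.ped"
    _write_vcf(vcf_path, samples, rows)
    ped_path.write_text(_ped_lines(families))

    # companion tables
    plant_genes = sorted({p.gene for p in spec.planted})
    gencc_lines = ["gene\tvalidity"]
    gencc_lines += [f"{g}\tdefinitive" for g in plant_genes]
    for i in range(0, 300, 6):  # a deterministic scatter of known genes
        validity = ("strong", "moderate", "limited")[(i // 6) % 3]
        gencc_lines.append(f"GENE{i:03d}\t{validity}")
    (out_dir / "gencc.tsv").write_text("\n".join(gencc_lines) + "\n")

    panel_lines = ["panel_id\tgene\trating"]
    panel_lines += [
        f"R29\t{p.gene}\tgreen" for p in spec.planted if p.on_panel
    ]
    for i in range(0, 300, 10):
        panel_lines.append(f"R29\tGENE{i:03d}\tgreen")
    (out_dir / "panels.tsv").write_text("\n".join(panel_lines) + "\n")

    ev_cols = (
        "variant_key\tsecond_hit_found\tphenotype_match\ttissue_expression_ok"
        "\tpathway_plausible\tlof_curation\tigv_artefact"
    )
    ev_lines = [ev_cols] + [
        f"{m['key']}\tunknown\tunknown\tunknown\tunknown\tunknown\tunknown"
        for m in manifest_plants
    ]
    (out_dir / "evidence.tsv").write_text("\n".join(ev_lines) + "\n")

    manifest = {
        "seed": spec.seed,
        "families": families,
        "planted": manifest_plants,
        "n_background": len(background_keys),
        "background_keys": background_keys,
    }
    (out_dir / "truth.json").write_text(json.dumps(manifest, indent=1))
    return {
        "vcf": vcf_path,
        "ped": ped_path,
        "gencc": out_dir / "gencc.tsv",
        "panels": out_dir / "panels.tsv",
        "evidence": out_dir / "evidence.tsv",
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# fixture 1: the 14 curated variants with their printed annotations

# per-family trio sample ids (proband, sample_2, sample_3); sample_2 is the
# father per the published footnote order except FAM_8, where the printed
# sexes put the mother second
_T4_FAMILIES = {
    "FAM_1": ("FAM_1_1", "FAM_1_2", "FAM_1_3", "male"),
    "FAM_2": ("FAM_2_4", "FAM_2_5", "FAM_2_6", "male"),
    "FAM_3": ("FAM_3_7", "FAM_3_8", "FAM_3_9", "female"),
    "FAM_5": ("FAM_5_14", "FAM_5_15", "FAM_5_16", "female"),
    "FAM_6": ("FAM_6_17", "FAM_6_18", "FAM_6_19", "female"),
    "FAM_7": ("FAM_7_20", "FAM_7_21", "FAM_7_22", "male"),
    "FAM_8": ("FAM_8_23", "FAM_8_25", "FAM_8_24", "female"),
}

# variant rows: key fields, gene, consequence, gnomAD AF, CADD, REVEL,
# ClinVar level, exomiser rank, and per-sample alt-allele counts
_T4_VARIANTS = [
    ("1:31731030:G:A", "ADGRB2", "stop_gained", 0.0, 38.0, None, "none", None,
     {"FAM_4_10": 1, "FAM_4_13": 1, "FAM_4_11": 0}),
    ("1:243341070:TG:T", "SDCCAG8", "frameshift", 0.0, 26.0, None, "P", None,
     {"FAM_8_23": 1, "FAM_8_24": 1, "FAM_8_25": 0}),
    ("1:243378799:A:G", "SDCCAG8", "missense", 9.55e-5, 22.2, 0.195, "VUS", None,
     {"FAM_8_23": 1, "FAM_8_24": 0, "FAM_8_25": 1}),
    ("2:28776944:C:G", "PPP1CB", "missense", 0.0, 26.7, 0.438, "P", 1,
     {"FAM_3_7": 1, "FAM_3_8": 0, "FAM_3_9": 0}),
    ("7:1480876:G:C", "INTS1", "missense", 5.56e-4, 23.5, 0.243, "none", None,
     {"FAM_2_4": 1, "FAM_2_5": 1, "FAM_2_6": 0}),
    ("7:1497193:C:G", "INTS1", "missense", 7.76e-5, 24.0, 0.315, "none", None,
     {"FAM_2_4": 1, "FAM_2_5": 0, "FAM_2_6": 1}),
    ("9:77020700:A:G", "FOXB2", "missense", 0.0, 25.3, 0.534, "none", None,
     {"FAM_7_20": 1, "FAM_7_21": 0, "FAM_7_22": 0}),
    ("11:17413408:G:A", "ABCC8", "stop_gained", 0.0, 43.0, None, "LP", None,
     {"FAM_5_14": 1, "FAM_5_15": 0, "FAM_5_16": 1}),
    ("13:30462666:CT:C", "HMGB1", "frameshift", 0.0, 38.0, None, "none", 1,
     {"FAM_1_1": 1, "FAM_1_2": 0, "FAM_1_3": 0}),
    ("13:114325034:C:T", "CHAMP1", "stop_gained", 0.0, 35.0, None, "P", 1,
     {"FAM_6_17": 1, "FAM_6_18": 0, "FAM_6_19": 0}),
    ("16:71951734:T:G", "PKD1L3", "missense", 5.09e-4, 23.1, None, "none", 33,
     {"FAM_7_20": 1, "FAM_7_21": 1, "FAM_7_22": 0}),
    ("16:71973386:C:T", "PKD1L3", "missense", 1.02e-4, 22.0, None, "none", None,
     {"FAM_7_20": 1, "FAM_7_21": 0, "FAM_7_22": 1}),
    ("19:23361341:G:C", "ZNF91", "stop_gained", 0.0, 32.0, None, "none", 3,
     {"FAM_8_23": 1, "FAM_8_24": 0, "FAM_8_25": 0}),
]

# expected surviving candidates: (family, proband, key, model)
_T4_EXPECTED = [
    ("FAM_1", "FAM_1_1", "13:30462666:CT:C", "de_novo"),
    ("FAM_2", "FAM_2_4", "7:1480876:G:C", "comp_het_member"),
    ("FAM_2", "FAM_2_4", "7:1497193:C:G", "comp_het_member"),
    ("FAM_3", "FAM_3_7", "2:28776944:C:G", "de_novo"),
    ("FAM_4", "FAM_4_10", "1:31731030:G:A", "dominant_inherited"),
    ("FAM_4", "FAM_4_13", "1:31731030:G:A", "dominant_inherited"),
    ("FAM_5", "FAM_5_14", "11:17413408:G:A", "dominant_inherited"),
    ("FAM_6", "FAM_6_17", "13:114325034:C:T", "de_novo"),
    ("FAM_7", "FAM_7_20", "9:77020700:A:G", "de_novo"),
    ("FAM_7", "FAM_7_20", "16:71951734:T:G", "comp_het_member"),
    ("FAM_7", "FAM_7_20", "16:71973386:C:T", "comp_het_member"),
    ("FAM_8", "FAM_8_23", "1:243341070:TG:T", "dominant_inherited"),
    ("FAM_8", "FAM_8_23", "1:243378799:A:G", "comp_het_member"),
    ("FAM_8", "FAM_8_23", "19:23361341:G:C", "de_novo"),
]

_T4_GENCC = [
    ("INTS1", "definitive"),
    ("PPP1CB", "definitive"),
    ("ABCC8", "definitive"),
    ("CHAMP1", "definitive"),
    ("SDCCAG8", "definitive"),
    ("CACNA1H", "limited"),
]

_T4_PANELS = [
    ("R29", "CHAMP1", "green"),
    ("R29", "PPP1CB", "green"),
    ("R29", "CACNA1H", "amber"),
    ("R195", "SDCCAG8", "green"),
]

# keys of the clinically agreed (partial) diagnoses
TABLE3_DIAGNOSTIC_KEYS = {
    ("FAM_3", "2:28776944:C:G"),
    ("FAM_5", "11:17413408:G:A"),
    ("FAM_6", "13:114325034:C:T"),
}


def table4_fixture(out_dir) -> dict:
    """Write the curated-variant fixture: the 14 reported variants with
    their printed coordinates, annotations and trio allele counts.

    Genotypes are reconstructed from the printed allele counts; the quad
    family is represented as in the research design — father plus two
    affected twins, no maternal sample.  Returns paths plus a truth manifest
    of the 14 expected (family, proband, variant, model) candidates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    samples: list[str] = []
    ped_lines = []
    for fam, (pro, fa, mo, sex) in _T4_FAMILIES.items():
        sex_code = "1" if sex == "male" else "2"
        # printed sample order: proband, father, mother (FAM_8 mother second)
        father, mother = (fa, mo) if fam != "FAM_8" else ("FAM_8_25", "FAM_8_24")
        ped_lines.append(f"{fam}\t{pro}\t{father}\t{mother}\t{sex_code}\t2")
        ped_lines.append(f"{fam}\t{father}\t0\t0\t1\t1")
        ped_lines.append(f"{fam}\t{mother}\t0\t0\t2\t1")
        samples += [pro, father, mother]
    # quad family: father + affected monozygotic twins, no maternal DNA
    ped_lines.append("FAM_4\tFAM_4_10\tFAM_4_11\t0\t2\t2")
    ped_lines.append("FAM_4\tFAM_4_13\tFAM_4_11\t0\t2\t2")
    ped_lines.append("FAM_4\tFAM_4_11\t0\t0\t1\t1")
    samples += ["FAM_4_10", "FAM_4_13", "FAM_4_11"]

    rows = []
    for key, gene, cons, gnomad, cadd, revel, clinvar, exo_rank, acs in _T4_VARIANTS:
        chrom, pos, ref, alt = key.split(":")
        calls = {}
        for sid, n_alt in acs.items():
            calls[sid] = (_gt_str(n_alt), (15, 13) if n_alt else (30, 0), 60)
        rows.append(
            {
                "chrom": chrom,
                "pos": int(pos),
                "ref": ref,
                "alt": alt,
                "filter": "PASS",
                "calls": calls,
                "info": {
                    "GNOMAD_EX_AF": _fmt(gnomad),
                    "COHORT_AF": "3.3e-05",
                    "CADD_PHRED": _fmt(cadd),
                    "REVEL": _fmt(revel) if revel is not None else None,
                    "CLNSIG": None if clinvar == "none" else clinvar,
                    "EXOMISER_RANK": exo_rank,
                    "CSQ_GENE": gene,
                    "CSQ_TERMS": cons,
                    "CSQ_DIST": 0,
                },
            }
        )

    vcf_path = out_dir / "table4.vcf"
    ped_path = out_dir / "table4.ped"
    _write_vcf(vcf_path, samples, rows)
    ped_path.write_text("\n".join(ped_lines) + "\n")

    (out_dir / "gencc.tsv").write_text(
        "gene\tvalidity\n" + "\n".join(f"{g}\t{v}" for g, v in _T4_GENCC) + "\n"
    )
    (out_dir / "panels.tsv").write_text(
        "panel_id\tgene\trating\n"
        + "\n".join(f"{p}\t{g}\t{r}" for p, g, r in _T4_PANELS)
        + "\n"
    )
    ev_header = (
        "variant_key\tsecond_hit_found\tphenotype_match\ttissue_expression_ok"
        "\tpathway_plausible\tlof_curation\tigv_artefact"
    )
    keys = [v[0] for v in _T4_VARIANTS]
    (out_dir / "evidence.tsv").write_text(
        ev_header
        + "\n"
        + "\n".join(f"{k}\tunknown\tunknown\tunknown\tunknown\tunknown\tunknown" for k in keys)
        + "\n"
    )

    manifest = {
        "variants": [
            {"family_id": f, "proband_id": p, "key": k, "model": m}
            for f, p, k, m in _T4_EXPECTED
        ],
        "n_expected_candidates": len(_T4_EXPECTED),
        "diagnostic": sorted(f"{f}|{k}" for f, k in TABLE3_DIAGNOSTIC_KEYS),
    }
    (out_dir / "truth.json").write_text(json.dumps(manifest, indent=1))
    return {
        "vcf": vcf_path,
        "ped": ped_path,
        "gencc": out_dir / "gencc.tsv",
        "panels": out_dir / "panels.tsv",
        "evidence": out_dir / "evidence.tsv",
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# fixture 2: the printed per-family comparison counts

# columns: family, assessed (hippo, gencc, gms), diagnostic (hippo, gencc,
# gms), reportable (hippo, gencc-restricted, gms), HPO terms (research,
# clinical).  The quad family FAM_4 lacked maternal research data and is the
# standard exclusion for paired analyses.
_T3_ROWS = [
    ("FAM_1", 8, 3, 9, 0, 0, 0, 1, 0, 1, 15, 8),
    ("FAM_2", 4, 4, 5, 0, 0, 0, 2, 2, 0, 10, 5),
    ("FAM_3", 4, 2, 7, 1, 1, 1, 1, 1, 1, 9, 6),
    ("FAM_4", 68, 23, 14, 0, 0, 0, 2, 0, 0, 4, 3),
    ("FAM_5", 8, 1, 5, 1, 1, 0, 1, 1, 0, 11, 5),
    ("FAM_6", 2, 1, 6, 1, 1, 1, 1, 1, 1, 5, 4),
    ("FAM_7", 10, 1, 7, 0, 0, 0, 3, 0, 0, 9, 7),
    ("FAM_8", 5, 3, 24, 0, 0, 0, 3, 2, 2, 5, 10),
]

EXCLUDED_FAMILY = "FAM_4"


def table3_fixture() -> list[FamilyCounts]:
    """Per-family counts as printed in the published comparison table."""
    out = []
    for (fam, a_h, a_g, a_n, d_h, d_g, d_n, r_h, r_g, r_n, hpo_r, hpo_c) in _T3_ROWS:
        out.append(
            FamilyCounts(
                family_id=fam,
                n_assessed_hippo=a_h,
                n_assessed_hippo_gencc=a_g,
                n_assessed_gms=a_n,
                n_diagnostic_hippo=d_h,
                n_diagnostic_hippo_gencc=d_g,
                n_diagnostic_gms=d_n,
                n_reportable_hippo=r_h,
                n_reportable_hippo_gencc=r_g,
                n_reportable_gms=r_n,
                n_hpo_research=hpo_r,
                n_hpo_clinical=hpo_c,
            )
        )
    return out


def write_table3_fixture(path) -> None:
    import pandas as pd

    df = pd.DataFrame([asdict(fc) for fc in table3_fixture()])
    df.to_csv(path, sep="\t", index=False)
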