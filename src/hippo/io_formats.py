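"""Readers and writers for every external artifact.

The annotation dialect is a minimal flat INFO schema rather than a packed
VEP CSQ string: population AFs (GNOMAD_EX_AF, GNOMAD_WG_AF, TOPMED_AF,
EXAC_AF, KG_AF), COHORT_AF, CADD_PHRED, REVEL, SPLICEAI_DS, CLNSIG,
EXOMISER_RANK / EXOMISER_SCORE and per-variant transcript consequences
(CSQ_GENE, CSQ_TERMS, CSQ_DIST).  Multi-allelic records are decomposed into
one :class:`~hippo.models.AnnotatedVariant` per (site, alt) with AD fields
re-indexed per alt.  An annotation that is missing or unparseable is stored
as absent — never silently defaulted to a number.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .models import (
    AnnotatedVariant,
    CandidateVariant,
    ComparisonReport,
    EvidenceFlags,
    GenCCRecord,
    PanelGene,
    Pedigree,
    PedigreeMember,
    SampleCall,
    normalize_chrom,
    variant_sort_key,
)

logger = logging.getLogger(__name__)

POP_AF_KEYS = {
    "GNOMAD_EX_AF": "gnomad_exomes",
    "GNOMAD_WG_AF": "gnomad_genomes",
    "TOPMED_AF": "topmed",
    "EXAC_AF": "exac",
    "KG_AF": "kg",
}

_SEX_CODES = {"1": "male", "2": "female"}
_AFFECTED_CODES = {"2": "yes", "1": "no"}


def _canon_term(term: str) -> str:
    """Canonical short form of an SO consequence term."""
    t = term.strip()
    return t[: -len("_variant")] if t.endswith("_variant") else t


def _info_scalar(info_value, alt_index: int):
    """Pick the per-alt entry of an INFO value that may be Number=A."""
    if isinstance(info_value, (tuple, list)):
        if alt_index < len(info_value):
            return info_value[alt_index]
        return info_value[0]
    return info_value


def _parse_float(raw, key: str, where: str) -> float | None:
    if raw is None:
        return None
    try:
        v = float(raw)
    except (TypeError, ValueError):
        warnings.warn(f"{where}: unparseable {key}={raw!r}, field set absent")
        return None
    # htslib hands INFO floats back as float32; restore the written precision
    return float(f"{v:.6g}")


def _parse_int(raw, key: str, where: str) -> int | None:
    if raw is None:
        return None
    try:
        return int(raw)
    except (TypeError, ValueError):
        warnings.warn(f"{where}: unparseable {key}={raw!r}, field set absent")
        return None


def read_cohort_vcf(path, pedigrees: list[Pedigree] | None = None) -> list[AnnotatedVariant]:
    """Read an annotated multi-sample VCF into decomposed variants.

    Every pedigree member must have a sample column (fatal otherwise).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sample_index = {s: i for i, s in enumerate(samples)}
    if pedigrees is not None:
        for ped in pedigrees:
            for m in ped.members:
                if m.sample_id not in sample_index:
                    raise ValueError(
                        f"sample {m.sample_id!r} (family {ped.family_id}) "
                        "missing from VCF"
                    )

    out: list[AnnotatedVariant] = []
    for rec in vcf:
        chrom = normalize_chrom(rec.CHROM)
        where = f"{chrom}:{rec.POS}"
        genotypes = rec.genotypes  # [[a0, a1, phased], ...]
        ad = rec.format("AD")
        gq = rec.format("GQ")
        filter_pass = rec.FILTER is None
        for ai, alt in enumerate(rec.ALT):
            alt_allele_num = ai + 1
            pop_afs: dict[str, float] = {}
            for key, source in POP_AF_KEYS.items():
                v = _parse_float(_info_scalar(rec.INFO.get(key), ai), key, where)
                if v is not None:
                    pop_afs[source] = v
            clnsig = rec.INFO.get("CLNSIG")
            if clnsig is None:
                clinvar = "none"
            elif str(clnsig) in ("P", "LP", "VUS", "LB", "B", "none"):
                clinvar = str(clnsig)
            else:
                warnings.warn(f"{where}: unrecognised CLNSIG={clnsig!r}, set absent")
                clinvar = "none"
            terms_raw = rec.INFO.get("CSQ_TERMS") or ""
            terms = frozenset(
                _canon_term(t) for t in str(terms_raw).split(",") if t.strip()
            )
            if not terms:
                terms = frozenset({"intergenic"})
            calls: dict[str, SampleCall] = {}
            for s, si in sample_index.items():
                entry = genotypes[si]
                alleles = entry[:-1]
                if any(a < 0 for a in alleles):
                    gt = "missing"
                else:
                    n_alt = sum(1 for a in alleles if a == alt_allele_num)
                    if len(alleles) == 1:
                        gt = "hemi" if n_alt == 1 else "hom_ref"
                    else:
                        gt = ("hom_ref", "het", "hom_alt")[n_alt]
                depths = None
                if ad is not None:
                    ref_reads = int(ad[si][0])
                    alt_reads = int(ad[si][alt_allele_num])
                    if ref_reads >= 0 and alt_reads >= 0:
                        depths = (ref_reads, alt_reads)
                gq_val = None
                if gq is not None:
                    g = int(gq[si][0]) if gq.ndim > 1 else int(gq[si])
                    if g >= 0:
                        gq_val = g
                calls[s] = SampleCall(
                    sample_id=s,
                    gt=gt,
                    allele_depths=depths,
                    gq=gq_val,
                    filter_pass=filter_pass,
                )
            out.append(
                AnnotatedVariant(
                    key=f"{chrom}:{rec.POS}:{rec.REF}:{alt}",
                    chrom=chrom,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=str(rec.INFO.get("CSQ_GENE") or "").strip(),
                    consequence_terms=terms,
                    coding_distance_bp=_parse_int(
                        rec.INFO.get("CSQ_DIST"), "CSQ_DIST", where
                    )
                    or 0,
                    pop_afs=pop_afs,
                    cohort_af=_parse_float(
                        _info_scalar(rec.INFO.get("COHORT_AF"), ai), "COHORT_AF", where
                    ),
                    cadd=_parse_float(
                        _info_scalar(rec.INFO.get("CADD_PHRED"), ai), "CADD_PHRED", where
                    ),
                    revel=_parse_float(
                        _info_scalar(rec.INFO.get("REVEL"), ai), "REVEL", where
                    ),
                    spliceai=_parse_float(
                        _info_scalar(rec.INFO.get("SPLICEAI_DS"), ai), "SPLICEAI_DS", where
                    ),
                    clinvar=clinvar,
                    exomiser_rank=_parse_int(
                        rec.INFO.get("EXOMISER_RANK"), "EXOMISER_RANK", where
                    ),
                    exomiser_score=_parse_float(
                        rec.INFO.get("EXOMISER_SCORE"), "EXOMISER_SCORE", where
                    ),
                    calls=calls,
                    filter_pass=filter_pass,
                )
            )
    out.sort(key=lambda v: variant_sort_key(v.key))
    return out


def read_ped(path) -> list[Pedigree]:
    """Parse a standard 6-column PED file into one Pedigree per family."""
    families: dict[str, list[PedigreeMember]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"PED line with {len(fields)} fields: {line!r}")
            fam, sid, fid, mid, sex, pheno = fields[:6]
            member = PedigreeMember(
                sample_id=sid,
                father_id=None if fid in ("0", "", ".") else fid,
                mother_id=None if mid in ("0", "", ".") else mid,
                sex=_SEX_CODES.get(sex, "unknown"),
                affected=_AFFECTED_CODES.get(pheno, "unknown"),
            )
            if fam not in families:
                families[fam] = []
                order.append(fam)
            families[fam].append(member)
    return [Pedigree(family_id=f, members=families[f]) for f in order]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_gencc(path) -> list[GenCCRecord]:
    df = _read_tsv(path, ["gene", "validity"])
    seen = set()
    out = []
    for _, row in df.iterrows():
        rec = GenCCRecord(row["gene"].strip(), row["validity"].strip())
        pair = (rec.gene_symbol, rec.validity)
        if pair in seen:
            continue
        seen.add(pair)
        out.append(rec)
    return out


def read_panels(path) -> list[PanelGene]:
    df = _read_tsv(path, ["panel_id", "gene", "rating"])
    return [
        PanelGene(row["panel_id"].strip(), row["gene"].strip(), row["rating"].strip())
        for _, row in df.iterrows()
    ]


def _flag(raw: str) -> bool | None:
    raw = raw.strip().lower()
    if raw in ("", "unknown", "na", "nan"):
        return None
    if raw in ("true", "1", "yes"):
        return True
    if raw in ("false", "0", "no"):
        return False
    raise ValueError(f"unrecognised evidence flag value {raw!r}")


def read_evidence(path) -> list[EvidenceFlags]:
    cols = [
        "variant_key",
        "second_hit_found",
        "phenotype_match",
        "tissue_expression_ok",
        "pathway_plausible",
        "lof_curation",
        "igv_artefact",
    ]
    df = _read_tsv(path, cols)
    out = []
    for _, row in df.iterrows():
        out.append(
            EvidenceFlags(
                variant_key=row["variant_key"].strip(),
                second_hit_found=_flag(row["second_hit_found"]),
                phenotype_match=_flag(row["phenotype_match"]),
                tissue_expression_ok=_flag(row["tissue_expression_ok"]),
                pathway_plausible=_flag(row["pathway_plausible"]),
                lof_curation=row["lof_curation"].strip() or "unknown",
                igv_artefact=_flag(row["igv_artefact"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# result writers (deterministic column order; round-trip through the readers)

CANDIDATE_COLUMNS = [
    "family_id",
    "proband_id",
    "variant_key",
    "gene",
    "strategy",
    "model",
    "partner_key",
    "confirmed_de_novo",
    "phase_unknown",
    "tier",
    "reportable",
    "diagnostic",
    "rule_trace",
]


def candidates_to_frame(cands: list[CandidateVariant]) -> pd.DataFrame:
    rows = []
    for c in cands:
        rows.append(
            {
                "family_id": c.family_id,
                "proband_id": c.proband_id,
                "variant_key": c.variant.key,
                "gene": c.variant.gene,
                "strategy": c.strategy,
                "model": c.inheritance.model,
                "partner_key": c.inheritance.partner_key or "",
                "confirmed_de_novo": c.inheritance.confirmed_de_novo,
                "phase_unknown": c.inheritance.phase_unknown,
                "tier": c.tier.tier if c.tier else "",
                "reportable": "" if c.reportable is None else c.reportable,
                "diagnostic": c.diagnostic,
                "rule_trace": ";".join(f"{r}={o}" for r, o in c.rule_trace),
            }
        )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def write_candidates(cands: list[CandidateVariant], path, fmt: str = "tsv",
                     header_comments: list[str] | None = None) -> None:
    df = candidates_to_frame(cands)
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            for line in header_comments or []:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_candidates(path) -> pd.DataFrame:
    """Read a candidate table back as the flat frame written out."""
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()), columns=CANDIDATE_COLUMNS)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        for col in ("confirmed_de_novo", "phase_unknown", "diagnostic", "reportable"):
            df[col] = df[col].map(
                lambda x: True if x == "True" else (False if x == "False" else "")
            )
    return df


def write_report(report: ComparisonReport, path, fmt: str = "json",
                 header_comments: list[str] | None = None) -> None:
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
    elif fmt == "tsv":
        from dataclasses import asdict

        df = pd.DataFrame([asdict(fc) for fc in report.per_family])
        with open(path, "w") as fh:
            for line in header_comments or []:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_report(path) -> ComparisonReport:
    return ComparisonReport.from_dict(json.loads(Path(path).read_text()))
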