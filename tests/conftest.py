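import pytest

from hippo import io_formats, synthetic
from hippo.models import AnnotatedVariant, SampleCall, TrioContext
from hippo.synthetic import CohortSpec, PlantSpec


def make_call(sample_id="pro", gt="het", ad=(15, 14), gq=60, filter_pass=True):
    return SampleCall(
        sample_id=sample_id, gt=gt, allele_depths=ad, gq=gq, filter_pass=filter_pass
    )


def make_variant(
    key="1:100:A:T",
    gene="GENEX",
    terms=("missense",),
    dist=0,
    pop_afs=None,
    cohort_af=1e-4,
    cadd=30.0,
    revel=None,
    spliceai=None,
    clinvar="none",
    exomiser_rank=None,
    exomiser_score=None,
    calls=None,
    filter_pass=True,
):
    chrom, pos, ref, alt = key.split(":")
    return AnnotatedVariant(
        key=key,
        chrom=chrom,
        pos=int(pos),
        ref=ref,
        alt=alt,
        gene=gene,
        consequence_terms=frozenset(terms),
        coding_distance_bp=dist,
        pop_afs=pop_afs or {},
        cohort_af=cohort_af,
        cadd=cadd,
        revel=revel,
        spliceai=spliceai,
        clinvar=clinvar,
        exomiser_rank=exomiser_rank,
        exomiser_score=exomiser_score,
        calls=calls or {},
        filter_pass=filter_pass,
    )


def make_trio(
    proband="het",
    father="hom_ref",
    mother="hom_ref",
    sex="male",
    chrom_class="autosome",
    father_affected="no",
    mother_affected="no",
    gq=(60, 60, 60),
    proband_ad=(15, 14),
):
    p = make_call("pro", proband, ad=proband_ad, gq=gq[0])
    f = None if father is None else make_call("fa", father, gq=gq[1])
    m = None if mother is None else make_call("mo", mother, gq=gq[2])
    return TrioContext(
        proband=p,
        father=f,
        mother=m,
        proband_sex=sex,
        chrom_class=chrom_class,
        father_affected=father_affected,
        mother_affected=mother_affected,
    )


@pytest.fixture(scope="session")
def table4(tmp_path_factory):
    """The curated-variant fixture, loaded once per session."""
    d = tmp_path_factory.mktemp("table4")
    fx = synthetic.table4_fixture(d)
    pedigrees = io_formats.read_ped(fx["ped"])
    variants = io_formats.read_cohort_vcf(fx["vcf"], pedigrees)
    return {
        "fx": fx,
        "pedigrees": pedigrees,
        "variants": variants,
        "gencc": io_formats.read_gencc(fx["gencc"]),
        "panels": io_formats.read_panels(fx["panels"]),
        "evidence": io_formats.read_evidence(fx["evidence"]),
    }


STANDARD_PLANTS = [
    PlantSpec("de_novo", "PLANT_DN", True, on_panel=True),
    PlantSpec("comp_het", "PLANT_CH", True),
    PlantSpec("x_linked", "PLANT_XL", True),
    PlantSpec("hom_recessive", "PLANT_HR", True),
    PlantSpec("clinvar_inherited", "PLANT_CI", True),
    PlantSpec("de_novo", "PLANT_V1", False),
    PlantSpec("comp_het", "PLANT_V2", False),
    PlantSpec("hom_recessive", "PLANT_V3", False),
]


@pytest.fixture(scope="session")
def random_cohort(tmp_path_factory):
    """A seeded 1000-variant synthetic cohort with planted variants."""
    d = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(
        seed=11, n_families=4, variants_per_family=250, planted=STANDARD_PLANTS
    )
    out = synthetic.generate(spec, d)
    pedigrees = io_formats.read_ped(out["ped"])
    variants = io_formats.read_cohort_vcf(out["vcf"], pedigrees)
    return {
        "out": out,
        "pedigrees": pedigrees,
        "variants": variants,
        "panels": io_formats.read_panels(out["panels"]),
        "gencc": io_formats.read_gencc(out["gencc"]),
    }
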