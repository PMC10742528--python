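"""Independent straight-line re-implementations used as test oracles.

Deliberately plain code: one predicate at a time, explicit loops, no reuse
of the package's filter internals (only the shared data types).  Scope: the
synthetic cohorts produced by the generator (complete trios, no missing
genotypes, cohort AF annotated or derivable).
"""

from __future__ import annotations

import itertools
import math

from hippo.models import AnnotatedVariant, GMSConfig, HiPPoConfig, Pedigree

CODING = {
    "missense", "stop_gained", "stop_lost", "start_lost", "frameshift",
    "inframe_deletion", "inframe_insertion", "protein_altering", "synonymous",
    "stop_retained", "start_retained", "coding_sequence", "transcript_ablation",
}
SYN = {"synonymous", "stop_retained", "start_retained"}
SPLICE = {"splice_donor", "splice_acceptor", "splice_region", "intron"}
PLOF = {
    "stop_gained", "frameshift", "splice_donor", "splice_acceptor",
    "start_lost", "stop_lost", "transcript_ablation",
}


def max_af(v: AnnotatedVariant, exclude=()) -> float:
    vals = [af for s, af in v.pop_afs.items() if s not in exclude]
    return max(vals) if vals else 0.0


def qual_terms(v: AnnotatedVariant, window: int) -> set[str]:
    if v.coding_distance_bp <= window:
        return set(v.consequence_terms)
    return {t for t in v.consequence_terms if t in CODING}


def type_ok(v: AnnotatedVariant, window: int) -> bool:
    q = qual_terms(v, window)
    return bool(q) and not (q <= SYN)


def _parents(v, ped, pro):
    def get(pid):
        if pid is None:
            return None
        c = v.calls.get(pid)
        if c is None or c.gt == "missing":
            return None
        return c

    return get(pro.father_id), get(pro.mother_id)


def _status(ped: Pedigree, pid):
    if pid is None:
        return "unknown"
    for m in ped.members:
        if m.sample_id == pid:
            return m.affected
    return "unknown"


def classify(v, ped, pro, min_gq):
    """Plain restatement of the trio inheritance rules."""
    pc = v.calls.get(pro.sample_id)
    if pc is None or pc.gt in ("missing", "hom_ref"):
        return "none", False
    cc = v.chrom_class
    if cc in ("chrY", "MT"):
        return "none", False
    fa, mo = _parents(v, ped, pro)
    male_x = cc == "chrX" and pro.sex == "male"

    def good(call):
        return min_gq <= 0 or (call.gq is not None and call.gq > min_gq)

    het_like = pc.gt == "het" or (male_x and pc.gt == "hemi")
    if (
        het_like
        and fa is not None and mo is not None
        and fa.gt == "hom_ref" and mo.gt == "hom_ref"
        and good(pc) and good(fa) and good(mo)
    ):
        return "de_novo", True
    if pc.gt == "hom_alt" and not male_x:
        if (fa is None or fa.gt == "het") and (mo is None or mo.gt == "het"):
            return "hom_recessive", False
        return "none", False
    if male_x and pc.gt in ("hemi", "hom_alt"):
        if mo is not None and mo.gt == "het" and not (fa is not None and fa.carries_alt()):
            return "x_linked_recessive", False
    if pc.gt == "het" or (male_x and pc.gt == "hemi"):
        for call, pid in ((fa, pro.father_id), (mo, pro.mother_id)):
            if call is not None and call.carries_alt() and _status(ped, pid) == "no":
                return "none", False
        return "dominant_inherited", False
    return "none", False


def shared_ok(v, call, cfg: HiPPoConfig, af_cap: float) -> bool:
    """All cascade rules except inheritance, one if-statement per rule."""
    retain = cfg.missing_score_policy == "retain"
    if not max_af(v) < af_cap:
        return False
    if v.cohort_af is None:
        if not retain:
            return False
    elif not v.cohort_af < cfg.cohort_af_max:
        return False
    q = qual_terms(v, cfg.coding_window_bp)
    if not q:
        return False
    if q <= SYN:
        # only a strong splice-disruption prediction rescues synonymous-only
        if not (v.spliceai is not None and v.spliceai > cfg.spliceai_min):
            return False
    override = v.clinvar in ("P", "LP")
    if q and q <= SPLICE:
        if v.spliceai is None:
            if not retain:
                return False
        elif not v.spliceai > cfg.spliceai_min and not override:
            return False
    if v.cadd is None:
        if not retain:
            return False
    elif not v.cadd > cfg.cadd_min and not override:
        return False
    if v.clinvar in ("B", "LB"):
        return False
    if call.gq is None:
        if not retain:
            return False
    elif not call.gq > cfg.gq_min:
        return False
    if call.gt == "het":
        if call.allele_depths is None or sum(call.allele_depths) == 0:
            if not retain:
                return False
        else:
            r, a = call.allele_depths
            if not a / (r + a) > cfg.allele_balance_min:
                return False
    return True


def comp_het_pairs(hets, ped, pro):
    """Brute-force in-trans pairs among proband-het variants of one gene."""
    pairs = []
    for v1, v2 in itertools.combinations(hets, 2):
        f1, m1 = _parents(v1, ped, pro)
        f2, m2 = _parents(v2, ped, pro)

        def origin(f, m):
            f_car = f is not None and f.carries_alt()
            m_car = m is not None and m.carries_alt()
            if f is None or m is None:
                return "paternal" if f_car else ("maternal" if m_car else "unknown")
            if f_car and m_car:
                return "both"
            if f_car:
                return "paternal"
            if m_car:
                return "maternal"
            return "neither"

        o1, o2 = origin(f1, m1), origin(f2, m2)
        all_present = None not in (f1, m1, f2, m2)
        if o1 == o2 and o1 in ("maternal", "paternal") and all_present:
            continue
        bad = False
        for role in range(2):
            c1 = (f1, m1)[role]
            c2 = (f2, m2)[role]
            pid = (pro.father_id, pro.mother_id)[role]
            if (
                _status(ped, pid) == "no"
                and c1 is not None and c1.carries_alt()
                and c2 is not None and c2.carries_alt()
            ):
                bad = True
        if bad:
            continue
        pairs.append((v1, v2))
    return pairs


def oracle_hippo(variants, pedigrees, cfg: HiPPoConfig | None = None):
    """Set of (family, proband, key) surviving the cascade."""
    cfg = cfg or HiPPoConfig()
    hits = set()
    for ped in pedigrees:
        for pro in [m for m in ped.members if m.affected == "yes"]:
            het_pool: dict[str, list] = {}
            for v in variants:
                call = v.calls.get(pro.sample_id)
                if call is None or not call.carries_alt():
                    continue
                model, _ = classify(v, ped, pro, cfg.gq_min)
                dominant = model in ("de_novo", "dominant_inherited") or (
                    call.gt == "het" and model == "none" and v.clinvar in ("P", "LP")
                )
                if dominant and shared_ok(v, call, cfg, cfg.af_dominant):
                    hits.add((ped.family_id, pro.sample_id, v.key))
                if model in ("hom_recessive", "x_linked_recessive") and shared_ok(
                    v, call, cfg, cfg.af_recessive
                ):
                    hits.add((ped.family_id, pro.sample_id, v.key))
                if call.gt == "het" and v.gene and shared_ok(v, call, cfg, cfg.af_recessive):
                    het_pool.setdefault(v.gene, []).append(v)
            for gene, hets in het_pool.items():
                for v1, v2 in comp_het_pairs(hets, ped, pro):
                    hits.add((ped.family_id, pro.sample_id, v1.key))
                    hits.add((ped.family_id, pro.sample_id, v2.key))
    return hits


def oracle_gms(variants, pedigrees, panels, cfg: GMSConfig | None = None):
    """Set of (family, proband, key, tier) assessed by the panel strategy."""
    cfg = cfg or GMSConfig()
    green: dict[str, set[str]] = {}
    for p in panels:
        if p.rating == "green":
            green.setdefault(p.gene_symbol, set()).add(p.panel_id)
    hits = set()
    for ped in pedigrees:
        for pro in [m for m in ped.members if m.affected == "yes"]:
            pool: dict[str, list] = {}
            for v in variants:
                call = v.calls.get(pro.sample_id)
                if call is None or not call.carries_alt():
                    continue
                pre = (not cfg.require_pass_filter or v.filter_pass) and (
                    call.gq is not None and call.gq > cfg.gq_min
                )
                if (
                    call.gt == "het"
                    and v.gene
                    and pre
                    and max_af(v, ("topmed",)) < cfg.af_recessive
                    and type_ok(v, cfg.coding_window_bp)
                ):
                    pool.setdefault(v.gene, []).append(v)
            ch_keys = set()
            for gene, hets in pool.items():
                for v1, v2 in comp_het_pairs(hets, ped, pro):
                    ch_keys.update((v1.key, v2.key))
            for v in variants:
                call = v.calls.get(pro.sample_id)
                if call is None or not call.carries_alt():
                    continue
                coding = type_ok(v, cfg.coding_window_bp)
                model, confirmed = classify(v, ped, pro, cfg.gq_min)
                pre = (not cfg.require_pass_filter or v.filter_pass) and (
                    call.gq is not None and call.gq > cfg.gq_min
                )
                arm = (
                    (model in ("de_novo", "dominant_inherited")
                     and max_af(v, ("topmed",)) < cfg.af_dominant)
                    or (model in ("hom_recessive", "x_linked_recessive")
                        and max_af(v, ("topmed",)) < cfg.af_recessive)
                    or (v.key in ch_keys and max_af(v, ("topmed",)) < cfg.af_recessive)
                )
                plof = bool(set(v.consequence_terms) & PLOF)
                tier = None
                if pre and arm and coding and v.gene in green:
                    tier = "tier1" if (plof or (model == "de_novo" and confirmed)) else "tier2"
                else:
                    m0, c0 = classify(v, ped, pro, 0)
                    if m0 == "de_novo" and c0 and coding and max_af(v, ("topmed",)) < cfg.af_dominant:
                        tier = "ga_denovo"
                    elif (
                        v.exomiser_rank is not None
                        and v.exomiser_rank <= cfg.exomiser_top_rank
                        and v.exomiser_score is not None
                        and v.exomiser_score >= cfg.exomiser_min_score
                        and coding
                    ):
                        tier = "ga_exomiser"
                if tier:
                    hits.add((ped.family_id, pro.sample_id, v.key, tier))
    return hits


# --- statistics oracles -----------------------------------------------------


def oracle_wilcoxon_exact(pairs):
    """Two-sided exact signed-rank p by looping over every sign assignment."""
    diffs = [a - b for a, b in pairs if a != b]
    n = len(diffs)
    absd = sorted((abs(d), i) for i, d in enumerate(diffs))
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and absd[j][0] == absd[i][0]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[absd[k][1]] = avg
        i = j
    t_plus = sum(r for r, d in zip(ranks, diffs) if d > 0)
    total = sum(ranks)
    t_small, t_large = min(t_plus, total - t_plus), max(t_plus, total - t_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        t = sum(r for r, s in zip(ranks, signs) if s)
        if t <= t_small + 1e-9 or t >= t_large - 1e-9:
            count += 1
    return min(1.0, count / 2 ** n)


def oracle_fisher(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with the fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))
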