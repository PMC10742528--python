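"""Diagnostic-efficiency metrics and the two significance tests.

The efficiency metric is the diagnostic (or reportable) rate per variant
assessed: how many variants a reporting laboratory had to review for each
diagnosis obtained.  Per-family assessed counts are compared between
strategies with the paired Wilcoxon signed-rank test; two-sided p-values
under the normal approximation use the tie-corrected variance with a
continuity correction, which is also what common statistics packages emit
for tied data.  The exact method enumerates the full sign-flip distribution
of the tied-rank statistic.  2x2 proportions use Fisher's exact test.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as _stats

from .models import CandidateVariant, ComparisonReport, FamilyCounts

__all__ = [
    "rate_per_assessed",
    "wilcoxon_signed_rank",
    "fisher_exact",
    "counts_from_candidates",
    "report_from_counts",
    "build_report",
]

STRATEGIES = ("hippo", "hippo_gencc", "gms")


def rate_per_assessed(numerator: int, n_assessed: int) -> float:
    """Percentage rate per variant assessed, rounded half-even to 2 dp."""
    if n_assessed <= 0:
        raise ValueError("rate undefined: no variants assessed")
    return round(100.0 * numerator / n_assessed, 2)


def _signed_rank_stats(diffs: np.ndarray) -> tuple[np.ndarray, float, float]:
    d = diffs[diffs != 0]
    if d.size == 0:
        raise ValueError("all differences zero: test undefined")
    ranks = _stats.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    return ranks, t_plus, float(ranks.sum())


def _exact_signed_rank_p(ranks: np.ndarray, t_plus: float, total: float) -> float:
    """Two-sided exact p by full enumeration of the 2^n sign assignments.

    Implemented as a convolution over the doubled (hence integral) tied
    ranks, equivalent to enumerating every assignment and averaging ranks
    for ties.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    size = int(doubled.sum()) + 1
    counts = np.zeros(size, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: size - r]
        counts = counts + shifted
    t2 = int(round(2 * t_plus))
    s2 = int(round(2 * total))
    t_small = min(t2, s2 - t2)
    t_large = max(t2, s2 - t2)
    p = (counts[: t_small + 1].sum() + counts[t_large:].sum()) / counts.sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(
    pairs: list[tuple[float, float]], method: str = "auto"
) -> tuple[float, float, str]:
    """Paired two-sided Wilcoxon signed-rank test.

    Returns ``(statistic, p, method_used)`` with the statistic being
    min(T+, T-) over the non-zero differences.  ``auto`` selects the exact
    enumeration unless tied absolute differences are present, in which case
    the tie-corrected normal approximation with continuity correction is
    used (this is what reproduces published p-values on tied count data).
    """
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    diffs = a - b
    ranks, t_plus, total = _signed_rank_stats(diffs)
    statistic = min(t_plus, total - t_plus)

    has_ties = len(np.unique(np.abs(diffs[diffs != 0]))) < np.count_nonzero(diffs)
    if method == "auto":
        method = "normal_cc" if has_ties else "exact"

    if method == "exact":
        if np.count_nonzero(diffs) > 25:
            raise ValueError("exact enumeration limited to 25 non-zero differences")
        p = _exact_signed_rank_p(ranks, t_plus, total)
    elif method == "normal_cc":
        d = diffs[diffs != 0]
        res = _stats.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return statistic, p, method


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Degenerate margins give p = 1 (no evidence either way).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(_stats.fisher_exact([[a, b], [c, d]]).pvalue)


def counts_from_candidates(
    hippo_cands: list[CandidateVariant],
    gencc_cands: list[CandidateVariant],
    gms_cands: list[CandidateVariant],
    diagnostic_truth: set[tuple[str, str]] | None = None,
    hpo_counts: dict[str, tuple[int, int]] | None = None,
) -> list[FamilyCounts]:
    """Tally per-family counts from tagged candidate lists.

    ``diagnostic_truth`` is a set of (family_id, variant_key) labels; the
    clinical causality of a variant is an input, never computed here.
    """
    truth = diagnostic_truth or set()
    families: list[str] = []
    tallies: dict[str, dict[str, int]] = {}

    def bucket(fam: str) -> dict[str, int]:
        if fam not in tallies:
            tallies[fam] = {}
            families.append(fam)
        return tallies[fam]

    for strat, cands in (
        ("hippo", hippo_cands),
        ("hippo_gencc", gencc_cands),
        ("gms", gms_cands),
    ):
        for c in cands:
            t = bucket(c.family_id)
            t[f"n_assessed_{strat}"] = t.get(f"n_assessed_{strat}", 0) + 1
            is_diag = (c.family_id, c.variant.key) in truth
            if is_diag:
                t[f"n_diagnostic_{strat}"] = t.get(f"n_diagnostic_{strat}", 0) + 1
            # a diagnostic variant is by definition returned to the clinician
            if c.reportable or is_diag:
                t[f"n_reportable_{strat}"] = t.get(f"n_reportable_{strat}", 0) + 1

    for fam, key in truth:
        if fam not in tallies:
            warnings.warn(f"diagnostic truth family {fam!r} has no candidates")
            bucket(fam)

    out = []
    for fam in families:
        hpo = (hpo_counts or {}).get(fam, (0, 0))
        out.append(
            FamilyCounts(
                family_id=fam,
                n_hpo_research=hpo[0],
                n_hpo_clinical=hpo[1],
                **tallies[fam],
            )
        )
    return out


def report_from_counts(
    counts: list[FamilyCounts],
    exclusions: list[str] | None = None,
    gencc_numerators: str = "unrestricted",
) -> ComparisonReport:
    """Build the comparison report from per-family counts.

    ``gencc_numerators`` controls the gene-validity-restricted rates:
    ``unrestricted`` (default) divides the diagnostic/reportable counts of
    the one curation pass over the full panel-agnostic candidate list by the
    restricted assessed count — the restriction narrows the assessment
    workload, not the curation verdicts.  ``restricted`` uses the restricted
    per-family numerators instead.
    """
    if gencc_numerators not in ("unrestricted", "restricted"):
        raise ValueError("gencc_numerators must be 'unrestricted' or 'restricted'")
    exclusions = list(exclusions or [])
    included = [fc for fc in counts if fc.family_id not in exclusions]

    def total(field: str) -> int:
        return sum(getattr(fc, field) for fc in included)

    totals = {
        strat: {
            "assessed": total(f"n_assessed_{strat}"),
            "diagnostic": total(f"n_diagnostic_{strat}"),
            "reportable": total(f"n_reportable_{strat}"),
        }
        for strat in STRATEGIES
    }
    if gencc_numerators == "unrestricted":
        totals["hippo_gencc"]["diagnostic"] = totals["hippo"]["diagnostic"]
        totals["hippo_gencc"]["reportable"] = totals["hippo"]["reportable"]

    rates = {}
    for strat, t in totals.items():
        if t["assessed"] > 0:
            rates[strat] = {
                "n_assessed": t["assessed"],
                "n_diagnostic": t["diagnostic"],
                "n_reportable": t["reportable"],
                "diagnostic_rate_pct": rate_per_assessed(t["diagnostic"], t["assessed"]),
                "reportable_rate_pct": rate_per_assessed(t["reportable"], t["assessed"]),
            }
        else:
            rates[strat] = {
                "n_assessed": 0,
                "n_diagnostic": t["diagnostic"],
                "n_reportable": t["reportable"],
                "diagnostic_rate_pct": None,
                "reportable_rate_pct": None,
                "undefined": True,
            }

    wilcoxon = {}
    for name, fa, fb in (
        ("hippo_gencc_vs_gms", "n_assessed_hippo_gencc", "n_assessed_gms"),
        ("hippo_vs_gms", "n_assessed_hippo", "n_assessed_gms"),
        ("hpo_research_vs_clinical", "n_hpo_research", "n_hpo_clinical"),
    ):
        pairs = [(getattr(fc, fa), getattr(fc, fb)) for fc in included]
        try:
            stat, p, method = wilcoxon_signed_rank(pairs, method="auto")
            wilcoxon[name] = {"statistic": stat, "p": p, "method": method}
        except ValueError as exc:
            wilcoxon[name] = {"statistic": None, "p": None, "undefined": str(exc)}

    fisher = {}
    for name, strat in (
        ("diagnostic_hippo_gencc_vs_gms", "hippo_gencc"),
        ("diagnostic_hippo_vs_gms", "hippo"),
    ):
        k1, n1 = totals[strat]["diagnostic"], totals[strat]["assessed"]
        k2, n2 = totals["gms"]["diagnostic"], totals["gms"]["assessed"]
        fisher[name] = {
            # published construction: diagnoses tabulated against the
            # assessed counts themselves
            "p": fisher_exact(k1, n1, k2, n2),
            "table": [[k1, n1], [k2, n2]],
            # properly conditioned 2x2: diagnostic vs non-diagnostic
            "p_conditional": fisher_exact(k1, n1 - k1, k2, n2 - k2),
            "table_conditional": [[k1, n1 - k1], [k2, n2 - k2]],
        }

    return ComparisonReport(
        per_family=list(counts),
        excluded_families=exclusions,
        rates=rates,
        wilcoxon=wilcoxon,
        fisher=fisher,
    )


def build_report(
    hippo_cands: list[CandidateVariant],
    gencc_cands: list[CandidateVariant],
    gms_cands: list[CandidateVariant],
    diagnostic_truth: set[tuple[str, str]] | None = None,
    exclusions: list[str] | None = None,
    hpo_counts: dict[str, tuple[int, int]] | None = None,
    gencc_numerators: str = "unrestricted",
) -> ComparisonReport:
    """End-to-end report from candidate lists (see ``report_from_counts``)."""
    counts = counts_from_candidates(
        hippo_cands, gencc_cands, gms_cands, diagnostic_truth, hpo_counts
    )
    return report_from_counts(counts, exclusions, gencc_numerators)
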