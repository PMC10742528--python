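# Methods

## Scope and data model

The package operates on decomposed variants: every multi-allelic VCF record
is split into one record per (site, alt allele), with AD fields re-indexed
and per-alt genotypes re-expressed against the single alt. Variants are
identified as `chrom:pos:ref:alt` (VCF convention, 1-based). Annotations
come from a flat INFO dialect (population AFs, cohort AF, CADD, REVEL,
SpliceAI, ClinVar level, Exomiser rank/score, gene symbol, consequence
terms, distance to the nearest coding exon) rather than packed VEP CSQ
strings; the pipeline consumes annotations, it does not produce them. A
missing annotation is stored as absent, never as zero: an unannotated CADD
is unknown evidence, not a score of 0.

Gene symbols match exactly (case-sensitive, whitespace-stripped). Alias
resolution is deliberately out of scope; it would make results depend on an
external alias table.

## Inheritance models

Each affected pedigree member is analysed as a trio unit with whatever
parents are available. A parent with a missing genotype at a site is absent
*at that site* — a no-call can neither confirm transmission nor a de novo
event. Rules, in precedence order:

- **de novo** (confirmed): proband het (or hemizygous male on chrX), both
  parents present and hom-ref, all three calls above the GQ threshold.
- **homozygous recessive**: proband hom-alt, every *present* parent a het
  carrier.
- **X-linked recessive**: hemizygous male proband, het carrier mother,
  non-carrier father.
- **dominant / inherited**: proband het and no unaffected sequenced parent
  carries the allele; a carrier parent who is affected or of unknown status,
  or an absent parent, keeps this reading open. This is what makes an
  incomplete trio inflate the dominant candidate count — exactly the
  behaviour the quad-family fixture exhibits (68 candidates without a
  maternal sample).
- chrY and mitochondrial variants are out of scope and classify as none.

Compound heterozygotes are sought per gene among proband-het variants: a
valid pair has one allele attributable only to the mother and one only to
the father (in trans), and no unaffected parent carrying both members. With
one parent unsequenced, pairs that cannot be proven cis are retained and
flagged `phase_unknown` — discarding them would silently disable the
recessive search in incomplete trios.

## The filter cascade

Thresholds (defaults in `HiPPoConfig`): dominant-arm max population AF
< 0.001, recessive-arm < 0.05, cohort AF < 0.01, coding window ± 20 bp,
SpliceAI > 0.2 (applied only to variants whose qualifying consequences are
all splice-region/intronic), CADD > 15 (all variants), GQ > 40, het allele
balance > 0.2. All comparisons are strict, matching the stated inequalities;
a CADD of exactly 15 fails.

Policy decisions the cascade encodes:

- **Missing scores fail open** (`missing_score_policy="retain"`): a
  pathogenicity filter should not discard a variant because evidence is
  absent. A `drop` mode exists for stricter workflows. The policy also
  covers missing AD/GQ.
- **ClinVar override**: a P/LP assertion rescues an inheritance-model
  failure (pathogenic variants are retained even when carried by an
  unaffected parent — reduced penetrance, imprinting and recessive partial
  hits are all real) and in-silico score failures. It never rescues the AF
  caps: AF is an unconditional row of the cascade, and the cap is what keeps
  recurrent benign P submissions on common variants out of the output.
  B/LB is an unconditional drop.
- **Synonymous variants**: a variant is excluded for variant type only when
  it is synonymous on *every* transcript. A synonymous-only variant with a
  SpliceAI score above threshold is retained and flagged `overridden` in the
  rule trace — a splice-disrupting "synonymous" change is precisely what the
  splice rule exists for.
- **Cohort AF**: taken from the `COHORT_AF` INFO field (the joint-call
  cohort the data came from, ~15k samples for the study design emulated
  here); when absent it is recomputed from founder genotypes in the input
  VCF. The fixtures annotate it explicitly because an 8-family cohort has
  too few founders for a meaningful frequency.
- The site FILTER column is ignored by this cascade ("QC: all variants");
  the panel-based emulation requires PASS. Call-level quality is still
  enforced via GQ and allele balance.

Every candidate carries an ordered rule trace with exactly one entry per
rule (`pass` / `fail` / `overridden` / `skipped`); a candidate exists only
if no rule failed. Output order is (chromosome, position, ref, alt), ties
broken by key, then family and proband — fully deterministic.

The GenCC restriction keeps candidates whose gene has a *definitive* or
*strong* validity assertion and relabels the strategy; it is always a subset
of the unrestricted output.

## Reportability engine

Six exclusion rules, driven by curator-supplied evidence flags (the
evidence itself — second-hit searches, OMIM/GenCC phenotype review, GTEx
expression, LoF curation, IGV inspection — cannot be computed offline and is
an input): (1) single het in a recessive disease gene with
`second_hit_found=false`; (2) known disease gene with a phenotype mismatch,
unless ClinVar P/LP (the carve-out that keeps a pathogenic comp-het member
on the report while its uncertain partner is excluded); (3) known gene
poorly expressed in the relevant tissue; (4) novel gene poorly expressed or
biologically implausible; (5) predicted LoF curated as (likely) not LoF;
(6) IGV artefact. Unknown flags never fire a rule: the engine defaults
open, and a candidate with no evidence is reportable.

## Panel-strategy emulation

Prefilters: mode of inheritance with AF caps (< 0.001 dominant, < 0.01
recessive — one cap for both homozygous and comp-het arms), GQ > 30, FILTER
PASS, coding ± 8 bp non-synonymous. Synonymous variants never tier, even
with splice predictions. TOPMed is excluded from the AF maximisation (it is
not part of this strategy's sources). Tier 1 = pLoF (stop-gain, frameshift,
essential splice, start/stop-lost, transcript ablation) or confirmed de novo
in a green panel gene; Tier 2 = other qualifying coding variants in a green
gene; multiple panels union their green genes. The gene-agnostic branch
assesses any coding de novo — detected with `min_gq=0` and no PASS
requirement, since this branch is explicitly not filtered on quality — and
Exomiser hits with rank ≤ 3 and score ≥ 0.95 (absent rank or score never
qualifies). The de novo branch keeps the dominant-arm AF cap: a common
variant is not a credible de novo call. Precedence for variants qualifying
twice is tier1 > tier2 > ga_denovo > ga_exomiser, so the tier sets are
disjoint by construction. No ClinVar, cohort-AF or in-silico rules exist in
this strategy — that asymmetry is the point of the comparison.

## Comparison statistics

The efficiency metric is the rate per variant assessed: 100·k/n, rounded
half-even to two decimals. Per-family assessed counts are compared with the
paired two-sided Wilcoxon signed-rank test. The `auto` method uses the
exact sign-flip distribution when the absolute differences are untied, and
otherwise the normal approximation with tie-corrected variance and a
continuity correction — the behaviour of the common statistics packages on
tied count data, and the computation under which the published p-values
(0.022 restricted, 0.35 all-genes) are reproduced; the method actually used
is recorded in the report. The exact method enumerates all 2^n sign
assignments (implemented as a convolution over doubled tied ranks, checked
in the tests against a literal enumeration loop).

Fisher's exact test is the standard two-sided hypergeometric summation.
The report exposes two constructions per comparison: the published one,
which tabulates diagnosis counts against the *assessed* counts themselves
(reproducing the published p = 0.06 restricted and p = 0.39 all-genes), and
the properly conditioned diagnostic/non-diagnostic table (`p_conditional`,
0.046 and 0.38 on the fixture). Users doing fresh inference should prefer
the conditional table.

Two conventions for the gene-validity-restricted rates exist, and the
difference matters. In the emulated study design, curation happens once, on
the full panel-agnostic candidate list; the GenCC restriction narrows the
assessment *workload* (the denominator), not the curation verdicts. The
default (`gencc_numerators="unrestricted"`) therefore divides the
unrestricted diagnostic/reportable counts by the restricted assessed count
— this is what yields 12/15 = 80.0% reportable on the fixture, where only 7
of the 12 reported variants are themselves in restricted genes. The
`restricted` option uses the restricted numerators instead. Because of the
default convention, the per-family invariant diagnostic ≤ reportable ≤
assessed is enforced for the unrestricted and panel strategies but not for
the restricted column.

"Diagnostic" is always an input truth label; clinical causality is decided
by clinicians, not computed here.

## Synthetic cohorts

The generator emulates a joint-called rare-disease trio cohort with the
study's shape: 8 families by default, one affected proband plus two
unaffected parents each (odd-numbered families have male probands, so
X-linked plants are placeable deterministically; requesting one in a
female-proband family is a hard error). Background variants (150 per family
by default) draw an allele frequency from a mixture (55% common 0.01–0.5,
25% low-frequency 0.001–0.01, 20% rare < 0.001), consequences from a
categorical mix dominated by missense/synonymous/intronic, CADD from a
gamma(2, 4) (mean 8, ~11% above 15), SpliceAI from a small beta, occasional
benign/pathogenic ClinVar labels, and genotypes by Mendelian transmission
from founder genotypes drawn at the population frequency, with a 0.3%
false-de-novo call rate and occasional low-GQ, skewed-AB or non-PASS calls.
Cohort AF mirrors the population AF, emulating a large external joint-call
cohort. Under these conditions fewer than 5% of background variants survive
the cascade (the suite asserts this bound; observed rates are far lower).

Planted variants are constructed to satisfy every cascade predicate under a
named model — or to violate exactly one, selectable or cycled
deterministically — and the truth manifest records each predicate's value
by construction, which the tests recompute from the emitted VCF. One RNG
stream per family plus one cohort-level stream make output byte-identical
for a given seed.

What the generator does not emulate: linkage and haplotype structure,
mosaicism, read-level artefacts, segmental duplications, or realistic
per-gene mutation rates. Passing tests therefore demonstrate the filter
logic and its invariants, not robustness to upstream calling error.

## Fixtures

The curated-variant fixture embeds the 14 published reported variants with
their printed coordinates, gnomAD AF, CADD, REVEL, consequence and trio
allele counts; genotypes are reconstructed from the allele-count columns
(sample 2 = father per the published footnote order; the one family whose
printed sexes reverse this is handled accordingly). ClinVar levels use the
printed ClinVar column where present, otherwise the printed P/LP
classification. The quad family appears as its research design: father and
two affected twins, no maternal sample, so the shared twin variant yields
two candidates from one VCF record. Evidence flags ship as unknown — all 14
variants were curated and returned, so all 14 are reportable; the exclusion
clauses are exercised separately with synthetic flags. The counts fixture
embeds the published per-family assessed/diagnostic/reportable columns
(totals 109, 38 and 77) plus HPO term counts tallied from the published
phenotype table.

## Problem sizes and numerics

Randomised checks run on 1000-variant four-family cohorts (oracle
equivalence, threshold monotonicity, panel monotonicity) and on twenty
90-variant three-family cohorts (planted recovery) — sizes chosen so the
whole suite exercises every property in seconds while still covering all
five plant models and all violation classes. Exact-test oracles enumerate
completely (≤ 10 Wilcoxon pairs, 2×2 tables with N ≤ 40). Rates are rounded
half-even to 2 decimals; p-values are reported unrounded.

## Known limitations

- Phase is inferred from parental genotypes only; read-backed phasing is
  out of scope, so comp-het pairs with an unsequenced parent remain
  `phase_unknown` rather than resolved.
- CNVs, SVs and STR expansions are outside the comparison by design.
- Exomiser rank/score are consumed as variant-level annotations; a true
  per-family rank would require per-sample INFO, which the flat dialect does
  not model.
- REVEL is carried as annotation only; no threshold is applied to it.
- The GMS emulation reproduces the documented tiering rules, not the
  laboratory's software; where the published rules are silent (carrier
  policy, de novo AF), it reuses this package's documented choices.
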