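# Methods

## Data model and conventions

A variant is keyed by its positional identifier,
`chr<label>:<position>_<ref>_<alt>`, with 1-based fully closed coordinates;
indels use `*` as the reference token and a `+SEQ`/`-SEQ` payload. The
identifier is the interchange key across all tables, so no coordinate
conversion happens anywhere. Cell lines are named `TISSUE:NAME` with nine
tissue prefixes (BR, CNS, CO, LC, LE, ME, OV, PR, RE); per-variant
*percent conversion* is the fraction of reads supporting the variant
allele in a line (≈ 50 heterozygous, ≈ 100 homozygous, 0 absent).

Missing numeric cells (SIFT, PolyPhen-2, population frequencies, assay
z-scores) are typed as unknown and excluded from statistics, never imputed
as zero: a zero SIFT would flip a variant into the damaging class, and a
zero z would count as "no response" where no assay was run. TSV is the
canonical on-disk dialect; the two-sheet summation workbook is an optional
writer (xlsx or sectioned TSV) with a reader provided for round-tripping.

## Functional classification

Amino-acid-changing consequences: missense, splicesense, frameshift,
read-through, non-frameshift indel, premature stop. Function-affecting
categories are mutually exclusive with priority splicesense > frameshift >
premature stop > score-based, so category counts partition the catalog.
Missense variants qualify via SIFT < `sift_max` (default 0.05, strict,
so a score exactly at the threshold is tolerated) **or** PolyPhen-2 ≥
`polyphen_min` (default 0.85, inclusive); either score alone suffices and
an unknown score never satisfies its criterion. Homozygosity is inferred
from percent conversion ≥ 95; "absent from the normal genomes" means the
frequency cell is missing *or* exactly 0 in both reference columns, since
exports encode absence both ways.

## Frequency enrichment

Panel frequency of a variant is the mean allelic fraction over the panel
(percent/100, absent lines contributing 0). The reference frequency uses
the exome-sequenced reference column only; the whole-genome reference
column is carried but unused here because mixing sequencing modalities
would distort the ratios. Variants absent from the reference have no
defined ratio and are excluded (they belong to the catalog filter's
cancer-associated class).

Enrichment takes the top `tail_fraction` (0.025) of the descending ratio
ranking, gated at ratio ≥ 10, and *extends the class to every variant tied
with the one at the cutoff position* — the tail boundary never splits a
group of equal ratios; depletion mirrors this at the bottom with ratio ≤
0.1. Tie equality is tested at relative tolerance 1e-12 (exact rational
comparison would require carrier counts that exported tables do not always
provide). The functional-fraction profile is a simple moving count over
the ratio-sorted list (window 2001, odd), reported against the
window-centre ratio.

## Drug response

GI50 rows are transformed per compound: `z = (−log10 GI50 − mean)/SD` over
observed lines, population SD, following the panel's established z-score
convention; precomputed z rows can be supplied directly and bypass this
step. All-missing and zero-variance rows are excluded and flagged rather
than NaN-propagated. Response categories use inclusive outer boundaries
(sensitive z ≥ 0.5, resistant z ≤ −0.5); missing cells are excluded from
counts and are distinct from "no response". Fold ranges between lines are
computed on raw resistance:sensitivity ratios, not the −log10 display
values, because an "N-fold range" is a ratio-of-ratios statement.

## The association screen

Carriers are lines with percent conversion > 0 — heterozygotes count,
which published carrier tallies require. Eligibility per variant:
amino-acid changing, ≤ 12 carrier lines, not in a segmental duplication,
not multi-mapping; presence in the normal genomes is deliberately *not* a
criterion, so both somatic and germline influences can surface.

For each gene × compound × direction the search enumerates all non-empty
variant subsets of size ≤ 5 (carrier set = union of the subset's
carriers, restricted to evaluable lines) and maximises MCC, with ties
broken toward fewer variants, then higher precision, then
lexicographically smaller identifiers. Carrier sets are packed into
integer bitmasks so a subset's table costs a few popcounts. Genes with
more than 25 eligible variants (≈ 68 k subsets) fall back to greedy
forward selection, flagged in the output; tests assert greedy MCC never
exceeds exhaustive MCC. The maximising subset is reported only if it
clears *all* gates — MCC ≥ 0.596, precision ≥ 0.70, gene overall
precision ≥ 0.50, TP ≥ 3 — and gates are applied to the MCC-optimal
subset, not searched for separately.

Interpretive choices where the procedure was underdetermined:

- **MCC significance.** MCC equals the Pearson correlation of the two
  binary indicator vectors (a property the tests assert exactly), so p
  uses the Pearson t transform, `t = mcc·√(n−2)/√(1−mcc²)` with n−2 df,
  two-tailed. This reproduces the stated gate (p ≤ 2×10⁻⁴ at MCC 0.596,
  n = 35). p is computed at each pairing's actual evaluable n; the MCC
  gate itself stays fixed at 0.596.
- **Gene overall precision** is defined as the precision of the union of
  *all* the gene's eligible variants' carriers against the same responder
  set.
- **Recall** is TP/(TP+FN), the standard definition matching the prose
  "fraction of cell lines with drug response that also have variant(s)";
  a conflicting printed formula (FN/(TP+FP)) is treated as a typo.
- **"At least three consistent cell lines"** is read as TP ≥ 3.
- No multiple-testing correction is applied beyond the fixed gates; the
  screen reports all passing pairs.

The provenance partition totals the winning subsets' variants at four p
thresholds (0.05, 2×10⁻⁴, 1×10⁻⁶, 1×10⁻⁸) by presence/absence in the
normal genomes; the two fractions sum to 1 per threshold.

## Variant summation

The per-gene combination `100·(1 − Π(1 − Pᵢ/100))` treats each variant's
percent as an independent event probability; the cap at 100 is a property
of the complement-product, not a clip, and a Monte-Carlo union-frequency
oracle (10⁵ draws, 3 SE) confirms the interpretation. The
function-affecting sheet applies the category and absence criteria but not
the homozygosity filter, matching the web tool's description of that
subset. The 150-gene query cap is a configuration default, not an
architectural limit. Multi-gene totals sum summaries per line without cap.

## Pattern comparison

Pearson correlation per compound over pairwise-complete observations
(per-drug n reported, minimum 3), t-based two-tailed p, ranking by |r|
with NSC id as the stable tie-break. A constant pattern is rejected
(correlation undefined). Pathway-target enrichment is the conventional
two-tailed Fisher exact test — the sum of all 2×2 table probabilities not
exceeding the observed table's — delegated to `scipy.stats.fisher_exact`
and cross-checked in tests against exhaustive hypergeometric enumeration
over every table with N ≤ 40.

## Synthetic panels: what they emulate, and what they do not

The generator reproduces the *shape* of the real screen: 60 lines over
nine tissue prefixes, sparse carriers at rate 0.08 per variant-line with
het/hom levels {50, 100}, change types cycled so every functional category
appears, and per-compound z rows drawn standard normal and restandardised
(population SD). Defaults of 20 genes × 3 variants and 10 compounds keep
desk-scale experiments fast while leaving ≈ 400 gene–drug–direction tests
per panel — enough for the null-rate checks to be meaningful. A planted
pair shifts its gene's carrier lines by `effect_sd` on the noise scale
*before* restandardisation; planted genes carry exactly
`planted_carrier_n` lines (default 8) spread over their variants and stay
screen-eligible. Reference-frequency simulation surrounds planted
enriched/depleted variants with a log-normal ratio background (σ = 0.5)
centred on parity, which essentially never crosses the ratio-10/0.1 gates
on its own.

Not emulated: mutational signatures, linkage between variants, tissue
effects on drug response, assay dropout patterns, or dose–response curve
shape. Passing tests therefore demonstrate correctness of the algorithms
under idealised independence assumptions, not recovery performance on
real panels.

### Detectability of planted effects at the screen's gates

The screen's gates set a hard floor on detectable effect sizes that is
worth stating explicitly. With 8 carriers of 60, a 2-SD pre-
standardisation shift leaves non-carrier lines responding at ≈ 19 % (the
restandardised threshold sits ≈ 0.87 noise-SD above their mean), i.e.
E[FN] ≈ 10 of 52. Even a *perfect* carrier classifier — table
(8, 0, FN, 52−FN) — clears MCC 0.596 only when FN ≤ 10, which happens in
roughly half of panels; the realised pass rate is ≈ 25–30 %. At a 3-SD
shift recovery reaches ≈ 85 %, and at 4 SD ≈ 99 %. The test suite
therefore asserts reliable recovery at the 4-SD effect and documents the
2-SD regime as fundamentally gate-limited, not an implementation defect.
Null panels (no planted effect) yield essentially zero reported pairs, so
the gates' specificity is intact at desk scale.

## Numerical choices and degenerate inputs

- MCC of a table with any empty marginal is 0 by contract; |MCC| = 1 maps
  to the smallest positive double rather than p = 0.
- Drug-row standardisation and the generator use population SD throughout.
- Subsets tie-break deterministically (fewer variants, higher precision,
  smaller identifiers), so outputs are reproducible across runs and
  platforms.
- Empty inputs degrade softly where a practitioner would expect (empty
  catalog → zero counts; empty gene list → headers-only workbook; unknown
  gene symbol → warning and empty profile) and raise where silence would
  corrupt results (empty panel, disjoint panels, constant pattern,
  out-of-range percents).
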