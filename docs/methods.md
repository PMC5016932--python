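# Methods

This note documents the statistical procedures, the model behind the
synthetic-screen generator, the numerical conventions, and the design choices
made where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Screen model and units

A pooled dropout screen measures, per sgRNA *i* and sample *s*, a read count
proportional to the guide's relative abundance in the cell pool. Samples are
labeled with a time point and replicate; exactly one time point is the
baseline (the pre-selection harvest). All downstream statistics operate on
log2 fold changes versus that baseline.

## Quantification

A read is assignable to a guide when some window of the read — or of its
reverse complement — equals the guide's 19–20-nt spacer within a Hamming
distance budget (default 1, maximum 1). "Mismatch" means substitution only:
with spacers this short, an indel-tolerant definition would both blur the
contract and preclude the exact brute-force oracle the tests use. A read
within budget of two or more distinct guides is *ambiguous* and is discarded
by default (`ambiguous_policy="first"` instead takes the first window's
lexicographically smallest id); discarding can undercount but never inflates
a guide. Conservation (`assigned + ambiguous + unassigned = total`) holds by
construction and is asserted in tests. The matcher indexes spacer halves
(pigeonhole: one substitution leaves at least one half exact), so the default
all-windows scan stays linear in read length; a fixed-offset fast path exists
for vectors without staggered primers.

## Normalization and fold changes

The normalization is upper-quartile based, in two steps:

1. scale each sample by `target / UQ_s`, where `UQ_s` is the sample's 75th
   percentile raw count (linear-interpolation quantile) and `target` is the
   mean of the `UQ_s`;
2. apply one global constant `g` chosen so the mean per-sample total equals
   10⁶.

Step 1 equalizes upper quartiles across samples (asserted to 1e-9 relative
tolerance); step 2 puts values on a counts-per-million magnitude so the
pseudocount of **0.1 CPM** has its stated unit. The composition `g · target /
UQ_s` makes each sample's normalized values invariant under rescaling of its
raw counts, and the single-sample case reduces exactly to plain CPM. Whether
"CPM" should be read as post-upper-quartile or as a plain per-million scale is
genuinely ambiguous; this construction satisfies both readings at once and is
declared, not inferred.

The pseudocount is added *after* normalization and *before* any averaging.
Replicates are averaged arithmetically on the pseudocounted normalized scale
— not as a mean of logs — and the fold change is
`log2(mean_timepoint / mean_baseline)` per guide. The pseudocount guarantees
finiteness; the baseline against itself is identically zero.

Percentile conventions, stated once and used everywhere: linear-interpolation
quantiles for count distributions (normalization, QC), nearest-rank for the
hit cutoff (below). Rank correlations (replicate QC) use average ranks on
ties.

## sgRNA-level hit calling

At a time point, let D be the guides with log2FC < 0. The cutoff is the
nearest-rank 5th percentile of D — the m-th smallest value with
m = ⌈fraction·|D|⌉ — and the hit set is every guide with log2FC ≤ cutoff.
Nearest-rank gives reproducible integer semantics; including ties at the
cutoff errs toward sensitivity and keeps the hit set closed. Hit-set size
equals m exactly when values are distinct, and never shrinks as the fraction
grows (both property-tested).

For the expression cross-check, a "hit gene" is any gene owning at least one
hit guide — the weakest consistent mapping from guide hits to genes. The
reported fraction-not-expressed uses only genes the expression table measures;
unmeasured genes are listed separately, never counted. The default expressed
threshold is 1.0 normalized expression unit (CPM/TPM-like), configurable —
no principled universal value exists, and 1 is the field's customary floor
for "expressed at all".

## Gene scores

**Q1** is the mean of a gene's two lowest guide log2FCs. With exactly two
guides it is their mean; with one it is undefined and the gene is flagged
(`q1_flag`) rather than dropped — degenerate libraries must still flow
through.

**RSA-down** ranks all targeting guides ascending by log2FC (rank 1 = most
depleted), breaking ties by sgrna_id for determinism. For a gene with k
guides at ranks r_1 < … < r_k among N, the score is log10 of the minimal
upper-tail hypergeometric probability P(X ≥ j) for X the number of the gene's
guides in a size-r_j draw without replacement from N items containing k.
Non-targeting controls are excluded from the universe N by default
(configurable): genes are being scored, and controls would dilute N without
ever receiving a score. No per-guide activity bounds are applied — every
guide participates — keeping the statistic free of tuning parameters. For
k = 1 the score reduces to log10(r_1/N) exactly; improving any guide's rank
can only improve the score (both tested, alongside equivalence to an exact
`Fraction`-arithmetic tail enumeration to 1e-9 in log10 p).

Candidate ranking is ascending RSA-down, ties broken by Q1 ascending
(undefined Q1 last), then gene symbol. Only the depletion side is computed;
an enrichment-side analogue would serve positive-selection screens, which are
out of scope here.

## Gene-set enrichment

Per gene, the summarized value is the guide log2FC of maximal absolute value
(sign kept); on an exact magnitude tie the negative value is returned,
consistent with a dropout screen's focus. Each gene set (GMT input) is first
intersected with the measured genes, then retained if its intersection size
lies within the inclusive bounds (default 20–2000). The test compares the set
against the **complement** of measured genes — set-vs-rest keeps the null
exact under exchangeability, whereas set-vs-all would test a set partly
against itself.

The one-sided KS statistic is D_neg = sup(F_set − F_bg) (depletion side) or
its mirror, and the p-value is the classical asymptotic exponential bound
`p = exp(−2D²mn/(m+n))`, capped at 1 and floored at 1e-300 so downstream
−log10 arithmetic stays finite. This bound is conservative-to-nominal under
the null; the acceptance suite verifies a rejection rate within [0.02, 0.08]
at α = 0.05 over 1,000 null sets. An exact-permutation mode
(`method="permutation"`, sets of ≤ 10 genes) enumerates all splits of the
pooled sample and serves as the oracle in tests. Benjamini–Hochberg
adjustment is applied separately to the negative and positive families,
matching the separate ranking of the two tails; selection takes, per
direction, the sets strictly above −log10 p = 7 (boundary excluded), best
first, truncated to 20.

## Synthetic screens

The generator emulates the screened library's shape — 3 guides/gene plus
non-targeting controls — and produces counts from:

    w_i(t) ∝ exp(a_i + δ_g(i) · e_i · t)

with baseline log-abundance a_i ~ Normal(μ₀ = 0, σ₀ = 1) (log-normal
abundances), per-day fitness effect δ_g per gene class, and per-guide
efficacy e_i from a mixture: with probability π_eff = 0.7 a high component
Beta(8, 2), else a low component Beta(2, 8). The mixture reproduces the
one-in-three-effective guide pattern seen in real screens without claiming
its true rates; all of these are declared free parameters. Each replicate is
an independent multinomial draw of `depth` reads from w(t) — totals are
conserved exactly, reflecting the compositional nature of pooled sequencing —
with an optional per-replicate Gamma(1/φ, φ) perturbation of w when the
overdispersion φ > 0 (default 0: multinomial noise only). Under this model a
guide's expected log2FC is δ·e·t/ln 2, which the tests verify in the
high-depth, flat-baseline limit.

Default study conditions: 1,000 genes (full scale would be ~19,000), 20
"core essential" genes at δ = −0.3/day and 5 "driver" genes at δ = −0.25/day,
1,000 controls, duplicates at elapsed days 0/24/31/38, depth 5×10⁶. The
elapsed-day convention folds the 10-day selection gap between the baseline
harvest and the later harvests into one monotone clock (baseline = day 0,
later harvests 24/31/38): effects accrue from transduction, not from the
first post-selection label. A planted gene whose three guides all drew the
low-efficacy component is an *allowed miss* and is flagged in the recovery
report rather than counted against recall — that failure mode is a property
of screens, not of the analysis.

What the simulation does **not** model: PCR amplification bias, copy-number
artifacts (sgRNAs in amplified regions depleting regardless of gene
function), guide off-target activity, and cell-cycle or density effects.
Passing recovery tests therefore demonstrates the pipeline's statistical
machinery under the declared generative model, not robustness to those
real-data artifacts.

The design calculators are exact integer arithmetic:
`required_cells = n_sgrna × representation` and
`required_infected_cells = ⌈required_cells / (moi × retained_fraction)⌉` —
ceiling, not rounding, because the quantity is a lower bound on cells.

## Pipeline determinism

The orchestrator runs library → counts (file or FASTQ) → QC → normalization →
fold changes → hit calling → gene scores → expression cross-check →
cumulative score → enrichment, wrapping each stage's errors with the stage
name. All TSVs are written with a fixed `%.10g` float format and fixed column
order; the manifest records a parameter hash and the sha256 of every
artifact, and reruns under the same config are byte-identical (asserted in
the acceptance suite). All simulator randomness flows from one integer seed
through `numpy.random.default_rng`.

## Problem sizes used in checks

The automated checks run the reference simulation at 1,000 genes / 4,000
guides and depth 5×10⁶ (seconds on one CPU), the RSA oracle on 200 random
instances with N ≤ 500 and k ≤ 5, and the KS calibration on 1,000 sets of 30
from a 5,000-gene background; the published-scale numbers that depend on the
original deposited sequencing data (hit counts per cell line, replicate
correlations, coverage percentages) are not reproducible from synthetic data
and are deliberately not asserted anywhere.

## Known limitations

- The quantifier's Hamming contract is a declared simplification of
  local-alignment-based counting; soft-clipped partial matches are not
  assignable.
- The asymptotic one-sided KS p-value is anti-conservative for very small
  sets; use the permutation mode there.
- RSA-down p-values are rank statistics for ordering, not calibrated
  significance levels; no FDR is attached to them.
- No copy-number correction is applied to depletion scores.
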