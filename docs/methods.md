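# Methods

## Model and coordinate system

All isomiR classification happens in hairpin space. A reference consists
of precursor hairpin sequences (RNA alphabet; DNA input is converted on
read) and mature annotations, stored internally as 0-based half-open
intervals on the hairpin. The canonical mature sequence is by definition
the annotated hairpin substring, so the reference is self-consistent and
round-trips through FASTA + TSV byte-for-byte. Genome alignment is out of
scope: every quantity the pipeline computes — offsets, tails,
substitutions, seeds — is defined relative to the hairpin and its mature
interval, so hairpin-space placement is sufficient and unambiguous.

## Read placement and variant classes

A read is evaluated against every candidate (mature, 5'-offset) pair
proposed by a k-mer anchor table (k = 12 by default) over the hairpins,
with an exhaustive fallback when no anchor fires (this covers
substitutions in the middle of short reads, where no error-free k-mer
window exists). For a candidate placement the read body is compared
base-by-base to the hairpin up to the mature 3' end; any 3' overhang is
split into a templated prefix (longest base-by-base match with the
hairpin downstream of the mature end) and a non-templated tail. The
placement minimizing the lexicographic key

    (substitutions, |d5|, |d3| + tail length)

wins; ties across distinct matures are dropped as ambiguous by default
(fractional assignment is available behind `AssignmentPolicy.multimap`).
Defaults: |d5| ≤ 3, |d3| + tail ≤ 5, at most one substitution, read
length 16–30 nt. The offset windows cover the deepest modifications seen
in beta-cell libraries (3' trims up to 4 nt); the 1-substitution cap
bounds false NucVar calls from sequencing error. Reads with two or more
substitutions are unassigned rather than called: with per-base error
rates at Q30 the double-error mass is negligible and a permissive cap
would mostly admit artefacts.

Classification order: Canonical (no change at all); substitution plus
any length change → MultiVariant; substitution only → NucVar; 5' and 3'
change together → MultiVariant; 5' only → Trim5p/Ext5p; any non-templated
tail → NTA; 3' trim → Trim3p; 3' templated extension → Ext3p. A
non-templated tail dominates the 3' call (NTA after trimming or after a
templated extension is still NTA, not MultiVariant): NTA is a standalone
class parallel to Trim3p/Ext3p, and MultiVariant is reserved for 5'+3'
or substitution+length combinations. RNA-editing-aware interpretation of
substitutions is not modelled; all substitutions are generic NucVar.

Display names are systematic and parseable: the species/"miR" prefix is
stripped from the mature name and components are printed 5'→3'
(`isomiR-411-5p-Ext5p(+1)`, `isomiR-1-5p-Trim3p(-2)`,
`isomiR-375-NucVar(5G>A)`); parsing a name recovers the offsets and,
through the classification procedure, the class.

Seeds: the conservation flag compares read and canonical seeds at
positions 2–7 (6-mer); report-facing seeds use positions 2–8 (7-mer).
Both are one configurable parameter (`seed_start`, `seed_length`), since
the two conventions coexist in the field and a 6-mer flag with a 7-mer
display matches how results are usually printed.

## Abundance filter

A sequence is removed when its share of its parent miRNA's summed RPM —
per-sample shares averaged over a dataset's samples, samples with a
silent parent excluded — is strictly below 1%. The share is per parent
miRNA, not per library: an isomiR of a weakly expressed miRNA would
otherwise always fail regardless of its relative weight. Removal is
decided per dataset (one decision per sequencing experiment); in a
multi-dataset matrix a row is dropped only if it fails in every dataset
where its parent is observed. The in-silico validation draws reads from
canonical sequences only, injects independent per-base substitution
errors, and runs the real caller and filter: each single-error sequence
captures an expected share ε/3 of its parent's reads (ε = 10⁻³ at Q30
gives ~0.03%), so every error-born row sits far below the 1% threshold
and is removed, while canonical signal is untouched. Spurious survival
is monotone non-increasing in the threshold by construction.

## Normalization

Median-of-ratios: the pseudo-reference is the per-row geometric mean
over samples (rows with any zero excluded), and each sample's size
factor is the median of its count/reference ratios. Under this
convention scaling one of m samples by c moves every factor through the
reference by c^(1/m); factor *ratios* scale exactly by c and normalized
counts are invariant up to the common constant. A pseudo-reference
fallback (geometric mean over nonzero entries) is available for sparse
matrices with no all-positive row. Normalization is applied at the
sequence (isomiR) level.

## Composition and signature

Class fractions are within-miRNA proportions averaged over a dataset's
samples (samples where the miRNA is silent are excluded), hence
invariant to per-sample scaling. Dominant-class ties break by the fixed
precedence Canonical > Trim3p > Ext3p > NTA > Trim5p > Ext5p > NucVar >
MultiVariant. Consistent miRNAs are those whose summed normalized
expression exceeds 20 in every dataset (strict inequality). The PCA
feature vector is the concatenated per-(miRNA, class) fractions —
the stricter reading of "composition of each miRNA" — centered but not
variance-scaled (features are same-unit fractions; scaling would inflate
rare classes; a flag enables it), with component signs fixed so the
largest-magnitude loading is positive.

The signature applies, per dataset: (1) drop canonical sequences;
(2) keep mean normalized counts ≥ 20 (the funnel legend excludes "<20",
hence ≥ at the boundary, whereas consistent-miRNA selection uses the
strict ">20" of its own definition — both are parameters and the
defaults mirror the two phrasings); (3) keep contribution ≥ 50%, where
contribution is the sequence's mean counts over the canonical
*sequence's* mean counts for the same miRNA (a flag switches the
denominator to the miRNA total). A miRNA with no expressed canonical
sequence yields an infinite ratio and passes — miRNAs expressed
exclusively as isomiRs exist and must not be silently dropped. The final
signature is the intersection of survivors across datasets, computed
dataset-wise (not pooled). The seed partition puts every 5' length
variant in the seed-shifted half and errors on a 5' variant flagged
seed-conserved, which would indicate a caller bug (a periodic seed
region could in principle legitimately trigger this; none of the
references used here do).

## Clinical association

For each (isomiR, parameter) pair: OLS of log2(normalized counts + 1)
(pseudocount avoids log 0 on sparse donors) on the parameter plus age,
sex and BMI with intercept; two-sided t test on the parameter
coefficient; partial R² = t²/(t² + df_resid), identical to the
SSE-reduction form against the model without the parameter (asserted to
1e-10 in tests). The expression-as-response direction is the default; a
`swap_response` flag fits the reverse direction, which is not equivalent
once covariates are present. Influential donors with Cook's distance
above 4/n are removed in a single pass and the model refit once — a
deterministic version of the standard rule. Note the calibration
trade-off: on clean Gaussian null data at n = 16 the removal pass
inflates the nominal 5% rejection rate to roughly 12%, so the package's
calibration checks exercise the fit with the pass disabled; the pass is
a robustness device against gross outliers, not part of the nominal
inference. No multiple-testing correction is applied by default
(matching the p < 0.05 reporting convention); Benjamini–Hochberg is
available behind `adjust="bh"`. The association matrix holds
sign(β)·√(partial R²) for significant pairs and 0 elsewhere.

## Targetome analysis

Differential-expression tables are consumed, never produced. Regulated
sets use adjusted p < FDR with strict sign on log2FC. Overlaps are
tested with the one-sided hypergeometric upper tail P(X ≥ k), summed
exactly in log space (gammaln + logsumexp) and exhaustively validated
against brute-force enumeration for all universes N ≤ 12; k at the
feasibility lower bound returns exactly 1. The default universe is the
intersection of genes tested in both tables (configurable) — the
appropriate choice when the two contrasts were measured on different
gene sets. Seed-site scanning implements the four canonical site
classes only — 6mer (perfect match to seed 2–7), 7mer-m8 (plus mature
position 8), 7mer-A1 (plus an A opposite position 1), 8mer (both) — with
each occurrence counted once in its most specific class; a transcript is
a predicted target if it has at least one 7mer or 8mer site. No
conservation weighting or context scoring is applied: for novel
(shifted) seeds the core prediction signal is seed-site matching, which
is what the divergence analysis needs.

## Synthetic data

The generators are pure functions of (spec, seed) and emit exact truth
tables.

*Reference*: random hairpins with one or two mature arms, ≥ 8 nt of
flanking context and a 12 nt loop, so every templated extension class is
realizable.

*Reads*: the planted variant universe is enumerated per miRNA — one
sequence per (class, offset) drawn from the configured offset/tail
distributions — and reads are drawn multinomially from it per sample,
then per-base substitution errors are injected at rate ε
(substitution-only error model; indel sequencing error in short reads is
comparatively rare and would complicate exact truth accounting). Default
composition echoes a 3'-dominant beta-cell-like profile (Canonical 0.45,
Trim3p 0.30, Ext3p and NTA 0.08 each, small 5' and substitution
classes); 3' trims span 1–4 nt; NTA tails are A/U-rich, with the first
tail base forced non-templated so the planted class is well defined;
trim lengths are capped so reads stay within the caller's length window.
A planted-variant sequence collision (two truth identities for one
sequence) would make scoring ambiguous and raises; with random
references it does not occur in practice.

*Cohorts*: donors with age ~ N(55, 10) years, BMI ~ N(26, 4) kg/m²,
sex ~ Bernoulli(0.5), a standard-normal clinical parameter, and focal
isomiR log2 expression = baseline + β·parameter + covariate effects +
N(0, σ²), back-transformed to counts.

*DE tables*: exact planted Venn structure over synthetic gene symbols,
significant genes below the 0.05 cutoff with sign-consistent fold
changes.

*UTRs*: planted sites are embedded in background rejection-sampled to
contain no 6mer core of any planted seed, with flank guards preventing
class upgrades; every transcript is verified by rescanning. For seed
pairs shifted by 1 nt some designs are structurally unrealizable (an
8mer for one seed can unavoidably contain a flagging site for the
other when the mature starts with U); the generator raises in that case
rather than emit a fixture that contradicts its own truth table.

What the synthetic data does *not* emulate: UMI structure, adapters,
quality-score profiles, ligation bias, expression heterogeneity across
miRNAs beyond the configured weights, or correlated errors. Passing
tests therefore demonstrate correctness of the algorithms under the
declared generative model, not robustness to every artefact of real
libraries.

## Problem sizes and numerics

The test suite and the acceptance script use 10 synthetic hairpins
(~13–16 matures), libraries of 10⁵ reads for recovery and filter
validation, 4 datasets × 3 samples for signature recovery, 2000
replicates of n = 16 donors for null calibration, and exhaustive
hypergeometric checks to N = 12 — sizes at which multinomial sampling
error (≤ ~0.2 percentage points on class fractions at 10⁵ reads) sits
comfortably inside the asserted tolerances. Ties in read placement
resolve by smallest (d5, d3); dominant-class ties by the fixed class
precedence; PCA signs by the largest-magnitude loading. RPM requires at
least one assigned read per sample; median-of-ratios requires two
samples and an all-positive row (or the pseudo-reference flag);
association fits require eight complete donors and a full-rank design.

## Known limitations

Multimapping reads are dropped (or split evenly with the fractional
flag) rather than rescued by expectation-maximization; hairpin-space
placement cannot detect isomiRs of unannotated loci; the NucVar cap of
one substitution conflates RNA editing with sequencing-error survivors
at very high depth; seed-site scanning ignores site context and
conservation, so predicted-target sets are noisier than scored
predictions; and the abundance filter assumes errors are independent
per base — systematic, position-correlated errors would evade the ε/3
expectation argument.
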