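# Methods

This note documents the models and procedures implemented in `hazardcp`,
the parameters that matter, the numerical conventions, and what the
synthetic benchmark does and does not demonstrate.

## Problem setting

One H-statement group at a time is treated as a binary task: a compound
is *active* (carries at least one statement of the group) or *inactive*
(conclusively data-sufficient but unclassified). Real datasets of this
kind are strongly imbalanced (from ≈3% actives for acute oral toxicity
groups to ≈49% for long-lasting aquatic toxicity), contain salts,
mixtures of fragments and metal-containing species, and carry label
ambiguity from conflicting dossier entries. All three properties shape
the design below.

## Standardization and splitting

SMILES are parsed and canonicalized with RDKit's sanitizing parser;
unparseable structures are flagged and excluded downstream, never
silently dropped mid-pipeline, and multi-fragment SMILES are kept whole
(the string featurizers handle every SMILES symbol, and a counter-ion
can be toxicologically relevant). Cross-validation uses k = 10 folds.
The fold blocks are drawn from a seeded permutation by default rather
than file order — ordered input files otherwise leak compound-series
structure into folds — with `shuffle=False` available to reproduce a
plain unshuffled k-fold. Within each fold, 20% of the training portion
(`cal_frac=0.2`, i.e. `|cal| = round(0.2·(n − |test|))`) is drawn at
random, unstratified by default, as the conformal calibration set; a
stratified option exists for very small minority classes. Duplicate
structures are not merged; an optional canonical-SMILES deduplication is
left to the caller since merging changes the class counts being
emulated.

## Featurization

**Character N-grams.** Every character is mapped to a fixed 3-digit code
(101–177, covering lower/upper-case letters, digits, ring, branch, bond,
charge and stereo punctuation). A window of *n* ∈ {4, 6} characters is
encoded by decimal concatenation of its codes — an arbitrary-precision
integer; no overflow is permitted — and reduced modulo the hash length
*h* ∈ {64, 256, 1024}; the landing position's count is incremented and
the window advances one character. A string shorter than *n* yields the
zero vector: no complete window exists, and discarding such records
would silently change dataset sizes. The count vector therefore sums to
max(0, L − n + 1) for a length-L string.

**Token N-grams (pair encoding).** SMILES are first split losslessly
into chemically atomic tokens (bracket atoms, two-letter halogens and
`%NN` ring closures stay whole); an optional set of byte-pair merges
learned from a corpus (greedy most-frequent-pair, lexicographic
tie-break for determinism) fuses frequent adjacent tokens. Each distinct
token receives a fixed-width 4-digit code (1001, 1002, ... in first-seen
order, persisted with the model); windows of 4 token codes are
concatenated and hashed exactly like character N-grams. Fixed width with
no leading zeros is what keeps decimal concatenation injective; running
out of 4-digit codes raises rather than wrapping.

**Re-encoded strings.** Two alternative molecular string encodings are
implemented in-package and fed to the same character-level k-merizer
(their alphabets are subsets of the N-gram dictionary): a
parenthesis-free rewriting in the DeepSMILES spirit (branches closed by
counted `)` symbols, rings by a size digit at the closing atom) and a
self-referencing bracket-token encoding in the SELFIES spirit (atom
tokens plus `[BranchK]`/`[RingN]` tokens carrying branch length and ring
reference inside the token). Both have exact decoders, and round-trip
equivalence (original vs decoded molecule, compared as RDKit canonical
SMILES) is enforced by tests over the synthetic chemical space; the
encodings are this package's own codecs and are not guaranteed
token-compatible with other implementations.

**Circular fingerprints.** Morgan count fingerprints (radius 2 or 4,
folded to 1024, chirality on) come from RDKit's fingerprint generator.
The binary SMILES extended-connectivity fingerprint is implemented here
as SHA-1-hashed circular-environment SMILES shingles (radii 1..r per
atom) folded to 1024 bits. Core–substituent fingerprints are exposed
only as an adapter slot (register a provider callable returning a
1000-bit vector); nothing in the core pipeline depends on one, and the
recommended consensus set deliberately contains only N-gram models.

## Mondrian inductive conformal prediction

The base classifier is a scikit-learn `RandomForestClassifier` with
library defaults, seeded. Nonconformity is α = 1 − P̂(hypothesized
class) — the common default for probabilistic classifiers; the p-value
of class *c* for a test score α is `(#{α_i ≥ α} + 1)/(n_c + 1)` over
class-c calibration scores. P-values are non-smoothed by default (ties
count toward the numerator), which makes predictions deterministic and
conservatively valid; a smoothed, seeded variant is available. Class
inclusion uses the strict rule p > ε, matching the form for which the
validity guarantee is proved; the boundary case p = ε excludes the
class. Prediction sets are therefore nested across ε by construction.
Per-class calibration (the Mondrian taxonomy) gives class-conditional
validity, which is what makes the approach usable on the heavily
imbalanced hazard groups — a global guarantee would be dominated by the
majority class.

## Consensus

`consensus_pvals` takes the per-compound, per-class median across models
(even counts: mean of the central pair, the standard convention) and
derives the set from the median pair. Median p-values are no longer
conformal p-values, so validity of this combination is empirical, not
guaranteed; the evaluation reports it like any other model.
`consensus_cls` takes a majority vote over sets computed at the single
reported ε, ties resolved active > inactive > both > empty, which
prefers flagging a potential hazard over missing one. A model that
cannot featurize a compound (possible for adapter fingerprints on exotic
species) loses its vote for that compound only — consensus stays defined
on salt/metal compounds as long as one member handles them.

## Metrics

Validity and efficiency are computed per class over the compounds whose
*true* label is that class ("both" counts correct, "empty" erroneous;
efficiency counts single-label sets regardless of correctness). The
per-true-class denominator is the reading consistent with the Mondrian
class-wise guarantee; an overall single-label fraction is reported
alongside. Acc, BA = (SE+SP)/2, SE, SP and MCC are computed on the
single-label predictions only; MCC returns 0 when a marginal is zero.
ROC AUC ranks compounds by p_active − p_inactive via the Mann–Whitney
statistic with mid-ranks (ties credit 0.5). Metrics with an empty
denominator are `None`/null, never 0 — silent zeros would corrupt
averages over folds and groups.

## Synthetic benchmark

The generator assembles molecules from ~10 scaffold templates and ~20
substituents, plants one of four toxicophore motifs (nitro, acyl
chloride, nitrile, epoxide) in actives and rejection-verifies their
absence in inactives, appends an ionic fragment to `salt_fraction`
(default 10%) of records, and flips each label independently with
probability `label_noise`. The pre-noise active count hits
`round(n·active_fraction)` exactly; named profiles reproduce the ten
hazard-group imbalance ratios. Defaults: n = 2000, 30% actives, 20%
label noise.

The 20% default noise is deliberate: noise-free labels are perfectly
learnable from structure, which puts conformal prediction in a
degenerate regime (efficiency falls with ε as singletons become empty
sets). With 20% noise the benchmark reproduces the operating
characteristics reported for real hazard data — validity ≈ 1 − ε per
class, efficiency around 0.7–0.8 at ε = 0.2 and increasing with ε over
{0.1, ..., 0.3}, balanced accuracy near 0.7–0.8. Learnability itself is
checked separately on a noise-free dataset (BA > 0.9 end to end).

What passing the synthetic benchmark shows: the conformal machinery is
calibrated (class-wise error ≤ ε within binomial fluctuation), the
featurizers carry real structural signal, salts and metals flow through
the string featurizers, and the consensus algebra behaves. What it does
not show: performance on real regulatory chemical space — the grammar
spans a tiny, clean subset of chemistry with four known toxicophores,
i.i.d. label noise rather than systematic annotation bias, and no
activity cliffs. Numbers on real data will differ; the guarantee (per
class, error ≤ ε under exchangeability) is the part that transfers.

## Problem sizes and determinism

The shipped evaluation and acceptance runs use n = 2000 compounds,
10-fold CV and default 100-tree forests — large enough for the binomial
error bars on a 20% error rate to be a few percent per class, small
enough to run in minutes on one CPU. Every stochastic step (generation,
permutation, calibration draw, forest, smoothed ties) is driven by an
explicit seed; two runs with the same seed produce byte-identical
reports.

## Known limitations

- The DeepSMILES/SELFIES-style codecs support the syntax RDKit's
  canonical writer emits (ring bonds crossing a `.` fragment separator
  are rejected).
- The pair-encoding token vocabulary is corpus-dependent: token codes
  are assigned in first-seen order, so a model's token dictionary must
  be persisted with it (it is) and differs between corpora.
- `consensus_pvals` has no formal validity guarantee (see above).
- Multi-class Mondrian taxonomies, cross-conformal/transductive CP and
  regression CP are out of scope.
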