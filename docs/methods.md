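# Methods

This note documents the models and procedures implemented in `protexp`, the
parameters that matter, the synthetic data the test suite runs on, and the
numerical choices made where the design was genuinely open.

## Expression dataset construction

Protein abundance tables (ppm, PaxDB dialect) are joined to sequences by
protein id (a leading `taxid.` prefix is stripped; unmatched ids are dropped
with a logged count). Proteins are ranked by abundance and split into
tertiles — high, medium, low. The tertile sizes are ⌈N/3⌉ for high, with
the remainder split as evenly as possible favouring medium; ties at a
boundary are broken by protein id ascending, so labeling is a deterministic
function of the table.

Redundancy is removed by greedy incremental clustering in the CD-HIT style:
sequences are visited longest-first and join the first cluster whose
representative they match at ≥ 90% identity, where identity is the number
of matched positions in a global alignment divided by the length of the
shorter sequence (CD-HIT's default normalisation). The clusterer is written
in-package (pairwise alignment via Biopython's `PairwiseAligner`; scores
match +1 / mismatch −1 / gap open −2 / extend −0.5) so no external binary
is needed; a `.clstr` parser is provided for parity checks against a
user-installed CD-HIT.

A cluster's representative is kept only when *every* member carries the
same label and that label is high or low. Clusters touching the medium
tertile, or mixing high and low, are discarded entirely. This is the
conservative anti-leakage reading: the alternative (keep any representative
that is not medium) would let near-duplicates of one class survive in the
other. Medium sequences do participate in clustering for the same reason.
Datasets need more than 1000 surviving entries to be flagged "core"
(training-grade).

Splits: 20% stratified independent test set, then stratified 5-fold
cross-validation on the remainder, all deterministic under one seed.

## Composition statistics

**AEI** (amino-acid expression index), per species and residue:

    AEI_a = mean-freq(a | high class) / mean-freq(a | low class)

where per-class expected frequencies are the arithmetic mean of
*per-sequence* frequency vectors (each protein weighs equally regardless of
length; a pooled-count mode exists behind a flag for sensitivity analysis).
Nonstandard residues (U/O/B/Z/X) are excluded from both numerator and
denominator of per-sequence frequencies. A residue present in the high
class but absent from the low class is an error — no silent pseudocount,
since real 1000+-sequence datasets cannot produce one and smoothing would
corrupt downstream scores. A residue absent from both classes is neutral
(AEI = 1).

**SRAB** (strength of relative amino-acid bias), per protein:

    SRAB = exp( Σ_{i=1..n} log(1 + AEI(a_i)) / (n − 1) )

summed over the n standard residues in sequence order. This geometric-mean
construction mirrors the relative codon bias strength (RCBS) statistic at
the amino-acid level. The placement of the `+1` inside the logarithm is the
adopted reading of the formula's flattened typesetting; it is supported by
the RCBS analogy and by the magnitude it produces (≈1.8 for a typical
protein under an AEI table averaging ≈0.8–1.0, matching reported values),
whereas the alternative reading `exp((Σ log AEI + 1)/(n−1))` would sit near
1.0. This is the single highest-risk interpretive decision in the package.
Useful closed forms: under an all-equal table AEI ≡ c, SRAB =
exp(n·log(1+c)/(n−1)); a homopolymer of residue a tends to 1 + AEI_a as
n → ∞; replacing any residue by one of strictly larger AEI strictly
increases SRAB.

**Cost analysis.** Per-residue biosynthetic costs in high-energy phosphate
bonds (~P) ship with the package (aerobic *E. coli* scale; tryptophan is
the costliest at 75.5 ~P). A protein's synthesis cost is the arithmetic
mean over its standard residues; the analysis reports the Spearman
correlation of cost with abundance and the class mean costs.

**AAindex analysis.** AAindex1 properties are z-scored per property row
with the population standard deviation (denominator 20). Per protein the
mean index value over residues, per species the Spearman correlation of
that value against abundance (abundance, not the binary label — the
continuous variable is what the correlation is reported against), per
property the mean correlation across species; properties with |mean r| >
0.2 are "key". Hierarchical clustering of the z-matrix uses average linkage
on Euclidean distances, with a deterministic child-order tie-break, emitted
as Newick.

## Encoder and training

The encoder is a BERT-style transformer over a 25-token vocabulary (20
residues + `[PAD] [CLS] [EOS] [MASK] [UNK]`): token + learned position
embeddings, an embedding layer norm, then post-layer-norm blocks
(multi-head self-attention and GELU feed-forward, each wrapped in
residual + layer norm), and an untied MLM output head with bias. Padding
keys are excluded from attention. Sequences are encoded as `[CLS]` +
residues + `[EOS]`, truncated to the first `max_seq_len − 2` N-terminal
residues, padded with `[PAD]`; nonstandard residues map to `[UNK]`.

Two presets:

| preset | layers | heads | hidden | ffn | max len | parameters |
|--------|--------|-------|--------|-----|---------|------------|
| full   | 8      | 16    | 1024   | 3200| 1024    | 87,184,409 |
| desk   | 2      | 4     | 64     | 128 | configurable | ~0.1M  |

The feed-forward inner size of the full preset is not independently
documented; 3200 was fixed because it lands the closed-form parameter count
within 0.1% of the reported ≈87.16M total. The closed form is

    V·H + L·H + n·[4(H²+H) + (H·F + F + F·H + H) + 2·2H] + 2H + (H·V + V)

and equals the instantiated count exactly (tested over random configs).

Masking: exactly `round(rate · n_residues)` residue positions per sequence
(minimum 1), chosen uniformly without replacement; special tokens are never
candidates. Each chosen position is rewritten 80% to `[MASK]`, 10% to a
random residue, 10% left unchanged. Exact-count masking (rather than
independent per-position coins) makes the masked-count dimension
deterministic at desk scale; an all-`[MASK]` mode (no 80/10/10) is used for
mutant-generator fine-tuning. Loss is cross-entropy over masked positions
only.

Optimization is Adam with decoupled weight decay (applied to matrix
parameters only) and linear warmup over the first 5% of steps. Defaults:
lr 1e-3, decay 0.01 at desk scale — the production-scale schedule is not
documented anywhere authoritative, so all of this is configurable. The
whole stack runs on an in-package reverse-mode autodiff core over float64
numpy arrays (`protexp.nn`), whose gradients are verified against finite
differences in the test suite; training is bit-reproducible under fixed
seeds on one CPU.

Fine-tuning heads: a 2-way softmax classifier on the `[CLS]`
representation (high = 1, low = 0), one model per cross-validation fold;
the ensemble's **HE-Value** for a sequence is the arithmetic mean of
per-fold high-class probabilities. The regression variant puts a scalar
head on `[CLS]`, trains with MSE on natural-log abundance, and reports
RMSE, R², Spearman.

## Mutant design

The generator is the pretrained encoder continued on a homolog family of
the wild type with 10% all-`[MASK]` masking. Generation masks
`round(0.10·n)` wild-type positions per sample, fresh mask each sample, and
fills each masked position with the argmax over the 20 residue tokens;
probabilities are the softmax renormalized over those 20 tokens (specials
are excluded — predicting `[PAD]` as an amino acid is meaningless; note the
renormalization choice sets the absolute M-Value scale). The **M-Value** of
a sample is the minimum predicted-residue probability over its masked
positions. Duplicate generated sequences are collapsed keeping the maximum
M-Value before the top-k (default 200) cut; ranking ties break by HE-Value
then lexicographically so shortlists are stable. The **mutation rate**
metric is 1 − (fraction of masked positions predicted back to the original
residue).

Per-position **entropy** across the generated pool uses natural log
(maximum ln 20 ≈ 3.0): S_i = −Σ_a p_{i,a} ln p_{i,a}. Positions never
mutated by the generator have S = 0.

The full design pipeline: generate → shortlist by M-Value → score each
survivor with the expression ensemble (HE-Value) → rank by HE-Value →
annotate SRAB under the host AEI table, reporting mutated sites in
`K45E`-style 1-based notation, with the wild type appended as a reference
row.

## Interpretability and cross-prediction

`[CLS]`-row attention: average the last-layer attention over ensemble
folds, average over heads, take the `[CLS]`-query row, drop
`[CLS]`/`[EOS]`/`[PAD]` columns and renormalize to sum 1 over residues.
Renormalization (the raw row is not kept) makes profiles comparable across
sequence lengths.

Cross-species prediction evaluates every species' ensemble on every other
species' independent test set after removing test sequences sharing a ≥90%
identity cluster with any training sequence of the predicting model (train
and foreign test are clustered jointly). Diagonal cells are unfiltered own
tests; empty post-exclusion cells are reported missing.

## Synthetic data

The generators plant known structure so every mechanism is testable
without downloads:

* **Expression datasets** draw high/low classes i.i.d. from residue
  distributions with known ratio; the default high-class distribution
  up-weights K, A, G, D, E, V by 2× over a uniform background (the residues
  consistently enriched in highly expressed proteins), so the ground-truth
  AEI is 2.0·c for favoured and c for unfavoured residues. Log-abundance is
  α·(favourable fraction) + N(0, σ) with α = 4, σ = 0.5, rank-shifted so
  every high abundance exceeds every low abundance — tertile labeling then
  reproduces the planted classes exactly, decoupling AEI-recovery tests
  from labeling noise.
* **Homolog families** substitute each position independently with its own
  tolerance (0 = conserved) from a per-position allowed alphabet.
* **Corpora** are background draws with an optional embedded motif.

What this synthetic world does *not* emulate: real length distributions,
phylogenetic correlation between sequences, domain structure, or any
relationship between composition and folding. Tests passing at desk scale
demonstrate that the mechanisms are implemented correctly and that the
learning dynamics behave as designed — not that the desk-scale models
predict real expression.

## Problem sizes used by the test suite and acceptance script

Desk runs use the 2-layer / hidden-64 encoder at sequence window 66
(sequences of 30–64 residues), a 2,000-sequence mixture pretraining corpus
(uniform + favoured-residue backgrounds, 2 epochs, batch 32), 150
sequences per class for classifier fine-tuning (5 folds, 2 epochs), and a
500-sequence external evaluation set where a stable AUC estimate is
needed. The learning benchmark plants its classes at a 2.5× favoured
weight — clearly separable by construction, so the check measures whether
training works, not where the Bayes boundary of a marginal task happens to
fall; the 2.0× default remains the condition for AEI-recovery statistics.
The shuffled-label control is the standard permutation null (labels
permuted before splitting; trained and evaluated under the same
permutation), averaged over three permutations. The pretraining-versus-scratch comparison runs 10 seeds at a
reduced budget (800-sequence corpus, 4 epochs; 25 sequences per class,
2 folds, 3 epochs) chosen so the whole comparison completes in minutes on
one CPU while the external 500-sequence evaluation keeps the per-seed AUC
estimate's noise well below the observed pretraining margin. AEI recovery
uses 1,000 sequences per class; the recovery check compares the
across-seed mean estimate against the planted truth at three standard
errors of that mean. The planted-conservation check trains the mutant
generator on a 200-member family over a 40-residue wild type with
alternating conserved (tolerance 0) and variable (tolerance 0.9,
two-residue substitution alphabet) positions — two near-equiprobable
alternatives are what make the argmax prediction context-sensitive enough
to show diversity at variable positions.

## Known limitations

* Float64 CPU training: the full-scale preset is constructable and
  countable but not trainable here; all learning results are desk-scale.
* Greedy clustering approximates CD-HIT: cluster memberships can differ
  from CD-HIT's word-filtered heuristics on borderline pairs.
* The SRAB `+1` placement is an interpretation (see above); AEI tables and
  SRAB scores should be compared across implementations before absolute
  values are quoted.
* Argmax generation yields no diversity from a near-deterministic
  generator; entropy profiles are informative only when the homolog family
  gives the model genuinely competing alternatives.
* No dropout or other stochastic regularisation: determinism was preferred
  at desk scale.
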