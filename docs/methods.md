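# Methods

## The model being interrogated

A masked protein language model assigns each sequence position a
predictive distribution over the 20 amino acids given the surrounding
context.  The package asks whether the model's competence on one
*structural category* — all sequences of one CATH-style class, or all
residues of one secondary-structure state — lives in an identifiable
subset of weights.  The probe is a binary mask over the weights: if a
small mask can erase the category's predictability while leaving
everything else intact, the category is factorized.

## Mask parameterisation and training

One logit per maskable slot.  The maskable set is the attention and
feed-forward projection matrices of every block; embeddings, biases,
normalization parameters and the output head are never masked, following
the convention that knowledge probes target representational projections.
Scores are sampled as `s = σ(−(l + g)/τ)` with logistic noise
`g = log(U/(1−U))`, and binarized with a strict threshold
(`m = 1(s > T)`) whose gradient is passed straight through to `s`.  Two
consequences of this parameterisation worth knowing:

* The sampled binary pattern is independent of τ (a slot is pruned with
  probability σ(l) regardless of temperature); τ only scales gradient
  sharpness.
* The *sign convention* is inverted relative to much of the pruning
  literature: a larger logit prunes.

At evaluation time the mask is the deterministic noise-free binarization
of `σ(−l/τ)` against T.  Logits start at −5 (all slots kept, sparsity
≈ 0), so training starts from the intact model and must actively discover
what to remove.

The objective combines suppression (KL to uniform on the suppressed
inputs), maintenance (KL to the frozen model on maintained inputs) and a
maintenance MLM loss under 15% / 80-10-10 corruption.  All three terms
are arithmetic means over included positions in nats.  Each step draws
one suppression and one maintenance minibatch of equal size so the λ
weights keep their meaning regardless of how unbalanced the two sides
are.  Positions whose true token is noncanonical (mapped to UNK) are
excluded from every loss.

### Optimiser and the sparsity-drift problem

Only the logits are trained (Adam, lr 0.05); model weights are frozen and
verified unchanged by hash.  A plain Adam run exhibits *sparsity drift*:
after the suppression loss saturates, tiny but persistent gradients on
weights that are merely unhelpful — not category-specific — are
normalised up to full-size steps, and the pruned fraction grows without
improving the factorization.  The default therefore raises Adam's ε to
1e-4, which damps updates for slots whose gradient magnitude sits well
below ε while leaving strongly-pulled (category-critical) slots at full
learning rate.  With this setting the pruned set concentrates on the
suppressed category's weights and the learned sparsity stays in the
low single digits of percent, the regime reported for large protein
language models.

Default loss weights are λ = (2, 1, 1): the doubled suppression weight
speeds up the suppression–maintenance separation without measurable
maintenance damage at this scale.  Defaults were chosen so the bundled
desk-scale pipeline meets its goals and are recorded in full in
`TrainConfig`; all are configurable.

### Snapshot selection

Every 100 steps the deterministic mask is scored on the validation split:
`composite = ppl_supp,sub / ppl_supp,base − 50 · max(0, ppl_maint,sub /
ppl_maint,base − 1.10)`, i.e. reward suppression, penalize maintenance
degradation beyond 10%.  Training stops early after 5 snapshots without
improvement.  The returned mask is the *earliest* snapshot whose
composite is within a margin (default 0.1) of the best one observed — a
parsimony rule in the spirit of the one-standard-error convention: since
the pruned fraction only grows with continued training while the
composite plateaus, the earliest plateau snapshot is the subnetwork with
the least incidental pruning.

## Synthetic testbed

The generator plants two kinds of learnable structure:

* **Class signal** (sequence level): per-class residue-frequency profiles
  (75% of mass on 5 class-specific residues) plus three class-exclusive
  motifs (5–7 residues, ~5 insertions per sequence).
* **State signal** (residue level): sequences are laid out as H/E/L
  segments with class-dependent state frequencies (class 1 helix-rich,
  class 2 strand-rich); residues are drawn from a blend of class and
  state profiles (blend 0.45); helix segments copy the previous residue
  with probability 0.25 and strand segments copy the residue two back,
  giving each state distinct dipeptide statistics.

Copying preserves the per-position marginal residue law, so with the
blend at 0 and motifs disabled, per-class empirical frequencies converge
exactly to the class profiles (used as a calibration check).

The conditions were chosen to place the pretrained toy model's held-out
perplexity in the high single digits — the regime where large protein
language models sit on real domain corpora.  This matters structurally:
the suppression objective drives predictions *toward uniform* (perplexity
20), so a "perplexity at least doubles" outcome is only reachable when
the baseline sits near or below 10.  Much of the corpus's predictability
is deliberately carried by class-exclusive motifs rather than by
class-agnostic copy rules: destroying a motif memory requires few,
localized weights, whereas gating a shared mechanism class-conditionally
requires many — the former is what keeps the learned sparsity low.

Defaults: 3 classes × 200 sequences, lengths 64–96 (the corpus filter
accepts 64–1024, matching a large model's context window, with both
bounds inclusive).  What the testbed does **not** emulate: evolutionary
couplings, long-range contacts, realistic amino-acid composition, or
homology structure between classes.  Passing tests certify the method's
mechanics (losses, gradients, selection, bookkeeping) and its behaviour
on cleanly separable categories — not performance on real proteins.

The toy model is a 2-block pre-norm bidirectional transformer (width 32,
4 heads, learned positions, weight-tied output head restricted to the
20-amino-acid support; K = 24,576 maskable slots).  It runs on a small
tape-based numpy autodiff engine written for this package, so pretraining
and mask learning differentiate through the same forward code.
Pretraining: 5,000 Adam steps, lr 3e-3 with ×1/3 and ×1/6 decay at 70%
and 90% of training, batch 16, standard 15% / 80-10-10 corruption.

## Evaluation

Perplexity is measured MLM-style: a seeded 15% of positions per sequence
are replaced by the mask token (mask-only at evaluation; mutate/keep are
training-time corruptions) and the true-residue NLL is pooled per
stratum.  The identical corrupted inputs are fed to the masked and
unmasked model, so differences are attributable to the mask alone.
Residue-level suppression scores only J* positions in the suppression
cell and J′ in the maintenance cell.  Empty strata are reported as
absent, never as zero.

Δmetric statistics consume externally computed structure metrics (RMSD /
TM-score / pLDDT) from a table; pairing is by input id.  Per set
(suppression, maintenance) a two-sided paired t-test compares subnetwork
vs baseline values; a two-sample Kolmogorov–Smirnov test compares the
|Δ| magnitudes between the two sets (exact enumeration for samples of
≤ 25, asymptotic above).  Significance (0.05 in the usual convention) is
reported, never enforced.

## Numerical choices

* ε = 1e-9 floors inside all logarithms; KL terms are exact to ~2e-8.
* Uniform noise for the Gumbel transform is clamped to (1e-6, 1−1e-6).
* Threshold comparisons are strict (`s > T`; a score exactly at T is
  pruned).
* Splits: validation and test take `floor(n·f)` records, the remainder
  goes to train (deterministic, maximises training data).  Stratified
  splitting by CATH Class is available by flag; the default is uniform.
* All randomness flows through seeded `numpy` generators; corpus,
  corruption plans, pretraining and mask training are bit-reproducible
  for fixed seeds.
* 0-based positions in memory; 1-based in written TSV reports.

## Known limitations

* The straight-through estimator is biased; gradients are exact only for
  functionals linear in the mask.  The tests therefore check the
  estimator against a central-difference oracle on linear functionals
  and check end-to-end behaviour separately.
* The prose convention for the residue-level MLM restriction is read as
  "selected positions on maintained residues" (M ∩ J′); the suppressed
  positions' MLM loss is intentionally never scored.
* Perplexity under the suppression objective cannot meaningfully exceed
  the uniform ceiling (20); categories whose baseline perplexity is
  already near 20 cannot show a doubled perplexity, at any scale.
* The per-sequence averaging of the maintenance KL (batch mean over
  positions) is one of several defensible conventions; per-sequence
  means differ negligibly at these sequence lengths.
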