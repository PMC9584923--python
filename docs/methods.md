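# Methods

## Scope and coordinate conventions

`ppv` scores candidate endogenous peptides by how their mass-spectrometric
footprint on the precursor backbone resembles that of known, annotated
peptides.  All coordinates are 1-based and inclusive at both ends
(`P41539:58-68` spans 11 residues).  A peptide *form* is one search-engine
row (modified and unmodified forms are distinct); forms are collapsed into
*candidates* at the `(protein, start, stop)` level, with post-translational
evidence carried as intensity-weighted fractions.  Missing per-sample
intensities mean "not detected" and enter totals as zero; no imputation is
performed anywhere.

## Ingestion and the two-engine merge

Identification tables from a MaxQuant-like and a Mascot-like dialect are
validated against the proteome (rows must reproduce the stated protein
subsequence; coordinate-free rows are located by exhaustive substring
search, multi-locus matches kept but flagged).  Standard row filters:
minimum length 7 residues; Mascot score ≥ 20.  Where both engines quantify
the same peptide form, the MaxQuant intensity is kept unchanged.
Mascot-only forms are mapped onto the MaxQuant intensity scale through a
transfer function `log10(y) = a·log10(x) + b` fitted by ordinary least
squares over the forms shared by both engines, applied per sample.  The fit
is per ingest call (per tissue in a multi-tissue workflow); pooling tissues
would entangle instrument batches.

## Backbone profiles and features

Per protein, observations aggregate into positional arrays: summed intensity
of peptides starting/stopping at each residue, positional coverage, and the
amidated-stop / acetylated-start subsets.  One element of zero padding at
each end makes boundary arithmetic total.  By construction the start, stop
and coverage arrays each redistribute the total abundance (coverage
weighted by peptide length) — identities enforced by property tests.
Maximal covered runs are peptide *clusters*.

The 14 features per candidate are listed in `ppv.features`.  Design choices
worth recording:

* **Pseudo-intensity ε** = half the smallest nonzero per-sample intensity in
  the dataset.  Scale-free, keeps every log ratio finite, and is below any
  real signal so it never dominates a populated position.
* Both the *start/stop-intensity* steps and the *coverage* steps at the
  boundaries are kept as separate features; they capture different cluster
  shapes (a boundary where many ladder species start vs a sheer coverage
  cliff) and the model is free to weight them independently.
* The ladder count excludes the candidate's own locus (self-counting would
  leak the label), and the cluster share divides by all overlapping
  peptides including the candidate, so a lone peptide scores exactly 1.
* Fractions (shares, penetrance, PTM fractions, span ratio) are bounded in
  [0, 1] before standardisation; monotonicity of the own-abundance features
  is property-tested.

Candidates are labelled against the annotation list: *full* requires exact
coordinates plus PTM consistency under the reporting rule used throughout
(amidated means fraction > 0.98, non-amidated < 0.02, unknown always
consistent); *partial* (strictly inside a known interval) stays negative but
flagged — deliberately reproducing the real-world hazard that recently
annotated peptides hide among the negatives.

## Model and nested cross-validation

Plain L2 logistic regression (scikit-learn, lbfgs) on z-scored features; no
class weighting, no non-linear models — more flexible learners and
resampling schemes offer no benefit on this kind of highly imbalanced
problem and cost the coefficient interpretability that motivates the linear
model.  Nested cross-validation: 5 outer × 4 inner folds → 20 inner models
whose coefficient spread is reported.  Folds are *group-aware by protein*:
overlapping variants of one precursor are near-duplicates, and splitting
them across folds would inflate test AUC.  Groups carrying positives are
dealt round-robin (so every outer training split keeps ≥ 2 positives);
negative-only groups then balance fold sizes.  Standardisation parameters
are always computed on the fitted rows only, never on a fold's held-out
rows.  The inner loop selects the regularisation strength C from a small
grid (0.01, 0.1, 1.0) by mean inner-validation AUC, ties to the stronger
regulariser.  All reported scores are out-of-fold; the deployable model is
a refit on all rows at the modal selected strength.  Everything is
deterministic given the seed.

Score tiers: very-high > 0.05, high > 0.01, boundary values fall to the
lower tier.  Cross-tissue consolidation uses noisy-OR, 1 − Π(1 − pₜ): it
preserves probability semantics, is symmetric in tissue order, and rewards
independent evidence; it is a package default, not a claim about how any
particular study combined tissues.  Ranked outputs break ties by (score
desc, abundance desc, accession asc, start asc) for bit-reproducibility.

Optional positive upsampling (with replacement, to a target
positive:negative ratio, default 1:10) exists for the assembly variant,
where synthetic candidates flood the negative class.  It is applied to
every set a model is *fitted* on — inner-train, outer-train, final refit —
and never to validation or test rows.

## In-silico assembly

The assembler proposes every (observed start, observed stop) span, up to
100 residues, that can be bridged by a chain of pairwise-overlapping
observed fragments lying inside the span (minimum overlap 1 residue).  The
greedy furthest-reach chain search is exact for the overlap graph whenever
every fragment is at least as long as the overlap threshold — always true
here given the 7-residue length filter — and is verified against brute-force
transitive-closure enumeration.  Assembled abundance is the minimum
positional coverage across the span: a chain is only as strong as its
weakest bridge.  Spans already observed are returned as non-synthetic;
output is capped (default 500/protein, by descending assembled abundance)
to bound combinatorics on extreme clusters, and capping is logged.
Assembly is idempotent at fixed parameters.

## Flanking-motif validation

No model feature encodes sequence, so flank composition is an independent
check.  Windows of w = 4 residues either side (gap-padded at termini, gaps
excluded from frequency mass) are contrasted between high-scoring
predictions (score > 0.01) and the 80 % lowest-scoring background, with
fully matched known peptides removed from both sets first.  Per position,
Kullback–Leibler divergence in bits with an additive pseudocount of 0.5 per
residue; the signed per-residue contributions form the logo matrix.
Amidation-motif enrichment contrasts confidently amidated candidates
(fraction > 0.98) whose +1 residue is not Glycine against all non-Gly(+1)
candidates, at the −1 and +1 slots and their pairs, with zero-support
flagging.

## The synthetic peptidome

The simulator generates the study conditions the pipeline is tested under.
Default preset: 300 proteins of 200–800 aa; 40 precursors carry 2 planted
mature peptides each (8–45 aa); planted flanks are rewritten to dibasic
convertase motifs (probability 0.8) with a +1 Glycine (probability 0.5)
that licenses amidation (probability 0.9); each planted peptide spawns 12
ladder fragments trimmed from either terminus by geometric(λ = 0.85)
residue counts, losing a factor λ per trimmed residue, amidation kept only
while the C-terminus survives; per-sample intensities over 12 samples are
log-normal (signal mean 10⁷, background 10⁶, sd 0.8 decades, sample noise
0.3 decades) with logistic detection (midpoint 10⁵·⁵, slope 1.5); 30 % of
non-Gly planted peptides are amidated anyway, with Glu/Pro biased (0.6)
into their −1/+1 positions — planting a recoverable non-canonical motif.

Background turnover is *clustered*: each protein sheds its 20 background
fragments with uniform starts inside one degradation-prone hotspot region
(40 aa) and gamma-distributed lengths.  This is the load-bearing generator
decision.  Scattering background fragments uniformly over whole proteins
produces isolated singletons — a morphology real tissue peptidomes do not
show (observed peptides overwhelmingly sit in overlapping clusters) — and
under the chain-requiring assembler such data yields almost no synthetic
peptides (expansion ≈ 1).  Hotspot background restores the cluster-dominated
morphology and places the assembly expansion factor at ≈ 5 synthetic per
observed peptide (5.06–5.26 across seeds 1–10), the regime the method is
designed for.  Crucially, background clusters remain *boundary-blurred*
(uniform starts, no dominant full-length form), whereas planted peptides
show the sharp boundary-intensity step the model exploits — so the
discrimination task stays non-trivial: an abundance-only null reaches AUC
≈ 0.78–0.87 while the full model reaches ≈ 0.99.

What the simulator does **not** emulate: real spectra and their biases
(ionisation efficiency, charge states, retention time), sequence-dependent
detectability, correlated sample structure (strain/diet effects), shared
subsequences between precursors, or annotation noise beyond the
partial-match mechanism.  Passing tests therefore demonstrate internal
correctness and recoverability of planted structure, not field performance
on tissue data.

## Numerical choices and degenerate inputs

Zero-variance features standardise with scale 1 (coefficient then rests at
0).  Degenerate inner-validation splits (single-class) contribute AUC 0.5 to
model selection.  Empty profiles yield empty cluster lists; empty foreground
sets are errors for logo selection but flagged tables for motif enrichment.
Probabilities outside [0, 1], single-class AUC inputs, sub-2-pair transfer
fits, and out-of-bounds candidates all raise rather than degrade.

## Problem sizes used in tests

The bundled suite trains on the default preset (≈ 6,500 candidates, 80
positives) in a few seconds; oracle-equivalence checks run on 100 random
small peptidomes (≤ 5 proteins, ≤ 50 peptides) and 50 random assembly toys
(≤ 10 fragments), sizes at which exhaustive brute-force recomputation is
feasible and exact.

## Known limitations

The 14-feature roster is this package's self-contained reference set,
anchored to the boundary-step/modification/abundance family of descriptors;
other implementations of the same idea may name or partition features
differently.  The flank window (4), the cross-tissue combiner (noisy-OR),
and the assembly upsampling ratio (1:10) are documented defaults where no
single canonical value exists.  Fold enrichment uses all scored candidates
in the tissue as its universe.  PeptideRanker-style sequence scores and
secretion flags are treated as optional pass-through columns, never as
model inputs.
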