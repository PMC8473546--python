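# Methods

## Descriptors

All four descriptor families are functions of the primary sequence over
the 20 standard residues; sequences are sanitized before encoding
(below). Blocks are normalized by their window counts — L for AAC, L−1
for DC and for CTD transitions, L−2 for AA-x-AA — so each composition
block is a probability distribution and the block-sum invariants
(AAC/DC/AA-x-AA sum to 1; per-property CTD composition sums to 1;
transition triple sums to ≤ 1) hold exactly. Residue order is
alphabetical one-letter (A, C, D, …, Y) everywhere, and the block order
AAC(20) + DC(400) + AA-x-AA(400) + CTD(168) is fixed, so feature index
and feature name are stable across runs and saved models remain valid.

### CTD conventions

* **Transition** a/b counts adjacent pairs `ab` and `ba` alike,
  normalized by L−1. Order of the triple: 1/2, 1/3, 2/3.
* **Distribution** reports positions as p/L (position over sequence
  length), not p/n_g. The anchor occurrence for fraction f of a class
  with n occurrences is k = max(1, round(f·n)) with half rounded away
  from zero, so for n = 8 the 25/50/75/100% anchors are the 2nd, 4th,
  6th and 8th occurrences; the "first" anchor is always occurrence 1.
  This is the convention of the standard CTD implementations and is
  pinned by the worked example in the test suite.
* A class with zero occurrences contributes five zeros to the
  distribution block (keeps the vector finite; the common convention).
* The minimum sequence length is 3, enforced at load and at assembly,
  because AA-x-AA has no window below that; failing early beats
  emitting NaN features.

### Property groupings

Eight three-class partitions of the 20 residues are built in
(`features.DEFAULT_GROUPINGS`), in the fixed property order
hydrophobicity, normalized van der Waals volume, polarity, charge,
secondary structure, solvent accessibility, polarizability, disorder
propensity. The seven classical properties use the standard
Dubchak-style partitions; the polarizability partition
(G1 = {G,A,S,D,T}, G2 = {C,P,N,V,E,Q,I,L}, G3 = {K,M,H,F,R,Y,W}) is
additionally confirmed letter-by-letter by the worked example
(`MAGGDLVYAGSIAEHRKL` → `311112231112123332`). Disorder propensity uses
disorder-promoting {A,R,S,Q,E,G,K,P}, order-promoting {W,C,F,I,Y,V,L,N}
and neutral {H,M,T,D}. The seven non-polarizability partitions are
assumptions in the sense that alternative published tables exist; any
grouping set can be substituted via a JSON config
(`--grouping-file` / `features.load_groupings`), which revalidates the
partition property on load.

## Sequence sanitization

UniProt-derived FASTA occasionally contains ambiguity or nonstandard
codes (B, Z, X, U, O, J) and alignment artifacts (`*`, `-`). Policy
`strict` rejects any such character. The default `tolerant` policy
removes them with a warning but rejects a record losing more than 5% of
its residues: composition descriptors degrade gracefully under a few
removals, but silent corruption must be bounded. Records shorter than 3
residues after cleaning are rejected at load. Species is parsed from
UniProt `OS=` tags or a trailing `[...]` bracket, with a sidecar TSV
(id, species, reviewed) as the fallback for unannotated headers.

## Curation utilities

* **Species representatives**: default rule `longest` (ties by smallest
  id) — the longest isoform preserves the most sequence signal; `first`
  preserves input order. Idempotent.
* **Identity clustering**: greedy incremental clustering in order of
  decreasing length; a sequence joins the first cluster whose *founder*
  it matches at ≥ the cutoff. Identity is defined as matched residues
  in a global alignment with no gap penalty divided by the shorter
  sequence's length (equivalently, longest-common-subsequence matches
  over the shorter length). This is a fixture-scale emulation of
  CD-HIT's behavior, adequate for redundancy removal at hundreds of
  sequences; `run_cdhit` is an optional hook to an external binary for
  large jobs and is never required.
* **Balanced negatives**: seeded uniform sampling without replacement,
  matching the positive count, so every training set is balanced and a
  0.5 decision threshold is canonical.
* **Splitting**: the 64/16/20 train/validation/test split and the
  k-fold folds are stratified by label (balanced small datasets make
  unstratified splits noisy); split sizes use largest-remainder
  rounding within each class, so n = 100 gives exactly 64/16/20.

## Classifier

LightGBM binary GBDT behind a thin deterministic contract: single
thread, `deterministic=true`, one explicit seed; defaults
n_estimators = 300, learning_rate = 0.05, num_leaves = 31,
min_child_samples = 10 (lowered from LightGBM's 20 because balanced
benchmark sets in this domain are often only a few hundred sequences).
When a validation set is supplied, training early-stops after 50
rounds without improvement in validation log-loss. The exact tuned
hyperparameters behind published AFP benchmarks are not public;
`tune_hyperparameters` provides a fixed-budget random search over
learning rate, leaf count, child size and L1/L2 regularization selected
by validation loss for users who want it. The decision threshold is
fixed at 0.5.

Feature importance is **total gain** normalized to sum 1 — the decrease
in the boosting objective from all splits that use the feature — sorted
descending with ties broken by feature name. Gain (not split count) is
used because it measures the objective decrease directly. A caveat that
matters for interpretation: under strongly correlated features (e.g.
`Ala`, `Thr`, `Ala-Ala` and `Ala-x-Ala` in Ala-Ala-Thr-repeat
sequences) trees concentrate gain on whichever correlated feature they
split first, so the credit assignment among a correlated group varies
with the seed even though the group as a whole is reliably ranked
highly.

## Metrics

Scalar formulas are evaluated exactly from the confusion counts; any
metric with a zero denominator is reported as NaN — an explicit
undefined marker, never 0 — so degenerate folds are visible in reports.
Youden's index is recall + specificity − 1 at the operating threshold.
The ROC curve sweeps thresholds over the descending unique scores with
ties grouped, always includes (0,0) and (1,1), and AUC is the
trapezoidal area, which equals the Mann–Whitney pair statistic
(positive–negative pairs correctly ordered, ties ½); the test suite
checks this equivalence against an independent pair-counting oracle.
In cross-validation the reported mean metrics are plain fold averages;
the pooled out-of-fold ROC points are retained for plotting and the
confusion counts are summed.

## Synthetic data generator

The generator emulates the compositional signatures that distinguish
classical AFP families, not their biology:

* `ala_rich` — background residue frequencies with the Ala weight ×6
  (Type-1-AFP-like, Ala composition ≈ 0.35);
* `cys_rich` — Cys weight ×8 (Type-2-AFP-like, Cys composition ≈ 0.10
  vs. ≈ 0.014 background);
* `thr_repeat` — Ala-Ala-Thr repeat units emitted with probability 0.65
  per step, interleaved with background residues (antifreeze-
  glycoprotein-like);
* `mixed` — one of the three profiles per positive, uniformly.

Negatives are i.i.d. draws from Swiss-Prot-style background
frequencies. Lengths are uniform on 60–300 residues (typical of small
AFPs); `label_noise` flips a rounded fraction of labels uniformly; all
draws flow from a single `numpy` Generator seed, so output FASTA is
byte-identical across runs.

What passing tests on this generator do and do not show: synthetic
positives differ from negatives in global composition by construction,
so recovery demonstrates that the descriptor pipeline, the learner and
the importance ranking work end-to-end and that planted signals surface
under realistic sample sizes and label noise. Real AFP/non-AFP
discrimination is harder — real negatives share compositional biases
with positives, homology induces dependence between training and test
sequences, and real signals are weaker and distributed — so synthetic
performance numbers are an upper bound on, not an estimate of,
real-data performance. Benchmarks on curated datasets must be run via
`scripts/reproduce_deposited.py` on locally downloaded FASTA files.

## Problem sizes

The bundled benchmark conditions are 400 sequences (200 positive, 200
negative), 2% label noise, five folds, and the 64/16/20 independent
split; importance-recovery checks use 400-sequence datasets over seeds
1–5. These sizes were chosen to match the scale of curated AFP
benchmark sets (hundreds of sequences per class) while keeping the full
pipeline runnable on a single CPU in well under five minutes.

## Known limitations

* Only the polarizability partition is externally pinned; the other
  seven default groupings are standard but substitutable assumptions.
* The internal clusterer is O(n·clusters) with full global alignments —
  fine for fixtures, not for 10^5-sequence redundancy removal.
* Gain-based importance under correlated descriptors spreads credit
  unpredictably within a correlated group (see above).
* No evolutionary-profile (PSSM), pseudo-AAC or predicted-structure
  features; the descriptor set is deliberately alignment-free and
  database-free.
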