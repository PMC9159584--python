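# Methods

## Model overview

`tisscan` treats translation initiation prediction as a local sequence
problem: whether a codon initiates is decided by the codon's identity
and the ten bases on each side of it.  Three components share this
23-base window:

1. a **sequence logo** over the 20 flank positions, built by the
   Shannon method from a Kozak-consensus frequency matrix;
2. the **Kozak similarity score (KSS)**, the logo-height sum of a
   codon's flanks normalised by the maximum attainable sum, with an
   optional threshold classifier on top;
3. two **random forest classifiers** over one-hot flank features, one
   for ATG and one for the near-cognate codons CTG/GTG/TTG.

A repeat-locus scanner combines them: it assembles
*upstream + copies × unit*, scores every candidate codon (ATG plus the
nine near-cognate codons), keeps forest votes ≥ 0.5, removes candidates
whose translation would hit an in-frame stop before the repeat, infers
the repeat polypeptide per frame, and ranks the survivors.

## The logo and its calibration

For flank position *p* with letter frequencies *f(p, l)*, entropy
*H(p) = −Σ_l f log₂ f* (zero terms for zero frequencies), information
*R(p) = 2 − H(p)* bits, heights *f(p, l)·R(p)*.  The KSS normaliser is
*B_max = Σ_p max_l height(p, l)*.  Positions are labelled −10..−1 and
+4..+13 (the codon occupies +1..+3 and carries no height).  No
small-sample entropy correction is applied.

The shipped frequency matrix
(`src/tisscan/data/kozak_context_synthetic.csv`) is a synthetic
reconstruction, not a measured table: it starts from vertebrate
Kozak-style context percentages (C-rich upstream positions, adenine
favoured at −3 with guanine the runner-up, guanine at +4, mildly
GC-biased coding-side positions) and is linearly rescaled toward the
uniform matrix so that the resulting logo satisfies the two published
summary constants of this scoring system: *B_max* ≈ 0.5990 bits and a
mean KSS of ≈ 0.59 for uniformly random complete contexts.  Those two
constants fix, respectively, the total information of the logo and the
information-weighted mean argmax frequency; the residual freedom (which
letters are preferred where) follows the literature consensus.  The
matrix is a loadable CSV so users can substitute a matrix estimated
from their own data; `calibrate_matrix` reproduces the rescaling for
any raw matrix and target normaliser.

Useful closed forms used throughout the tests: a uniformly random
complete context has expected KSS `(Σ_p R(p)/4) / B_max`, and a context
drawn from composition *c* has expectation
`Σ_{p,l} c(p,l)·height(p,l) / B_max`.

## KSS classification

* A score **greater than or equal to** the cutoff predicts initiation
  (the boundary rule is a package convention; ties at the boundary are
  rare at float precision).
* The cutoff sweep balances classes per simulation by subsampling the
  larger class without replacement, averages misclassification over
  simulations on a default grid of 0.580–0.700 in steps of 0.001 (both
  codon classes use the same grid), and breaks ties toward the smaller
  cutoff — the more sensitive classifier.
* ROC curves and AUROC come from scikit-learn's threshold sweep with
  trapezoidal integration; the tests cross-check the area against an
  O(n²) Mann–Whitney pairwise oracle.
* The proportion-above-threshold table uses strict inequality
  ("score > t"), reports cells with no examples above *t* as missing,
  and averages defined cells over simulations.

## Forests

* Features: position-major one-hot with five states per flank slot
  (A, C, G, T, missing), 100 features for ATG; the near-cognate schema
  appends five first-base indicators (105 features).  The near-cognate
  model is trained on CTG/GTG/TTG only; predictions for
  ACG/AAG/AGG/ATA/ATC/ATT reuse it and are flagged as extrapolations.
* Imbalance handling: the negative pool keeps all complete-flank
  negatives plus `floor(0.9 × that count)` missing-flank negatives
  sampled without replacement (the count can be overridden exactly),
  tilting training toward the complete contexts that dominate real
  scanning input.  A balanced holdout of `round(5% × pool)` negatives
  plus as many positives is excluded from training.  Each tree then
  trains on a balanced subsample: all training negatives (configurable)
  and an equal number of positives drawn without replacement — or, when
  positives are the scarcer class, both classes subsampled to the
  smaller size, so every tree always sees equal label counts.
* Tree settings: √n candidate features per split, minimum leaf of two
  instances, 1000 trees by default (tests and examples use 100–200
  trees, which this data size saturates).  The vote fraction has
  resolution 1/n_trees.
* Near-cognate evaluation sets aside 20 positives and 20 negatives per
  trained codon (120 cases) before training.
* Models persist via joblib with a format version and a schema
  checksum; loading refuses a mismatched schema.

## Scanner conventions

* **Offset** = `repeat_start − codon_start` in bases: 0 means the codon
  begins at the repeat, negative offsets are inside it.  Frame is
  `codon_start mod 3` of the assembled sequence.
* The stop filter examines in-frame codons starting at
  `codon_start + 3, +6, …` strictly before `repeat_start`, including
  codons that straddle the junction into the repeat.  Candidates at or
  inside the repeat are exempt (they are reported — e.g. every CTG of a
  CTG repeat reads poly-L).
* The peptide unit translates one full cycle of `lcm(3, k)` repeat
  bases starting at the phase reached by stepping in threes from the
  initiation codon; a stop inside the cycle truncates the unit and sets
  a flag.  Peptide naming is rotation-sensitive; comparisons against
  conventional names (poly-GA vs poly-AG) should accept cyclic
  rotations.
* Antisense analysis is the caller's responsibility: build a second
  locus from the reverse complement (`reverse_complement` is provided);
  the scanner itself is strand-agnostic.
* Reports print KSS to two decimals.  In the marked-up sequence view,
  codons are coloured by reading frame and bolded iff the model was
  trained on that codon; where predicted codons overlap, the shared
  bases take the downstream codon's colour.

## Ranking

Categories (editable via a JSON table): 1 = ATG, 2 = CTG, 3 = GTG/TTG,
4 = extrapolated codons with KSS ≥ 0.70, 5 = other extrapolated codons.
The 0.70 split mirrors the display threshold used when reporting
high-scoring predictions.  Within a category predictions sort by KSS
(default) or vote probability, then by offset.  KSS is the default key
because it is independent of the forests, giving a second opinion.

## Synthetic data

The generator draws each flank base independently per position — the
same independence the logo assumes — so it exercises exactly the
structure the classifiers model.  Defaults (the conditions under which
the test suite evaluates the stack):

* **Class centres.**  Compositions are exponential tilts of the uniform
  background along the logo heights, calibrated by root-finding so the
  expected KSS is 0.73 for positives and 0.52 for negatives — the
  published centres of the score histograms for initiating and
  non-initiating ATG contexts.
* **Reference/dataset mismatch.**  The positive tilt swaps the two
  tallest letters at the three most informative positions (e.g. the
  other purine at −3).  A fixed reference logo never matches any
  particular dataset's preferences exactly; this is the property that
  lets a trained classifier outperform a fixed similarity score, and
  without it the KSS would be the Bayes-optimal statistic for its own
  generative model and no classifier could beat it.
* **Missing bases.**  20% of examples have one flank truncated at a
  depth uniform on 1..10, exercising every missing-state feature.
* **Sizes.**  Default 500 positives / 800 negatives; the comparative
  tests run 10 training seeds at this size and the end-to-end suite 20
  locus seeds, which keeps the whole suite around ten seconds while
  leaving the measured effects many standard errors wide.

Toy loci plant codons with full argmax-consensus flanks (KSS = 1.0,
maximally detectable), scrub accidental in-frame stops from the
background (no stop codon contains C, so scrubbing writes a C), and can
plant deliberately stop-blocked decoys to test the filter.

What the generator does **not** emulate: positional dependence between
flank bases, transcript-position and secondary-structure effects,
read-level ribosome-profiling signal, and the sequence-composition
quirks of real 5'UTRs.  Passing tests therefore demonstrate the
correctness of the machinery and the expected qualitative orderings,
not real-data accuracy figures.

## Numerical choices and degenerate inputs

* Frequency rows must sum to 1 within 1e-9; heights live in [0, 2].
* A logo with zero normaliser (all-uniform matrix) is rejected by the
  scorer.
* Empty score classes, single-label training sets and single-class ROC
  inputs raise errors rather than returning degenerate values;
  unbalanced evaluation requires an explicit `force=True`.
* All randomness flows through `numpy.random.Generator` objects or
  integer seeds; identical seeds give identical datasets, splits,
  forests and loci.

## Known limitations

* The shipped matrix is a calibrated reconstruction, so absolute KSS
  values for real sequences are indicative, not comparable against
  scores computed with a different matrix.
* Accuracy numbers quoted anywhere in this repository are measured on
  synthetic data and do not transfer to real transcripts.
* The near-cognate model's extrapolated codons share the trained
  codons' flank patterns by assumption; there is no data-driven check
  of that assumption here.
* Repeat interruptions, multiple transcript variants and
  repeat-length-dependent mechanisms are out of scope.
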