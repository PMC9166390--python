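# Methods

## Problem and models

A pairwise-selection (CAP-SELEX-style) library is a set of short
fixed-length DNA reads enriched for molecules bound simultaneously by two
transcription factors.  Each read is known to contain a joint binding site
*somewhere*, on either strand; the site's position, orientation (which
factor's motif comes first along the strand) and spacing (number of
background bases — possibly negative, i.e. overlap — between the two
motifs) are unknown.  The package trains classifiers that, given an unseen
read, score how likely it is to carry a joint site for the pair.

Every read is treated as a *double strand*: a sequence paired with its
reverse complement, scanned jointly, because the physical molecule carries
the site on one of its two strands.

**Negative class.**  The library provides positives only.  Negatives are
built by shuffling each positive once while exactly preserving its multiset
of overlapping dinucleotides (random Euler-path construction on the
base-transition multigraph, after Altschul & Erickson).  This removes motif
content but conserves length, mononucleotide and dinucleotide composition
and the terminal bases, so a classifier cannot separate the classes on
composition alone.

**Window selection.**  Forests operate on fixed-length windows, one per
read, selected by PWM scan.  During selection PWMs are used as position
*probability* matrices: a window's score is the product of per-position
base probabilities, maximized over all window offsets of both strands
(ties: + strand first, then smallest offset; across candidate matrices the
earlier matrix wins).  Training reads are pure A/C/G/T and windows stay
inside the read, so no N handling is needed here.

* *JointRF* selects windows with a known composite (pairwise) motif that
  fixes orientation and spacing; its window length is the motif length.
  When several composite motifs exist for a pair, one forest is trained
  per motif and the best by held-out AUROC is kept (selection never
  touches the final test split).
* *ComBind* needs only the two individual-TF motifs.  For orientation
  TF1-TF2 the candidates are TF1's motif extended on the right and TF2's
  extended on the left with uniform (0.25, 0.25, 0.25, 0.25) columns to 25
  positions; for TF2-TF1 the sides swap.  The uniform columns reserve
  space for the partner motif without constraining its sequence.  One
  forest is trained per orientation; the remaining two physical
  orientations are opposite-strand reflections and are covered because
  every scan considers both strands.  25 positions fits two 8-12 nt motifs
  plus up to ~9 nt of spacing while still allowing the window to sit
  anywhere inside a 40-nt read.

**Forests.**  Windows enter the forest as positional categorical features
(the base at each window position), realized as four-indicator blocks per
position.  Trees split on Gini impurity; a node with fewer than
`min_node_size` rows is not split; each split draws `mtry` candidate
variables, where `mtry = round(mtry_fraction x window_length)` with
half-to-even rounding computed on exact decimals (0.30 x 25 = 7.5 -> 8;
binary floating point would give 7).  `mtry` counts original per-position
variables, not expanded indicators, preserving the fraction-of-variables
meaning.  Ensembles hold 200 trees by default; bootstrap resampling leaves
about one third of rows out-of-bag (OOB) per tree, and aggregated OOB
probabilities are retained for motif visualization.  The ensemble is
scikit-learn's `RandomForestClassifier` held behind this contract.

**Scoring.**  An unseen double strand is scored by the forest's class-1
probability at every window offset on both strands; the maximum is the
(orientation-specific) score.  ComBind's final score is the arithmetic
mean of its two orientation scores — averaging stabilizes the score, and
both orientations carry signal whenever binding reflects onto the opposite
strand.  Scores therefore live in [0, 1].

**PWM baseline.**  The comparator scores reads with the composite motifs
directly: log-odds sums against a uniform background, maximum per position
over both strands, after padding each read with five N characters per end
(N scores probability 0.25, i.e. exactly zero log-odds, letting a motif
overhang the read edge).  With multiple motifs each read takes the highest
score.  Zero probabilities with zero pseudocount give -inf log-odds; a
read whose every window hits one keeps -inf until dataset-level
replacement by the minimum finite score of the dataset.

## Evaluation protocol

Reads are split class-balanced: floor(0.75 n) per class to training (the
remainder, i.e. any rounding surplus, to test); for oversized libraries
the fraction drops to 0.50.  A quarter of the training rows (floor again)
form the *pre-training* subset used solely for hyperparameter search: each
cell of the 4 x 5 grid (min node size {1, 5, 10, 15} x mtry fraction {10,
20, 30, 40, 50}%) is fit on 75% of pre-training and scored by AUROC on the
remaining 25%; ties prefer the smaller node size, then the smaller
fraction, making the result independent of grid enumeration order.  The
final model is retrained on the full training split with the chosen cell
(pre-training selects, it does not produce the final fit).  For ComBind
the grid trains a single-orientation forest per cell as a proxy for the
two-forest model — both orientation forests share hyperparameters, and
this halves the search cost.

AUROC is computed from ranks (Mann-Whitney U / (n1 n0), ties half); tests
cross-check it against trapezoidal ROC integration.  Across libraries,
models are compared by median AUROC and paired two-sided Wilcoxon
signed-rank tests: zero differences dropped, exact null distribution up to
25 surviving pairs, normal approximation with continuity correction
beyond.

## Synthetic benchmark

The generator emulates a pairwise-selection library at desk scale.
Positive reads are 40 nt of first-order Markov background (uniform
dinucleotide distribution by default) carrying one planted composite site:
letters sampled per column from the two motifs, gap filled with background
letters, gap drawn uniformly from 0..10, orientation uniform over the four
order/strand combinations, position uniform among feasible offsets;
`planted_fraction` defaults to 1 because a selection library is, by
construction, enriched so that essentially every read entails a site.
Negative gaps (overlap) average the overlapped motif columns, keeping
columns stochastic.  Default motifs are two 10-nt consensus PWMs with 0.85
on the consensus base (~1.15 bits/column).  Ground truth (start, gap,
orientation, strand) is recorded per read.

Because the background is first-order Markov and negatives are
dinucleotide-preserving shuffles, the two classes differ only in motif
content — exactly the discrimination the models target.  The generator
does not simulate selection-round enrichment dynamics, PCR bias,
sequencing error, or the heterogeneous motif quality of real libraries,
so passing benchmarks demonstrate correct mechanics and qualitative model
ordering (ComBind above a fixed-spacing PWM under variable spacing; chance
behaviour without signal), not real-data accuracy levels.

## Numerical and design choices

- Log-odds background is uniform and the default pseudocount is 0,
  consistent with the N-scores-zero identity; both are configurable.
  Natural log by default — AUROC is rank-based, so the base is
  inconsequential.
- Motifs longer than the 25-column ComBind window raise an error rather
  than truncate (truncation would silently discard motif information).
- Scan tie-breaks are fixed (+ strand, then leftmost, then earlier
  matrix).  Minus-strand windows are scored by scanning the
  reverse-complement sequence directly, so identical letter sequences on
  the two strands produce bit-identical floats and ties break
  deterministically.
- Splits use floor rounding per class with the remainder going to the test
  side.  All randomness flows from a master seed; per-forest seeds are
  spawned deterministically (`numpy.random.SeedSequence`) and logged.
- `min_node_size` is enforced as "nodes with fewer rows are not split"
  (`min_samples_split`), the contract stated for the forest; R's
  `randomForest::nodesize` bounds terminal-leaf size instead, a slightly
  different but practically close control.
- Degenerate inputs error early: single-class training sets, mixed window
  lengths, windows containing N, all--inf score vectors, empty PWM sets,
  fractions yielding empty splits.

## Problem sizes

The shipped benchmark runs use 20,000 positive reads (40,000 with
negatives; 30,000 training / 10,000 test) for signal recovery — the scale
at which forest AUROC saturates on this generator — and 3,000 positives
for the no-signal control, where the chance band [0.45, 0.55] is ~3
standard errors wide.  Unit tests run at a few hundred reads.

## Known limitations

- Real libraries mix motif qualities, replicate structure and
  between-experiment variation that the simulator does not model; absolute
  AUROCs here do not transfer to real data.
- ComBind's averaged score cannot be decomposed into spacing or
  orientation preferences; the OOB-derived motif visualization is
  informative only for fixed-configuration (JointRF-style) forests.
- Forest storage grows with training size and tree depth; 200 deep trees
  on tens of thousands of rows serialize to tens of megabytes.
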