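# Methods

## Problem and model

`spliceid` frames splicing-factor identification as binary protein
classification. Each protein is represented by concatenating any subset of
five feature blocks, always in the fixed order

    aac (20) | dpc (400) | sig_dpc (|selected|) | pssm (400) | domain (|vocab|)

and classified by a soft-margin SVM with RBF kernel exp(−γ‖u−v‖²). The
modelling assumptions are those of the feature blocks themselves: that
class membership is detectable from global residue usage (splicing factors
carry RNA-binding and protein-interaction surfaces rich in R/K/D/E/G),
from over-represented residue pairs, from evolutionary conservation pooled
over residue types, and from a small set of hallmark functional domains.
Order-dependent sequence structure beyond adjacent pairs is deliberately
not modelled.

## Conventions and definitions

- **Alphabet.** All 20- and 400-dim vectors are indexed in alphabetical
  one-letter order (A C D E F G H I K L M N P Q R S T V W Y). PSI-BLAST's
  native PSSM column order is remapped to this at parse time, so encoders
  can never misalign. Dipeptide index = 20·first + second.
- **Non-standard letters** (B J O U X Z *) are kept in stored sequences
  but excluded from composition numerators and denominators; dipeptide
  windows overlapping one are skipped; PSSM rows at such positions are
  excluded from row sums (the divisor stays the full profile length m).
  This avoids inventing pseudo-counts for letters the model does not score.
- **Dipeptide windows** are the L−1 overlapping adjacent pairs, the
  universal convention for dipeptide composition.
- **Presence, not frequency**, drives the dipeptide screen: a protein
  either contains a pair or it does not, matching the counting rule the
  screen's hypergeometric model assumes.

## Hypergeometric dipeptide screen

For a pair present in t of T positives and k of K proteins overall, the
p-value is the upper tail P(X ≥ t) with X ~ Hypergeom(K, T, k), computed
by `scipy.stats.hypergeom.sf` (log-space internally, stable at K ~ 10⁴).
The upper tail (rather than a point mass or lower tail) is the direction
consistent with the accompanying over-representation filter
prob_diff = t/T − (k−t)/(K−T) > 0. Both filters are strict inequalities;
the default alpha is 0.05 with no multiple-testing correction, matching
the original selection rule (a Bonferroni switch exists but is off by
default). Selected pairs are ordered by ascending p-value with
lexicographic tie-breaks, and the restricted encoding keeps raw DPC values
without renormalisation, so a value remains interpretable as a window
fraction.

## PSSM pooling

Only the log-odds block (first 20 integer columns) of the ASCII PSSM is
used; the weighted-percentage block is ignored. Row sums are taken first
and scaled once (sum-then-scale): x(r,c)/m is pushed through the logistic
1/(1+e^(−x)), mapping into (0,1) with 0.5 as the neutral point, so residue
types absent from a sequence encode as 0.5 (an `absent_as_zero` switch
zeroes them instead; the squashing function is pluggable). Pooling makes
the vector invariant to position permutation and to profile
self-concatenation, both covered by tests.

## Domain vocabulary

Built from positive training records only — negatives never influence it —
by counting distinct positive proteins per accession and keeping those
with support strictly greater than 5 ("more than five" is read as ≥ 6;
the off-by-one changes the vocabulary, so the strictness is explicit and
configurable). Entries are ordered by descending support then accession.
The vocabulary is frozen inside the model bundle so independent-test
encoding cannot drift from training.

## Training and evaluation

- **SVM**: scikit-learn `SVC` (libsvm), RBF kernel, no class weighting by
  default despite class imbalance (the original protocol reports none); a
  balanced mode can be added by callers via sample weighting if needed.
- **Folds**: stratified 5-fold with a seeded shuffle; per-fold class
  counts stay within one sample of proportional; every sample is validated
  exactly once.
- **Grid search**: exhaustive over C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and
  γ ∈ {2⁻¹⁵, …, 2³} (the libsvm guide convention; the original work states
  grid search without ranges), every point on the *same* seeded folds,
  maximising pooled accuracy with ties broken toward smaller C then
  smaller γ. Search and CV share folds (non-nested), matching the
  described protocol; callers wanting unbiased model selection can nest by
  running `grid_search` inside their own outer split.
- **Metrics**: Sn, Sp and Acc in percent are recomputable identities of
  the stored confusion counts; the cross-validation headline is the
  pooled (micro-averaged) confusion over folds, which weights every sample
  equally regardless of fold-size rounding.
- **No feature standardisation**: composition and PSSM blocks already lie
  in [0,1] and the domain block is binary.

## Synthetic data generator

The generator defines the package's reference study conditions: 200
positives vs 800 negatives, lengths uniform on [80, 600] (protein-like
scale; no length distribution is prescribed by the source material).
Negatives draw residues i.i.d. from approximate human-proteome
frequencies; positives shift R, K, E by +2, D by +1.5 and G by +1
percentage points and deplete L by 2 and C by 1, with the balance
reabsorbed proportionally by the untouched residues — the direction and
upper end of the compositional contrast observed between real splicing
factors and the proteome, so synthetic difficulty is comparable to, not
easier than, the real compositional signal. Two dipeptides are planted by
overwriting a random adjacent pair (WC in 90%/5% and WM in 85%/5% of
positives/negatives; tryptophan pairs keep background presence low so the
plant, not base composition, carries the signal). Five domains mirror the
real hallmark support profile scaled to 200 positives (two ~26%
markers and a minor tail), on top of a 40-accession background pool at 1%
prevalence in both classes. Toy PSSMs score each position's own residue
+5 against a −2 background with Gaussian noise (sd = `pssm_noise`,
default 1), integer-rounded.

What the generator does **not** emulate: real protein family structure,
homology between records (no CD-HIT-like redundancy), realistic
evolutionary profiles (true PSSMs encode family conservation, not
identity), domain co-occurrence patterns, or length–class correlation.
Passing tests therefore demonstrate that the pipeline recovers planted
compositional, dipeptide and domain signal under its own model
assumptions — not that the original study's absolute accuracies are
reproduced, which would require the external curated datasets, PSI-BLAST
against nr, and a matching InterPro release.

## Numerical and design notes

- Hypergeometric p-values are clipped to [0, 1]; t at the support minimum
  returns exactly 1.
- Fractions are kept internally; percent conversion happens only at
  reporting time (class profiles, metrics).
- Grid ties and selection ties are broken deterministically (smaller C
  then γ; p-value then pair), so identical seeds reproduce winners,
  fold assignments, datasets and predictions bit-for-bit.
- Empty vocabularies and empty selections refuse to encode with a clear
  error rather than emitting zero-width blocks.
- Problem sizes used by the test and acceptance runs — the 200/800
  default, a 100/400 independent set, 200 label permutations for null
  calibration, K ≤ 30 for the exact hypergeometric sweep — were chosen as
  the smallest sizes at which the planted effects and exact oracles are
  conclusive.
- The model bundle (joblib, versioned tag) freezes the SVC, C, γ, seed,
  and the full feature config including selection result and vocabulary.
- The CLI is a thin layer over the library; every subcommand runs
  end-to-end on generator output with no network access, and all tables
  are TSV with `#` header lines recording version, seed and parameters.

## Known limitations

- Non-nested grid search can be optimistic relative to nested selection.
- The domain block is only as good as the annotation table supplied;
  unannotated true positives encode as all-zero and drive sensitivity
  down, which is the expected behaviour of the original design as well.
- PSI-BLAST execution and CD-HIT clustering are out of scope; the package
  consumes their outputs.
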