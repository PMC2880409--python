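# Methods

## Problem and model

`nabind` treats DNA/RNA-binding site prediction as residue-wise binary
classification. The model assumes that a residue's binding status is
determined by the local sequence context (five residues on either side)
together with per-position evolutionary information, and that binding
residues differ from non-binding ones in three measurable ways: amino-acid
composition (basic and polar residues are over-represented at nucleic-acid
interfaces, hydrophobic ones under-represented), conservation (functional
residues drift more slowly), and the biochemical *profile* of the residues
tolerated at a position across homologues.

A window of w = 11 consecutive residues centred on the target residue is
encoded as the concatenation of per-residue feature blocks and classified
by an RBF-kernel support vector machine. Training uses the n − w + 1 fully
interior windows of each sequence; at prediction time one window per
residue is formed, padding past the termini with all-zero blocks so every
residue of a query receives a score (the training construction leaves the
first and last five residues uncovered, which is acceptable for fitting
but not for a per-residue report).

## Features and encoding

Per-residue block, in fixed order:

| group | values | notes |
|---|---|---|
| `hkm` | H, K, M | Kyte–Doolittle hydrophobicity; side-chain pKa (0 for non-ionizable side chains); monoisotopic residue mass (Da) |
| `descriptors` | H̄, σ_H, K̄, σ_K, M̄, σ_M | per-column mean and population SD over aligned homologues, query included |
| `pssm` | 20 scores | logistic-squashed PSI-BLAST substitution scores |

All inputs to the kernel are scaled to [0, 1]: the raw H/K/M values by
per-feature min–max over the 20 standard amino acids, descriptor means
with those same bounds, descriptor SDs by the feature's raw range, and
PSSM scores by 1/(1 + e^−s). The RBF kernel is isotropic, so commensurate
feature scales are a prerequisite rather than a refinement. The specific
H/K/M scales are a configuration choice (a 4-column TSV; the packaged
default is stated above): predictions depend on them, and alternates can
be swapped in without code change.

Conservation statistics use the population (1/N) standard deviation and
always include the query residue in the column, which guarantees non-empty
columns and makes a homologue-free profile degenerate gracefully to the
query's own feature values with σ = 0. Gap characters and ambiguity codes
contribute nothing to columns (no defined single feature value). When
homologues arrive as pairwise local alignments, each homologue contributes
at most one residue per query position — from its best-scoring alignment
covering that position — and duplicate subject ids are collapsed;
positions outside all of a homologue's alignments get nothing from it.
Unknown residue letters in the *query* (X and friends) take per-feature
mean values rather than failing, so real sequences with ambiguity codes
remain predictable.

## Structural labelling

A residue is labelled binding when the minimum Euclidean distance between
its heavy atoms and any heavy atom of the target-kind nucleic chains is
≤ 3.5 Å. Choices a user should know:

* the comparison is inclusive (a contact at exactly 3.5 Å is binding);
* hydrogens/deuteriums are excluded (crystal structures usually lack
  them, and including them where present would shift distances);
* waters and heteroatom residues are excluded; only the first model of a
  multi-model file is used;
* each protein chain is labelled against the union of all nucleic chains
  of the requested kind, and a complex without such a chain raises an
  error instead of silently producing an all-negative labelling;
* non-standard amino acids map to 'X' in the sequence but keep their
  labels.

Chain kinds are inferred from residue names by majority vote (standard
amino acids → protein; DA/DC/DG/DT → DNA; A/C/G/U → RNA).

## Classifier and model selection

Fitting is delegated to a standard quadratic-programming SVM solver
(scikit-learn's SVC, solver tolerance 1e-3) behind a thin contract: the
model exposes real-valued decision outputs, stores the encoding descriptor
(window size + active feature groups) and refuses to score instances
encoded differently. Defaults γ = 0.05, C = 2 sit at the centre of the
grid-search grids (γ ∈ {0.01, 0.05, 0.1, 0.5, 1}, C ∈ {0.5, 1, 2, 5, 10});
grid search evaluates each cell by cross-validated strength (at threshold
0) or AUC and breaks ties toward smaller C, then smaller γ — preferring
the smoother model when performance is equal. Class weights default to
1:1; operating points are set afterwards by thresholding, not by
reweighting the loss.

## Evaluation machinery

Five-fold cross-validation assigns instances to folds randomly with
stratification on the label (an unstratified split of a 15%-positive
dataset can starve a fold of positives); a `group_by_sequence` option
forces all windows of one sequence into the same fold, because overlapping
windows that straddle folds share 10 of 11 residues with training
instances and flatter the estimate. Held-out decision values from all
folds are pooled before computing metrics and the ROC curve.

Hard calls use score ≥ t (ties are positive calls, consistent with the
confidence rule below). Metrics with a zero denominator return 0 and set
a degeneracy flag rather than raising mid-sweep. MCC returns 0 when any
marginal is empty. The ROC staircase has one point per distinct score
plus sentinels at ±∞, so it runs from (1, 1) to (0, 0); the trapezoidal
area equals the tie-corrected Mann–Whitney statistic (a property the test
suite checks against an O(n²) pair-count oracle at 1e-9).

## Operating points and confidence

The threshold for a requested specificity level is the smallest threshold
whose cross-validated specificity reaches the level (the most sensitive
compliant point); for a requested sensitivity, the largest threshold whose
sensitivity reaches it. Lookup is a step function on the empirical curve —
no interpolation between ROC points — and an unreachable level returns the
nearest extreme with a saturation flag. Confidence of a positive call at
output o is the fraction of calibration positives scoring *strictly*
below o (equivalently 1 − sensitivity at threshold o); of a negative call,
the fraction of calibration negatives at or above o (1 − specificity at
o). The overview digit is ⌊10 × confidence⌋ clamped to 9.

## Synthetic data: what it emulates and what it does not

The generator produces the three kinds of input the pipeline consumes.

*Toy complexes* place a straight protein backbone (3.8 Å CA spacing, four
heavy atoms per residue) with nucleic atoms at controlled distances above
chosen residues — chemically naive, but every pairwise distance is known
by construction, including a planted contact at exactly the 3.5 Å cutoff.

*Datasets* (defaults, chosen once as the study conditions): 60 sequences,
lengths uniform on [90, 150], 15% binding residues placed in short blocks,
25 homologues per sequence, per-position substitution rates 0.05 at
binding and 0.40 at non-binding positions, gap rate 0.05 outside binding
positions. Binding residues are drawn from a basic/polar-enriched letter
distribution and non-binding residues from a hydrophobic-enriched one.
Synthetic PSSMs are log-odds of the alignment's own column frequencies
against a uniform background with pseudocount 1. A `signal` parameter
interpolates both mechanisms toward a null model: at signal = 0 the two
letter distributions and the two mutation rates coincide, so no feature
carries label information and cross-validated AUC sits at chance.

The generator plants exactly the statistical regularities the features
measure, with none of real data's nuisance structure: no sequence
redundancy or phylogenetic correlation among homologues, no alignment
errors, no composition gradients along the chain, substitutions drawn
uniformly rather than from a substitution matrix, and binding sites that
are compositionally homogeneous. Passing the planted-signal tests
therefore shows that the pipeline recovers the signal class it was built
for — it does not certify accuracy on real interface datasets, where the
same ordering of feature sets but substantially lower absolute numbers
should be expected.

## Numerical choices and degenerate inputs

* Zero is the padding value for terminal prediction windows (the floor of
  every scaled feature, distinct from any realizable full block).
* PSSM parsing takes the first 20 numeric columns of each row and reports
  the line number on malformed rows; logistic scaling keeps raw-score
  ordering at every position.
* Sequences shorter than the window yield an empty training set with a
  logged warning, not an error; prediction mode still covers them.
* Fold assignment, SVM seeds and all generator draws are driven by
  explicit seeds; repeated runs are bit-identical.
* Deterministic tie-breaks throughout: grid-search ties → smaller C then
  smaller γ; equal-score pairwise alignments → file order; score ties at
  a threshold → positive call.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline on the
default 60-sequence set (~6,600 windows of 319 features), a size at which
five-fold SVM cross-validation completes in seconds while leaving the
class imbalance and signal structure intact; the generator scales to
larger sets by changing `SyntheticSpec` fields.

## Known limitations

* The published reference datasets for this task cannot be reconstructed
  exactly (membership and redundancy-reduction procedure unpublished), so
  absolute published performance figures are not reproduction targets;
  the package's quantitative claims are the analytic identities and
  planted-signal results its own tests compute.
* The exact H/K/M scales used by the original predictors are not printed
  in the literature the method derives from; results depending on the
  specific scale cannot be bit-matched (the table is swappable).
* Homologues are weighted uniformly in the conservation statistics; no
  identity- or E-value-based weighting, and no correction for redundant
  homologue sets.
* mmCIF structures are out of scope (PDB format only), as are kernels
  other than RBF and probability calibration beyond the ROC machinery.
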