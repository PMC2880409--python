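# nabind

Sequence-based prediction of DNA- and RNA-binding residues in proteins.

Protein–nucleic-acid recognition underlies transcription, translation and
their regulation, but solved complex structures exist for only a small
fraction of binding proteins. `nabind` predicts, from the amino-acid
sequence alone, which residues of a protein contact DNA or RNA, so that
interface residues can be proposed for proteins with no structural data —
for mutagenesis planning, interaction modelling or genome-scale annotation
of nucleic-acid-binding proteins.

## Method

**Labels.** When a complex structure *is* available, a residue is labelled
a binding site if any of its side-chain or backbone heavy atoms lies
within 3.5 Å (inclusive) of any atom of the DNA or RNA molecule; all other
residues are non-binding. Real interface datasets built this way are
imbalanced, with roughly 15% binding residues.

**Features.** Each residue is described by three biochemical properties —
hydrophobicity index *H* (Kyte–Doolittle), side-chain pK<sub>a</sub> *K*
(0 for non-ionizable side chains) and monoisotopic residue mass *M* — and
by evolutionary information from a PSI-BLAST search against a reference
database (3 iterations, inclusion E ≤ 1e-5):

* the 20 per-position PSSM substitution scores, squashed to (0, 1) by the
  logistic map 1/(1 + e<sup>−s</sup>);
* three *conservation descriptors*: for each feature X ∈ {H, K, M}, the
  mean X̄<sub>i</sub> and population standard deviation σ<sub>i</sub> of X
  over the residues aligned to query position *i* in the homologues
  (query included). Binding residues tend to be conserved, and they are
  enriched for basic/polar residues, so a high K̄ with a small σ is
  evidence for a binding site that PSSM scores do not express directly.

**Classifier.** Each instance is a sliding window of *w* = 11 consecutive
residues centred on the target residue (a sequence of length *n* yields
*n* − *w* + 1 training instances), encoded as the concatenation of
per-residue feature blocks — 319 values per instance with all feature
groups active. A support vector machine with the radial basis function
kernel

&nbsp;&nbsp;&nbsp;&nbsp;K(x₁, x₂) = exp(−γ‖x₁ − x₂‖²)

separates binding from non-binding windows; γ and the regularization
factor C are chosen by cross-validated grid search.

**Evaluation.** Stratified five-fold cross-validation pools the held-out
decision values of all folds and reports accuracy, sensitivity,
specificity, *strength* (the mean of sensitivity and specificity — the
fair summary for imbalanced data), the Matthews correlation coefficient,
and the ROC curve with its trapezoidal AUC.

**Reports.** At prediction time the user requests a sensitivity or
specificity level; the output threshold *t* is read off the deployed
model's cross-validation ROC curve. Each residue gets a '+'/'−' call
(*o* ≥ *t* counts as '+'), a confidence — for a positive call, the
fraction of calibration positives scoring below *o*; for a negative call,
the fraction of calibration negatives scoring at or above *o* — and a
single-digit confidence level ⌊10 × confidence⌋.

## Worked example

The synthetic generator plants the signal structure the method is built to
exploit — basic/polar-enriched binding residues, stronger conservation at
binding columns, ~15% positives — so the whole pipeline can be exercised
end to end without any downloads:

```python
from nabind import (SyntheticSpec, synth_dataset, load_feature_table,
                    EncodingDescriptor, encode_dataset, KernelParams,
                    cross_validate, roc_points, evaluate_at_threshold)

table = load_feature_table()
dataset = synth_dataset(SyntheticSpec(seed=7))
profiles = dataset.sequence_profiles(table)
print(f"{len(dataset.records)} sequences, "
      f"{100 * dataset.positive_fraction:.1f}% binding residues")

for groups in [("hkm",), ("hkm", "descriptors"), ("hkm", "descriptors", "pssm")]:
    inst = encode_dataset(dataset.records, profiles,
                          EncodingDescriptor(groups=groups))
    labels, scores, _, _ = cross_validate(inst, KernelParams(), k=5, seed=17)
    m = evaluate_at_threshold(labels, scores, 0.0)
    auc = roc_points(labels, scores).auc
    print(f"{'+'.join(groups):24s} strength={100 * m.strength:.1f}% "
          f"(sn={100 * m.sensitivity:.1f}%, sp={100 * m.specificity:.1f}%) "
          f"MCC={m.mcc:.3f} AUC={auc:.3f}")
```

prints

```
60 sequences, 15.0% binding residues
hkm                      strength=74.5% (sn=51.7%, sp=97.4%) MCC=0.586 AUC=0.912
hkm+descriptors          strength=97.0% (sn=94.7%, sp=99.4%) MCC=0.949 AUC=0.998
hkm+descriptors+pssm     strength=97.8% (sn=95.8%, sp=99.8%) MCC=0.968 AUC=0.999
```

Biochemical features alone rank residues well (AUC 0.91) but, at the raw
threshold 0, trade most of the sensitivity away; adding the conservation
descriptors recovers the planted evolutionary signal and lifts every
measure, with the PSSM block contributing a further small gain. The same
ordering — features < features+descriptors < features+descriptors+PSSM —
is the behaviour expected of the method on real interface data, though
absolute numbers on this clean synthetic benchmark are naturally higher.

The same steps are available from the shell:

```sh
nabind synth dataset --seed 7 --out data/
nabind encode --labeled data/sequences.labeled.fa --aln-dir data/ \
       --pssm-dir data/ --features hkm,desc,pssm --out data/inst
nabind crossval --instances data/inst --k 5 --seed 17 --out cv/
nabind train --instances data/inst --out model.joblib
nabind predict --fasta query.fa --model model.joblib \
       --calibration cv/calibration.json --specificity 0.95 \
       --msa data/synth000.aln --pssm data/synth000.pssm --out report.txt
```

and `nabind label --pdb complex.pdb --target dna --out prefix` applies the
3.5 Å distance rule to a protein–nucleic-acid complex structure.

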