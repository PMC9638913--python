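# ssmotif

Interpretable sequence–structure motif models for RNA-binding proteins.

Given two pools of RNA probes — one enriched for binding to a protein, one
background — `ssmotif` learns a small, human-readable model of what the
protein recognizes: a handful of position frequency matrices (PFMs) over
sequence and secondary-structure alphabets, combined by a sparse logistic
regression. The model answers two questions at once: *does this protein bind
a sequence motif, a structure, or both?* and *how well does that compact
description predict binding on held-out probes?*

## The model

1. **Annotation.** Each probe is folded (or supplied with a dot-bracket
   structure) and annotated in seven alphabets: the 4-letter sequence, three
   structure alphabets (2-letter paired/unpaired, 4-letter, and a 7-letter
   loop-context alphabet distinguishing external, bulge, left/right helix
   strand, internal loop, multiloop, and hairpin positions), and the three
   products of sequence with each structure alphabet (8, 16, and 28 symbols).
2. **Discovery.** In each alphabet, k-mers of width 4–6 that are
   significantly enriched in the bound pool (one-sided hypergeometric test,
   Bonferroni-corrected p < 0.01) seed PFMs; after a redundancy filter at
   most 40 PFMs per alphabet are kept.
3. **Scanning.** Every PFM is scanned over every probe's annotation with
   log₂-odds scores against a uniform background (probability floor 10⁻³);
   the probe's feature is the sum of its top 4 window scores.
4. **Regression.** An L1-penalized logistic regression over all features is
   tuned by cross-validation, then *simplified*: the penalty is repeatedly
   scaled by 1.25 until the validation AUROC drops below 90% of the initial
   predictive power (AUROC − 0.5). The last passing model — typically a few
   motifs — is returned.
5. **Interpretation.** Coefficient magnitudes are aggregated per alphabet
   and split into sequence / unpaired / paired information, quantifying the
   protein's structural specificity.
6. **Gap-HMM extension (optional).** Retained PFMs can be assembled into a
   hidden Markov model with recursive gap states (frozen emissions, EM on
   transitions only) to capture bipartite motifs with variable spacing, and
   the per-alphabet log-probabilities combined by a random forest.

A seeded synthetic-data generator (`ssmotif simulate`) produces benchmark
pools with motifs planted in unstructured probes, in hairpin loops, or as
bipartite pairs, together with a ground-truth table.

## Worked example

Simulate a pool whose bound probes carry UGCAUG inside a hairpin loop, train,
and interpret:

```sh
$ ssmotif simulate --out demo --n-probes 600 --plant-rate 0.5 \
    --structure-mode hairpin_loop --seed 7
$ ssmotif train --positives demo/positives.db --negatives demo/negatives.db \
    --model-out demo/model.json --seed 7
{
 ...
 "initial_auroc": 0.7667,
 "final_auroc": 0.7667,
 "heldout_auroc": 0.7467,
 "retained_pfms": 2,
 ...
}
$ ssmotif interpret --model demo/model.json --out demo/report.tsv
{
 "per_alphabet_weight": {
  "sequence": 0.0,
  "structure2": 0.786,
  "structure7": 0.214,
  ...
 },
 "sequence_weight_fraction": 0.0,
 "paired_weight_fraction": 0.9995,
 ...
}
$ cut -f1-4 demo/report.tsv
pfm                 alphabet    consensus  coefficient
structure2-00-PPPP  structure2  PPPP       0.1809
structure7-11-LLLL  structure7  LLLL       0.0492
```

The model correctly reports a structure-dominated specificity: the hairpin
stem (paired runs, helix left strands) is the strongest discriminating
signal at this problem size. With `--structure-mode none` the same pipeline
instead retains the UGCAUG sequence motif with a sequence weight fraction
of 1.0. Score new probes with `ssmotif score`, and fit the gap-HMM extension
with `ssmotif hmm`.

The same pipeline is available as a library:

```python
from ssmotif import DatasetConfig, GeneratorConfig, generate_dataset, train_pipeline

ds = generate_dataset(GeneratorConfig(n_probes=600, seed=7))
records = [p.record for p in ds.positives + ds.negatives]
labels = [1] * len(ds.positives) + [0] * len(ds.negatives)
result = train_pipeline(records, labels, DatasetConfig(seed=7))
print(result.model.retained, result.heldout_auroc)
```

## Testing

```sh
python -m pytest -q tests/
```

The suite checks each module against independently written oracles
(brute-force loop decomposition, naive window scanning, pairwise-concordance
AUROC, proximal-gradient LASSO, path-enumeration HMM forward) plus
property-based tests, and ends with end-to-end planted-motif recovery runs.

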