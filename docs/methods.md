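# Methods

This note records the model, its parameters and their defaults, the
numerical choices made in the implementation, and the scope and limitations
of the synthetic benchmark generator. Nothing here reports empirical
numbers; those are produced at runtime by the test suite and by
`scripts/acceptance.py`.

## Structure annotation

Probes are represented by a sequence over {A, C, G, U} (T is normalized to
U on input) and a dot-bracket secondary structure. Structures may be
supplied directly (Vienna-style files; free-energy suffixes are ignored) or
computed by calling `RNAfold -p` and taking the **centroid** structure of
the Boltzmann ensemble. Only plain nested brackets are accepted;
pseudoknotted notations are rejected.

Each structure is decomposed into loops. Paired positions are labelled L or
R (5′/3′ strand of a helix). Each unpaired position is labelled by its
enclosing loop: `E` external (no enclosing pair), `H` hairpin loop (no
child helices), `B` bulge (one child helix, unpaired bases on one side
only), `T` internal loop (one child helix, unpaired bases on both sides),
`M` multiloop (two or more child helices). This 7-letter alphabet projects
onto a 4-letter one (P = paired, L = hairpin loop, U = external, M = all
other unpaired) and a 2-letter one (P/U). Products of the sequence alphabet
with each structure alphabet give 8-, 16-, and 28-symbol combined
alphabets; each (nucleotide, context) pair is encoded as a single character
drawn from uppercase letters, lowercase letters, and digits in
nucleotide-major order. Every probe therefore carries seven parallel
annotations of equal length.

## Motif discovery

The built-in discoverer tests every k-mer of width 4–6 present in the data
for per-probe **presence** enrichment in the bound pool: with `a` of
`n_pos` bound probes and `b` of `n_neg` background probes containing the
k-mer, the one-sided hypergeometric tail probability (equivalent to a
one-sided Fisher exact test) is Bonferroni-corrected over the number of
distinct k-mers tested. K-mers with corrected p < 0.01 become PFM seeds,
ordered by corrected p-value; a greedy redundancy filter drops any seed
within Hamming distance 1 of an already accepted one, and at most **40
PFMs per alphabet** are returned. Each PFM is the position-wise frequency
matrix of the exact-match sites in the bound pool, with pseudocount 0.1
per symbol.

An alternative backend shells out to the STREME motif discoverer with the
equivalent settings (`-pvt 0.01 -minw 4 -maxw 6`, custom alphabet
definitions); it is opt-in and raises a configuration error when the
binary is absent, so the k-mer discoverer is the default and the one the
tests exercise.

## Feature scanning

A PFM of width *w* over an alphabet of size |A| is converted to log₂-odds
against the uniform background: `log2(max(f, 1e-3) * |A|)`, the 10⁻³ floor
preventing −∞ scores. Every length-*w* window of a probe's annotation is
scored and the probe's feature for that PFM is the **sum of the top 4
window scores** (all windows, if fewer than 4 exist). Probes shorter than
*w* receive the floor value `4 * w * log2(1e-3 * |A|)`. Equal-length probe
sets use a vectorized scanning path; the result is bit-identical to the
per-probe path.

Feature columns that are exact duplicates after z-scoring on the training
split are collapsed to a single column (the first in canonical alphabet
order). This matters whenever two alphabets are relabelings of each other
on a given dataset — e.g. unstructured probes, where every combined
alphabet reduces to the sequence alphabet — because the L1 optimizer would
otherwise split weight arbitrarily among identical columns, making both
the fit and the per-alphabet weight attribution nondeterministic.

## Regression and simplification

Features are z-scored with statistics frozen from the training split. An
L1-penalized logistic regression (scikit-learn `saga`, unpenalized
intercept, `C = 1/λ`) is tuned over a 33-point logarithmic grid of λ from
10⁻⁴ to 10⁴ by 3-fold stratified cross-validated AUROC, warm-starting each
fit from the previous grid point; ties prefer the stronger penalty. When a
fit drives all coefficients to zero, the intercept is set analytically to
the log-odds of the class balance (the exact MLE for an intercept-only
model), because the stochastic solver's intercept is unreliable in that
regime.

The tuned model is then **simplified**: λ is scaled by 1.25 per round, and
a round is accepted while the validation AUROC stays at or above
`0.5 + 0.9 × (initial AUROC − 0.5)`, i.e. while at least 90% of the
initial predictive power is retained. The last accepted model is returned,
together with the full trace (λ, AUROC, number of nonzero coefficients,
accepted flag). AUROC is computed rank-based (Mann–Whitney) with half
credit for ties.

Datasets are preprocessed by removing probes with non-ACGU letters, then
subsampling both pools (seeded, without replacement) to
`min(cap, size of the smaller pool)` with a default cap of 10⁶. Splits are
stratified per class with largest-remainder rounding into
discovery/train/validation/held-out = 50/20/5/25 (75/25 between model
fitting and held-out evaluation).

## Interpretation

Structural specificity is summarized from coefficient magnitudes.
Per-alphabet weight proportions are `Σ|β|` over the alphabet's retained
PFMs divided by the total; absolute values are used because a negative
coefficient is still evidence that the motif informs binding. The paired
fraction of a combined- or structure-alphabet PFM splits each column's
information content (`log2|A| −` entropy) by the probability mass on
paired symbols (P, or L/R in the 7-letter alphabet); a PFM with zero total
information counts as unpaired. The three-way decomposition
sequence/unpaired/paired sums to 1 by construction.

## Gap-HMM extension

Retained PFMs of one alphabet (at most 10) are assembled into an HMM:
a recursive `begin` state, a chain of match states per PFM (emissions =
PFM columns, frozen), a recursive gap state for every **ordered pair** of
PFMs including self-pairs (modeling variable spacing and repeated
occurrences), and an absorbing `end` state. Non-match states emit
uniformly. Only transition and start probabilities are trained, by EM
(single-step iterations, relative log-likelihood tolerance 10⁻⁴, at most
100 iterations); structural zeros are re-imposed and rows renormalized
after every step, and a degenerate (non-finite) row update restores the
previous row. Training uses at most 10 000 probes; when fewer than 20 000
are available, half of them. Per-alphabet log-probabilities are combined
by a random forest tuned by small-grid cross-validation.

## Synthetic benchmark generator

The generator emulates an in-vitro selection experiment at desk scale:
uniform (or user-specified) random probes of fixed length (default 40 nt)
with optional constant flanks; the bound pool carries a consensus
(IUPAC-sampled, default UGCAUG) planted at a per-probe rate (default 0.5)
at a uniform random offset. Three modes:

- `none` — plant in an unstructured probe; emitted structures are all-dots.
- `hairpin_loop` — the motif becomes the loop of a hairpin with a random
  Watson–Crick stem (default 5 bp); the dot-bracket is emitted by
  construction rather than by folding.
- `bipartite` — two sub-motifs separated by a uniform random gap from a
  configurable range (default 1–20 nt).

Every probe's ground truth (planted flag, offset, realized site, gap) is
recorded. **Limitations:** emitted structures are constructions, not
thermodynamic predictions — background probes are reported unpaired even
though a folding program would pair some of them, so structure-mode
benchmarks measure recovery of the constructed signal, not folding
fidelity; planting does not model selection-round enrichment dynamics or
sequencing noise; and at a 50% plant rate the positive-vs-negative AUROC
has a ceiling well below 1 by design, since half the bound pool is
indistinguishable from background.

## Test problem sizes

Module and end-to-end test sizes (probe counts, replicate counts, HMM
state counts for brute-force oracles) are this package's own choices,
selected so the whole suite runs in minutes on one CPU while keeping each
statistical assertion comfortably powered; signal parameters (plant rate,
consensus, probe length) are fixed independently of outcomes. Stochastic
recovery tests assert success counts over 20 fixed seeds with explicit
failure allowances rather than tuning per-seed behavior.

## Known limitations

- The Bayesian-optimization alternative for the λ search is not
  implemented; only the deterministic log-grid search is available.
- The STREME backend requires an external binary and is untested where
  that binary is unavailable.
- Folding uses the centroid structure only; no base-pair probability or
  ensemble-weighted annotation is implemented.
- The gap-HMM scores whole annotations; it does not report motif
  occurrence positions (no posterior decoding).
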