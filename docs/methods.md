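# Methods

## Sequence model

The generator is a stack of two LSTM layers with a dropout layer between
them and a time-distributed dense softmax over the vocabulary. Conventions
follow the common Keras layout: per LSTM an input kernel (I × 4U), a
recurrent kernel (U × 4U) and a bias (4U), gate order
(input, forget, cell, output), forget-gate bias initialised to 1, Glorot
uniform kernels. The trainable-parameter count is therefore
4·(U·(I+U)+U) per LSTM plus U·V+V for the dense layer; at U = 256 and
V = 29 this totals 825,629.

The engine (`molgen.nn`) is implemented directly in NumPy: forward pass,
backpropagation through time, inverted dropout, masked categorical
cross-entropy and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7). Gradient
correctness is pinned by a central finite-difference test through the full
stack. Sequences are framed with begin/end sentinels `G`/`E`, padded to the
batch maximum, and padded positions are excluded from loss and accuracy via
an explicit mask (the pad is an all-zero input row, never a vocabulary
token). Accuracy is per-token top-1. All randomness — initialisation, the
80/20 train/validation split, batch shuffling, dropout masks, sampling —
flows from explicit seeds, so runs are bit-reproducible in single-threaded
BLAS conditions.

Defaults: 256 units, dropout 0.3, batch 512, Adam learning rate 1e-3,
validation fraction 0.2, no gradient clipping, no early stopping (training
runs a fixed epoch budget and every epoch is checkpointed; checkpoints are
NumPy `.npz` weight files beside a portable JSON manifest, so any epoch can
be reloaded or resumed).

### Per-epoch diagnostics

Besides train/validation loss and accuracy, each epoch records validation
log-loss (identical to the masked cross-entropy on the validation tensors)
and a 1-D Wasserstein distance between the token-frequency distribution of
a small seeded model sample and that of the validation corpus, with tokens
placed at their vocabulary indices and sentinels excluded. The Wasserstein
number is deliberately labelled a *diagnostic*: token frequencies are a
coarse summary, the distance depends on the arbitrary token ordering, and
it is meant only to trend downward as the model's output statistics
approach the corpus. It is cheap (default 64 samples) and can be disabled
(`diag_samples=0`).

## Tokenisation and vocabulary

Tokens are raw single characters — `Cl` is two tokens, `Br` is two tokens —
and the two sentinels are counted inside the vocabulary size V. The
vocabulary is the sorted character set of the corpus with sentinels
appended, so rebuilding from the same corpus is deterministic. A corpus
character colliding with a sentinel letter is a hard error. Fine-tuning
never grows the vocabulary: target-corpus characters absent from the base
vocabulary raise an error listing them, because silently remapping one-hot
columns would corrupt every pre-trained weight. In practice the base
vocabulary should be built from a corpus (or corpus union) that covers the
expected target chemistry, which is how the tests and examples proceed.

## Rooted scaffold spellings

To grow a substituent at a chosen atom, the scaffold must be spelled so
that the string *ends* at that atom with free valence. Attachment sites are
all heavy atoms with ≥ 1 hydrogen, in atom-index order, with no symmetry
reduction (benzene has six equivalent sites; indole has seven sites).

Correctness of a rooted spelling is defined by a verification test, not by
its construction: the spelling must parse back to the scaffold, and the
spelling plus `"C"` must parse to the scaffold carrying one methyl at the
designated atom (canonical-structure comparison, so a symmetry-equivalent
atom is accepted — the product molecule is identical). Candidates come from
two deterministic, seeded sources and are filtered by that test:

* canonical traversals rooted at every atom, plus seeded random traversals,
  in Kekulé form (uppercase spellings avoid bracket-hydrogen bookkeeping
  when substituting aromatic N–H);
* "methyl-strip" spellings: traversals of scaffold-plus-methyl that end
  with the methyl carbon, with that final character stripped. A plain
  traversal can only end at a terminal atom, so mid-chain sites need
  spellings that end with the site atom carrying its remaining substituents
  in closed branches (for ethanol's middle carbon: `OC(C)`); these are
  exactly the methyl-strip candidates.

A site for which no candidate passes reports a per-site error without
affecting the other sites.

## Sampling and campaigns

Sampling is batched and autoregressive: the begin sentinel plus an optional
rooted prefix primes the hidden state, then characters are drawn from the
temperature-adjusted distribution `q ∝ p^(1/T)` until `E` or the length cap
(default 140 tokens, a convention chosen comfortably above typical
drug-like SMILES lengths). Strings hitting the cap are kept and flagged;
downstream they count as sampled-but-invalid. The transform is monotone, so
it never reorders probabilities; T = 1 is the identity.

A campaign crosses checkpoints × temperatures × attachment sites with
n samples per cell. Each cell draws its own sub-seed as a CRC-32 hash of
the campaign coordinates, so any cell is reproducible in isolation and the
full table is reproducible from one seed. The row skeleton can be built
without any inference (`plan_campaign`) for bookkeeping and auditing; the
production-shaped plan (4 × 4 × 7 × 2000) books out to 224,000 rows.

## Library metrics

Validity, uniqueness and novelty use chained denominators: valid/sampled,
unique/valid, novel/unique, so the counts are always nested. Uniqueness
deduplicates by canonical structure (two spellings of one molecule count
once); a raw-string mode exists behind a flag. Novelty compares 166-bit
MACCS keys with the Tanimoto coefficient against an explicit reference set
and calls a molecule novel iff its maximum similarity is strictly below
0.85. Tanimoto is used because it is the field's default similarity for
binary fingerprints; the choice is recorded in output metadata.
Descriptors are standard published definitions via RDKit: molecular weight,
Ertl TPSA, Crippen SMR and SlogP, the Ertl–Schuffenhauer synthetic
accessibility score (RDKit's shipped implementation and fragment-score
data) and Bickerton QED. Descriptor failures flag the row rather than drop
it. The 2-D chemical-space view standardises features and runs seeded
t-SNE; perplexity is clamped below (N−1)/3 so small inputs stay valid.

## Discriminator

Ligands with measured Ki are split at 100 nM — active iff Ki < cutoff,
boundary values inactive — and combined with decoys (always labelled
nonactive) into a 166-bit MACCS matrix (RDKit's placeholder bit 0 is
dropped). The classifier is scikit-learn's MLP with three hidden layers of
166 ReLU units and Adam. Evaluation is stratified six-fold cross-validation
(stratification avoids empty-class folds under heavy decoy imbalance; no
re-weighting or oversampling is applied, imbalance is just reported), with
confusion-matrix metrics at a 0.5 probability threshold and per-fold
ROC/AUC from held-out scores. Precision, recall, F1, accuracy, Cohen's
kappa and MCC are implemented from their closed forms so the degenerate
cases are explicit: any zero-denominator ratio reports 0 and sets a flag —
decoy-heavy designs can produce folds with no predicted positives, and a
silent NaN would poison fold averages.

## Synthetic data

The fixture generators make every stage testable offline; they emulate the
*statistical shape* of the real inputs, not their chemistry.

* **Toy corpus** — molecules assembled atom-by-atom under explicit valence
  caps (C 4, N 3, O 2), single bonds with occasional doubles (15%), chain
  growth with occasional branching (25%), one optional ring closure (35%),
  elements drawn C-heavy (75/15/10) and sizes right-skewed (geometric
  growth, default cap 12 heavy atoms), exported as Kekulé SMILES. Validity
  is guaranteed by construction — no rejection sampling. The C-heavy,
  right-skewed design matters: it gives the corpus the skewed character
  statistics of real drug-like SMILES, which is what makes low-temperature
  sampling collapse onto repeated molecules (the validity/uniqueness
  temperature trade-off). A uniform grammar would not show that behaviour.
* **Motif-enriched corpus** — a stand-in for a target-ligand set: a set
  fraction of molecules is the motif (default furan, Kekulé `C1=CC=CO1`)
  carrying a short random substituent, the rest plain toy molecules.
* **Separable fingerprint set** — two fixed 166-bit class templates (drawn
  once from an internal constant seed, so they are identical across
  datasets) with independent per-bit flips at a configurable rate; the flip
  rate is the single difficulty dial and must stay below 0.5.

What passing tests on these fixtures do *not* show: real SMILES corpora
have aromatic systems, charges, stereochemistry and far longer strings;
real activity data has label noise, similarity between actives and
inactives and non-template structure. The fixtures establish that the
machinery is correct and that the qualitative trends appear, not that
production-scale metric values are reproduced.

## Problem sizes and numerical choices

The test suite and examples run the toy study: a 2,000-molecule corpus,
64-unit model, 30 epochs, batch 128, 500 samples per temperature cell,
949-molecule transfer corpus (20 epochs, first LSTM frozen), and a
600-row fingerprint set at flip rate 0.05 for six-fold CV. These sizes
train in tens of seconds while leaving the qualitative behaviour intact;
the production defaults (256 units, batch 512, 100 epochs, 2,000 samples
per cell) are supported but not exercised by tests. Batch 128 and learning
rate 1e-3 for the toy study are small-corpus choices: at batch 512 the
2,000-string corpus would yield only three updates per epoch.

Other numerical conventions: probability vectors entering the temperature
transform must be normalised to 1e-9; softmax and sigmoid use
numerically stable forms; cross-entropy clips probabilities at 1e-12;
non-finite training loss aborts with context rather than continuing.

## Known limitations

* Character-level tokenisation treats `Cl`/`Br` as two tokens each, which
  slightly inflates the invalid-string rate on halogen-rich corpora; an
  atom-aware tokenizer is a possible extension, deliberately not the
  default.
* The Wasserstein diagnostic depends on token ordering and is comparable
  only within a run.
* Rooted-spelling search is stochastic-complete in practice but not proven
  exhaustive; a site failure is reported, never silently skipped.
* Attachment requires an available hydrogen; substitution at
  fully-substituted atoms (bond breaking) is out of scope, as are SELFIES
  representations, SMILES augmentation, beam/nucleus decoding and
  reinforcement-learning fine-tuning.
* The single-threaded bit-reproducibility guarantee weakens under
  multi-threaded BLAS reductions.
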