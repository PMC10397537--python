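# Methods

## View construction and the invariance argument

A molecule is parsed (RDKit) into a hydrogen-depleted annotated graph
`G = {V, E, X_atom, X_bond}`. The atom annotation deliberately includes
`heavy_degree`, the number of heavy-atom bonds of each atom; this redundancy
between topology and annotation is load-bearing. A fragment-pair view removes
one *breakable* bond — a non-aromatic single bond lying on no cycle — giving
`G' = {V, E − {e_ij}, X_atom, X_bond}` with exactly two connected components.

Two properties make `G'` semantically invariant, and both are verified
mechanically rather than assumed:

1. **Conflict freedom.** `is_valid_molecular_graph` checks whether every
   atom's degree in `E'` matches its recorded `heavy_degree`. In any view the
   two severed endpoints are deficient by exactly one, so the check fails:
   `G'` cannot be the graph of any real molecule.
2. **Ambiguity freedom.** `reconstruct` enumerates every unordered atom pair
   with deficit 1 at both ends, re-adds a single bond, and keeps candidates
   whose topology again matches the annotations (realised through RDKit and
   compared by canonical SMILES). For a view the deficient pair is unique, so
   exactly one molecule — the parent — can have produced it.

Design choices: bond acyclicity is decided by ring membership of the *bond*
(removing a ring bond would leave one component, not a fragment pair);
aromatic bonds are never breakable even when a kekulised form writes them as
single; terminal bonds are breakable (single-atom fragments are legitimate);
molecules with `Nb = 0` (benzene, cyclohexane, …) produce no view and are
filtered from pre-training corpora at load time. Stereochemistry is dropped:
the definitions operate on 2-D annotated topology. Multi-fragment inputs keep
the largest fragment. The exact feature columns are declared in
`chem_io` (element one-hot over the organic subset plus "other",
heavy degree, formal charge, aromaticity, hybridisation, ring flag; bond
order, conjugation, ring membership) and versioned
(`FEATURE_SCHEME_VERSION`); checkpoints refuse to load across scheme changes.

## Encoders

Both branches use an attentive message-passing encoder (neighbour attention
with edge features, gated recurrent atom updates, then a recurrent
attention readout per component — the attentive-fingerprint family). The two
branches have separate weights. The fragment encoder runs on the
disconnected view; messages can only travel along existing edges, so the
components are structurally isolated, and the per-component readouts are
summed element-wise. Atoms without incident edges still pass through the
recurrent update with a zero message, so a component embeds identically
whether it appears alone or inside a view — a property the tests check
exactly.

The per-view embeddings are fused by a standard Transformer encoder
(multi-head self-attention + feed-forward, residuals, layer norm) with **no
positional encoding**: the views are an unordered set, and their enumeration
order is an artifact of bond indexing. The fused fragment-view
representation is the element-wise sum of the output tokens, making `h_fv`
permutation-invariant (checked to < 1e-5 under random permutations; observed
deviations are at float64 rounding level). The fused tokens are taken to be
the Transformer outputs themselves. Because molecules are processed one at a
time at their natural `Nb`, no padding or attention masking is needed.

Three separate two-layer projection heads (`mol`, `fv`, `frag`) map
embeddings to the unit sphere (`v / ||v||`). Default architecture:
embedding dim 256, 2 message-passing steps, 2 readout steps, 2 fusion layers,
4 heads, projection hidden dim 256. Tests and the acceptance script use a
32-dimensional single-fusion-layer configuration — the properties under test
(invariance, alignment, collapse, transfer contracts) are scale-free, and
this size keeps full runs to minutes on one CPU.

All numerics run in float64 on a small reverse-mode autodiff engine
(`fragclr.autodiff`) whose gradients are finite-difference-tested; runs with
the same seed are bitwise reproducible.

## Losses

NT-Xent uses inner-product similarity of unit projections with temperature
τ (default 0.1). The per-molecule terms are the standard negative-log form;
minimising them pulls a molecule's two views together and pushes different
molecules apart. The denominator excludes the positive pair
(`denominator_mode="as_printed"`, the indicator `k ≠ i` applied to both the
same-branch and cross-branch sums); a `simclr` mode that keeps the positive
in the denominator is available as a flag. Batch reduction is a sum; a mean
is easily obtained by rescaling the learning rate.

The auxiliary loss compares each molecule's fragment-projection similarity
matrix `S` to the all-ones matrix: `L_sim_k = (1/Nb_k²) Σ (s_ij − 1)²`,
bounded in [0, 4] and zero exactly when all of a molecule's view projections
coincide. That zero is the collapse fixed point: with γ large (e.g. 10) the
optimiser drives within-molecule fragment-projection variance down, which the
tests demonstrate directionally at desk scale. Default γ = 0.01, the weight
at which the auxiliary nudge helps without dominating.

## Pre-training and transfer

Pre-training: Adam (lr 1e-3), batch size 16, 5% of the corpus held out for
model selection on validation total loss; the returned checkpoint is the
validation-best epoch. A one-molecule validation set has no negatives, so
selection then falls back to the train loss. An optional `nb_cap` subsamples
views of very flexible molecules (off by default). Divergence (non-finite
loss) aborts with a diagnostic.

Transfer: four settings — {`ft` fine-tune, `fr` freeze} × {`mol` uses
`h_mol`, `frag` uses `h_fv`} — with a fresh two-layer prediction head.
Datasets are split by Bemis–Murcko scaffold 8:1:1, groups assigned greedily
from largest to smallest (train, then valid, then test; seeded shuffle breaks
ties), so no scaffold spans two splits. In `fr` mode only head parameters
enter the optimiser; encoder bit-identity is asserted by hashing. Model
selection on validation ROC-AUC / RMSE prefers the later epoch on ties,
because small validation splits saturate early while the model is still
improving. Classification uses logit binary cross-entropy and ROC-AUC;
regression uses squared error and RMSE. Multi-task averaging over per-task
ROC-AUC applies only to tasks with both classes present.

## Synthetic data

The generator grows a random bonded tree under fixed valence caps
(C 4, N 3, O 2, S 2, halogens 1 — caps chosen so the generator can never
emit an invalid molecule, not to mimic real valence distributions), with an
optional single-bond ring closure at `ring_probability`. It therefore covers
acyclic, ring-containing and view-less (pure ring) molecules, but its
chemistry is intentionally plain: no multiple bonds outside the toy corpus,
no charged species, no realistic functional-group frequencies. Passing tests
show the machinery is correct on valid chemistry at small scale; they say
nothing about predictive performance on real benchmark chemistry, which
requires large-scale pre-training out of scope here.

Problem sizes used by the test suite and acceptance script, chosen as
desk-scale defaults: 500 random molecules (≤ 12 heavy atoms) for exhaustive
invariance certification; 100 molecules / 20 epochs for the pre-training
runs; 200 ring-rich molecules (`ring_probability` 0.6) for transfer tasks —
ring variety is needed because all acyclic molecules share the empty
Bemis–Murcko scaffold, which would starve the scaffold split. Synthetic
labels (`has_oxygen`, `nb_count`, an additive LogP-like score) are
deterministic functions of the graph, so transfer metrics have a known
learnable signal.

## Known limitations

* The encoder is attentive-fingerprint-*style*, not a line-by-line
  reproduction of any published architecture; contracts (determinism,
  permutation invariance, separate readout) define its correctness here.
* Pure-NumPy training is single-threaded and desk-scale; hundreds of
  thousands of molecules would require a GPU framework.
* `evaluate` refuses ROC-AUC on single-class splits rather than imputing.
* Trailing validation batches of size one are skipped when computing
  validation loss (no negatives exist for them).
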