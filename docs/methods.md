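# Methods

This note documents the models, conventions and design choices behind
`deepvs`, in the order the cascade runs them.

## Pocket definition and units

Structures are handled in Å internally. A binding pocket is the set of
residues with at least one heavy atom within a cutoff of the reference
ligand; the cutoff is accepted in nanometres (default 1.0 nm = 10 Å), the
unit binding-site definitions are usually quoted in. The boundary is
inclusive (`distance ≤ cutoff`), hydrogens are ignored on the protein side
(crystal structures usually lack them), and the pocket "mass center" is the
unweighted arithmetic mean of the pocket heavy-atom coordinates — no
atomic-mass weighting, since nothing downstream is sensitive to the few
tenths of an Å the weighting would move the docking-box center.

## Substructure sentences and embeddings

A molecule becomes an ordered token list with one Morgan substructure
identifier per heavy atom per radius 0..R (default R = 1), generated from a
canonicalized molecule so the sentence is independent of the input SMILES
spelling. Pockets are treated as disconnected residue fragments of one
molecular graph: each residue is rebuilt from its coordinates with
proximity bonding, sentences are generated per residue and concatenated in
residue order. Residue-level fragments keep the construction robust to
missing inter-residue bonds; the choice is configurable in principle but
fixed here.

Token vectors are trained with skip-gram + negative sampling (5 negatives,
window 10 for chemical corpora; the synthetic experiments use window 5 and
one epoch). Training is single-threaded and deterministic. Input vectors are
initialized near-unit-norm Gaussian (σ = 1/√dim): the vocabulary matrix then
starts well conditioned, so a summed molecule vector is an approximate
isometry of its token counts even when the corpus carries little
co-occurrence structure, and gradient updates add structure on top instead
of collapsing the space. A molecule vector is the sum of its token vectors;
out-of-vocabulary tokens map to the zero vector so unknown substructures
contribute nothing rather than noise. The classifier input is the
concatenated (pocket ++ ligand) vector z-normalized per dimension with
training-set statistics only (std floored at 1e-8).

## Pair-vector classifier (DFCNN-style)

A fully connected ReLU stack with a sigmoid output trained on binary
cross-entropy with Adam (optional decoupled weight decay). The library
default is four hidden layers (512, 256, 128, 64). Cross-combination
negatives are sampled uniformly without replacement from all (pocket_i,
ligand_j) pairs with i ≠ j, excluding any ligand identical (by canonical
SMILES key) to the pocket's own ligand, so repeated ligands never create
mislabeled negatives.

The networks are implemented in numpy rather than a GPU framework: at desk
scale the matrices are small, and single-threaded numpy training is exactly
reproducible from a seed, which the determinism contracts in the test suite
rely on. Backpropagation through every layer type is verified against
central finite differences in the tests.

## Docking adapter

Configuration mirrors the standard screening protocol: box centered on the
pocket mass center, 25 Å (2.5 nm) per axis, exhaustiveness 8, 20 binding
modes, energy range 3 kcal/mol — all overridable. Scores are kcal/mol with
more negative = better, and the cascade compares docking scores with `≤`.
The mock engine used by tests and dry runs returns a deterministic affinity
(−(2.0 + 0.18·heavy atoms) plus seeded jitter, in the typical Vina score
range) and places poses 4–10 Å off the box center: a non-cognate ligand
settles in shallow peripheral minima rather than the pocket focus, which is
what makes mock cross-docked poses geometrically decoy-like (sparser,
longer-range contacts). Vina-style config files and result tables are
written/parsed so an external engine can be substituted without touching the
rest of the pipeline.

## Interface maps and pose classifier

A pose's interface map has one row per (protein heavy atom, ligand heavy
atom) pair within 10 Å, sorted ascending by distance (ties broken by atom
indices), truncated to the `max_rows` closest contacts and zero-padded to
fixed size. Each row is a one-hot protein element over {C, N, O, S, P,
halogens-grouped, other}, a one-hot ligand element, and the distance scaled
by 1/cutoff into [0, 1] — 15 channels. The default 256 rows matter: with
dense toy interfaces, aggressive truncation discards the contact-count
signal that separates natives from decoys. The layout is a declared
convention, versioned inside saved model files.

The classifier is a 1-D convolutional network over the distance-sorted rows
with at least one identity skip connection (`y = relu(x + conv(relu(conv
x)))`), global average pooling and a sigmoid head. The desk-scale default in
the synthetic experiment is 16 channels and one residual block trained 100
epochs at batch 16, which generalizes reliably from ~50 training maps.

## Cascade, ranking, clustering

Selection keeps a compound iff `deepbindbc > a`, `docking ≤ b` and
`dfcnn > c`, with the operators exactly as the criteria are quoted — strict
on the two probabilities, inclusive on the docking score (a published
candidate sits exactly on a −8.5 boundary, confirming the inclusive
convention). Comparisons use values as given, without rounding. Ranking is a
stable sort (probabilities descending, docking ascending); ties keep input
order. Chemotype grouping uses 2048-bit hashed circular fingerprints
(radius 2), Tanimoto similarity and Butina clustering at threshold 0.6 by
default; the number of groups is an outcome, never a target. The cluster
representative is the highest-scoring member when scores are supplied,
otherwise the Butina centroid.

## Enrichment statistic

`Ratio_c = (N_c/N_total) / (NN_c/N_all)` with strict `>` at the cutoff
(default 0.9): the recall of known actives above the cutoff divided by the
fraction of all compounds above it. No smoothing or pseudocounts — a zero
denominator is an error, not infinity. AUC is the rank-based (Mann–Whitney)
statistic with ties counting 1/2.

## Trajectory post-analysis

Ligand RMSD is computed after least-squares (Kabsch/SVD) superposition of
each frame onto the reference over the protein Cα selection — superposing on
the protein separates ligand motion from global tumbling. The hydrogen-bond
criterion defaults to donor–acceptor distance ≤ 3.5 Å and D–H···A angle
≥ 130°, a common geometric choice; both are configurable since published
criteria vary. Stability ranking orders candidates by ascending mean ligand
RMSD over the analyzed window.

The free-energy surface along a 1-D collective variable is the negated sum
of deposited Gaussian hills, computed vectorized over a grid (default 512
points spanning hill centers ± 3σ_max). Well-tempered rescaling γ/(γ−1) is
available but off by default, since the plain negated-bias estimate is the
variant-agnostic baseline. Hills files are whitespace-delimited
(time, center, sigma, height), the common HILLS layout.

## Synthetic data: what it emulates and what it does not

The **planted library** stands in for a curated complex database. Each
pocket sentence carries a hidden key token; a ligand truly binds iff it
contains the complementary key. Defaults: 50 pockets × 40 ligands = 2,000
pairs, key alphabet 6, binder rate 0.1 (actives are the minority, as in a
screening library), signal strength 0.9 — labels flip with probability
(1 − 0.9)/2 = 0.05, emulating annotation noise. One in five non-binders
carries a mismatched key token, the way screening libraries contain actives
of *other* targets, so presence of a key alone is not sufficient — the
classifier must learn the pocket–ligand pairing. Evaluation is
planted-signal *recovery*: training uses the noisy labels, but AUC and
Ratio_0.9 are measured against the true planted rule (the synthetic
analogue of recalling known actives). With rare actives and symmetric label
noise this distinction is essential — measured against the noisy labels,
even a Bayes-optimal scorer is capped near 0.84 AUC at these rates, which
says nothing about whether the signal was recovered.

The headline synthetic experiment uses 5-fold cross-validation (every pair
scored out-of-fold) with 256-dimensional embeddings and a single 128-unit
hidden layer trained 400 epochs: at 2,000 pairs the deep default stack
memorizes the training pairs instead of generalizing the pairing rule, and
a single 20 % holdout leaves only ~40 true binders in the evaluation, too
few for a stable ratio estimate.

**Toy 3-D complexes** are spherical heavy-atom shells (radius 5–8 Å) with
the cognate ligand inside — compact interfaces — against mock cross-docked
decoys that land off-center. **Trajectories** are a near-rigid Cα cage with
a ligand that either fluctuates around its reference (stable) or
additionally drifts at a constant rate along a fixed direction. **Hills
logs** are uniform draws inside stated ranges. All generators are pure
functions of (spec, seed).

What passing these tests shows: the implementation recovers signals it
plants, exactly matches brute-force oracles, and honors its contracts. What
it does not show: performance on real chemistry — real pockets, poses and
trajectories have correlations, conformational physics and class overlap
that the generators deliberately omit, and the published large-scale
accuracies (e.g. AUC ≈ 0.91 on an external complex database) are
out of desk scope.

## Numerical conventions

- Strict vs inclusive comparisons as above; no rounding anywhere in the
  cascade.
- Distance ties in interface maps broken by (protein index, ligand index);
  sort stability makes maps independent of input atom order.
- Gaussian-sum FES agrees with the direct double loop to ≤ 1e-12; Kabsch
  RMSD agrees with an independent superposition implementation to ≤ 1e-9.
- All stochastic components (generators, negative sampling, initialization,
  batching) draw from seeded `numpy` generators; derived seeds are reduced
  mod 2³¹−1.

## Known limitations

- The pocket-fragment sentence construction depends on proximity bonding;
  exotic residues degrade to element-level tokens rather than failing.
- The external-engine adapter shells out to a `vina` binary and is untested
  against real output beyond the documented log dialect.
- The interface-map layout is a declared stand-in for the original
  "figure-like" encoding, which is not fully specified publicly.
- FES reconstruction is 1-D; multi-CV landscapes are out of scope.
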