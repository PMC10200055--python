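# Methods

This note records the models, conventions and numerical choices behind
sefkit, and what the synthetic test bed does and does not establish.

## Descriptors

**Token entropy.** A string notation is split into tokens and the
Shannon entropy of the token frequencies, `S = −Σ f_i log2 f_i`, is the
scalar descriptor, in bits (base-2 logarithms throughout). The
tokenizer is the community-standard atom-wise SMILES grammar: bracket
atoms `[...]` are atomic tokens, the organic-subset digraphs `Cl` and
`Br` are single tokens, `%nn` two-digit ring closures are single
tokens, and every other character (aromatic atoms, bond symbols,
parentheses, dots, ring digits) is its own token. The grammar is
deterministic and lossless (`"".join(tokens)` reproduces the input), so
no trained vocabulary is needed; learned byte-pair merges are
deliberately out of scope. SMARTS is tokenized with the same scanner —
the logical operators `& ; , !` and recursive-pattern characters fall
through as single-character tokens and bracket expressions like `[C,N]`
stay atomic — and InChIKeys character-wise, hyphens included.
Validation at this layer is purely syntactic (balanced brackets,
complete `%nn`); chemical validity is the parser's job downstream.

Entropy is evaluated as `log2 N − (Σ n_i log2 n_i)/N` over the integer
counts, so frequencies enter as exact ratios; the counts are summed in
sorted order so the result depends only on the count multiset, and a
single-unique-token table returns exactly 0.0 (the `0·log 0 := 0`
convention applies). The value is bounded by `log2 k` for `k` distinct
tokens, with equality at uniform counts.

**Fractional entropy.** The molecule's total entropy is apportioned to
atoms by species, analogously to partial pressures in a gas mixture:
each atom of species *j* carries `s_j = f_j · S`, with `f_j` the
species' share of the counted atoms. All atoms of one species share one
value and the distinct-species values sum to `S` exactly (to float
round-off; the test bound is 1e-12 bits). The source entropy is
configurable — SMILES by default, SMARTS or InChIKey on request — since
the apportionment is generic over any scalar entropy.

**Atom counting and hydrogens.** Atoms are counted as the chemical
parser (RDKit) produces them from the string. Implicit hydrogens never
appear in the string and are therefore not counted by default
(`hydrogen_mode="explicit"`); hydrogens written as `[H]` atom nodes are
counted. Note that an in-bracket hydrogen count such as the `H` in
`[C@@H]` is an atom *property*, not an atom node, and is not counted in
explicit mode. `hydrogen_mode="all"` adds every hydrogen as an atom for
users who want composition-complete counts. Aromatic atoms count under
their element symbol (`c` → C).

**Padding.** Per-atom vectors are zero-padded to a fixed width `N_max`
with the surplus split `(N_max − m)/2` per side; an odd surplus puts the
extra zero on the right (floor left / ceil right), a fixed convention
that keeps batches reproducible. `N_max` defaults to the largest atom
count in the batch the featurizer was fitted on and can be pinned so
train and test share one width; a molecule wider than `N_max` raises a
capacity error rather than truncating. Padding preserves the per-atom
sum exactly.

**Bond profile.** Bond-type frequencies are tallied over the fixed list
`[SINGLE, DOUBLE, TRIPLE, QUADRUPLE, AROMATIC, HYDROGEN, IONIC]`, in
that order; a bond outside the list raises rather than being silently
binned. The bond entropy `S_bf` uses the same formula as token entropy
and is zero exactly when at most one bond type is present. A molecule
without bonds gets an all-zero frequency vector and entropy 0.

**Matrix assembly.** Columns are emitted in a fixed order — scalars
(mw, shannon_smiles, shannon_smarts, shannon_inchikey), the
fractional-entropy block, the 7 bond frequencies, shannon_bonds, then
fingerprint bits — so downstream models are reproducible from the
config alone. Molecular weight uses average atomic masses from the
parsed structure. Morgan fingerprints (radius 2, 2048 bits by default)
are optional comparator columns delegated to RDKit, not part of the
entropy framework itself. SMARTS strings, when not supplied, are
written from the parsed molecule by RDKit's SMARTS writer — a
convention, since patterns have no canonical origin for plain
molecules. Strings are featurized as given by default: entropy is a
property of the *representation*, and two SMILES of one molecule can
differ. A `canonicalize` flag re-writes the canonical SMILES first for
users who need representation-independent values; InChIKey-based
columns are canonical either way.

**Node features.** For graph models each atom becomes a node carrying
element, atomic mass, its fractional entropy and the molecule's total
SMILES entropy replicated per node; edges carry bond connectivity and a
normalized bond order (order divided by the maximum order present in
the molecule, aromatic bonds entering as 1.5).

## Baseline models

**Tanimoto-kNN.** ECFP4 fingerprints (Morgan, radius 2, 2048 bits) and
Tanimoto similarity; the prediction is the mean target of the k most
similar training molecules, or the majority vote for classification
with vote ties broken toward the most similar neighbour. k is swept
over {1, 2, 3} and chosen on a seeded 20 % held-out validation split of
the training set — never on test — then the final model uses all of
train. Similarity ties at the k-th rank resolve by stable training-set
order. A query fingerprint with no bits set has undefined similarity;
it still receives a (stable-order) prediction but is flagged.

**Grid random forest.** The full 3×3×3 grid — trees {25, 100, 200},
minimum samples per leaf {1, 2, 5}, minimum samples per split
{2, 3, 5} — is scored by at least 5-fold cross-validation on train
(mean absolute error for regression, accuracy for classification), the
best triple refit on all of train. Everything is seed-reproducible via
`random_state`.

**Metrics.** MAPE is `mean(|y−ŷ|/|y|)·100` with zero-target rows
excluded and counted (the common convention; division by zero has no
standard value). R² is `1 − SS_res/SS_tot` and is flagged undefined
when the truths are constant. ROC AUC is the rank statistic on raw
scores; accuracy thresholds at 0.5. Stochastic model comparisons should
be averaged over ≥5 seeds; the report carries a `replicates` field for
that purpose.

## Synthetic test bed

Fixtures are assembled by concatenating SMILES fragments from a
valence-safe pool (alkyl chains, an aromatic and an aliphatic ring,
ether/amine/thioether/carbonyl linkers, terminal halogens, nitrile,
carboxyl, trifluoromethyl), joined implicitly by single bonds, 2–6
fragments per molecule. Every fragment's token list, atom composition
and bond composition are declared by hand in the pool table, so each
fixture carries exact ground truth that the tokenizer and entropy code
are tested against; truths are additive under concatenation plus one
SINGLE bond per join. Assemblies the parser rejects are resampled and
counted. Targets follow a declared rule — linear in SMILES entropy
(default slope 2, intercept 0), linear in molecular weight, or a
binary median split — plus Gaussian noise (default σ = 0.01), all
reproducible under one seed.

The benchmark configuration used by the test suite and the acceptance
script is 200 molecules, target `2·S_m + N(0, 0.01)`, with a 160/40
train/test split for the forest. These sizes keep a full grid search
comfortable on a laptop while leaving the noise small relative to the
entropy spread (roughly 0.8–2.5 bits across the pool), which is what
makes near-perfect recovery (R² > 0.9) the correct expectation rather
than a tuned outcome; the threshold was pre-validated with an
independent scikit-learn reference run of the same protocol.

What the fixtures do *not* emulate: realistic chemical-space coverage,
ChEMBL-like property distributions, activity cliffs, measurement error
structure, or stereochemistry-rich molecules. Passing tests establish
that the descriptors and models are implemented correctly and that the
pipeline recovers a signal it is built to carry — not that SEF
descriptors are predictive on any particular real assay.

## Known limitations

- Entropy of a non-canonical SMILES depends on how the string was
  written; use `canonicalize=True` when representation invariance
  matters.
- The per-molecule token frequencies carry no corpus-level vocabulary;
  the token sets are exposed so a shared-vocabulary variant could be
  layered on later.
- The HYDROGEN and IONIC bond-type slots are carried for completeness
  but RDKit's SMILES parser will rarely produce them.
- kNN classification's tie rule (side with the nearest neighbour) is a
  convention; other choices are defensible.
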