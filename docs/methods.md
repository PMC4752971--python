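# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the design was open,
and what the synthetic studies do and do not demonstrate.

## Activity orientation and z-standardization

Ten bioactivity readouts are supported. Six are raw concentrations stored
in nM after unit normalization (IC50, EC50, Potency, AC50, Kd, Ki; accepted
input units M, mM, µM/uM, nM — anything else is a rejected row, never a
guess); three are already on the −log10 molar scale (pIC50, pKi, pEC50);
LogKi is a log10 molar value and is negated. A single per-type transform
table maps everything onto the oriented scale so that "larger = stronger"
holds uniformly; handling the direction in one place, rather than with
post-hoc sign flips, is what makes downstream monotonicity guarantees
(halving an IC50 strictly raises its z) structural rather than incidental.

z-scores are computed within each (target, data type) group with the
sample (n−1) standard deviation — stated explicitly so that the two-point
group is exactly ±1/√2. Degenerate groups (n = 1 or SD = 0) are kept and
assigned z = 0, flagged in the group statistics, so that every stored
interaction still renders on the heatmap; excluding them was the
alternative, but a silent hole in a visualization matrix is worse than a
neutral cell. Duplicate measurements are kept as separate records; no
aggregation rule is imposed at this layer (the heatmap applies max-z at
display time, with mean available via configuration).

## Fingerprints and similarity

Five 1024-bit binary fingerprints: `path1024` (hashed linear paths of 1–7
bonds, the Daylight convention), Morgan radius 2 and 3, and their
pharmacophore-feature variants. The set was chosen to span the two classic
fingerprint families with standard radii; bit generation is delegated to
RDKit and is deterministic for a given canonical SMILES. Tanimoto is
computed directly on the bit vectors with 0/0 defined as 0. The similarity
search default threshold Tc > 0.85 is *strict*; at threshold 1.0 only
structurally identical fingerprints would pass, so the inclusive variant
(≥) is an explicit opt-in (`strict=False`, `--inclusive`). Ties in the
ranking are broken by compound id so output order is total.

No standardization beyond SMILES canonicalization is attempted (no
tautomer or salt handling) — compound identity is canonical-SMILES
equality.

## Scaffold trees

The Murcko framework (rings plus linkers, side chains stripped; atoms
double-bonded directly to a ring are retained) is reduced one ring per
step until a single ring remains, so a k-ring molecule always yields a
k-step chain. Ring choice follows an ordered prioritization list:
3-membered heterocycles first; macrocycles (≥12) last; fewest acyclic
linker bonds in the resulting parent; ring sizes 3/5/6 removed before
other sizes; fewest heteroatoms first with N > O > S precedence; smaller
rings first; and a final lexicographic tie-break on the canonical SMILES
of the candidate parent, which makes the decomposition a total
deterministic function of structure. The bridged/spiro retention rules and
the aromatic-disruption rule of the full published scheme are not
implemented; candidates whose removal disconnects the scaffold or does not
survive sanitization are simply discarded, which covers the same intent
for the chemistry exercised here. Scaffold identity keeps atom types (no
generic carbon-skeleton tier).

Acyclic molecules get their own forest partition so ring and non-ring
chemistry never merge. Their pruning chain removes one terminal atom per
step — heteroatoms first, then carbons off the longest carbon chain —
ending in the carbon backbone (n-octanol → octane). This is the package's
deterministic interpretation of iterative side-chain pruning for non-ring
molecules; branched molecules resolve ties by canonical atom order.

## SEA

The raw score of two compound sets is the sum of cross-pair Tanimoto
values at or above the inclusion threshold, default Tc ≥ 0.57 — the
established optimum for Daylight-style path fingerprints — configurable.
Background calibration draws random disjoint set pairs from a library
(default 100 pairs per size combination over sizes {4, 8, 16, 32}, i.e.
1000 pairs total; the fit refuses to run on fewer than 100) and fits the
mean and SD of the raw score linearly in n₁·n₂. The expectation is exactly
linear in n₁·n₂ by construction; the SD is treated as approximately linear,
which empirically calibrates fresh random pairs to mean ≈ 0 and SD within
~5% of 1 on the synthetic libraries. A fitted SD floor of 1e−12 keeps z
finite for degenerate libraries.

Significance uses the zero-mean unit-variance Gumbel parameterization,
P(Z > z) = 1 − exp(−e^(−(zπ/√6 + γ))) with γ the Euler–Mascheroni
constant, evaluated via expm1 so the far tail stays positive. The E-value
multiplies by the number of targets actually scored in the call — the
tool is self-contained, so the multiplicity is the analysis's own, not a
database constant. Targets need more than 10 ligands to be scored; smaller
sets are reported as skipped, not silently dropped. A target's ligand set
is any compound with a recorded activity (no potency filter), since the
gap-filling use case wants the prediction layer defined wherever data
exist.

## QSAR ensembles

Per target with more than 20 distinct measured compounds (a strict gate:
exactly 20 is refused), 15 models are trained — 5 fingerprint variants × 3
oriented-activity cutoffs {4, 5, 6}. A compound is active at a cutoff iff
its strongest oriented measurement on the target reaches it (inclusive
boundary). Training sets are exactly balanced: measured inactives are
topped up (or subsampled) with seeded uniform draws from a structure pool
that excludes every compound measured on the target — the leakage guard —
until negatives equal positives.

The classifier is Bernoulli Naive Bayes over fingerprint bits with
Laplace (add-one) smoothing, the standard choice for binary substructure
features. Performance is assessed by stratified 5-fold cross-validation
with seeded shuffling (fold assignment is part of the deterministic
contract); a model whose minority class cannot fill 5 folds, or a cutoff
with no positives, is recorded as degenerate with weight 0 and never
votes. The ensemble weight is the cross-validated MCC clipped at zero
(AUROC is computed and stored for reporting alongside); the prediction is
the weight-normalized convex combination of member active-class
probabilities, so it is always in [0, 1], and an ensemble whose weights
are all zero refuses to emit a number rather than returning noise. Models
persist as transparent JSON (NB log-probabilities, weights, CV metrics) —
no binary blobs.

## Enrichment

The "protein complex" proxy is the depth-1 PPI neighborhood (protein plus
direct partners; depth configurable). Terms are scored with the upper-tail
hypergeometric probability P(X ≥ overlap) against a universe defaulting to
the network's node set (tests and examples pass the full synthetic target
universe explicitly, since in a small sparse graph the node set
under-represents the study population). Correction is Benjamini–Hochberg
within each annotation category, with Bonferroni available; BH is the
standard choice for term enrichment where terms overlap heavily.

## Heatmap assembly

Rows are a depth-first linearization of the scaffold forest (siblings in
canonical-SMILES order, a node's own compounds before its children,
compounds in id order); columns are the depth-first family-tree order,
equivalent to sorting targets by (family path, id). The cell for a pair is
the maximum z over all its records — the strongest evidence is displayed —
with mean aggregation available. Gap filling never touches a measured
cell: predictions enter only empty cells, origin-tagged (`sea` / `qsar`).
SEA fills display the calibrated z with the raw score kept alongside;
QSAR probabilities stay on their own [0, 1] origin-tagged scale because no
principled map from a class probability to a z-score exists. The legend
metadata records the blue (weak) → orange (strong) convention. TSV export
writes values with `str(float)` so export → import → export is
byte-identical; the origin grid travels as a sidecar file, and the JSON
form additionally carries the predictor-native raw values.

## Synthetic studies

The generator enumerates libraries from a five-scaffold grammar (benzene,
pyridine, cyclohexane, thiophene, benzofuran — the last chosen so its tree
root, furan, is distinct from every other root) decorated at up to two
sites from a 25-fragment list: 10 neutral fragments plus three variants of
each of five pharmacophores (sulfonamide, nitrile, carboxyl/ester, amide,
bromo). Each target is assigned a pharmacophore cyclically; compounds
containing it draw oriented activities from N(7.0, 0.2) (≈100 nM, a
realistic potent hit) and the rest from N(3.5, 0.2) (sub-millimolar). The
inactive mean sits below the lowest QSAR cutoff (4) by 2.5 SD because an
inactive population centered exactly on a cutoff would make that cutoff's
class labels a coin flip, independent of structure — the planted signal,
not the boundary, should decide the labels. Three decoration variants per
pharmacophore give each target on the order of 15–30 planted actives in a
200-compound library, enough positives for stratified 5-fold CV to be
meaningful. Activities are drawn in oriented space and back-converted to a
randomly chosen data type and unit, exercising the normalization layer;
the PPI generator plants one clique covered exactly by one annotation term
over an Erdős–Rényi (p = 0.1) background.

What the synthetic studies emulate: heterogeneous readouts and units,
scaffold-clustered chemistry, structure-driven activity, network modules.
What they do not: assay noise structure of real databases (inter-lab
variability, censored values), promiscuity, activity cliffs, scaffold
sizes beyond three rings, or realistic class imbalance. Passing tests
therefore demonstrate correctness and recoverability of planted signal
under controlled conditions, not real-world predictive performance.

## Problem sizes and numerics

The default study is 200 compounds × 20 targets; the similarity-search
check runs a 1000-compound library, SEA calibration a 640-compound library
with 1000 background pairs and 1000 fresh evaluation pairs, and the QSAR
recovery check three replicate studies (seeds differing by 1), sizes
chosen so the full pipeline and its checks complete in well under a
minute each on a single core. All randomness flows from explicit
`numpy.random.default_rng` seeds; per-model QSAR seeds are drawn from a
`SeedSequence` so members are independent but reproducible. Ties anywhere
(ranking, sibling order, ring choice) are broken lexicographically so
every output is a total function of input + seed.

## Known limitations

* Scaffold prioritization implements the deterministic core of the
  published rule list, not the bridged/spiro/aromaticity refinements;
  heavily bridged polycycles may raise rather than decompose.
* The SEA SD model is linear in n₁·n₂, adequate on these libraries but not
  guaranteed for very heterogeneous ones.
* Naive Bayes probabilities are used as-is (calibrated by construction on
  balanced sets); no extra calibration layer.
* The readout-type enum implements the ten types listed above and is the
  single place to extend when further types are needed.
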