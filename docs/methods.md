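# Methods

This note documents the models and procedures implemented in `combosyn`,
the parameters that matter, the synthetic study conditions, and the
design decisions taken where more than one reasonable choice existed.

## Problem setting

The unit of analysis is a *(drug pair, cell line)* instance with a
continuous Loewe-additivity synergy score (typical screen range −60 to
60; positive means supra-additive). Scores are binarized at a threshold
of **10** — inclusive, so score ≥ 10 ⇒ synergistic (class 1), otherwise
antagonistic (class 0). The classifier sees only the two drugs'
structures: cell line and tissue are carried as metadata for grouping
and evaluation, never as model inputs. A consequence worth stating
plainly is that the same pair measured on two cell lines produces
identical feature vectors, possibly with different labels; the model
therefore learns the *propensity* of a chemical pair to synergize across
contexts, not a context-specific prediction.

Replicate rows sharing a (pair, cell line) key are either rejected or,
with `aggregate="mean"`, averaged before binarization — both behaviours
are explicit because screens differ in whether they ship replicate-level
or aggregated scores.

## Pharmacophore typing and graph signatures

Atoms are typed by an ordered SMARTS rule table
(`combosyn/data/pharmacophores.tsv`) over eight classes: Donor,
Acceptor, Hydrophobe, Aromatic, PositiveIonizable, NegativeIonizable,
Sulfur, and Neutral as the guaranteed fallback. Typing is multi-label
across classes (a hydroxyl oxygen is both Donor and Acceptor; an
aromatic carbon both Aromatic and Hydrophobe); within a class the first
matching pattern (lowest priority number) grants the label. An atom is
labelled when it is the *first* atom of a match, which lets multi-atom
patterns (e.g. the acidic oxygen of a carboxyl) designate a specific
atom. The table is deliberately compact and auditable rather than
exhaustive — charged nitrogens are excluded from Donor so that, e.g.,
ammonium types as PositiveIonizable only — and it is user-replaceable;
the class vocabulary is derived from whatever table is loaded.

Distances are topological: shortest path in covalent bonds
(breadth-first search via `scipy.sparse.csgraph`), hydrogens implicit,
heavy atoms only, no conformers. Disconnected fragments (salts, mixtures)
are allowed; cross-fragment distances are infinite and never counted.

The signature entry for class pair (P, Q) at cutoff c counts unordered
atom pairs {i, j} with the classes on either side and d(i, j) ≤ c. An
atom pair contributes at most once per class pair regardless of how many
label combinations match, which keeps same-class entries un-doubled.
Counts are cumulative in c by construction. The default cutoff schedule
is **1–6 bonds in steps of 1**; with 8 classes this gives 36 class pairs
× 6 cutoffs = 216 signature features per drug. The schedule is
config-exposed (`FeatureConfig(cutoffs=...)`) since different feature
dimensions in the literature trace to different schedules, and published
dimension arithmetic is not always self-consistent; this implementation
documents its own: per-drug length = 36 × |cutoffs| + |manifest|, pair
length exactly twice that (482 under the defaults).

## Descriptors and pair assembly

The descriptor block is a versioned manifest
(`combosyn/data/descriptors.tsv`, 25 names by default) resolving to
RDKit descriptor functions plus registered SMARTS counts (pyrimidine
rings, which RDKit's fragment set lacks). Unknown names and non-finite
values raise — there is no silent zero. The manifest spans size and
shape (heavy atoms, κ₂, χ0n/χ1n/χ4v), lipophilicity (MolLogP,
SlogP_VSA bins), electrostatics and polarity (PEOE_VSA bins, TPSA,
H-bond donor/acceptor counts), refractivity (SMR_VSA bins) and
functional groups (ester, aniline, piperazine, pyridine, pyrimidine,
methoxy).

Pair vectors concatenate the two per-drug blocks with `_drug_A` /
`_drug_B` name suffixes. Default policy is **canonical**: drugs are
sorted by canonical SMILES before concatenation, making the
representation order-invariant with no training-set inflation. The
**symmetric-augment** alternative emits both orderings at training time
and averages the two orderings at prediction time; it exists for parity
with augmentation-style training but is not the default. A SHA-256 hash
of the full feature configuration is embedded in every trained model,
and prediction refuses matrices produced under a different
configuration.

## Redundancy-aware splitting

Drugs are clustered by the Butina sphere-exclusion procedure on
Morgan-fingerprint (radius 2, 2048 bits) Tanimoto similarity at a **0.6**
threshold. The procedure is pinned exactly: neighbour lists at
similarity ≥ threshold; repeatedly seed a cluster at the unassigned item
with the most unassigned neighbours, ties to the lowest input index;
absorb its unassigned neighbours; leftovers are singletons. It is
implemented natively because the tie-break is part of the contract, and
is verified against an exhaustive independent re-trace in the tests.

An instance's group key is the unordered pair of its drugs' cluster ids.
The non-redundant split shuffles groups by seed and greedily assigns
whole groups to the test side until the target share (default 20 %) is
first reached; a single group larger than the whole test budget is
forced to train with a warning. Every split carries a leakage report
proving no group key straddles it. Granularity means the achieved test
fraction can overshoot the target by up to one group.

Cross-validation schemes: stratified k-fold (the only scheme using
labels), leave-one-drug-pair-out, leave-one-drug-out and
leave-one-tissue-out. All but leave-one-drug-out are partitions of the
dataset; leave-one-drug-out folds overlap by construction (each instance
contains two drugs) and its fold-mean metrics should be read
accordingly. Folds whose test side is single-class get NaN AUROC,
excluded from fold means with an explicit count rather than imputed.
Both pooled out-of-fold metrics and fold means are reported, since the
literature is often silent about which convention it uses.

## Learning and selection

Families: random forest, extremely randomized trees (the default, 300
trees), gradient boosting, k-NN, XGBoost, and an additive logistic
glass-box (standardized logistic regression) that provides exact
per-feature contributions. An Explainable Boosting Machine family is
exposed behind the same `ModelSpec` contract and activates when the
optional `interpret` backend is installed; its internals are
deliberately not re-implemented here.

Grid search is exhaustive over documented default grids (e.g. trees:
n_estimators {100, 300, 600} × max_depth {None, 8, 16}), scored by mean
stratified 5-fold CV MCC; ties break to the lowest-complexity point
(fewest estimators, then smallest numeric settings, then lexicographic).
The default grids make no claim of matching any published tuned values
and are fully overridable.

Greedy forward selection starts from the empty set; each round scores
every unselected feature by mean **10-fold** CV MCC of the learner on
the selected set plus that feature and appends the best (ties to the
lowest column index). It stops at the feature budget or at the first
round with no MCC improvement. MCC is used throughout selection and
tuning because it is robust to class imbalance.

A caveat established during development and worth knowing when using
greedy selection on real descriptor pools: molecular descriptors are
strongly collinear (connectivity and size indices track ring content
almost perfectly over small libraries), so when a planted or true signal
has near-perfect substitutes in the pool, greedy may select a substitute
— higher CV MCC, different name. That is correct behaviour of the
procedure, not a defect; recovery of *named* features is only a
well-posed expectation when the remaining candidates are uninformative.
The recovery test in the acceptance suite is constructed accordingly
(rule-input features plus seeded noise candidates), while behaviour on
the full collinear pool is assessed by held-out discrimination (AUROC)
and the KS feature screen, where the planted motif counts do rank top.

## Interpretability

Three attribution routes share one report format:

* **Permutation importance** (always available): mean MCC drop over
  seeded column shuffles.
* **Glass-box contributions**: for additive models, the exact mean
  |weight × standardized value| per feature; for an EBM backend, its
  term importances.
* **Risk profiles**: per-feature contribution curves on a grid spanning
  the observed range (exact centered weight-line for additive models,
  centered partial dependence otherwise), with the observed-value
  histogram attached. Positive values push toward the synergistic
  class. A feature the fitted model never saw yields a flat zero
  profile.

The two-sample Kolmogorov–Smirnov screen compares each feature's
distribution between classes at pair level; per-drug features are
aggregated by *summing* the two drugs' values, the symmetric,
order-invariant choice. D statistics are ranked descending and p-values
Benjamini–Hochberg adjusted (no correction convention is standard in
this niche; BH is reported explicitly).

## Synthetic study conditions

The generator emulates the shape of a large pairwise oncology screen.
Defaults, chosen once as the study conditions: **36 molecules** (the
scale of a real combination screen's drug panel), **6 tissues × 5 cell
lines**, **2,000** pair×cell-line instances, planted rule *pair methoxy
count ≥ 1 AND pair ring count ≥ 2* (echoing motifs reported enriched
among synergistic combinations), label-flip noise **ε = 0.05**, and
scores drawn uniformly on [10, 60] for observed-synergistic and
[−60, 10) for observed-antagonistic instances, so binarization
round-trips the observed labels exactly.

Molecules are assembled by concatenating self-contained SMILES fragments
(each with balanced ring closures), which always yields a parseable
string; every candidate is re-parsed, canonicalized and deduplicated.
The methoxy motif enters only through a dedicated tail fragment whose
inclusion is decided *before* body resampling, so its frequency is
exactly Binomial(n, p_methoxy = 0.4) and unbiased by uniqueness
rejections; ring fragments are drawn 0–2 per molecule with weights
(0.3, 0.5, 0.2). These rates put the planted rule's prevalence near
0.4, giving a roughly balanced classification problem. Generation is a
pure function of the config (byte-identical CSV at a fixed seed), and a
truth sidecar (true labels and motif totals) supports recovery tests.

What the generator does *not* emulate — and hence what passing tests do
not establish about real screens: dose–response structure and
replicate noise; any cell-line- or tissue-dependence of synergy (the
planted rule is context-free); realistic pharmacology or chemistry
beyond fragment plausibility; and real screens' much weaker, highly
redundant structure–synergy signal. Performance numbers on synthetic
data characterize the pipeline's correctness, not expected real-world
accuracy.

## Numerical and degenerate-input choices

* MCC is defined 0 when a confusion-matrix denominator factor vanishes;
  AUROC uses the rank statistic with ties counted ½ and is NaN (never
  imputed) for single-class fold test sets.
* Probability threshold for classification is 0.5 unless configured.
* Constant features get KS D = 0 and permutation importance 0 rather
  than errors.
* All randomness (generation, shuffling, fold assignment, tree seeds,
  permutation repeats) flows from explicit integer seeds recorded in
  outputs and manifests.
* Problem sizes in the test and acceptance suites — e.g. 50 molecules ×
  3 schedules for the signature oracle, 100 seeded datasets for the
  leakage audit, 20 replicates at n = 2,000 for rule recovery — were
  chosen as the smallest sizes at which the checked property is
  statistically meaningful.

## Known limitations

* Structure-only features cannot express context-specific synergy; on
  datasets where the same pair flips label across cell lines the
  achievable accuracy is bounded below 1 by construction.
* The pharmacophore table is compact; users with stricter medicinal-
  chemistry conventions (e.g. amide nitrogens, tautomer-aware acidity)
  should supply their own table — the pipeline treats it as data.
* No 3-D information: conformer-dependent pharmacophore geometry,
  stereochemistry-aware distances and tautomer enumeration are out of
  scope.
* Probabilities are uncalibrated scores from the underlying ensembles.
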