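# Methods

This note documents the models and procedures implemented in `chargeshell`,
the choices made where the design was genuinely open, and what the
synthetic test conditions do and do not demonstrate.

## Problem setting

Nucleophilicity and electrophilicity of individual atoms govern which site
of a molecule reacts. Methyl cation affinity (MCA) and methyl anion
affinity (MAA) — the negative reaction energies of bonding CH₃⁺ to a
nucleophilic atom or CH₃⁻ to an electrophilic atom, in kJ/mol — are
computable proxies for these properties: the larger the MCA the more
nucleophilic the site, the larger the MAA the more electrophilic. The
package predicts these affinities per atomic site from a charge-based
descriptor, with calibrated uncertainty estimates that say when a
prediction should be recomputed with the reference quantum-chemistry
workflow instead.

## Molecule preparation

SMILES inputs are canonicalised (so atom indexing is independent of input
spelling) and hydrogens are made explicit. Training-data admission follows
the neutral drug-like envelope: total charge 0, no radical electrons,
10–30 heavy atoms, ≤ 24 rotatable bonds. Rotatable bonds use the strict
convention (acyclic single bonds between non-terminal heavy atoms,
amide C–N excluded); the source protocol does not pin a definition, so the
common cheminformatics one is used.

Conformers are embedded with ETKDG: `min(1 + 3·n_rot, 20)` in descriptor
mode, a flat 20 in the mode that mirrors the reference-label protocol.
Embedding is deterministic per seed, with up to three retries at
incremented seeds. All conformers are optimised with MMFF94s (engine
defaults, ≤ 200 iterations) and the lowest-energy conformer is selected,
ties broken by lowest index.

**Charge backends.** The reference charge model is CM5 extracted from a
GFN1-xTB single point on the selected conformer; this path requires the
`xtb` Python bindings and raises a clear error without them. The default
backend is geometry-free empirical Gasteiger charges from RDKit. The
descriptor machinery, tests and synthetic data all run on the Gasteiger
backend; CM5 charges shift descriptor *values* but not descriptor
*mechanics* (layout, ordering, invariances), which is what the test suite
verifies. Elements outside the Gasteiger parameter table (e.g. boron)
yield non-finite charges that are zeroed with a warning.

## Site detection

Each role carries an ordered SMARTS table; the first pattern to claim an
atom assigns its group label, so labels resolve from most specific
(named functional groups) through charge classes to the generic
multiple-bond and lone-pair classes, and each `(atom, role)` pair appears
at most once. The pattern strings are this package's own; they are
validated against a hand-written exemplar panel with at least one molecule
per named class, where a small "locator" SMARTS identifies the expected
atom independently of atom numbering. Site anchors are chemical: carbonyl
oxygen for the oxygen-donor classes, enolate α-carbon, Michael-acceptor
β-carbon, the carbon bonded to an oxonium oxygen. Carbamate carbonyls are
detected as their own electrophile class (needed by the stability
application). Aromatic atoms count as double/triple-bonded atoms, so
(hetero)aromatic carbons appear as sites of both roles.

## Descriptor

The feature vector concatenates partial charges over shells up to three
bonds from the query atom, with layout `1 + 4 + 12 + 36 = 53`: four child
slots at shell 1 and three per parent deeper down (the fourth valence
points back up the tree) — the only arity consistent with the fixed
length. Absent positions pad with exactly 0.0. Hydrogens are included as
shell members: their charges exist on the explicit-H graph, and padding
alone could not distinguish CH₃ from CCl₃ otherwise.

Children are ordered by modified CIP priority:

1. atomic number, descending;
2. ties: each tied candidate's subtree is expanded one bond at a time
   (bond orders disregarded, atoms already included are skipped) and the
   summed atomic numbers of successive frontiers are compared
   lexicographically; a subtree that exhausts contributes 0 at later
   depths, so deeper substitution wins at equal sums;
3. remaining ties: partial charge, descending, stable with respect to
   canonical input order (symmetric subtrees give identical features, so
   residual order cannot affect the descriptor).

Ring closures use visited-set semantics: an atom placed in an inner shell
is never re-placed downstream; its slot pads. Hypervalent atoms (more
neighbours than slots) keep their top-priority children and log a warning.
Shell membership is tested against an independent breadth-first-layers
oracle, and the full vector against random atom renumberings at 1e-12.

## Dataset assembly

Outliers are removed by Chauvenet's criterion, read as a plain tail
threshold: iteratively, the two-sided Gaussian tail probability
`2·(1 − Φ(|x−μ|/σ))` of the most extreme remaining value is compared to 1%;
values below are removed until the most extreme passes. The classical
sample-size-scaled variant (`n·p < 0.5`) is available behind a flag. On
clean Gaussian data the plain 1% rule trims a small percentage of genuine
tail values — by construction — and is idempotent on the kept set.

The train/test split bins targets into 10 equal-width bins (bin count and
boundary rule are this package's defaults; equal-count bins are available)
and assigns `round(0.85·n_bin)` records per bin to train (ties toward
train), preserving the target distribution across partitions
(Kolmogorov–Smirnov distance < 0.03 at n = 10,000). Cross-validation folds
deal the shuffled training records of each bin round-robin into k = 5
folds, so per-bin fold composition deviates by at most one record. All
shuffles are seeded.

## Models

**Point predictor.** One LightGBM regressor per property, trained per
cross-validation fold on 4/5 of the training set; the fold model with the
lowest validation RMSE (√(Σε²/N)) is retained for prediction. Boosters run
single-threaded and deterministic for a fixed seed.

**Hyperparameter search.** A seeded TPE-style sampler written in this
package: uniform warm-up over the declared space (learning rate, leaves,
depth, min-child samples, subsampling, L1/L2 regularisation; log scales
where spans are multiplicative), then candidates drawn from a Parzen
density over the best 25% of trials and scored by the good/bad density
ratio, objective = mean 5-fold CV RMSE. Default budget 100 trials;
budget 0 returns the declared defaults.

**Uncertainty.** The recommended estimator is the standard deviation
(population, ddof = 0) over the 200 per-tree predictions of a random
forest fitted to the same features and targets; forest settings beyond the
tree count are library defaults. Alternatives: the spread of the five CV
fold models, and the mean Manhattan/Euclidean distance to the k ∈ {1, 10}
nearest training points.

## Calibration and flagging

Predictions are sorted by σ and cut into 10 equal-count bins (count sorted
by uncertainty is the natural reading; the bin count is a package
default). Per bin, RMSE = √(Σε²/N) and RMV = √(Σσ²/N); unweighted OLS of
RMSE on RMV gives the calibration line (slope 1, intercept 0 for
well-calibrated uncertainties). Estimated error = max(0, slope·σ +
intercept); the floor removes unphysical negative extrapolations. A
degenerate abscissa (all bins equal RMV) raises rather than fits.

Flagging is strictly greater-than the per-property cutoff: 25 kJ/mol (MCA)
and 30 kJ/mol (MAA) by default, with tighter presets 20/25 and 15/20.
Boundary values pass.

## Applications

**Selectivity ranking.** All sites of the requested role across the given
reactants are predicted and ranked by affinity, descending; ties break
toward lower estimated error, then input order. A proposed reactive atom
"agrees" when it is the top-ranked site; the margin between the top two
sites is reported, and estimated errors annotate every entry rather than
dropping flagged sites. The margin threshold for calling a step risky
defaults to 0 (any outranking disagrees).

**Hydrolysis stability.** Candidate atoms are the ester and carbamate
carbonyl carbons; the score is the maximum MAA over candidates (higher =
more electrophilic = less stable), molecules without candidates get an
explicit status. Molecules are scored in the protonation state given in
the input SMILES; speciation/pKa handling is out of scope.

## Synthetic study conditions

Real labels are QM-computed affinity tables far beyond desk scale, so the
test suite and acceptance script run on generators with known structure:

* descriptors are *real* charge-shell vectors of the 40-molecule fixture
  panel (every named functional-group class plus degenerate topologies),
  resampled with small Gaussian jitter (std 0.02 e) on non-pad entries;
* targets are linear in those descriptors (query-charge weight 500,
  first-shell weights 80/60/40/20, intercept 100), spanning a few hundred
  kJ/mol like real affinity tables, plus optional Gaussian noise;
* uncertainty samples draw σ ~ U(0.5, 3) and ε ~ N(0, (m·σ)²) with a
  controllable miscalibration factor m.

Problem sizes used: n = 10,000 for split and calibration checks,
n = 20,000 for model recovery — large enough for the statistical
tolerances (slope 1 ± 0.05, train fraction ± 1 record per bin, RMSE at
the noise floor) while keeping the whole suite in minutes on one core.

What passing shows: the descriptor contract and its invariances, the
split/fold accounting, that the boosted model recovers a recoverable
signal to the noise floor, and that the calibration machinery measures
miscalibration correctly. What it does not show: accuracy on real
QM-labelled chemistry. The published-scale figures — held-out Pearson
0.97 (MCA) / 0.95 (MAA), RMSE ≈ 17.5 / 22.1 kJ/mol, the worked selectivity
affinities, and the hydrolysis correlations against experimental
half-lives — require the full QM dataset, the production models trained on
it, and external measurements; they are integration expectations, not
tests here.

## Known limitations

* Gasteiger charges are a coarser electronic description than CM5; trained
  models are backend-specific and the two must not be mixed at inference.
* The SMARTS tables are this package's interpretation of the named
  functional-group classes; border cases (amide N vs amine, enol ethers)
  follow the first-match specificity order documented above.
* Ring-closure padding means highly fused polycyclics fill fewer than 53
  informative positions from some query atoms.
* The TPE sampler is intentionally compact (per-dimension Parzen
  densities, no prior weighting or multivariate coupling); for very large
  budgets a dedicated optimisation library would explore more efficiently.
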