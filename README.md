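# chargeshell

Atom-based machine learning for estimating **nucleophilicity** and
**electrophilicity** of atomic sites in organic molecules, via predicted
**methyl cation affinities** (MCA) and **methyl anion affinities** (MAA).

Quantum-chemistry workflows can compute MCA/MAA values — the negative
reaction energies of adding CH₃⁺ to a nucleophilic site or CH₃⁻ to an
electrophilic site — but take minutes per molecule. `chargeshell`
implements the fast surrogate route: a gradient-boosted model predicts the
affinity of a site directly from a 53-dimensional descriptor of sorted
atomic partial charges, in well under a second per molecule. Higher MCA
means a more nucleophilic site; higher MAA a more electrophilic one. Two
application layers sit on top: ranking reactive sites to post-filter
retrosynthetic routes for selectivity problems, and scoring the hydrolytic
stability of esters and carbamates by their maximum MAA.

## Method in brief

For each molecule (SMILES input):

1. **Preparation** — canonicalise, add explicit hydrogens, embed
   `min(1 + 3·n_rot, 20)` conformers, optimise with MMFF94s, keep the
   lowest-energy conformer, and compute per-atom partial charges. The
   reference charge model is CM5 from a GFN1-xTB single point; a
   geometry-free empirical (Gasteiger) backend is built in so the whole
   package runs without a semiempirical engine.
2. **Site detection** — SMARTS pattern tables mark nucleophilic sites
   (lone-pair donors, anions, π systems, amines, enolates, nitronates, …)
   and electrophilic sites (carbonyl carbons, Michael-acceptor β-carbons,
   cations, boranes, …), one site per atom with its most specific group
   label.
3. **Descriptor** — charges of the query atom and of its neighbours up to
   three bonds away are concatenated into a fixed
   `[query:1 | shell1:4 | shell2:12 | shell3:36]` = 53-value vector.
   Children are ordered by modified Cahn–Ingold–Prelog priority: atomic
   number, then summed atomic numbers over expanding subtree frontiers
   (bond orders ignored), then partial charge. Absent positions pad with
   0.0, so the vector is numbering-invariant and fixed-length.
4. **Models** — per property (MCA/MAA), a LightGBM regressor trained with
   stratified 5-fold cross-validation on an 85/15 binned split; the fold
   model with the lowest validation RMSE is retained. A 200-tree random
   forest provides an uncertainty σ as the standard deviation over the
   per-tree predictions (alternatives: CV-ensemble spread, kNN distance).
5. **Calibration & flagging** — predictions and uncertainties are sorted
   by σ into equal-count bins; an OLS fit of per-bin RMSE against RMV
   (ideal: slope 1, intercept 0) converts σ into an estimated error.
   Estimated errors above 25 kJ/mol (MCA) or 30 kJ/mol (MAA) flag sites
   where the reference QM workflow is recommended (tighter presets: 20/25
   and 15/20 kJ/mol).

## Worked example

Detect and featurize the electrophilic sites of methyl acrylate:

```python
from chargeshell import (parse_molecule, compute_charges,
                         find_electrophilic_sites, featurize)

mol = parse_molecule("C=CC(=O)OC")          # methyl acrylate
compute_charges(mol)                        # Gasteiger fallback backend
for site in find_electrophilic_sites(mol):
    print(f"atom {site.atom_index:2d}  {site.group_label}")

site = find_electrophilic_sites(mol)[0]
vec = featurize(site, mol)
print("descriptor length:", len(vec))
print("first five values:", [round(float(v), 4) for v in vec.values[:5]])
```

```
atom  0  Michael acceptors
atom  1  double/triple-bonded atoms
atom  2  esters
atom  3  double/triple-bonded atoms
descriptor length: 53
first five values: [-0.0918, 0.016, 0.054, 0.054, 0.0]
```

The β-carbon (atom 0) is claimed by the Michael-acceptor pattern and the
ester carbonyl carbon (atom 2) by the ester pattern; the descriptor starts
with the query atom's charge followed by its first-shell neighbours (one
pad already visible at position 4).

Train and calibrate on a synthetic labelled table (linear ground truth
built from real panel descriptors; targets in kJ/mol):

```python
from chargeshell import (binned_split, stratified_folds, train_regressor,
                         train_uncertainty, error_calibration, estimate_error)
from chargeshell.fixtures import make_labeled_table

tab = make_labeled_table(10_000, noise_std=12.0, seed=5)
a = binned_split(tab.y, n_bins=10, seed=5)
folds = stratified_folds(a, k=5, seed=5)
tr, te = a.train_mask, a.test_mask

reg = train_regressor(tab.X[tr], tab.y[tr], folds[tr], seed=5)
unc = train_uncertainty(tab.X[tr], tab.y[tr], method="forest_std", seed=5)
print("cv rmse (kJ/mol):", [round(r, 2) for r in reg.cv_rmse_],
      "-> retained fold", reg.best_fold_)

sigma = unc.predict_std(tab.X[te])
eps = reg.predict(tab.X[te]) - tab.y[te]
fit = error_calibration(sigma, eps, n_bins=10)
print(f"calibration: slope {fit.slope:.3f}, intercept {fit.intercept:.2f}, "
      f"r2 {fit.r2:.3f}")
print("estimated error at sigma=12:",
      round(float(estimate_error(12.0, fit)), 2), "kJ/mol")
```

```
cv rmse (kJ/mol): [13.31, 12.97, 13.07, 13.07, 13.2] -> retained fold 1
calibration: slope 0.302, intercept 9.62, r2 0.410
estimated error at sigma=12: 13.24 kJ/mol
```

The cross-validation RMSE sits just above the injected noise level
(12 kJ/mol), as it should. On this easy synthetic task the forest spread is
under-dispersed relative to the true errors — which is exactly what the
calibration line corrects when σ is converted into an estimated error.

A command-line interface mirrors the library
(`chargeshell sites|featurize|train|predict|calibrate|flag|rank-sites|check-route|stability|fixtures`);
run `chargeshell --help` for details.

## Scope notes

Out of scope by design: the quantum-chemistry affinity workflow itself
(the DFT/semiempirical reaction energies the reference labels come from),
reaction-rate prediction from affinities, retrosynthetic route
*generation*, and pKa/protonation-state handling — molecules are scored in
the protonation state given in the input SMILES. Reproducing the
published-scale held-out metrics requires the full QM-labelled dataset
(~650k MCA / ~534k MAA sites) and is documented in `docs/methods.md` as an
integration-level expectation, not a test.
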