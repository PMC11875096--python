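import numpy as np
import pytest

from chargeshell.dataset import binned_split, stratified_folds
from chargeshell.fixtures import make_labeled_table, make_molecule_panel
from chargeshell.models import train_regressor
from chargeshell.molprep import compute_charges, parse_molecule


@pytest.fixture(scope="session")
def panel():
    return make_molecule_panel()


@pytest.fixture(scope="session")
def prepared_panel(panel):
    """Parsed + fallback-charged molecules for every panel SMILES."""
    out = {}
    for smi, _ in panel:
        mol = parse_molecule(smi)
        compute_charges(mol)
        out[smi] = mol
    return out


@pytest.fixture(scope="session")
def noiseless_table():
    return make_labeled_table(4000, seed=7)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_table):
    """A regressor trained on a binned split of the noiseless table,
    shared by the recovery and prediction tests."""
    tab = noiseless_table
    assignment = binned_split(tab.y, n_bins=10, seed=7)
    fold_id = stratified_folds(assignment, k=5, seed=7)
    tr = assignment.train_mask
    reg = train_regressor(tab.X[tr], tab.y[tr], fold_id[tr], seed=7)
    return tab, assignment, reg


def rng(seed=0):
    return np.random.default_rng(seed)
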