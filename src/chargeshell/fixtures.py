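"""Synthetic-data generators used by the test suite and the examples.

Real training data for these models are quantum-chemistry-labelled affinity
tables (~10^5 atomic sites), which cannot be produced at desk scale. The
generators here stand in for them with known structure:

* a hand-curated molecule panel spanning every named functional-group
  class plus degenerate topologies (methane, neopentane, cyclopropane,
  hypervalent sulfur);
* labelled tables whose targets are a linear combination of the real
  charge-shell descriptors of panel sites (plus Gaussian noise), so ground
  truth is recoverable and model-recovery tests have an exact reference;
* uncertainty/error samples with a controllable miscalibration factor for
  the error-based calibration tests.

Every generator is pure given its seed. The whole suite runs on the
Gasteiger charge backend, so no external engine is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptor import N_FEATURES, ChargeShellFeaturizer
from .molprep import parse_molecule
from .sites import (
    ELECTROPHILE,
    NUCLEOPHILE,
    exemplar_panel,
    find_sites,
)

__all__ = [
    "SyntheticTable",
    "make_molecule_panel",
    "panel_smiles",
    "make_labeled_table",
    "make_uq_sample",
    "default_coefficients",
]

#: degenerate / stress-test molecules appended to the exemplar molecules
_EXTRA_MOLECULES: list[tuple[str, dict]] = [
    ("C", {}),  # methane: all-padding descriptor
    ("CC(C)(C)C", {}),  # neopentane: rule-3 symmetric ties
    ("C1CC1", {}),  # cyclopropane: ring-closure handling
    ("FS(F)(F)(F)(F)F", {}),  # hypervalent sulfur: >4 neighbours
    ("CC(=O)Oc1ccccc1C(=O)O", {"electrophile": {"esters"}}),  # aspirin
    ("Cn1cnc2c1c(=O)n(C)c(=O)n2C", {"nucleophile": {"double/triple-bonded atoms"}}),
    ("O=Cc1ccccc1", {"electrophile": {"aldehydes"}}),  # benzaldehyde
    ("C=CC(=O)OC", {"electrophile": {"Michael acceptors", "esters"}}),
    ("Nc1ccccc1", {"nucleophile": {"amines"}}),  # aniline
    ("Oc1ccccc1", {"nucleophile": {"lone pairs"}}),  # phenol
    ("c1ccncc1", {"nucleophile": {"double/triple-bonded atoms"}}),  # pyridine
    ("CCOC(=O)c1ccccc1", {"electrophile": {"esters"}}),
    ("CN(C)C(=O)Oc1ccccc1", {"electrophile": {"carbamates"}}),
    ("NCCNc1cccc2ccccc12", {"nucleophile": {"amines"}}),
]


def make_molecule_panel() -> list[tuple[str, dict]]:
    """The fixture molecule panel: ``(smiles, expected)`` pairs.

    ``expected`` maps a role to the set of group labels that detection must
    produce on that molecule (empty dict: no expectation, topology-only
    fixture). Contains every exemplar of both roles plus degenerate cases;
    always >= 30 molecules.
    """
    panel: list[tuple[str, dict]] = []
    seen = set()
    for role in (NUCLEOPHILE, ELECTROPHILE):
        for ex in exemplar_panel(role):
            if ex.smiles in seen:
                for i, (smi, exp) in enumerate(panel):
                    if smi == ex.smiles:
                        exp.setdefault(role, set()).add(ex.group_label)
                continue
            seen.add(ex.smiles)
            panel.append((ex.smiles, {role: {ex.group_label}}))
    for smi, exp in _EXTRA_MOLECULES:
        if smi not in seen:
            seen.add(smi)
            panel.append((smi, {k: set(v) for k, v in exp.items()}))
    return panel


def panel_smiles() -> list[str]:
    return [smi for smi, _ in make_molecule_panel()]


@dataclass
class SyntheticTable:
    """A labelled descriptor table with a fully specified generator."""

    X: np.ndarray  # (n, 53)
    y: np.ndarray  # kJ/mol
    coeffs: np.ndarray
    intercept: float
    noise_std: float
    jitter_std: float
    seed: int
    property_tag: str = "MCA"
    site_smiles: list = field(default_factory=list)


def default_coefficients() -> np.ndarray:
    """Default linear map from descriptors to kJ/mol-scale targets.

    The query-atom charge dominates (weight 500), first-shell charges
    contribute with decaying weights, deeper shells are inert. With
    Gasteiger charges in roughly [-0.5, 0.5] this spans a few hundred
    kJ/mol, mimicking the magnitude of real affinity tables.
    """
    coeffs = np.zeros(N_FEATURES)
    coeffs[0] = 500.0
    coeffs[1:5] = [80.0, 60.0, 40.0, 20.0]
    return coeffs


def _base_descriptors(property_tag: str) -> tuple[np.ndarray, list]:
    role = NUCLEOPHILE if property_tag == "MCA" else ELECTROPHILE
    feat = ChargeShellFeaturizer().fit()
    sites = []
    for smi in panel_smiles():
        mol = parse_molecule(smi)
        sites.extend(find_sites(mol, role))
    X = feat.transform(sites)
    return X, [s.smiles for s in sites]


def make_labeled_table(
    n: int,
    coeffs=None,
    noise_std: float = 0.0,
    seed: int = 0,
    property_tag: str = "MCA",
    intercept: float = 100.0,
    jitter_std: float = 0.02,
) -> SyntheticTable:
    """Generate ``n`` labelled descriptor rows with linear ground truth.

    Rows are drawn (with replacement) from the real charge-shell
    descriptors of the panel's sites; non-pad entries are jittered with
    Gaussian noise of std ``jitter_std`` so rows are distinct. Targets are
    ``X @ coeffs + intercept + N(0, noise_std^2)`` — exactly linear in the
    jittered descriptors, so ``noise_std=0`` gives a noiseless recoverable
    target.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    coeffs = np.asarray(
        default_coefficients() if coeffs is None else coeffs, dtype=float
    )
    if coeffs.shape != (N_FEATURES,):
        raise ValueError(f"coeffs must have length {N_FEATURES}")
    base, base_smiles = _base_descriptors(property_tag)
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, base.shape[0], size=n)
    X = base[picks].copy()
    mask = X != 0.0  # keep pad positions exactly zero
    X[mask] += rng.normal(0.0, jitter_std, size=int(mask.sum()))
    y = X @ coeffs + intercept
    if noise_std > 0:
        y = y + rng.normal(0.0, noise_std, size=n)
    return SyntheticTable(
        X=X,
        y=y,
        coeffs=coeffs,
        intercept=float(intercept),
        noise_std=float(noise_std),
        jitter_std=float(jitter_std),
        seed=int(seed),
        property_tag=property_tag,
        site_smiles=[base_smiles[p] for p in picks],
    )


def make_uq_sample(
    n: int,
    sigma_range: tuple[float, float] = (0.5, 3.0),
    miscalibration: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated (sigma, epsilon) pairs for calibration tests.

    ``sigma ~ U(low, high)`` and ``epsilon ~ N(0, (miscalibration *
    sigma)^2)``; a miscalibration factor of 1 is a well-calibrated sample
    (expected calibration slope 1, intercept 0), factor m shifts the
    expected slope to m.
    """
    low, high = sigma_range
    if low <= 0:
        raise ValueError("sigma_range low bound must be positive")
    rng = np.random.default_rng(seed)
    sigma = rng.uniform(low, high, size=n)
    epsilon = rng.normal(0.0, 1.0, size=n) * miscalibration * sigma
    return sigma, epsilon
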