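"""Application layers: retrosynthesis selectivity ranking and hydrolysis
stability scoring.

Both applications run the same machinery: detect sites of a role, featurize
them, predict the corresponding affinity (MCA for nucleophiles, MAA for
electrophiles), attach calibrated error estimates and cutoff flags, then
reduce — ranking for selectivity, max over ester/carbamate carbonyls for
stability. Molecules are used in the protonation state given by the input
SMILES; no speciation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    CUTOFF_PROFILES,
    CalibrationFit,
    PredictionResult,
    estimate_error,
    flag_predictions,
)
from .descriptor import ChargeShellFeaturizer
from .molprep import parse_molecule
from .sites import ELECTROPHILE, NUCLEOPHILE, AtomicSite, find_sites

logger = logging.getLogger(__name__)

__all__ = [
    "ModelBundle",
    "SelectivityReport",
    "StabilityResult",
    "ROLE_PROPERTY",
    "rank_sites",
    "check_step",
    "stability_score",
]

#: which affinity each role's reactivity is scored by
ROLE_PROPERTY = {NUCLEOPHILE: "MCA", ELECTROPHILE: "MAA"}

#: electrophile group labels that count as hydrolysable carbonyls
HYDROLYSABLE_GROUPS = frozenset({"esters", "carbamates"})


@dataclass
class ModelBundle:
    """Trained models for one or both properties plus shared featurizer.

    ``regressors``/``uncertainties`` map property tags ("MCA"/"MAA") to
    objects with ``predict(X)`` / ``predict_std(X)``; ``calibrations`` maps
    them to :class:`CalibrationFit`. Any mock obeying those protocols works,
    which is how the unit tests exercise the applications without training.
    """

    regressors: dict
    uncertainties: dict
    calibrations: dict[str, CalibrationFit]
    featurizer: ChargeShellFeaturizer = field(default_factory=ChargeShellFeaturizer)
    cutoff_profile: str = "default"

    def predict_sites(self, sites: list[AtomicSite], property_tag: str
                      ) -> list[PredictionResult]:
        if property_tag not in self.regressors:
            raise ValueError(f"bundle has no model for {property_tag!r}")
        X = self.featurizer.transform(sites)
        y = np.asarray(self.regressors[property_tag].predict(X), dtype=float)
        sigma = np.asarray(
            self.uncertainties[property_tag].predict_std(X), dtype=float
        )
        fit = self.calibrations.get(property_tag)
        results = []
        for site, yp, sg in zip(sites, y, sigma):
            est = estimate_error(float(sg), fit) if fit is not None else float("nan")
            results.append(
                PredictionResult(
                    site=site, property_tag=property_tag,
                    y_pred=float(yp), sigma=float(sg), estimated_error=est,
                )
            )
        if fit is not None:
            flag_predictions(results, profile=self.cutoff_profile)
        return results


@dataclass
class SelectivityReport:
    """Ranked site predictions across one or more reactants."""

    results: list  # PredictionResult, sorted descending by y_pred
    role: str
    top_site: PredictionResult | None = None
    margin: float = float("nan")  # kJ/mol between top two sites
    proposed_site: tuple | None = None  # (reactant_index, atom_index)
    agrees: bool | None = None
    status: str = "ok"


@dataclass
class StabilityResult:
    """Max-MAA hydrolysis-stability score for one molecule."""

    smiles: str
    group_results: list  # PredictionResult per ester/carbamate carbonyl
    score: float | None = None  # max MAA, kJ/mol; higher = less stable
    any_flagged: bool = False
    status: str = "ok"


def _sort_results(results: list[PredictionResult]) -> list[PredictionResult]:
    # descending affinity; ties -> lower estimated error, then input order
    keyed = list(enumerate(results))
    keyed.sort(
        key=lambda t: (
            -t[1].y_pred,
            t[1].estimated_error if np.isfinite(t[1].estimated_error) else 0.0,
            t[0],
        )
    )
    return [r for _, r in keyed]


def rank_sites(
    reactants: list[str], role: str, bundle: ModelBundle
) -> SelectivityReport:
    """Rank every site of ``role`` across all reactants by predicted
    affinity (descending). The margin is the affinity gap between the top
    two sites over the whole reactant set."""
    property_tag = ROLE_PROPERTY[role]
    all_sites: list[AtomicSite] = []
    reactant_of: dict[int, int] = {}
    for i, smi in enumerate(reactants):
        mol = parse_molecule(smi)
        for site in find_sites(mol, role):
            reactant_of[len(all_sites)] = i
            all_sites.append(site)
    if not all_sites:
        return SelectivityReport(results=[], role=role, status="no-sites-found")
    results = bundle.predict_sites(all_sites, property_tag)
    for pos, r in enumerate(results):
        r.extra["reactant_index"] = reactant_of[pos]
    results = _sort_results(results)
    margin = (
        results[0].y_pred - results[1].y_pred if len(results) > 1 else float("nan")
    )
    return SelectivityReport(
        results=results, role=role, top_site=results[0], margin=margin
    )


def check_step(
    reactants: list[str],
    proposed: dict[str, tuple[int, int]],
    bundle: ModelBundle,
) -> dict[str, SelectivityReport]:
    """Check one reaction step's proposed reactive atoms against the models.

    ``proposed`` maps role -> ``(reactant_index, atom_index)``. For each
    role the step agrees when the proposed site is the top-ranked site; a
    proposed atom that is not a detected site of that role yields status
    ``"site-not-detected"`` with ``agrees`` undefined (None).
    """
    reports = {}
    for role, (ri, atom) in proposed.items():
        report = rank_sites(reactants, role, bundle)
        report.proposed_site = (ri, atom)
        match = [
            r for r in report.results
            if r.extra.get("reactant_index") == ri and r.site.atom_index == atom
        ]
        if not match:
            report.status = "site-not-detected"
            report.agrees = None
        else:
            top = report.results[0]
            report.agrees = (
                top.extra.get("reactant_index") == ri
                and top.site.atom_index == atom
            )
        reports[role] = report
    return reports


def count_disagreements(step_reports: list[dict]) -> int:
    """Route-level score: number of role-checks that disagree across steps."""
    return sum(
        1
        for reports in step_reports
        for rep in reports.values()
        if rep.agrees is False
    )


def stability_score(
    molecules: list[str], bundle: ModelBundle
) -> list[StabilityResult]:
    """Score hydrolysis liability as the maximum MAA over ester/carbamate
    carbonyl carbons; higher scores mean more electrophilic, hence less
    hydrolytically stable. Molecules without such groups get an explicit
    status and no score."""
    out = []
    for smi in molecules:
        mol = parse_molecule(smi)
        candidates = [
            s
            for s in find_sites(mol, ELECTROPHILE)
            if s.group_label in HYDROLYSABLE_GROUPS
        ]
        if not candidates:
            out.append(
                StabilityResult(
                    smiles=mol.smiles, group_results=[],
                    status="no ester/carbamate group",
                )
            )
            continue
        results = bundle.predict_sites(candidates, "MAA")
        score = float(max(r.y_pred for r in results))
        out.append(
            StabilityResult(
                smiles=mol.smiles,
                group_results=results,
                score=score,
                any_flagged=any(r.flagged for r in results),
            )
        )
    return out
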