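"""Error-based calibration of prediction uncertainties.

Predicted uncertainties (sigma) and signed errors (epsilon = y_pred -
y_true) are sorted by sigma and cut into equal-count bins. Per bin,

    RMSE = sqrt( sum(epsilon^2) / N_bin )
    RMV  = sqrt( sum(sigma^2)   / N_bin )

and an ordinary least-squares fit of RMSE on RMV gives the calibration
line. Well-calibrated uncertainties yield slope 1 and intercept 0; the line
converts a sigma into an estimated error (floored at zero), and estimated
errors above a per-property cutoff flag predictions for which the reference
quantum-chemistry workflow is recommended instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "CalibrationFit",
    "PredictionResult",
    "CUTOFF_PROFILES",
    "error_calibration",
    "estimate_error",
    "flag_predictions",
    "ErrorCalibrator",
]

#: estimated-error cutoffs (kJ/mol) above which the reference workflow is
#: recommended; "default" admits ~10% of a typical test set, "tight" ~25%,
#: "strict" ~45%.
CUTOFF_PROFILES: dict[str, dict[str, float]] = {
    "default": {"MCA": 25.0, "MAA": 30.0},
    "tight": {"MCA": 20.0, "MAA": 25.0},
    "strict": {"MCA": 15.0, "MAA": 20.0},
}


@dataclass
class CalibrationFit:
    """Binned RMSE/RMV table and the linear sigma -> error map."""

    bins: list  # (N_bin, RMV, RMSE), ordered by increasing uncertainty
    slope: float
    intercept: float
    r2: float
    n_bins: int

    def to_dict(self) -> dict:
        return {
            "bins": [
                {"n": int(n), "rmv": float(rmv), "rmse": float(rmse)}
                for n, rmv, rmse in self.bins
            ],
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "n_bins": self.n_bins,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationFit":
        return cls(
            bins=[(b["n"], b["rmv"], b["rmse"]) for b in d["bins"]],
            slope=d["slope"],
            intercept=d["intercept"],
            r2=d["r2"],
            n_bins=d["n_bins"],
        )


@dataclass
class PredictionResult:
    """One site's predicted affinity with uncertainty and flag."""

    site: object
    property_tag: str
    y_pred: float
    sigma: float
    estimated_error: float = float("nan")
    flagged: bool = False
    cutoff_used: float = float("nan")
    extra: dict = field(default_factory=dict)


def _equal_count_bins(n: int, n_bins: int) -> list[np.ndarray]:
    """Split ``range(n)`` into ``n_bins`` contiguous chunks; the remainder
    is spread one record at a time over the first bins."""
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    edges = np.cumsum([0] + sizes)
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_bins)]


def error_calibration(sigma, epsilon, n_bins: int = 10) -> CalibrationFit:
    """Fit the error-based calibration line.

    Parameters
    ----------
    sigma : array-like
        Predicted uncertainties (kJ/mol).
    epsilon : array-like
        Signed errors ``y_pred - y_true`` (kJ/mol).
    n_bins : int
        Number of equal-count uncertainty bins (>= 2 for the regression).
    """
    sigma = np.asarray(sigma, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    if sigma.shape != epsilon.shape or sigma.ndim != 1:
        raise ValueError("sigma and epsilon must be 1D arrays of equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2 for the calibration regression")
    if sigma.size < n_bins:
        raise ValueError("need at least one record per bin")
    order = np.argsort(sigma, kind="stable")
    s, e = sigma[order], epsilon[order]
    bins = []
    for idx in _equal_count_bins(s.size, n_bins):
        rmv = float(np.sqrt(np.mean(s[idx] ** 2)))
        rmse = float(np.sqrt(np.mean(e[idx] ** 2)))
        bins.append((len(idx), rmv, rmse))
    rmvs = np.array([b[1] for b in bins])
    rmses = np.array([b[2] for b in bins])
    if np.allclose(rmvs, rmvs[0]):
        raise ValueError(
            "degenerate abscissa: all bins have the same RMV; "
            "cannot regress RMSE on RMV"
        )
    fit = stats.linregress(rmvs, rmses)
    return CalibrationFit(
        bins=bins,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n_bins=n_bins,
    )


def error_calibration_table(sigma, epsilon, n_bins: int = 10) -> CalibrationFit:
    """Alias kept for symmetry with the CLI ``calibrate`` stage."""
    return error_calibration(sigma, epsilon, n_bins=n_bins)


def estimate_error(sigma, fit: CalibrationFit):
    """Convert predicted uncertainty into an estimated error (kJ/mol),
    ``max(0, slope * sigma + intercept)``."""
    est = fit.slope * np.asarray(sigma, dtype=float) + fit.intercept
    return np.maximum(est, 0.0) if est.ndim else float(max(est, 0.0))


def flag_predictions(
    results: list[PredictionResult],
    profile: str = "default",
    cutoffs: dict[str, float] | None = None,
) -> list[PredictionResult]:
    """Flag predictions whose estimated error strictly exceeds the cutoff.

    A flagged prediction is one where running the reference QM workflow is
    recommended. Boundary values (estimated error equal to the cutoff) are
    not flagged. Mutates and returns ``results``.
    """
    table = cutoffs if cutoffs is not None else CUTOFF_PROFILES[profile]
    for r in results:
        if r.property_tag not in table:
            raise ValueError(
                f"no cutoff for property {r.property_tag!r}; "
                f"known: {sorted(table)}"
            )
        r.cutoff_used = float(table[r.property_tag])
        r.flagged = bool(r.estimated_error > r.cutoff_used)
    return results


class ErrorCalibrator(BaseEstimator):
    """Estimator-style wrapper around :func:`error_calibration`.

    ``fit(sigma, epsilon)`` learns the calibration line; ``predict(sigma)``
    returns estimated errors. Fitted attributes: ``slope_``, ``intercept_``,
    ``r2_``, ``bins_``.
    """

    def __init__(self, n_bins: int = 10):
        self.n_bins = n_bins

    def fit(self, sigma, epsilon):
        fit = error_calibration(sigma, epsilon, n_bins=self.n_bins)
        self.slope_ = fit.slope
        self.intercept_ = fit.intercept
        self.r2_ = fit.r2
        self.bins_ = fit.bins
        self.fit_ = fit
        return self

    def predict(self, sigma):
        return estimate_error(np.asarray(sigma, dtype=float), self.fit_)
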