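"""Single-hit Poisson model of lentiviral integration and related analyses.

Under single-hit kinetics the number of integrated vector copies per cell is
Poisson with mean λ, so

    fraction transduced      p(λ) = 1 - exp(-λ)
    copies per transduced cell m(λ) = λ / (1 - exp(-λ))   (zero-truncated mean)

and λ = 1 predicts 63% positive cells.  Observed products often fall short of
this (sub-Poisson transduction: a permissive subfraction of cells takes all
the copies), which is exactly what comparing an observed positive fraction
against the Poisson expectation at the measured bulk VCN reveals.  λ is
identified with the bulk VCN for that comparison.

The same model gives the dose-response of a titration, p(d) = 1 - exp(-αd)
with α the per-viral-particle infectivity, fitted here by bounded 1-D least
squares (the high-dose points are far outside the linear regime, so a straight
line would be wrong).  Serial-dilution linearity and Pearson correlation
utilities for assay-validation readouts live here as well.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from ._errors import ParameterError
from .gating import GatingResult

__all__ = [
    "TransductionModelFit",
    "TitrationFit",
    "DilutionLinearity",
    "CorrelationResult",
    "poisson_expected_fraction",
    "lambda_from_fraction",
    "zero_truncated_mean",
    "compare_to_poisson",
    "fit_titration",
    "dilution_linearity",
    "pairwise_correlation",
]

# below this λ the closed form 1/(1-e^-λ) loses digits to cancellation;
# switch to the series expansion of λ/(1-e^-λ)
_SERIES_CUTOFF = 1e-8


def poisson_expected_fraction(lam: float) -> float:
    """Expected transduced fraction 1 - e^(-λ) under the single-hit model."""
    if lam < 0:
        raise ParameterError(f"Poisson mean must be non-negative, got {lam}")
    return -math.expm1(-lam)


def lambda_from_fraction(p: float) -> float:
    """Poisson mean λ = -ln(1 - p) implied by an observed positive fraction."""
    if not (0.0 <= p < 1.0):
        raise ParameterError(f"fraction must be in [0, 1), got {p}")
    return -math.log1p(-p)


def zero_truncated_mean(lam: float) -> float:
    """Mean copies per transduced cell, λ/(1 - e^(-λ)).

    Tends to 1 as λ -> 0 (a transduced cell carries at least one copy) and to
    λ as λ grows.  Below λ = 1e-8 the series 1 + λ/2 + λ²/12 is used to avoid
    catastrophic cancellation in the denominator.
    """
    if lam < 0:
        raise ParameterError(f"Poisson mean must be non-negative, got {lam}")
    if lam < _SERIES_CUTOFF:
        return 1.0 + lam / 2.0 + lam * lam / 12.0
    return lam / -math.expm1(-lam)


@dataclass
class TransductionModelFit:
    """Observed-vs-expected comparison of a product against the Poisson model."""

    lam: float
    expected_fraction: float
    zero_truncated_mean: float
    observed_fraction: float
    obs_over_exp: float
    classification: str  # "consistent" | "sub-Poisson" | "super-Poisson"

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "expected_fraction": self.expected_fraction,
            "zero_truncated_mean": self.zero_truncated_mean,
            "observed_fraction": self.observed_fraction,
            "obs_over_exp": self.obs_over_exp,
            "classification": self.classification,
        }


def compare_to_poisson(
    bulk_vcn: float,
    observed_fraction: float,
    tolerance: float = 0.1,
) -> TransductionModelFit:
    """Compare an observed positive fraction with the Poisson expectation.

    λ is taken to be the measured bulk VCN.  The product is classified
    sub-Poisson when observed/expected < 1 - tolerance (fewer cells carry the
    copies than random integration predicts, i.e. heterogeneous
    permissiveness), super-Poisson when > 1 + tolerance, and consistent
    otherwise.  The default tolerance of 0.1 is a pragmatic band, not a
    formal test.
    """
    if bulk_vcn < 0:
        raise ParameterError(f"bulk VCN must be non-negative, got {bulk_vcn}")
    if not (0.0 < observed_fraction < 1.0):
        raise ParameterError(
            f"observed fraction must be in (0, 1), got {observed_fraction}"
        )
    expected = poisson_expected_fraction(bulk_vcn)
    if expected == 0.0:
        raise ParameterError(
            "expected fraction is 0 at bulk VCN 0 but positives were observed"
        )
    ratio = observed_fraction / expected
    if ratio < 1.0 - tolerance:
        label = "sub-Poisson"
    elif ratio > 1.0 + tolerance:
        label = "super-Poisson"
    else:
        label = "consistent"
    return TransductionModelFit(
        lam=bulk_vcn,
        expected_fraction=expected,
        zero_truncated_mean=zero_truncated_mean(bulk_vcn),
        observed_fraction=observed_fraction,
        obs_over_exp=ratio,
        classification=label,
    )


@dataclass
class TitrationFit:
    """Single-hit fit of a dose-response titration p(d) = 1 - e^(-αd)."""

    alpha: float
    points: list[tuple[float, float]]
    r_squared: float
    residuals: list[float]
    alpha_linear: float | None  # low-dose (p < 0.1) linear approximation, if any

    def predict(self, dose: float) -> float:
        return -math.expm1(-self.alpha * float(dose))


def fit_titration(points: Sequence[tuple[float, float]]) -> TitrationFit:
    """Fit the per-particle infectivity α to (dose, observed fraction) pairs.

    Least squares on the saturating single-hit curve via bounded 1-D
    minimisation of the sum of squared residuals.  A single point is solved
    exactly (α = -ln(1-p)/d).  Also reports the through-origin linear slope
    over the low-dose points (p < 0.1), the regime where p ≈ αd.
    """
    pts = [(float(d), float(p)) for d, p in points]
    if len(pts) < 1:
        raise ParameterError("at least one (dose, fraction) point required")
    doses = np.array([d for d, _ in pts])
    fracs = np.array([p for _, p in pts])
    if np.any(doses <= 0):
        raise ParameterError("doses must be positive")
    if len(set(doses.tolist())) != len(doses):
        raise ParameterError("doses must be distinct")
    if np.any((fracs < 0) | (fracs >= 1)):
        raise ParameterError("fractions must lie in [0, 1)")
    if np.all(fracs == 0):
        raise ParameterError("all observed fractions are zero; α is undefined")

    if len(pts) == 1:
        alpha = -math.log1p(-fracs[0]) / doses[0]
    else:
        # bracket α using the per-point exact solutions
        per_point = -np.log1p(-fracs[fracs > 0]) / doses[fracs > 0]
        lo, hi = per_point.min() / 10.0, per_point.max() * 10.0

        def sse(a: float) -> float:
            return float(np.sum((fracs - (-np.expm1(-a * doses))) ** 2))

        res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                                       options={"xatol": lo * 1e-10})
        alpha = float(res.x)

    fitted = -np.expm1(-alpha * doses)
    residuals = fracs - fitted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((fracs - fracs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    low = fracs < 0.1
    alpha_lin = None
    if low.any():
        d, p = doses[low], fracs[low]
        alpha_lin = float(np.sum(d * p) / np.sum(d * d))

    return TitrationFit(
        alpha=float(alpha),
        points=pts,
        r_squared=r2,
        residuals=residuals.tolist(),
        alpha_linear=alpha_lin,
    )


@dataclass
class DilutionLinearity:
    """Log-log regression of positive fraction on dilution factor.

    A gating readout that is linear in the true transduced fraction gives a
    slope of 1; MFI of the positives should not move with dilution, so
    ``mfi_constancy`` (the largest relative deviation of the MFI ratio from
    its median across the series) should stay small.
    """

    slope: float
    intercept: float
    r_squared: float
    mfi_constancy: float | None
    n_used: int


def dilution_linearity(
    series: Sequence[tuple[float, GatingResult]],
) -> DilutionLinearity:
    """Assess sensitivity of the gated readout across a serial dilution.

    ``series`` pairs each dilution factor d in (0, 1] with the GatingResult
    measured on that diluted sample.  Points with zero positive fraction are
    dropped with a warning (they carry no log-scale information).  Requires
    at least three retained dilutions.
    """
    kept: list[tuple[float, GatingResult]] = []
    for factor, g in series:
        if not (0.0 < factor <= 1.0):
            raise ParameterError(f"dilution factor must be in (0, 1], got {factor}")
        if g.fraction_positive <= 0.0:
            warnings.warn(
                f"dilution {factor}: zero positive fraction, point dropped",
                stacklevel=2,
            )
            continue
        kept.append((factor, g))
    if len(kept) < 3:
        raise ParameterError("at least 3 dilutions with nonzero fractions required")
    x = np.log([f for f, _ in kept])
    y = np.log([g.fraction_positive for _, g in kept])
    fit = stats.linregress(x, y)
    ratios = [g.mfi_ratio for _, g in kept if g.mfi_ratio is not None]
    constancy = None
    if ratios:
        med = float(np.median(ratios))
        constancy = float(max(abs(r - med) / med for r in ratios))
    return DilutionLinearity(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        mfi_constancy=constancy,
        n_used=len(kept),
    )


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int


def pairwise_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Two-tailed Pearson correlation between two measurement series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ParameterError("at least 3 paired measurements required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("correlation undefined for a zero-variance series")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), r_squared=float(r**2), p_value=float(p), n=x.size)
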