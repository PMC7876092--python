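"""qPCR relative quantification: bulk VCN and transgene expression from Ct values.

Vector copy number (VCN) is measured on genomic DNA as the abundance of a
vector-specific target (WPRE) relative to a genomic reference locus (PTBP2);
transgene expression is measured on cDNA relative to a reference transcript
(ABL-I).  Both reduce to the exponential ΔCt model

    quantity_ratio = E^-(Ct_target - Ct_reference)

with amplification efficiency E per cycle (E = 2 is perfect doubling).  VCN
additionally carries a ploidy factor: with a diploid reference locus, equal
abundance (ΔCt = 0) means two vector copies per cell, so

    VCN = ploidy * E^-(meanCt_WPRE - meanCt_PTBP2),   ploidy default 2.

The ploidy convention is recorded on the estimate so results can be restated
per haploid genome.  Replicates (typically triplicates) are aggregated as the
arithmetic mean of Ct; standard errors follow by first-order propagation of
the replicate SDs through the exponential.

Undetectable targets ("Undetermined" on the instrument) are encoded as
censored measurements, never as a sentinel cycle number.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._errors import EstimationError, ParameterError

__all__ = [
    "CtMeasurement",
    "VcnEstimate",
    "ExpressionEstimate",
    "StandardCurveFit",
    "ct_to_vcn",
    "ct_to_expression",
    "standard_curve_calibrate",
]


@dataclass
class CtMeasurement:
    """Replicate Ct values for one target on one sample.

    ``censored`` marks an undetectable target (no amplification within the
    run); a censored measurement carries no usable Ct values.
    """

    target: str
    replicates: tuple[float, ...] = ()
    efficiency: float = 2.0
    censored: bool = False

    def __post_init__(self) -> None:
        self.replicates = tuple(float(c) for c in self.replicates)
        if not (1.0 < self.efficiency <= 2.0):
            raise ParameterError(
                f"amplification efficiency must be in (1, 2], got {self.efficiency}"
            )
        if self.censored:
            return
        if len(self.replicates) < 1:
            raise ParameterError(f"{self.target}: at least one Ct replicate required")
        if not np.all(np.isfinite(self.replicates)):
            raise ParameterError(f"{self.target}: non-finite Ct; use censored=True")

    @property
    def n(self) -> int:
        return len(self.replicates)

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd_ct(self) -> float:
        if self.n < 2:
            return 0.0
        return float(np.std(self.replicates, ddof=1))


@dataclass
class VcnEstimate:
    """Bulk vector copy number (copies per cell) with propagated uncertainty."""

    bulk_vcn: float
    se: float
    ploidy: float = 2.0
    censored: bool = False  # True when the vector target was undetectable

    def to_dict(self) -> dict:
        return {
            "bulk_vcn": self.bulk_vcn,
            "se": self.se,
            "ploidy": self.ploidy,
            "censored": self.censored,
        }


@dataclass
class ExpressionEstimate:
    """Relative transgene expression (dimensionless) with propagated uncertainty."""

    relative_expression: float
    se: float
    censored: bool = False

    def to_dict(self) -> dict:
        return {
            "relative_expression": self.relative_expression,
            "se": self.se,
            "censored": self.censored,
        }


def _relative_quantity(target: CtMeasurement, reference: CtMeasurement) -> tuple[float, float]:
    """E^-(ΔCt) and its first-order SE, supporting per-target efficiencies.

    With a shared efficiency E this is E^-(Ct_t - Ct_r).  With per-target
    efficiencies the quantity is E_r^Ct_r / E_t^Ct_t (each Ct converted to
    quantity on its own curve, anchored at unit quantity for Ct = 0).
    """
    log_q = (reference.mean_ct * np.log(reference.efficiency)
             - target.mean_ct * np.log(target.efficiency))
    q = float(np.exp(log_q))
    var = (np.log(target.efficiency) ** 2 * target.sd_ct**2 / target.n
           + np.log(reference.efficiency) ** 2 * reference.sd_ct**2 / reference.n)
    return q, q * float(np.sqrt(var))


def ct_to_vcn(
    wpre: CtMeasurement,
    reference: CtMeasurement,
    ploidy: float = 2.0,
) -> VcnEstimate:
    """Bulk VCN from vector (WPRE) and genomic reference (PTBP2) Ct values.

    A censored vector target means no detectable integration: VCN 0, flagged.
    A censored genomic reference leaves the sample unquantifiable and raises.
    """
    if ploidy <= 0:
        raise ParameterError(f"ploidy must be positive, got {ploidy}")
    if reference.censored:
        raise EstimationError(
            f"reference target {reference.target!r} is censored; VCN cannot be estimated"
        )
    if wpre.censored:
        return VcnEstimate(bulk_vcn=0.0, se=0.0, ploidy=ploidy, censored=True)
    q, se = _relative_quantity(wpre, reference)
    return VcnEstimate(bulk_vcn=ploidy * q, se=ploidy * se, ploidy=ploidy)


def ct_to_expression(
    transgene: CtMeasurement,
    reference: CtMeasurement,
) -> ExpressionEstimate:
    """Relative transgene expression from cDNA Ct values (transgene vs ABL-I)."""
    if reference.censored:
        raise EstimationError(
            f"reference target {reference.target!r} is censored; "
            "expression cannot be estimated"
        )
    if transgene.censored:
        return ExpressionEstimate(relative_expression=0.0, se=0.0, censored=True)
    q, se = _relative_quantity(transgene, reference)
    return ExpressionEstimate(relative_expression=q, se=se)


@dataclass
class StandardCurveFit:
    """Dilution-series calibration of amplification efficiency."""

    efficiency: float
    slope: float
    intercept: float
    r_squared: float
    valid: bool = True


def standard_curve_calibrate(
    series: Sequence[tuple[float, CtMeasurement]],
) -> StandardCurveFit:
    """Estimate amplification efficiency from a standard dilution series.

    Fits mean Ct against log10(known quantity) by least squares; the slope of
    an ideal doubling assay is -1/log10(2) = -3.3219 cycles per decade, and in
    general  efficiency = 10^(-1/slope).  Requires at least three points
    spanning at least two orders of magnitude in quantity.  A non-negative
    slope cannot arise from dilution and marks the fit invalid.
    """
    points = [(q, ct) for q, ct in series]
    if len(points) < 3:
        raise ParameterError("standard curve needs at least 3 dilution points")
    quantities = np.array([q for q, _ in points], dtype=float)
    if np.any(quantities <= 0):
        raise ParameterError("standard-curve quantities must be positive")
    if np.log10(quantities.max() / quantities.min()) < 2.0:
        raise ParameterError("standard curve must span at least 2 logs of quantity")
    x = np.log10(quantities)
    y = np.array([ct.mean_ct for _, ct in points])
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        return StandardCurveFit(
            efficiency=float("nan"), slope=float(fit.slope),
            intercept=float(fit.intercept), r_squared=float(fit.rvalue**2),
            valid=False,
        )
    efficiency = 10.0 ** (-1.0 / fit.slope)
    return StandardCurveFit(
        efficiency=float(efficiency),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
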