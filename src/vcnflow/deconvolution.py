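"""Deconvolution of bulk vector copy number into the per-transduced-cell VCN.

Bulk qPCR averages integrated copies over every cell, transduced or not, so a
product that is 20% transduced at bulk VCN 0.3 actually carries ~1.5 copies in
each modified cell.  The "real" VCN of the transduced cells is

    real VCN = bulk VCN / fraction positive,

with the fraction measured by single-cell flow (branched-DNA assay).  Two
cross-checks close the loop:

* sorted populations reconstruct the bulk, Σ fᵢ·vᵢ over (fraction of bulk,
  VCN) pairs measured on sorted positive/negative gates; and
* the reconstruction is compared with the directly measured bulk VCN, with a
  pass/fail at a relative-discrepancy tolerance.

Percent inputs (> 1) are auto-converted to proportions with a warning, since
published tables print percentages.  Sorted fractions that do not sum to 1
(sort losses) are used as reported; renormalisation is opt-in.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._errors import EstimationError, ParameterError
from ._utils import as_proportion, round_half_up
from .gating import GatingResult
from .qpcr import VcnEstimate

__all__ = [
    "SortedPopulation",
    "DeconvolutionResult",
    "real_vcn",
    "reconstruct_bulk_vcn",
    "consistency_check",
    "bootstrap_real_vcn",
]


@dataclass
class SortedPopulation:
    """One sorted gate: its share of the bulk and its independently measured VCN."""

    fraction_of_bulk: float
    vcn: float
    label: str = ""

    def __post_init__(self) -> None:
        self.fraction_of_bulk = as_proportion(self.fraction_of_bulk, "fraction_of_bulk")
        if self.vcn < 0:
            raise ParameterError(f"VCN must be non-negative, got {self.vcn}")


@dataclass
class DeconvolutionResult:
    """Real VCN with the bulk-reconstruction cross-check.

    ``relative_discrepancy`` is |reconstructed - measured| / measured;
    ``passed`` says whether it is within the configured tolerance.
    ``real_vcn`` is populated when a positive-fraction is available, and the
    bootstrap CI when one was computed.
    """

    measured_bulk: float
    reconstructed_bulk: float | None = None
    relative_discrepancy: float | None = None
    passed: bool | None = None
    real_vcn: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def to_dict(self) -> dict:
        return {
            "measured_bulk": self.measured_bulk,
            "reconstructed_bulk": self.reconstructed_bulk,
            "relative_discrepancy": self.relative_discrepancy,
            "passed": self.passed,
            "real_vcn": self.real_vcn,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def real_vcn(bulk_vcn: float, fraction_positive: float) -> float:
    """Copies per transduced cell: bulk VCN divided by the positive fraction.

    ``fraction_positive`` may be a proportion or a percentage (values > 1 are
    divided by 100 with a warning).  A zero fraction leaves the quantity
    undefined and raises.  The result is returned at full precision; round to
    2 decimals for tables and 1 for headline figures (``round_half_up``).
    """
    if bulk_vcn < 0:
        raise ParameterError(f"bulk VCN must be non-negative, got {bulk_vcn}")
    p = as_proportion(fraction_positive, "fraction_positive")
    if p == 0:
        raise ParameterError("fraction_positive is 0; per-transduced-cell VCN undefined")
    return bulk_vcn / p


def reconstruct_bulk_vcn(
    populations: Sequence[SortedPopulation | tuple[float, float]],
    renormalize: bool = False,
) -> float:
    """Bulk VCN implied by sorted populations: Σ fractionᵢ × VCNᵢ.

    Accepts ``SortedPopulation`` objects or bare ``(fraction, vcn)`` tuples.
    Fractions summing below 1 represent unsorted remainder and are legitimate;
    a sum above 1 is warned about and — like any other sum — only rescaled to
    1 when ``renormalize`` is set.  Published sort data are used as printed by
    default, so small sort losses propagate into the reconstruction instead of
    being silently hidden.
    """
    pops = [p if isinstance(p, SortedPopulation) else SortedPopulation(*p)
            for p in populations]
    if not pops:
        raise ParameterError("at least one sorted population required")
    fractions = np.array([p.fraction_of_bulk for p in pops])
    vcns = np.array([p.vcn for p in pops])
    total = fractions.sum()
    if total > 1.0 + 1e-9:
        warnings.warn(
            f"sorted fractions sum to {total:.4f} > 1"
            + ("" if renormalize else "; using as given (renormalize=True to rescale)"),
            stacklevel=2,
        )
    if renormalize and total > 0:
        fractions = fractions / total
    return float(np.sum(fractions * vcns))


def consistency_check(
    measured_bulk: float,
    populations: Sequence[SortedPopulation | tuple[float, float]],
    tolerance: float = 0.15,
    renormalize: bool = False,
) -> DeconvolutionResult:
    """Cross-check a measured bulk VCN against its sorted-population reconstruction.

    Passes when the relative discrepancy |reconstructed - measured|/measured
    is within ``tolerance`` (default 0.15).  A zero measured bulk with a
    nonzero reconstruction fails outright (the discrepancy is undefined).
    When a population labelled "positive" is present its fraction also yields
    the real VCN of the transduced cells.
    """
    if measured_bulk < 0:
        raise ParameterError(f"measured bulk VCN must be non-negative, got {measured_bulk}")
    reconstructed = reconstruct_bulk_vcn(populations, renormalize=renormalize)
    if measured_bulk == 0:
        return DeconvolutionResult(
            measured_bulk=0.0,
            reconstructed_bulk=reconstructed,
            relative_discrepancy=None,
            passed=reconstructed == 0.0,
        )
    discrepancy = abs(reconstructed - measured_bulk) / measured_bulk
    rv = None
    for p in populations:
        pop = p if isinstance(p, SortedPopulation) else SortedPopulation(*p)
        if pop.label == "positive" and pop.fraction_of_bulk > 0:
            rv = real_vcn(measured_bulk, pop.fraction_of_bulk)
            break
    return DeconvolutionResult(
        measured_bulk=float(measured_bulk),
        reconstructed_bulk=reconstructed,
        relative_discrepancy=discrepancy,
        passed=discrepancy <= tolerance,
        real_vcn=rv,
    )


def bootstrap_real_vcn(
    gating: GatingResult,
    vcn: VcnEstimate,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the per-transduced-cell VCN.

    Resamples the positive count as Binomial(n_total, p̂) and the bulk VCN as
    Normal(v̂, se) truncated at zero, then takes percentile bounds of the
    ratio.  Deterministic for a fixed seed.  Replicates drawing zero
    positives (possible only at extreme p̂·n_total) are floored at one
    positive event so the ratio stays finite.
    """
    if gating.n_positive == 0 or gating.fraction_positive == 0:
        raise EstimationError("no positive events; real-VCN CI undefined")
    if n_boot < 2:
        raise ParameterError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    n_pos = rng.binomial(gating.n_total, gating.fraction_positive, size=n_boot)
    n_pos = np.maximum(n_pos, 1)
    p_star = n_pos / gating.n_total
    if vcn.se > 0:
        # truncated-normal draws by rejection; the truncation at 0 only bites
        # when se is comparable to the estimate itself
        v_star = rng.normal(vcn.bulk_vcn, vcn.se, size=n_boot)
        bad = v_star < 0
        while bad.any():
            v_star[bad] = rng.normal(vcn.bulk_vcn, vcn.se, size=int(bad.sum()))
            bad = v_star < 0
    else:
        v_star = np.full(n_boot, vcn.bulk_vcn)
    ratios = v_star / p_star
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(ratios, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
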