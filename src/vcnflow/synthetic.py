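"""Ground-truth generators for every stage of the pipeline.

No raw cytometry or qPCR data accompany the assay this package analyses, so
validation runs on synthetic experiments with known truth.  The generative
model is:

* **Integration.** Copies per cell are Poisson(λ); the sub-Poisson variant
  confines integration to a permissive subfraction π of cells, which then
  draw Poisson(λ/π) so the population mean stays λ.  This two-component
  mixture is the simplest mechanism by which a product at bulk VCN 1 can show
  ~40% positives instead of the Poisson 63%.
* **Fluorescence.** Autofluorescence background is log-normal; the signal
  channel adds mfi_per_copy per integrated copy (optionally saturating above
  ``saturation_copies``) with multiplicative log-normal noise of coefficient
  of variation ``signal_cv``.  A housekeeping channel is positive for every
  intact cell.  Promoter presets set mfi_per_copy so that gated MFI ratios
  land near published promoter-strength readouts (MND ≈ 8.9, PGK ≈ 3.1).
* **qPCR.** Ct = ct_ref - log_E(quantity) + Normal(0, sd_ct) per replicate,
  triplicate by default; a zero quantity yields a censored measurement.
* **Assay designs.** Serial dilution with non-transduced cells, sorting with
  imperfect purity, and dose titrations with λ(dose) = α·dose.

All generators draw from one ``numpy.random.Generator`` seeded per call; the
same seed and configuration always reproduce the same output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ParameterError, StructuralError
from .gating import HOUSEKEEPING, SIGNAL, EventTable
from .qpcr import CtMeasurement

__all__ = [
    "PROMOTER_PRESETS",
    "SimConfig",
    "CellGroundTruth",
    "DilutionSeries",
    "TitrationDesign",
    "SortedFraction",
    "SortResult",
    "TitrationSample",
    "simulate_copy_numbers",
    "simulate_flow_events",
    "simulate_qpcr",
    "simulate_serial_dilution",
    "simulate_sort",
    "simulate_titration",
]

# mfi_per_copy presets calibrated so a λ=1 Poisson sample gated against the
# default background reproduces published promoter MFI ratios (MND ~8.9,
# PGK ~3.1); EFS and UCOE are intermediate-strength placeholders
PROMOTER_PRESETS: dict[str, float] = {
    "PGK": 17.0,
    "EFS": 25.0,
    "UCOE": 35.0,
    "MND": 57.0,
}


@dataclass
class SimConfig:
    """Parameters of one simulated transduction experiment.

    λ is the mean integrated copies per cell (the true bulk VCN);
    ``permissive_fraction`` < 1 switches on the sub-Poisson mixture.
    Fluorescence units are arbitrary; defaults put the autofluorescence
    median at 10 with a bright, well-separated one-copy signal, as branched
    signal amplification produces in practice.
    """

    n_cells: int = 10_000
    lam: float = 1.0
    permissive_fraction: float = 1.0
    mfi_per_copy: float = 50.0
    background_mu: float = math.log(10.0)
    background_sigma: float = 0.25
    signal_cv: float = 0.25
    saturation_copies: int | None = None
    promoter_preset: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.lam < 0:
            raise ParameterError(f"lambda must be non-negative, got {self.lam}")
        if not (0.0 < self.permissive_fraction <= 1.0):
            raise ParameterError(
                f"permissive_fraction must be in (0, 1], got {self.permissive_fraction}"
            )
        if self.promoter_preset is not None:
            if self.promoter_preset not in PROMOTER_PRESETS:
                raise ParameterError(
                    f"unknown promoter preset {self.promoter_preset!r}; "
                    f"choose from {sorted(PROMOTER_PRESETS)}"
                )
            self.mfi_per_copy = PROMOTER_PRESETS[self.promoter_preset]
        if self.mfi_per_copy <= 0:
            raise ParameterError(f"mfi_per_copy must be positive, got {self.mfi_per_copy}")
        if self.signal_cv < 0:
            raise ParameterError(f"signal_cv must be non-negative, got {self.signal_cv}")
        if self.saturation_copies is not None and self.saturation_copies < 1:
            raise ParameterError("saturation_copies must be >= 1 when set")


@dataclass
class CellGroundTruth:
    """Per-cell integrated copy counts; the hidden state every estimator targets."""

    copies: np.ndarray  # int, >= 0, one entry per cell

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=np.int64)
        if np.any(self.copies < 0):
            raise ParameterError("copy counts must be non-negative")

    @property
    def transduced(self) -> np.ndarray:
        return self.copies >= 1

    @property
    def n_cells(self) -> int:
        return self.copies.size

    @property
    def bulk_vcn(self) -> float:
        """True mean copies over all cells."""
        return float(self.copies.mean())

    @property
    def fraction_positive(self) -> float:
        return float(self.transduced.mean())

    @property
    def real_vcn(self) -> float | None:
        """True mean copies over transduced cells only; None if none are."""
        if not self.transduced.any():
            return None
        return float(self.copies[self.transduced].mean())


def simulate_copy_numbers(config: SimConfig) -> CellGroundTruth:
    """Draw per-cell integrated copy counts.

    Pure Poisson (permissive_fraction = 1): copies ~ Poisson(λ), so the
    expected positive fraction is 1 - e^(-λ).  Sub-Poisson: a fraction π of
    cells is permissive and draws Poisson(λ/π); the rest stay at zero.  Both
    models have expected mean copies exactly λ.
    """
    rng = np.random.default_rng(config.seed)
    n, lam, pi = config.n_cells, config.lam, config.permissive_fraction
    if lam == 0:
        return CellGroundTruth(np.zeros(n, dtype=np.int64))
    if pi >= 1.0:
        return CellGroundTruth(rng.poisson(lam, size=n))
    permissive = rng.random(n) < pi
    copies = np.zeros(n, dtype=np.int64)
    copies[permissive] = rng.poisson(lam / pi, size=int(permissive.sum()))
    return CellGroundTruth(copies)


def _multiplicative_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Log-normal noise with unit mean and the requested coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=size)


def simulate_flow_events(
    truth: CellGroundTruth,
    config: SimConfig,
    markers: Mapping[str, np.ndarray] | None = None,
    label: str = "",
) -> EventTable:
    """Render ground-truth copies into a flow cytometry event table.

    Every cell gets a log-normal autofluorescence background; the signal
    channel adds mfi_per_copy × (copies, clipped at ``saturation_copies``)
    × multiplicative noise.  Cells with zero copies therefore carry pure
    background, so the non-transduced control and the negative population are
    distributionally identical.  The housekeeping channel is bright for all
    cells (intact-cell control).  Extra surface-marker channels are passed
    through unchanged.
    """
    rng = np.random.default_rng(config.seed)
    n = truth.n_cells
    background = rng.lognormal(config.background_mu, config.background_sigma, size=n)
    effective = truth.copies.astype(float)
    if config.saturation_copies is not None:
        effective = np.minimum(effective, float(config.saturation_copies))
    signal = background + config.mfi_per_copy * effective * _multiplicative_noise(
        rng, config.signal_cv, n
    )
    # housekeeping mRNA: bright in every intact cell, independent of transduction
    housekeeping = rng.lognormal(math.log(100.0), 0.3, size=n)
    columns = {SIGNAL: signal, HOUSEKEEPING: housekeeping}
    if markers is not None:
        for name, values in markers.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (n,):
                raise StructuralError(
                    f"marker channel {name!r} has {values.size} values for {n} events"
                )
            columns[name] = values
    return EventTable(pd.DataFrame(columns), label=label)


def simulate_qpcr(
    true_quantity: float,
    reps: int = 3,
    ct_ref: float = 24.0,
    efficiency: float = 2.0,
    sd_ct: float = 0.0,
    seed: int = 0,
    target: str = "target",
) -> CtMeasurement:
    """Generate replicate Ct values for a known relative quantity.

    Ct_i = ct_ref - log_E(quantity) + Normal(0, sd_ct); ``ct_ref`` anchors
    unit quantity.  A quantity of zero is undetectable and returns a censored
    measurement.
    """
    if true_quantity < 0:
        raise ParameterError(f"true_quantity must be non-negative, got {true_quantity}")
    if reps < 1:
        raise ParameterError("at least one replicate required")
    if sd_ct < 0:
        raise ParameterError(f"sd_ct must be non-negative, got {sd_ct}")
    if true_quantity == 0:
        return CtMeasurement(target=target, censored=True, efficiency=efficiency)
    rng = np.random.default_rng(seed)
    center = ct_ref - math.log(true_quantity, efficiency)
    cts = center + rng.normal(0.0, sd_ct, size=reps) if sd_ct > 0 else np.full(reps, center)
    return CtMeasurement(target=target, replicates=tuple(cts), efficiency=efficiency)


@dataclass
class DilutionSeries:
    """A transduced sample serially diluted with non-transduced cells.

    ``factors`` starts at 1 (undiluted) and decreases strictly; ``samples``
    pairs each factor with its event table and ground truth.
    """

    factors: list[float]
    samples: list[tuple[EventTable, CellGroundTruth]]

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.factors, self.factors[1:])):
            raise ParameterError("dilution factors must be strictly decreasing")
        if self.factors and self.factors[0] != 1.0:
            raise ParameterError("the first sample must be undiluted (factor 1)")


def simulate_serial_dilution(
    truth: CellGroundTruth,
    events: EventTable,
    config: SimConfig,
    steps: int = 6,
    ratio: float = 0.5,
) -> DilutionSeries:
    """Serially dilute a transduced sample with non-transduced cells.

    Step k keeps each original cell with probability ratio^k and replaces the
    rest with fresh background-only cells, so the expected positive fraction
    at factor d is d·p₀ and the true bulk VCN scales by d, while the signal
    distribution of the surviving positives is untouched (their events are
    carried over verbatim).  Default six halving steps: 1/2 … 1/64.
    """
    if not (0.0 < ratio < 1.0):
        raise ParameterError(f"dilution ratio must be in (0, 1), got {ratio}")
    if steps < 1:
        raise ParameterError("at least one dilution step required")
    rng = np.random.default_rng(config.seed)
    n = truth.n_cells
    blank_config = replace(config, lam=0.0, seed=config.seed + 1)

    factors = [1.0]
    samples: list[tuple[EventTable, CellGroundTruth]] = [(events, truth)]
    for k in range(1, steps + 1):
        d = ratio**k
        keep = rng.random(n) < d
        blank_truth = CellGroundTruth(np.zeros(n, dtype=np.int64))
        blank_events = simulate_flow_events(
            blank_truth, replace(blank_config, seed=blank_config.seed + k)
        )
        copies = np.where(keep, truth.copies, 0)
        data = blank_events.data.copy()
        carried = events.data.loc[keep, events.data.columns.intersection(data.columns)]
        data.loc[keep, carried.columns] = carried.to_numpy()
        diluted_events = EventTable(data, label=f"{events.label}/dilution-{d:g}")
        factors.append(d)
        samples.append((diluted_events, CellGroundTruth(copies)))
    return DilutionSeries(factors=factors, samples=samples)


@dataclass
class SortedFraction:
    """One output gate of a simulated sort, with its per-subset truth."""

    label: str
    events: EventTable | None
    truth: CellGroundTruth | None
    fraction_of_bulk: float
    true_vcn: float | None  # None when the subset is empty (flagged undefined)

    @property
    def empty(self) -> bool:
        return self.truth is None or self.truth.n_cells == 0


@dataclass
class SortResult:
    positive: SortedFraction
    negative: SortedFraction


def simulate_sort(
    events: EventTable,
    truth: CellGroundTruth,
    threshold: float,
    purity: float = 1.0,
    channel: str = SIGNAL,
    seed: int = 0,
) -> SortResult:
    """Sort events at a gate threshold with imperfect sorter purity.

    Each event lands on its gated side with probability ``purity`` and on the
    other side otherwise — impurity is what gives a sorted-negative fraction
    its small but nonzero VCN.  Returns both subsets with their true mean
    copies and their share of the bulk; an empty subset is flagged with an
    undefined VCN.
    """
    if not (0.5 < purity <= 1.0):
        raise ParameterError(f"purity must be in (0.5, 1], got {purity}")
    if events.n_events != truth.n_cells:
        raise StructuralError(
            f"{events.n_events} events but {truth.n_cells} ground-truth cells"
        )
    rng = np.random.default_rng(seed)
    gated_positive = events.channel(channel) > threshold
    correct = rng.random(events.n_events) < purity
    goes_positive = np.where(correct, gated_positive, ~gated_positive)

    def subset(mask: np.ndarray, label: str) -> SortedFraction:
        frac = float(mask.mean())
        if not mask.any():
            return SortedFraction(label=label, events=None, truth=None,
                                  fraction_of_bulk=frac, true_vcn=None)
        sub_truth = CellGroundTruth(truth.copies[mask])
        return SortedFraction(
            label=label,
            events=events.subset(mask, label=f"{events.label}/{label}"),
            truth=sub_truth,
            fraction_of_bulk=frac,
            true_vcn=sub_truth.bulk_vcn,
        )

    return SortResult(
        positive=subset(goes_positive, "positive"),
        negative=subset(~goes_positive, "negative"),
    )


@dataclass
class TitrationDesign:
    """Dose escalation: viral particles per cell, with λ(dose) = α·dose.

    ``alpha`` is the effective integrations per viral particle; ``moi_per_vp``
    converts particle dose to infectious MOI for reporting (infectious titre /
    physical titre).
    """

    doses: tuple[float, ...]
    alpha: float
    moi_per_vp: float = 0.00213

    def __post_init__(self) -> None:
        self.doses = tuple(float(d) for d in self.doses)
        if any(d <= 0 for d in self.doses):
            raise ParameterError("doses must be positive")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ParameterError("doses must be strictly increasing")
        if self.alpha <= 0:
            raise ParameterError(f"alpha must be positive, got {self.alpha}")

    @property
    def moi(self) -> tuple[float, ...]:
        return tuple(self.moi_per_vp * d for d in self.doses)


@dataclass
class TitrationSample:
    dose: float
    moi: float
    lam: float
    truth: CellGroundTruth
    events: EventTable


def simulate_titration(design: TitrationDesign, config: SimConfig) -> list[TitrationSample]:
    """Simulate one sample per dose with λ = α·dose.

    Under the Poisson model the positive fraction follows the single-hit
    curve 1 - e^(-α·dose).  Each dose gets an independent child seed derived
    from ``config.seed`` so the series is reproducible as a whole.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * len(design.doses))
    out = []
    for i, (dose, moi) in enumerate(zip(design.doses, design.moi)):
        lam = design.alpha * dose
        cfg = replace(config, lam=lam, seed=int(seeds[2 * i] % (2**31)))
        truth = simulate_copy_numbers(cfg)
        events = simulate_flow_events(
            truth, replace(cfg, seed=int(seeds[2 * i + 1] % (2**31))),
            label=f"dose-{dose:g}",
        )
        out.append(TitrationSample(dose=dose, moi=moi, lam=lam, truth=truth, events=events))
    return out
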