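"""Control-anchored gating of event-level flow cytometry data.

The branched-DNA (PrimeFlow) readout of a gene-therapy product is an event
table: one row per cell, one column per fluorescence channel.  Two numbers are
extracted from it, mirroring how such panels are reported:

* the fraction of transgene-positive cells — cells whose signal-channel
  intensity exceeds a threshold derived from a non-transduced control; and
* the MFI ratio — mean fluorescence intensity of the positive population
  divided by that of the negative population, a scale-free proxy for per-cell
  transgene expression (and hence promoter strength).

The threshold is a nearest-rank quantile of the control sample (default
0.9999, so a re-gated control shows at most ~0.01% positivity).  This is a
deterministic, control-anchored rule; no mixture model is fitted.  Events
exactly at the threshold count as negative (the gate is strict ``>``).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._errors import ParameterError, StructuralError
from ._utils import geometric_mean, round_half_up

__all__ = [
    "EventTable",
    "GatingResult",
    "fit_threshold",
    "gate_sample",
    "gate_with_marker",
]

SIGNAL = "signal"
HOUSEKEEPING = "housekeeping"


@dataclass
class EventTable:
    """Per-cell fluorescence intensities across named channels.

    ``data`` has one row per event; every column is a channel.  Intensities
    must be finite and non-negative.
    """

    data: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise StructuralError("an EventTable needs at least one event")
        values = self.data.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(values)):
            raise StructuralError("event intensities must be finite")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def channel(self, name: str) -> np.ndarray:
        """Intensities of one channel as a float array."""
        if name not in self.data.columns:
            raise StructuralError(
                f"channel {name!r} not present; available: {list(self.data.columns)}"
            )
        return self.data[name].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray, label: str | None = None) -> "EventTable":
        return EventTable(self.data.loc[np.asarray(mask, bool)].reset_index(drop=True),
                          label=label if label is not None else self.label)


@dataclass
class GatingResult:
    """Flow readout of one sample: positive fraction, MFI ratio, counts.

    ``mfi_ratio`` is None when either side of the gate is empty (the ratio is
    then undefined, matching how an all-negative control panel is reported).
    """

    fraction_positive: float
    n_positive: int
    n_total: int
    threshold: float
    mfi_positive: float | None
    mfi_negative: float | None
    mfi_ratio: float | None
    channel: str = SIGNAL
    label: str = ""

    @property
    def percent_positive(self) -> float:
        """Positive fraction as a percentage, one decimal (reporting convention)."""
        return round_half_up(100 * self.fraction_positive, 1)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "channel": self.channel,
            "fraction_positive": self.fraction_positive,
            "percent_positive": self.percent_positive,
            "n_positive": self.n_positive,
            "n_total": self.n_total,
            "threshold": self.threshold,
            "mfi_positive": self.mfi_positive,
            "mfi_negative": self.mfi_negative,
            "mfi_ratio": self.mfi_ratio,
        }


def fit_threshold(
    control: EventTable,
    channel: str = SIGNAL,
    quantile: float = 0.9999,
) -> float:
    """Gate threshold from a non-transduced control: nearest-rank quantile.

    With the default quantile of 0.9999, re-gating the control itself yields a
    positive fraction of at most 0.01% — the false-positive budget of the
    assay.  Nearest-rank means the threshold is always an observed intensity:
    for n events the k-th order statistic with k = ceil(quantile * n).

    A warning is raised when the control has fewer than 1/(1 - quantile)
    events, in which case the extreme quantile is estimated from the sample
    maximum and is unstable.
    """
    if not (0.5 < quantile <= 1.0):
        raise ParameterError(f"quantile must be in (0.5, 1], got {quantile}")
    values = control.channel(channel)
    n = values.size
    if quantile < 1.0 and n < 1.0 / (1.0 - quantile):
        warnings.warn(
            f"control has {n} events; the {quantile} quantile needs "
            f">= {math.ceil(1.0 / (1.0 - quantile))} events to be stable",
            stacklevel=2,
        )
    k = min(n, max(1, math.ceil(quantile * n)))
    return float(np.partition(values, k - 1)[k - 1])


def _mfi(values: np.ndarray, statistic: str) -> float | None:
    if values.size == 0:
        return None
    if statistic == "geometric":
        return geometric_mean(values)
    if statistic == "arithmetic":
        return float(np.mean(values))
    raise ParameterError(f"unknown MFI statistic {statistic!r}")


def gate_sample(
    sample: EventTable,
    threshold: float,
    channel: str = SIGNAL,
    mfi_statistic: str = "geometric",
) -> GatingResult:
    """Gate one sample at a fixed threshold.

    Positive events are those with intensity strictly above the threshold.
    MFIs default to geometric means, the natural location statistic for
    log-distributed fluorescence; pass ``mfi_statistic="arithmetic"`` for the
    instrument-style arithmetic mean.  If either side of the gate is empty the
    MFI ratio is undefined and returned as None.
    """
    values = sample.channel(channel)
    positive = values > threshold
    n_total = values.size
    n_positive = int(np.count_nonzero(positive))
    mfi_pos = _mfi(values[positive], mfi_statistic)
    mfi_neg = _mfi(values[~positive], mfi_statistic)
    ratio = None
    if mfi_pos is not None and mfi_neg is not None and mfi_neg > 0:
        ratio = mfi_pos / mfi_neg
    return GatingResult(
        fraction_positive=n_positive / n_total,
        n_positive=n_positive,
        n_total=n_total,
        threshold=float(threshold),
        mfi_positive=mfi_pos,
        mfi_negative=mfi_neg,
        mfi_ratio=ratio,
        channel=channel,
        label=sample.label,
    )


def gate_with_marker(
    sample: EventTable,
    marker_gates: Mapping[str, Mapping[str, tuple[float, float]]],
    threshold: float,
    channel: str = SIGNAL,
    mfi_statistic: str = "geometric",
) -> dict[str, GatingResult | None]:
    """Hierarchical gating: select sub-populations by marker gates, then gate
    the transgene channel within each.

    ``marker_gates`` maps a sub-population name to rectangular gates, each a
    ``{marker_channel: (low, high)}`` mapping; an event belongs to the
    sub-population when every marker intensity lies in ``[low, high]``.  The
    returned dict always contains the ungated sample under ``"bulk"``.  An
    empty sub-population is flagged with a warning and maps to None — no
    estimate is produced for it.
    """
    out: dict[str, GatingResult | None] = {
        "bulk": gate_sample(sample, threshold, channel, mfi_statistic)
    }
    for name, gates in marker_gates.items():
        mask = np.ones(sample.n_events, dtype=bool)
        for marker, (low, high) in gates.items():
            values = sample.channel(marker)
            mask &= (values >= low) & (values <= high)
        if not mask.any():
            warnings.warn(f"marker gate {name!r} selects no events", stacklevel=2)
            out[name] = None
            continue
        sub = sample.subset(mask, label=f"{sample.label}/{name}" if sample.label else name)
        out[name] = gate_sample(sub, threshold, channel, mfi_statistic)
    return out
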