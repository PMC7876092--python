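"""Small numeric helpers used throughout the package."""
from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from ._errors import ParameterError

__all__ = ["round_half_up", "as_proportion", "geometric_mean"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Published tables in this field are rounded half-up (2.555 -> 2.56), whereas
    Python's built-in ``round`` uses banker's rounding. Internal math is always
    carried at full precision; this is an output convention only.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def as_proportion(value: float, name: str = "fraction") -> float:
    """Normalise a positive-fraction argument that may be given as a percent.

    Values in (1, 100] are interpreted as percentages and divided by 100 with
    a warning; published tables print percentages while formulas use
    proportions, and silently mixing the two is the classic failure mode here.
    """
    value = float(value)
    if value < 0:
        raise ParameterError(f"{name} must be non-negative, got {value}")
    if value > 100:
        raise ParameterError(f"{name}={value} is neither a proportion nor a percentage")
    if value > 1:
        warnings.warn(
            f"{name}={value} > 1; interpreting as a percentage ({value / 100})",
            stacklevel=3,
        )
        return value / 100
    return value


def geometric_mean(x: np.ndarray) -> float:
    """Geometric mean of strictly positive intensities; NaN on empty input."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return float("nan")
    if np.any(x <= 0):
        # fluorescence intensities are modelled strictly positive; a zero
        # would send the log to -inf, so fail loudly instead
        raise ParameterError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(x))))
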