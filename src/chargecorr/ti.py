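"""Thermodynamic integration and block-averaging error estimation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LambdaSeries


@dataclass
class TIResult:
    value: float  # kJ/mol
    error: float  # kJ/mol, 0 when no per-point errors are available
    n_lambda: int
    method: str = "trapezoid"

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("error must be nonnegative")


def trapezoid_ti(series: LambdaSeries) -> TIResult:
    """Trapezoidal-rule integral of <dH/dlambda> over lambda in [0, 1].

    The statistical error is obtained by applying the same trapezoidal
    quadrature to the per-point errors (treating them as additive over
    the integration weights).
    """
    lam, v = series.lambdas, series.values
    value = float(np.trapezoid(v, lam))
    error = 0.0
    if series.errors is not None:
        error = float(np.trapezoid(series.errors, lam))
    return TIResult(value=value, error=error, n_lambda=len(lam))


def block_average_error(samples: np.ndarray, min_blocks: int = 4) -> float:
    """Standard error of the mean from block averaging.

    The series is split into blocks of geometrically growing size
    (powers of two); for each block size the standard error of the block
    means is computed.  Correlated data give estimates that grow with
    block size and level off once blocks exceed the correlation time;
    the plateau value (first window where successive estimates differ by
    less than 5%, else the largest-block estimate) is returned.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 16:
        raise ValueError("need at least 16 samples for block averaging")
    if np.allclose(x, x[0]):
        return 0.0
    estimates = []
    size = 1
    while n // size >= min_blocks:
        nb = n // size
        blocks = x[: nb * size].reshape(nb, size).mean(axis=1)
        se = blocks.std(ddof=1) / np.sqrt(nb)
        estimates.append(se)
        size *= 2
    for prev, cur in zip(estimates, estimates[1:]):
        if prev > 0 and abs(cur - prev) / prev < 0.05:
            return float(cur)
    return float(estimates[-1])
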