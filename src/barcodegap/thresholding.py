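"""Data-driven identification thresholds from the pairwise-distance density.

On barcoded data the pooled pairwise distances are bimodal: a tight mode of
conspecific distances near zero and a broad heterospecific mode.  A
Gaussian-kernel density estimate of all pairwise distances therefore shows
a dip between the modes; the location of that dip is a data-driven
threshold for identification and MOTU delimitation.

Numerical conventions (fixed so results are reproducible bit-for-bit):

* bandwidth ``0.9 * min(sd, IQR/1.34) * n**(-1/5)`` (the classical
  rule of thumb; sd is the n-1 sample standard deviation).  If the IQR is
  zero the sd alone is used; if both are zero the input is degenerate.
* 512 equally spaced grid points spanning ``[min - 3*bw, max + 3*bw]``.
* a local minimum is a grid point strictly lower than both neighbours;
  plateaus are not minima unless the plateau-tolerant mode is enabled, in
  which case the leftmost point of a flat valley is reported.
* the selected threshold is the first (smallest) local minimum; all minima
  are reported so callers can override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix
from .errors import AlignmentError, DegenerateInputError

GRID_SIZE = 512
GRID_CUT = 3.0  # grid extension in bandwidths beyond the data range


@dataclass(frozen=True)
class DensityCurve:
    """Gaussian-kernel density of pairwise distances on a fixed grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        """Trapezoidal integral over the grid (~1 by construction)."""
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class ThresholdResult:
    """Local density minima and the chosen threshold.

    ``selected`` is None when the curve has no interior minimum (e.g. a
    unimodal distance distribution); callers must then fall back to a fixed
    threshold.
    """

    minima: tuple[float, ...]
    selected: float | None
    bandwidth: float
    selection_rule: str = "first-local-minimum"


def rule_of_thumb_bandwidth(values: np.ndarray) -> float:
    """Bandwidth ``0.9 * min(sd, IQR/1.34) * n**(-1/5)`` with IQR=0 fallback."""
    v = np.asarray(values, dtype=float)
    if np.ptp(v) == 0:
        raise DegenerateInputError("all distance values identical: zero bandwidth")
    sd = float(np.std(v, ddof=1))
    q1, q3 = np.percentile(v, [25, 75])
    iqr = float(q3 - q1)
    sigma = min(sd, iqr / 1.34) if iqr > 0 else sd
    if sigma <= 0:
        raise DegenerateInputError(
            "all distance values identical: zero bandwidth"
        )
    return 0.9 * sigma * len(v) ** (-1.0 / 5.0)


def distance_density(values: np.ndarray) -> DensityCurve:
    """Gaussian KDE of pairwise distances on the fixed 512-point grid."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise DegenerateInputError("need at least 2 distance values for a density")
    bw = rule_of_thumb_bandwidth(v)
    grid = np.linspace(v.min() - GRID_CUT * bw, v.max() + GRID_CUT * bw, GRID_SIZE)
    # mean of standard-normal kernels centred on the data
    z = (grid[:, None] - v[None, :]) / bw
    density = np.exp(-0.5 * z**2).sum(axis=1) / (v.size * bw * np.sqrt(2 * np.pi))
    return DensityCurve(grid=grid, density=density, bandwidth=bw)


def local_minima(curve: DensityCurve, *, plateau_tolerant: bool = False) -> ThresholdResult:
    """Interior local minima of a density curve; first minimum selected.

    Default mode requires strict inequality against both neighbours.  The
    plateau-tolerant mode also accepts the leftmost point of a flat valley
    (density constant over a run, strictly lower than the values flanking
    the run).
    """
    y = curve.density
    x = curve.grid
    minima: list[float] = []
    if plateau_tolerant:
        i = 1
        while i < len(y) - 1:
            j = i
            while j + 1 < len(y) and y[j + 1] == y[i]:
                j += 1
            if j < len(y) - 1 and y[i - 1] > y[i] and y[j + 1] > y[j]:
                minima.append(float(x[i]))
            i = j + 1
    else:
        interior = (y[1:-1] < y[:-2]) & (y[1:-1] < y[2:])
        minima = [float(v) for v in x[1:-1][interior]]
    return ThresholdResult(
        minima=tuple(minima),
        selected=minima[0] if minima else None,
        bandwidth=curve.bandwidth,
    )


def optimise_threshold(
    dm: DistanceMatrix, *, plateau_tolerant: bool = False
) -> ThresholdResult:
    """Density-dip threshold from all pairwise distances of a matrix."""
    if dm.n < 3:
        raise AlignmentError(
            "threshold optimisation needs at least 3 specimens"
        )
    return local_minima(
        distance_density(dm.condensed()), plateau_tolerant=plateau_tolerant
    )
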