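"""Percentile-trajectory summaries and the AUC elastance severity metric.

For one patient and mode, the 5th/25th/50th/75th/95th percentile of all
breath trajectories is taken pointwise across breaths at every normalised
inspiratory-time grid point.  Each percentile curve is then reduced to the
area under its elastance between 30% and 100% of normalised inspiration
(the early, mask-prone and effort-dominated first 30% is excluded).  The
normalised time axis carries nominal units of seconds, so a constant
elastance E yields an AUC of 0.7*E in cmH2O*s/L, and an AUC at or above
25 cmH2O*s/L flags ARDS-like respiratory-system stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .elastance import EdrsSurface
from .errors import ConsistencyError, InsufficientDataError, ParameterError

#: Percentile levels reported by default (percent).
DEFAULT_LEVELS = (5, 25, 50, 75, 95)

#: Normalised-inspiration window over which the AUC is taken.
DEFAULT_AUC_WINDOW = (0.3, 1.0)

#: AUC at or above this value (cmH2O*s/L) flags ARDS-like stiffness.
SEVERITY_THRESHOLD = 25.0


class TauSeries(NamedTuple):
    """A curve on the normalised inspiratory-time grid (duck-typed like a
    breath trajectory: ``tau``, ``edrs``, ``valid``)."""

    tau: np.ndarray
    edrs: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class PercentileSummary:
    """Pointwise percentile curves of a surface.

    ``values`` has shape (n_levels, n_grid); a grid point is valid only
    where at least two breaths contribute.
    """

    levels: tuple
    tau: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    n_breaths: int

    def trajectory(self, level) -> TauSeries:
        """The curve for one percentile level as a TauSeries."""
        try:
            i = self.levels.index(level)
        except ValueError as exc:
            raise ConsistencyError(f"level {level} not in {self.levels}") from exc
        return TauSeries(self.tau, self.values[i], self.valid)


@dataclass(frozen=True)
class AUCResult:
    """AUC of each percentile curve plus the stiffness flag per level."""

    window: tuple
    levels: tuple
    auc_per_level: dict
    severity_flag_per_level: dict
    n_breaths: int


def percentile_trajectories(
    surface: EdrsSurface, levels: Sequence = DEFAULT_LEVELS
) -> PercentileSummary:
    """Pointwise empirical percentiles of elastance across breaths.

    At each grid point the requested percentiles are taken over the breaths
    valid there, with linear interpolation between order statistics; points
    where fewer than two breaths are valid are invalid in the output.
    """
    if surface.n_breaths == 0:
        raise ConsistencyError("empty surface")
    levels = tuple(levels)
    if any(not (0 <= lv <= 100) for lv in levels):
        raise ParameterError("percentile levels must lie in [0, 100]")
    mat = surface.matrix()
    counts = np.sum(~np.isnan(mat), axis=0)
    valid = counts >= 2
    values = np.full((len(levels), surface.tau.size), np.nan)
    if valid.any():
        values[:, valid] = np.nanpercentile(mat[:, valid], levels, axis=0)
    return PercentileSummary(
        levels=levels,
        tau=surface.tau.copy(),
        values=values,
        valid=valid,
        n_breaths=surface.n_breaths,
    )


def auc_edrs(trajectory, window: tuple = DEFAULT_AUC_WINDOW) -> float:
    """Area under an elastance curve over a normalised-inspiration window.

    Parameters
    ----------
    trajectory : object with ``tau``, ``edrs``, ``valid`` arrays
        A breath trajectory or one percentile curve.
    window : (float, float)
        Fraction interval of normalised inspiration, default (0.3, 1.0).

    Returns
    -------
    float
        Trapezoidal integral of the linear interpolant over the window,
        cmH2O*s/L (the normalised axis carries nominal units of seconds).

    Raises
    ------
    InsufficientDataError
        If any grid point needed to cover the window is invalid.
    """
    lo, hi = float(window[0]), float(window[1])
    if not (0.0 <= lo < hi <= 1.0):
        raise ParameterError(f"window must satisfy 0 <= lo < hi <= 1, got {window}")
    tau = np.asarray(trajectory.tau, dtype=float)
    edrs = np.asarray(trajectory.edrs, dtype=float)
    valid = np.asarray(trajectory.valid, dtype=bool)
    # the node at or just below `lo` anchors the interpolation at the window edge
    i_lo = int(np.searchsorted(tau, lo, side="right")) - 1
    i_lo = max(i_lo, 0)
    i_hi = int(np.searchsorted(tau, hi, side="left"))
    needed = np.arange(i_lo, min(i_hi + 1, tau.size))
    bad = needed[~valid[needed]]
    if bad.size:
        raise InsufficientDataError(
            f"invalid grid point at tau={tau[bad[0]]:.4f} inside AUC window "
            f"[{lo}, {hi}]"
        )
    inside = (tau > lo) & (tau < hi)
    xs = np.concatenate(([lo], tau[inside], [hi]))
    ys = np.interp(xs, tau[valid], edrs[valid])
    return float(np.trapezoid(ys, xs))


def severity_flag(auc: float, threshold: float = SEVERITY_THRESHOLD) -> bool:
    """True iff the AUC is at or above the ARDS-like stiffness threshold."""
    if not np.isfinite(auc):
        raise ParameterError("auc must be finite")
    return bool(auc >= threshold)


def summarize_surface(
    surface: EdrsSurface,
    levels: Sequence = DEFAULT_LEVELS,
    window: tuple = DEFAULT_AUC_WINDOW,
    threshold: float = SEVERITY_THRESHOLD,
) -> AUCResult:
    """Percentile curves -> AUC per level -> stiffness flag per level."""
    summary = percentile_trajectories(surface, levels)
    auc = {}
    flags = {}
    for level in summary.levels:
        value = auc_edrs(summary.trajectory(level), window)
        auc[level] = value
        flags[level] = severity_flag(value, threshold)
    return AUCResult(
        window=tuple(window),
        levels=summary.levels,
        auc_per_level=auc,
        severity_flag_per_level=flags,
        n_breaths=summary.n_breaths,
    )
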