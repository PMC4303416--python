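"""Per-breath time-varying elastance and normalised-time surfaces.

The respiratory system is modelled as a single compartment in which airway
pressure divides into a resistive drop, an elastic term, and — for a
spontaneously breathing patient — pleural-pressure changes split into a
constant chest-wall component and a breath-specific demand component.
Lumping the lung, chest and demand elastances into a single time-varying
respiratory-system elastance keeps the model identifiable from airway
pressure and flow alone:

    E_drs(t) = (P_aw(t) - PEEP - R_rs * Q(t)) / V(t)

with the airway resistance R_rs held at a fixed physiological constant
(default 5 cmH2O*s/L) and the baseline (offset) pressure removed per breath.
During active patient effort the demand component is negative, so E_drs < 0
at the start of a patient-initiated breath — the model's key qualitative
signature.

Because the denominator V(t) vanishes at onset, samples whose inspired
volume is below a small fraction of the breath's tidal volume are masked
rather than clipped: this preserves the genuinely negative early E_drs while
excluding numerically meaningless ratios.

Each breath's trace is then mapped onto a common normalised inspiratory-time
grid (0..100% of inspiration) so breaths of different duration can be
stacked into a breath-ordered surface per patient and mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError, DegenerateBreathError, ParameterError
from .io import WaveformRecord
from .segmentation import (
    DEFAULT_PEEP_WINDOW,
    DEFAULT_Q_ON,
    DEFAULT_T_MIN,
    Breath,
    VolumeTrace,
    compute_volume,
    detect_breaths,
)

logger = logging.getLogger(__name__)

#: Constant airway resistance assumed throughout, cmH2O*s/L.
DEFAULT_RRS = 5.0


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the elastance estimate.

    Attributes
    ----------
    rrs : float
        Assumed constant airway resistance, cmH2O*s/L.
    v_min_frac : float
        Fraction of tidal volume below which samples are masked (the
        early-volume singularity guard).
    n_grid : int
        Number of points of the normalised inspiratory-time grid.
    """

    rrs: float = DEFAULT_RRS
    v_min_frac: float = 0.02
    n_grid: int = 100

    def __post_init__(self):
        if self.rrs <= 0:
            raise ParameterError("rrs must be positive")
        if not (0.0 < self.v_min_frac < 0.5):
            raise ParameterError("v_min_frac must be in (0, 0.5)")
        if self.n_grid < 10:
            raise ParameterError("n_grid must be at least 10")


@dataclass(frozen=True)
class EdrsTrajectory:
    """One breath's elastance on the normalised inspiratory-time grid.

    ``tau`` spans [0, 1] uniformly; ``edrs`` is NaN wherever ``valid`` is
    False (the masked low-volume prefix).
    """

    breath_index: int
    tau: np.ndarray
    edrs: np.ndarray
    valid: np.ndarray
    ti: float

    @property
    def n_grid(self) -> int:
        return int(self.tau.size)


@dataclass
class EdrsSurface:
    """Breath-ordered stack of trajectories for one patient and mode."""

    patient_id: str
    mode: str
    trajectories: list[EdrsTrajectory] = field(default_factory=list)

    @property
    def n_breaths(self) -> int:
        return len(self.trajectories)

    @property
    def tau(self) -> np.ndarray:
        return self.trajectories[0].tau

    def matrix(self) -> np.ndarray:
        """(n_breaths, n_grid) elastance matrix, NaN where invalid."""
        out = np.vstack([t.edrs for t in self.trajectories])
        out[~self.valid_matrix()] = np.nan
        return out

    def valid_matrix(self) -> np.ndarray:
        return np.vstack([t.valid for t in self.trajectories])


def compute_edrs_trace(
    paw: np.ndarray,
    flow: np.ndarray,
    volume: VolumeTrace,
    peep: float,
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Elastance per sample over one inspiratory window.

    Parameters
    ----------
    paw, flow : ndarray
        Airway pressure (cmH2O) and flow (L/s) over ``[onset, end_insp)``.
    volume : VolumeTrace
        Inspired volume from :func:`~edrs.segmentation.compute_volume`.
    peep : float
        Baseline pressure subtracted so the estimate is a ratio of elastic
        pressure rise to inspired volume.
    params : ModelParams

    Returns
    -------
    (edrs, valid)
        ``edrs[k] = (paw[k] - peep - rrs*flow[k]) / volume[k]`` wherever the
        volume is at least ``v_min_frac`` of tidal volume; NaN and
        ``valid=False`` elsewhere (a prefix of the window).
    """
    v = volume.volume
    if not (paw.size == flow.size == v.size):
        raise ConsistencyError("paw, flow and volume must have equal length")
    vmax = float(np.max(v))
    if vmax <= 0.0:
        raise DegenerateBreathError(
            f"breath {volume.breath_index}: no inspired volume"
        )
    threshold = params.v_min_frac * vmax
    above = np.flatnonzero(v >= threshold)
    if above.size == 0:
        raise DegenerateBreathError(
            f"breath {volume.breath_index}: all samples below volume mask"
        )
    valid = np.zeros(v.size, dtype=bool)
    first = int(above[0])
    valid[first:] = v[first:] > 0.0
    edrs = np.full(v.size, np.nan)
    edrs[valid] = (paw[valid] - peep - params.rrs * flow[valid]) / v[valid]
    return edrs, valid


def normalize_trajectory(
    edrs: np.ndarray,
    valid: np.ndarray,
    ti: float,
    params: ModelParams,
    breath_index: int = 0,
) -> EdrsTrajectory:
    """Interpolate a per-sample trace onto the uniform normalised-time grid.

    Sample positions map linearly onto tau in [0, 1]; the valid portion is
    linearly interpolated (exact at sample positions that coincide with grid
    nodes) and grid points earlier than the first valid sample stay invalid.
    """
    m = edrs.size
    if m < 2:
        raise DegenerateBreathError(
            f"breath {breath_index}: need at least 2 samples to normalise"
        )
    if int(np.count_nonzero(valid)) < 2:
        raise DegenerateBreathError(
            f"breath {breath_index}: fewer than 2 valid samples"
        )
    x = np.linspace(0.0, 1.0, m)
    xs = x[valid]
    ys = edrs[valid]
    tau = np.linspace(0.0, 1.0, params.n_grid)
    grid_valid = tau >= xs[0] - 1e-12
    out = np.full(params.n_grid, np.nan)
    out[grid_valid] = np.interp(tau[grid_valid], xs, ys)
    return EdrsTrajectory(
        breath_index=breath_index, tau=tau, edrs=out, valid=grid_valid, ti=ti
    )


def build_surface(
    trajectories: list[EdrsTrajectory], patient_id: str, mode: str
) -> EdrsSurface:
    """Assemble a breath-ordered surface, checking grid homogeneity."""
    if not trajectories:
        raise ConsistencyError("cannot build a surface from zero trajectories")
    n_grid = trajectories[0].n_grid
    for t in trajectories:
        if t.n_grid != n_grid:
            raise ConsistencyError(
                f"mixed grid sizes: {t.n_grid} != {n_grid} "
                f"(breath {t.breath_index})"
            )
    idx = [t.breath_index for t in trajectories]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ConsistencyError("breath_index must be strictly increasing")
    return EdrsSurface(patient_id=patient_id, mode=mode, trajectories=list(trajectories))


def breath_edrs(
    record: WaveformRecord,
    breath: Breath,
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray, VolumeTrace]:
    """Per-sample elastance for one breath: volume, offset removal, Eq. ratio.

    Convenience wrapper used by :func:`analyze_session` and by consumers that
    need the un-normalised per-sample trace (e.g. parameter-recovery checks).
    """
    vol = compute_volume(record, breath)
    edrs, valid = compute_edrs_trace(
        record.paw[breath.onset : breath.end_insp],
        record.flow[breath.onset : breath.end_insp],
        vol,
        breath.peep,
        params,
    )
    return edrs, valid, vol


def analyze_session(
    record: WaveformRecord,
    params: ModelParams | None = None,
    q_on: float = DEFAULT_Q_ON,
    t_min: float = DEFAULT_T_MIN,
    peep_window: float = DEFAULT_PEEP_WINDOW,
) -> EdrsSurface:
    """Full per-session estimation: segment, estimate, normalise, stack.

    Degenerate breaths (no usable volume) are skipped with a logged count
    rather than aborting the session.
    """
    params = params or ModelParams()
    breaths = detect_breaths(record, q_on=q_on, t_min=t_min, peep_window=peep_window)
    trajectories = []
    skipped = 0
    for breath in breaths:
        try:
            edrs, valid, _ = breath_edrs(record, breath, params)
            trajectories.append(
                normalize_trajectory(
                    edrs, valid, breath.ti, params, breath_index=breath.index
                )
            )
        except DegenerateBreathError:
            skipped += 1
    if skipped:
        logger.warning(
            "session %s/%s: skipped %d degenerate breath(s)",
            record.patient_id, record.mode, skipped,
        )
    return build_surface(trajectories, record.patient_id, record.mode)
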