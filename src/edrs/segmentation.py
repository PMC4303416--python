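"""Breath detection and per-breath volume / baseline-pressure bookkeeping.

A breath is found from the flow waveform alone: inspiration onset where flow
rises through a trigger threshold ``q_on`` (backtracked to the zero-flow
sample so the inspired-volume integral starts at the true zero crossing),
end of inspiration at the first subsequent negative-flow sample, end of the
breath at the next onset.  Only the inspiratory limb is analysed downstream;
expiration merely delimits breaths.

Inspired volume is the running trapezoidal integral of flow, reset to zero
at every onset so cross-breath sensor drift cannot corrupt the within-breath
volume that the elastance estimate divides by.  The baseline (offset)
pressure is a pre-onset median of airway pressure, robust to brief
artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ParameterError, SegmentationError
from .io import WaveformRecord

#: Default flow trigger threshold, L/s.
DEFAULT_Q_ON = 0.05
#: Default minimum inspiratory duration, s.
DEFAULT_T_MIN = 0.2
#: Default pre-onset window for the baseline-pressure median, s.
DEFAULT_PEEP_WINDOW = 0.05


@dataclass(frozen=True)
class Breath:
    """Index boundaries of one breath within a session.

    ``onset`` is the first inspiratory sample, ``end_insp`` the exclusive end
    of inspiration, ``end_breath`` the exclusive end of the whole breath.
    ``ti`` is the inspiratory time in seconds and ``peep`` the baseline
    airway pressure (cmH2O) estimated immediately before onset.
    """

    index: int
    onset: int
    end_insp: int
    end_breath: int
    ti: float
    peep: float

    def __post_init__(self):
        if not (self.onset < self.end_insp <= self.end_breath):
            raise SegmentationError(
                f"breath {self.index}: onset {self.onset} < end_insp "
                f"{self.end_insp} <= end_breath {self.end_breath} violated"
            )


@dataclass(frozen=True)
class VolumeTrace:
    """Inspired volume (litres) per sample over one inspiration.

    ``volume[0]`` is 0 at onset; subsequent samples are the cumulative
    trapezoidal integral of flow.
    """

    breath_index: int
    volume: np.ndarray


def detect_breaths(
    record: WaveformRecord,
    q_on: float = DEFAULT_Q_ON,
    t_min: float = DEFAULT_T_MIN,
    peep_window: float = DEFAULT_PEEP_WINDOW,
) -> list[Breath]:
    """Partition a session into breaths from the flow waveform.

    Parameters
    ----------
    record : WaveformRecord
        Validated session.
    q_on : float
        Flow trigger threshold, L/s.  A breath candidate starts where flow
        rises through ``+q_on`` and stays above ``-q_on/2`` (noise allowance)
        for at least `t_min` seconds.
    t_min : float
        Minimum inspiratory duration, s; shorter candidates are discarded.
    peep_window : float
        Window used for the per-breath baseline-pressure estimate, s.

    Returns
    -------
    list of Breath
        Ordered, non-overlapping breaths.  An empty list (not an error) if
        no breath is found.
    """
    if q_on <= 0 or t_min <= 0:
        raise ParameterError("q_on and t_min must be positive")
    flow = record.flow
    dt = record.sample_interval
    n = flow.size
    n_min = max(1, int(round(t_min / dt)))

    crossings = np.flatnonzero((flow[:-1] < q_on) & (flow[1:] >= q_on)) + 1
    if flow[0] >= q_on:
        crossings = np.concatenate(([0], crossings))

    bounds: list[tuple[int, int]] = []
    search_from = 0
    for i in crossings:
        if i < search_from:
            continue
        if i + n_min > n:
            break
        if np.any(flow[i : i + n_min] <= -0.5 * q_on):
            continue  # not a sustained inspiration (noise blip)
        # Backtrack to the zero crossing so the volume integral starts at
        # (approximately) zero flow.  If the preceding flow is still deeply
        # negative (abrupt flow step), inspiration starts at the step itself.
        prev = np.flatnonzero(flow[search_from : i + 1] <= 0.0)
        if prev.size:
            j = search_from + prev[-1]
            onset = j if flow[j] > -q_on else j + 1
        else:
            onset = search_from
        neg = np.flatnonzero(flow[i:] < 0.0)
        if neg.size == 0:
            break  # trailing partial breath: inspiration never ends
        end_insp = int(i + neg[0])
        if (end_insp - onset) * dt >= t_min:
            bounds.append((int(onset), end_insp))
        search_from = end_insp

    breaths: list[Breath] = []
    for k, (onset, end_insp) in enumerate(bounds):
        end_breath = bounds[k + 1][0] if k + 1 < len(bounds) else n
        breath = Breath(
            index=k,
            onset=onset,
            end_insp=end_insp,
            end_breath=end_breath,
            ti=(end_insp - onset) * dt,
            peep=np.nan,
        )
        peep = estimate_peep(record, breath, window=peep_window)
        breaths.append(
            Breath(k, onset, end_insp, end_breath, breath.ti, peep)
        )
    return breaths


def compute_volume(record: WaveformRecord, breath: Breath) -> VolumeTrace:
    """Cumulative trapezoidal integral of flow over the inspiratory window.

    Volume is reset to zero at onset; the result has one value per sample of
    ``[onset, end_insp)``.
    """
    if breath.end_insp - breath.onset < 2:
        raise SegmentationError(
            f"breath {breath.index}: inspiratory window has fewer than 2 samples"
        )
    if breath.end_insp > record.n_samples:
        raise SegmentationError(
            f"breath {breath.index}: window exceeds session length"
        )
    flow = record.flow[breath.onset : breath.end_insp]
    volume = cumulative_trapezoid(flow, dx=record.sample_interval, initial=0.0)
    return VolumeTrace(breath_index=breath.index, volume=volume)


def estimate_peep(
    record: WaveformRecord, breath: Breath, window: float = DEFAULT_PEEP_WINDOW
) -> float:
    """Median airway pressure over `window` seconds immediately before onset.

    The median makes the estimate robust to brief pressure artefacts.  Falls
    back to ``paw[onset]`` when no pre-onset samples exist (first breath at
    the very start of a session).
    """
    if window <= 0:
        raise ParameterError("window must be positive")
    w = max(1, int(round(window / record.sample_interval)))
    lo = max(0, breath.onset - w)
    if lo == breath.onset:
        return float(record.paw[breath.onset])
    return float(np.median(record.paw[lo : breath.onset]))
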