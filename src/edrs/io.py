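"""Reading and writing ventilator waveform sessions and elastance surfaces.

The on-disk format is a plain CSV dialect designed to be diff-friendly and
trivially produced from ventilator data exports:

* optional leading ``#`` metadata lines (``# patient_id: P01``, ``# mode: PS``)
  plus a units comment;
* one header line ``time_s,paw_cmH2O,flow_L_s[,eadi_uV]``;
* ``.`` decimal separator, full float precision (17 significant digits, so a
  write/read round trip is bit exact).

Units are fixed: seconds, cmH2O, L/s (inspiration positive), uV.  The reader
validates but never resamples, filters or otherwise mutates values.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DataError, FormatError, SchemaError

#: Canonical channel -> column-name mapping of the CSV dialect.
DEFAULT_SCHEMA = {
    "time": "time_s",
    "paw": "paw_cmH2O",
    "flow": "flow_L_s",
    "eadi": "eadi_uV",
}

#: Tolerance on time-grid uniformity, seconds.
TIME_TOL = 1e-9

#: Slowest acceptable sampling for breath segmentation (10 Hz).
MAX_SAMPLE_INTERVAL = 0.1

MODES = ("PS", "NAVA")

_FMT = "%.17g"


@dataclass
class WaveformRecord:
    """One ventilation session on a uniform time grid.

    Attributes
    ----------
    patient_id : str
        Identifier of the patient the session belongs to.
    mode : str
        Ventilation mode, ``"PS"`` or ``"NAVA"``.
    sample_interval : float
        Uniform sampling interval, seconds; must lie in ``(0, 0.1]``.
    time : ndarray
        Sample times in seconds, strictly increasing from 0.
    paw : ndarray
        Airway pressure per sample, cmH2O.
    flow : ndarray
        Airway flow per sample, L/s, positive during inspiration.
    eadi : ndarray or None
        Electrical diaphragm activity, uV.  Optional.
    """

    patient_id: str
    mode: str
    sample_interval: float
    time: np.ndarray
    paw: np.ndarray
    flow: np.ndarray
    eadi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.paw = np.asarray(self.paw, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.eadi is not None:
            self.eadi = np.asarray(self.eadi, dtype=float)

    # -- validation -----------------------------------------------------

    def validate(self) -> "WaveformRecord":
        """Check every invariant; raise on the first violation."""
        if self.mode not in MODES:
            raise ConsistencyError(f"mode must be one of {MODES}, got {self.mode!r}")
        n = self.time.size
        if n < 2:
            raise FormatError("a session needs at least 2 samples")
        for name in ("paw", "flow", "eadi"):
            ch = getattr(self, name)
            if ch is None:
                continue
            if ch.size != n:
                raise FormatError(
                    f"channel {name!r} has {ch.size} samples, time has {n}"
                )
            bad = np.flatnonzero(~np.isfinite(ch))
            if bad.size:
                raise DataError(f"non-finite value in {name!r} at row {bad[0]}")
        if not np.isfinite(self.time).all():
            bad = np.flatnonzero(~np.isfinite(self.time))
            raise DataError(f"non-finite value in time at row {bad[0]}")
        if abs(self.time[0]) > TIME_TOL:
            raise FormatError(f"time must start at 0, got {self.time[0]!r}")
        if not (0.0 < self.sample_interval <= MAX_SAMPLE_INTERVAL + TIME_TOL):
            raise FormatError(
                f"sample_interval must be in (0, {MAX_SAMPLE_INTERVAL}] s, "
                f"got {self.sample_interval!r}"
            )
        dt = np.diff(self.time)
        off = np.flatnonzero(np.abs(dt - self.sample_interval) > TIME_TOL)
        if off.size:
            raise FormatError(
                f"non-uniform sampling at index {off[0] + 1}: "
                f"step {dt[off[0]]!r} != {self.sample_interval!r}"
            )
        return self

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return float(self.time[-1])


def _parse_metadata(path) -> dict:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def read_waveform(path, schema: dict | None = None) -> WaveformRecord:
    """Read and validate one session CSV.

    Parameters
    ----------
    path : str or Path
        CSV file in the dialect above (or any delimited export whose column
        names are supplied through `schema`).
    schema : dict, optional
        Mapping from canonical channel names (``time``, ``paw``, ``flow``,
        ``eadi``) to the column names used in the file.  Defaults to
        :data:`DEFAULT_SCHEMA`.

    Returns
    -------
    WaveformRecord
        Validated record.  Non-uniform time grids are rejected, never
        resampled.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    meta = _parse_metadata(path)
    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for key in ("time", "paw", "flow"):
        if colmap[key] not in frame.columns:
            raise SchemaError(
                f"missing column {colmap[key]!r} (channel {key!r}) in {path}"
            )
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = np.flatnonzero(coerced.isna() & frame[col].notna())
            if bad.size:
                raise DataError(
                    f"unparseable value {frame[col].iloc[bad[0]]!r} in column "
                    f"{col!r} at row {bad[0]}"
                )
            frame[col] = coerced
    time = frame[colmap["time"]].to_numpy(dtype=float)
    if time.size >= 2:
        interval = float(time[1] - time[0])
    else:
        raise FormatError(f"{path}: a session needs at least 2 samples")
    eadi = None
    if colmap["eadi"] in frame.columns:
        eadi = frame[colmap["eadi"]].to_numpy(dtype=float)
    record = WaveformRecord(
        patient_id=meta.get("patient_id", "unknown"),
        mode=meta.get("mode", "PS"),
        sample_interval=interval,
        time=time,
        paw=frame[colmap["paw"]].to_numpy(dtype=float),
        flow=frame[colmap["flow"]].to_numpy(dtype=float),
        eadi=eadi,
    )
    return record.validate()


def write_waveform(record: WaveformRecord, path) -> None:
    """Write `record` in the canonical dialect.

    The record is validated first; files are only produced for records that
    :func:`read_waveform` will accept, and the round trip is bit exact.
    """
    record.validate()
    columns = [("time_s", record.time), ("paw_cmH2O", record.paw),
               ("flow_L_s", record.flow)]
    if record.eadi is not None:
        columns.append(("eadi_uV", record.eadi))
    buf = _io.StringIO()
    buf.write(f"# patient_id: {record.patient_id}\n")
    buf.write(f"# mode: {record.mode}\n")
    buf.write("# units: time=s, paw=cmH2O, flow=L/s, eadi=uV\n")
    buf.write(",".join(name for name, _ in columns) + "\n")
    data = np.column_stack([ch for _, ch in columns])
    np.savetxt(buf, data, fmt=_FMT, delimiter=",")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


# -- elastance surface serialisation ------------------------------------
#
# Long-form CSV: one row per (breath, tau) grid point, preceded by the same
# '#' metadata block as session files.  Used by the CLI to hand surfaces
# between the compute / summarize / compare stages.

def write_surface(surface, path) -> None:
    """Serialise an :class:`~edrs.elastance.EdrsSurface` as long-form CSV."""
    buf = _io.StringIO()
    buf.write(f"# patient_id: {surface.patient_id}\n")
    buf.write(f"# mode: {surface.mode}\n")
    buf.write("breath_index,ti_s,tau,edrs_cmH2O_L,valid\n")
    for traj in surface.trajectories:
        for k in range(traj.tau.size):
            edrs = traj.edrs[k] if traj.valid[k] else np.nan
            buf.write(
                f"{traj.breath_index},{_FMT % traj.ti},{_FMT % traj.tau[k]},"
                f"{_FMT % edrs},{int(traj.valid[k])}\n"
            )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_surface(path):
    """Read a surface written by :func:`write_surface`."""
    from .elastance import EdrsSurface, EdrsTrajectory

    meta = _parse_metadata(path)
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    needed = {"breath_index", "ti_s", "tau", "edrs_cmH2O_L", "valid"}
    missing = needed - set(frame.columns)
    if missing:
        raise SchemaError(f"surface file {path} lacks columns {sorted(missing)}")
    trajectories = []
    for idx, group in frame.groupby("breath_index", sort=False):
        trajectories.append(
            EdrsTrajectory(
                breath_index=int(idx),
                tau=group["tau"].to_numpy(dtype=float),
                edrs=group["edrs_cmH2O_L"].to_numpy(dtype=float),
                valid=group["valid"].to_numpy(dtype=bool),
                ti=float(group["ti_s"].iloc[0]),
            )
        )
    if not trajectories:
        raise ConsistencyError(f"surface file {path} contains no trajectories")
    return EdrsSurface(
        patient_id=meta.get("patient_id", "unknown"),
        mode=meta.get("mode", "PS"),
        trajectories=trajectories,
    )
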