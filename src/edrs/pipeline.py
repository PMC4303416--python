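"""End-to-end orchestration: sessions in, per-patient report out.

Reads every session CSV in an input set, estimates each session's elastance
surface, writes the surfaces, summarises AUC per percentile level, and for
every patient with both ventilation modes runs the two-mode comparison.
The report mirrors a per-patient table: one row per patient, AUC per level
per mode, a significance column and the wider-variability mode.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import compare_modes
from .elastance import ModelParams, analyze_session
from .errors import EdrsError, SampleSizeError
from .io import read_waveform, write_surface
from .metrics import (
    DEFAULT_AUC_WINDOW,
    DEFAULT_LEVELS,
    SEVERITY_THRESHOLD,
    summarize_surface,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters in one place.

    Defaults are the values the elastance model is defined with: constant
    airway resistance 5 cmH2O*s/L, percentile levels {5, 25, 50, 75, 95},
    AUC window [0.3, 1.0] of normalised inspiration, severity threshold
    25 cmH2O*s/L and alpha 0.05.
    """

    rrs: float = 5.0
    v_min_frac: float = 0.02
    n_grid: int = 100
    q_on: float = 0.05
    t_min: float = 0.2
    peep_window: float = 0.05
    levels: tuple = DEFAULT_LEVELS
    auc_window: tuple = DEFAULT_AUC_WINDOW
    severity_threshold: float = SEVERITY_THRESHOLD
    alpha: float = 0.05
    schema: dict | None = None

    def model_params(self) -> ModelParams:
        return ModelParams(rrs=self.rrs, v_min_frac=self.v_min_frac, n_grid=self.n_grid)


def _collect_sessions(inputs) -> list[Path]:
    if isinstance(inputs, (str, os.PathLike)):
        root = Path(inputs)
        if root.is_dir():
            return sorted(root.glob("*.csv"))
        return [root]
    return [Path(p) for p in inputs]


def run_pipeline(inputs, out_dir, config: RunConfig | None = None) -> dict:
    """Run the full analysis over a set of session CSVs.

    Parameters
    ----------
    inputs : path or sequence of paths
        A directory of session CSVs, or explicit file paths.
    out_dir : path
        Output directory (created if absent).  Receives one surface CSV per
        session plus ``report.csv`` and ``comparison.csv``.
    config : RunConfig, optional

    Returns
    -------
    dict
        ``{"report": path, "comparison": path, "surfaces": [paths]}``.

    Any stage failure is re-raised with the stage and file named; partial
    outputs written before the failure are removed.
    """
    config = config or RunConfig()
    paths = _collect_sessions(inputs)
    if not paths:
        raise EdrsError(f"no sessions found in {inputs!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        surfaces: dict[tuple[str, str], object] = {}
        surface_paths = []
        for path in paths:
            stage = "read"
            try:
                record = read_waveform(path, schema=config.schema)
                stage = "compute"
                surface = analyze_session(
                    record,
                    params=config.model_params(),
                    q_on=config.q_on,
                    t_min=config.t_min,
                    peep_window=config.peep_window,
                )
            except EdrsError as exc:
                raise EdrsError(f"stage {stage!r} failed for {path}: {exc}") from exc
            key = (record.patient_id, record.mode)
            if key in surfaces:
                logger.warning(
                    "duplicate session for patient %s mode %s; keeping the first",
                    *key,
                )
                continue
            surfaces[key] = surface
            spath = out_dir / f"{record.patient_id}_{record.mode}_surface.csv"
            write_surface(surface, spath)
            written.append(spath)
            surface_paths.append(spath)

        patients = sorted({pid for pid, _ in surfaces})
        report_rows = []
        comparison_rows = []
        for pid in patients:
            row: dict = {"patient_id": pid}
            for mode in ("PS", "NAVA"):
                surface = surfaces.get((pid, mode))
                if surface is None:
                    continue
                result = summarize_surface(
                    surface,
                    levels=config.levels,
                    window=config.auc_window,
                    threshold=config.severity_threshold,
                )
                for level in result.levels:
                    row[f"auc_{mode.lower()}_p{level}"] = result.auc_per_level[level]
                row[f"severe_{mode.lower()}_p95"] = result.severity_flag_per_level[
                    max(result.levels)
                ]
                row[f"n_breaths_{mode.lower()}"] = result.n_breaths
            ps = surfaces.get((pid, "PS"))
            nava = surfaces.get((pid, "NAVA"))
            if ps is not None and nava is not None:
                try:
                    cmp = compare_modes(
                        ps, nava, alpha=config.alpha, window=config.auc_window
                    )
                except SampleSizeError as exc:
                    logger.warning("patient %s: %s", pid, exc)
                else:
                    row["ks_p"] = cmp.ks_p
                    row["significant"] = cmp.significant
                    wider = {"A": "PS", "B": "NAVA", "tie": "tie"}[cmp.wider_mode]
                    row["wider_mode"] = wider
                    comparison_rows.append(
                        {
                            "patient_id": pid,
                            "ks_statistic": cmp.ks_statistic,
                            "ks_p": cmp.ks_p,
                            "wilcoxon_p": cmp.wilcoxon_p,
                            "significant": cmp.significant,
                            "range_width_ps": cmp.range_width_a,
                            "range_width_nava": cmp.range_width_b,
                            "wider_mode": wider,
                            "n_breaths_ps": cmp.n_breaths_a,
                            "n_breaths_nava": cmp.n_breaths_b,
                        }
                    )
            report_rows.append(row)

        report_path = out_dir / "report.csv"
        pd.DataFrame(report_rows).to_csv(report_path, index=False, float_format="%.6g")
        written.append(report_path)
        comparison_path = out_dir / "comparison.csv"
        pd.DataFrame(comparison_rows).to_csv(
            comparison_path, index=False, float_format="%.6g"
        )
        written.append(comparison_path)
    except Exception:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise
    return {
        "report": report_path,
        "comparison": comparison_path,
        "surfaces": surface_paths,
    }


def plot_surface(surface, path) -> None:
    """Breath-ordered elastance surface as a PNG (non-contractual extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = surface.matrix()
    fig, ax = plt.subplots(figsize=(6, 4))
    mesh = ax.pcolormesh(
        surface.tau, np.arange(surface.n_breaths), mat, shading="nearest"
    )
    fig.colorbar(mesh, ax=ax, label="E_drs (cmH2O/L)")
    ax.set_xlabel("normalised inspiratory time")
    ax.set_ylabel("breath")
    ax.set_title(f"{surface.patient_id} {surface.mode}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_percentiles(surface, path, levels=DEFAULT_LEVELS) -> None:
    """Percentile elastance curves as a PNG (non-contractual extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .metrics import percentile_trajectories

    summary = percentile_trajectories(surface, levels)
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, level in enumerate(summary.levels):
        ax.plot(summary.tau, summary.values[i], label=f"{level}th")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("normalised inspiratory time")
    ax.set_ylabel("E_drs (cmH2O/L)")
    ax.set_title(f"{surface.patient_id} {surface.mode}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
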