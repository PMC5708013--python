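"""Results serialization: probe/field CSVs, damage JSON, run manifest.

All numerics are written with 9 significant digits so reruns of the same
configuration produce byte-identical files.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .damage import DamageResult, burn_depth
from .scenarios import CaseResult

__all__ = ["write_results", "damage_summary"]

_FLOAT_FMT = "%.9g"


def damage_summary(result: CaseResult, include_depth: bool = True) -> dict[str, Any]:
    """JSON-ready damage summary for one scenario run."""
    dmg: DamageResult = result.damage
    depth = burn_depth(result.history) if include_depth else None
    return {
        "case": result.case.id,
        "omega_final": round(dmg.omega_final, 9),
        "undamaged_fraction": round(dmg.undamaged_fraction, 9),
        "burn_class": dmg.burn_class,
        "burn_depth_m": None if depth is None else round(depth, 9),
        "time_above_43C_s": round(dmg.time_above_threshold, 9),
        "basal_peak_C": round(result.basal_peak_temp, 9),
        "basal_peak_time_s": round(result.basal_peak_time, 9),
    }


def _probe_frame(result: CaseResult) -> pd.DataFrame:
    h = result.history
    data = {"time_s": h.times}
    data.update(h.probes)
    return pd.DataFrame(data)


def _field_frame(result: CaseResult) -> pd.DataFrame:
    """Long-format field snapshots: time_s, depth_m, temp_C (skin only)."""
    h = result.history
    nt, nx = h.skin_fields.shape
    return pd.DataFrame(
        {
            "time_s": np.repeat(h.field_times, nx),
            "depth_m": np.tile(h.skin_nodes, nt),
            "temp_C": h.skin_fields.ravel(),
        }
    )


def _omega_frame(result: CaseResult) -> pd.DataFrame:
    dmg = result.damage
    return pd.DataFrame(
        {
            "time_s": dmg.times,
            "basal_temp_C": result.history.basal,
            "omega": dmg.omega_series,
            "undamaged_fraction": np.exp(-dmg.omega_series),
        }
    )


def write_results(
    results: list[CaseResult],
    out_dir: str | Path,
    *,
    config_snapshot: dict[str, Any] | None = None,
    write_fields: bool = False,
) -> list[Path]:
    """Write per-case CSV/JSON artifacts plus a run manifest.

    Emits, per case: ``<id>_probes.csv``, ``<id>_omega.csv``,
    ``<id>_damage.json`` and optionally ``<id>_field.csv``; for multi-case
    runs also ``cases.csv`` (one summary row per case); always
    ``manifest.json`` listing every artifact with the config snapshot and
    the stability report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_csv(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)

    for result in results:
        cid = result.case.id
        emit_csv(_probe_frame(result), f"{cid}_probes.csv")
        emit_csv(_omega_frame(result), f"{cid}_omega.csv")
        if write_fields:
            emit_csv(_field_frame(result), f"{cid}_field.csv")
        path = out / f"{cid}_damage.json"
        path.write_text(json.dumps(damage_summary(result), indent=2) + "\n")
        written.append(path)

    if len(results) > 1:
        rows = [
            {
                "case": r.case.id,
                "Lepi_um": r.case.L_epi_um,
                "Lfabric_mm": r.case.L_fabric_mm,
                "Tw_C": r.case.T_spill,
                "toff_s": r.case.t_off,
                "tcool_s": r.case.t_cool,
                "omega": r.omega_final,
                "burn_class": r.burn_class,
            }
            for r in results
        ]
        emit_csv(pd.DataFrame(rows), "cases.csv")

    manifest = {
        "software": {"name": "scaldsim", "version": __version__},
        "timestamp_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "config": config_snapshot,
        "stability_report": results[0].history.stability_report if results else None,
        "cases": [r.case.id for r in results],
        "artifacts": [p.name for p in written] + ["manifest.json"],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    written.append(manifest_path)
    return written
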