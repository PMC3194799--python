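"""Result writers: CSV data, JSON metadata sidecars, and a checksum manifest.

Every output directory is self-describing: the metadata sidecar records the
parameters, seeds, thresholds and software version that produced the CSVs,
and the manifest lists each file with its SHA-256 checksum.  Deterministic
analyses re-run from the same config reproduce the CSVs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bifurcation import BranchDiagram, PhaseDiagram2D
from .dynamics import Trajectory
from .ensemble import EnsembleResult
from .steady_states import steady_state_table

__all__ = ["write_results"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_meta(outdir: Path, payload: dict) -> Path:
    payload = dict(payload)
    payload["software_version"] = __version__
    payload["written_at"] = datetime.now(timezone.utc).isoformat()
    path = outdir / "metadata.json"
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))
    return path


def _branch_frames(d: BranchDiagram) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for alpha, states in zip(d.alpha_grid, d.states):
        q = d.params.with_alpha(float(alpha))
        rows.append(steady_state_table(q, states))
    branch = pd.concat(rows, ignore_index=True)
    points = pd.DataFrame(
        [
            {
                "kind": b.kind,
                "alpha_at": b.alpha_at,
                "phi_at": b.phi_at,
                "bracket_width": b.bracket_width,
            }
            for b in d.saddle_nodes + d.hopf_points
        ]
    )
    return branch, points


def write_results(result, outdir) -> dict:
    """Write a result object; returns the file manifest (name -> sha256)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    if isinstance(result, BranchDiagram):
        branch, points = _branch_frames(result)
        f1 = outdir / "branches.csv"
        branch.to_csv(f1, index=False)
        f2 = outdir / "bifurcation_points.csv"
        points.to_csv(f2, index=False)
        files += [f1, f2]
        files.append(
            _write_meta(
                outdir,
                {
                    "result": "branch_diagram",
                    "params": result.params,
                    "alpha_grid": {
                        "start": result.alpha_grid[0],
                        "stop": result.alpha_grid[-1],
                        "num": len(result.alpha_grid),
                    },
                    "switch_character": result.switch_character,
                },
            )
        )
    elif isinstance(result, PhaseDiagram2D):
        mat = pd.DataFrame(
            result.labels, index=result.y_grid, columns=result.x_grid
        )
        f1 = outdir / "regime_matrix.csv"
        mat.to_csv(f1, index_label=f"{result.y_param}\\{result.x_param}")
        rows = [
            {"kind": "saddle_node", result.x_param: x, result.y_param: y}
            for x, y in result.saddle_node_boundary
        ] + [
            {"kind": "hopf", result.x_param: x, result.y_param: y}
            for x, y in result.hopf_boundary
        ]
        f2 = outdir / "boundaries.csv"
        pd.DataFrame(rows).to_csv(f2, index=False)
        files += [f1, f2]
        files.append(
            _write_meta(
                outdir,
                {
                    "result": "phase_diagram",
                    "mode": result.mode,
                    "fixed": result.fixed,
                    "x_param": result.x_param,
                    "y_param": result.y_param,
                },
            )
        )
    elif isinstance(result, Trajectory):
        df = pd.DataFrame(
            {"t": result.t, "alpha_t": result.alpha, "phi": result.phi,
             "mu": result.mu}
        )
        f1 = outdir / "trajectory.csv"
        df.to_csv(f1, index=False)
        files.append(f1)
        files.append(
            _write_meta(
                outdir,
                {"result": "trajectory", "protocol": result.protocol,
                 "integrator": result.meta},
            )
        )
    elif isinstance(result, EnsembleResult):
        df = pd.DataFrame(
            {"t": result.t, "F": result.fraction, "F_occupancy": result.occupancy}
        )
        f1 = outdir / "fraction.csv"
        df.to_csv(f1, index=False)
        f2 = outdir / "first_transition_times.csv"
        pd.DataFrame(
            {
                "cell": np.arange(result.n_cells),
                "seed": result.base_seed + np.arange(result.n_cells),
                "first_transition_time": result.first_transition_times,
            }
        ).to_csv(f2, index=False)
        files += [f1, f2]
        files.append(
            _write_meta(
                outdir,
                {
                    "result": "ensemble",
                    "n_cells": result.n_cells,
                    "base_seed": result.base_seed,
                    "threshold": result.threshold,
                    "threshold_rule": result.threshold_rule,
                    "params": result.params,
                    "protocol": result.protocol,
                    "run": result.meta,
                },
            )
        )
    elif isinstance(result, pd.DataFrame):
        f1 = outdir / "table.csv"
        result.to_csv(f1, index=False)
        files.append(f1)
        files.append(_write_meta(outdir, {"result": "table"}))
    else:
        raise TypeError(f"don't know how to write {type(result).__name__}")

    manifest = {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in files
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
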