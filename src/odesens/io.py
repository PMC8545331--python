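"""Result serialization: TSV mirrors, hierarchical HDF5 files and JSON."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np


def trajectory_to_tsv(traj, model, path):
    """Column-oriented table: time, states, outputs."""
    header = ["time"] + [f"x_{s}" for s in model.state_ids] + [
        f"y_{o}" for o in model.observable_ids
    ]
    lines = ["\t".join(header)]
    for i, t in enumerate(traj.timepoints):
        row = [repr(float(t))]
        row += [repr(float(v)) for v in traj.states[i]]
        row += [repr(float(v)) for v in traj.outputs[i]]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def save_results_h5(path, model, trajectory=None, forward=None, gradient=None,
                    meta=None):
    """One hierarchical results file per run.

    Groups: ``meta`` (ids and free-form attributes), ``trajectory`` (time, x,
    y, solver stats), ``sensitivities`` (sx, sy) and ``gradient`` (value,
    gradient, method).
    """
    with h5py.File(path, "w") as f:
        g = f.create_group("meta")
        g.attrs["model"] = model.name
        g.create_dataset("state_ids", data=np.array(model.state_ids, dtype="S"))
        g.create_dataset(
            "parameter_ids", data=np.array(model.parameter_ids, dtype="S")
        )
        g.create_dataset(
            "observable_ids", data=np.array(model.observable_ids, dtype="S")
        )
        for key, val in (meta or {}).items():
            g.attrs[key] = val
        traj = trajectory if trajectory is not None else (
            forward.trajectory if forward is not None else None
        )
        if traj is not None:
            g = f.create_group("trajectory")
            g.create_dataset("time", data=np.asarray(traj.timepoints))
            g.create_dataset("x", data=np.asarray(traj.states))
            g.create_dataset("y", data=np.asarray(traj.outputs))
            g.attrs["steps"] = traj.stats.steps
            g.attrs["rhs_evaluations"] = traj.stats.rhs_evaluations
            g.attrs["jacobian_evaluations"] = traj.stats.jacobian_evaluations
        if forward is not None:
            g = f.create_group("sensitivities")
            g.create_dataset("sx", data=np.asarray(forward.sx))
            g.create_dataset("sy", data=np.asarray(forward.sy))
        if gradient is not None:
            g = f.create_group("gradient")
            g.create_dataset("value", data=float(gradient.value))
            g.create_dataset("gradient", data=np.asarray(gradient.gradient))
            g.attrs["method"] = gradient.method


def gradient_to_json(result, parameter_ids, path=None):
    """Gradient result as JSON: value, per-parameter gradient, method."""
    payload = {
        "value": float(result.value),
        "gradient": {
            pid: float(g) for pid, g in zip(parameter_ids, result.gradient)
        },
        "method": result.method,
        "conditions": {
            "|".join(k) if isinstance(k, tuple) else str(k): {
                "value": float(v["value"]),
                "n_measurements": int(v.get("n_measurements", 0)),
            }
            for k, v in result.per_condition.items()
        },
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return payload
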