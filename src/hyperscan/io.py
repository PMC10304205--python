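"""Container I/O: HDF5 recordings, YAML coil configs, CSV exports."""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .coilfield import CoilArray, WireLoop
from .forward import Pose, Recording


# ---------------------------------------------------------------------------
# Recording container (HDF5)
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path) -> None:
    """Write a Recording to HDF5.

    Layout: ``/data`` (channels x samples, float64 tesla), ``/channels``
    (table), ``/events`` (table), ``/pose/<helmet_id>`` (timestamped
    transforms as times, quaternions, translations), plus ``sample_rate``
    as a root attribute.
    """
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["sample_rate"] = rec.sample_rate
        f.create_dataset("data", data=rec.data)
        ch = f.create_group("channels")
        ch.create_dataset(
            "name", data=np.array(rec.channel_table["name"], dtype="S64")
        )
        ch.create_dataset(
            "helmet", data=np.array(rec.channel_table["helmet"], dtype="S64")
        )
        ch.create_dataset(
            "sensor_index", data=np.asarray(rec.channel_table["sensor_index"], int)
        )
        ev = f.create_group("events")
        ev.create_dataset("time", data=np.asarray(rec.events["time"], float))
        ev.create_dataset("code", data=np.array(rec.events["code"], dtype="S16"))
        pg = f.create_group("pose")
        for helmet_id, pose in rec.poses.items():
            g = pg.create_group(str(helmet_id))
            g.create_dataset("times", data=pose.times)
            g.create_dataset("quaternions", data=pose.rotations.as_quat())
            g.create_dataset("translations", data=pose.translations)


def load_recording(path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["data"][()]
        sample_rate = float(f.attrs["sample_rate"])
        channel_table = pd.DataFrame(
            {
                "name": [s.decode() for s in f["channels/name"][()]],
                "helmet": [s.decode() for s in f["channels/helmet"][()]],
                "sensor_index": f["channels/sensor_index"][()],
            }
        )
        events = pd.DataFrame(
            {
                "time": f["events/time"][()],
                "code": [s.decode() for s in f["events/code"][()]],
            }
        )
        poses = {}
        for helmet_id, g in f["pose"].items():
            poses[helmet_id] = Pose(
                g["times"][()],
                Rotation.from_quat(g["quaternions"][()]),
                g["translations"][()],
            )
    return Recording(data, sample_rate, channel_table, events, poses)


# ---------------------------------------------------------------------------
# Coil geometry (YAML / CSV)
# ---------------------------------------------------------------------------

def coil_array_to_yaml(array: CoilArray, path) -> None:
    doc = {
        "plane_separation": float(array.plane_separation),
        "side_length": float(array.side_length),
        "coils": [
            {
                "id": int(i),
                "plane": int(pid[0]),
                "grid": str(pid[1]),
                "row": int(pid[2]),
                "col": int(pid[3]),
                "turns": int(c.turns),
                "vertices": np.asarray(c.vertices).tolist(),
            }
            for i, (c, pid) in enumerate(zip(array.coils, array.layout_ids))
        ],
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f)


def coil_array_from_yaml(path) -> CoilArray:
    with open(path) as f:
        doc = yaml.safe_load(f)
    coils = []
    ids = []
    for entry in doc["coils"]:
        coils.append(WireLoop(np.array(entry["vertices"], float), int(entry["turns"])))
        ids.append((entry["plane"], entry["grid"], entry["row"], entry["col"]))
    return CoilArray(
        tuple(coils),
        float(doc["plane_separation"]),
        float(doc["side_length"]),
        tuple(ids),
    )


def coil_array_to_csv(array: CoilArray, path) -> None:
    """One row per vertex: coil_id, plane, turn_count, x, y, z (metres)."""
    rows = []
    for i, (c, pid) in enumerate(zip(array.coils, array.layout_ids)):
        for v in c.vertices:
            rows.append(
                {
                    "coil_id": i,
                    "plane": pid[0],
                    "turn_count": c.turns,
                    "x": v[0],
                    "y": v[1],
                    "z": v[2],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Nulling log (HDF5 + CSV summary)
# ---------------------------------------------------------------------------

def save_nulling_log(result, path) -> None:
    """Store the quantities a nulling run produces.

    Datasets: ``/pre_fields``, ``/post_fields``, ``/A``,
    ``/final_currents``, ``/final_voltages``, ``/residual_norms``.
    """
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("pre_fields", data=result.pre_fields)
        f.create_dataset("post_fields", data=result.post_fields)
        f.create_dataset("A", data=result.calibration.A)
        f.create_dataset("final_currents", data=result.state.x)
        f.create_dataset("final_voltages", data=result.final_voltages)
        f.create_dataset("residual_norms", data=np.asarray(result.residual_norms))
        f.attrs["converged"] = bool(result.converged)
        f.attrs["iterations"] = int(result.state.iteration)


def nulling_summary_csv(result, path) -> None:
    """Per-measurement summary: label, pre-field and post-field in nT."""
    labels = result.calibration.row_labels
    pd.DataFrame(
        {
            "measurement": ["%s/ax%d" % (s, a) for s, a in labels],
            "pre_nT": np.asarray(result.pre_fields) * 1e9,
            "post_nT": np.asarray(result.post_fields) * 1e9,
        }
    ).to_csv(path, index=False)
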