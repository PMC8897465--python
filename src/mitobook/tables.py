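"""CSV exchange schemas for traces, ACFs, spots, and activation tables.

Column schemas
--------------
FRAP traces (long format): nucleus_id, time_s, I_bl, I_unbl, I_out
ACF curves: lag_s, G  (optional: weight)
Activation records: nucleus_id, movie_id, mother_state, t_activation_s
    (empty = censored), t_end_s
Spots: frame, z, y, x, intensity  (voxel coordinates)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fcs import AcfCurve
from .frap import FrapTrace
from .imaging import Spot, SpotSet
from .memory import ActivationRecord

__all__ = [
    "read_frap_traces_csv",
    "write_frap_traces_csv",
    "read_acf_csv",
    "write_acf_csv",
    "read_activation_records_csv",
    "write_activation_records_csv",
    "read_spots_csv",
    "write_spots_csv",
]


def read_frap_traces_csv(
    path: str | Path, n_prebleach: int = 10, bleach_index: int | None = None
) -> dict[str, FrapTrace]:
    df = pd.read_csv(path)
    out = {}
    for nid, grp in df.groupby("nucleus_id", sort=True):
        grp = grp.sort_values("time_s")
        out[str(nid)] = FrapTrace(
            times=grp["time_s"].to_numpy(),
            I_bl=grp["I_bl"].to_numpy(),
            I_unbl=grp["I_unbl"].to_numpy(),
            I_out=grp["I_out"].to_numpy(),
            n_prebleach=n_prebleach,
            bleach_index=n_prebleach if bleach_index is None else bleach_index,
        )
    return out


def write_frap_traces_csv(traces: dict[str, FrapTrace], path: str | Path) -> None:
    frames = []
    for nid, tr in traces.items():
        frames.append(
            pd.DataFrame(
                {
                    "nucleus_id": nid,
                    "time_s": tr.times,
                    "I_bl": tr.I_bl,
                    "I_unbl": tr.I_unbl,
                    "I_out": tr.I_out,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_acf_csv(path: str | Path) -> AcfCurve:
    df = pd.read_csv(path)
    return AcfCurve(
        lags=df["lag_s"].to_numpy(),
        G=df["G"].to_numpy(),
        weights=df["weight"].to_numpy() if "weight" in df else None,
    )


def write_acf_csv(curve: AcfCurve, path: str | Path) -> None:
    df = pd.DataFrame({"lag_s": curve.lags, "G": curve.G})
    if curve.weights is not None:
        df["weight"] = curve.weights
    df.to_csv(path, index=False)


def read_activation_records_csv(path: str | Path) -> list[ActivationRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        t_act = row["t_activation_s"]
        records.append(
            ActivationRecord(
                nucleus_id=str(row["nucleus_id"]),
                movie_id=str(row["movie_id"]),
                mother_state=str(row["mother_state"]),
                t_activation=None if pd.isna(t_act) else float(t_act),
                t_end=float(row["t_end_s"]),
            )
        )
    return records


def write_activation_records_csv(
    records: list[ActivationRecord], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "nucleus_id": [r.nucleus_id for r in records],
            "movie_id": [r.movie_id for r in records],
            "mother_state": [r.mother_state for r in records],
            "t_activation_s": [
                r.t_activation if r.observed else np.nan for r in records
            ],
            "t_end_s": [r.t_end for r in records],
        }
    ).to_csv(path, index=False)


def read_spots_csv(
    path: str | Path, voxel_xy: float = 1.0, voxel_z: float = 1.0
) -> SpotSet:
    df = pd.read_csv(path)
    spots = [
        Spot(
            center=(row.z, row.y, row.x),
            center_um=(row.z * voxel_z, row.y * voxel_xy, row.x * voxel_xy),
            total_intensity=float(row.intensity),
            n_voxels=int(getattr(row, "n_voxels", 0)),
            frame=int(row.frame),
        )
        for row in df.itertuples()
    ]
    return SpotSet(spots, voxel_xy, voxel_z)


def write_spots_csv(spots: SpotSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame": [s.frame for s in spots],
            "z": [s.center[0] for s in spots],
            "y": [s.center[1] for s in spots],
            "x": [s.center[2] for s in spots],
            "intensity": [s.total_intensity for s in spots],
            "n_voxels": [s.n_voxels for s in spots],
        }
    ).to_csv(path, index=False)
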