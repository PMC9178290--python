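"""Interchange data model and file formats for simulation result bundles.

A result bundle is one directory per (run, direction) holding:

* ``kinematics.csv`` — time plus the six Grood & Suntay joint coordinates
  (rotations in degrees, translations in mm), one row per converged time step;
* ``contact.csv`` — long-format per-face contact fields on the tibial
  cartilage articulating surfaces: time, side (medial/lateral), face id,
  face-centroid coordinates (mm) and contact pressure (N/mm^2, i.e. MPa);
* ``convergence.json`` — the last converged time step, an early-termination
  flag, run identity (plan id, model id, direction) and the schema version.

Units are fixed throughout: mm, degrees, N/mm^2 (MPa), Nmm.  Writes are
deterministic (stable column order, sorted rows, fixed float formatting) so
identical results produce byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA_VERSION",
    "DOF_COLUMNS",
    "SIDES",
    "BundleError",
    "KinematicsSeries",
    "ContactFrame",
    "ConvergenceRecord",
    "SimulationResult",
    "read_result_bundle",
    "write_result_bundle",
]

SCHEMA_VERSION = "1.0"

#: The six joint-coordinate DOF (Grood & Suntay): three rotations in degrees,
#: three translations in mm.
DOF_COLUMNS = (
    "flexion_deg",
    "valgus_deg",
    "internal_rotation_deg",
    "anterior_mm",
    "distal_mm",
    "lateral_mm",
)

SIDES = ("medial", "lateral")

_FLOAT_FMT = "%.9g"


class BundleError(ValueError):
    """Raised when a result bundle is missing, malformed or inconsistent."""


@dataclass(frozen=True)
class KinematicsSeries:
    """Six-DOF joint kinematics at the converged time steps of one run."""

    times: np.ndarray  # strictly increasing
    values: np.ndarray  # (n_times, 6), columns as DOF_COLUMNS

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.shape != (times.size, len(DOF_COLUMNS)):
            raise BundleError(
                f"kinematics shape mismatch: {times.size} times vs values {values.shape}"
            )
        if times.size and not np.all(np.diff(times) > 0):
            raise BundleError("kinematics times must be strictly increasing")
        if not (np.isfinite(times).all() and np.isfinite(values).all()):
            raise BundleError("kinematics contain non-finite entries")

    def dof(self, name: str) -> np.ndarray:
        return self.values[:, DOF_COLUMNS.index(name)]

    @property
    def valgus(self) -> np.ndarray:
        return self.dof("valgus_deg")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(DOF_COLUMNS))
        df.insert(0, "time", self.times)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KinematicsSeries":
        missing = [c for c in ("time", *DOF_COLUMNS) if c not in df.columns]
        if missing:
            raise BundleError(f"kinematics table missing column(s): {', '.join(missing)}")
        return cls(df["time"].to_numpy(float), df[list(DOF_COLUMNS)].to_numpy(float))


@dataclass(frozen=True)
class ContactFrame:
    """Per-face contact pressure field on one tibial compartment at one time."""

    time: float
    side: str
    face_ids: np.ndarray  # (n,) int, unique
    centroids: np.ndarray  # (n, 3) mm
    pressures: np.ndarray  # (n,) N/mm^2, >= 0

    def __post_init__(self) -> None:
        face_ids = np.asarray(self.face_ids, dtype=int)
        centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 3)
        pressures = np.asarray(self.pressures, dtype=float)
        object.__setattr__(self, "face_ids", face_ids)
        object.__setattr__(self, "centroids", centroids)
        object.__setattr__(self, "pressures", pressures)
        if self.side not in SIDES:
            raise BundleError(f"unknown side {self.side!r} (expected medial/lateral)")
        n = face_ids.size
        if centroids.shape != (n, 3) or pressures.shape != (n,):
            raise BundleError("contact frame arrays have inconsistent lengths")
        if np.unique(face_ids).size != n:
            raise BundleError(f"duplicate face ids in contact frame at t={self.time}")
        if not np.isfinite(centroids).all():
            raise BundleError(f"non-finite centroid in contact frame at t={self.time}")
        neg = np.where(pressures < 0)[0]
        if neg.size:
            raise BundleError(
                f"negative pressure at t={self.time}, side={self.side}, "
                f"face_id={int(face_ids[neg[0]])}"
            )

    @property
    def n_faces(self) -> int:
        return int(self.face_ids.size)


@dataclass(frozen=True)
class ConvergenceRecord:
    last_converged_time: float
    terminated_early: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.last_converged_time <= 3.0:
            raise BundleError(
                f"last_converged_time {self.last_converged_time} outside [0, 3]"
            )


@dataclass(frozen=True)
class SimulationResult:
    """Everything the analysis needs from one varus or valgus run."""

    plan_id: str  # "original" for the baseline run
    model_id: str
    direction: str
    kinematics: KinematicsSeries
    contact_frames: tuple[ContactFrame, ...]
    convergence: ConvergenceRecord

    def __post_init__(self) -> None:
        object.__setattr__(self, "contact_frames", tuple(self.contact_frames))
        if self.direction not in ("varus", "valgus"):
            raise BundleError(f"unknown direction {self.direction!r}")
        t_last = self.convergence.last_converged_time
        if self.kinematics.times.size and self.kinematics.times[-1] > t_last + 1e-9:
            raise BundleError(
                f"kinematics extend to t={self.kinematics.times[-1]} beyond "
                f"last converged time {t_last}"
            )
        for frame in self.contact_frames:
            if frame.time > t_last + 1e-9:
                raise BundleError(
                    f"contact frame at t={frame.time} beyond last converged time {t_last}"
                )

    @property
    def is_baseline(self) -> bool:
        return self.plan_id == "original"

    def frame_at(self, time: float, side: str, atol: float = 1e-6) -> ContactFrame | None:
        for frame in self.contact_frames:
            if frame.side == side and abs(frame.time - time) <= atol:
                return frame
        return None


# ---------------------------------------------------------------------------
# serialization

_KINEMATICS_FILE = "kinematics.csv"
_CONTACT_FILE = "contact.csv"
_CONVERGENCE_FILE = "convergence.json"
_CONTACT_COLUMNS = ("time", "side", "face_id", "cx_mm", "cy_mm", "cz_mm", "pressure_mpa")


def write_result_bundle(result: SimulationResult, path: str | Path) -> Path:
    """Write one bundle directory; byte-stable given identical input."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    result.kinematics.to_frame().to_csv(
        out / _KINEMATICS_FILE, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )

    rows = []
    for frame in result.contact_frames:
        rows.append(
            pd.DataFrame(
                {
                    "time": frame.time,
                    "side": frame.side,
                    "face_id": frame.face_ids,
                    "cx_mm": frame.centroids[:, 0],
                    "cy_mm": frame.centroids[:, 1],
                    "cz_mm": frame.centroids[:, 2],
                    "pressure_mpa": frame.pressures,
                }
            )
        )
    if rows:
        contact = pd.concat(rows, ignore_index=True)
        contact = contact.sort_values(["time", "side", "face_id"], kind="mergesort")
    else:
        contact = pd.DataFrame(columns=list(_CONTACT_COLUMNS))
    contact.to_csv(
        out / _CONTACT_FILE, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )

    meta = {
        "schema_version": SCHEMA_VERSION,
        "plan_id": result.plan_id,
        "model_id": result.model_id,
        "direction": result.direction,
        "last_converged_time": result.convergence.last_converged_time,
        "terminated_early": result.convergence.terminated_early,
    }
    (out / _CONVERGENCE_FILE).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return out


def read_result_bundle(path: str | Path) -> SimulationResult:
    """Read and validate one bundle directory.

    Invariant violations (non-monotone times, negative pressure, unknown side,
    contact beyond the last converged time, unknown schema major version) are
    rejected with diagnostics naming the file and offending row.
    """
    root = Path(path)
    for name in (_KINEMATICS_FILE, _CONTACT_FILE, _CONVERGENCE_FILE):
        if not (root / name).is_file():
            raise BundleError(f"bundle {root} is missing {name}")

    meta = json.loads((root / _CONVERGENCE_FILE).read_text())
    version = str(meta.get("schema_version", ""))
    if version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise BundleError(
            f"{root / _CONVERGENCE_FILE}: unsupported schema version {version!r}"
        )

    try:
        kinematics = KinematicsSeries.from_frame(pd.read_csv(root / _KINEMATICS_FILE))
    except BundleError as exc:
        raise BundleError(f"{root / _KINEMATICS_FILE}: {exc}") from exc

    contact = pd.read_csv(root / _CONTACT_FILE)
    missing = [c for c in _CONTACT_COLUMNS if c not in contact.columns]
    if missing:
        raise BundleError(f"{root / _CONTACT_FILE}: missing column(s) {', '.join(missing)}")
    frames: list[ContactFrame] = []
    if len(contact):
        for (time, side), grp in contact.groupby(["time", "side"], sort=True):
            try:
                frames.append(
                    ContactFrame(
                        time=float(time),
                        side=str(side),
                        face_ids=grp["face_id"].to_numpy(int),
                        centroids=grp[["cx_mm", "cy_mm", "cz_mm"]].to_numpy(float),
                        pressures=grp["pressure_mpa"].to_numpy(float),
                    )
                )
            except BundleError as exc:
                raise BundleError(
                    f"{root / _CONTACT_FILE}: rows for t={time}, side={side}: {exc}"
                ) from exc

    try:
        convergence = ConvergenceRecord(
            last_converged_time=float(meta["last_converged_time"]),
            terminated_early=bool(meta["terminated_early"]),
        )
        return SimulationResult(
            plan_id=str(meta["plan_id"]),
            model_id=str(meta["model_id"]),
            direction=str(meta["direction"]),
            kinematics=kinematics,
            contact_frames=tuple(frames),
            convergence=convergence,
        )
    except KeyError as exc:
        raise BundleError(f"{root / _CONVERGENCE_FILE}: missing field {exc}") from exc
    except BundleError as exc:
        raise BundleError(f"bundle {root}: {exc}") from exc
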