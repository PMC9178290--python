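"""One-at-a-time perturbation design for knee finite-element sensitivity studies.

The study varies one modelling parameter at a time around a calibrated
baseline model and reruns a varus and a valgus simulation for every perturbed
configuration.  Four categories of parameters are covered:

* ligament / meniscus material properties (per-ligament prestretch factor and
  Young's modulus sweeps, ligament attachment node-set halving, meniscus horn
  spring stiffness),
* the sliding-elastic cartilage contact formulation (penalty factor,
  Augmented Lagrangian, auto-penalty, two-pass, search radius),
* simulation control settings (Quasi-Newton update method, displacement
  tolerance),
* rigid cylindrical joint (RCJ) penalties and tolerances.

This module enumerates that design deterministically, models the loading
schedule of the simulations (settling phases followed by a linear
varus/valgus moment ramp to +/-40,000 Nmm), and implements the geometric
halving rule for ligament attachment node sets.
"""

from __future__ import annotations

import enum
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Category",
    "ParameterAxis",
    "PerturbationPlan",
    "LoadingSchedule",
    "Phase",
    "AttachmentNodeSet",
    "ModelBaselines",
    "DesignError",
    "LIGAMENTS",
    "MODEL_MASSES_KG",
    "PRESTRETCH_STEP",
    "YOUNGS_MODULUS_STEP_MPA",
    "MOMENT_MAGNITUDE_NMM",
    "HORN_SPRINGS_PER_ATTACHMENT",
    "prestretch_values",
    "youngs_modulus_values",
    "attachment_combinations",
    "halve_node_set",
    "build_axes",
    "enumerate_design",
    "applied_moment_at",
    "make_schedule",
    "axial_load_newtons",
    "horn_stiffness_total_range",
    "design_manifest",
    "write_design_manifest",
]

LIGAMENTS = ("ACL", "PCL", "MCL", "LCL")

#: Specimen masses in kg used to derive the model-specific 0.5-body-weight
#: axial load.
MODEL_MASSES_KG = {"du02": 70.31, "oks001": 77.10, "oks003": 68.0, "oks006": 49.4}

PRESTRETCH_STEP = 0.025
PRESTRETCH_HALF_RANGE = 0.1
YOUNGS_MODULUS_STEP_MPA = 25.0
YOUNGS_MODULUS_HALF_RANGE_MPA = 100.0
MOMENT_MAGNITUDE_NMM = 40_000.0
HORN_SPRINGS_PER_ATTACHMENT = 18
GRAVITY_M_S2 = 9.81


class DesignError(ValueError):
    """Raised for invalid or incomplete design configuration."""


class Category(enum.Enum):
    LIGAMENT_MENISCUS = "ligament_meniscus"
    CONTACT = "contact"
    CONTROL = "control"
    RCJ = "rcj"


_CATEGORY_ORDER = {c: i for i, c in enumerate(Category)}


@dataclass(frozen=True)
class ParameterAxis:
    """One parameter of interest: its baseline and the perturbed values.

    ``values`` excludes the baseline (the baseline configuration is the
    original simulation, never re-enumerated).  ``per_structure`` tags axes
    swept once per ligament (ACL/PCL/MCL/LCL).
    """

    name: str
    category: Category
    baseline: object
    values: tuple
    per_structure: str | None = None

    def __post_init__(self) -> None:
        if not self.values:
            raise DesignError(f"axis {self.name!r} has an empty values list")
        if any(v == self.baseline for v in self.values):
            raise DesignError(
                f"axis {self.name!r}: baseline {self.baseline!r} must not appear "
                "in the perturbed values"
            )
        if self.per_structure is not None and self.per_structure not in LIGAMENTS:
            raise DesignError(f"unknown ligament tag {self.per_structure!r}")


@dataclass(frozen=True)
class PerturbationPlan:
    """A single one-at-a-time configuration: one axis moved to one value."""

    model_id: str
    axis: str
    category: Category
    value: object
    structure: str | None = None

    @property
    def plan_id(self) -> str:
        parts = [self.model_id, self.axis, self.structure or "-", _value_token(self.value)]
        return "__".join(parts)

    @property
    def parameter_of_interest(self) -> str:
        """Grouping key: all values of one swept parameter share it."""
        return f"{self.axis}[{self.structure}]" if self.structure else self.axis


def _value_token(value: object) -> str:
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


# ---------------------------------------------------------------------------
# value sweeps


def prestretch_values(calibrated: float) -> list[float]:
    """Perturbed prestretch factors: calibrated +/- 0.1 in steps of 0.025.

    Eight values per ligament; the calibrated value itself is excluded.
    """
    if not calibrated > 0:
        raise DesignError(f"calibrated prestretch must be positive, got {calibrated}")
    vals = [round(calibrated + k * PRESTRETCH_STEP, 10) for k in range(-4, 5) if k != 0]
    return sorted(vals)


def youngs_modulus_values(calibrated_mpa: float) -> list[float]:
    """Perturbed Young's moduli: calibrated +/- 100 MPa in steps of 25 MPa.

    A calibrated modulus of 100 MPa or less would produce non-positive
    perturbed values, which cannot be realised physically; that is an error
    rather than a silent clamp (clamping would change the design).
    """
    vals = [calibrated_mpa + k * YOUNGS_MODULUS_STEP_MPA for k in range(-4, 5) if k != 0]
    bad = [v for v in vals if v <= 0]
    if bad:
        raise DesignError(
            f"calibrated Young's modulus {calibrated_mpa} MPa yields non-positive "
            f"perturbed values {bad}"
        )
    return sorted(vals)


ATTACHMENT_PAIRS = (("set1", "set2"), ("set2", "set2"), ("set2", "set1"))


def attachment_combinations(ligament: str) -> list[tuple[str, str]]:
    """The three perturbed (femur set, tibia/fibula set) attachment pairs.

    (set1, set1) is the baseline and is never emitted.  Order is fixed:
    (set1, set2), (set2, set2), (set2, set1).
    """
    if ligament not in LIGAMENTS:
        raise DesignError(f"unknown ligament tag {ligament!r}")
    return list(ATTACHMENT_PAIRS)


# ---------------------------------------------------------------------------
# attachment node-set halving


@dataclass(frozen=True)
class AttachmentNodeSet:
    """Nodes of one ligament-bone rigid tied contact.

    ``bone_end`` is ``"femur"`` or ``"tibia_fibula"``; coordinates are mm in
    the model's global frame.
    """

    ligament: str
    bone_end: str
    node_ids: tuple[int, ...]
    node_coords: np.ndarray  # (n, 3) mm
    set_label: str = "set1"

    def __post_init__(self) -> None:
        coords = np.asarray(self.node_coords, dtype=float)
        object.__setattr__(self, "node_coords", coords)
        if self.bone_end not in ("femur", "tibia_fibula"):
            raise DesignError(f"unknown bone end {self.bone_end!r}")
        if coords.shape != (len(self.node_ids), 3):
            raise DesignError(
                f"node_coords shape {coords.shape} does not match "
                f"{len(self.node_ids)} node ids"
            )
        if not np.isfinite(coords).all():
            raise DesignError("node coordinates must be finite")

    def __len__(self) -> int:
        return len(self.node_ids)


def halve_node_set(set1: AttachmentNodeSet, axis_direction: Sequence[float]) -> AttachmentNodeSet:
    """Select the anatomical half of an attachment node set (set 2).

    ``axis_direction`` is the proximal-pointing anatomical axis.  The femoral
    end keeps the most proximal half of the nodes, the tibia/fibula end the
    most distal half.  For odd counts the half rounds up
    (``|set2| = ceil(|set1| / 2)``); projection ties break by node id
    ascending for reproducibility.
    """
    if len(set1) < 2:
        raise DesignError("need at least 2 nodes to halve an attachment set")
    axis = np.asarray(axis_direction, dtype=float)
    norm = np.linalg.norm(axis)
    if not norm > 0:
        raise DesignError("axis_direction must be a non-zero vector")
    axis = axis / norm
    proj = set1.node_coords @ axis
    n2 = (len(set1) + 1) // 2  # round-half-up of n/2
    ids = np.asarray(set1.node_ids)
    if set1.bone_end == "femur":
        # most proximal half: largest projections first
        order = np.lexsort((ids, -proj))
    else:
        # most distal half: smallest projections first
        order = np.lexsort((ids, proj))
    keep = np.sort(order[:n2])
    return AttachmentNodeSet(
        ligament=set1.ligament,
        bone_end=set1.bone_end,
        node_ids=tuple(int(i) for i in ids[keep]),
        node_coords=set1.node_coords[keep],
        set_label="set2",
    )


# ---------------------------------------------------------------------------
# design enumeration


@dataclass(frozen=True)
class ModelBaselines:
    """Calibrated per-ligament material values for one model."""

    prestretch: Mapping[str, float]
    youngs_modulus_mpa: Mapping[str, float]

    def require(self, mapping: Mapping[str, float], kind: str) -> None:
        missing = [lig for lig in LIGAMENTS if lig not in mapping]
        if missing:
            raise DesignError(f"missing calibrated {kind} for ligament(s): {', '.join(missing)}")


def build_axes(baselines: ModelBaselines) -> list[ParameterAxis]:
    """All parameter axes of the design, in deterministic study order."""
    baselines.require(baselines.prestretch, "prestretch")
    baselines.require(baselines.youngs_modulus_mpa, "Young's modulus")
    axes: list[ParameterAxis] = []
    for lig in LIGAMENTS:
        axes.append(
            ParameterAxis(
                "prestretch",
                Category.LIGAMENT_MENISCUS,
                baselines.prestretch[lig],
                tuple(prestretch_values(baselines.prestretch[lig])),
                per_structure=lig,
            )
        )
    for lig in LIGAMENTS:
        axes.append(
            ParameterAxis(
                "youngs_modulus_mpa",
                Category.LIGAMENT_MENISCUS,
                baselines.youngs_modulus_mpa[lig],
                tuple(youngs_modulus_values(baselines.youngs_modulus_mpa[lig])),
                per_structure=lig,
            )
        )
    for lig in LIGAMENTS:
        axes.append(
            ParameterAxis(
                "attachment_sets",
                Category.LIGAMENT_MENISCUS,
                "set1-set1",
                tuple("-".join(pair) for pair in attachment_combinations(lig)),
                per_structure=lig,
            )
        )
    axes += [
        # per-spring stiffness, applied uniformly to all 18 springs of a horn
        ParameterAxis("meniscus_horn_stiffness_n_mm", Category.LIGAMENT_MENISCUS, 1.0, (5.0, 10.0, 20.0)),
        ParameterAxis("augmented_lagrangian", Category.CONTACT, 0, (1,)),
        ParameterAxis("penalty_factor", Category.CONTACT, 1.0, (0.5, 2.0, 5.0, 10.0)),
        ParameterAxis("auto_penalty", Category.CONTACT, 0, (1,)),
        ParameterAxis("two_pass", Category.CONTACT, 1, (0,)),
        ParameterAxis("search_radius", Category.CONTACT, 0.005, (1.0,)),
        # BFGS / Broyden run with max_ups = 10 (the baseline Full Newton has none)
        ParameterAxis("quasi_newton", Category.CONTROL, "full_newton", ("bfgs", "broyden")),
        ParameterAxis("displacement_tolerance", Category.CONTROL, 0.01, (0.001,)),
        ParameterAxis("rcj_force_penalty_n_mm", Category.RCJ, 10_000.0, (5_000.0, 20_000.0)),
        ParameterAxis("rcj_moment_penalty_nmm_rad", Category.RCJ, 3_000_000.0, (5_000.0, 10_000.0, 20_000.0)),
        ParameterAxis("rcj_gap_tolerance", Category.RCJ, 0.01, (0.0001, 0.001, 0.1)),
        ParameterAxis("rcj_angular_tolerance", Category.RCJ, 0.0001, (0.001, 0.01, 0.1)),
    ]
    return axes


def enumerate_design(model_id: str, baselines: ModelBaselines) -> list[PerturbationPlan]:
    """Enumerate the full one-at-a-time design for one model: 101 plans.

    Ordering is deterministic: category (ligament/meniscus, contact, control,
    RCJ), then axis name, then structure (ACL, PCL, MCL, LCL), then value in
    the axis's ascending order.
    """
    axes = build_axes(baselines)
    lig_order = {lig: i for i, lig in enumerate(LIGAMENTS)}

    def sort_key(ax: ParameterAxis):
        return (
            _CATEGORY_ORDER[ax.category],
            ax.name,
            lig_order.get(ax.per_structure, -1),
        )

    plans: list[PerturbationPlan] = []
    for ax in sorted(axes, key=sort_key):
        for value in ax.values:
            plans.append(
                PerturbationPlan(
                    model_id=model_id,
                    axis=ax.name,
                    category=ax.category,
                    value=value,
                    structure=ax.per_structure,
                )
            )
    return plans


def horn_stiffness_total_range(
    per_spring_values: Iterable[float] = (1.0, 5.0, 10.0, 20.0),
    n_springs: int = HORN_SPRINGS_PER_ATTACHMENT,
) -> tuple[float, float]:
    """Total per-horn stiffness range spanned by the design (parallel springs)."""
    totals = [n_springs * v for v in per_spring_values]
    return (min(totals), max(totals))


# ---------------------------------------------------------------------------
# loading schedule


@dataclass(frozen=True)
class Phase:
    label: str
    t_start: float
    t_end: float
    quantity: str
    units: str
    target: float | None = None


@dataclass(frozen=True)
class LoadingSchedule:
    """Phased loading of one varus or valgus simulation over time 0..3.

    The varus/valgus moment ramps linearly from 0 at time 2.0 to
    +/-40,000 Nmm at time 3.0 (valgus positive, varus negative).
    """

    phases: tuple[Phase, ...]
    direction: str  # "varus" | "valgus"
    moment_magnitude_nmm: float = MOMENT_MAGNITUDE_NMM

    def __post_init__(self) -> None:
        if self.direction not in ("varus", "valgus"):
            raise DesignError(f"unknown direction {self.direction!r}")
        ts = [(p.t_start, p.t_end) for p in self.phases]
        if ts[0][0] != 0.0 or ts[-1][1] != 3.0:
            raise DesignError("phases must span [0.0, 3.0]")
        for (a0, a1), (b0, b1) in zip(ts, ts[1:]):
            if not math.isclose(a1, b0):
                raise DesignError("phases must be contiguous and non-overlapping")
        moment = self.phases[-1]
        if not (math.isclose(moment.t_start, 2.0) and math.isclose(moment.t_end, 3.0)):
            raise DesignError("the moment phase must span [2.0, 3.0]")


def axial_load_newtons(mass_kg: float) -> float:
    """Model-specific 0.5-body-weight axial load, rounded to 0.01 N."""
    return round(0.5 * mass_kg * GRAVITY_M_S2, 2)


def make_schedule(direction: str, model_id: str = "oks001", mass_kg: float | None = None) -> LoadingSchedule:
    """Loading schedule preset for one model family and moment direction.

    The oks specimens settle with a -20 N axial phase before flexion reset;
    du02 uses a single longer rotation phase.  Both apply 0.5 body weight of
    axial load over 1.5-2.0 and the moment ramp over 2.0-3.0.
    """
    if mass_kg is None:
        mass_kg = MODEL_MASSES_KG.get(model_id, 70.0)
    bw_load = axial_load_newtons(mass_kg)
    sign = 1.0 if direction == "valgus" else -1.0
    if model_id.startswith("du"):
        settle = (
            Phase("prestretch", 0.0, 0.1, "prestretch", "-"),
            Phase("rotate_to_flexion", 0.1, 1.0, "rotation", "deg"),
        )
    else:
        settle = (
            Phase("prestretch", 0.0, 0.1, "prestretch", "-"),
            Phase("rotate_to_flexion", 0.1, 0.5, "rotation", "deg"),
            Phase("axial_settle", 0.5, 1.0, "axial_load", "N", -20.0),
        )
    phases = settle + (
        Phase("rotate_to_zero_flexion", 1.0, 1.5, "rotation", "deg", 0.0),
        Phase("bodyweight_axial_load", 1.5, 2.0, "axial_load", "N", bw_load),
        Phase("moment_ramp", 2.0, 3.0, "moment", "Nmm", sign * MOMENT_MAGNITUDE_NMM),
    )
    return LoadingSchedule(phases=phases, direction=direction)


def applied_moment_at(t: float, schedule: LoadingSchedule) -> float:
    """Applied varus/valgus moment in Nmm at time ``t``.

    Zero through the settling phases (t <= 2.0), then a linear ramp reaching
    +/-40,000 Nmm at t = 3.0.  Outside [0, 3] the time is invalid.
    """
    if not 0.0 <= t <= 3.0:
        raise DesignError(f"time {t} outside the simulation window [0, 3]")
    if t <= 2.0:
        return 0.0
    sign = 1.0 if schedule.direction == "valgus" else -1.0
    return sign * schedule.moment_magnitude_nmm * (t - 2.0) / 1.0


# ---------------------------------------------------------------------------
# manifest


def design_manifest(plans: Sequence[PerturbationPlan], directions: Sequence[str] = ("varus", "valgus")) -> pd.DataFrame:
    """One row per (plan, direction), in design order."""
    rows = []
    for plan in plans:
        for direction in directions:
            rows.append(
                {
                    "plan_id": plan.plan_id,
                    "model_id": plan.model_id,
                    "category": plan.category.value,
                    "axis": plan.axis,
                    "structure": plan.structure or "",
                    "value": _value_token(plan.value),
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows)


def write_design_manifest(plans: Sequence[PerturbationPlan], out_dir: str | Path) -> tuple[Path, Path]:
    """Write the design manifest as CSV and JSON; returns both paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = design_manifest(plans)
    csv_path = out / "design_manifest.csv"
    json_path = out / "design_manifest.json"
    df.to_csv(csv_path, index=False, lineterminator="\n")
    json_path.write_text(json.dumps(df.to_dict(orient="records"), indent=1) + "\n")
    return csv_path, json_path


def stable_seed(*tokens: object) -> int:
    """Deterministic 32-bit seed component from string tokens (crc32)."""
    text = "|".join(str(t) for t in tokens)
    return zlib.crc32(text.encode("utf-8"))
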