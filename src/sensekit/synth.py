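"""Synthetic FE-like simulation outputs with known ground-truth effects.

Real inputs to this pipeline are post-processed finite-element runs of
cadaver-specific tibiofemoral models; producing them needs an FE solver and
hours of compute.  This module generates result bundles with the same shape
and the statistical structure the analysis assumes — a parameter change may

* scale the contact-pressure magnitude (factor ``s``),
* shift the contact-patch location (vector ``d`` in mm),
* change the valgus compliance (factor ``c`` on degrees per Nmm),
* truncate convergence at an earlier time ``T``,

optionally with additive Gaussian noise — so every pipeline stage can be
tested against closed-form expectations:

* ``pressure_pct_diff`` recovers ``100 |s - 1|`` exactly at zero noise,
* ``location_distance`` recovers ``|d|`` up to patch discretisation,
* ``valgus_rmse`` equals the RMS of ``(c - 1) k M(t)`` over the moment
  window,
* ``T <= 2.25`` triggers the exclusion rule.

The tibial contact surface is two disjoint elliptical face patches (medial /
lateral plateau).  Pressure on each patch is a Gaussian bump; faces where the
bump's unit shape falls below a fixed support fraction of its maximum carry
exactly zero pressure, so the in-contact subset is a fixed fraction of the
patch and — deliberately — independent of the injected scale ``s``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import (
    PerturbationPlan,
    applied_moment_at,
    make_schedule,
    stable_seed,
)
from .fe_io import (
    ContactFrame,
    ConvergenceRecord,
    KinematicsSeries,
    SimulationResult,
    write_result_bundle,
)

__all__ = [
    "TIME_STEP",
    "PatchConfig",
    "SyntheticModelConfig",
    "Effect",
    "EffectConfig",
    "make_surface",
    "simulate_run",
    "simulate_study",
    "load_effects",
]

#: Uniform output time step; FEBio's adaptive stepping is emulated only to
#: the extent the analysis needs (irregular grids are exercised in tests).
TIME_STEP = 0.05

#: Fraction of the bump maximum below which a face is not in contact.  0.35
#: puts roughly a fifth of each patch in contact, a regime where the top-10%
#: face subset is meaningful.
CONTACT_SUPPORT_FRACTION = 0.35


@dataclass(frozen=True)
class PatchConfig:
    """One elliptical tibial-plateau contact patch."""

    center: tuple[float, float, float]  # mm
    radii: tuple[float, float]  # mm, in-plane semi-axes
    n_faces: int = 120

    def __post_init__(self) -> None:
        if self.n_faces < 10:
            raise ValueError("patch needs at least 10 faces")
        if min(self.radii) <= 0:
            raise ValueError("degenerate patch radii")


@dataclass(frozen=True)
class SyntheticModelConfig:
    """Shape and response of one synthetic knee model.

    ``compliance_deg_per_nmm`` sets the valgus rotation per unit applied
    moment (1e-4 deg/Nmm gives 4 degrees at the full 40,000 Nmm, a realistic
    frontal-plane laxity); ``pressure_amplitude_mpa`` is the bump peak, of
    the order of physiological tibiofemoral contact pressure.
    """

    model_id: str = "synth01"
    mass_kg: float = 70.0
    compliance_deg_per_nmm: float = 1.0e-4
    pressure_amplitude_mpa: float = 3.0
    medial_patch: PatchConfig = field(
        default_factory=lambda: PatchConfig(center=(-22.0, 0.0, 0.0), radii=(12.0, 8.0))
    )
    lateral_patch: PatchConfig = field(
        default_factory=lambda: PatchConfig(center=(22.0, 0.0, 0.0), radii=(12.0, 8.0))
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.compliance_deg_per_nmm <= 0 or self.pressure_amplitude_mpa <= 0:
            raise ValueError("compliance and pressure amplitude must be positive")


@dataclass(frozen=True)
class Effect:
    """Ground-truth effect of one perturbed configuration."""

    pressure_scale: float = 1.0  # s > 0
    location_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)  # d, mm
    compliance_multiplier: float = 1.0  # c
    truncate_time: float = 3.0  # T in (0, 3]

    def __post_init__(self) -> None:
        if self.pressure_scale <= 0:
            raise ValueError("pressure scale must be positive")
        if not 0.0 < self.truncate_time <= 3.0:
            raise ValueError("truncation time must lie in (0, 3]")


NULL_EFFECT = Effect()


@dataclass(frozen=True)
class EffectConfig:
    """Per-axis effect maps plus the noise model.

    ``per_axis`` maps an axis name either to a single :class:`Effect`
    (applied to every value of that axis) or to a ``{value_token: Effect}``
    mapping.  Axes not listed have the null effect.  Noise is additive
    Gaussian — kinematics in degrees, pressures in MPa (truncated at zero);
    the real study is deterministic FE, noise exists to harden the pipeline.
    """

    per_axis: Mapping[str, object] = field(default_factory=dict)
    kinematics_sigma_deg: float = 0.0
    pressure_sigma_mpa: float = 0.0

    def effect_for(self, plan: PerturbationPlan | None) -> Effect:
        if plan is None:
            return NULL_EFFECT
        entry = self.per_axis.get(plan.axis)
        if entry is None:
            return NULL_EFFECT
        if isinstance(entry, Effect):
            return entry
        token = plan.plan_id.split("__")[-1]
        return entry.get(token, entry.get(str(plan.value), NULL_EFFECT))


def load_effects(path: str | Path) -> EffectConfig:
    """Read an effect configuration from YAML.

    Layout::

        noise: {kinematics_sigma_deg: 0.0, pressure_sigma_mpa: 0.0}
        axes:
          penalty_factor:            # one effect for the whole axis
            pressure_scale: 1.3
          prestretch:                # or one per value token
            "0.925": {compliance_multiplier: 1.1}
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    noise = doc.get("noise", {})
    per_axis: dict[str, object] = {}
    for axis, entry in (doc.get("axes") or {}).items():
        if entry and all(isinstance(v, dict) for v in entry.values()):
            per_axis[axis] = {str(k): _effect_from_dict(v) for k, v in entry.items()}
        else:
            per_axis[axis] = _effect_from_dict(entry or {})
    return EffectConfig(
        per_axis=per_axis,
        kinematics_sigma_deg=float(noise.get("kinematics_sigma_deg", 0.0)),
        pressure_sigma_mpa=float(noise.get("pressure_sigma_mpa", 0.0)),
    )


def _effect_from_dict(d: Mapping) -> Effect:
    return Effect(
        pressure_scale=float(d.get("pressure_scale", 1.0)),
        location_shift=tuple(float(x) for x in d.get("location_shift", (0.0, 0.0, 0.0))),
        compliance_multiplier=float(d.get("compliance_multiplier", 1.0)),
        truncate_time=float(d.get("truncate_time", 3.0)),
    )


# ---------------------------------------------------------------------------
# surface


def make_surface(config: SyntheticModelConfig) -> pd.DataFrame:
    """Face-centroid table of the two tibial contact patches.

    Deterministic given ``config.seed``; face ids are unique across sides
    (medial first).  Centroids are sampled uniformly inside each ellipse.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    next_id = 0
    for side, patch in (("medial", config.medial_patch), ("lateral", config.lateral_patch)):
        # uniform in the unit disc, stretched to the ellipse
        r = np.sqrt(rng.uniform(0.0, 1.0, patch.n_faces))
        phi = rng.uniform(0.0, 2.0 * np.pi, patch.n_faces)
        cx = patch.center[0] + patch.radii[0] * r * np.cos(phi)
        cy = patch.center[1] + patch.radii[1] * r * np.sin(phi)
        cz = np.full(patch.n_faces, patch.center[2])
        frames.append(
            pd.DataFrame(
                {
                    "face_id": np.arange(next_id, next_id + patch.n_faces),
                    "side": side,
                    "cx_mm": cx,
                    "cy_mm": cy,
                    "cz_mm": cz,
                }
            )
        )
        next_id += patch.n_faces
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# single run


def _time_grid(truncate_time: float) -> np.ndarray:
    times = np.round(np.arange(0.0, 3.0 + TIME_STEP / 2, TIME_STEP), 6)
    return times[times <= truncate_time + 1e-9]


def _pressure_field(
    centroids: np.ndarray,
    patch: PatchConfig,
    shift: np.ndarray,
    amplitude: float,
) -> np.ndarray:
    """Gaussian bump with scale-invariant support (see module docstring)."""
    rho = 0.4 * min(patch.radii)  # bump width tied to patch size
    center = np.asarray(patch.center) + shift
    dist2 = ((centroids - center) ** 2).sum(axis=1)
    shape = np.exp(-dist2 / (2.0 * rho**2))
    shape[shape <= CONTACT_SUPPORT_FRACTION] = 0.0
    return amplitude * shape


def simulate_run(
    plan: PerturbationPlan | None,
    model: SyntheticModelConfig,
    effects: EffectConfig,
    direction: str,
    rng: np.random.Generator | None = None,
    surface: pd.DataFrame | None = None,
) -> SimulationResult:
    """One synthetic varus or valgus run (``plan=None`` is the baseline).

    Valgus rotation follows ``theta(t) = c * k * M(t)`` with ``M(t)`` the
    loading schedule's moment ramp; contact pressure is the patch bump scaled
    by ``s`` and shifted by ``d``; the series stops at the truncation time.
    Contact fields are emitted for the moment window (t >= 2.0), where the
    joint is loaded.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    if surface is None:
        surface = make_surface(model)
    effect = effects.effect_for(plan)
    schedule = make_schedule(direction, model.model_id, model.mass_kg)
    times = _time_grid(effect.truncate_time)

    moments = np.array([applied_moment_at(t, schedule) for t in times])
    valgus = effect.compliance_multiplier * model.compliance_deg_per_nmm * moments
    if effects.kinematics_sigma_deg > 0:
        valgus = valgus + rng.normal(0.0, effects.kinematics_sigma_deg, valgus.shape)
    # remaining DOF: a flexion reset during settling, quiet elsewhere
    flexion = np.clip(10.0 * (1.5 - times) / 0.5, 0.0, 10.0)
    zeros = np.zeros_like(times)
    kinematics = KinematicsSeries(
        times=times,
        values=np.column_stack([flexion, valgus, zeros, zeros, zeros, zeros]),
    )

    shift = np.asarray(effect.location_shift, dtype=float)
    amplitude = effect.pressure_scale * model.pressure_amplitude_mpa
    frames: list[ContactFrame] = []
    for side, patch in (("medial", model.medial_patch), ("lateral", model.lateral_patch)):
        part = surface[surface["side"] == side]
        centroids = part[["cx_mm", "cy_mm", "cz_mm"]].to_numpy(float)
        face_ids = part["face_id"].to_numpy(int)
        base = _pressure_field(centroids, patch, shift, amplitude)
        for t in times[times >= 2.0 - 1e-9]:
            pressures = base
            if effects.pressure_sigma_mpa > 0:
                noise = rng.normal(0.0, effects.pressure_sigma_mpa, base.shape)
                pressures = np.where(base > 0, np.maximum(base + noise, 0.0), 0.0)
            frames.append(
                ContactFrame(
                    time=float(t),
                    side=side,
                    face_ids=face_ids,
                    centroids=centroids,
                    pressures=pressures,
                )
            )
    frames.sort(key=lambda f: (f.time, f.side))

    last_t = float(times[-1]) if times.size else 0.0
    return SimulationResult(
        plan_id=plan.plan_id if plan is not None else "original",
        model_id=model.model_id,
        direction=direction,
        kinematics=kinematics,
        contact_frames=tuple(frames),
        convergence=ConvergenceRecord(
            last_converged_time=last_t,
            terminated_early=bool(last_t < 3.0 - 1e-9),
        ),
    )


# ---------------------------------------------------------------------------
# full study


def _run_rng(seed: int, plan_id: str, direction: str) -> np.random.Generator:
    return np.random.default_rng(
        [int(seed) % (2**31), stable_seed(plan_id), stable_seed(direction)]
    )


def simulate_study(
    plans: Sequence[PerturbationPlan],
    model: SyntheticModelConfig,
    effects: EffectConfig,
    out_dir: str | Path,
    seed: int = 0,
    directions: Sequence[str] = ("varus", "valgus"),
) -> Path:
    """Generate and write a full study: baselines plus one bundle per plan
    and direction, with a ground-truth manifest for recovery tests.

    Bundles are independent of generation order: each run draws from its own
    generator seeded by (study seed, plan id, direction), so identical seeds
    give byte-identical studies.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    surface = make_surface(model)
    truth: dict[str, dict] = {}
    for direction in directions:
        baseline = simulate_run(
            None, model, effects, direction, rng=_run_rng(seed, "original", direction), surface=surface
        )
        write_result_bundle(baseline, out / f"original__{direction}")
    for plan in plans:
        effect = effects.effect_for(plan)
        truth[plan.plan_id] = {
            "axis": plan.axis,
            "structure": plan.structure,
            "value": str(plan.value),
            "pressure_scale": effect.pressure_scale,
            "location_shift": list(effect.location_shift),
            "compliance_multiplier": effect.compliance_multiplier,
            "truncate_time": effect.truncate_time,
        }
        for direction in directions:
            run = simulate_run(
                plan, model, effects, direction,
                rng=_run_rng(seed, plan.plan_id, direction), surface=surface,
            )
            write_result_bundle(run, out / f"{plan.plan_id}__{direction}")
    manifest = {
        "model_id": model.model_id,
        "seed": int(seed),
        "noise": {
            "kinematics_sigma_deg": effects.kinematics_sigma_deg,
            "pressure_sigma_mpa": effects.pressure_sigma_mpa,
        },
        "plans": truth,
    }
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out
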