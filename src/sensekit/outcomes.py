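"""Outcome extraction and baseline comparison for varus/valgus simulations.

Four outcome parameters are tracked per run:

1. **Convergence** — the last converged time step, compared as a percentage
   difference against the original (baseline) simulation.
2. **Valgus kinematics** — RMSE of the valgus/varus rotation between the
   perturbed and the original run, with the original linearly interpolated
   onto the perturbed run's converged time steps.
3. **Peak contact pressure** — per tibial compartment, the mean pressure over
   the top 10% highest-pressure faces in contact (pressure > 0); averaging
   the top decile avoids single deformed elements dominating the peak.
4. **Peak-pressure location** — the mean centroid of that same top-decile
   face set; compared as a Euclidean distance, averaged over the medial and
   lateral compartments.

Pressure and location are evaluated at a per-parameter analysis time: the
latest time step to which the baseline and every retained run of that
parameter converged, required to exceed 2.25 (10,000 Nmm of applied moment).
Runs that never converge past 2.25 are excluded from the kinematics and
pressure comparisons but still count toward the convergence metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fe_io import ContactFrame, KinematicsSeries, SimulationResult, SIDES

__all__ = [
    "EXCLUSION_TIME",
    "MOMENT_WINDOW_START",
    "AnalysisError",
    "PeakPressureSummary",
    "OutcomeComparison",
    "ParameterAggregate",
    "peak_contact_pressure",
    "select_analysis_time",
    "convergence_pct_diff",
    "valgus_rmse",
    "pressure_pct_diff",
    "location_distance",
    "compare_run",
    "analyze_group",
    "aggregate_parameter",
    "comparisons_table",
]

#: Runs whose last converged time step does not exceed this are excluded from
#: the kinematics / pressure / location analysis (2.25 corresponds to
#: 10,000 Nmm of applied varus or valgus moment).
EXCLUSION_TIME = 2.25

#: The moment ramp starts here; kinematics differencing is restricted to it.
MOMENT_WINDOW_START = 2.0

_TIME_DECIMALS = 6


class AnalysisError(ValueError):
    """Raised when a comparison group cannot be analyzed at all."""


@dataclass(frozen=True)
class PeakPressureSummary:
    """Top-decile peak pressure summary of one compartment at one time."""

    side: str
    peak_pressure: float | None  # N/mm^2; None when nothing is in contact
    location: np.ndarray | None  # (3,) mm mean centroid of the top set
    n_contact_faces: int
    n_top_faces: int

    @property
    def has_contact(self) -> bool:
        return self.n_contact_faces > 0


def peak_contact_pressure(frame: ContactFrame) -> PeakPressureSummary:
    """Peak contact pressure and its location for one contact frame.

    Faces with pressure strictly greater than zero are the contact set; the
    top ``ceil(0.1 * n)`` of them by pressure form the peak set whose
    unweighted mean pressure and mean centroid are reported.  Ties at the
    cutoff pressure are resolved by face id ascending so the result does not
    depend on input ordering.  An empty contact set yields an explicit
    no-contact summary rather than an error.
    """
    in_contact = frame.pressures > 0
    n_contact = int(np.count_nonzero(in_contact))
    if n_contact == 0:
        return PeakPressureSummary(frame.side, None, None, 0, 0)
    n_top = math.ceil(0.1 * n_contact)
    ids = frame.face_ids[in_contact]
    pressures = frame.pressures[in_contact]
    centroids = frame.centroids[in_contact]
    # descending pressure, ties by ascending face id
    order = np.lexsort((ids, -pressures))[:n_top]
    return PeakPressureSummary(
        side=frame.side,
        peak_pressure=float(pressures[order].mean()),
        location=centroids[order].mean(axis=0),
        n_contact_faces=n_contact,
        n_top_faces=n_top,
    )


def select_analysis_time(
    baseline: SimulationResult,
    runs: Sequence[SimulationResult],
    threshold: float = EXCLUSION_TIME,
) -> tuple[float, list[SimulationResult], list[tuple[SimulationResult, str]]]:
    """Pick the common analysis time step for one parameter of interest.

    Returns ``(analysis_time, included_runs, excluded)`` where the analysis
    time is the **latest** time step present in the converged kinematics of
    the baseline and of every included run, strictly greater than
    ``threshold``.  Runs not converging past the threshold are excluded first
    (with a reason); a baseline not converging past the threshold is a
    group-level error.
    """
    if baseline.convergence.last_converged_time <= threshold:
        raise AnalysisError(
            f"baseline for {baseline.model_id}/{baseline.direction} only converged "
            f"to t={baseline.convergence.last_converged_time} <= {threshold}"
        )
    included: list[SimulationResult] = []
    excluded: list[tuple[SimulationResult, str]] = []
    for run in runs:
        t_last = run.convergence.last_converged_time
        if t_last <= threshold:
            excluded.append(
                (run, f"did not converge past t={threshold} (stopped at {t_last:g})")
            )
        else:
            included.append(run)
    common = set(np.round(baseline.kinematics.times, _TIME_DECIMALS))
    for run in included:
        common &= set(np.round(run.kinematics.times, _TIME_DECIMALS))
    candidates = [t for t in common if t > threshold]
    if not candidates:
        raise AnalysisError(
            "no common converged time step above "
            f"t={threshold} for {baseline.model_id}/{baseline.direction}"
        )
    return max(candidates), included, excluded


def convergence_pct_diff(t_interest: float, t_original: float) -> float:
    """Percentage difference of last converged time steps, |Δ|/original × 100."""
    if t_original <= 0:
        raise AnalysisError("original run has no converged time steps")
    return 100.0 * abs(t_interest - t_original) / t_original


def valgus_rmse(
    original: KinematicsSeries,
    interest: KinematicsSeries,
    window_start: float = MOMENT_WINDOW_START,
) -> float | None:
    """RMSE of the valgus rotation between a perturbed run and the baseline.

    Evaluated on the perturbed run's converged time steps, clipped to the
    span of the baseline's converged steps (the baseline's valgus angle is
    linearly interpolated; no extrapolation).  Only the moment window
    (t >= ``window_start``) is differenced — earlier settling phases are
    shared by construction.  Returns ``None`` when the windows do not
    overlap.
    """
    if original.times.size == 0 or interest.times.size == 0:
        return None
    lo = max(window_start, float(original.times[0]))
    hi = float(original.times[-1])
    mask = (interest.times >= lo - 1e-9) & (interest.times <= hi + 1e-9)
    grid = interest.times[mask]
    if grid.size == 0:
        return None
    ref = np.interp(grid, original.times, original.valgus)
    cur = interest.valgus[mask]
    return float(np.sqrt(np.mean((cur - ref) ** 2)))


def _per_side(
    interest: Mapping[str, PeakPressureSummary],
    original: Mapping[str, PeakPressureSummary],
) -> list[str]:
    """Sides usable for comparison: original has contact there."""
    return [s for s in SIDES if s in original and original[s].has_contact and s in interest]


def pressure_pct_diff(
    interest: Mapping[str, PeakPressureSummary],
    original: Mapping[str, PeakPressureSummary],
) -> tuple[float | None, dict[str, float]]:
    """Mean medial/lateral percentage difference of peak contact pressure.

    Per side: ``100 |p_int − p_orig| / p_orig``; sides without baseline
    contact are dropped.  Returns the cross-side mean (``None`` when no side
    is comparable) and the signed per-side diagnostics.
    """
    diffs: list[float] = []
    signed: dict[str, float] = {}
    for side in _per_side(interest, original):
        p0 = original[side].peak_pressure
        p1 = interest[side].peak_pressure if interest[side].has_contact else 0.0
        signed[side] = 100.0 * (p1 - p0) / p0
        diffs.append(abs(signed[side]))
    return (float(np.mean(diffs)) if diffs else None), signed


def location_distance(
    interest: Mapping[str, PeakPressureSummary],
    original: Mapping[str, PeakPressureSummary],
) -> float | None:
    """Mean medial/lateral distance (mm) between peak-pressure locations."""
    dists: list[float] = []
    for side in _per_side(interest, original):
        if not interest[side].has_contact:
            continue
        dists.append(float(np.linalg.norm(interest[side].location - original[side].location)))
    return float(np.mean(dists)) if dists else None


@dataclass(frozen=True)
class OutcomeComparison:
    """The four comparison metrics of one perturbed run vs its baseline."""

    plan_id: str
    direction: str
    analysis_time: float | None
    convergence_pct_diff: float
    convergence_diff_signed: float
    valgus_rmse: float | None
    pressure_pct_diff: float | None
    pressure_diff_signed: dict[str, float]
    location_distance: float | None
    excluded: bool = False
    exclusion_reason: str = ""


def compare_run(
    interest: SimulationResult,
    original: SimulationResult,
    analysis_time: float,
) -> OutcomeComparison:
    """All four metrics for one retained (non-excluded) perturbed run."""
    t_int = interest.convergence.last_converged_time
    t_orig = original.convergence.last_converged_time
    summaries_int: dict[str, PeakPressureSummary] = {}
    summaries_orig: dict[str, PeakPressureSummary] = {}
    for side in SIDES:
        f_int = interest.frame_at(analysis_time, side)
        f_orig = original.frame_at(analysis_time, side)
        if f_int is not None:
            summaries_int[side] = peak_contact_pressure(f_int)
        if f_orig is not None:
            summaries_orig[side] = peak_contact_pressure(f_orig)
    p_diff, p_signed = pressure_pct_diff(summaries_int, summaries_orig)
    return OutcomeComparison(
        plan_id=interest.plan_id,
        direction=interest.direction,
        analysis_time=analysis_time,
        convergence_pct_diff=convergence_pct_diff(t_int, t_orig),
        convergence_diff_signed=100.0 * (t_int - t_orig) / t_orig,
        valgus_rmse=valgus_rmse(original.kinematics, interest.kinematics),
        pressure_pct_diff=p_diff,
        pressure_diff_signed=p_signed,
        location_distance=location_distance(summaries_int, summaries_orig),
    )


def analyze_group(
    original: SimulationResult,
    runs: Sequence[SimulationResult],
    threshold: float = EXCLUSION_TIME,
) -> list[OutcomeComparison]:
    """Compare every run of one parameter of interest against the baseline.

    Excluded runs (no convergence past the threshold) still yield a
    comparison carrying the convergence metric only.
    """
    analysis_time, included, excluded = select_analysis_time(original, runs, threshold)
    t_orig = original.convergence.last_converged_time
    out = [compare_run(run, original, analysis_time) for run in included]
    for run, reason in excluded:
        t_int = run.convergence.last_converged_time
        out.append(
            OutcomeComparison(
                plan_id=run.plan_id,
                direction=run.direction,
                analysis_time=None,
                convergence_pct_diff=convergence_pct_diff(t_int, t_orig),
                convergence_diff_signed=100.0 * (t_int - t_orig) / t_orig,
                valgus_rmse=None,
                pressure_pct_diff=None,
                pressure_diff_signed={},
                location_distance=None,
                excluded=True,
                exclusion_reason=reason,
            )
        )
    return out


@dataclass(frozen=True)
class ParameterAggregate:
    """Per-direction means of the four metrics for one parameter of interest."""

    direction: str
    convergence_pct_diff: float | None
    valgus_rmse: float | None
    pressure_pct_diff: float | None
    location_distance: float | None
    n_runs: int
    n_excluded: int

    @property
    def available(self) -> bool:
        return self.n_runs > 0


def aggregate_parameter(
    comparisons: Sequence[OutcomeComparison], direction: str
) -> ParameterAggregate:
    """Arithmetic means per metric over one direction's comparisons.

    Excluded runs contribute to the convergence mean (their early stop *is*
    the convergence outcome) but never to the kinematics/pressure/location
    means.
    """
    group = [c for c in comparisons if c.direction == direction]
    retained = [c for c in group if not c.excluded]
    n_excluded = len(group) - len(retained)

    def mean_of(values: Iterable[float | None]) -> float | None:
        vals = [v for v in values if v is not None]
        return float(np.mean(vals)) if vals else None

    return ParameterAggregate(
        direction=direction,
        convergence_pct_diff=mean_of(c.convergence_pct_diff for c in group),
        valgus_rmse=mean_of(c.valgus_rmse for c in retained),
        pressure_pct_diff=mean_of(c.pressure_pct_diff for c in retained),
        location_distance=mean_of(c.location_distance for c in retained),
        n_runs=len(group),
        n_excluded=n_excluded,
    )


def comparisons_table(comparisons: Sequence[OutcomeComparison]) -> pd.DataFrame:
    """Flat per-run comparison table (one row per run and direction)."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "plan_id": c.plan_id,
                "direction": c.direction,
                "analysis_time": c.analysis_time,
                "convergence_pct_diff": c.convergence_pct_diff,
                "convergence_diff_signed": c.convergence_diff_signed,
                "valgus_rmse_deg": c.valgus_rmse,
                "pressure_pct_diff": c.pressure_pct_diff,
                "pressure_diff_signed_medial": c.pressure_diff_signed.get("medial"),
                "pressure_diff_signed_lateral": c.pressure_diff_signed.get("lateral"),
                "location_distance_mm": c.location_distance,
                "excluded": c.excluded,
                "reason": c.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)
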