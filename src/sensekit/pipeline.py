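"""End-to-end study pipeline: design -> synthetic bundles -> comparison
tables -> rating matrix -> report, with seeded determinism and provenance.

The pipeline is a thin orchestration of the library modules; every stage can
also be run on its own (see :mod:`sensekit.cli`).  All randomness flows from
the single study seed; a hash of the resolved configuration is recorded in
``provenance.json`` together with per-output file digests, so a tampered
config or output is detectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .design import (
    LIGAMENTS,
    DesignError,
    ModelBaselines,
    PerturbationPlan,
    enumerate_design,
    write_design_manifest,
)
from .fe_io import BundleError, SimulationResult, read_result_bundle
from .outcomes import (
    AnalysisError,
    OutcomeComparison,
    ParameterAggregate,
    aggregate_parameter,
    analyze_group,
    comparisons_table,
)
from .rating import default_scales, load_scales, rate_study, rating_table
from .synth import EffectConfig, SyntheticModelConfig, PatchConfig, load_effects, simulate_study

__all__ = ["StudyConfig", "PipelineError", "run_pipeline", "analyze_bundles", "load_config"]

log = logging.getLogger("sensekit")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class StudyConfig:
    """Resolved configuration of one synthetic sensitivity study."""

    model_id: str = "synth01"
    mass_kg: float = 70.0
    prestretch: Mapping[str, float] = field(
        default_factory=lambda: {lig: 1.0 for lig in LIGAMENTS}
    )
    youngs_modulus_mpa: Mapping[str, float] = field(
        default_factory=lambda: {lig: 300.0 for lig in LIGAMENTS}
    )
    faces_per_patch: int = 120
    compliance_deg_per_nmm: float = 1.0e-4
    pressure_amplitude_mpa: float = 3.0
    effects_file: str | None = None
    rating_scale_file: str | None = None
    seed: int = 0
    out_dir: str = "study_out"

    def baselines(self) -> ModelBaselines:
        return ModelBaselines(dict(self.prestretch), dict(self.youngs_modulus_mpa))

    def model(self) -> SyntheticModelConfig:
        return SyntheticModelConfig(
            model_id=self.model_id,
            mass_kg=self.mass_kg,
            compliance_deg_per_nmm=self.compliance_deg_per_nmm,
            pressure_amplitude_mpa=self.pressure_amplitude_mpa,
            medial_patch=PatchConfig((-22.0, 0.0, 0.0), (12.0, 8.0), self.faces_per_patch),
            lateral_patch=PatchConfig((22.0, 0.0, 0.0), (12.0, 8.0), self.faces_per_patch),
            seed=int(self.seed),
        )

    def canonical_json(self) -> str:
        d = asdict(self)
        d["prestretch"] = dict(d["prestretch"])
        d["youngs_modulus_mpa"] = dict(d["youngs_modulus_mpa"])
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a study configuration YAML."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = set(StudyConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise PipelineError(f"config: unknown field(s) {sorted(unknown)}")
    cfg = StudyConfig(**doc)
    for name in ("effects_file", "rating_scale_file"):
        value = getattr(cfg, name)
        if value is not None and not Path(value).is_file():
            raise PipelineError(f"config: {name} {value!r} does not exist")
    missing = [l for l in LIGAMENTS if l not in cfg.prestretch or l not in cfg.youngs_modulus_mpa]
    if missing:
        raise PipelineError(f"config: missing ligament baseline(s) {missing}")
    return cfg


# ---------------------------------------------------------------------------
# analysis over a directory of bundles


def _parameter_key(plan_id: str) -> str:
    # plan ids are model__axis__structure__value; "-" marks no structure
    parts = plan_id.split("__")
    if len(parts) != 4:
        return plan_id
    _, axis, structure, _ = parts
    return f"{axis}[{structure}]" if structure != "-" else axis


def analyze_bundles(
    bundles_dir: str | Path,
    directions: Sequence[str] = ("varus", "valgus"),
) -> tuple[list[OutcomeComparison], dict[str, dict[str, ParameterAggregate]]]:
    """Read every bundle under ``bundles_dir`` and compare against baselines.

    Runs are grouped per parameter of interest (one axis, one structure) and
    per direction; each group shares one analysis time step.  Returns the
    flat comparison list and ``parameter -> direction -> aggregate``.
    """
    root = Path(bundles_dir)
    results: dict[str, dict[str, list[SimulationResult]]] = {d: {} for d in directions}
    baselines: dict[str, SimulationResult] = {}
    for bundle in sorted(p for p in root.iterdir() if p.is_dir()):
        res = read_result_bundle(bundle)
        if res.direction not in results:
            continue
        if res.is_baseline:
            baselines[res.direction] = res
        else:
            key = _parameter_key(res.plan_id)
            results[res.direction].setdefault(key, []).append(res)
    for direction in directions:
        if direction not in baselines:
            raise PipelineError(
                f"analyze: missing baseline bundle 'original__{direction}' under {root}"
            )
    comparisons: list[OutcomeComparison] = []
    aggregates: dict[str, dict[str, ParameterAggregate]] = {}
    parameters = sorted({k for d in directions for k in results[d]})
    for parameter in parameters:
        aggregates[parameter] = {}
        for direction in directions:
            runs = results[direction].get(parameter, [])
            if not runs:
                continue
            group = analyze_group(baselines[direction], runs)
            comparisons.extend(group)
            for c in group:
                if c.excluded:
                    log.warning("excluded %s (%s): %s", c.plan_id, direction, c.exclusion_reason)
            aggregates[parameter][direction] = aggregate_parameter(group, direction)
    return comparisons, aggregates


# ---------------------------------------------------------------------------
# the full pipeline


def run_pipeline(config: StudyConfig) -> Path:
    """Run design -> synth -> analyze -> rate -> report; returns the out dir.

    A stage failure aborts with the failing stage named; outputs of earlier
    stages are preserved for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done in %.2fs", name, timings.get(name, 0.0))

        return _Timer()

    with stage("design"):
        plans = enumerate_design(config.model_id, config.baselines())
        write_design_manifest(plans, out)

    with stage("synth"):
        effects = load_effects(config.effects_file) if config.effects_file else EffectConfig()
        bundles_dir = simulate_study(plans, config.model(), effects, out / "bundles", seed=config.seed)

    with stage("analyze"):
        comparisons, aggregates = analyze_bundles(bundles_dir)
        comp_df = comparisons_table(comparisons)
        comp_df.to_csv(out / "comparisons.csv", index=False, lineterminator="\n")

    with stage("rate"):
        scales = (
            load_scales(config.rating_scale_file) if config.rating_scale_file else default_scales()
        )
        ratings = rate_study(aggregates, config.model_id, scales)
        ratings_df = rating_table(ratings)
        ratings_df.to_csv(out / "ratings.csv", index=False, lineterminator="\n")

    with stage("report"):
        from .report import render_report

        render_report(ratings_df, comp_df, out / "figures", bundles_dir=bundles_dir)

    provenance = {
        "package": "sensekit",
        "version": __version__,
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "config": json.loads(config.canonical_json()),
        "timings_s": timings,
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
            for p in sorted(out.glob("*.csv"))
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True) + "\n")
    return out
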