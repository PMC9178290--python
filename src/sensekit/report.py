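"""Figure and table rendering: 0-3 influence heatmaps, per-parameter
kinematics overlays and pressure-difference bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .fe_io import read_result_bundle

__all__ = ["render_report", "rating_heatmap"]

_METRIC_LABELS = {
    "convergence_pct": "Convergence",
    "valgus_rmse": "Valgus kinematics",
    "pressure_pct": "Peak pressure",
    "location_mm": "Pressure location",
}


def rating_heatmap(ratings: pd.DataFrame, out_path: str | Path) -> Path:
    """Heatmap of combined 0-3 scores, parameters x outcome metrics."""
    pivot = ratings.pivot_table(
        index="parameter_of_interest",
        columns="metric_kind",
        values="combined_score",
        sort=True,
    )
    pivot = pivot.reindex(columns=[k for k in _METRIC_LABELS if k in pivot.columns])
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(pivot) + 1.5))
    data = pivot.to_numpy(float)
    im = ax.imshow(data, cmap="YlOrRd", vmin=0.0, vmax=3.0, aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), [_METRIC_LABELS[c] for c in pivot.columns], rotation=30, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            v = data[i, j]
            ax.text(j, i, "n/a" if np.isnan(v) else f"{v:g}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Influence score (0 none - 3 large)")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def _parameter_figure(
    parameter: str, comp: pd.DataFrame, bundles_dir: Path | None, out_path: Path
) -> None:
    fig, (ax_kin, ax_bar) = plt.subplots(1, 2, figsize=(10, 4))

    plotted_kin = False
    if bundles_dir is not None:
        for bundle in sorted(bundles_dir.iterdir()):
            name = bundle.name
            if not bundle.is_dir() or not name.endswith("__valgus"):
                continue
            plan_id = name[: -len("__valgus")]
            is_base = plan_id == "original"
            if not is_base and plan_id not in set(comp["plan_id"]):
                continue
            res = read_result_bundle(bundle)
            ax_kin.plot(
                res.kinematics.times,
                res.kinematics.valgus,
                color="k" if is_base else "C0",
                lw=2.0 if is_base else 0.8,
                alpha=1.0 if is_base else 0.6,
                label="original" if is_base else None,
            )
            plotted_kin = True
    if plotted_kin:
        ax_kin.legend(loc="upper left", fontsize=8)
    ax_kin.set_xlabel("time step")
    ax_kin.set_ylabel("valgus rotation (deg)")
    ax_kin.set_title(f"{parameter}: valgus kinematics")

    rows = comp.sort_values(["direction", "plan_id"])
    labels = [f"{p.split('__')[-1]} ({d[:3]})" for p, d in zip(rows["plan_id"], rows["direction"])]
    values = rows["pressure_pct_diff"].to_numpy(float)
    colors = ["0.6" if exc else "C1" for exc in rows["excluded"]]
    ax_bar.bar(range(len(rows)), np.nan_to_num(values), color=colors)
    for i, exc in enumerate(rows["excluded"]):
        if exc:
            ax_bar.text(i, 0.5, "excl.", rotation=90, ha="center", va="bottom", fontsize=7)
    ax_bar.set_xticks(range(len(rows)), labels, rotation=60, ha="right", fontsize=7)
    ax_bar.set_ylabel("peak pressure diff (%)")
    ax_bar.set_title(f"{parameter}: peak contact pressure")

    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def render_report(
    ratings: pd.DataFrame,
    comparisons: pd.DataFrame,
    out_dir: str | Path,
    bundles_dir: str | Path | None = None,
) -> Path:
    """Render the heatmap and one figure per parameter of interest.

    Excluded runs are drawn greyed-out and annotated.  Output is
    deterministic for a fixed rating matrix and comparison table.
    """
    if ratings.empty:
        raise ValueError("rating matrix is empty; nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rating_heatmap(ratings, out / "rating_heatmap.png")
    bundles = Path(bundles_dir) if bundles_dir is not None else None
    if not comparisons.empty:
        comparisons = comparisons.copy()
        comparisons["parameter"] = [
            pid.split("__")[1] + (f"[{pid.split('__')[2]}]" if pid.split("__")[2] != "-" else "")
            if len(pid.split("__")) == 4
            else pid
            for pid in comparisons["plan_id"]
        ]
        for parameter, group in comparisons.groupby("parameter"):
            safe = parameter.replace("[", "_").replace("]", "")
            _parameter_figure(parameter, group, bundles, out / f"param_{safe}.png")
    return out
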