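"""End-to-end orchestration: fixture reproduction and synthetic runs.

Two entry points cover the two ways the pipeline is exercised:

* :func:`run_fixture_comparison` replays the published quantification
  tables through normalization-free fixture mode — two-fold
  classification of the TM vs CON and CWP vs CON tables, their
  overlap, and the functional-class proportions of the catalog;
* :func:`run_synthetic` generates a seeded synthetic scene, quantifies
  the rendered gels, classifies fold changes, and scores the result
  against the scene's ground truth.

Reports are plain JSON with a provenance block (config, seed,
package version) so every threshold actually used is recorded.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .differential import (
    class_proportions,
    classify_twofold,
    differential_frame,
    match_spots,
    normalize_ppm,
    overlap_analysis,
    passing,
)
from .fixtures import load_catalog, load_table2, load_table3
from .io import write_report
from .quantify import quantify_gel
from .simulate import GelScene, SimulationConfig, simulate_scene


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run."""

    mode: str = "fixtures"  # "fixtures" | "simulate"
    fold: float = 2.0
    match_tol: tuple[float, float] = (0.1, 0.05)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    background_radius: int = 25
    min_separation: int = 8
    threshold_k: float = 5.0
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold threshold must be > 1")


def _finite(x: float) -> float | str:
    if math.isnan(x):
        return "nan"
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return x


def _records_json(records) -> list[dict]:
    frame = differential_frame(records)
    out = frame.to_dict(orient="records")
    for row in out:
        row["ratio"] = _finite(row["ratio"])
    return out


def run_fixture_comparison(fold: float = 2.0) -> dict:
    """Reproduce the published differential analysis from the fixtures.

    Returns a report whose summary block carries the headline counts:
    passing spots in TM vs CON and in CWP vs CON, the number shared
    between the two comparisons, and how many of those move in the
    same versus opposite directions, plus the catalog's class
    proportions.
    """
    t2, t3 = load_table2(), load_table3()
    pairs_tm = match_spots(t2["TM"], t2["CON"])
    pairs_cwp = match_spots(t3["CWP"], t3["CON"])
    recs_tm = classify_twofold(pairs_tm, fold=fold)
    recs_cwp = classify_twofold(pairs_cwp, fold=fold)
    overlap = overlap_analysis(passing(recs_tm), passing(recs_cwp))
    catalog = load_catalog()
    classes = class_proportions(catalog)
    inflammatory = classes.set_index("functional_class")
    report = {
        "schema_version": 1,
        "summary": {
            "n_passing_tm": len(passing(recs_tm)),
            "n_passing_cwp": len(passing(recs_cwp)),
            "n_shared": overlap.n_shared,
            "n_same_direction": overlap.n_same_direction,
            "n_opposite_direction": overlap.n_opposite_direction,
            "n_catalog": len(catalog),
            "inflammatory_percent": float(inflammatory.loc["inflammatory", "percent"]),
            "inflammatory_percent_display": int(
                inflammatory.loc["inflammatory", "percent_display"]
            ),
        },
        "comparisons": {
            "TM_vs_CON": _records_json(recs_tm),
            "CWP_vs_CON": _records_json(recs_cwp),
        },
        "overlap": {
            "shared_ids": overlap.shared_ids,
            "same_direction_ids": overlap.same_direction_ids,
            "opposite_direction_ids": overlap.opposite_direction_ids,
        },
        "class_proportions": classes.to_dict(orient="records"),
        "provenance": {"mode": "fixtures", "fold": fold, "version": __version__},
    }
    return report


def evaluate_scene(
    scene: GelScene,
    fold: float = 2.0,
    match_tol: tuple[float, float] = (0.1, 0.05),
    background_radius: int = 25,
    min_separation: int = 8,
    threshold_k: float = 5.0,
) -> dict:
    """Quantify a scene's gels, classify, and score against ground truth.

    Truth spots are assigned to differential records by nearest
    coordinates within ``match_tol``; a truth spot with no nearby
    record counts as a miss (differential) or a non-call (null).
    """
    case = normalize_ppm(quantify_gel(
        scene.images["case"], background_radius=background_radius,
        min_separation=min_separation, threshold_k=threshold_k))
    control = normalize_ppm(quantify_gel(
        scene.images["control"], background_radius=background_radius,
        min_separation=min_separation, threshold_k=threshold_k))
    pairs = match_spots(case, control, tol=match_tol)
    records = classify_twofold(pairs, fold=fold)

    # locate each record at its observed coordinates (case side wins)
    rec_coords = []
    for (case_rec, control_rec), rec in zip(pairs, records):
        src = case_rec if case_rec is not None else control_rec
        rec_coords.append((src.pi_coord, math.log10(src.mw_coord), rec))
    truth = scene.truth
    tol_pi, tol_lmw = match_tol
    assigned: dict[str, object] = {}
    for pi, lmw, rec in rec_coords:
        d = np.sqrt(
            ((truth["pi"] - pi) / tol_pi) ** 2
            + ((np.log10(truth["mw_kda"]) - lmw) / tol_lmw) ** 2
        )
        k = int(d.idxmin())
        if d[k] <= 1.0:
            sid = truth.loc[k, "spot_id"]
            prev = assigned.get(sid)
            # keep the closer record if two land on the same truth spot
            if prev is None or d[k] < prev[0]:
                assigned[sid] = (float(d[k]), rec)

    is_diff = dict(zip(truth["spot_id"], truth["differential"]))
    true_ratio = dict(zip(truth["spot_id"], truth["true_ratio"]))
    n_diff = int(truth["differential"].sum())
    n_null = len(truth) - n_diff
    diff_hits = sum(
        1 for sid, (_, rec) in assigned.items()
        if is_diff[sid] and rec.passes_twofold
    )
    null_passes = sum(
        1 for sid, (_, rec) in assigned.items()
        if not is_diff[sid] and rec.passes_twofold
    )
    rel_errors = [
        abs(rec.ratio / true_ratio[sid] - 1.0)
        for sid, (_, rec) in assigned.items()
        if math.isfinite(rec.ratio) and rec.ratio > 0
    ]
    n_detected = {g: len([r for r in t]) for g, t in (("case", case), ("control", control))}
    return {
        "n_truth_spots": len(truth),
        "n_truth_differential": n_diff,
        "n_truth_null": n_null,
        "n_detected": n_detected,
        "n_assigned": len(assigned),
        "differential_recall": diff_hits / n_diff if n_diff else float("nan"),
        "null_pass_rate": null_passes / n_null if n_null else float("nan"),
        "median_ratio_rel_error": float(np.median(rel_errors)) if rel_errors else float("nan"),
        "n_passing": len(passing(records)),
    }


def run_synthetic(config: RunConfig) -> dict:
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    scene = simulate_scene(sim)
    metrics = evaluate_scene(
        scene, fold=config.fold, match_tol=config.match_tol,
        background_radius=config.background_radius,
        min_separation=config.min_separation, threshold_k=config.threshold_k,
    )
    return {
        "schema_version": 1,
        "summary": metrics,
        "provenance": {
            "mode": "simulate",
            "fold": config.fold,
            "seed": config.seed,
            "simulation": dataclasses.asdict(sim),
            "version": __version__,
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute one configured run and (optionally) write its report."""
    if config.mode == "fixtures":
        report = run_fixture_comparison(fold=config.fold)
    elif config.mode == "simulate":
        report = run_synthetic(config)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
        manifest = {
            "complete": True,
            "mode": config.mode,
            "artifacts": ["report.json"],
        }
        write_report(manifest, out / "manifest.json")
    return report


def make_figures(report: dict, out_dir: str | Path) -> list[Path]:
    """Bar chart of functional-class proportions + the underlying CSV."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    rows = report.get("class_proportions")
    if not rows:
        raise ValueError("report has no class_proportions block")
    frame = pd.DataFrame(rows)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "class_proportions.csv"
    frame.to_csv(csv_path, index=False)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(frame["functional_class"], frame["percent"], color="#47697E")
    ax.set_ylabel("identified spots (%)")
    ax.set_xlabel("functional class")
    ax.set_title("Functional classes of identified proteins")
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    png_path = out / "class_proportions.png"
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return [csv_path, png_path]
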