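"""End-to-end orchestration: simulate -> classify -> evaluate -> stats -> maps.

A run is driven by one YAML config (single source of truth) and a seed;
given the same config and seed the artifact directory is byte-identical.
Layout::

    <out>/
      annotations/   truth, observer and automated per-second labels (CSV)
      metrics/       confusion matrix, per-class metrics, concordance JSON
      budgets/       time budgets and cumulative durations (CSV)
      stats/         daily table and non-parametric test results (CSV)
      heatmaps/      per-period density grids, difference map (CSV + PNG)
      logs/          stage log
      manifest.json  config hash, seed, package version, stage list

A stage failure leaves ``FAILED_<stage>`` in the output directory so a
partial run is recognisable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import RuleConfig, classify_track
from .ethogram_stats import (
    chi_square_counts,
    chi_square_pairwise,
    daily_values,
    fligner_killeen,
    mann_whitney,
    time_budget,
)
from .evaluation import build_confusion, cumulative_budget, kendalls_w, per_class_metrics
from .pose_io import write_annotations_csv, write_pose_csv, write_tracking_points
from .spatial import difference_map, heatmap, render_heatmap
from .synthetic import (
    PERIODS,
    SimConfig,
    StudySimConfig,
    realize_keypoints,
    simulate_behavior_sequence,
    simulate_observer,
    simulate_study_table,
    simulate_tracking_points,
)

log = logging.getLogger("ethopose.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"duration_s": 1800, "jitter_px": 1.0, "miss_prob": 0.02},
    "observer": {"error_rate": 0.05, "out_of_sight_rate": 0.05},
    "rules": {},
    "study": {"n_days_per_period": 8, "effect": {"category": "Scenting", "shift": 6.0}},
    "heatmap": {
        "n_points": 3000,
        "scent_xy": [1500.0, 300.0],
        "home_xy": [600.0, 600.0],
        "shift_weight": 0.4,
    },
}


def load_run_config(path: str | Path | None) -> dict:
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(out_dir: str | Path, config: dict | None = None, seed: int | None = None) -> Path:
    """Run the full synthetic pipeline into ``out_dir``; returns the path."""
    config = config or load_run_config(None)
    if seed is not None:
        config = {**config, "seed": int(seed)}
    seed = int(config["seed"])
    out = Path(out_dir)
    for sub in ("annotations", "metrics", "budgets", "stats", "heatmaps", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "logs" / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s [%(stage)s] %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    stage = "init"

    def info(msg: str) -> None:
        log.info(msg, extra={"stage": stage})

    try:
        stage = "simulate"
        sim = SimConfig(seed=seed, **config.get("simulate", {}))
        sequence = simulate_behavior_sequence(sim)
        track, truth = realize_keypoints(sequence, sim)
        write_pose_csv([track], out / "annotations" / "pose_track.csv")
        write_annotations_csv([truth], out / "annotations" / "truth.csv")
        info(f"simulated {len(truth)} s of behavior")

        stage = "classify"
        rules = RuleConfig(**config.get("rules", {}))
        predicted = classify_track(track, rules)
        write_annotations_csv([predicted], out / "annotations" / "automated.csv")
        obs_cfg = config.get("observer", {})
        observed = simulate_observer(truth, seed=seed + 1, **obs_cfg)
        write_annotations_csv([observed], out / "annotations" / "manual.csv")
        info("classified track and simulated manual observer")

        stage = "evaluate"
        cm = build_confusion(observed, predicted)
        cm.to_frame().to_csv(out / "metrics" / "confusion.csv")
        metrics = per_class_metrics(cm)
        metrics.to_csv(out / "metrics" / "metrics.csv")
        budget_manual = cumulative_budget(observed, observed.categories)
        budget_auto = cumulative_budget(predicted, predicted.categories)
        from .evaluation import DEFAULT_CATEGORY_MAP

        def _merged_counts(series):
            mapped = series.labels.map(lambda c: DEFAULT_CATEGORY_MAP.get(c, c))
            vc = mapped.value_counts()
            return [int(vc.get(c, 0)) for c in cm.categories]

        durations = np.vstack([_merged_counts(observed), _merged_counts(predicted)])
        conc = kendalls_w(durations)
        (out / "metrics" / "concordance.json").write_text(
            json.dumps(dataclasses.asdict(conc), indent=2) + "\n"
        )
        info(f"W={conc.W:.3f} p={conc.p:.3f} over {conc.n} categories")

        stage = "budget"
        tb = time_budget(predicted)
        tb.proportions.rename("proportion").to_csv(out / "budgets" / "automated_budget.csv")
        budget_manual.rename("seconds").to_csv(out / "budgets" / "manual_durations.csv")
        budget_auto.rename("seconds").to_csv(out / "budgets" / "automated_durations.csv")
        info(f"time budget over {tb.observed_s} observed seconds")

        stage = "stats"
        study_cfg = dict(config.get("study", {}))
        effect = study_cfg.pop("effect", None)
        study = StudySimConfig(seed=seed + 2, **study_cfg)
        if effect:
            study = study.with_effect(effect["category"], float(effect["shift"]))
        table = simulate_study_table(study)
        table.to_csv(out / "stats" / "daily_table.csv", index=False)
        results = []
        for ind in study.individuals:
            for cat in study.categories:
                x = daily_values(table, ind, "control", cat)
                y = daily_values(table, ind, "test", cat)
                u, p = mann_whitney(x, y)
                results.append(
                    {
                        "comparison": f"{ind}: control vs test",
                        "behavior": cat,
                        "test": "mann-whitney",
                        "statistic": u,
                        "p": p,
                    }
                )
                fk_stat, _, fk_p = fligner_killeen([x, y])
                results.append(
                    {
                        "comparison": f"{ind}: control vs test",
                        "behavior": cat,
                        "test": "fligner-killeen",
                        "statistic": fk_stat,
                        "p": fk_p,
                    }
                )
            mean_day_s = 3600  # nominal observed seconds/day for count-based tests
            counts = {
                period: np.array(
                    [
                        daily_values(table, ind, period, c).mean() * mean_day_s
                        for c in study.categories
                    ]
                )
                for period in PERIODS
            }
            chi = chi_square_counts(counts["control"], counts["test"])
            results.append(
                {
                    "comparison": f"{ind}: control vs test",
                    "behavior": "all",
                    "test": "chi-square",
                    "statistic": chi.chi2,
                    "p": chi.p,
                }
            )
            pairwise = chi_square_pairwise(
                counts["control"], counts["test"], study.categories
            )
            for _, row in pairwise.iterrows():
                results.append(
                    {
                        "comparison": f"{ind}: control vs test",
                        "behavior": row["category"],
                        "test": "chi-square-2x2",
                        "statistic": row["chi2"],
                        "p": row["p"],
                    }
                )
        pd.DataFrame(results).to_csv(out / "stats" / "tests.csv", index=False)
        info(f"ran {len(results)} non-parametric comparisons")

        stage = "heatmap"
        hm_cfg = config.get("heatmap", {})
        n_pts = int(hm_cfg.get("n_points", 3000))
        scent = tuple(hm_cfg.get("scent_xy", (1500.0, 300.0)))
        home = tuple(hm_cfg.get("home_xy", (600.0, 600.0)))
        w_shift = float(hm_cfg.get("shift_weight", 0.4))
        control_pts = simulate_tracking_points(
            n_pts, [(1.0, home, 160.0)], seed=seed + 3, period="control"
        )
        test_pts = simulate_tracking_points(
            n_pts,
            [(1.0 - w_shift, home, 160.0), (w_shift, scent, 90.0)],
            seed=seed + 4,
            period="test",
        )
        write_tracking_points(
            pd.concat([control_pts, test_pts], ignore_index=True),
            out / "heatmaps" / "tracking_points.csv",
        )
        grid_c = heatmap(control_pts)
        grid_t = heatmap(test_pts)
        diff = difference_map(grid_t, grid_c)
        grid_c.to_csv(out / "heatmaps" / "control.csv")
        grid_t.to_csv(out / "heatmaps" / "test.csv")
        pd.DataFrame(diff).to_csv(out / "heatmaps" / "difference.csv", index=False, header=False)
        render_heatmap(grid_c.values, grid_c, out / "heatmaps" / "control.png", title="control")
        render_heatmap(grid_t.values, grid_t, out / "heatmaps" / "test.png", title="test")
        render_heatmap(
            diff, grid_c, out / "heatmaps" / "difference.png", diverging=True,
            title="test - control",
        )
        info("wrote heat maps")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": seed,
            "config_sha256": _config_hash(config),
            "stages": ["simulate", "classify", "evaluate", "budget", "stats", "heatmap"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return out
    except Exception:
        (out / f"FAILED_{stage}").write_text(f"pipeline failed during stage {stage}\n")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
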