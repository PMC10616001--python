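"""End-to-end orchestration: simulate -> derive -> score -> burden -> stats.

A single run config (YAML/JSON-friendly dict) drives every stage with one
master seed; per-stage seeds are split from it so toggling a stage never
shifts the random draws of another.  All artifacts land in one output
directory:

* ``pattern/``      — covariance-pattern sidecar (weight/GMP/mask NIfTI + JSON)
* ``scores.csv``    — id, timepoint, raw, z for every scored scan
* ``declines.csv``  — paired baseline/post expression declines
* ``burden.json``   — phantom lesion burden + brain glycolysis metrics
* ``stats.json``    — group comparisons and pattern-recovery checks
* ``truth.csv``     — planted ground-truth expression per subject
* ``run.log``       — seed, versions, stage progress

A failed run removes whatever partial artifacts it created and re-raises.
"""

from __future__ import annotations

import json
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, burden, scoring, ssm, stats, synthetic

log = logging.getLogger("covpet")

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "grid_shape": [64, 64, 48],
    "spacing_mm": [2.0, 2.0, 2.0],
    "cohort": {
        "n_control": synthetic.DEFAULT_N_CONTROL,
        "n_patient": synthetic.DEFAULT_N_PATIENT,
        "delta": synthetic.DEFAULT_DELTA,
        "tau": synthetic.DEFAULT_TAU,
        "sigma_noise": 0.02,
        "sigma_global": 0.15,
    },
    "posttreatment": {"delta": 0.9, "tau": 0.78},
    "preprocess": {"fwhm_mm": 10.0, "mask_fraction": 0.2},
    "derivation": {"vaf_cutoff": 0.5, "z_convention": "control"},
    "burden": {"fraction": 0.41, "min_suv": 2.5},
    "stages": ["simulate", "derive", "score", "burden", "stats"],
}


def make_demo_config(out_dir: str | Path) -> Path:
    """Write the default demo config (derivation-size cohort, seed 7)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "demo_config.yaml"
    path.write_text(yaml.safe_dump(DEFAULT_CONFIG, sort_keys=True))
    return path


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _merged(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(int(seed)).generate_state(3)
    return {
        "cohort": int(state[0] % 2**31),
        "posttreatment": int(state[1] % 2**31),
    }


def _demo_body_spec(grid, spacing) -> synthetic.LesionPhantomSpec:
    """Three disjoint ellipsoidal lesions + one high-uptake 'organ'."""
    extent = [n * s for n, s in zip(grid, spacing)]
    cx, cy, cz = (e / 2 for e in extent)
    return synthetic.LesionPhantomSpec(
        grid_shape=tuple(grid),
        spacing_mm=tuple(spacing),
        background_suv=0.5,
        lesions=[
            synthetic.Solid((cx * 0.5, cy * 0.6, cz * 0.7), (14, 12, 12), 12.0),
            synthetic.Solid((cx * 1.4, cy * 1.3, cz * 0.9), (10, 10, 14), 8.0),
            synthetic.Solid((cx * 0.8, cy * 1.5, cz * 1.3), (8, 8, 8), 6.0),
        ],
        organs=[synthetic.Solid((cx * 1.2, cy * 0.5, cz * 1.4), (16, 14, 12), 9.0)],
    )


def run_pipeline(config: dict | None = None, out_dir: str | Path = "covpet_run") -> Path:
    """Execute the configured stages; returns the artifact directory."""
    cfg = _merged(config)
    out_dir = Path(out_dir)
    created_out_dir = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts.append(out_dir / "run.log")

    try:
        seed = int(cfg["seed"])
        seeds = _stage_seeds(seed)
        stages = list(cfg["stages"])
        log.info("covpet %s, numpy %s, seed %d, stages %s",
                 __version__, np.__version__, seed, stages)

        grid = tuple(int(n) for n in cfg["grid_shape"])
        spacing = tuple(float(s) for s in cfg["spacing_mm"])
        template = synthetic.make_template(grid, spacing)
        pattern_truth = synthetic.make_planted_pattern(
            template, synthetic.default_pattern_spec(template)
        )

        cohort = post_cohort = None
        if "simulate" in stages:
            cohort_cfg = synthetic.CohortConfig(seed=seeds["cohort"], **cfg["cohort"])
            cohort = synthetic.simulate_cohort(template, pattern_truth, cohort_cfg)
            truth = pd.DataFrame({
                "id": [s.id for s in cohort.scans],
                "label": cohort.labels,
                "true_score": cohort.true_scores,
            })
            truth.to_csv(out_dir / "truth.csv", index=False)
            artifacts.append(out_dir / "truth.csv")
            log.info("simulated cohort: %d controls, %d patients on grid %s",
                     cohort_cfg.n_control, cohort_cfg.n_patient, grid)

        pattern = raw = z = None
        if "derive" in stages:
            if cohort is None:
                raise ValueError("derive stage requires the simulate stage")
            pattern, raw, z = ssm.derive(
                cohort.scans, cohort.labels,
                fwhm_mm=cfg["preprocess"]["fwhm_mm"],
                mask_fraction=cfg["preprocess"]["mask_fraction"],
                vaf_cutoff=cfg["derivation"]["vaf_cutoff"],
                z_convention=cfg["derivation"]["z_convention"],
            )
            pattern.provenance["seed"] = seed
            pattern.save(out_dir / "pattern")
            artifacts.append(out_dir / "pattern")
            log.info("derived pattern: %d candidate components, mask %d voxels",
                     len(pattern.component_indices), pattern.mask.n_voxels)

        scores_df = declines = None
        if "score" in stages:
            if pattern is None or cohort is None:
                raise ValueError("score stage requires simulate and derive stages")
            scores_df = scoring.score_scans(pattern, cohort.scans, timepoint="baseline")
            pt_cfg = synthetic.CohortConfig(
                n_control=3,  # placeholder controls, dropped below
                n_patient=int(cfg["cohort"]["n_patient"]),
                delta=float(cfg["posttreatment"]["delta"]),
                tau=float(cfg["posttreatment"]["tau"]),
                sigma_noise=float(cfg["cohort"]["sigma_noise"]),
                sigma_global=float(cfg["cohort"]["sigma_global"]),
                seed=seeds["posttreatment"],
            )
            post_cohort = synthetic.simulate_cohort(template, pattern_truth, pt_cfg)
            post_scans = [s for s, lab in zip(post_cohort.scans, post_cohort.labels)
                          if lab == "patient"]
            baseline_pat = scores_df[scores_df["id"].str.startswith("pat")]
            for scan, pat_id in zip(post_scans, baseline_pat["id"]):
                scan.id = pat_id
            post_df = scoring.score_scans(pattern, post_scans, timepoint="post")
            scores_df = pd.concat([scores_df, post_df], ignore_index=True)
            scores_df.to_csv(out_dir / "scores.csv", index=False)
            artifacts.append(out_dir / "scores.csv")
            declines = scoring.score_change(baseline_pat, post_df)
            declines.to_csv(out_dir / "declines.csv", index=False)
            artifacts.append(out_dir / "declines.csv")
            log.info("scored %d baseline + %d post-treatment scans",
                     len(cohort.scans), len(post_scans))

        burden_out = None
        if "burden" in stages:
            body_scan, body_truth = synthetic.simulate_body_phantom(
                _demo_body_spec(grid, spacing)
            )
            seg = burden.segment_all(
                body_scan, exclusion_mask=body_truth < 0,
                fraction=cfg["burden"]["fraction"], min_suv=cfg["burden"]["min_suv"],
            )
            metrics = burden.burden_metrics(seg, body_scan)
            brain_scan = synthetic.Scan(
                values=np.where(template.brain_mask, np.exp(template.mu), 0.0),
                spacing_mm=spacing, id="brain", units="SUV",
            )
            brain = burden.brain_glycolysis(brain_scan, template.mask)
            burden_out = {
                "n_lesions": metrics.n_lesions,
                "tmtv_ml": metrics.tmtv_ml,
                "suv_max": metrics.suv_max,
                "suv_mean": metrics.suv_mean,
                "tlg": metrics.tlg,
                "lg_tmtv": metrics.lg_tmtv,
                "lg_tlg": metrics.lg_tlg,
                "brain_suv_max": brain.suv_max,
                "brain_suv_mean": brain.suv_mean,
                "brain_volume_ml": brain.volume_ml,
                "tbg": brain.tbg,
            }
            (out_dir / "burden.json").write_text(json.dumps(burden_out, indent=2, sort_keys=True))
            artifacts.append(out_dir / "burden.json")
            log.info("burden: %d lesions, TMTV %.1f mL, TLG %.1f, TBG %.1f",
                     metrics.n_lesions, metrics.tmtv_ml, metrics.tlg, brain.tbg)

        if "stats" in stages:
            if pattern is None or cohort is None or scores_df is None:
                raise ValueError("stats stage requires simulate, derive and score stages")
            labels = np.asarray(cohort.labels)
            baseline = scores_df[scores_df["timepoint"] == "baseline"]
            z_ctrl = baseline[labels == "control"]["z"].to_numpy()
            z_pat = baseline[labels == "patient"]["z"].to_numpy()
            group_cmp = stats.compare_two(z_ctrl, z_pat)
            paired = stats.paired_compare(
                declines["baseline_z"].to_numpy(), declines["post_z"].to_numpy()
            )
            truth_mask = pattern.mask.indicator
            r_weights = float(np.corrcoef(
                pattern.weight_volume()[truth_mask], cohort.pattern_truth[truth_mask]
            )[0, 1])
            r_scores = float(np.corrcoef(baseline["raw"], cohort.true_scores)[0, 1])
            corr = stats.correlate(baseline["z"], cohort.true_scores, "pearson")
            stats_out = {
                "control_vs_patient": {
                    "test": group_cmp.name, "statistic": group_cmp.statistic,
                    "p": group_cmp.p, "n": group_cmp.n,
                },
                "baseline_vs_post_paired": {
                    "test": paired.name, "statistic": paired.statistic, "p": paired.p,
                    "mean_decline": float(declines["decline"].mean()),
                },
                "recovery": {
                    "r_weights_vs_truth": r_weights,
                    "r_scores_vs_truth": r_scores,
                    "criterion_r_ge_0.9": bool(abs(r_weights) >= 0.9 and r_scores >= 0.9),
                },
                "z_vs_truth_pearson": {"r": corr.statistic, "p": corr.p},
                "group_z_means": {
                    "control": float(z_ctrl.mean()), "patient": float(z_pat.mean()),
                },
                "seed": seed,
            }
            (out_dir / "stats.json").write_text(json.dumps(stats_out, indent=2, sort_keys=True))
            artifacts.append(out_dir / "stats.json")
            log.info("stats: control vs patient p=%.3g, recovery r_weights=%.3f "
                     "r_scores=%.3f", group_cmp.p, r_weights, r_scores)
        return out_dir
    except Exception:
        log.exception("pipeline failed; removing partial artifacts")
        handler.close()
        log.removeHandler(handler)
        for path in artifacts:
            if path.is_dir():
                shutil.rmtree(path, ignore_errors=True)
            elif path.exists():
                path.unlink()
        if created_out_dir and not any(out_dir.iterdir()):
            out_dir.rmdir()
        raise
    finally:
        if handler in log.handlers:
            handler.close()
            log.removeHandler(handler)
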