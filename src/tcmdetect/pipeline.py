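"""End-to-end pipeline driver: simulate -> preprocess -> extract -> select
-> train -> evaluate -> report, with every artifact written to a run
directory together with its SHA-256 content hash so a run is reproducible
from config + seed alone."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as tio
from .features import MODES, build_feature_matrix
from .preprocessing import preprocess_cohort
from .selection import SelectionConfig, cv_loss, forward_select
from .synthetic import EXERCISE_NAMES, SensorModel, generate_cohort
from .tree import fit_cart, loso_evaluate, plot_feature_scatter

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("tcmdetect")


@dataclass
class PipelineConfig:
    """Validated, fully serializable pipeline configuration."""

    n_subjects: int = 30
    exercises: list[str] = field(default_factory=lambda: list(EXERCISE_NAMES))
    effect_scale: float = 1.0
    seed: int = 0
    mode: str = "all"  # all | s1 | s2 | s3
    cv_folds: int = 5
    max_subset_size: int = 5
    scaling: str = "full"  # full | train_only (z-score leakage mode)
    keep_sides: bool = False
    sampling_rate: float = 200.0
    resolution_bits: int = 12
    noise_sd: float = 0.15
    full_scale_g: float = 4.0
    make_plots: bool = True

    def __post_init__(self):
        from .synthetic import DEFAULT_EXERCISES

        unknown = [e for e in self.exercises if e not in DEFAULT_EXERCISES]
        if unknown:
            raise ValueError(f"unknown exercises: {unknown}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.scaling not in ("full", "train_only"):
            raise ValueError("scaling must be 'full' or 'train_only'")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be non-negative")

    def sensor_model(self) -> SensorModel:
        from .synthetic import GRAVITY

        return SensorModel(
            sampling_rate=self.sampling_rate,
            resolution_bits=self.resolution_bits,
            noise_sd=self.noise_sd,
            full_scale=self.full_scale_g * GRAVITY,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the whole pipeline; returns the per-exercise result summary.

    Writes per-exercise feature matrices, selection results, fitted models,
    evaluation reports (5-fold CV and leave-one-subject-out) and scatter
    plots into ``out_dir``; ``run.json`` records the config, per-artifact
    SHA-256 hashes and the headline numbers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    try:
        return _run(config, out_dir)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(config: PipelineConfig, out_dir: Path) -> dict:
    log.info("stage=simulate subjects=%d exercises=%s effect_scale=%s seed=%d",
             config.n_subjects, config.exercises, config.effect_scale, config.seed)
    try:
        recordings, manifest = generate_cohort(
            n_subjects=config.n_subjects,
            exercises=config.exercises,
            sensor_model=config.sensor_model(),
            effect_scale=config.effect_scale,
            master_seed=config.seed,
            keep_sides=config.keep_sides,
        )
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc
    manifest.to_csv(out_dir / "manifest.csv", index=False)

    artifacts = {"manifest.csv": tio.sha256_file(out_dir / "manifest.csv")}
    results: dict = {}
    exercise_labels = sorted(manifest["exercise"].unique())
    for exercise in exercise_labels:
        log.info("stage=preprocess exercise=%s", exercise)
        recs = [r for r in recordings if r.exercise == exercise]
        try:
            sets = preprocess_cohort(recs)
        except Exception as exc:
            raise RuntimeError(f"stage preprocess failed ({exercise}): {exc}") from exc

        log.info("stage=extract exercise=%s mode=%s n_sets=%d", exercise, config.mode, len(sets))
        try:
            matrix = build_feature_matrix(sets, mode=config.mode)
        except Exception as exc:
            raise RuntimeError(f"stage extract failed ({exercise}): {exc}") from exc
        mat_path = out_dir / f"features_{exercise}_{config.mode}.csv"
        tio.write_feature_matrix(matrix, mat_path)
        artifacts[mat_path.name] = tio.sha256_file(mat_path)

        log.info("stage=select exercise=%s", exercise)
        sel_config = SelectionConfig(
            max_subset_size=config.max_subset_size,
            cv_folds=config.cv_folds,
            rng_seed=config.seed,
            mode=config.mode,
            scaling=config.scaling,
        )
        try:
            selection = forward_select(matrix, sel_config)
        except Exception as exc:
            raise RuntimeError(f"stage select failed ({exercise}): {exc}") from exc
        sel_path = out_dir / f"selection_{exercise}.json"
        sel_path.write_text(json.dumps(selection.to_dict(), indent=2) + "\n")
        artifacts[sel_path.name] = tio.sha256_file(sel_path)

        features = selection.accepted_features
        if not features:
            log.warning("exercise=%s: no feature improved on the baseline", exercise)
            results[exercise] = {"selection": selection.to_dict(), "features": []}
            continue

        log.info("stage=train exercise=%s features=%s", exercise, features)
        try:
            model = fit_cart(matrix.X, matrix.y, features)
        except Exception as exc:
            raise RuntimeError(f"stage train failed ({exercise}): {exc}") from exc
        model_path = out_dir / f"model_{exercise}.json"
        model.to_json(model_path)
        artifacts[model_path.name] = tio.sha256_file(model_path)

        log.info("stage=evaluate exercise=%s", exercise)
        try:
            cv = cv_loss(matrix, features, sel_config)
            loso = loso_evaluate(matrix, features, scaling=config.scaling)
        except Exception as exc:
            raise RuntimeError(f"stage evaluate failed ({exercise}): {exc}") from exc
        report = {
            "exercise": exercise,
            "features": features,
            "split_values": model.split_values(),
            "cv5": {"loss": cv, "accuracy": 1.0 - cv},
            "loso": loso.to_dict(),
        }
        rep_path = out_dir / f"evaluation_{exercise}.json"
        rep_path.write_text(json.dumps(report, indent=2) + "\n")
        artifacts[rep_path.name] = tio.sha256_file(rep_path)

        if config.make_plots:
            plot_path = out_dir / f"scatter_{exercise}.png"
            try:
                plot_feature_scatter(matrix, features, model, plot_path)
                artifacts[plot_path.name] = tio.sha256_file(plot_path)
            except Exception as exc:  # plotting must never sink a run
                log.warning("scatter plot failed for %s: %s", exercise, exc)

        results[exercise] = report | {"selection": selection.to_dict()}
        log.info(
            "exercise=%s features=%s cv5_acc=%.3f loso_acc=%.3f",
            exercise, features, 1.0 - cv, loso.accuracy,
        )

    run_record = {
        "config": dataclasses.asdict(config),
        "n_recordings": len(recordings),
        "artifacts": artifacts,
        "results": {
            ex: {k: v for k, v in r.items() if k in ("features", "split_values", "cv5", "loso")}
            for ex, r in results.items()
        },
    }
    (out_dir / "run.json").write_text(json.dumps(run_record, indent=2) + "\n")
    return results
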