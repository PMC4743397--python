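"""End-to-end orchestration: synth → prep → background filter → features →
train/predict → evaluate, with per-stage artifacts and seeded determinism.

Two entry points:

* :func:`run_synthetic_experiment` — the whole screen on a seeded synthetic
  dataset, in memory, returning every intermediate quantity.  This is what
  the acceptance script and the worked README example call.
* :func:`run_pipeline` — stage-wise execution writing artifacts (PNG
  slides, manifest/feature CSVs, model JSON, results CSV/text) under an
  output directory, resumable from any stage.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import classify, evaluate, features as feat
from .background_filter import classify_background, removal_accuracy_from_counts
from .config import RunConfig
from .image_prep import WorkingImage, load_and_resize, tile, to_color_planes
from .synthetic import GroundTruth, SyntheticDataset, SyntheticSpec, generate_dataset

log = logging.getLogger("cytoblock")

STAGES = ("synth", "prep", "features", "train", "predict", "evaluate")

_FEATURE_COLS = list(feat.FEATURE_NAMES)


def extract_image_features(
    image: WorkingImage,
    config: RunConfig | None = None,
    image_id: str = "image",
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Background decisions + 11 features for every block of one image.

    Returns one row per block with the filter decision; feature columns are
    NaN for blocks judged background (unless ``config.keep_background``).
    Ground-truth phenotype/label columns are attached when available.
    """
    config = config or RunConfig()
    grid = tile(image, config.block_size)
    rows = []
    for (i, j), block in grid:
        planes = to_color_planes(block, config.median_window)
        decision = classify_background(
            planes, config.min_peak_proportion, config.riu_non_background_bin
        )
        row: dict = {
            "image_id": image_id,
            "row": i,
            "col": j,
            "is_background": decision.is_background,
            "peak_bin": decision.peak_bin,
        }
        if truth is not None:
            row["phenotype"] = truth.phenotypes[i, j]
            row["label"] = int(truth.labels[i, j])
        if not decision.is_background or config.keep_background:
            vec = feat.assemble(
                planes,
                check_background=False,
                glcm_levels=config.glcm_levels,
                glcm_distance=config.glcm_distance,
            )
            row.update(dict(zip(_FEATURE_COLS, vec.values)))
        else:
            row.update(dict.fromkeys(_FEATURE_COLS, np.nan))
        rows.append(row)
    return pd.DataFrame(rows)


def build_feature_table(
    images: list[tuple[WorkingImage, GroundTruth]],
    config: RunConfig | None = None,
    prefix: str = "image",
) -> pd.DataFrame:
    frames = [
        extract_image_features(img, config, f"{prefix}_{idx:03d}", truth)
        for idx, (img, truth) in enumerate(images)
    ]
    return pd.concat(frames, ignore_index=True)


def _train_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Non-background (by ground truth) blocks with complete features."""
    rows = table[(table["label"] != 0) & table[_FEATURE_COLS].notna().all(axis=1)]
    return rows[_FEATURE_COLS].to_numpy(float), rows["label"].to_numpy(int)


def fit_model(
    table: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[classify.TrainedModel, classify.GridSearchResult | None]:
    """Normalize, optionally grid-search (c, g) with tenfold CV, and train."""
    config = config or RunConfig()
    X, y = _train_matrix(table)
    norm = feat.fit_normalizer(X)
    Xn = norm.transform(X)
    grid = None
    if config.use_grid_search:
        grid = classify.grid_search(
            Xn, y,
            folds=config.folds,
            log10_c_range=config.grid_log10_c,
            log10_g_range=config.grid_log10_g,
            step=config.grid_step,
            seed=config.seed,
        )
        c, g, cv_acc = grid.best_c, grid.best_g, grid.best_accuracy
        log.info("grid search: best c=%.4g g=%.4g (CV accuracy %.4f)", c, g, cv_acc)
    else:
        c, g = config.svm_c, config.svm_g
        cv_acc = classify.cv_accuracy(Xn, y, c, g, config.folds, config.seed)
    model = classify.train(Xn, y, c, g, normalization=norm)
    model.cv_accuracy = cv_acc
    model.fold_seed = config.seed
    return model, grid


def predict_blocks(model: classify.TrainedModel, table: pd.DataFrame) -> pd.DataFrame:
    """Predicted labels for every truth non-background block of a table.

    Blocks removed by the background filter never reach the classifier and
    are scored as predicted-normal: a wrongly removed abnormal block is a
    genuine miss of the screen, not an excluded sample.

    Tables without a ``label`` column (features from unannotated slides)
    are predicted over every filter-passing block instead.
    """
    if "label" in table.columns:
        rows = table[table["label"] != 0].copy()
    else:
        rows = table[~table["is_background"]].copy()
    pred = np.full(len(rows), feat.LABEL_NORMAL, dtype=int)
    usable = (~rows["is_background"]).to_numpy() & rows[_FEATURE_COLS].notna().all(axis=1).to_numpy()
    if usable.any():
        X = rows.loc[usable, _FEATURE_COLS].to_numpy(float)
        pred[usable] = classify.predict(model, X, prenormalized=False)
    rows["predicted"] = pred
    return rows


def run_synthetic_experiment(config: RunConfig | None = None) -> dict:
    """The full screen on a seeded synthetic dataset.

    Returns a dict with the dataset, feature tables, background-removal
    summary, fitted model (+ grid search), per-block predictions, and the
    confusion metrics with a rendered report.
    """
    config = config or RunConfig()
    config.echo("run_synthetic_experiment")
    dataset = generate_dataset(
        n_train_images=config.n_train_images,
        n_test_images=config.n_test_images,
        spec=SyntheticSpec(seed=config.seed),
    )
    train_table = build_feature_table(dataset.train, config, prefix="train")
    test_table = build_feature_table(dataset.test, config, prefix="test")

    # Background-removal score on the test slides (Eq.-29-style: FP = true
    # non-background blocks judged background).
    fp_removed = int(((test_table["label"] != 0) & test_table["is_background"]).sum())
    n_images = config.n_test_images
    bg = {
        "total_blocks": int(len(test_table)),
        "true_background": int((test_table["label"] == 0).sum()),
        "background_blocks": int(test_table["is_background"].sum()),
        "fp_removed": fp_removed,
        "accuracy_pct": removal_accuracy_from_counts(fp_removed, n_images, 80),
    }

    model, grid = fit_model(train_table, config)

    X_train, y_train = _train_matrix(train_table)
    ttest = feat.t_test_report(
        X_train[y_train == feat.LABEL_NORMAL], X_train[y_train == feat.LABEL_SUSPICIOUS]
    )

    predictions = predict_blocks(model, test_table)
    metrics = evaluate.confusion(predictions["predicted"], predictions["label"])
    text, csv = evaluate.report(metrics, background=bg, seed=config.seed)

    return {
        "config": config,
        "dataset": dataset,
        "train_table": train_table,
        "test_table": test_table,
        "background": bg,
        "model": model,
        "grid": grid,
        "t_test": ttest,
        "predictions": predictions,
        "metrics": metrics,
        "report_text": text,
        "report_csv": csv,
    }


# --- stage-wise disk pipeline ----------------------------------------------

def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name} for stage '{needed_by}': run stage '{stage}' first"
        )
    return path


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
    input_images: list[str | Path] | None = None,
) -> dict[str, Path]:
    """Execute a subset of pipeline stages, writing artifacts under ``out_dir``.

    Without ``input_images`` the synth stage provides seeded synthetic
    slides; with them, prep/features run on real image files (labels absent,
    so train/evaluate then need an external labeled feature table).
    Re-running with an identical config rewrites identical artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    artifacts: dict[str, Path] = {}

    if "synth" in stages:
        config.echo("synth")
        dataset = generate_dataset(
            n_train_images=config.n_train_images,
            n_test_images=config.n_test_images,
            spec=SyntheticSpec(seed=config.seed),
        )
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for split, bucket in (("train", dataset.train), ("test", dataset.test)):
            for idx, (img, _truth) in enumerate(bucket):
                Image.fromarray(img.pixels).save(img_dir / f"{split}_{idx:03d}.png")
        dataset.manifest.to_csv(out / "manifest.csv", index=False)
        artifacts["manifest"] = out / "manifest.csv"
        _dataset_cache[out] = dataset

    if "features" in stages or "prep" in stages:
        config.echo("features")
        if input_images:
            images = [(load_and_resize(p, config.target_shape()), None) for p in input_images]
            frames = [
                extract_image_features(img, config, Path(str(p)).stem, None)
                for (img, _), p in zip(images, input_images)
            ]
            table = pd.concat(frames, ignore_index=True)
            table.to_csv(out / "features.csv", index=False)
        else:
            dataset = _dataset_cache.get(out) or _regenerate(config)
            build_feature_table(dataset.train, config, "train").to_csv(
                out / "features_train.csv", index=False
            )
            build_feature_table(dataset.test, config, "test").to_csv(
                out / "features_test.csv", index=False
            )
            artifacts["features_train"] = out / "features_train.csv"
            artifacts["features_test"] = out / "features_test.csv"

    if "train" in stages:
        config.echo("train")
        table = pd.read_csv(_require(out / "features_train.csv", "features", "train"))
        model, _grid = fit_model(table, config)
        classify.save_model(model, out / "model.json")
        artifacts["model"] = out / "model.json"

    if "predict" in stages:
        config.echo("predict")
        model = classify.load_model(_require(out / "model.json", "train", "predict"))
        table = pd.read_csv(_require(out / "features_test.csv", "features", "predict"))
        predictions = predict_blocks(model, table)
        predictions.to_csv(out / "predictions.csv", index=False)
        artifacts["predictions"] = out / "predictions.csv"

    if "evaluate" in stages:
        config.echo("evaluate")
        predictions = pd.read_csv(_require(out / "predictions.csv", "predict", "evaluate"))
        test_table = pd.read_csv(_require(out / "features_test.csv", "features", "evaluate"))
        fp_removed = int(((test_table["label"] != 0) & test_table["is_background"]).sum())
        bg = {
            "total_blocks": int(len(test_table)),
            "background_blocks": int(test_table["is_background"].sum()),
            "accuracy_pct": removal_accuracy_from_counts(
                fp_removed, config.n_test_images, 80
            ),
        }
        metrics = evaluate.confusion(predictions["predicted"], predictions["label"])
        text, csv = evaluate.report(metrics, background=bg, seed=config.seed)
        (out / "results.txt").write_text(text)
        (out / "results.csv").write_text(csv)
        artifacts["results"] = out / "results.csv"
        if config.sensitivity_floor is not None and (
            metrics.sensitivity is None or metrics.sensitivity < config.sensitivity_floor
        ):
            raise SystemExit(
                f"sensitivity {metrics.sensitivity} below floor {config.sensitivity_floor}"
            )
    return artifacts


_dataset_cache: dict[Path, SyntheticDataset] = {}


def _regenerate(config: RunConfig) -> SyntheticDataset:
    return generate_dataset(
        n_train_images=config.n_train_images,
        n_test_images=config.n_test_images,
        spec=SyntheticSpec(seed=config.seed),
    )
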