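"""End-to-end age-estimation pipeline and ablation runner.

Flow: load cohort manifest -> clean -> stratified train/test split ->
per-image min-max scaling and train-fitted Z-scoring of records -> train
the 2-D (image) and 1-D (record) CNN extractors on the training split ->
extract features for all rows -> early fusion -> MG-RF on the training
rows -> regression report on the held-out test rows. Every fitted
statistic (standardisation parameters, extractor weights, GA fitness,
feature ranking) depends only on training rows.

The ablation runner executes six configurations on one shared split with
shared trained extractors: the full fused model; record-features-only
("without 2-D CNN") and image-features-only ("without 1-D CNN"); late
fusion averaging two single-path models ("without concatenation"); and
the two single-path models on their own.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from sklearn.model_selection import train_test_split

from .cnn_features import (
    ArchSpec1D,
    ArchSpec2D,
    TrainConfig,
    build_extractor,
    extract_features,
    train_extractor,
)
from .fusion import FeatureMatrix, concatenate_features
from .metrics import RegressionReport, evaluate_regression
from .mgrf import GAConfig, HyperGrid, fit_mgrf, predict_ages
from .preprocessing import drop_incomplete, minmax_scale_image, zscore_apply, zscore_fit_transform

__all__ = [
    "PipelineConfig",
    "AblationReport",
    "ABLATION_MODES",
    "load_manifest",
    "run_pipeline",
    "run_ablation",
    "desk_scale_config",
]

ABLATION_MODES = ("full", "no_2d", "no_1d", "no_concat", "only_2d", "only_1d")


def desk_scale_config(manifest_path: str | Path, out_dir: str | Path,
                      seed: int = 0) -> "PipelineConfig":
    """The package's desk-scale study configuration.

    A single-CPU-friendly reduction of the full pipeline: 64x64 images
    into a narrower 4-block image CNN (8/16/32/32 filters, 128-unit dense),
    8 training epochs, and a GA of population 20 over 10 generations on a
    reduced tree grid (100/200 estimators). Per-path feature width stays
    at 128, so the fused width is the canonical 256. Both extractor
    architectures and the GA keep their structure; only sizes shrink.
    """
    return PipelineConfig(
        manifest_path=str(manifest_path),
        out_dir=str(out_dir),
        seed=seed,
        arch2d=ArchSpec2D(
            input_shape=(64, 64, 3),
            conv_blocks=((8, 3), (16, 3), (32, 3), (32, 3)),
            dense_units=128,
            feature_units=128,
        ),
        arch1d=ArchSpec1D(feature_units=128),
        train=TrainConfig(epochs=8, batch_size=32, learning_rate=1e-3),
        ga=GAConfig(population_size=20, generations=10),
        grid=HyperGrid(
            max_depth=(10, 20, None),
            n_estimators=(100, 200),
        ),
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; the written snapshot reproduces the run."""

    manifest_path: str
    out_dir: str
    train_fraction: float = 0.8
    stratify_by_age: bool = True
    seed: int = 0
    arch2d: ArchSpec2D = field(default_factory=ArchSpec2D)
    arch1d: ArchSpec1D = field(default_factory=ArchSpec1D)
    train: TrainConfig = field(default_factory=TrainConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    grid: HyperGrid = field(default_factory=HyperGrid)
    ablation_mode: str = "full"

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.ablation_mode not in ABLATION_MODES:
            raise ValueError(f"ablation_mode must be one of {ABLATION_MODES}")

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("arch2d", ArchSpec2D), ("arch1d", ArchSpec1D),
                         ("train", TrainConfig), ("ga", GAConfig)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for tkey in ("input_shape", "conv_blocks"):
                    if tkey in sub and isinstance(sub[tkey], list):
                        sub[tkey] = tuple(
                            tuple(v) if isinstance(v, list) else v for v in sub[tkey]
                        )
                d[key] = typ(**sub)
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = HyperGrid(**{
                k: tuple(None if v in ("None", "null") else v for v in vals)
                for k, vals in d["grid"].items()
            })
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class AblationReport:
    """Per-configuration regression reports on one shared test split."""

    reports: dict  # mode -> RegressionReport
    test_patient_ids: list

    def to_dict(self) -> dict:
        return {
            "test_patient_ids": list(self.test_patient_ids),
            "reports": {m: r.to_dict() for m, r in self.reports.items()},
        }


def load_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV; image paths resolve against its folder."""
    path = Path(manifest_path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    df.attrs["base_dir"] = str(path.parent)
    return df


def _record_columns(df: pd.DataFrame) -> list[str]:
    cols = sorted(
        (c for c in df.columns if c.startswith("record_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not cols:
        raise ValueError("manifest has no record_* columns")
    return cols


def _load_images(df: pd.DataFrame, base_dir: Path, size: tuple[int, int]) -> np.ndarray:
    """Load, resize (bilinear) and per-image min-max scale all images."""
    h, w = size
    out = np.empty((len(df), h, w))
    for i, rel in enumerate(df["image_path"]):
        p = Path(rel)
        if not p.is_absolute():
            p = base_dir / p
        img = Image.open(p).convert("L")
        if img.size != (w, h):
            img = img.resize((w, h), Image.BILINEAR)
        out[i] = minmax_scale_image(np.asarray(img, dtype=float))
    return out


def _stratified_split(ages: np.ndarray, train_fraction: float, stratify: bool,
                      seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic train/test split, optionally stratified by age-year.

    The test set size is exactly ``round((1 - train_fraction) * n)``.
    Integer-year strata with fewer than two members are merged into one
    bucket so stratification never fails on sparse tails.
    """
    n = ages.size
    idx = np.arange(n)
    strat = None
    if stratify:
        years = np.floor(ages).astype(int)
        uniq, counts = np.unique(years, return_counts=True)
        rare = set(uniq[counts < 2])
        strat = np.array([-999 if y in rare else y for y in years])
        # the merged bucket itself must have >= 2 members to stratify on
        if np.sum(strat == -999) == 1:
            strat = None
    tr, te = train_test_split(
        idx, test_size=round((1 - train_fraction) * n), random_state=seed,
        shuffle=True, stratify=strat,
    )
    return np.sort(tr), np.sort(te)


def _record_matrix(df: pd.DataFrame) -> np.ndarray:
    """Record fields plus sex encoded as a trailing 0/1 (male=1) column."""
    cols = _record_columns(df)
    X = df[cols].to_numpy(dtype=float)
    sex01 = (df["sex"].astype(str).str.lower() == "male").to_numpy(dtype=float)
    return np.hstack([X, sex01[:, None]])


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []
        self._t0 = time.perf_counter()

    def stage(self, name: str, **info) -> None:
        t = time.perf_counter() - self._t0
        extras = " ".join(f"{k}={v}" for k, v in info.items())
        self.lines.append(f"[{t:9.2f}s] {name} {extras}".rstrip())

    def write(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _prepare(cfg: PipelineConfig, log: _RunLog):
    """Shared front half: load, clean, split, normalise, train extractors,
    extract features for every row."""
    df = load_manifest(cfg.manifest_path)
    base_dir = Path(df.attrs["base_dir"])
    df, clean_report = drop_incomplete(df)
    log.stage("clean", kept=len(df), dropped=clean_report.n_dropped_rows)
    if len(df) < 20:
        raise ValueError("cohort too small after cleaning (< 20 rows)")

    ages = df["age_years"].to_numpy(dtype=float)
    ids = df["patient_id"].tolist()
    tr, te = _stratified_split(ages, cfg.train_fraction, cfg.stratify_by_age, cfg.seed)
    log.stage("split", train=tr.size, test=te.size)

    h, w, _ = cfg.arch2d.input_shape
    images = _load_images(df, base_dir, (h, w))
    log.stage("images", n=images.shape[0], size=f"{h}x{w}")

    records = _record_matrix(df)
    rec_tr_std, _, std_params = zscore_fit_transform(records[tr])
    records_std = zscore_apply(records, std_params)
    arch1d = dataclasses.replace(cfg.arch1d, input_length=records.shape[1])

    age_range = (float(ages[tr].min()), float(ages[tr].max()))
    train_cfg = dataclasses.replace(cfg.train, rng_seed=cfg.seed)

    ext2d = build_extractor(cfg.arch2d, seed=cfg.seed, n_age_bins=train_cfg.n_age_bins)
    train_extractor(ext2d, images[tr], ages[tr], train_cfg, age_range=age_range)
    log.stage("train_2d", final_loss=round(ext2d.training_history[-1], 4))

    ext1d = build_extractor(arch1d, seed=cfg.seed + 1, n_age_bins=train_cfg.n_age_bins)
    train_extractor(ext1d, records_std[tr], ages[tr], train_cfg, age_range=age_range)
    log.stage("train_1d", final_loss=round(ext1d.training_history[-1], 4))

    f_img = extract_features(ext2d, images, patient_ids=ids)
    f_rec = extract_features(ext1d, records_std, patient_ids=ids)
    log.stage("extract", img_width=f_img.width, rec_width=f_rec.width)
    return {
        "df": df, "ages": ages, "ids": ids, "train_idx": tr, "test_idx": te,
        "f_img": f_img, "f_rec": f_rec, "std_params": std_params,
        "clean_report": clean_report,
    }


def _subset(F: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        patient_ids=[F.patient_ids[i] for i in idx],
        values=F.values[idx],
        modality=F.modality,
        column_names=F.column_names,
    )


def _fit_and_score(F: FeatureMatrix, ages, tr, te, cfg: PipelineConfig):
    model = fit_mgrf(_subset(F, tr), ages[tr],
                     dataclasses.replace(cfg.ga, rng_seed=cfg.seed), cfg.grid)
    pred = predict_ages(model, _subset(F, te))
    return model, pred, evaluate_regression(ages[te], pred)


def _write_common(cfg: PipelineConfig, prep: dict, out: Path) -> None:
    prep["f_img"].to_csv(out / "features_image.csv")
    prep["f_rec"].to_csv(out / "features_record.csv")
    (out / "standardization_params.json").write_text(prep["std_params"].to_json())
    (out / "config_snapshot.json").write_text(
        json.dumps(cfg.to_dict(), sort_keys=True, indent=2, default=str)
    )


def run_pipeline(cfg: PipelineConfig) -> RegressionReport:
    """Run the full flow and return the held-out test regression report.

    Deterministic under ``cfg.seed``: two identical runs write
    byte-identical reports. All artifacts (features, model summary,
    report, config snapshot, log) land in ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run.log")
    prep = _prepare(cfg, log)
    ages, tr, te = prep["ages"], prep["train_idx"], prep["test_idx"]

    fused = concatenate_features(prep["f_img"], prep["f_rec"])
    fused.to_csv(out / "features_fused.csv")
    model, pred, report = _fit_and_score(fused, ages, tr, te, cfg)
    log.stage("mgrf", best_fitness=model.best_fitness, retained=int(model.retained.size))

    _write_common(cfg, prep, out)
    (out / "model_summary.json").write_text(json.dumps({
        "model_spec": model.model_spec,
        "retained_trees": model.retained.tolist(),
        "feature_ranking": model.feature_ranking.tolist(),
        "ga_history": model.ga_history,
        "best_fitness": model.best_fitness,
    }, sort_keys=True, default=str))
    pd.DataFrame({
        "patient_id": [prep["ids"][i] for i in te],
        "actual_age": ages[te],
        "predicted_age": pred,
    }).to_csv(out / "predictions_test.csv", index=False)
    (out / "report.json").write_text(report.to_json())
    log.stage("done", r2=round(report.r2, 4), mae=round(report.mae, 4))
    log.write()
    return report


def run_ablation(cfg: PipelineConfig) -> AblationReport:
    """Run the six ablation configurations on one shared split.

    The two extractors are trained once and shared. Record-only and
    image-only feature sets back both the "without X" and "only Y"
    configurations (they differ in pipeline wiring, not in the numbers);
    "without concatenation" is late fusion: the average of the two
    single-path models' predictions.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run.log")
    prep = _prepare(cfg, log)
    ages, tr, te = prep["ages"], prep["train_idx"], prep["test_idx"]

    fused = concatenate_features(prep["f_img"], prep["f_rec"])
    _, pred_full, rep_full = _fit_and_score(fused, ages, tr, te, cfg)
    log.stage("mgrf_full", mae=round(rep_full.mae, 4))
    _, pred_img, rep_img = _fit_and_score(prep["f_img"], ages, tr, te, cfg)
    log.stage("mgrf_image_only", mae=round(rep_img.mae, 4))
    _, pred_rec, rep_rec = _fit_and_score(prep["f_rec"], ages, tr, te, cfg)
    log.stage("mgrf_record_only", mae=round(rep_rec.mae, 4))

    pred_late = 0.5 * (pred_img + pred_rec)
    rep_late = evaluate_regression(ages[te], pred_late)
    log.stage("late_fusion", mae=round(rep_late.mae, 4))

    report = AblationReport(
        reports={
            "full": rep_full,
            "no_2d": rep_rec,
            "no_1d": rep_img,
            "no_concat": rep_late,
            "only_2d": rep_img,
            "only_1d": rep_rec,
        },
        test_patient_ids=[prep["ids"][i] for i in te],
    )
    _write_common(cfg, prep, out)
    (out / "ablation_report.json").write_text(
        json.dumps(report.to_dict(), sort_keys=True, indent=2)
    )
    log.write()
    return report
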