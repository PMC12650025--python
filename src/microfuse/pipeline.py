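"""End-to-end orchestration: synthesize/ingest → preprocess → features →
fuse → train → evaluate, under a single config and a single global seed.

Stage seeds are derived from the global seed with a documented spawn
scheme (``SeedSequence(seed).spawn(...)``: child 0 = cohort synthesis,
1 = fold plan, 2 = template clustering, 3 = feature selection,
4 = training), so stages rerun independently stay reproducible.

Subject independence: individual microstate templates are per-subject
(never cross-subject); the group-level templates, the Gini feature
selection and the fusion normaliser are fitted on each fold's training
subjects only and applied unchanged to validation and test subjects.
Per-epoch case probabilities of a test subject are averaged into one
subject-level prediction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import EEGRecord
from . import synth
from .preprocess import PreprocessConfig, preprocess
from .stats_features import FeatureConfig, extract_features, gini_select, INFO_THEORETIC_FEATURES
from . import microstate as ms
from .fusion import fit_normalizer, fuse_matrix
from .network import ConvGRUNet, NetworkConfig
from .training import TrainerConfig, FeedbackConfig, AugmentationConfig, train_model
from .evaluation import (
    FoldPlan, make_subject_folds, confusion_from_predictions,
    classification_metrics, rmse, ConfusionCounts, group_compare,
)

__all__ = [
    "RunConfig", "MicrostateConfig", "epoch_slices", "subject_templates",
    "MicrostateFeaturizer", "stat_feature_table", "microstate_feature_table",
    "cross_validate_cohort", "CVResult", "run_pipeline",
]


@dataclass
class MicrostateConfig:
    K: int = 4
    n_init: int = 10
    max_iter: int = 100
    min_peak_separation_ms: float = 10.0
    min_duration_ms: float = 0.0       # 0 disables label smoothing


@dataclass
class RunConfig:
    """Everything needed for one run; loadable from YAML."""

    # synthetic cohort
    n_subjects_per_group: int = 20
    record_seconds: float = 30.0
    fs_hz: float = 128.0
    noise_sd: float = 0.05
    input_dir: str | None = None       # ingest instead of synthesize when set
    # analysis
    epoch_seconds: float | None = 7.5  # None = one epoch per record
    run_preprocess: bool = True
    gini_threshold: float = 0.002
    cv_folds: int = 5
    microstate: MicrostateConfig = field(default_factory=MicrostateConfig)
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    trainer: TrainerConfig = field(default_factory=TrainerConfig)
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    conv_filters_1: int = 32
    conv_filters_2: int = 64
    gru_units: int = 64
    dense_units: int = 64
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        nested = {
            "microstate": MicrostateConfig, "feature": FeatureConfig,
            "trainer": TrainerConfig, "feedback": FeedbackConfig,
            "augmentation": AugmentationConfig,
        }
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(raw) - known)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        kwargs = {}
        for key, value in raw.items():
            if key in nested and isinstance(value, dict):
                sub_known = {f.name for f in dataclasses.fields(nested[key])}
                sub_bad = sorted(set(value) - sub_known)
                if sub_bad:
                    raise ValueError(f"unknown config keys under {key}: {sub_bad}")
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _stage_seeds(seed: int, n: int = 6) -> list[int]:
    return [int(c.generate_state(1)[0] % (2 ** 31))
            for c in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def epoch_slices(n_samples: int, fs_hz: float, epoch_seconds: float | None) -> list[slice]:
    """Non-overlapping fixed windows (whole record when ``None``)."""
    if epoch_seconds is None:
        return [slice(0, n_samples)]
    step = int(round(epoch_seconds * fs_hz))
    if step < 1:
        raise ValueError("epoch_seconds too small")
    return [slice(s, s + step) for s in range(0, n_samples - step + 1, step)]


def subject_templates(rec: EEGRecord, cfg: MicrostateConfig, seed: int) -> np.ndarray:
    """Individual microstate templates from the record's GFP-peak maps."""
    gfp = ms.compute_gfp(rec)
    peaks = ms.detect_gfp_peaks(gfp, cfg.min_peak_separation_ms)
    if len(peaks) < cfg.K:
        raise ValueError(f"record {rec.subject_id}: only {len(peaks)} GFP peaks")
    maps = rec.data[:, peaks].T
    return ms.cluster_templates(maps, K=cfg.K, n_init=cfg.n_init,
                                max_iter=cfg.max_iter, seed=seed)


class MicrostateFeaturizer:
    """Fits group-level templates on training subjects; transforms any
    record into per-epoch 28-D microstate feature rows."""

    def __init__(self, cfg: MicrostateConfig, reference: np.ndarray | None = None,
                 seed: int = 0) -> None:
        self.cfg = cfg
        self.reference = reference
        self.seed = seed
        self.templates: np.ndarray | None = None

    def fit(self, template_sets: list[np.ndarray]) -> "MicrostateFeaturizer":
        global_templates = ms.two_level_cluster(
            template_sets, K=self.cfg.K, n_init=self.cfg.n_init,
            max_iter=self.cfg.max_iter, seed=self.seed,
        )
        if self.reference is not None:
            global_templates, _, _ = ms.align_to_reference(global_templates, self.reference)
        self.templates = global_templates
        return self

    def transform(self, rec: EEGRecord, epoch_seconds: float | None) -> pd.DataFrame:
        if self.templates is None:
            raise RuntimeError("featurizer not fitted")
        labels = ms.backfit(rec, self.templates)
        if self.cfg.min_duration_ms > 0:
            labels = ms.smooth_labels(labels, rec.fs_hz, self.cfg.min_duration_ms)
        gfp = ms.compute_gfp(rec)
        rows = []
        for sl in epoch_slices(rec.n_samples, rec.fs_hz, epoch_seconds):
            summary = ms.summarize(labels[sl], rec.fs_hz, K=self.cfg.K)
            sub = rec.with_data(rec.data[:, sl])
            gev = ms.compute_gev(sub, labels[sl], self.templates,
                                 ms.GFPSeries(gfp.values[sl], gfp.fs_hz))
            feats = ms.feature_vector(summary, gev)
            rows.append(dict(zip(feats.names, feats.values)))
        df = pd.DataFrame(rows)
        df.insert(0, "subject_id", rec.subject_id)
        df.insert(1, "group", rec.group_label)
        return df


def stat_feature_table(records: list[EEGRecord], epoch_seconds: float | None,
                       cfg: FeatureConfig) -> pd.DataFrame:
    """Per-epoch statistical feature rows for every record."""
    rows = []
    for rec in records:
        for sl in epoch_slices(rec.n_samples, rec.fs_hz, epoch_seconds):
            sub = rec.with_data(rec.data[:, sl])
            fv = extract_features(sub, cfg)
            row = dict(zip(fv.names, fv.values))
            row["subject_id"] = rec.subject_id
            row["group"] = rec.group_label
            rows.append(row)
    df = pd.DataFrame(rows)
    meta = ["subject_id", "group"]
    return df[meta + [c for c in df.columns if c not in meta]]


def microstate_feature_table(records: list[EEGRecord],
                             featurizer: MicrostateFeaturizer,
                             epoch_seconds: float | None) -> pd.DataFrame:
    return pd.concat(
        [featurizer.transform(rec, epoch_seconds) for rec in records],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# cross-validated classification
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    metrics: dict
    fold_metrics: list[dict]
    confusion: ConfusionCounts
    subject_probs: dict[str, float]
    rmse: float
    fold_logs: list[list[dict]]

    def summary(self) -> dict:
        keys = ("accuracy", "precision", "recall", "f1", "kappa")
        per_fold = {k: [m[k] for m in self.fold_metrics] for k in keys}
        return {
            "pooled": {k: self.metrics[k] for k in keys},
            "mean": {k: float(np.nanmean(v)) for k, v in per_fold.items()},
            "sd": {k: float(np.nanstd(v)) for k, v in per_fold.items()},
            "rmse": self.rmse,
        }


def _epoch_matrix(df: pd.DataFrame, names: list[str]) -> np.ndarray:
    return df[names].to_numpy(dtype=float)


def cross_validate_cohort(
    records: list[EEGRecord],
    config: RunConfig,
    use_micro: bool = True,
    use_stat: bool = True,
    precomputed_stats: pd.DataFrame | None = None,
    precomputed_templates: dict[str, np.ndarray] | None = None,
    reference: np.ndarray | None = None,
) -> CVResult:
    """Subject-independent k-fold evaluation of the full fused classifier.

    ``use_micro`` / ``use_stat`` toggle the feature blocks (ablation).
    Precomputed per-subject statistical features and individual templates
    may be passed to avoid recomputation across ablation arms.
    """
    if not (use_micro or use_stat):
        raise ValueError("at least one feature block required")
    seeds = _stage_seeds(config.seed)
    subjects = [r.subject_id for r in records]
    groups = [r.group_label for r in records]
    y_by_subject = {s: 1 if g == "case" else 0 for s, g in zip(subjects, groups)}

    stats_df = precomputed_stats
    if use_stat and stats_df is None:
        stats_df = stat_feature_table(records, config.epoch_seconds, config.feature)

    templ = precomputed_templates
    if use_micro and templ is None:
        templ = {
            r.subject_id: subject_templates(r, config.microstate, seeds[2] + i)
            for i, r in enumerate(records)
        }

    plan = make_subject_folds(subjects, groups, k=config.cv_folds, seed=seeds[1])
    stat_names = ([c for c in stats_df.columns if c not in ("subject_id", "group")]
                  if use_stat else [])

    confusion = ConfusionCounts()
    fold_metrics: list[dict] = []
    fold_logs: list[list[dict]] = []
    subject_probs: dict[str, float] = {}
    y_all, p_all = [], []

    for fold_i, fold in enumerate(plan.folds):
        rec_by_id = {r.subject_id: r for r in records}
        train_recs = [rec_by_id[s] for s in fold.train_subjects]

        micro_df = None
        micro_names: list[str] = []
        if use_micro:
            featurizer = MicrostateFeaturizer(
                config.microstate, reference=reference, seed=seeds[2] + 1000 + fold_i
            ).fit([templ[s] for s in fold.train_subjects])
            micro_df = microstate_feature_table(records, featurizer, config.epoch_seconds)
            micro_names = [c for c in micro_df.columns if c not in ("subject_id", "group")]

        # align epoch rows across blocks by construction (same epoching order)
        base_df = micro_df if use_micro else stats_df
        subj_col = base_df["subject_id"].to_numpy()
        y_epoch = np.array([y_by_subject[s] for s in subj_col])
        in_train = np.isin(subj_col, fold.train_subjects)
        in_val = np.isin(subj_col, fold.val_subjects)
        in_test = np.isin(subj_col, fold.test_subjects)

        kept_stat_names = stat_names
        if use_stat and config.gini_threshold > 0:
            sel = gini_select(
                _epoch_matrix(stats_df[in_train], stat_names), y_epoch[in_train],
                stat_names, threshold=config.gini_threshold, seed=seeds[3],
            )
            kept_stat_names = sel.names

        micro_mat = (_epoch_matrix(micro_df, micro_names)
                     if use_micro else np.zeros((len(subj_col), 0)))
        stat_mat = (_epoch_matrix(stats_df, kept_stat_names)
                    if use_stat else np.zeros((len(subj_col), 0)))
        norm = fit_normalizer(np.concatenate([micro_mat, stat_mat], axis=1)[in_train])
        fused = fuse_matrix(micro_mat, stat_mat, norm,
                            micro_names=micro_names, stat_names=kept_stat_names)
        X = np.atleast_2d(fused.values)

        net_cfg = NetworkConfig(
            input_steps=X.shape[1], conv_filters_1=config.conv_filters_1,
            conv_filters_2=config.conv_filters_2, gru_units=config.gru_units,
            dense_units=config.dense_units,
        )
        model = ConvGRUNet(net_cfg, seed=seeds[4] + fold_i)
        tcfg = dataclasses.replace(config.trainer, seed=seeds[4] + 5000 + fold_i)
        result = train_model(
            model, X[in_train], y_epoch[in_train], X[in_val], y_epoch[in_val],
            trainer=tcfg, feedback=config.feedback, augmentation=config.augmentation,
        )
        fold_logs.append(result.log)

        probs = model.predict_proba(X[in_test])
        test_subjects = subj_col[in_test]
        y_true, y_pred = [], []
        for s in fold.test_subjects:
            p = float(probs[test_subjects == s].mean())
            subject_probs[s] = p
            y_true.append(y_by_subject[s])
            y_pred.append(int(p >= 0.5))
            y_all.append(y_by_subject[s])
            p_all.append(p)
        cm = confusion_from_predictions(np.array(y_true), np.array(y_pred))
        confusion = confusion + cm
        fold_metrics.append(classification_metrics(cm))

    return CVResult(
        metrics=classification_metrics(confusion),
        fold_metrics=fold_metrics,
        confusion=confusion,
        subject_probs=subject_probs,
        rmse=rmse(np.array(y_all, dtype=float), np.array(p_all)),
        fold_logs=fold_logs,
    )


# ---------------------------------------------------------------------------
# full pipeline with on-disk artifacts
# ---------------------------------------------------------------------------

def make_default_cohort(config: RunConfig, seed: int) -> synth.Cohort:
    gt_control = synth.default_control_ground_truth(noise_sd=config.noise_sd, seed=seed)
    gt_case = synth.make_case_ground_truth(gt_control)
    spec = synth.CohortSpec(
        n_subjects_per_group=config.n_subjects_per_group,
        record_seconds=config.record_seconds, fs_hz=config.fs_hz,
    )
    return synth.generate_cohort(spec, gt_control, gt_case, seed)


def load_records(input_dir: str | Path) -> list[EEGRecord]:
    """Load a cohort directory written by :meth:`synth.Cohort.save`."""
    from .io import read_cohort_dir
    return read_cohort_dir(input_dir)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full study and write features, metrics, logs and
    provenance to a deterministic directory layout."""
    out = Path(out_dir)
    for sub in ("features", "metrics", "logs", "models"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    if config.input_dir is not None:
        if not Path(config.input_dir).is_dir():
            raise ValueError(f"input_dir does not exist: {config.input_dir}")
        records = load_records(config.input_dir)
    else:
        cohort = make_default_cohort(config, seeds[0])
        records = cohort.records
        cohort.save(out / "cohort")

    if config.run_preprocess:
        pcfg = PreprocessConfig()
        records = [preprocess(r, pcfg) for r in records]

    result = cross_validate_cohort(records, config)

    stats_df = stat_feature_table(records, config.epoch_seconds, config.feature)
    stats_df.to_csv(out / "features" / "statistical.csv", index=False)

    summary = result.summary()
    payload = {
        "seed": config.seed,
        "n_subjects": len(records),
        "metrics": summary,
        "confusion": asdict(result.confusion),
        "subject_probs": result.subject_probs,
    }
    (out / "metrics" / "metrics.json").write_text(json.dumps(payload, indent=1))
    with (out / "logs" / "training.jsonl").open("w") as fh:
        for fold_i, log in enumerate(result.fold_logs):
            for entry in log:
                fh.write(json.dumps({"fold": fold_i, **entry}) + "\n")
    cfg_dict = asdict(config)
    provenance = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "numpy": np.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
    return payload
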