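"""End-to-end orchestration of the four-model experiment.

For each patient: segment lungs in CT and SPECT, resize and register the
SPECT onto the CT grid, normalize (max and 99th-percentile variants),
enumerate window samples inside the annotated ROIs and extract the 28-long
radiomic feature vectors. The four model configurations (3x3 / 5x5 windows
x max / percentile normalization) are then trained and compared:
leave-one-patient-out on the training cohort selects the gold model
(highest mean clinical-class AUC), every model is refit on the full
training cohort and evaluated on the held-out test cohort at sample level
(ROC/AUC, sens/spec/PPV/NPV) and at lesion level (majority-vote ROI
diagnosis). 3x3 tables are count-matched to the 5x5 tables per
(patient, class) stratum before any cross-model statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import DEFAULT_CONFIGS, ModelConfig, TissuePatternNet
from .diagnosis import aggregate_roi
from .evaluation import (
    compare_auc_to_gold,
    compare_auc_unpaired,
    confusion_metrics,
    leave_one_patient_out,
    roc_auc,
)
from .phantom import PhantomPatient
from .preprocess import (
    NormalizationMode,
    apply_transform,
    normalize_spect,
    register_masks_affine,
    resize_spect_to_ct,
    segment_lungs_ct,
    segment_lungs_spect,
)
from .radiomics2d import FEATURE_COLUMNS, RadiomicsConfig, _modality_features
from .sampling import enumerate_window_samples, match_sample_counts
from .volume_io import (
    CLINICAL_CLASSES,
    Modality,
    RoiAnnotation,
    TissueClass,
    Volume3D,
    feature_columns,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessedPatient",
    "preprocess_patient",
    "build_sample_tables",
    "extract_cohort_tables",
    "run_experiment",
]

WINDOW_SIDES = (3, 5)
MODES = (NormalizationMode.MAX, NormalizationMode.PERCENTILE99)


@dataclass
class PreprocessedPatient:
    patient_id: str
    ct: Volume3D
    spect_registered: Volume3D  # counts, on the CT grid
    normalized: dict  # NormalizationMode -> Volume3D
    rois: list[RoiAnnotation]


def preprocess_patient(
    ct: Volume3D, spect: Volume3D, rois: list[RoiAnnotation], patient_id: str
) -> PreprocessedPatient:
    """Full preprocessing chain for one patient.

    Resize SPECT to the CT grid, register the lung masks (affine, MSE),
    resample the SPECT counts through the recovered transform, then produce
    both normalized variants.
    """
    ct_mask = segment_lungs_ct(ct)
    spect_resized = resize_spect_to_ct(spect, ct)
    spect_mask = segment_lungs_spect(spect_resized)
    transform = register_masks_affine(spect_mask, ct_mask)
    spect_reg = apply_transform(spect_resized, transform, ct)
    normalized = {mode: normalize_spect(spect_reg, mode) for mode in MODES}
    return PreprocessedPatient(patient_id, ct, spect_reg, normalized, rois)


def build_sample_tables(
    pre: PreprocessedPatient,
    window_side: int,
    radiomics_config: RadiomicsConfig | None = None,
) -> dict:
    """Per-normalization sample/feature tables for one patient and side.

    CT features are shared between the two normalization modes (the CT
    window does not change), so they are computed once. Returned tables
    have identical row order across modes.
    """
    config = radiomics_config or RadiomicsConfig()
    if config.voxel_volume == 1.0:
        config = RadiomicsConfig(
            ct_range=config.ct_range,
            ct_bin_width=config.ct_bin_width,
            spect_range=config.spect_range,
            spect_bin_width=config.spect_bin_width,
            gldm_alpha=config.gldm_alpha,
            voxel_volume=pre.ct.voxel_volume,
        )
    half = window_side // 2
    meta_rows = []
    ct_feats = []
    spect_feats: dict = {mode: [] for mode in MODES}
    for roi in pre.rois:
        z = roi.slice_index
        ct_slice = pre.ct.values[z]
        norm_slices = {mode: pre.normalized[mode].values[z] for mode in MODES}
        for sample in enumerate_window_samples(roi, window_side):
            r, c = sample.center
            win = np.s_[r - half : r + half + 1, c - half : c + half + 1]
            ct_feats.append(_modality_features(ct_slice[win], Modality.CT, config))
            for mode in MODES:
                spect_feats[mode].append(
                    _modality_features(norm_slices[mode][win], Modality.SPECT, config)
                )
            meta_rows.append(
                (pre.patient_id, roi.roi_id, z, r, c, window_side, int(roi.label))
            )
    meta = pd.DataFrame(
        meta_rows,
        columns=["patient_id", "roi_id", "slice_index", "row", "col", "window_side", "label"],
    )
    tables = {}
    for mode in MODES:
        feats = np.hstack([np.asarray(ct_feats), np.asarray(spect_feats[mode])]) if meta_rows else np.zeros((0, 28))
        table = pd.concat(
            [meta, pd.DataFrame(feats, columns=FEATURE_COLUMNS)], axis=1
        )
        tables[mode] = table
    return tables


def extract_cohort_tables(
    patients: list[PhantomPatient],
    radiomics_config: RadiomicsConfig | None = None,
) -> dict:
    """Preprocess a cohort and pool per-(side, mode) sample tables."""
    pooled: dict = {(side, mode): [] for side in WINDOW_SIDES for mode in MODES}
    for patient in patients:
        pre = preprocess_patient(
            patient.ct, patient.spect_native, patient.rois, patient.patient_id
        )
        for side in WINDOW_SIDES:
            tables = build_sample_tables(pre, side, radiomics_config)
            for mode in MODES:
                pooled[(side, mode)].append(tables[mode])
    return {
        key: pd.concat(parts, axis=0).reset_index(drop=True)
        for key, parts in pooled.items()
    }


def _match_tables(tables: dict, seed: int) -> dict:
    """Count-match the 3x3 tables to the 5x5 per-stratum counts.

    The same subsampled window centres are used for both normalization
    modes so that models of equal window size stay sample-paired.
    """
    out = dict(tables)
    ref5 = tables[(5, MODES[0])]
    base3 = tables[(3, MODES[0])].copy()
    base3["_pos"] = np.arange(len(base3))
    matched = match_sample_counts(base3, ref5, seed=seed)
    pos = matched["_pos"].to_numpy()
    for mode in MODES:
        out[(3, mode)] = tables[(3, mode)].iloc[pos].reset_index(drop=True)
    return out


def _clinical_scores(table_pred: pd.DataFrame, cls: TissueClass):
    """Score vector and truth for one clinical class, one-vs-rest.

    Positives are samples of the class, negatives the other *clinical*
    classes; extra categories are excluded from diagnostic statistics.
    """
    clinical = table_pred["label"].isin([int(c) for c in CLINICAL_CLASSES])
    sub = table_pred[clinical]
    scores = sub[f"score_{int(cls)}"].to_numpy(float)
    truth = (sub["label"] == int(cls)).to_numpy(bool)
    pred = (sub["predicted"] == int(cls)).to_numpy(bool)
    return scores, truth, pred


def _sample_metrics(table_pred: pd.DataFrame) -> dict:
    out = {}
    for cls in CLINICAL_CLASSES:
        scores, truth, pred = _clinical_scores(table_pred, cls)
        auc, ci = roc_auc(scores, truth)
        metrics = confusion_metrics(pred, truth)
        metrics.auc = (auc, ci[0], ci[1])
        out[cls.name] = metrics
    return out


def _roi_metrics(table_pred: pd.DataFrame) -> dict:
    """Lesion-level diagnosis: majority vote per ROI, then binary metrics."""
    rows = []
    for (pid, roi_id), grp in table_pred.groupby(["patient_id", "roi_id"]):
        truth = TissueClass(int(grp["label"].iloc[0]))
        diag = aggregate_roi(grp["predicted"].to_numpy(int), roi_id=roi_id)
        rows.append((pid, roi_id, int(truth), int(diag.modal_class)))
    roi_table = pd.DataFrame(rows, columns=["patient_id", "roi_id", "label", "modal"])
    clinical = roi_table[roi_table["label"].isin([int(c) for c in CLINICAL_CLASSES])]
    out = {}
    for cls in CLINICAL_CLASSES:
        truth = (clinical["label"] == int(cls)).to_numpy(bool)
        pred = (clinical["modal"] == int(cls)).to_numpy(bool)
        out[cls.name] = confusion_metrics(pred, truth)
    return out, roi_table


def _metrics_to_json(metrics_by_class: dict) -> dict:
    return {name: m.as_dict() for name, m in metrics_by_class.items()}


def run_experiment(
    train_patients: list[PhantomPatient],
    test_patients: list[PhantomPatient],
    seed: int,
    configs: tuple[ModelConfig, ...] = DEFAULT_CONFIGS,
    radiomics_config: RadiomicsConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """The four-model experiment; returns the full report bundle.

    Reproducible: all randomness (count matching, network initialization
    and shuffling) derives from ``seed``.
    """
    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError("model configurations must be distinct")
    rng = np.random.default_rng(seed)
    match_seed = int(rng.integers(2**31))
    config_seeds = {c.label: int(rng.integers(2**31)) for c in configs}

    logger.info("extracting training tables (%d patients)", len(train_patients))
    train_tables = _match_tables(extract_cohort_tables(train_patients, radiomics_config), match_seed)
    logger.info("extracting test tables (%d patients)", len(test_patients))
    test_tables = _match_tables(extract_cohort_tables(test_patients, radiomics_config), match_seed)

    train_pids = {p.patient_id for p in train_patients}
    test_pids = {p.patient_id for p in test_patients}
    if train_pids & test_pids:
        raise ValueError(f"train/test patient overlap: {sorted(train_pids & test_pids)}")

    report: dict = {"seed": seed, "models": labels}

    # --- leave-one-patient-out on the training cohort --------------------
    loso_preds: dict = {}
    loso_auc: dict = {}
    for config in configs:
        cfg = ModelConfig(
            config.window_side,
            config.normalization,
            seed=config_seeds[config.label],
            hyperparameters=config.hyperparameters,
        )
        table = train_tables[(config.window_side, config.normalization)]
        logger.info("LOSO for %s (%d samples)", config.label, len(table))
        preds = leave_one_patient_out(table, cfg)
        loso_preds[config.label] = preds
        loso_auc[config.label] = {}
        for cls in CLINICAL_CLASSES:
            scores, truth, _ = _clinical_scores(preds, cls)
            auc, ci = roc_auc(scores, truth)
            loso_auc[config.label][cls.name] = {"auc": auc, "ci": list(ci)}

    mean_auc = {
        label: float(np.mean([v["auc"] for v in per_class.values()]))
        for label, per_class in loso_auc.items()
    }
    gold_label = max(mean_auc, key=mean_auc.get)
    gold_config = next(c for c in configs if c.label == gold_label)
    report["gold_model"] = gold_label
    report["loso_mean_auc"] = mean_auc

    # AUC-equality tests vs the gold model (paired within a window size,
    # unpaired across sizes; Bonferroni over the non-gold models)
    m_comp = len(configs) - 1
    for config in configs:
        per_class = loso_auc[config.label]
        for cls in CLINICAL_CLASSES:
            if config.label == gold_label:
                per_class[cls.name]["p_vs_gold"] = None  # the gold cell stays blank
                continue
            g_scores, g_truth, _ = _clinical_scores(loso_preds[gold_label], cls)
            o_scores, o_truth, _ = _clinical_scores(loso_preds[config.label], cls)
            if config.window_side == gold_config.window_side:
                res = compare_auc_to_gold(g_scores, [o_scores], g_truth)[0]
                p_raw = res["p_raw"]
            else:
                p_raw = compare_auc_unpaired(g_scores, g_truth, o_scores, o_truth)
            per_class[cls.name]["p_vs_gold"] = min(1.0, m_comp * p_raw)
    report["loso_auc"] = loso_auc

    # --- refit on the full training cohort, evaluate on test -------------
    cols = None
    test_results: dict = {}
    for config in configs:
        key = (config.window_side, config.normalization)
        train = train_tables[key]
        test = test_tables[key]
        cols = feature_columns(train)
        model = TissuePatternNet(
            random_state=config_seeds[config.label], **config.hyperparameters
        )
        model.fit(train[cols].to_numpy(float), train["label"].to_numpy(int))
        scores = model.predict_proba(test[cols].to_numpy(float))
        pred_table = test.drop(columns=cols).copy()
        pred_table["predicted"] = model.classes_[np.argmax(scores, axis=1)]
        for k, cls in enumerate(model.classes_):
            pred_table[f"score_{int(cls)}"] = scores[:, k]
        test_results[config.label] = pred_table

    report["test_sample_metrics"] = {}
    report["test_roi_metrics"] = {}
    roi_tables: dict = {}
    for config in configs:
        preds = test_results[config.label]
        sample_metrics = _sample_metrics(preds)
        roi_metrics, roi_table = _roi_metrics(preds)
        roi_tables[config.label] = roi_table
        report["test_sample_metrics"][config.label] = _metrics_to_json(sample_metrics)
        report["test_roi_metrics"][config.label] = _metrics_to_json(roi_metrics)

    # test-set AUC comparisons vs gold
    test_comparisons: dict = {}
    for config in configs:
        if config.label == gold_label:
            continue
        per_class = {}
        for cls in CLINICAL_CLASSES:
            g_scores, g_truth, _ = _clinical_scores(test_results[gold_label], cls)
            o_scores, o_truth, _ = _clinical_scores(test_results[config.label], cls)
            if config.window_side == gold_config.window_side:
                res = compare_auc_to_gold(g_scores, [o_scores], g_truth)[0]
                p_raw = res["p_raw"]
            else:
                p_raw = compare_auc_unpaired(g_scores, g_truth, o_scores, o_truth)
            per_class[cls.name] = {
                "p_raw": p_raw,
                "p_adjusted": min(1.0, m_comp * p_raw),
            }
        test_comparisons[config.label] = per_class
    report["test_auc_vs_gold"] = test_comparisons

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        for label, preds in test_results.items():
            preds.to_csv(out_dir / f"test_predictions_{label}.tsv", sep="\t", index=False)
        for label, roi_table in roi_tables.items():
            roi_table.to_csv(out_dir / f"test_roi_calls_{label}.tsv", sep="\t", index=False)
        _write_auc_table(out_dir / "loso_auc.tsv", loso_auc)
    report["_test_predictions"] = test_results
    return report


def run_phantom_experiment(
    n_train: int,
    n_test: int,
    seed: int,
    configs: tuple[ModelConfig, ...] = DEFAULT_CONFIGS,
    spec=None,
    out_dir: str | Path | None = None,
) -> dict:
    """Generate phantom cohorts and run the four-model experiment.

    Train and test cohorts are generated independently (seeds derived from
    ``seed``), test patient ids are prefixed so the two sets are disjoint.
    """
    from .phantom import PhantomSpec, generate_cohort

    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    train, _ = generate_cohort(spec, n_train, int(rng.integers(2**31)))
    test, _ = generate_cohort(spec, n_test, int(rng.integers(2**31)))
    for p in test:
        p.patient_id = "t_" + p.patient_id
        for roi in p.rois:
            roi.patient_id = p.patient_id
    return run_experiment(train, test, seed=seed, configs=configs, out_dir=out_dir)


def _write_auc_table(path: Path, loso_auc: dict) -> None:
    rows = []
    for label, per_class in loso_auc.items():
        row: dict = {"model": label}
        for cls_name, vals in per_class.items():
            row[f"{cls_name}_auc"] = vals["auc"]
            row[f"{cls_name}_ci_low"], row[f"{cls_name}_ci_high"] = vals["ci"]
            row[f"{cls_name}_p_vs_gold"] = vals.get("p_vs_gold")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
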