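"""Diagnostic-test statistics and leave-one-patient-out cross-validation.

Proportion metrics (sensitivity, specificity, PPV, NPV, accuracy) carry
exact Clopper-Pearson 95% confidence intervals; the area under the ROC
curve is the Mann-Whitney pair statistic (ties counted 1/2) with a DeLong
variance estimate for its interval and for paired tests of AUC equality
against a gold-standard model (Bonferroni-adjusted across models).

Cross-validation is grouped by patient: every fold holds out all samples of
one patient, so performance estimates are not inflated by within-patient
correlation between windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .classifier import ModelConfig
from .volume_io import feature_columns

__all__ = [
    "ProportionEstimate",
    "DiagnosticMetrics",
    "confusion_metrics",
    "roc_auc",
    "compare_auc_to_gold",
    "compare_auc_unpaired",
    "leave_one_patient_out",
]


@dataclass
class ProportionEstimate:
    """A proportion with its exact (Clopper-Pearson) 95% CI."""

    value: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(cls, successes: int, total: int) -> "ProportionEstimate":
        lo, hi = proportion_confint(successes, total, alpha=0.05, method="beta")
        return cls(successes / total, float(lo), float(hi))


@dataclass
class DiagnosticMetrics:
    sensitivity: ProportionEstimate | None
    specificity: ProportionEstimate | None
    ppv: ProportionEstimate | None
    npv: ProportionEstimate | None
    accuracy: ProportionEstimate | None
    auc: tuple[float, float, float] | None  # (auc, ci_low, ci_high)
    n_pos: int
    n_neg: int
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        out: dict = {"n_pos": self.n_pos, "n_neg": self.n_neg}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            est = getattr(self, name)
            out[name] = None if est is None else [est.value, est.ci_low, est.ci_high]
        out["auc"] = None if self.auc is None else list(self.auc)
        return out


def confusion_metrics(pred: np.ndarray, truth: np.ndarray) -> DiagnosticMetrics:
    """Sens/spec/PPV/NPV/accuracy with exact 95% CIs from binary vectors.

    A metric whose denominator is zero is flagged in ``undefined`` and
    returned as None; the others are still computed.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length non-empty vectors")
    tp = int(np.sum(pred & truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return None
        return ProportionEstimate.from_counts(num, den)

    metrics = DiagnosticMetrics(
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        accuracy=ratio(tp + tn, tp + fn + tn + fp, "accuracy"),
        auc=None,
        n_pos=tp + fn,
        n_neg=tn + fp,
    )
    metrics.undefined = tuple(undefined)
    return metrics


# ---------------------------------------------------------------------------
# AUC / DeLong
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, truth: np.ndarray):
    """AUC and the DeLong structural components (V10, V01)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    pos = scores[truth]
    neg = scores[~truth]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present for ROC analysis")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC with a DeLong 95% confidence interval."""
    auc, v10, v01 = _delong_components(scores, truth)
    var = 0.0
    if len(v10) > 1:
        var += np.var(v10, ddof=1) / len(v10)
    if len(v01) > 1:
        var += np.var(v01, ddof=1) / len(v01)
    se = np.sqrt(var)
    z = stats.norm.ppf(0.975)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return float(auc), (float(lo), float(hi))


def _paired_delong_p(scores_a, scores_b, truth) -> tuple[float, float, float]:
    auc_a, v10_a, v01_a = _delong_components(scores_a, truth)
    auc_b, v10_b, v01_b = _delong_components(scores_b, truth)
    m, n = len(v10_a), len(v01_a)
    var = 0.0
    if m > 1:
        s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 1e-16:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
        return auc_a, auc_b, p
    z = diff / np.sqrt(var)
    return auc_a, auc_b, float(2 * stats.norm.sf(abs(z)))


def compare_auc_to_gold(
    gold_scores: np.ndarray,
    other_scores_list: list[np.ndarray],
    truth: np.ndarray,
) -> list[dict]:
    """Paired DeLong tests of AUC equality against a gold-standard model.

    All score vectors must be computed on the same samples. Returns one
    record per comparison with the raw and Bonferroni-adjusted p-value
    (adjusted = min(1, m * raw) for m comparisons).
    """
    truth = np.asarray(truth, dtype=bool)
    m_comp = len(other_scores_list)
    results = []
    for other in other_scores_list:
        other = np.asarray(other, dtype=float)
        if other.shape != np.asarray(gold_scores).shape:
            raise ValueError("score vectors are not paired (length mismatch)")
        auc_g, auc_o, p_raw = _paired_delong_p(gold_scores, other, truth)
        results.append(
            {
                "auc_gold": auc_g,
                "auc_other": auc_o,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, m_comp * p_raw),
            }
        )
    return results


def compare_auc_unpaired(
    scores_a: np.ndarray, truth_a: np.ndarray, scores_b: np.ndarray, truth_b: np.ndarray
) -> float:
    """Two-sided z-test of AUC equality for two independent samples.

    Used where predictions are not sample-paired (models built on different
    window sizes share no window centres, only matched counts).
    """
    auc_a, (lo_a, hi_a) = roc_auc(scores_a, truth_a)
    auc_b, (lo_b, hi_b) = roc_auc(scores_b, truth_b)
    z975 = stats.norm.ppf(0.975)
    se_a = (hi_a - lo_a) / (2 * z975)
    se_b = (hi_b - lo_b) / (2 * z975)
    var = se_a**2 + se_b**2
    if var <= 1e-16:
        return 1.0 if abs(auc_a - auc_b) < 1e-12 else 0.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# leave-one-patient-out
# ---------------------------------------------------------------------------


def leave_one_patient_out(table: pd.DataFrame, config: ModelConfig) -> pd.DataFrame:
    """Patient-grouped cross-validation, pooled out-of-fold predictions.

    One fold per patient; all of a patient's samples are held out together
    and predicted by a model trained on everyone else. Returns the input
    rows (metadata + true label) with fold id, predicted label and the
    per-class scores appended; every sample appears exactly once.
    """
    patients = sorted(table["patient_id"].unique())
    if len(patients) < 3:
        raise ValueError(f"need >= 3 patients for leave-one-patient-out, got {len(patients)}")
    cols = feature_columns(table)
    out_rows = []
    for fold, patient in enumerate(patients):
        test_mask = (table["patient_id"] == patient).to_numpy()
        train = table[~test_mask]
        test = table[test_mask]
        if train["label"].nunique() < 2:
            raise ValueError(
                f"removing patient {patient} leaves a single-class training set"
            )
        model = config.make_estimator(seed=config.seed)
        model.fit(train[cols].to_numpy(float), train["label"].to_numpy(int))
        scores = model.predict_proba(test[cols].to_numpy(float))
        pred = model.classes_[np.argmax(scores, axis=1)]
        rec = test.drop(columns=cols).copy()
        rec["fold"] = fold
        rec["predicted"] = pred
        for k, cls in enumerate(model.classes_):
            rec[f"score_{int(cls)}"] = scores[:, k]
        out_rows.append(rec)
    return pd.concat(out_rows, axis=0).reset_index(drop=True)
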