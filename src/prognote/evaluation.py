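"""Quantitative evaluation on non-padded, outcome-defined timesteps.

All metrics treat one visit (one timestep with a POS or NEG label) as
one observation, mirroring the time-to-event bookkeeping where a patient
seen four times in a day contributes four entries. Padded and
censored-undefined timesteps never enter any metric.

The bootstrap confidence interval for the AUC resamples *patients*, not
visits: visits within a patient are correlated, and a visit-level
bootstrap would understate the variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

__all__ = [
    "EvaluationReport",
    "roc_auc",
    "brier",
    "precision_recall_auc",
    "calibration_deciles",
    "stratified_auc",
    "evaluate_predictions",
]


@dataclass
class EvaluationReport:
    auc: float
    auc_ci: tuple[float, float]
    best_cutoff: float
    brier: float
    pr_auc: float
    calibration: pd.DataFrame
    per_stratum_auc: dict[str, float | None] = field(default_factory=dict)
    n_evaluated: int = 0

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "best_cutoff": self.best_cutoff,
            "brier": self.brier,
            "pr_auc": self.pr_auc,
            "n_evaluated": self.n_evaluated,
            "per_stratum_auc": self.per_stratum_auc,
            "calibration": self.calibration.to_dict(orient="records"),
        }


def _check_binary(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # rank (Mann-Whitney) AUC; tied scores contribute 1/2 by convention
    return float(_skm.roc_auc_score(labels, scores))


def roc_auc(
    scores,
    labels,
    patient_ids=None,
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[float, float, float, float]:
    """(auc, ci_low, ci_high, best_cutoff).

    ``labels`` are 1 for Survival-positive. The best cutoff maximises
    Youden's J = sensitivity + specificity - 1, ties resolved toward the
    lower threshold. With ``n_boot`` 0 the CI degenerates to the point
    estimate; otherwise it is a patient-level (cluster) bootstrap when
    ``patient_ids`` is given, visit-level otherwise.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_binary(labels)
    auc = _auc(scores, labels)

    fpr, tpr, thresholds = _skm.roc_curve(labels, scores)
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # roc_curve lists thresholds descending; the last maximiser is lowest
    best_cutoff = float(thresholds[best[-1]])

    lo = hi = auc
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        stats = []
        if patient_ids is not None:
            patient_ids = np.asarray(patient_ids)
            unique = np.unique(patient_ids)
            groups = {p: np.flatnonzero(patient_ids == p) for p in unique}
            for _ in range(n_boot):
                take = rng.choice(unique, size=len(unique), replace=True)
                idx = np.concatenate([groups[p] for p in take])
                if len(np.unique(labels[idx])) < 2:
                    continue
                stats.append(_auc(scores[idx], labels[idx]))
        else:
            n = len(scores)
            for _ in range(n_boot):
                idx = rng.integers(0, n, size=n)
                if len(np.unique(labels[idx])) < 2:
                    continue
                stats.append(_auc(scores[idx], labels[idx]))
        if stats:
            lo, hi = (float(q) for q in np.percentile(stats, [2.5, 97.5]))
    return auc, lo, hi, best_cutoff


def brier(scores, labels) -> float:
    """Mean squared difference between predicted survival probability
    and the binary outcome."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("brier: empty input")
    return float(np.mean((scores - labels) ** 2))


def precision_recall_auc(scores, labels) -> float:
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    return float(_skm.auc(recall, precision))


def calibration_deciles(scores, labels) -> pd.DataFrame:
    """Ten half-open probability bins [0,0.1), …, [0.9,1.0].

    Returns one row per bin: n, mean predicted survival probability (%),
    observed survival rate (%); empty bins keep n=0 with NaN rates. Bin
    counts always sum to the number of evaluated visits.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("calibration_deciles: empty input")
    bins = np.minimum((scores * 10).astype(int), 9)
    rows = []
    for b in range(10):
        in_bin = bins == b
        n = int(in_bin.sum())
        rows.append(
            {
                "bin": b + 1,
                "lo": b / 10,
                "hi": (b + 1) / 10,
                "n": n,
                "mean_predicted_pct": float(scores[in_bin].mean() * 100) if n else float("nan"),
                "observed_survival_pct": float(labels[in_bin].mean() * 100) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def stratified_auc(scores, labels, strata) -> dict[str, float | None]:
    """AUC per stratum (e.g. primary cancer site). Strata lacking one of
    the classes are reported as None rather than silently dropped."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    strata = np.asarray(strata)
    out: dict[str, float | None] = {}
    for s in sorted(set(strata.tolist())):
        idx = strata == s
        if len(np.unique(labels[idx])) < 2:
            out[str(s)] = None
        else:
            out[str(s)] = _auc(scores[idx], labels[idx])
    return out


def evaluate_predictions(
    pred_frame: pd.DataFrame,
    strata: dict[str, str] | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> EvaluationReport:
    """Full report from a predictions table (one row per evaluated visit,
    columns patient_id / p_survival / true_label with POS|NEG values)."""
    frame = pred_frame[pred_frame["true_label"].isin(["POS", "NEG"])]
    if frame.empty:
        raise ValueError("no evaluable (POS/NEG) visits in predictions")
    scores = frame["p_survival"].to_numpy(dtype=np.float64)
    labels = (frame["true_label"] == "POS").to_numpy(dtype=np.int64)
    pids = frame["patient_id"].to_numpy()
    auc, lo, hi, cutoff = roc_auc(scores, labels, patient_ids=pids,
                                  n_boot=n_boot, seed=seed)
    report = EvaluationReport(
        auc=auc,
        auc_ci=(lo, hi),
        best_cutoff=cutoff,
        brier=brier(scores, labels),
        pr_auc=precision_recall_auc(scores, labels),
        calibration=calibration_deciles(scores, labels),
        n_evaluated=int(len(frame)),
    )
    if strata:
        stratum_per_visit = np.array([strata.get(p, "unknown") for p in pids])
        report.per_stratum_auc = stratified_auc(scores, labels, stratum_per_visit)
    return report
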