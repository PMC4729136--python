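"""Evaluation pipeline for switch predictions.

Mirrors the standard assessment of a per-bin switch predictor: quick
point-biserial correlations against the realized switches (with a permuted
baseline), an 11-bin calibration table with a linear fit, logistic
regressions of the switch outcome on several feature sets under
leave-one-participant-out cross-validation, and accuracy summaries (ROC
AUC, precision/recall at a 0.5 threshold, and participant-level agreement
between predicted and observed switch rates).

Undefined metrics (single outcome class, empty cells, zero variance) are
reported as missing with a reason rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .constants import ModelConfig
from .model import FluidEventsModel
from .streams import EventStream


class UndefinedMetricError(ValueError):
    """The requested metric is undefined on these inputs (e.g. a single
    outcome class); the message states why."""


class FitError(RuntimeError):
    """A logistic fit failed to converge or the data were separable."""


# ---------------------------------------------------------------------------
# quick hits

def point_biserial(p_hat: Sequence[float], shifts: Sequence[int]) -> float:
    """Point-biserial correlation between predicted probabilities and the
    0/1 switch outcomes — identically the Pearson correlation with the
    binary coding."""
    p = np.asarray(p_hat, dtype=float)
    h = np.asarray(shifts, dtype=float)
    if p.size != h.size or p.size < 2:
        raise UndefinedMetricError("need >= 2 paired observations")
    if len(np.unique(h)) < 2:
        raise UndefinedMetricError("both outcome classes must be present")
    if np.std(p) == 0:
        raise UndefinedMetricError("predictions have zero variance")
    return float(stats.pearsonr(p, h)[0])


def randomized_baseline(p_hat: Sequence[float], shifts: Sequence[int],
                        seed: int) -> float:
    """Point-biserial after permuting the switch outcomes with a seeded
    generator — the no-structure reference against which the real
    correlation is judged."""
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(np.asarray(shifts))
    return point_biserial(p_hat, shuffled)


@dataclass
class CalibrationResult:
    """Observed switch rate per predicted-probability bin plus a linear fit.

    Bins are centred on 0.0, 0.1, ..., 1.0; bin k collects predictions in
    [k/10 - 0.05, k/10 + 0.05), so the two edge bins are half-width. The
    least-squares line is fitted to (bin centre, observed rate) over the
    non-empty bins; perfect calibration gives slope 1, intercept 0.
    """

    table: pd.DataFrame
    slope: Optional[float]
    intercept: Optional[float]
    note: Optional[str] = None


def calibration_bins(p_hat: Sequence[float], shifts: Sequence[int]) -> CalibrationResult:
    p = np.asarray(p_hat, dtype=float)
    h = np.asarray(shifts, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predictions must be in [0, 1]")
    idx = np.clip(np.floor(10 * p + 0.5).astype(int), 0, 10)
    rows = []
    for k in range(11):
        sel = idx == k
        n = int(sel.sum())
        rows.append({
            "bin_center": k / 10,
            "n": n,
            "observed_rate": float(h[sel].mean()) if n else np.nan,
        })
    table = pd.DataFrame(rows)
    filled = table.dropna(subset=["observed_rate"])
    if len(filled) < 2:
        return CalibrationResult(table, None, None,
                                 note="fewer than two non-empty bins; fit undefined")
    fit = stats.linregress(filled["bin_center"], filled["observed_rate"])
    return CalibrationResult(table, float(fit.slope), float(fit.intercept))


# ---------------------------------------------------------------------------
# model variants and cross-validated logistic fits

FACTOR_FEATURES = ("env_change", "time_on_task", "just_shifted", "num_shifts",
                   "performance_dip", "bad_shift", "flexibility")

VARIANT_NAMES = ("null", "sum", "individual", "event_structure", "experience")


@dataclass(frozen=True)
class ModelVariant:
    """A named feature set for the logistic switch regression.

    ``null`` uses only the trial number; ``sum`` the single summed
    prediction; ``individual`` every factor separately (optionally folding
    the bad-shift duplicate into the dip term); ``event_structure`` the two
    task-driven factors; ``experience`` the four history-driven ones.
    """

    name: str
    features: Tuple[str, ...]

    @classmethod
    def from_name(cls, name: str, separate_bad_shift: bool = True) -> "ModelVariant":
        table: Dict[str, Tuple[str, ...]] = {
            "null": ("trial_number",),
            "sum": ("p_sum",),
            "individual": FACTOR_FEATURES if separate_bad_shift else (
                "env_change", "time_on_task", "just_shifted", "num_shifts",
                "dip_plus_bad", "flexibility"),
            "event_structure": ("env_change", "time_on_task"),
            "experience": ("just_shifted", "num_shifts", "performance_dip",
                           "flexibility"),
        }
        if name not in table:
            raise ValueError(f"unknown variant {name!r}; choose from {VARIANT_NAMES}")
        return cls(name, table[name])


def design_matrix(records: pd.DataFrame, variant: ModelVariant) -> pd.DataFrame:
    df = records.copy()
    if "dip_plus_bad" in variant.features:
        df["dip_plus_bad"] = df["performance_dip"] + df["bad_shift"]
    return df[list(variant.features)].astype(float)


def fit_logit(records: pd.DataFrame, variant: ModelVariant,
              tol: float = 1e-8, maxiter: int = 100) -> pd.Series:
    """Unpenalized maximum-likelihood logistic fit (with intercept) of the
    switch outcome on the variant's features. Raises :class:`FitError` on
    separation or non-convergence."""
    y = records["shift"].astype(float)
    if len(np.unique(y)) < 2:
        raise FitError("training data contain a single outcome class")
    X = sm.add_constant(design_matrix(records, variant), has_constant="add")
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", tol=tol,
                                     maxiter=maxiter, disp=0)
    except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    if not np.all(np.isfinite(res.params)):
        raise FitError("logistic fit produced non-finite coefficients")
    return res.params


def predict_logit(params: pd.Series, records: pd.DataFrame,
                  variant: ModelVariant) -> np.ndarray:
    X = sm.add_constant(design_matrix(records, variant), has_constant="add")
    z = X[params.index].to_numpy() @ params.to_numpy()
    return 1.0 / (1.0 + np.exp(-z))


def lopo_cv(records: pd.DataFrame, variant: ModelVariant,
            tol: float = 1e-8, maxiter: int = 100,
            ) -> Tuple[pd.DataFrame, List[str]]:
    """Leave-one-participant-out cross-validation.

    Each participant's bins are predicted by a logistic model trained on
    all other participants; the held-out predictions are pooled into one
    frame (column ``p_model``). Folds whose training fit fails are skipped
    with a warning message, never silently.
    """
    participants = sorted(records["participant"].unique())
    if len(participants) < 2:
        raise ValueError("leave-one-participant-out CV needs >= 2 participants")
    pooled = []
    warnings: List[str] = []
    for pid in participants:
        train = records[records["participant"] != pid]
        test = records[records["participant"] == pid]
        try:
            params = fit_logit(train, variant, tol=tol, maxiter=maxiter)
        except FitError as exc:
            warnings.append(f"fold {pid!r} skipped: {exc}")
            continue
        out = test.copy()
        out["p_model"] = predict_logit(params, test, variant)
        pooled.append(out)
    if not pooled:
        raise FitError("every cross-validation fold failed: " + "; ".join(warnings))
    return pd.concat(pooled, ignore_index=True), warnings


# ---------------------------------------------------------------------------
# accuracy metrics

def roc_auc(p_hat: Sequence[float], shifts: Sequence[int]) -> float:
    """Area under the ROC curve: the probability that a random switch bin
    is ranked above a random non-switch bin, ties counted half."""
    h = np.asarray(shifts)
    if len(np.unique(h)) < 2:
        raise UndefinedMetricError("both outcome classes must be present")
    return float(roc_auc_score(h, np.asarray(p_hat, dtype=float)))


def roc_points(p_hat: Sequence[float], shifts: Sequence[int]) -> pd.DataFrame:
    """ROC curve points (false-positive rate, true-positive rate,
    threshold), exportable as CSV for plotting."""
    fpr, tpr, thr = roc_curve(np.asarray(shifts), np.asarray(p_hat, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class ClassificationMetrics:
    precision: Optional[float]
    recall: float
    switch_rate: float
    threshold: float = 0.5
    note: Optional[str] = None


def precision_recall(p_hat: Sequence[float], shifts: Sequence[int],
                     threshold: float = 0.5) -> ClassificationMetrics:
    """Precision and recall from the 2x2 table at an inclusive threshold
    (probability >= threshold counts as a predicted switch), plus the base
    switch rate."""
    p = np.asarray(p_hat, dtype=float)
    h = np.asarray(shifts).astype(int)
    if len(np.unique(h)) < 2:
        raise UndefinedMetricError("both outcome classes must be present")
    pred = p >= threshold
    tp = int(np.sum(pred & (h == 1)))
    fp = int(np.sum(pred & (h == 0)))
    fn = int(np.sum(~pred & (h == 1)))
    precision = tp / (tp + fp) if (tp + fp) else None
    note = None if precision is not None else "no predicted switches; precision undefined"
    recall = tp / (tp + fn)
    return ClassificationMetrics(precision, float(recall), float(h.mean()),
                                 threshold, note)


def switch_rate_correlation(pooled: pd.DataFrame, threshold: float = 0.5,
                            prob_column: str = "p_model") -> float:
    """Pearson correlation, across participants, between the rate of
    predicted switches (probability >= threshold) and the observed switch
    rate — how well the model recovers *how often* each person switches."""
    grouped = pooled.groupby("participant")
    predicted = grouped[prob_column].apply(lambda p: float(np.mean(p >= threshold)))
    observed = grouped["shift"].mean()
    if len(predicted) < 3:
        raise UndefinedMetricError("need >= 3 participants")
    if predicted.std(ddof=0) == 0 or observed.std(ddof=0) == 0:
        raise UndefinedMetricError("zero variance in per-participant rates")
    return float(stats.pearsonr(predicted, observed)[0])


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class VariantResult:
    name: str
    auc: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    switch_rate: Optional[float] = None
    switch_rate_correlation: Optional[float] = None
    n_pooled: int = 0
    notes: List[str] = field(default_factory=list)


@dataclass
class EvalReport:
    """Aggregated evaluation output, serializable to JSON and flat CSVs."""

    n_participants: int
    n_bins: int
    seed: int
    point_biserial: Optional[float] = None
    point_biserial_note: Optional[str] = None
    randomized_r: Optional[float] = None
    calibration: Optional[CalibrationResult] = None
    variants: Dict[str, VariantResult] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def variant_table(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(v) for v in self.variants.values()]
        for r in rows:
            r["notes"] = "; ".join(r["notes"])
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {
            "n_participants": self.n_participants,
            "n_bins": self.n_bins,
            "seed": self.seed,
            "point_biserial": self.point_biserial,
            "point_biserial_note": self.point_biserial_note,
            "randomized_r": self.randomized_r,
            "warnings": self.warnings,
            "variants": {k: dataclasses.asdict(v) for k, v in self.variants.items()},
        }
        if self.calibration is not None:
            out["calibration"] = {
                "slope": self.calibration.slope,
                "intercept": self.calibration.intercept,
                "note": self.calibration.note,
                "table": self.calibration.table.to_dict(orient="records"),
            }
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_sanitize(self.to_dict()), fh, indent=2)
            fh.write("\n")


def _sanitize(obj):
    """Make a nested structure JSON-clean: numpy scalars to Python ones,
    NaN to null."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if f != f else f
    return obj


def evaluate_cohort(streams: Sequence[EventStream],
                    variants: Sequence[str] = VARIANT_NAMES,
                    config: Optional[ModelConfig] = None,
                    seed: int = 0,
                    cv: bool = True,
                    initial_flexibility: float = 0.0,
                    separate_bad_shift: bool = True) -> EvalReport:
    """Run the full pipeline on a set of streams.

    The switch model is replayed over every stream to produce per-bin
    records; the summed prediction is scored directly (correlation,
    permuted baseline, calibration), and each requested logistic variant is
    assessed under leave-one-participant-out CV (or in-sample when ``cv``
    is off, e.g. for a single participant).
    """
    model = FluidEventsModel(config)
    records = model.run_cohort(streams, initial_flexibility=initial_flexibility)
    if cv and records["participant"].nunique() < 2:
        raise ValueError("leave-one-participant-out CV needs >= 2 participants; "
                         "pass cv=False for in-sample evaluation")
    report = EvalReport(
        n_participants=records["participant"].nunique(),
        n_bins=len(records),
        seed=seed,
    )

    try:
        report.point_biserial = point_biserial(records["p_sum"], records["shift"])
        report.randomized_r = randomized_baseline(records["p_sum"],
                                                  records["shift"], seed)
    except UndefinedMetricError as exc:
        report.point_biserial_note = str(exc)
    report.calibration = calibration_bins(records["p_sum"], records["shift"])

    for name in variants:
        variant = ModelVariant.from_name(name, separate_bad_shift)
        result = VariantResult(name=name)
        try:
            if cv:
                pooled, fold_warnings = lopo_cv(records, variant)
                result.notes.extend(fold_warnings)
            else:
                params = fit_logit(records, variant)
                pooled = records.copy()
                pooled["p_model"] = predict_logit(params, records, variant)
        except (FitError, ValueError) as exc:
            result.notes.append(str(exc))
            report.variants[name] = result
            continue
        result.n_pooled = len(pooled)
        try:
            result.auc = roc_auc(pooled["p_model"], pooled["shift"])
        except UndefinedMetricError as exc:
            result.notes.append(f"AUC undefined: {exc}")
        try:
            cm = precision_recall(pooled["p_model"], pooled["shift"])
            result.precision = cm.precision
            result.recall = cm.recall
            result.switch_rate = cm.switch_rate
            if cm.note:
                result.notes.append(cm.note)
        except UndefinedMetricError as exc:
            result.notes.append(f"classification undefined: {exc}")
        try:
            result.switch_rate_correlation = switch_rate_correlation(pooled)
        except UndefinedMetricError as exc:
            result.notes.append(f"switch-rate correlation undefined: {exc}")
        report.variants[name] = result
    return report
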