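"""Classifier evaluation: ROC/AUC, confusion matrices, inconclusive rates,
per-patient summaries, per-grade correct rates and tiled probability maps.

Class encoding matches the classifier: 0 = liver, 1 = tumor; the score is
always the posterior probability of the tumor class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .classify import INCONCLUSIVE_BAND

LABELS = ("liver", "tumor")


class EvaluationError(ValueError):
    """Raised for inputs an evaluation statistic is undefined on."""


def roc_auc(posteriors: np.ndarray, truths: Sequence) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from a threshold sweep and the trapezoidal AUC.

    Ties in the scores are handled by the rank-based (Mann–Whitney) AUC
    definition, which the trapezoidal rule on the tied ROC reproduces.
    """
    y = _as_codes(truths)
    if len(np.unique(y)) < 2:
        raise EvaluationError("ROC requires both classes in the truth labels")
    scores = np.asarray(posteriors, dtype=np.float64)
    fpr, tpr, _ = skm.roc_curve(y, scores)
    auc = float(skm.roc_auc_score(y, scores))
    return np.column_stack([fpr, tpr]), auc


def _as_codes(truths: Sequence) -> np.ndarray:
    arr = np.asarray(truths)
    if arr.dtype.kind in "SU O":
        unknown = set(arr.tolist()) - set(LABELS)
        if unknown:
            raise EvaluationError(f"unknown labels {sorted(unknown)}")
        return (arr == "tumor").astype(np.int64)
    codes = arr.astype(np.int64)
    if not np.isin(codes, [0, 1]).all():
        raise EvaluationError("numeric labels must be 0 (liver) or 1 (tumor)")
    return codes


@dataclass(frozen=True)
class ConfusionSummary:
    confusion: np.ndarray  # rows: truth (liver, tumor); cols: prediction
    correct_rate: float
    sensitivity: float | None  # tumor recall; None if no tumor truths
    specificity: float | None  # liver recall; None if no liver truths


def confusion_and_rates(predicted: Sequence, truths: Sequence) -> ConfusionSummary:
    """2×2 confusion counts plus overall correct rate and class recalls.

    A recall is ``None`` (flagged undefined) when its truth class is absent.
    """
    y_true = _as_codes(truths)
    y_pred = _as_codes(predicted)
    if y_true.size == 0:
        raise EvaluationError("empty results")
    confusion = skm.confusion_matrix(y_true, y_pred, labels=[0, 1])
    total = confusion.sum()
    correct = float(np.trace(confusion) / total)
    n_liver = confusion[0].sum()
    n_tumor = confusion[1].sum()
    sensitivity = float(confusion[1, 1] / n_tumor) if n_tumor else None
    specificity = float(confusion[0, 0] / n_liver) if n_liver else None
    return ConfusionSummary(confusion, correct, sensitivity, specificity)


def inconclusive_rate(results: pd.DataFrame | Sequence[float]) -> float:
    """Fraction of predictions with posterior in the closed band [0.3, 0.7]."""
    if isinstance(results, pd.DataFrame):
        if len(results) == 0:
            raise EvaluationError("empty results")
        if "inconclusive" in results.columns:
            return float(results["inconclusive"].mean())
        posteriors = results["posterior_tumor"].to_numpy()
    else:
        posteriors = np.asarray(results, dtype=np.float64)
        if posteriors.size == 0:
            raise EvaluationError("empty results")
    lo, hi = INCONCLUSIVE_BAND
    return float(np.mean((posteriors >= lo) & (posteriors <= hi)))


def per_patient_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per (patient, sample) image counts, misclassified fraction and mean
    posterior of the true class.

    The mean true-class posterior is the quantity behind per-patient average
    classification probability plots; the misclassified fraction is the
    per-patient error bar. Both are reported side by side.
    """
    required = {"patient_id", "sample", "true_label", "predicted", "posterior_tumor"}
    missing = required - set(results.columns)
    if missing:
        raise EvaluationError(f"results lack columns {sorted(missing)}")
    df = results.copy()
    df["misclassified"] = df["predicted"] != df["true_label"]
    df["posterior_true_class"] = np.where(
        df["true_label"] == "tumor", df["posterior_tumor"], 1.0 - df["posterior_tumor"]
    )
    grouped = (
        df.groupby(["patient_id", "sample"], sort=True)
        .agg(
            n_images=("misclassified", "size"),
            n_misclassified=("misclassified", "sum"),
            misclassified_fraction=("misclassified", "mean"),
            mean_true_class_posterior=("posterior_true_class", "mean"),
        )
        .reset_index()
    )
    return grouped


def per_grade_rates(results: pd.DataFrame, grade_labels: Mapping[str, str]) -> pd.DataFrame:
    """Correct classification rate of tumor images, by tumor grade.

    ``grade_labels`` maps patient_id → grade; patients without a grade are
    grouped as ``ungraded``.
    """
    tumor = results[results["true_label"] == "tumor"].copy()
    if len(tumor) == 0:
        raise EvaluationError("no tumor images in results")
    tumor["grade"] = [grade_labels.get(p, "ungraded") for p in tumor["patient_id"]]
    tumor["correct"] = tumor["predicted"] == tumor["true_label"]
    out = (
        tumor.groupby("grade", sort=True)
        .agg(n_images=("correct", "size"), correct_rate=("correct", "mean"))
        .reset_index()
    )
    return out


@dataclass
class EvalReport:
    """Bundle of test-set statistics for one model."""

    model_name: str
    roc_points: np.ndarray
    auc: float
    confusion: np.ndarray
    correct_rate: float
    sensitivity: float | None
    specificity: float | None
    inconclusive_rate: float
    per_patient: pd.DataFrame
    n_images: int

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "n_images": self.n_images,
            "auc": self.auc,
            "correct_rate": self.correct_rate,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "inconclusive_rate": self.inconclusive_rate,
            "confusion": self.confusion.tolist(),
        }

    def to_markdown(self) -> str:
        lines = [
            f"# Evaluation report — {self.model_name}",
            "",
            f"- images evaluated: {self.n_images}",
            f"- AUC: {self.auc:.4f}",
            f"- correct rate: {self.correct_rate:.4f}",
            f"- sensitivity (tumor recall): {self.sensitivity if self.sensitivity is None else f'{self.sensitivity:.4f}'}",
            f"- specificity (liver recall): {self.specificity if self.specificity is None else f'{self.specificity:.4f}'}",
            f"- inconclusive fraction (posterior in [0.3, 0.7]): {self.inconclusive_rate:.4f}",
            "",
            "Confusion matrix (rows: truth liver/tumor; cols: predicted liver/tumor):",
            "",
            f"    {self.confusion[0].tolist()}",
            f"    {self.confusion[1].tolist()}",
        ]
        return "\n".join(lines)


def evaluate_model(results: pd.DataFrame, model_name: str = "model") -> EvalReport:
    """Full report from a prediction table (one row per evaluated FoV)."""
    if len(results) == 0:
        raise EvaluationError("empty results")
    roc_points, auc = roc_auc(results["posterior_tumor"].to_numpy(), results["true_label"])
    summary = confusion_and_rates(results["predicted"], results["true_label"])
    return EvalReport(
        model_name=model_name,
        roc_points=roc_points,
        auc=auc,
        confusion=summary.confusion,
        correct_rate=summary.correct_rate,
        sensitivity=summary.sensitivity,
        specificity=summary.specificity,
        inconclusive_rate=inconclusive_rate(results),
        per_patient=per_patient_summary(results) if "patient_id" in results.columns else pd.DataFrame(),
        n_images=len(results),
    )


# ---------------------------------------------------------------------------
# Probability maps
# ---------------------------------------------------------------------------


@dataclass
class ProbabilityMap:
    """Tile grid of tumor posteriors for one mapped (border) sample."""

    values: np.ndarray  # (rows, cols) float, NaN where missing
    present: np.ndarray  # bool mask of filled tiles
    inconclusive: np.ndarray  # bool mask, False where missing
    sample_id: str


def build_probability_map(
    results: pd.DataFrame, grid: tuple[int, int] | None = None, sample_id: str = "sample"
) -> ProbabilityMap:
    """Arrange per-tile posteriors on the sample's grid.

    ``results`` must carry row, col and posterior_tumor for a single sample;
    duplicate tile coordinates are an error; tiles absent from the table
    (e.g. QC-rejected) are masked out.
    """
    required = {"row", "col", "posterior_tumor"}
    missing = required - set(results.columns)
    if missing:
        raise EvaluationError(f"results lack columns {sorted(missing)}")
    coords = list(zip(results["row"].astype(int), results["col"].astype(int)))
    if len(set(coords)) != len(coords):
        raise EvaluationError("duplicate tile coordinates in map results")
    if grid is None:
        grid = (max(r for r, _ in coords) + 1, max(c for _, c in coords) + 1)
    rows, cols = grid
    values = np.full((rows, cols), np.nan)
    inconclusive = np.zeros((rows, cols), dtype=bool)
    lo, hi = INCONCLUSIVE_BAND
    posteriors = results["posterior_tumor"].to_numpy(dtype=np.float64)
    flags = (
        results["inconclusive"].to_numpy(dtype=bool)
        if "inconclusive" in results.columns
        else (posteriors >= lo) & (posteriors <= hi)
    )
    for (r, c), p, flag in zip(coords, posteriors, flags):
        values[r, c] = p
        inconclusive[r, c] = bool(flag)
    present = ~np.isnan(values)
    return ProbabilityMap(values=values, present=present, inconclusive=inconclusive, sample_id=sample_id)


def estimate_boundary_col(pmap: ProbabilityMap) -> int:
    """Column of the first 0.5-crossing of the column-wise median posterior.

    Returns the first column whose median posterior exceeds 0.5 (the start of
    the tumor side), i.e. the liver/tumor boundary column; ``cols`` if no
    column is tumor-dominated. Used for boundary-localization checks on
    synthetic border samples.
    """
    rows, cols = pmap.values.shape
    medians = np.full(cols, np.nan)
    for c in range(cols):
        col_vals = pmap.values[:, c][pmap.present[:, c]]
        if col_vals.size:
            medians[c] = np.median(col_vals)
    for c in range(cols):
        if np.isfinite(medians[c]) and medians[c] > 0.5:
            return c
    return cols


def render_probability_map(pmap: ProbabilityMap, path: str | Path) -> None:
    """Save the map as a PNG: two-ended colormap (liver blue → tumor red),
    missing tiles neutral gray, inconclusive tiles hatched."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, pmap.values.shape[1] * 0.5), max(2.5, pmap.values.shape[0] * 0.5)))
    cmap = plt.get_cmap("coolwarm").copy()
    cmap.set_bad(color="0.6")
    masked = np.ma.masked_invalid(pmap.values)
    im = ax.imshow(masked, cmap=cmap, vmin=0.0, vmax=1.0, interpolation="nearest")
    for r, c in zip(*np.nonzero(pmap.inconclusive)):
        ax.add_patch(
            plt.Rectangle((c - 0.5, r - 0.5), 1, 1, fill=False, hatch="///", edgecolor="k", linewidth=0.5)
        )
    fig.colorbar(im, ax=ax, label="posterior probability (tumor)")
    ax.set_title(pmap.sample_id)
    ax.set_xlabel("tile column")
    ax.set_ylabel("tile row")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def write_report(report: EvalReport, out_dir: str | Path) -> None:
    """Write an EvalReport as JSON + Markdown + ROC CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = report.model_name.lower().replace("-", "_")
    (out_dir / f"report_{stem}.json").write_text(json.dumps(report.to_dict(), indent=2))
    (out_dir / f"report_{stem}.md").write_text(report.to_markdown() + "\n")
    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
        out_dir / f"roc_{stem}.csv", index=False
    )
    if len(report.per_patient):
        report.per_patient.to_csv(out_dir / f"per_patient_{stem}.csv", index=False)
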