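"""Binary-classification evaluation: confusion matrix, ratio metrics,
ROC/AUC and PR/AP curves, and report bundles.

The positive class throughout is ``without_stress`` — sensitivity is the
fraction of resting recordings recognized as resting.  This is the
reverse of the disease-positive convention common in clinical work, so
it is stated on every type here.

Percentages are rendered at one decimal with half-up rounding, matching
how such tables are usually printed.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn import metrics as skm

POSITIVE_LABEL = "without_stress"


def percent(value: float) -> float:
    """Render a proportion as a percentage at one decimal, half-up."""
    if np.isnan(value):
        return float("nan")
    return float(Decimal(repr(value * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts with positive class = without_stress."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(y_true, y_pred, positive: str = POSITIVE_LABEL) -> ConfusionMatrix:
    """Count TP/FN/FP/TN; labels must be binary."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    seen = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(seen) > 2:
        raise ValueError(f"labels are not binary: {sorted(map(str, seen))}")
    t_pos = y_true == positive
    p_pos = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(t_pos & p_pos)),
        fn=int(np.sum(t_pos & ~p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
        tn=int(np.sum(~t_pos & ~p_pos)),
    )


@dataclass(frozen=True)
class MetricReport:
    """The five ratio metrics as proportions in [0, 1].

    accuracy    = (TP + TN) / n
    sensitivity = TP / (TP + FN)    (recall on without_stress)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    npv         = TN / (TN + FN)    (negative predictive value)

    A zero denominator yields NaN for that metric only — never 0.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    npv: float

    _FIELDS = ("accuracy", "sensitivity", "specificity", "precision", "npv")

    def as_percent(self) -> dict[str, float]:
        return {name: percent(getattr(self, name)) for name in self._FIELDS}

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self._FIELDS}


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """The five ratios from a confusion matrix."""
    return MetricReport(
        accuracy=_ratio(cm.tp + cm.tn, cm.n),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
    )


@dataclass
class Curve:
    """An ROC or PR curve with its summary area.

    For ROC, ``x``/``y`` are FPR/TPR swept over grouped score thresholds
    and ``area`` the trapezoidal AUC; for PR they are recall/precision
    and ``area`` the step-wise average precision
    AP = Σ (R_k − R_{k−1}) · P_k.
    """

    kind: str  # "roc" | "pr"
    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray
    area: float

    def frame(self) -> pd.DataFrame:
        names = ("fpr", "tpr") if self.kind == "roc" else ("recall", "precision")
        return pd.DataFrame({names[0]: self.x, names[1]: self.y})


def _binarize(labels, positive: str) -> np.ndarray:
    labels = np.asarray(labels)
    return (labels == positive).astype(int)


def roc_curve(scores, labels, positive: str = POSITIVE_LABEL) -> Curve:
    """ROC curve over all distinct score thresholds, AUC by trapezoid.

    ``scores`` are the positive-class scores.  Tied scores collapse into
    a single threshold step.
    """
    y = _binarize(labels, positive)
    if y.min() == y.max():
        raise ValueError("ROC needs at least one positive and one negative sample")
    fpr, tpr, thr = skm.roc_curve(y, scores)
    return Curve(kind="roc", x=fpr, y=tpr, thresholds=thr, area=float(skm.auc(fpr, tpr)))


def pr_curve(scores, labels, positive: str = POSITIVE_LABEL) -> Curve:
    """Precision–recall curve with step-wise (non-interpolated) AP."""
    y = _binarize(labels, positive)
    if y.sum() == 0:
        raise ValueError("PR curve needs at least one positive sample")
    precision, recall, thr = skm.precision_recall_curve(y, scores)
    ap = float(skm.average_precision_score(y, scores))
    # sklearn returns points from high threshold to low; store recall ascending
    return Curve(kind="pr", x=recall[::-1], y=precision[::-1], thresholds=thr[::-1], area=ap)


def invert_rates(
    n: int,
    accuracy: float,
    sensitivity: float,
    specificity: float,
    precision: float,
    npv: float,
) -> list[ConfusionMatrix]:
    """All 2×2 matrices of total ``n`` whose five metrics round (one
    decimal, half-up, in percent) to the given targets.

    Exhaustive enumeration — the independent check that a printed row of
    rates pins down a unique confusion matrix.
    """
    targets = dict(
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        precision=precision, npv=npv,
    )
    found = []
    for tp in range(n + 1):
        for fn in range(n + 1 - tp):
            for fp in range(n + 1 - tp - fn):
                tn = n - tp - fn - fp
                cm = ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
                rep = metrics(cm).as_percent()
                if all(
                    not np.isnan(rep[k]) and abs(rep[k] - v) < 1e-9
                    for k, v in targets.items()
                ):
                    found.append(cm)
    return found


def report(
    models: dict[str, object],
    datasets: dict[str, tuple[np.ndarray, np.ndarray]],
    out_dir: str | None = None,
    positive: str = POSITIVE_LABEL,
) -> dict[tuple[str, str], dict]:
    """Evaluate every (model, domain) pair.

    ``models`` maps model names to fitted estimators; ``datasets`` maps
    domain names to ``(X, y)``.  Each bundle holds one confusion matrix,
    the five metrics, and ROC + PR curves.  With ``out_dir`` set, metric
    and curve tables are written as CSV and the curves plotted to PNG;
    identical inputs reproduce identical CSVs.
    """
    bundles: dict[tuple[str, str], dict] = {}
    rows = []
    for mname, model in models.items():
        pos_col = int(np.where(model.classes_ == positive)[0][0])
        for dname, (X, y) in datasets.items():
            scores = model.predict_proba(X)[:, pos_col]
            preds = model.predict(X)
            cm = confusion(y, preds, positive=positive)
            rep = metrics(cm)
            bundle = dict(
                confusion=cm,
                metrics=rep,
                roc=roc_curve(scores, y, positive=positive),
                pr=pr_curve(scores, y, positive=positive),
            )
            bundles[(mname, dname)] = bundle
            for metric, value in rep.as_percent().items():
                rows.append(dict(model=mname, domain=dname, metric=metric, value=value))
            rows.append(dict(model=mname, domain=dname, metric="auc", value=percent(bundle["roc"].area)))
            rows.append(dict(model=mname, domain=dname, metric="ap", value=percent(bundle["pr"].area)))
    table = pd.DataFrame(rows, columns=["model", "domain", "metric", "value"])

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        for (mname, dname), bundle in bundles.items():
            for kind in ("roc", "pr"):
                curve: Curve = bundle[kind]
                curve.frame().to_csv(
                    os.path.join(out_dir, f"{mname}_{dname}_{kind}.csv"), index=False
                )
            fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
            axes[0].plot(bundle["roc"].x, bundle["roc"].y)
            axes[0].set(xlabel="FPR", ylabel="TPR", title=f"ROC AUC={bundle['roc'].area:.3f}")
            axes[1].plot(bundle["pr"].x, bundle["pr"].y)
            axes[1].set(xlabel="Recall", ylabel="Precision", title=f"PR AP={bundle['pr'].area:.3f}")
            fig.suptitle(f"{mname} / {dname}")
            fig.tight_layout()
            fig.savefig(os.path.join(out_dir, f"{mname}_{dname}_curves.png"), dpi=100)
            plt.close(fig)
    for bundle in bundles.values():
        bundle["table"] = table
    return bundles
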