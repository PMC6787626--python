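"""Pairwise ROC curves and AUC between severity classes.

Scores are the forest's out-of-bag vote fractions for the higher-severity
class of the pair, so an AUC above 0.5 means the model pushes genuinely
more-severe cases toward higher scores.  The trapezoidal AUC equals the
Mann-Whitney pair-count probability (ties counted half), an identity the
test-suite checks to 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from wstkit.forest import RFModelResult, correctly_predicted_subset


@dataclass
class ROCResult:
    class_pair: tuple
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    restricted_to_correct: bool = False

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        )


def roc_curve(scores, labels, class_pair=(0, 1), restricted_to_correct=False) -> ROCResult:
    """ROC curve and trapezoidal AUC for binary labels.

    Thresholds sweep the unique score values; tied scores move the curve
    diagonally in one step.  The returned curve starts at (0,0) and ends
    at (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        class_pair=tuple(class_pair),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        restricted_to_correct=restricted_to_correct,
    )


def pairwise_class_roc(
    model: RFModelResult,
    table: pd.DataFrame,
    pair: tuple,
    correct_only: bool = False,
    class_column: str = "class3",
) -> ROCResult:
    """ROC between two severity classes from OOB vote fractions.

    The score is the OOB vote fraction for the *second* (higher-severity)
    member of ``pair``; only cases of the two classes enter.  With
    ``correct_only`` the table is first restricted to OOB-correct cases.
    """
    a, b = pair
    if len(table) != len(model.labels):
        raise ValueError("table is not row-aligned with the fitted model")
    work = table.copy()
    work["_score"] = model.oob_votes[:, int(np.searchsorted(model.classes, b))]
    work["_true"] = model.labels
    if correct_only:
        work = correctly_predicted_subset(model, work)
    sel = work[work["_true"].isin([a, b])]
    if (sel["_true"] == a).sum() == 0 or (sel["_true"] == b).sum() == 0:
        raise ValueError(
            f"class pair {pair}: one class is empty"
            + (" after restricting to correctly predicted cases" if correct_only else "")
        )
    return roc_curve(
        sel["_score"].to_numpy(),
        (sel["_true"] == b).to_numpy(),
        class_pair=(a, b),
        restricted_to_correct=correct_only,
    )
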