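"""Leave-one-joint-out cross-validation, latent-variable selection, and
confusion-matrix reporting.

Paired damage/control specimens come from the same knee joint, so random
sample-level folds would leak joint-specific signal between training and
test sets.  Here every fold holds out *all* samples of one joint; centring
means and Frobenius block norms are recomputed from the training rows of
each fold, so no statistic ever sees the held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import BlockSet, StudyDesign
from .multiblock import fit_mbpls
from .pls import classify, confusion_stats

__all__ = ["CVResult", "logo_folds", "run_cv", "select_lv", "report"]


def logo_folds(design: StudyDesign) -> dict[str, list[int]]:
    """One fold per distinct joint id: joint -> sample row indices.

    A joint's damaged specimens and their adjacent controls leave together.
    """
    joints = design.joints
    uniq = list(dict.fromkeys(joints))
    if len(uniq) < 2:
        raise ValueError("leave-one-joint-out needs at least 2 joints")
    return {j: np.flatnonzero(joints == j).tolist() for j in uniq}


@dataclass
class CVResult:
    """Out-of-fold predictions for every LV count 1..A_max."""

    fold_map: dict[str, list[int]]       # joint -> test sample indices
    scores: np.ndarray                   # (samples, A_max) continuous scores
    labels: np.ndarray                   # (samples,) ground truth 0/1
    sample_ids: list[str]
    selection: str = "misclassification"
    chosen_a: int | None = None

    @property
    def a_max(self) -> int:
        return self.scores.shape[1]

    def predictions(self, a: int) -> np.ndarray:
        return classify(self.scores[:, a - 1])

    def error_curve(self, criterion: str | None = None) -> np.ndarray:
        """Per-A out-of-fold prediction error (index 0 <-> 1 LV)."""
        crit = criterion or self.selection
        if crit == "misclassification":
            return np.array(
                [(self.predictions(a) != self.labels).mean() for a in range(1, self.a_max + 1)]
            )
        if crit == "rmse":
            return np.sqrt(((self.scores - self.labels[:, None]) ** 2).mean(axis=0))
        raise ValueError(f"unknown selection criterion {crit!r}")

    def accuracy_curve(self) -> np.ndarray:
        return 1.0 - self.error_curve("misclassification")

    def stats(self, a: int | None = None) -> dict:
        a = a or self.chosen_a or select_lv(self)
        return confusion_stats(self.predictions(a), self.labels)


def run_cv(
    blocks: BlockSet,
    y: np.ndarray,
    design: StudyDesign,
    A_max: int,
    selection: str = "misclassification",
) -> CVResult:
    """Grouped cross-validation of a (multi-)block PLS-DA model.

    ``blocks`` must hold one preprocessed, replicate-averaged row per design
    sample, in design order.  For each fold the model is fitted once at the
    largest supported LV count and the whole nested sequence of per-A
    predictions is extracted.
    """
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    ids = [k[0] for k in blocks.row_keys]
    if ids != design.sample_ids:
        raise ValueError("block rows are not aligned with the design table")
    y = np.asarray(y, int)
    folds = logo_folds(design)
    n = len(ids)
    p_total = sum(b.n_channels for b in blocks.blocks)
    a_eff = min(A_max, min(n - len(te) for te in folds.values()) - 1, p_total)

    scores = np.full((n, a_eff), np.nan)
    for joint, test_idx in folds.items():
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        y_tr = y[train_idx]
        if len(set(y_tr.tolist())) < 2:
            raise ValueError(
                f"training set is single-class when holding out joint {joint!r}"
            )
        model = fit_mbpls(blocks.select_rows(train_idx), y_tr, a_eff)
        test_blocks = blocks.select_rows(np.asarray(test_idx))
        for a in range(1, a_eff + 1):
            scores[test_idx, a - 1] = model.predict(test_blocks, a=a)

    cv = CVResult(
        fold_map=folds,
        scores=scores,
        labels=y,
        sample_ids=ids,
        selection=selection,
    )
    cv.chosen_a = select_lv(cv)
    return cv


def select_lv(cv: CVResult, criterion: str | None = None) -> int:
    """LV count minimising the cross-validated prediction error; ties are
    broken toward fewer components (parsimony)."""
    err = cv.error_curve(criterion)
    return int(np.argmin(err)) + 1  # argmin returns the first minimum


def report(cv: CVResult, label: str = "") -> dict:
    """Machine-readable confusion report at the chosen LV count.

    The 2x2 matrix is row-normalised to integer percentages (rows: true
    damaged / true healthy; columns: called damaged / called healthy); each
    row sums to 100 by construction.  Accuracy is recomputed from the
    unrounded per-class fractions.
    """
    a = cv.chosen_a or select_lv(cv)
    s = cv.stats(a)
    sens_pct = round(100.0 * s["sensitivity"])
    spec_pct = round(100.0 * s["specificity"])
    return {
        "model": label,
        "lv": a,
        "accuracy_pct": round(100.0 * s["accuracy"]),
        "sensitivity_pct": sens_pct,
        "specificity_pct": spec_pct,
        "confusion_pct": [[sens_pct, 100 - sens_pct], [100 - spec_pct, spec_pct]],
        "counts": s["counts"],
        "accuracy": s["accuracy"],
        "sensitivity": s["sensitivity"],
        "specificity": s["specificity"],
        "selection": cv.selection,
        "note": "LV count selected on the same cross-validation used for "
                "reporting (non-nested); estimates carry selection optimism",
    }
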