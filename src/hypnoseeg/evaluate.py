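"""Confusion-matrix metrics for the binary RH/ND decision.

RH (road hypnosis) is the positive class. The four statistics are

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SEN = TP / (TP + FN)          (recall on road hypnosis)
    SPE = TN / (TN + FP)          (recall on normal driving)
    GM  = sqrt(SEN * SPE)         (geometric mean)

A metric whose denominator is zero is reported as ``None`` (undefined),
never as 0 — a degenerate predictor must not look perfect. GM as the
literal product SEN*SPE (no radical) is available behind a flag for
auditability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .recording import CLASSES


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion-matrix counts must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    acc: float | None
    sen: float | None
    spe: float | None
    gm: float | None
    model: str = ""
    dataset: str = ""

    def as_dict(self) -> dict:
        return {"ACC": self.acc, "SEN": self.sen, "SPE": self.spe, "GM": self.gm}


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Counts with RH positive; raises on length mismatch or unknown labels."""
    y_true = np.asarray(y_true, dtype="U2")
    y_pred = np.asarray(y_pred, dtype="U2")
    if y_true.shape != y_pred.shape:
        raise ValidationError(
            f"label length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    bad = (set(y_true) | set(y_pred)) - set(CLASSES)
    if bad:
        raise ValidationError(f"unknown labels {sorted(bad)}")
    pos_t, pos_p = y_true == "RH", y_pred == "RH"
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def metrics(
    cm: ConfusionMatrix,
    model: str = "",
    dataset: str = "",
    gm_literal_product: bool = False,
) -> MetricReport:
    """ACC/SEN/SPE/GM from counts; undefined ratios become ``None``."""
    acc = (cm.tp + cm.tn) / cm.total
    sen = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    spe = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else None
    if sen is None or spe is None:
        gm = None
    elif gm_literal_product:
        gm = sen * spe
    else:
        gm = math.sqrt(sen * spe)
    return MetricReport(acc=acc, sen=sen, spe=spe, gm=gm, model=model, dataset=dataset)


def metrics_from_labels(y_true, y_pred, model: str = "", dataset: str = "") -> MetricReport:
    return metrics(confusion(y_true, y_pred), model=model, dataset=dataset)


def compare_models(reports: list[MetricReport]) -> pd.DataFrame:
    """Rank reports by accuracy (ties stable by model name order given).

    All reports must carry the same dataset provenance tag.
    """
    if len(reports) < 2:
        raise ValidationError("need at least 2 reports to compare")
    datasets = {r.dataset for r in reports}
    if len(datasets) != 1:
        raise ValidationError(
            f"reports come from different datasets: {sorted(datasets)}"
        )
    frame = pd.DataFrame(
        [{"model": r.model, **r.as_dict()} for r in reports]
    )
    return frame.sort_values(
        "ACC", ascending=False, kind="stable", ignore_index=True
    )
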