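"""Accuracy metrics: ROC-AUC, sensitivity/specificity at a fixed cutoff."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score


def _binary_labels(labels) -> np.ndarray:
    y = np.asarray(
        [1 if v in (1, "case", True) else 0 for v in np.asarray(labels).ravel()],
        dtype=int,
    )
    return y


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney probability that a randomly chosen case outscores
    a randomly chosen control, with ties counted one half.
    """
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and labels must align")
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(y, s))


def mean_sens_spec(scores, labels, cutoff: float = 0.5) -> tuple[float, float, float]:
    """Sensitivity, specificity and their mean at a fixed score cutoff.

    Subjects with score strictly above the cutoff are classified as cases.
    If a class is absent its rate is NaN and the mean is NaN (signalled).
    """
    if not 0.0 < cutoff < 1.0 and not np.isfinite(cutoff):
        raise ValueError("cutoff must be a finite value in (0, 1) for vote fractions")
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    pred = (s > cutoff).astype(int)
    n_case, n_ctrl = int((y == 1).sum()), int((y == 0).sum())
    sens = float(np.mean(pred[y == 1] == 1)) if n_case else float("nan")
    spec = float(np.mean(pred[y == 0] == 0)) if n_ctrl else float("nan")
    return sens, spec, (sens + spec) / 2.0


@dataclass
class EvaluationResult:
    """Per-evaluation accuracy summary."""

    auc: float
    sensitivity: float
    specificity: float
    mean_sens_spec: float
    n: int
    site: str | None = None
    p_value: float | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_scores(cls, scores, labels, cutoff: float = 0.5, site=None, p_value=None):
        sens, spec, mss = mean_sens_spec(scores, labels, cutoff)
        return cls(
            auc=roc_auc(scores, labels),
            sensitivity=sens,
            specificity=spec,
            mean_sens_spec=mss,
            n=len(np.asarray(scores)),
            site=site,
            p_value=p_value,
        )

    def to_dict(self) -> dict:
        out = {
            "site": self.site,
            "n": self.n,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mean_sens_spec": self.mean_sens_spec,
        }
        if self.p_value is not None:
            out["p_value"] = self.p_value
        out.update(self.extra)
        return out
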