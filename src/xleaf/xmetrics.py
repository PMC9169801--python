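"""Explanation assessment: RMSE, cosine similarity and PIP against reference masks.

An explanation is compared with the *useful-region* mask (the complement of
the annotation matrix).  Heatmaps are max-normalized to [0, 1] first, since
Grad-CAM magnitudes are scale-arbitrary:

    RMSE    = sqrt( sum_i (a_i - b_i)^2 / N )
    CosineS = sum_i a_i b_i / (||a|| * ||b||)
    PIP@p%  = |IP intersect RM| / |IP|

where IP is the set of the ceil(N * p / 100) pixels with the highest
explanation values (ties broken toward the lowest flat index) and RM the set
of mask pixels.  Lower RMSE and higher CosineS / PIP indicate explanations
closer to the reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gradcam import Explanation, gradcam_explain
from .leafsim import LabeledDataset
from .nets import Model, evaluate_accuracy

__all__ = ["normalize_explanation", "rmse", "cosine_similarity", "pip",
           "AssessmentReport", "assess_model"]


def normalize_explanation(e) -> np.ndarray:
    """Scale a nonnegative heatmap by its maximum; all-zero maps pass through."""
    h = e.heatmap if isinstance(e, Explanation) else np.asarray(e)
    h = np.asarray(h, dtype=np.float64)
    if (h < 0).any():
        raise ValueError("explanations must be nonnegative")
    m = h.max()
    return (h / m if m > 0 else h).astype(np.float32)


def _flat_pair(a, b):
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return a, b


def rmse(a, b) -> float:
    a, b = _flat_pair(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def cosine_similarity(a, b) -> float:
    a, b = _flat_pair(a, b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm input")
    return float(np.dot(a, b) / (na * nb))


def pip(a, b, percent: float) -> float:
    """Proportion of the top-``percent``% pixels that fall in the mask.

    Ties in the explanation are broken toward the lowest flat index.  Warns
    when percent/100 is not below |RM|/N (the metric saturates there).
    """
    if not (0 < percent <= 100):
        raise ValueError(f"percent must be in (0, 100], got {percent}")
    a, b = _flat_pair(a, b)
    n = a.size
    n_mask = int((b > 0).sum())
    if percent / 100.0 >= n_mask / n:
        warnings.warn(f"PIP percent {percent} is not below the mask fraction "
                      f"{100 * n_mask / n:.2f}%; the score saturates",
                      stacklevel=2)
    k = math.ceil(n * percent / 100.0)
    top = np.argsort(-a, kind="stable")[:k]
    return float((b[top] > 0).sum() / k)


@dataclass
class AssessmentReport:
    """Aggregate accuracy and explanation metrics for one model on one split."""

    model_id: str
    accuracy_pct: float
    mean_rmse: float
    mean_cosine: float
    mean_pip: dict[float, float]      # percent -> mean PIP, on a 0-100 scale
    n_samples: int
    n_metric_samples: int             # samples with a usable assessment mask
    n_cosine_excluded: int            # zero-norm heatmaps skipped for CosineS
    percents: tuple = (1.0, 5.0, 10.0)

    def to_row(self) -> dict:
        row = {"model": self.model_id, "accuracy_pct": self.accuracy_pct,
               "rmse": self.mean_rmse, "cosines": self.mean_cosine}
        for p in self.percents:
            row[f"pip_{p:g}"] = self.mean_pip[p]
        row["n_samples"] = self.n_samples
        row["n_cosine_excluded"] = self.n_cosine_excluded
        return row


def assess_model(model: Model, data: LabeledDataset, split: str = "test",
                 percents=(1.0, 5.0, 10.0), class_choice: str = "true",
                 model_id: str = "model") -> AssessmentReport:
    """Grad-CAM every split sample, normalize, and average the three metrics.

    Explanations are computed for the sample's true class by default
    (``class_choice="predicted"`` switches to the argmax class).  Samples
    with a trivial assessment mask — all-zero (no useful region) or all-one
    (no excluded region, e.g. the unmodified scenes of the fake-vs-real task,
    whose annotation is the zero opt-out matrix) — cannot discriminate
    between explanations and are excluded from the metric means;
    ``n_metric_samples`` reports how many samples were used.  All-zero
    heatmaps are additionally excluded from the cosine mean.  Accuracy is
    computed over the full split.
    """
    idx = data.splits[split]
    if len(idx) == 0:
        raise ValueError(f"split {split!r} is empty")
    missing = [int(i) for i in idx if data.samples[i].assessment is None]
    if missing:
        raise ValueError(f"samples without assessment masks: {missing}")

    percents = tuple(float(p) for p in percents)
    rmses, cosines = [], []
    pips: dict[float, list[float]] = {p: [] for p in percents}
    n_cos_skip = 0
    n_used = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PIP saturation handled by design here
        for i in idx:
            s = data.samples[i]
            mask = s.assessment
            msum = int(mask.sum())
            if msum == 0 or msum == mask.size:
                continue
            n_used += 1
            if class_choice == "true":
                c = s.label
            elif class_choice == "predicted":
                c = int(model.predict(s.image.transpose(2, 0, 1)[None])[0])
            else:
                raise ValueError(f"unknown class_choice {class_choice!r}")
            a = normalize_explanation(gradcam_explain(model, s.image, c))
            rmses.append(rmse(a, mask))
            if a.max() > 0:
                cosines.append(cosine_similarity(a, mask))
            else:
                n_cos_skip += 1
            for p in percents:
                pips[p].append(pip(a, mask, p))

    acc = evaluate_accuracy(model, data, split)
    return AssessmentReport(
        model_id=model_id,
        accuracy_pct=100.0 * acc,
        mean_rmse=float(np.mean(rmses)) if rmses else float("nan"),
        mean_cosine=float(np.mean(cosines)) if cosines else float("nan"),
        mean_pip={p: 100.0 * float(np.mean(v)) if v else float("nan")
                  for p, v in pips.items()},
        n_samples=len(idx),
        n_metric_samples=n_used,
        n_cosine_excluded=n_cos_skip,
        percents=percents,
    )


def reports_to_csv(reports, path) -> None:
    """Write AssessmentReport rows in the standard column layout."""
    pd.DataFrame([r.to_row() for r in reports]).to_csv(path, index=False)
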