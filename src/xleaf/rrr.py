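"""The balanced right-for-the-right-reasons (RRR) loss.

Training with expert guidance adds a penalty on the model's *input gradient*
over pixels an annotation matrix marks as useless (1 = useless).  The total
loss is

    NLoss = CLoss + lambda * Balance(RLoss, CLoss)

where CLoss is cross-entropy, RLoss the masked input-gradient penalty and
``Balance(l1, l2) = 10^ceil(log10(l2 / l1)) * l1`` rescales the penalty into
the decade of the classification loss, so one lambda works across tasks
whose raw gradient magnitudes differ by orders of magnitude.

The input gradient is taken on the log-transformed class probabilities,
``d(sum_c ln(p_c + 1))/dx``; probabilities keep the logarithm finite for any
logits.  The default penalty squares the masked gradient (guaranteeing
RLoss >= 0 as Balance requires); a ``literal_sum`` variant that sums the raw
masked gradient is selectable for comparison.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "LossSpec",
    "input_gradient",
    "rrr_penalty",
    "balance",
    "combined_loss",
    "BALANCE_EPS",
]

BALANCE_EPS = 1e-12


@dataclass(frozen=True)
class LossSpec:
    """Configuration of the training loss.

    ``lambda_weight = 0`` (or all-zero annotations) reduces training to plain
    cross-entropy.

    ``balance_mode`` chooses when the Balance rescaling is evaluated:

    ``"calibrated"`` (default)
        a cross-entropy warm-up covers the first ``warmup_frac`` of the
        epochs, then the Balance factor is computed once, from the first
        penalized batch, and held fixed.  Rationale: re-evaluating Balance on
        every batch creates a positive feedback loop — as the penalty drives
        the masked gradients toward zero, the rescaling grows like
        CLoss/RLoss, so the *gradient* of the balanced term diverges (for the
        squared penalty it scales as 1/sqrt(RLoss)) and training collapses
        into a constant predictor.  A one-time decade calibration keeps the
        two losses comparable without the runaway amplification.
    ``"per_batch"``
        the literal form: Balance recomputed from each batch's loss values.
    """

    lambda_weight: float = 0.0
    rloss_variant: str = "squared"  # or "literal_sum"
    closs_name: str = "cross_entropy"
    balance_mode: str = "calibrated"  # or "per_batch"
    warmup_frac: float = 1.0 / 3.0

    def __post_init__(self):
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be >= 0")
        if self.rloss_variant not in ("squared", "literal_sum"):
            raise ValueError(f"unknown rloss_variant {self.rloss_variant!r}")
        if self.closs_name != "cross_entropy":
            raise ValueError("only cross_entropy is supported as the common loss")
        if self.balance_mode not in ("calibrated", "per_batch"):
            raise ValueError(f"unknown balance_mode {self.balance_mode!r}")
        if not (0.0 <= self.warmup_frac < 1.0):
            raise ValueError("warmup_frac must be in [0, 1)")

    def describe(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def input_gradient(model, x) -> Tensor:
    """Gradient of ``sum_c ln(softmax(f(x))_c + 1)`` with respect to ``x``.

    ``x`` may be a NumPy array (single image HWC or batch NCHW) or a Tensor
    in NCHW layout.  The result stays connected to the autodiff graph, so a
    penalty built from it can itself be differentiated with respect to the
    model parameters (double backpropagation).
    """
    single_hwc = False
    if not isinstance(x, Tensor):
        arr = np.asarray(x, dtype=np.float32)
        if arr.ndim == 3:  # HWC -> NCHW
            single_hwc = True
            arr = arr.transpose(2, 0, 1)[None]
        xt = Tensor(arr, requires_grad=True)
    else:
        xt = x
        xt.requires_grad = True
    logits = model.forward(xt)
    probs = ad.softmax(logits)
    s = ad.tsum(ad.log(probs + Tensor(np.float32(1.0))))
    (g,) = ad.grad(s, [xt], create_graph=True)
    if not np.isfinite(g.data).all():
        raise FloatingPointError("non-finite input gradient")
    if single_hwc:
        return Tensor(g.data[0].transpose(1, 2, 0), requires_grad=False)
    return g


def rrr_penalty(grad, annotation, variant: str = "squared"):
    """Masked input-gradient penalty for one sample or a batch.

    ``annotation`` is (U, V) or (B, U, V) with 1 marking useless pixels; it is
    broadcast across the image channels.  ``grad`` may be (U, V), (U, V, B),
    or a batched NCHW array/Tensor.  The squared variant sums
    ``annotation * grad**2``; the literal variant sums ``annotation * grad``.
    Batched inputs return the mean of per-sample penalties.  Returns a Tensor
    when given one (for training), otherwise a float.
    """
    is_tensor = isinstance(grad, Tensor)
    ann = np.asarray(annotation, dtype=np.float32)

    if is_tensor:  # NCHW batch
        if grad.ndim != 4:
            raise ValueError("Tensor penalty path expects NCHW gradients")
        B = grad.shape[0]
        if ann.ndim != 3 or ann.shape != (B,) + tuple(grad.shape[2:]):
            raise ValueError(f"annotation shape {ann.shape} does not match "
                             f"gradient {grad.shape}")
        mask = Tensor(ann[:, None, :, :])
        masked = ad.mul(mask, ad.pow_const(grad, 2.0)) if variant == "squared" \
            else ad.mul(mask, grad)
        return ad.tmean(ad.tsum(masked, axis=(1, 2, 3)))

    g = np.asarray(grad, dtype=np.float32)
    if g.ndim == 3 and ann.ndim == 2:  # HWC single sample
        if g.shape[:2] != ann.shape:
            raise ValueError(f"annotation shape {ann.shape} does not match "
                             f"gradient {g.shape}")
        ann = ann[:, :, None]
    elif g.shape != ann.shape:
        raise ValueError(f"annotation shape {ann.shape} does not match "
                         f"gradient {g.shape}")
    masked = ann * (g ** 2) if variant == "squared" else ann * g
    return float(masked.sum())


def balance(l1: float, l2: float, eps: float = BALANCE_EPS) -> float:
    """Order-of-magnitude rescaling: ``10^ceil(log10(l2/l1)) * l1``.

    Brings ``l1`` into the decade just above ``l2``: the result r satisfies
    ``l2 <= r < 10 * l2`` and is positively homogeneous in (l1, l2).
    """
    if l2 <= 0:
        raise ValueError(f"balance requires l2 > 0, got {l2}")
    if l1 <= eps:
        raise ValueError(f"balance undefined for l1 <= {eps} (got {l1}); "
                         "the penalty term should be skipped for this batch")
    return (10.0 ** math.ceil(math.log10(l2 / l1))) * l1


def combined_loss(closs: float, rloss: float, spec: LossSpec,
                  eps: float = BALANCE_EPS) -> float:
    """Total loss ``CLoss + lambda * Balance(RLoss, CLoss)`` on scalars.

    Returns ``closs`` unchanged when lambda is zero or the penalty is below
    the guard threshold (e.g. all-zero annotation matrices).
    """
    if spec.lambda_weight == 0.0 or rloss <= eps:
        return float(closs)
    return float(closs) + spec.lambda_weight * balance(rloss, closs, eps=eps)
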