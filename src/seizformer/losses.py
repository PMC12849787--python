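"""Binary cross-entropy and focal loss.

With p the predicted seizure probability and y the true label::

    CE = -log p          if y = 1        FL = -alpha (1-p)^gamma log p       if y = 1
         -log(1 - p)     if y = 0             -(1-alpha) p^gamma log(1 - p)  if y = 0

``gamma`` down-weights easy samples (large p for y=1) so training focuses on
the hard ones; ``alpha`` re-balances the two classes. Note that at gamma = 0
the focal loss is the *alpha-weighted* cross-entropy — it equals CE/2 for
both classes only when alpha = 0.5.

Probabilities are clamped to [1e-7, 1 - 1e-7] before the logarithm.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor

P_EPS = 1e-7


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=np.float64), P_EPS, 1.0 - P_EPS)


def cross_entropy(p, y) -> np.ndarray | float:
    """Elementwise binary cross-entropy; scalar in, scalar out."""
    pc = _clamp(p)
    y = np.asarray(y, dtype=np.float64)
    out = -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
    return float(out) if out.ndim == 0 else out


def focal_loss(p, y, alpha: float = 0.25, gamma: float = 2.0) -> np.ndarray | float:
    """Elementwise focal loss; scalar in, scalar out."""
    pc = _clamp(p)
    y = np.asarray(y, dtype=np.float64)
    pos = -alpha * (1.0 - pc) ** gamma * np.log(pc)
    neg = -(1.0 - alpha) * pc ** gamma * np.log(1.0 - pc)
    out = y * pos + (1.0 - y) * neg
    return float(out) if out.ndim == 0 else out


def focal_loss_batch(probs: Tensor, y: np.ndarray, alpha: float = 0.25,
                     gamma: float = 2.0) -> Tensor:
    """Mean focal loss over a batch, differentiable.

    ``probs`` is the ``(B, 2)`` softmax output (column 1 = seizure);
    ``y`` the integer labels.
    """
    p = probs[:, 1].clip(P_EPS, 1.0 - P_EPS)
    yv = Tensor(np.asarray(y, dtype=np.float64))
    one = 1.0
    pos = (yv * ((one - p).pow(gamma)) * p.log()) * (-alpha)
    neg = ((one - yv) * (p.pow(gamma)) * (one - p).log()) * (-(1.0 - alpha))
    return (pos + neg).mean()
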