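"""Pixelwise categorical cross-entropy with a fused softmax."""
from __future__ import annotations

import numpy as np

__all__ = ["softmax", "SoftmaxCrossEntropy"]


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class SoftmaxCrossEntropy:
    """Mean per-pixel cross-entropy over integer class targets.

    ``forward`` takes logits (N, K, H, W) and targets (N, H, W); ``backward``
    returns the gradient w.r.t. the logits.
    """

    def forward(self, logits: np.ndarray, targets: np.ndarray) -> float:
        probs = softmax(logits, axis=1)
        n, k, h, w = logits.shape
        picked = probs.transpose(0, 2, 3, 1)[
            np.arange(n)[:, None, None], np.arange(h)[None, :, None],
            np.arange(w)[None, None, :], targets,
        ]
        self._probs, self._targets = probs, targets
        return float(-np.log(np.clip(picked, 1e-12, None)).mean())

    def backward(self) -> np.ndarray:
        probs, targets = self._probs, self._targets
        n, k, h, w = probs.shape
        onehot = np.zeros_like(probs)
        np.put_along_axis(onehot, targets[:, None, :, :], 1.0, axis=1)
        return (probs - onehot) / (n * h * w)
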