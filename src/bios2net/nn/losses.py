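"""Weighted multi-head categorical cross-entropy."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, softmax_cross_entropy

DEFAULT_LOSS_WEIGHTS = (0.5, 0.35, 0.15)


def combined_loss(main_logits: Tensor,
                  struct_logits: Tensor | None,
                  temporal_logits: Tensor | None,
                  labels: np.ndarray,
                  weights: tuple[float, float, float] = DEFAULT_LOSS_WEIGHTS,
                  ) -> Tensor:
    """0.5·CE(main) + 0.35·CE(structure) + 0.15·CE(temporal).

    Each CE term is the batch-mean categorical cross-entropy of one
    classification head. Heads disabled by ablation pass ``None``; their
    weight is redistributed proportionally among the remaining heads so the
    effective weights always sum to 1.
    """
    heads = [(main_logits, weights[0]), (struct_logits, weights[1]),
             (temporal_logits, weights[2])]
    active = [(logits, w) for logits, w in heads if logits is not None]
    if not active:
        raise ValueError("no classification heads enabled")
    total_w = sum(w for _, w in active)
    loss: Tensor | None = None
    for logits, w in active:
        term = (w / total_w) * softmax_cross_entropy(logits, labels)
        loss = term if loss is None else loss + term
    return loss
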