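"""Shared label-image helpers."""

from __future__ import annotations

import numpy as np

from .dataio import AIR, NECROTIC, NORMAL, VIABLE

# Tie-break priority for plurality votes (first wins).
LABEL_PRIORITY = (VIABLE, NECROTIC, NORMAL, AIR)


def majority_from_scores(scores: np.ndarray) -> np.ndarray:
    """Pick the winning label per pixel from per-label scores.

    ``scores`` has shape ``(4, ...)`` ordered as :data:`LABEL_PRIORITY`;
    ties go to the earlier (higher-priority) label via ``argmax``.
    """
    win = np.argmax(scores, axis=0)
    return np.asarray(LABEL_PRIORITY, dtype=np.int64)[win]


def block_majority(fine: np.ndarray, factor: int) -> np.ndarray:
    """Downsample a 2-D label image by plurality over ``factor x factor`` blocks.

    Ties break viable > necrotic > normal > air. Both dimensions must be
    divisible by ``factor``.
    """
    fine = np.asarray(fine)
    if factor < 1 or fine.shape[0] % factor or fine.shape[1] % factor:
        raise ValueError(f"shape {fine.shape} not divisible by factor {factor}")
    nx, ny = fine.shape[0] // factor, fine.shape[1] // factor
    blocks = fine.reshape(nx, factor, ny, factor)
    scores = np.stack(
        [(blocks == lab).sum(axis=(1, 3)) for lab in LABEL_PRIORITY], axis=0
    )
    return majority_from_scores(scores)
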