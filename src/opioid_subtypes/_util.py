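"""Small shared numerics helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["sample_categorical_by_class", "sample_categorical"]


def sample_categorical(rng: np.random.Generator, probs: np.ndarray, size: int) -> np.ndarray:
    """Draw ``size`` samples from one categorical distribution ``probs``."""
    cum = np.cumsum(np.asarray(probs, dtype=float))
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(size), side="right").astype(np.int64)


def sample_categorical_by_class(
    rng: np.random.Generator, probs_per_class: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    """Per-row categorical draws where row i uses distribution ``probs_per_class[classes[i]]``.

    ``probs_per_class`` is (C, L); returns int levels in [0, L).
    """
    probs = np.asarray(probs_per_class, dtype=float)
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(classes.size)
    return (u[:, None] > cum[classes]).sum(axis=1).astype(np.int64)
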