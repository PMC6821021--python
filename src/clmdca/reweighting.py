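"""Sequence reweighting and the effective sequence count N_eff.

Real alignments oversample some clades; near-duplicate sequences are
down-weighted so they do not dominate the fit.  Each sequence gets weight
1 / (number of sequences at fractional identity >= threshold, itself
included), and N_eff is the sum of weights.  The default threshold is 0.8
(the conventional 80% redundancy level).  Gap-gap columns count as matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SequenceWeights:
    """Per-sequence weights and the derived effective sequence count."""

    weights: np.ndarray
    n_eff: float
    threshold: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)


def pairwise_identity(a, b) -> float:
    """Fraction of columns with identical codes (gap-gap counts as a match)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"sequences must share one shape, got {a.shape} vs {b.shape}")
    return float((a == b).mean())


def compute_weights(aln, threshold: float = 0.8, chunk: int = 256) -> SequenceWeights:
    """Compute redundancy weights at the given identity threshold.

    The weight of row i is 1 / |{j : identity(i, j) >= threshold}| with j
    ranging over all rows including i itself, so every weight lies in
    (0, 1] and N_eff = sum(weights) lies in [1, M].
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    mat = getattr(aln, "sequences", aln)
    mat = np.ascontiguousarray(np.asarray(mat))
    m, length = mat.shape
    min_matches = threshold * length
    counts = np.zeros(m, dtype=np.int64)
    for start in range(0, m, chunk):
        block = mat[start : start + chunk]
        matches = (block[:, None, :] == mat[None, :, :]).sum(axis=2)
        counts[start : start + chunk] = (matches >= min_matches).sum(axis=1)
    weights = 1.0 / counts
    return SequenceWeights(weights, float(weights.sum()), threshold)
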