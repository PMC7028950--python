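"""Genome-wide frequency-binned standardization of raw scan scores.

Raw iHS/XP-EHH/nSL scores depend systematically on the core allele
frequency, so scores are standardized within equal-width allele-1 frequency
bins pooled over all chromosomes: z = (raw - bin mean) / bin SD.  SNPs with
|z| > 2 (strict) are called significant, retaining the sign — both large
positive and large negative scores are informative.

Bins holding fewer than min_bin_size scores are merged into the nearest
populated bin before standardizing (deterministic; logged), so every score
is standardized against an adequately sized empirical distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_model import HapsweepError

logger = logging.getLogger("hapsweep")


@dataclass
class NormParams:
    n_bins: int = 100  # equal-width on allele-1 frequency in [0, 1]
    threshold: float = 2.0
    min_bin_size: int = 2

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise HapsweepError("n_bins must be >= 1")
        if self.threshold <= 0:
            raise HapsweepError("threshold must be positive")


def _merged_bin_assignment(bin_idx: np.ndarray, params: NormParams) -> np.ndarray:
    """Map raw bin indices to merged bins: sparse bins join the nearest
    populated one (ties broken toward the lower-frequency bin)."""
    counts = np.bincount(bin_idx, minlength=params.n_bins)
    populated = np.flatnonzero(counts >= params.min_bin_size)
    if populated.size == 0:
        # nothing meets the occupancy floor: pool everything
        logger.info("no frequency bin reaches min_bin_size; pooling all scores")
        return np.zeros_like(bin_idx)
    mapping = np.arange(params.n_bins)
    for b in np.flatnonzero((counts > 0) & (counts < params.min_bin_size)):
        nearest = populated[np.argmin(np.abs(populated - b))]
        mapping[b] = nearest
        logger.debug("merging sparse frequency bin %d (n=%d) into bin %d", b, counts[b], nearest)
    return mapping[bin_idx]


def normalize(
    scores: np.ndarray, freqs: np.ndarray, params: NormParams | None = None
) -> np.ndarray:
    """Standardize raw scores within allele-frequency bins.

    scores and freqs are aligned arrays pooled across all chromosomes;
    non-finite scores (skipped cores) pass through as NaN.  Raises if a bin
    has zero spread (its scores cannot be standardized).
    """
    params = params or NormParams()
    scores = np.asarray(scores, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if scores.shape != freqs.shape:
        raise HapsweepError("scores and freqs must be aligned")
    out = np.full_like(scores, np.nan)
    valid = np.isfinite(scores)
    if not valid.any():
        return out
    s = scores[valid]
    bin_idx = np.clip(
        (freqs[valid] * params.n_bins).astype(int), 0, params.n_bins - 1
    )
    merged = _merged_bin_assignment(bin_idx, params)
    z = np.empty_like(s)
    for b in np.unique(merged):
        m = merged == b
        vals = s[m]
        if len(vals) < 2:
            # an isolated singleton bin (only possible when it is the sole
            # populated bin); cannot be standardized
            raise HapsweepError(f"frequency bin {b} has fewer than 2 scores")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise HapsweepError(f"frequency bin {b} has zero standard deviation")
        z[m] = (vals - vals.mean()) / sd
    out[valid] = z
    return out


def call_significant(
    standardized: np.ndarray, params: NormParams | None = None
) -> np.ndarray:
    """Boolean mask of SNPs with |z| strictly greater than the threshold."""
    params = params or NormParams()
    z = np.asarray(standardized, dtype=float)
    return np.isfinite(z) & (np.abs(z) > params.threshold)
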