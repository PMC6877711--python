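"""Condition dissimilarity: normalized sum-of-squares over the ten metrics.

Each condition's 10 × N profile is normalized metric-by-metric by the
highest value observed for that metric across all conditions and time
stamps, so no single metric bears more weight than another.  For a pair
of conditions the per-timestamp dissimilarity is the mean squared
difference of the ten normalized metrics,

    SS_{i,j}(n) = (1/10) Σ_k (P'_{i,k}(n) − P'_{j,k}(n))²,

and the total dissimilarity SST_{i,j} is the sum of SS over all N time
stamps.  SS is symmetric, non-negative, zero for identical profiles and
bounded by 1 when all normalized entries lie in [0, 1].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .model import METRIC_NAMES, ConditionProfile


@dataclass
class DissimilarityResult:
    """SS series and integrated SST for one condition pair."""

    pair: tuple[str, str]
    ss_series: np.ndarray
    sst: float
    normalization_maxima: np.ndarray  # the 10 per-metric maxima used

    def __post_init__(self) -> None:
        self.ss_series = np.asarray(self.ss_series, dtype=float)
        if np.any(self.ss_series < 0):
            raise ValueError("SS values must be non-negative")


def normalize_profiles(
    profiles: list[ConditionProfile],
) -> tuple[list[np.ndarray], np.ndarray]:
    """Scale every metric into [0, 1] by its across-condition maximum.

    Returns the normalized 10 × N arrays (one per condition, same order)
    and the 10 per-metric maxima (the diagonal of the normalization
    matrix).  A metric that is identically zero (or entirely missing)
    across all conditions is left at zero with a warning; negative raw
    values are rejected, since all ten metrics are non-negative by
    construction.
    """
    if not profiles:
        raise ValueError("need at least one condition profile")
    n_frames = profiles[0].n_frames
    for p in profiles[1:]:
        if p.n_frames != n_frames:
            raise ValueError("all profiles must share the same number of time stamps")
    stacked = np.stack([p.profile for p in profiles])  # (C, 10, N)
    if np.any(stacked[np.isfinite(stacked)] < 0):
        raise ValueError("metric profiles must be non-negative")
    finite = np.where(np.isfinite(stacked), stacked, -np.inf)
    maxima = finite.max(axis=(0, 2))  # per metric
    maxima = np.where(np.isfinite(maxima), maxima, 0.0)

    normalized = []
    degenerate = [METRIC_NAMES[k] for k in range(len(METRIC_NAMES)) if maxima[k] == 0]
    if degenerate:
        warnings.warn(
            f"metrics {degenerate} have maximum 0 across all conditions; "
            "their normalized values are set to 0",
            stacklevel=2,
        )
    safe = np.where(maxima > 0, maxima, 1.0)
    for p in profiles:
        norm = p.profile / safe[:, None]
        norm[maxima == 0, :] = 0.0
        normalized.append(norm)
    return normalized, maxima


def sum_of_squares(p_i_norm: np.ndarray, p_j_norm: np.ndarray) -> np.ndarray:
    """Per-timestamp mean squared difference across the ten normalized
    metrics.

    Entries missing (NaN) in either profile contribute 0 to the sum
    while the divisor stays 10 (pairwise-complete policy).
    """
    a = np.asarray(p_i_norm, dtype=float)
    b = np.asarray(p_j_norm, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != len(METRIC_NAMES):
        raise ValueError(f"profiles must share shape (10, N); got {a.shape} and {b.shape}")
    diff = a - b
    diff = np.where(np.isfinite(diff), diff, 0.0)
    return (diff**2).sum(axis=0) / len(METRIC_NAMES)


def integrate_ss(ss_series) -> float:
    """Total dissimilarity: sum of the SS values over all time stamps."""
    ss_series = np.asarray(ss_series, dtype=float)
    if np.any(ss_series < 0):
        raise ValueError("SS values must be non-negative")
    return float(ss_series.sum())


def compare_conditions(profiles: list[ConditionProfile]) -> list[DissimilarityResult]:
    """All pairwise dissimilarities between condition profiles.

    Profiles are normalized jointly (shared per-metric maxima), then
    every unordered pair gets an SS series and its integrated SST.
    """
    normalized, maxima = normalize_profiles(profiles)
    results = []
    for (ia, pa), (ib, pb) in itertools.combinations(enumerate(profiles), 2):
        ss = sum_of_squares(normalized[ia], normalized[ib])
        results.append(
            DissimilarityResult(
                pair=(pa.condition_id, pb.condition_id),
                ss_series=ss,
                sst=integrate_ss(ss),
                normalization_maxima=maxima,
            )
        )
    return results
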