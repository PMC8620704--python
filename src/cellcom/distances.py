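"""Histogram similarity scores used to validate simulated distributions.

All three scores compare two histograms built on a *shared* bin grid:

cosine distance
    ``1 − h1·h2 / (‖h1‖‖h2‖)``; 0 for proportional histograms, 1 for
    histograms with disjoint support.  Scale invariant.
histogram overlap
    ``Σ_bins min(p_i, q_i)`` on probability-normalized histograms;
    1 for identical, 0 for disjoint support.
Hellinger distance
    ``(1/√2)·sqrt(Σ (√p_i − √q_i)²)``; 0 for identical, 1 for disjoint
    support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import DomainError

log = logging.getLogger(__name__)


def _check_pair(h1, h2) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(h1, dtype=float).ravel()
    b = np.asarray(h2, dtype=float).ravel()
    if a.shape != b.shape:
        raise DomainError(f"histograms need identical bins: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise DomainError("empty histogram")
    if np.any(a < 0) or np.any(b < 0):
        raise DomainError("histogram counts must be nonnegative")
    return a, b


def cosine_distance(h1, h2) -> float:
    """Cosine of the angle between two histogram vectors, as a distance."""
    a, b = _check_pair(h1, h2)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DomainError("cosine distance undefined for a zero histogram")
    # clip FP noise so proportional histograms give exactly 0
    return float(min(max(1.0 - float(a @ b) / (na * nb), 0.0), 1.0))


def _normalize(h: np.ndarray, name: str) -> np.ndarray:
    total = h.sum()
    if not total > 0:
        raise DomainError(f"{name}: histogram with zero total")
    if not np.isclose(total, 1.0):
        log.debug("%s: normalizing histogram with total %g", name, total)
    return h / total


def histogram_overlap(h1, h2) -> float:
    """Shared probability mass of two histograms (1 = perfect overlap)."""
    a, b = _check_pair(h1, h2)
    p = _normalize(a, "histogram_overlap")
    q = _normalize(b, "histogram_overlap")
    return float(min(np.minimum(p, q).sum(), 1.0))


def hellinger_distance(h1, h2) -> float:
    """Discrete Hellinger distance; inputs are normalized internally."""
    a, b = _check_pair(h1, h2)
    p = _normalize(a, "hellinger_distance")
    q = _normalize(b, "hellinger_distance")
    h = np.sqrt(0.5 * np.sum((np.sqrt(p) - np.sqrt(q)) ** 2))
    return float(min(h, 1.0))


@dataclass(frozen=True)
class SimilarityReport:
    """The three distances between one experimental and one simulated sample."""

    cosine_distance: float
    histogram_overlap: float
    hellinger: float
    bin_edges: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("cosine_distance", "histogram_overlap", "hellinger"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} out of range: {v}")


def shared_bin_edges(a, b, bins: int | None = None) -> np.ndarray:
    """Bin edges spanning the union of two samples.

    Bin count defaults to Sturges' rule on the larger sample; the edges
    are recorded in the :class:`SimilarityReport` for reproducibility.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("cannot bin an empty sample")
    if bins is None:
        bins = int(np.ceil(np.log2(max(a.size, b.size))) + 1)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:  # degenerate: widen a hair so the histogram is well formed
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, bins + 1)


def compare_samples(experimental, simulated, bins: int | None = None) -> SimilarityReport:
    """Histogram an experimental and a simulated sample on shared bins
    and score their similarity with all three distances."""
    edges = shared_bin_edges(experimental, simulated, bins=bins)
    h1, _ = np.histogram(np.asarray(experimental, dtype=float), bins=edges)
    h2, _ = np.histogram(np.asarray(simulated, dtype=float), bins=edges)
    return SimilarityReport(
        cosine_distance=cosine_distance(h1, h2),
        histogram_overlap=histogram_overlap(h1, h2),
        hellinger=hellinger_distance(h1, h2),
        bin_edges=tuple(edges),
    )
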