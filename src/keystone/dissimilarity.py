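"""Dissimilarity measures between relative-abundance profiles.

All profiles handled here are compositional: non-negative vectors summing
to one. The central trick used throughout the package is *focal-taxon
exclusion*: before comparing two communities with respect to taxon ``i``,
the abundance of ``i`` itself is removed and the remaining entries are
renormalized to one. This removes the purely arithmetic coupling that
compositionality induces between a taxon and the rest of its community,
so that any remaining difference between profiles reflects genuine
restructuring of the other taxa.

Two metrics are provided:

* Bray-Curtis dissimilarity, ``1 - sum_j min(p_j, q_j)`` on unit-sum
  vectors (the general Bray-Curtis form reduces to this when both inputs
  sum to one).
* Root Jensen-Shannon divergence with base-2 logarithms, a true metric
  bounded in [0, 1].
"""

from __future__ import annotations

from enum import Enum
from typing import Callable, Union

import numpy as np
from scipy.spatial import distance as _ssd

from ._exceptions import DegenerateProfileError

__all__ = [
    "Metric",
    "bray_curtis",
    "root_jsd",
    "get_metric",
    "renormalize_excluding",
    "pairwise_distances",
    "cross_distances",
]

_SQRT_LN2 = np.sqrt(np.log(2.0))


class Metric(str, Enum):
    """Distance measures between relative-abundance profiles."""

    BRAY_CURTIS = "bc"
    ROOT_JSD = "rjsd"


MetricLike = Union[str, Metric]


def _check_pair(p, q):
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.ndim != 1 or q.ndim != 1:
        raise ValueError("profiles must be one-dimensional vectors")
    if p.shape != q.shape:
        raise ValueError(
            f"profile length mismatch: {p.shape[0]} vs {q.shape[0]}"
        )
    return p, q


def bray_curtis(p, q) -> float:
    """Bray-Curtis dissimilarity between two relative-abundance profiles.

    For unit-sum vectors this equals ``1 - sum_j min(p_j, q_j)`` and lies
    in [0, 1]; it is 0 for identical profiles and 1 for profiles with
    disjoint support.
    """
    p, q = _check_pair(p, q)
    return float(_ssd.braycurtis(p, q))


def root_jsd(p, q) -> float:
    """Square root of the Jensen-Shannon divergence (base-2 logarithm).

    A metric on probability vectors bounded in [0, 1]; ``0 * log 0`` is
    treated as 0, so zero entries are handled exactly.
    """
    p, q = _check_pair(p, q)
    # scipy's jensenshannon returns sqrt(JSD); rescale from nats to bits.
    return float(min(_ssd.jensenshannon(p, q) / _SQRT_LN2, 1.0))


_METRICS: dict[Metric, Callable] = {
    Metric.BRAY_CURTIS: bray_curtis,
    Metric.ROOT_JSD: root_jsd,
}


def get_metric(metric: MetricLike) -> Callable:
    """Resolve a metric name ('bc' or 'rjsd') to its pairwise function."""
    return _METRICS[Metric(metric)]


def renormalize_excluding(profile, taxon: int) -> np.ndarray:
    """Drop one taxon from a profile and renormalize the rest to one.

    Parameters
    ----------
    profile : array-like
        Relative-abundance vector over N taxa.
    taxon : int
        Index of the focal taxon to exclude.

    Returns
    -------
    numpy.ndarray of length N - 1 summing to one.

    Raises
    ------
    DegenerateProfileError
        If all abundance mass sits on the excluded taxon.
    """
    profile = np.asarray(profile, dtype=float)
    reduced = np.delete(profile, taxon)
    total = reduced.sum()
    if total <= 0:
        raise DegenerateProfileError(
            f"all abundance mass sits on excluded taxon {taxon}; "
            "the reduced profile cannot be renormalized"
        )
    return reduced / total


def _matrix_metric_name(metric: MetricLike) -> str:
    return {
        Metric.BRAY_CURTIS: "braycurtis",
        Metric.ROOT_JSD: "jensenshannon",
    }[Metric(metric)]


def _rescale(d: np.ndarray, metric: MetricLike) -> np.ndarray:
    if Metric(metric) is Metric.ROOT_JSD:
        return np.minimum(d / _SQRT_LN2, 1.0)
    return d


def pairwise_distances(profiles: np.ndarray, metric: MetricLike = Metric.BRAY_CURTIS,
                       *, condensed: bool = False) -> np.ndarray:
    """All pairwise distances between the rows of ``profiles``.

    Returns a square symmetric matrix, or the condensed upper-triangle
    vector (scipy ``pdist`` order) if ``condensed`` is true.
    """
    profiles = np.asarray(profiles, dtype=float)
    d = _rescale(_ssd.pdist(profiles, _matrix_metric_name(metric)), metric)
    d = np.nan_to_num(d, nan=0.0)  # pdist yields nan for identical all-zero rows
    if condensed:
        return d
    return _ssd.squareform(d)


def cross_distances(a: np.ndarray, b: np.ndarray,
                    metric: MetricLike = Metric.BRAY_CURTIS) -> np.ndarray:
    """Distance matrix between the rows of ``a`` and the rows of ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = _rescale(_ssd.cdist(a, b, _matrix_metric_name(metric)), metric)
    return np.nan_to_num(d, nan=0.0)
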