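"""Longitudinal EPI from paired two-time-point cohorts.

The cross-sectional EPI compares *different* subjects and can therefore
be confounded by inter-personal heterogeneity. The longitudinal EPI L
sidesteps this by comparing each subject with itself: for taxon i and
subject h, whenever the taxon's presence state differs between the two
collections, L_h^i is the distance between the subject's two abundance
profiles, excluding taxon i and renormalized to one. L^i averages over
all such *reversal* subjects; taxa whose measure rests on too few
reversals (10 or fewer by default) are marked ineligible, since low
prevalence biases the measure.

Agreement between L and a cross-sectional EPI (correlation of the value
vectors; overlap of the top candidate sets, tested with a one-sided
Fisher exact test) supports that the cross-sectional signal reflects
presence-impact rather than cohort structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .abundance_data import PairedCohort
from .dissimilarity import Metric, get_metric, renormalize_excluding

__all__ = [
    "LongitudinalResult",
    "ComparisonReport",
    "longitudinal_epi",
    "compare_epi_longitudinal",
]


@dataclass
class LongitudinalResult:
    """Per-taxon longitudinal EPI L with reversal counts and eligibility."""

    taxon_ids: list
    L: np.ndarray  # NaN where no reversal observed
    n_subjects_used: np.ndarray
    eligible: np.ndarray
    metric: Metric
    min_subjects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "taxon": self.taxon_ids, "L": self.L,
            "n_subjects": self.n_subjects_used, "eligible": self.eligible,
        })


@dataclass
class ComparisonReport:
    """Agreement between a cross-sectional EPI vector and the longitudinal L."""

    pearson_r: float
    pearson_p: float
    n_common: int
    overlap: int
    fisher_p: float
    epi_candidates: list
    longitudinal_candidates: list


def longitudinal_epi(paired: PairedCohort, metric=Metric.BRAY_CURTIS,
                     min_subjects: int = 10,
                     presence_first: Optional[np.ndarray] = None,
                     presence_second: Optional[np.ndarray] = None
                     ) -> LongitudinalResult:
    """Longitudinal EPI L^i for every taxon of a paired cohort.

    For each taxon, subjects whose presence state reverses between the
    collections contribute the distance between their two reduced,
    renormalized profiles; L^i is the mean contribution. Taxa with
    ``min_subjects`` or fewer reversals are flagged ineligible (the
    default keeps taxa with at least 11 reversal subjects). The optional
    presence overrides support shuffle-null analyses.
    """
    dist = get_metric(metric)
    a, b = paired.first, paired.second
    pres_a = presence_first if presence_first is not None else a.presence
    pres_b = presence_second if presence_second is not None else b.presence
    N, H = a.n_taxa, paired.n_subjects
    L = np.full(N, np.nan)
    n_used = np.zeros(N, dtype=int)
    for i in range(N):
        reversed_h = np.flatnonzero(pres_a[i] != pres_b[i])
        vals = []
        for h in reversed_h:
            pa = np.delete(a.abundances[:, h], i)
            pb = np.delete(b.abundances[:, h], i)
            if pa.sum() <= 0 or pb.sum() <= 0:
                continue
            vals.append(dist(pa / pa.sum(), pb / pb.sum()))
        n_used[i] = len(vals)
        if vals:
            L[i] = float(np.mean(vals))
    eligible = n_used > min_subjects
    if not eligible.any():
        warnings.warn("no taxon has enough presence reversals; "
                      "longitudinal EPI is empty")
    return LongitudinalResult(list(a.taxon_ids), L, n_used, eligible,
                              Metric(metric), min_subjects)


def _top_fraction(values: np.ndarray, idx: np.ndarray, frac: float) -> np.ndarray:
    """Indices of the top ``frac`` of ``values`` restricted to ``idx``.

    Strict ranking with a stable tie-break by taxon order."""
    k = max(int(np.ceil(frac * idx.size)), 1)
    order = idx[np.argsort(-values[idx], kind="stable")]
    return order[:k]


def compare_epi_longitudinal(epi_values, longitudinal: LongitudinalResult,
                             top_fraction: float = 0.05) -> ComparisonReport:
    """Compare a cross-sectional EPI column with the longitudinal EPI.

    Parameters
    ----------
    epi_values : array-like
        Per-taxon cross-sectional EPI values aligned with
        ``longitudinal.taxon_ids`` (NaN for ineligible taxa).
    longitudinal : LongitudinalResult
    top_fraction : float
        Fraction of the common taxon set declared candidates by each
        measure (default 5%).

    Returns
    -------
    ComparisonReport with the Pearson correlation over the common taxa,
    the candidate-set overlap, and a one-sided (enrichment) Fisher exact
    p-value for the overlap.
    """
    epi_values = np.asarray(epi_values, dtype=float)
    if epi_values.shape[0] != len(longitudinal.taxon_ids):
        raise ValueError("EPI vector not aligned with longitudinal taxa")
    common = np.flatnonzero(np.isfinite(epi_values) & np.isfinite(longitudinal.L)
                            & longitudinal.eligible)
    if common.size < 10:
        raise ValueError(f"only {common.size} taxa eligible in both measures; "
                         "need at least 10")
    x, y = epi_values[common], longitudinal.L[common]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(x, y)
    cand_epi = _top_fraction(epi_values, common, top_fraction)
    cand_long = _top_fraction(longitudinal.L, common, top_fraction)
    overlap = len(set(cand_epi) & set(cand_long))
    n = common.size
    a = overlap
    b = len(cand_epi) - overlap
    c = len(cand_long) - overlap
    d = n - a - b - c
    _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    ids = longitudinal.taxon_ids
    return ComparisonReport(float(r), float(p), int(n), int(overlap),
                            float(fisher_p),
                            [ids[i] for i in cand_epi],
                            [ids[i] for i in cand_long])
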