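"""Empirical Presence-abundance Interrelation (EPI) from cross-sectional data.

A taxon with a strong presence-impact should leave a footprint in
naturally assembled communities: samples where it is present should
differ systematically, in the abundances of *all other* taxa, from
samples where it is absent. The EPI quantifies that footprint from a
single cross-sectional cohort, with three interchangeable measures for a
focal taxon i (samples split into G^i, present, and its complement,
absent; all profiles exclude taxon i and are renormalized to one):

* D1 — mean distance over all present/absent sample pairs;
* D2 — distance between the mean profiles of the two groups;
* Q  — modularity of a sample-similarity network (edges join the most
  similar sample pairs, up to the p_Q distance quantile) with nodes
  labeled by the presence of taxon i. Q is bounded in [-0.5, 1]; high Q
  means the network splits naturally along the presence labels.

Because the EPI is computed from observational data it flags *candidate*
keystones (correlation, not causation); candidates are taxa whose EPI
exceeds the across-taxa mean by two standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import (
    TooFewSamplesError,
    TooFewTaxaError,
    UndefinedEPIError,
)
from .abundance_data import Cohort, frequency_filter
from .dissimilarity import (
    Metric,
    cross_distances,
    get_metric,
    pairwise_distances,
)

__all__ = [
    "PresenceSplit",
    "SampleSimilarityNetwork",
    "EPITable",
    "split_by_presence",
    "epi_d1",
    "epi_d2",
    "build_similarity_network",
    "epi_modularity",
    "epi_screen",
    "expected_normal_tail_fraction",
    "EPI_MEASURES",
]

EPI_MEASURES = ("d1", "d2", "q")


@dataclass
class PresenceSplit:
    """Samples partitioned by the presence of a focal taxon.

    ``reduced_profiles`` holds, per sample (rows), the relative
    abundances of all taxa except the focal one, renormalized to one.
    """

    taxon: int
    present_samples: np.ndarray
    absent_samples: np.ndarray
    reduced_profiles: np.ndarray  # (M, N-1), rows sum to 1


@dataclass
class SampleSimilarityNetwork:
    """Sample-to-sample similarity network for one focal taxon.

    ``adjacency`` is the symmetric binary matrix B^i (edge where the
    reduced-profile distance is at most the threshold T, chosen as the
    p_Q quantile of all pair distances); ``labels`` are +1 where the
    focal taxon is present and -1 where absent.
    """

    adjacency: np.ndarray
    labels: np.ndarray
    threshold: float
    edge_fraction: float


@dataclass
class EPITable:
    """Per-taxon EPI values with frequency metadata and candidate flags.

    Values are NaN for taxa outside the frequency window (explicit
    missing markers, never zeros). ``flags[measure]`` marks taxa whose
    value exceeds the across-eligible-taxa mean by two SDs.
    """

    taxon_ids: list
    frequency: np.ndarray
    values: dict  # measure -> np.ndarray (NaN where ineligible)
    flags: dict  # measure -> boolean np.ndarray
    eligible: np.ndarray
    metric: Metric
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data = {"taxon": self.taxon_ids, "frequency": self.frequency,
                "eligible": self.eligible}
        for m, v in self.values.items():
            data[m] = v
        for m, f in self.flags.items():
            data[f"{m}_flag"] = f
        return pd.DataFrame(data)


def split_by_presence(cohort: Cohort, taxon, presence: Optional[np.ndarray] = None
                      ) -> PresenceSplit:
    """Partition samples by the presence of ``taxon`` and build reduced profiles.

    ``presence`` optionally overrides the cohort's own presence matrix
    (used for label-shuffling null analyses); profiles are always built
    from the cohort's abundances.

    Raises :class:`UndefinedEPIError` if the taxon is present in every
    sample or absent from every sample — the EPI needs both groups.
    """
    i = cohort.taxon_index(taxon)
    pres = (presence if presence is not None else cohort.presence)[i]
    g = np.flatnonzero(pres)
    gbar = np.flatnonzero(~pres)
    if g.size == 0 or gbar.size == 0:
        raise UndefinedEPIError(
            f"taxon {cohort.taxon_ids[i]!r} is {'present in all' if gbar.size == 0 else 'absent from all'}"
            " samples; its EPI is undefined")
    reduced = np.delete(cohort.abundances, i, axis=0).T  # (M, N-1)
    totals = reduced.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        bad = int(np.argmin(totals))
        raise UndefinedEPIError(
            f"sample {cohort.sample_ids[bad]!r} holds no abundance outside "
            f"taxon {cohort.taxon_ids[i]!r}")
    return PresenceSplit(i, g, gbar, reduced / totals)


def epi_d1(split: PresenceSplit, metric=Metric.BRAY_CURTIS) -> float:
    """D1: mean distance over all present/absent cross sample pairs."""
    d = cross_distances(split.reduced_profiles[split.present_samples],
                        split.reduced_profiles[split.absent_samples], metric)
    return float(d.mean())


def epi_d2(split: PresenceSplit, metric=Metric.BRAY_CURTIS) -> float:
    """D2: distance between the mean reduced profiles of the two groups."""
    dist = get_metric(metric)
    mean_g = split.reduced_profiles[split.present_samples].mean(axis=0)
    mean_gbar = split.reduced_profiles[split.absent_samples].mean(axis=0)
    return float(dist(mean_g, mean_gbar))


def build_similarity_network(cohort: Cohort, taxon, p_Q: float = 0.1,
                             metric=Metric.BRAY_CURTIS,
                             presence: Optional[np.ndarray] = None
                             ) -> SampleSimilarityNetwork:
    """Threshold the reduced-profile distance matrix into a similarity network.

    All M(M-1)/2 pair distances are computed on the focal-taxon-excluded
    profiles; the threshold T is the empirical ``p_Q`` quantile (linear
    interpolation) and sample pairs with distance <= T become edges, so
    roughly a fraction p_Q of pairs are connected (ties at T are all
    admitted). Nodes are labeled +1/-1 by the focal taxon's presence.
    """
    if cohort.n_samples < 3:
        raise TooFewSamplesError("similarity network needs at least 3 samples")
    if not 0 < p_Q < 1:
        raise ValueError("p_Q must lie strictly between 0 and 1")
    split = split_by_presence(cohort, taxon, presence=presence)
    condensed = pairwise_distances(split.reduced_profiles, metric, condensed=True)
    threshold = float(np.quantile(condensed, p_Q))
    M = cohort.n_samples
    adj = np.zeros((M, M), dtype=bool)
    from scipy.spatial.distance import squareform

    adj = squareform(condensed <= threshold).astype(bool)
    labels = np.where(np.isin(np.arange(M), split.present_samples), 1, -1)
    return SampleSimilarityNetwork(adj, labels, threshold, p_Q)


def epi_modularity(network: SampleSimilarityNetwork) -> float:
    """Two-group Newman modularity Q of a labeled similarity network.

        Q = (1/2w) sum_{a,b} [ b_ab - d_a d_b / 2w ] (s_a s_b + 1) / 2,

    summed over all ordered node pairs (no self-edges; the diagonal
    null-model term is included, which is what pins Q to 0 for uniform
    labels and keeps it inside [-0.5, 1]). ``w`` is the number of edges
    and ``d_a`` node degrees. Returns NaN with a warning for an edgeless
    network, where Q is undefined.
    """
    B = np.asarray(network.adjacency, dtype=float)
    s = np.asarray(network.labels, dtype=float)
    d = B.sum(axis=1)
    two_w = d.sum()
    if two_w == 0:
        warnings.warn("similarity network has no edges; modularity undefined")
        return float("nan")
    same = (np.outer(s, s) + 1.0) / 2.0
    Q = ((B - np.outer(d, d) / two_w) * same).sum() / two_w
    return float(Q)


def expected_normal_tail_fraction(n_sd: float = 2.0) -> float:
    """Fraction of a normal population above mean + n_sd standard deviations.

    The baseline candidate rate expected if EPI values were normally
    distributed; observed keystone-candidate rates are compared to it.
    """
    return float(stats.norm.sf(n_sd))


def _flag_two_sd(values: np.ndarray) -> np.ndarray:
    """Candidate rule: value > mean + 2 SD, statistics over eligible taxa."""
    finite = values[np.isfinite(values)]
    flags = np.zeros(values.shape, dtype=bool)
    if finite.size >= 2:
        sd = finite.std(ddof=1)
        if sd > 0:
            with np.errstate(invalid="ignore"):
                flags = values > finite.mean() + 2.0 * sd
    return flags


def epi_screen(cohort: Cohort, measures: Iterable[str] = EPI_MEASURES,
               metric=Metric.BRAY_CURTIS, p_Q: float = 0.1,
               freq_lo: float = 0.25, freq_hi: float = 0.75,
               presence: Optional[np.ndarray] = None) -> EPITable:
    """Compute the requested EPI measures for every frequency-eligible taxon.

    Taxa outside the [freq_lo, freq_hi] relative-frequency window are
    reported with missing values. Candidate flags mark taxa whose EPI
    exceeds the mean over eligible taxa by two standard deviations.
    """
    measures = [m.lower() for m in measures]
    unknown = set(measures) - set(EPI_MEASURES)
    if unknown:
        raise ValueError(f"unknown EPI measures: {sorted(unknown)}")
    pres = presence if presence is not None else cohort.presence
    freq = pres.mean(axis=1)
    eligible_idx = np.flatnonzero((freq >= freq_lo) & (freq <= freq_hi))
    # EPI additionally needs both a present and an absent group
    eligible_idx = np.array([
        i for i in eligible_idx if 0 < pres[i].sum() < cohort.n_samples
    ], dtype=int)
    if eligible_idx.size < 3:
        raise TooFewTaxaError(
            f"only {eligible_idx.size} taxa pass the frequency window "
            f"[{freq_lo}, {freq_hi}]; need at least 3")
    N = cohort.n_taxa
    values = {m: np.full(N, np.nan) for m in measures}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in eligible_idx:
            split = split_by_presence(cohort, int(i), presence=pres)
            if "d1" in values:
                values["d1"][i] = epi_d1(split, metric)
            if "d2" in values:
                values["d2"][i] = epi_d2(split, metric)
            if "q" in values:
                net = build_similarity_network(cohort, int(i), p_Q, metric,
                                               presence=pres)
                values["q"][i] = epi_modularity(net)
    flags = {m: _flag_two_sd(v) for m, v in values.items()}
    eligible = np.zeros(N, dtype=bool)
    eligible[eligible_idx] = True
    return EPITable(list(cohort.taxon_ids), freq, values, flags, eligible,
                    Metric(metric),
                    params={"p_Q": p_Q, "freq_lo": freq_lo, "freq_hi": freq_hi})
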