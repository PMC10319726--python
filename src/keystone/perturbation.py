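"""Presence-impact from in-silico perturbation experiments.

The presence-impact of taxon i in community k is measured by reversing
the taxon's presence state — removing it if present, introducing it at a
small inoculum if absent — letting the community relax to its new steady
state, and computing the distance between the pre- and post-perturbation
abundance profiles of *all other taxa*, each renormalized to one:

    I_k^i = < S_k^i, S_k^{i*} >,        I^i = mean_k I_k^i.

Excluding the focal taxon before renormalizing removes the compositional
artifact whereby adding or deleting one taxon mechanically rescales
everyone else. A taxon is called a keystone when its cohort-averaged
impact I^i lies more than two standard deviations above the mean impact
of all taxa; significance is assessed with a one-tailed z-test in which
the focal taxon is excluded from the background mean and SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from ._exceptions import DegenerateProfileError, NoDataError
from .abundance_data import Cohort
from .dissimilarity import Metric, get_metric, renormalize_excluding
from .glv_sim import GLVModel, simulate_steady_state

__all__ = [
    "PresenceImpactResult",
    "presence_impact_single",
    "presence_impact",
    "impact_screen",
    "DEFAULT_INOCULUM",
]

#: abundance at which an absent taxon is introduced (midpoint of the
#: U(0,1) initial-condition law); relevant in multistable systems.
DEFAULT_INOCULUM = 0.5


@dataclass
class PresenceImpactResult:
    """Per-taxon presence-impact with the per-sample breakdown.

    ``per_sample_I[i, k]`` is I_k^i (NaN where the perturbed integration
    failed to converge); ``per_taxon_I[i]`` averages the valid entries.
    ``z_scores``/``p_values`` come from the one-tailed z-test against
    the other taxa; ``keystone_flags`` applies the 2-SD rule over all
    taxa.
    """

    per_taxon_I: np.ndarray
    per_sample_I: np.ndarray
    metric: Metric
    z_scores: np.ndarray
    p_values: np.ndarray
    keystone_flags: np.ndarray
    n_valid: np.ndarray
    taxon_ids: Optional[list] = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "taxon": self.taxon_ids or list(range(len(self.per_taxon_I))),
            "I": self.per_taxon_I,
            "z": self.z_scores,
            "p": self.p_values,
            "keystone": self.keystone_flags,
            "n_valid": self.n_valid,
        })


def _reduced_profile(abs_abundances: np.ndarray, taxon: int) -> np.ndarray:
    """Relative abundances of all taxa except ``taxon``, renormalized."""
    others = np.delete(abs_abundances, taxon)
    total = others.sum()
    if total <= 0:
        raise DegenerateProfileError(
            f"community holds no abundance outside taxon {taxon}")
    return others / total


def presence_impact_single(model: GLVModel, sample: np.ndarray, taxon: int,
                           metric=Metric.BRAY_CURTIS,
                           inoculum: float = DEFAULT_INOCULUM,
                           **integrate_kw) -> float:
    """Presence-impact I_k^i of one taxon in one community.

    ``sample`` is the community's absolute steady-state abundance
    vector. The taxon's presence state is flipped (removal sets it to
    zero; addition introduces it at ``inoculum``), the system is
    re-integrated from the perturbed state, and the Bray-Curtis (or root
    JSD) distance between the renormalized pre- and post-perturbation
    profiles of the other taxa is returned. NaN marks a perturbation
    whose re-integration did not converge (excluded from averages).
    """
    sample = np.asarray(sample, dtype=float)
    dist = get_metric(metric)
    before = _reduced_profile(sample, taxon)
    perturbed = sample.copy()
    perturbed[taxon] = 0.0 if sample[taxon] > 0 else inoculum
    ss = simulate_steady_state(model, perturbed, full_output=True,
                               **integrate_kw)
    if not ss.converged:
        return float("nan")
    after_abs = np.delete(ss.x, taxon)
    if after_abs.sum() <= 0:
        # perturbation wiped out every other taxon; no profile to compare
        return float("nan")
    after = after_abs / after_abs.sum()
    return float(dist(before, after))


def presence_impact(model: GLVModel, cohort: Cohort, taxon: int,
                    metric=Metric.BRAY_CURTIS,
                    inoculum: float = DEFAULT_INOCULUM,
                    **integrate_kw) -> float:
    """Cohort-averaged presence-impact I^i (mean of valid I_k^i)."""
    values = _impact_row(model, cohort, taxon, metric, inoculum, **integrate_kw)
    valid = values[~np.isnan(values)]
    if valid.size == 0:
        raise NoDataError(f"no valid perturbation for taxon {taxon}")
    return float(valid.mean())


def _impact_row(model, cohort, taxon, metric, inoculum, **integrate_kw):
    if cohort.absolute is None:
        raise ValueError(
            "perturbation experiments need absolute steady states; use a "
            "cohort produced by generate_cohort (or attach `absolute`)")
    M = cohort.n_samples
    out = np.full(M, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(M):
            if cohort.converged is not None and not cohort.converged[k]:
                continue
            try:
                out[k] = presence_impact_single(
                    model, cohort.absolute[:, k], taxon, metric, inoculum,
                    **integrate_kw)
            except DegenerateProfileError:
                continue
    return out


def impact_screen(model: GLVModel, cohort: Cohort, metric=Metric.BRAY_CURTIS,
                  inoculum: float = DEFAULT_INOCULUM,
                  **integrate_kw) -> PresenceImpactResult:
    """Presence-impact of every taxon, with z-test and 2-SD keystone rule.

    For each taxon the screen perturbs every sample in the cohort and
    averages the valid per-sample impacts. The z-score of taxon i is
    computed against the mean and SD of the *other* taxa's impacts
    (one-tailed p from the normal tail); the keystone flag applies the
    cruder candidate rule I^i > mean + 2 SD with statistics over all
    taxa. With fewer than three taxa, or zero variance across taxa, no
    flags are raised and p-values are reported missing.
    """
    N = cohort.n_taxa
    if N < 3:
        raise ValueError("impact screen needs at least 3 taxa")
    per_sample = np.vstack([
        _impact_row(model, cohort, i, metric, inoculum, **integrate_kw)
        for i in range(N)
    ])
    n_valid = (~np.isnan(per_sample)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_taxon = np.nanmean(per_sample, axis=1)

    z = np.full(N, np.nan)
    p = np.full(N, np.nan)
    for i in range(N):
        others = np.delete(per_taxon, i)
        others = others[~np.isnan(others)]
        sd = others.std(ddof=1) if others.size > 1 else 0.0
        if sd > 0:
            z[i] = (per_taxon[i] - others.mean()) / sd
            p[i] = stats.norm.sf(z[i])
    mean_all = np.nanmean(per_taxon)
    sd_all = np.nanstd(per_taxon, ddof=1)
    if sd_all > 0:
        flags = per_taxon > mean_all + 2.0 * sd_all
    else:
        flags = np.zeros(N, dtype=bool)
    return PresenceImpactResult(per_taxon, per_sample, Metric(metric), z, p,
                                flags, n_valid, taxon_ids=list(cohort.taxon_ids))
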