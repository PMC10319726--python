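"""Abundance tables: the :class:`Cohort` data model, I/O, filters and nulls.

A :class:`Cohort` is the universal container shared by every other module:
a taxa-by-samples matrix of relative abundances (each sample column sums
to one), taxon and sample identifiers, and a derived presence mask. It
holds real survey data (e.g. OTU tables) and simulated communities alike;
simulated cohorts additionally retain the absolute steady-state
abundances needed by in-silico perturbation experiments.

The module also implements the two filtering steps used for real survey
data (top-N taxa by mean abundance, then a relative-frequency window) and
the fixed-margin presence-matrix shuffle used as a null model: repeated
checkerboard (2x2 submatrix) swaps that preserve every taxon's frequency
and every sample's richness exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._exceptions import (
    DegenerateSampleError,
    IdentifierError,
    MalformedDataError,
)

__all__ = [
    "Cohort",
    "PairedCohort",
    "load_abundance_table",
    "write_abundance_table",
    "filter_top_taxa",
    "frequency_filter",
    "shuffle_preserving_margins",
]

_NORM_TOL = 1e-9


@dataclass
class Cohort:
    """A cohort of relative-abundance profiles over a fixed taxon set.

    Attributes
    ----------
    abundances : numpy.ndarray, shape (n_taxa, n_samples)
        Relative abundances; every column sums to one within 1e-9.
    taxon_ids, sample_ids : list of str
        Unique identifiers for rows and columns.
    detection_threshold : float
        A taxon counts as *present* in a sample when its relative
        abundance strictly exceeds this value (default 0: any positive
        abundance is a detection).
    absolute : numpy.ndarray or None
        For simulated cohorts, the absolute steady-state abundances the
        relative profiles were derived from.
    converged : numpy.ndarray of bool or None
        Per-sample integration convergence flags (simulated cohorts).
    meta : dict
        Provenance: generator parameters, seed, filter settings.
    """

    abundances: np.ndarray
    taxon_ids: list
    sample_ids: list
    detection_threshold: float = 0.0
    absolute: Optional[np.ndarray] = None
    converged: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 2:
            raise MalformedDataError("abundances must be a 2-D taxa x samples matrix")
        n, m = self.abundances.shape
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.taxon_ids) != n or len(self.sample_ids) != m:
            raise IdentifierError("identifier lists do not match matrix shape")
        if len(set(self.taxon_ids)) != n:
            raise IdentifierError("duplicate taxon identifiers")
        if len(set(self.sample_ids)) != m:
            raise IdentifierError("duplicate sample identifiers")
        if np.any(self.abundances < 0) or not np.all(np.isfinite(self.abundances)):
            raise MalformedDataError("abundances must be non-negative and finite")
        colsums = self.abundances.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _NORM_TOL):
            k = int(np.argmax(np.abs(colsums - 1.0)))
            raise MalformedDataError(
                f"sample {self.sample_ids[k]!r} sums to {colsums[k]:.6g}, not 1; "
                "use Cohort.from_counts to normalize raw tables"
            )

    @classmethod
    def from_counts(cls, counts, taxon_ids, sample_ids,
                    detection_threshold: float = 0.0, **kwargs) -> "Cohort":
        """Build a cohort from raw (count or un-normalized) abundances.

        Each sample column is rescaled to sum to one. Zero-sum samples
        are rejected with a :class:`DegenerateSampleError` naming the
        offending sample.
        """
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise MalformedDataError("abundances must be non-negative and finite")
        colsums = counts.sum(axis=0)
        zero = np.flatnonzero(colsums == 0)
        if zero.size:
            names = [str(sample_ids[k]) for k in zero]
            raise DegenerateSampleError(
                f"sample(s) {names} have zero total abundance and cannot be normalized"
            )
        return cls(counts / colsums, list(taxon_ids), list(sample_ids),
                   detection_threshold=detection_threshold, **kwargs)

    @property
    def n_taxa(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[1]

    @property
    def presence(self) -> np.ndarray:
        """Boolean taxa x samples matrix: abundance > detection threshold."""
        return self.abundances > self.detection_threshold

    @property
    def frequencies(self) -> np.ndarray:
        """Per-taxon relative frequency: fraction of samples where present."""
        return self.presence.mean(axis=1)

    def taxon_index(self, taxon) -> int:
        """Resolve a taxon identifier (or integer index) to a row index."""
        if isinstance(taxon, (int, np.integer)):
            return int(taxon)
        return self.taxon_ids.index(str(taxon))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundances, index=self.taxon_ids,
                            columns=self.sample_ids)


@dataclass
class PairedCohort:
    """Two collections of samples from the same subjects, aligned on taxa.

    ``first`` and ``second`` share identical taxon ordering; sample
    identifiers index subjects, so column ``h`` of both cohorts belongs
    to the same subject.
    """

    first: Cohort
    second: Cohort

    def __post_init__(self):
        if self.first.taxon_ids != self.second.taxon_ids:
            raise IdentifierError("paired cohorts must share taxon identifiers")
        if self.first.n_samples != self.second.n_samples:
            raise IdentifierError("paired cohorts must have the same subjects")

    @property
    def n_subjects(self) -> int:
        return self.first.n_samples


def load_abundance_table(path, orientation: str = "taxa-by-samples",
                         detection_threshold: float = 0.0,
                         sep: Optional[str] = None) -> Cohort:
    """Read a delimited abundance table into a normalized :class:`Cohort`.

    The file must have one header row and one identifier column; values
    must be non-negative and finite. Columns are rescaled to sum to one.
    ``orientation`` says whether rows are taxa (default) or samples.
    Lines starting with ``#`` (parameter headers written by this package)
    are ignored. The delimiter is inferred from the suffix when not given
    (.csv -> comma, otherwise tab).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MalformedDataError(f"non-numeric entry in {path}: {exc}") from exc
    if orientation == "samples-by-taxa":
        values = values.T
        taxon_ids, sample_ids = list(df.columns), list(df.index)
    elif orientation == "taxa-by-samples":
        taxon_ids, sample_ids = list(df.index), list(df.columns)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if len(set(taxon_ids)) != len(taxon_ids) or len(set(sample_ids)) != len(sample_ids):
        raise IdentifierError(f"duplicate identifiers in {path}")
    return Cohort.from_counts(values, taxon_ids, sample_ids,
                              detection_threshold=detection_threshold,
                              meta={"source": str(path)})


def write_abundance_table(cohort: Cohort, path, sep: str = "\t") -> None:
    """Write a cohort as a delimited table with a ``# params:`` header."""
    path = Path(path)
    header = "# params: " + json.dumps(cohort.meta, default=str, sort_keys=True)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        cohort.to_frame().to_csv(fh, sep=sep)


def filter_top_taxa(cohort: Cohort, n_top: int) -> Cohort:
    """Keep the ``n_top`` taxa with highest mean relative abundance.

    After dropping the other taxa, every sample is renormalized to sum
    to one. Ties at the cutoff are broken by input order (stable sort),
    so results are reproducible.
    """
    if not 1 <= n_top <= cohort.n_taxa:
        raise ValueError(f"n_top must be in [1, {cohort.n_taxa}], got {n_top}")
    means = cohort.abundances.mean(axis=1)
    order = np.argsort(-means, kind="stable")[:n_top]
    keep = np.sort(order)  # preserve original taxon order
    sub = cohort.abundances[keep]
    meta = dict(cohort.meta, n_top=n_top)
    return Cohort.from_counts(
        sub, [cohort.taxon_ids[i] for i in keep], list(cohort.sample_ids),
        detection_threshold=cohort.detection_threshold, meta=meta,
        absolute=cohort.absolute[keep] if cohort.absolute is not None else None,
        converged=cohort.converged,
    )


def frequency_filter(cohort: Cohort, lo: float = 0.25, hi: float = 0.75) -> np.ndarray:
    """Indices of taxa whose relative frequency lies in [lo, hi] (inclusive).

    The relative frequency of a taxon is the fraction of samples where it
    is detected. Taxa present in every sample (or in none) carry no
    presence/absence contrast and are excluded whenever hi < 1 (lo > 0).
    """
    if not 0 <= lo < hi <= 1:
        raise ValueError(f"require 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    f = cohort.frequencies
    return np.flatnonzero((f >= lo) & (f <= hi))


def shuffle_preserving_margins(presence: np.ndarray, n_swaps: Optional[int] = None,
                               seed: int = 0) -> np.ndarray:
    """Randomize a binary presence matrix with fixed row and column sums.

    Repeated checkerboard swaps — finding a 2x2 submatrix equal to
    ``[[1,0],[0,1]]`` or ``[[0,1],[1,0]]`` and flipping it — preserve
    both every taxon's relative frequency (row sums) and every sample's
    observed richness (column sums) exactly, giving the standard
    fixed-margin null for presence/absence data.

    Parameters
    ----------
    presence : boolean/0-1 matrix, taxa x samples
    n_swaps : int, optional
        Number of successful swaps to perform; defaults to 10x the
        number of ones in the matrix.
    seed : int
        Seed for the swap sequence; the result is deterministic given it.

    Returns
    -------
    A new matrix with identical margins. If the matrix admits no
    checkerboard at all (e.g. all ones), a copy of the input is returned
    and a warning is issued.
    """
    p = np.asarray(presence)
    if p.ndim != 2 or not np.isin(p, [0, 1]).all():
        raise MalformedDataError("presence must be a binary 2-D matrix")
    out = p.astype(bool).copy()
    n_rows, n_cols = out.shape
    if n_rows < 2 or n_cols < 2:
        warnings.warn("matrix too small for checkerboard swaps; returned unchanged")
        return out
    if n_swaps is None:
        n_swaps = max(10 * int(out.sum()), 1)
    if n_swaps <= 0:
        raise ValueError("n_swaps must be positive")
    rng = np.random.default_rng(seed)
    done = 0
    attempts = 0
    max_attempts = max(200 * n_swaps, 10_000)
    # rejection sampling over random row/column pairs; draw in batches
    while done < n_swaps and attempts < max_attempts:
        batch = min(4096, max_attempts - attempts)
        rows = rng.integers(0, n_rows, size=(batch, 2))
        cols = rng.integers(0, n_cols, size=(batch, 2))
        for (r1, r2), (c1, c2) in zip(rows, cols):
            attempts += 1
            if r1 == r2 or c1 == c2:
                continue
            a, b = out[r1, c1], out[r1, c2]
            c, d = out[r2, c1], out[r2, c2]
            if a == d and b == c and a != b:
                out[r1, c1] = b
                out[r1, c2] = a
                out[r2, c1] = d
                out[r2, c2] = c
                done += 1
                if done >= n_swaps:
                    break
    if done == 0:
        warnings.warn("no swappable checkerboard found; matrix returned unchanged")
    return out
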