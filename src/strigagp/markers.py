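"""Dominant marker QC and the genomic relationship matrix (GRM).

rAmpSeq tags are dominant presence/absence markers: each line carries a
0 or 1 per tag.  The minor "allele" frequency of such a marker is the
frequency of the rarer of the two classes.  After QC (monomorphic and
low-MAF markers removed) the marker matrix is centred and standardised
by column and the VanRaden-style relationship matrix

    G = S S' / p

is formed, where S is the standardised lines x markers matrix and p the
number of markers.  Population (divide-by-n) variance is used for the
standardisation so that the mean diagonal of G is exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, DomainError, EmptyResultError

__all__ = ["MarkerMatrix", "Kernel", "qc_markers", "standardize_markers", "compute_grm"]


@dataclass
class MarkerMatrix:
    """Lines x markers matrix of dominant {0,1} calls.

    Missing calls are held as NaN; they are mean-imputed per marker only
    at standardisation time, never stored imputed.
    """

    values: np.ndarray
    line_ids: list = field(default_factory=list)
    marker_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("marker matrix must be 2-d (lines x markers)")
        n, p = self.values.shape
        if not self.line_ids:
            self.line_ids = [f"L{i:04d}" for i in range(n)]
        if not self.marker_ids:
            self.marker_ids = [f"M{j:05d}" for j in range(p)]
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise DimensionError("id lists must match matrix shape")
        if len(set(self.line_ids)) != n:
            raise DimensionError("duplicate line identifiers")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise DomainError("marker calls must be 0, 1 or missing")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def presence_frequencies(self) -> np.ndarray:
        """Frequency of the presence (1) class per marker, missing excluded."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)

    def minor_class_frequencies(self) -> np.ndarray:
        f = self.presence_frequencies()
        return np.minimum(f, 1.0 - f)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.marker_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MarkerMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class Kernel:
    """Symmetric PSD similarity matrix with axis identifiers."""

    values: np.ndarray
    ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise DimensionError("kernel must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise DomainError("kernel must be symmetric")
        self.values = (self.values + self.values.T) / 2.0
        if not self.ids:
            self.ids = [f"L{i:04d}" for i in range(n)]
        self.ids = [str(x) for x in self.ids]
        if len(self.ids) != n:
            raise DimensionError("ids must match kernel dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def submatrix(self, ids) -> "Kernel":
        pos = {x: i for i, x in enumerate(self.ids)}
        idx = [pos[str(x)] for x in ids]
        return Kernel(self.values[np.ix_(idx, idx)], [self.ids[i] for i in idx])


def qc_markers(raw: MarkerMatrix, maf_threshold: float = 0.05) -> MarkerMatrix:
    """Drop monomorphic / zero-variance markers and those with minor-class
    frequency below ``maf_threshold``.  Marker order is preserved."""
    if not (0 <= maf_threshold <= 0.5):
        raise DomainError("maf_threshold must be within [0, 0.5]")
    maf = raw.minor_class_frequencies()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        variances = np.nanvar(raw.values, axis=0)
    keep = np.isfinite(maf) & (variances > 0) & (maf >= maf_threshold)
    if not keep.any():
        raise EmptyResultError(
            f"no markers survive QC at MAF threshold {maf_threshold}"
        )
    return MarkerMatrix(
        raw.values[:, keep],
        list(raw.line_ids),
        [m for m, k in zip(raw.marker_ids, keep) if k],
    )


def standardize_markers(m: MarkerMatrix) -> np.ndarray:
    """Centre and scale each marker column to mean 0, variance 1.

    Missing calls are mean-imputed per column first (variance-neutral).
    Uses the population (divide-by-n) variance so that the resulting
    GRM has mean diagonal exactly 1.
    """
    x = m.values.copy()
    col_means = m.presence_frequencies()
    nan_rows, nan_cols = np.nonzero(np.isnan(x))
    x[nan_rows, nan_cols] = col_means[nan_cols]
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population variance
    if np.any(sd == 0) or np.any(~np.isfinite(sd)):
        raise DomainError("zero-variance marker column: run qc_markers first")
    return (x - mu) / sd


def compute_grm(m: MarkerMatrix) -> Kernel:
    """Genomic relationship matrix G = S S' / p from standardised markers."""
    if m.n_markers == 0:
        raise DomainError("cannot build a GRM from zero markers")
    s = standardize_markers(m)
    g = s @ s.T / m.n_markers
    return Kernel(g, list(m.line_ids))
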