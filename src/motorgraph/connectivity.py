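"""Functional connectivity from ROI time series.

Connectivity between two ROIs is the absolute Fisher z-transform of the
Pearson correlation of their BOLD-like signals.  Absolute values are used
because the analysis concerns the *magnitude* of coupling; the diagonal is
zeroed since self-connections carry no information.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeriesSet",
    "ConnectivityMatrix",
    "correlation_matrix",
    "to_connectivity",
    "significant_edge_fraction",
    "group_median_matrix",
    "read_timeseries_csv",
    "write_connectivity_csv",
    "read_connectivity_csv",
]

#: Two-tailed z criterion at alpha = 0.05, used for the significance-based
#: edge-fraction scan that motivates the study density.
Z_CRIT_DEFAULT = 1.96


@dataclass(frozen=True)
class RoiTimeSeriesSet:
    """One session's ROI signal matrix: rows = time points, columns = ROIs."""

    subject_id: str
    session: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.session not in {"pre", "post"}:
            raise ValueError(f"session must be 'pre' or 'post', got {self.session!r}")
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        if self.data.isna().any().any():
            raise ValueError("time series contains missing values")
        variances = self.data.var(axis=0, ddof=1)
        dead = variances.index[variances == 0].tolist()
        if dead:
            raise ValueError(f"zero-variance ROI signal(s): {dead}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def labels(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N matrix of absolute Fisher z values, zero diagonal."""

    values: np.ndarray
    labels: tuple[str, ...]
    subject_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix has non-finite entries")
        if (v < 0).any():
            raise ValueError("absolute connectivity must be non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def correlation_matrix(ts: RoiTimeSeriesSet) -> np.ndarray:
    """Pearson correlation matrix of the ROI columns (diagonal = 1)."""
    r = np.corrcoef(ts.data.to_numpy(), rowvar=False)
    np.fill_diagonal(r, 1.0)
    return r


def to_connectivity(ts: RoiTimeSeriesSet, clip: float = 1e-7) -> ConnectivityMatrix:
    """Absolute Fisher-z connectivity: ``|atanh(r)|`` with r clipped to ±(1-clip).

    Clipping keeps z finite when two signals are (numerically) identical.
    """
    if not 0 < clip < 1:
        raise ValueError("clip must be in (0, 1)")
    r = correlation_matrix(ts)
    r = np.clip(r, -(1.0 - clip), 1.0 - clip)
    z = np.abs(np.arctanh(r))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # guard against asymmetric rounding
    return ConnectivityMatrix(
        values=z,
        labels=tuple(ts.labels),
        subject_id=ts.subject_id,
        session=ts.session,
    )


def significant_edge_fraction(
    cm: ConnectivityMatrix, z_crit: float = Z_CRIT_DEFAULT
) -> float:
    """Fraction of the N(N-1)/2 possible edges with z above ``z_crit``.

    The cohort minimum of this fraction is the density at which every
    subject's suprathreshold edges all survive proportional thresholding.
    """
    if not z_crit > 0:
        raise ValueError("z_crit must be positive")
    n = cm.n_rois
    iu = np.triu_indices(n, k=1)
    return float(np.count_nonzero(cm.values[iu] > z_crit) / (n * (n - 1) / 2))


def group_median_matrix(cms: Sequence[ConnectivityMatrix]) -> np.ndarray:
    """Element-wise median connectivity across subjects (robust group summary)."""
    if len(cms) == 0:
        raise ValueError("need at least one connectivity matrix")
    n = cms[0].n_rois
    if any(cm.n_rois != n for cm in cms):
        raise ValueError("matrices differ in size")
    med = np.median(np.stack([cm.values for cm in cms]), axis=0)
    med = (med + med.T) / 2.0
    np.fill_diagonal(med, 0.0)
    return med


def read_timeseries_csv(
    path: str | Path, subject_id: str, session: str
) -> RoiTimeSeriesSet:
    """Read a session CSV: header row of ROI labels, one row per TR."""
    return RoiTimeSeriesSet(subject_id=subject_id, session=session, data=pd.read_csv(path))


def write_connectivity_csv(cm: ConnectivityMatrix, path: str | Path) -> None:
    pd.DataFrame(cm.values, index=list(cm.labels), columns=list(cm.labels)).to_csv(path)


def read_connectivity_csv(
    path: str | Path, subject_id: str = "", session: str = ""
) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float),
        labels=tuple(df.columns),
        subject_id=subject_id,
        session=session,
    )
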