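"""Synthetic paired-session cohorts of motor-network ROI time series.

The generator emulates the *output* of a resting-state preprocessing chain:
per subject and session it draws T correlated Gaussian samples over the N
atlas ROIs (block-structured target correlation: higher within functional
communities than between), applies first-order autoregressive smoothing to
mimic the temporal autocorrelation of bandpassed BOLD, and adds white
observation noise.  A pre-to-post "reorganization" is injected by raising
the target correlation of designated edges in the post session only, and
behavioral change scores are linearly coupled to each subject's realized
connectivity change so that brain-behavior correlation analyses have a known
ground truth.  Everything is reproducible from a single integer seed.

Defaults mirror the study's data regime: 13 subjects, T = 230 time points
(ten minutes at TR 2.6 s), within-community r = 0.45, between-community
r = 0.10, AR coefficient 0.3.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import RoiAtlas, load_atlas
from .connectivity import RoiTimeSeriesSet
from .stats import ARAT_MAX, BehavioralRecord

__all__ = [
    "CohortSpec",
    "Cohort",
    "default_communities",
    "build_target_correlation",
    "generate_cohort",
    "node_effect_edges",
    "within_community_effect_edges",
    "write_cohort",
    "read_cohort",
]

logger = logging.getLogger(__name__)

_CORTICAL = {"M1", "SPL", "SMA", "PMd", "PMv", "PCG"}
_SUBCORTICAL = {"Th", "BG"}
_CEREBELLAR = {"SCb", "DN", "AICb"}

_EIG_FLOOR = 1e-6


def default_communities(atlas: RoiAtlas) -> dict[str, list[str]]:
    """Partition ROIs into four functional communities.

    Ipsilesional (right, matching the right-hemisphere-lesion cohort) and
    contralesional (left) cortical sensorimotor regions, plus bilateral
    subcortical (thalamus, basal ganglia) and bilateral cerebellar blocks.
    """
    groups: dict[str, list[str]] = {
        "ipsilesional_cortical": [],
        "contralesional_cortical": [],
        "subcortical": [],
        "cerebellar": [],
    }
    for entry in atlas:
        if entry.abbreviation in _CORTICAL:
            key = (
                "ipsilesional_cortical" if entry.side == "R" else "contralesional_cortical"
            )
        elif entry.abbreviation in _SUBCORTICAL:
            key = "subcortical"
        elif entry.abbreviation in _CEREBELLAR:
            key = "cerebellar"
        else:  # pragma: no cover - atlas validation forbids this
            raise ValueError(f"unclassifiable ROI {entry.label}")
        groups[key].append(entry.label)
    return groups


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic paired-session cohort."""

    n_subjects: int = 13
    n_timepoints: int = 230
    atlas: RoiAtlas = field(default_factory=load_atlas)
    base_correlation: float = 0.45
    cross_correlation: float = 0.10
    communities: dict[str, list[str]] | None = None
    effect_edges: tuple[tuple[str, str, float], ...] = ()
    ar_coefficient: float = 0.3
    noise_sd: float = 0.2
    behavior_coupling: float = 20.0
    behavior_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_timepoints < 3:
            raise ValueError("need at least 1 subject and 3 time points")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.noise_sd < 0 or self.behavior_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        for r in (self.base_correlation, self.cross_correlation):
            if not -1 < r < 1:
                raise ValueError(f"correlation target out of (-1, 1): {r}")
        labels = set(self.atlas.labels)
        for a, b, dr in self.effect_edges:
            if a not in labels or b not in labels:
                raise ValueError(f"effect edge ({a}, {b}) names unknown ROI")
            if a == b:
                raise ValueError("effect edge cannot be a self-loop")
        # fail fast on impossible correlation structures
        for session in ("pre", "post"):
            build_target_correlation(self, session)

    def resolved_communities(self) -> dict[str, list[str]]:
        return (
            self.communities
            if self.communities is not None
            else default_communities(self.atlas)
        )


@dataclass(frozen=True)
class Cohort:
    """Generated cohort: per-subject pre/post time series plus behavior."""

    spec: CohortSpec
    sessions: tuple[tuple[RoiTimeSeriesSet, RoiTimeSeriesSet], ...]
    behavior: tuple[BehavioralRecord, ...]
    effect_strengths: tuple[float, ...]  # realized mean delta-r on effect edges

    @property
    def n_subjects(self) -> int:
        return len(self.sessions)


def node_effect_edges(
    atlas: RoiAtlas, label: str, dr: float
) -> tuple[tuple[str, str, float], ...]:
    """All edges incident to ``label`` with the same correlation increment."""
    if label not in atlas.labels:
        raise ValueError(f"unknown ROI label {label!r}")
    return tuple((label, other, dr) for other in atlas.labels if other != label)


def within_community_effect_edges(
    communities: dict[str, list[str]], dr: float
) -> tuple[tuple[str, str, float], ...]:
    """Every within-community pair with the same correlation increment."""
    edges = []
    for members in communities.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges.append((members[i], members[j], dr))
    return tuple(edges)


def build_target_correlation(spec: CohortSpec, session: str) -> np.ndarray:
    """Block target correlation for one session, repaired to positive definite.

    Within-community entries get ``base_correlation``, between-community
    entries ``cross_correlation``; for the post session each effect edge's
    entry is incremented by its delta-r.  If the raw matrix is not positive
    definite its eigenvalues are floored and the matrix rescaled back to
    unit diagonal (logged when triggered).
    """
    if session not in {"pre", "post"}:
        raise ValueError("session must be 'pre' or 'post'")
    labels = spec.atlas.labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)

    community_of = {}
    for name, members in spec.resolved_communities().items():
        for lab in members:
            community_of[lab] = name

    target = np.full((n, n), spec.cross_correlation)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j and community_of.get(a) == community_of.get(b):
                target[i, j] = spec.base_correlation
    np.fill_diagonal(target, 1.0)

    if session == "post":
        for a, b, dr in spec.effect_edges:
            i, j = index[a], index[b]
            target[i, j] += dr
            target[j, i] += dr

    off = target[~np.eye(n, dtype=bool)]
    if np.any(np.abs(off) >= 1):
        raise ValueError("target correlations must stay within (-1, 1)")

    eigval, eigvec = np.linalg.eigh(target)
    if eigval.min() < _EIG_FLOOR:
        logger.info(
            "target correlation (%s) not positive definite (min eig %.3g); "
            "applying eigenvalue floor repair",
            session,
            eigval.min(),
        )
        eigval = np.clip(eigval, _EIG_FLOOR, None)
        repaired = eigvec @ np.diag(eigval) @ eigvec.T
        d = np.sqrt(np.diag(repaired))
        if np.any(d <= 0):
            raise ValueError("positive-definite repair cannot restore unit diagonal")
        target = repaired / np.outer(d, d)
        np.fill_diagonal(target, 1.0)
    return target


def _simulate_session(
    target: np.ndarray, spec: CohortSpec, rng: np.random.Generator
) -> np.ndarray:
    """T x N correlated Gaussian draws, AR(1)-smoothed, plus white noise."""
    t, n = spec.n_timepoints, target.shape[0]
    chol = np.linalg.cholesky(target)
    innovations = rng.standard_normal((t, n)) @ chol.T
    phi = spec.ar_coefficient
    if phi > 0:
        out = np.empty_like(innovations)
        out[0] = innovations[0] / np.sqrt(1.0 - phi**2)  # stationary start
        for k in range(1, t):
            out[k] = phi * out[k - 1] + innovations[k]
    else:
        out = innovations
    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    return out


def _edge_indices(spec: CohortSpec) -> list[tuple[int, int]]:
    index = {lab: i for i, lab in enumerate(spec.atlas.labels)}
    return [(index[a], index[b]) for a, b, _ in spec.effect_edges]


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw the full cohort (time series + behavior) from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    labels = spec.atlas.labels
    targets = {s: build_target_correlation(spec, s) for s in ("pre", "post")}
    pairs = _edge_indices(spec)

    sessions = []
    strengths = []
    behavior = []
    for s in range(spec.n_subjects):
        subject_id = f"sub-{s + 1:02d}"
        ts_by_session = {}
        corr_by_session = {}
        for session in ("pre", "post"):
            data = _simulate_session(targets[session], spec, rng)
            ts_by_session[session] = RoiTimeSeriesSet(
                subject_id=subject_id,
                session=session,
                data=pd.DataFrame(data, columns=labels),
            )
            corr_by_session[session] = np.corrcoef(data, rowvar=False)
        sessions.append((ts_by_session["pre"], ts_by_session["post"]))

        if pairs:
            strength = float(
                np.mean(
                    [
                        corr_by_session["post"][i, j] - corr_by_session["pre"][i, j]
                        for i, j in pairs
                    ]
                )
            )
        else:
            strength = 0.0
        strengths.append(strength)

        arat_pre = int(rng.integers(0, ARAT_MAX - 16))
        arat_gain = spec.behavior_coupling * strength + rng.normal(
            0.0, spec.behavior_noise_sd
        )
        arat_post = int(np.clip(round(arat_pre + arat_gain), 0, ARAT_MAX))
        hpt_pre = float(rng.uniform(18.0, 38.0))
        hpt_change = -spec.behavior_coupling * strength + rng.normal(
            0.0, spec.behavior_noise_sd
        )
        hpt_post = float(max(1.0, hpt_pre + hpt_change))
        behavior.append(
            BehavioralRecord(
                subject_id=subject_id,
                arat_pre=float(arat_pre),
                arat_post=float(arat_post),
                hpt_pre=hpt_pre,
                hpt_post=hpt_post,
            )
        )

    return Cohort(
        spec=spec,
        sessions=tuple(sessions),
        behavior=tuple(behavior),
        effect_strengths=tuple(strengths),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write the cohort in the CSV layouts the pipeline reads.

    One ``<subject>_ses-<session>.csv`` per session (header = ROI labels,
    one row per TR) plus ``behavior.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pre_ts, post_ts in cohort.sessions:
        for ts in (pre_ts, post_ts):
            ts.data.to_csv(out / f"{ts.subject_id}_ses-{ts.session}.csv", index=False)
    rows = [
        {
            "subject_id": rec.subject_id,
            "arat_pre": rec.arat_pre,
            "arat_post": rec.arat_post,
            "hpt_pre": rec.hpt_pre,
            "hpt_post": rec.hpt_post,
        }
        for rec in cohort.behavior
    ]
    pd.DataFrame(rows).to_csv(out / "behavior.csv", index=False)


def read_cohort(
    in_dir: str | Path,
) -> tuple[list[tuple[RoiTimeSeriesSet, RoiTimeSeriesSet]], list[BehavioralRecord]]:
    """Read a cohort directory written by :func:`write_cohort`."""
    from .stats import load_behavior

    in_dir = Path(in_dir)
    subjects: dict[str, dict[str, RoiTimeSeriesSet]] = {}
    for path in sorted(in_dir.glob("*_ses-*.csv")):
        stem = path.stem
        subject_id, _, session_part = stem.rpartition("_ses-")
        ts = RoiTimeSeriesSet(
            subject_id=subject_id, session=session_part, data=pd.read_csv(path)
        )
        subjects.setdefault(subject_id, {})[session_part] = ts
    sessions = []
    for subject_id in sorted(subjects):
        both = subjects[subject_id]
        if {"pre", "post"} <= set(both):
            sessions.append((both["pre"], both["post"]))
        else:
            warnings.warn(f"{subject_id}: missing a session; excluded", stacklevel=2)
    behavior_path = in_dir / "behavior.csv"
    behavior = load_behavior(behavior_path) if behavior_path.exists() else []
    return sessions, behavior
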