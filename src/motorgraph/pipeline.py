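"""Study-level orchestration: sparsity sweep, fixed-density regional tests,
and brain-behavior correlations.

Statistics are within-subject paired tests: each subject contributes a
pre and a post graph at each density, and Wilcoxon signed-rank tests compare
the per-subject metric values across sessions.  Group-median connectivity
matrices are produced only as descriptive output.  FDR families follow the
study protocol: betweenness tests across regions, degree tests across
regions, and behavior correlations each form one family; the global sweep
is adjusted within measure across the sparsity grid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (
    ConnectivityMatrix,
    RoiTimeSeriesSet,
    group_median_matrix,
    significant_edge_fraction,
    to_connectivity,
)
from .graph_build import threshold_to_graph
from .graph_metrics import (
    betweenness_centrality,
    char_path_length,
    degree_centrality,
    mean_clustering,
)
from .stats import (
    ALPHA_DEFAULT,
    TREND_CUT_DEFAULT,
    BehavioralRecord,
    UndefinedTestError,
    change_scores,
    classify,
    fdr_bh,
    pearson_with_p,
    wilcoxon_signed_rank_exact,
)

__all__ = [
    "AnalysisConfig",
    "ResultsBundle",
    "session_connectivity",
    "run_sweep",
    "run_regional",
    "run_behavior_correlation",
    "run_all",
]

logger = logging.getLogger(__name__)

SessionPair = tuple[RoiTimeSeriesSet, RoiTimeSeriesSet]


def _default_grid() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.05, 0.5001, 0.01), 2))


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full analysis; defaults reproduce the study protocol."""

    sparsity_grid: tuple[float, ...] = field(default_factory=_default_grid)
    fixed_density: float = 0.42
    z_crit: float = 1.96
    alpha: float = ALPHA_DEFAULT
    trend_cut: float = TREND_CUT_DEFAULT
    clustering_variant: str = "barrat"
    data_dir: str | None = None
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sparsity_grid:
            raise ValueError("sparsity grid must be non-empty")
        if any(not 0 < s <= 1 for s in self.sparsity_grid):
            raise ValueError("sparsity grid values must be in (0, 1]")
        if not 0 < self.fixed_density <= 1:
            raise ValueError("fixed_density must be in (0, 1]")
        if self.fixed_density not in self.sparsity_grid:
            object.__setattr__(
                self,
                "sparsity_grid",
                tuple(sorted({*self.sparsity_grid, self.fixed_density})),
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sparsity_grid" in raw:
            raw["sparsity_grid"] = tuple(float(s) for s in raw["sparsity_grid"])
        return cls(**raw)


@dataclass
class ResultsBundle:
    global_sweep: pd.DataFrame
    regional: pd.DataFrame
    regional_deltas: pd.DataFrame
    correlations: pd.DataFrame
    behavioral: pd.DataFrame
    median_pre: np.ndarray
    median_post: np.ndarray
    labels: tuple[str, ...]
    provenance: dict


def session_connectivity(
    sessions: Sequence[SessionPair],
) -> list[tuple[ConnectivityMatrix, ConnectivityMatrix]]:
    return [(to_connectivity(pre), to_connectivity(post)) for pre, post in sessions]


def _paired_p(pre_vals: np.ndarray, post_vals: np.ndarray) -> tuple[float, float, int]:
    """Wilcoxon p across subjects, mapping the all-zero case to p = 1."""
    try:
        res = wilcoxon_signed_rank_exact(pre_vals, post_vals)
        return res.p, res.statistic, res.n_effective
    except UndefinedTestError:
        warnings.warn(
            "all paired differences zero; reporting p = 1", stacklevel=2
        )
        return 1.0, 0.0, 0


def run_sweep(
    sessions: Sequence[SessionPair],
    config: AnalysisConfig,
    cms: Sequence[tuple[ConnectivityMatrix, ConnectivityMatrix]] | None = None,
) -> pd.DataFrame:
    """Per-sparsity paired comparison of C and L across the cohort."""
    if len(sessions) < 2:
        raise ValueError("sweep needs at least 2 subjects with both sessions")
    if cms is None:
        cms = session_connectivity(sessions)

    rows = []
    for s in config.sparsity_grid:
        metrics = {"C": {"pre": [], "post": []}, "L": {"pre": [], "post": []}}
        for pre_cm, post_cm in cms:
            for session, cm in (("pre", pre_cm), ("post", post_cm)):
                g = threshold_to_graph(cm, s)
                metrics["C"][session].append(
                    mean_clustering(g, config.clustering_variant)
                )
                metrics["L"][session].append(char_path_length(g))
        for name in ("C", "L"):
            pre_v = np.asarray(metrics[name]["pre"])
            post_v = np.asarray(metrics[name]["post"])
            p, w, n_eff = _paired_p(pre_v, post_v)
            rows.append(
                {
                    "sparsity": s,
                    "measure": name,
                    "pre_median": float(np.median(pre_v)),
                    "post_median": float(np.median(post_v)),
                    "delta_median": float(np.median(post_v - pre_v)),
                    "W": w,
                    "n_effective": n_eff,
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    for name in ("C", "L"):
        mask = df["measure"] == name
        df.loc[mask, "q"] = fdr_bh(df.loc[mask, "p"].to_numpy())
    df["family"] = "sweep_" + df["measure"]
    df["flag"] = [
        classify(p, q, config.alpha, config.trend_cut)
        for p, q in zip(df["p"], df["q"])
    ]
    return df


def _regional_values(
    cms: Sequence[tuple[ConnectivityMatrix, ConnectivityMatrix]],
    config: AnalysisConfig,
) -> tuple[dict[str, dict[str, np.ndarray]], tuple[str, ...]]:
    """Per-subject BC_norm and DC arrays at the fixed density."""
    labels = cms[0][0].labels
    values: dict[str, dict[str, list[np.ndarray]]] = {
        "BC": {"pre": [], "post": []},
        "DC": {"pre": [], "post": []},
    }
    for pre_cm, post_cm in cms:
        for session, cm in (("pre", pre_cm), ("post", post_cm)):
            g = threshold_to_graph(cm, config.fixed_density)
            values["BC"][session].append(betweenness_centrality(g, normalize=True))
            values["DC"][session].append(degree_centrality(g).astype(float))
    stacked = {
        m: {sess: np.vstack(vals) for sess, vals in by_sess.items()}
        for m, by_sess in values.items()
    }
    return stacked, labels


def run_regional(
    sessions: Sequence[SessionPair],
    config: AnalysisConfig,
    cms: Sequence[tuple[ConnectivityMatrix, ConnectivityMatrix]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region BC and DC paired tests at the fixed density.

    Returns (tests, deltas): ``tests`` has one row per region x metric with
    W, p, q (FDR within metric family) and flag; ``deltas`` has per-subject
    post - pre values for downstream behavior correlation.
    """
    if len(sessions) < 2:
        raise ValueError("regional tests need at least 2 subjects")
    if cms is None:
        cms = session_connectivity(sessions)
    stacked, labels = _regional_values(cms, config)
    subject_ids = [pre.subject_id for pre, _ in sessions]

    rows = []
    delta_rows = []
    for metric in ("BC", "DC"):
        pre_m = stacked[metric]["pre"]
        post_m = stacked[metric]["post"]
        for j, label in enumerate(labels):
            p, w, n_eff = _paired_p(pre_m[:, j], post_m[:, j])
            rows.append(
                {
                    "region": label,
                    "metric": metric,
                    "W": w,
                    "n_effective": n_eff,
                    "delta_median": float(np.median(post_m[:, j] - pre_m[:, j])),
                    "p": p,
                }
            )
        for i, sid in enumerate(subject_ids):
            for j, label in enumerate(labels):
                delta_rows.append(
                    {
                        "subject_id": sid,
                        "region": label,
                        "metric": metric,
                        "delta": float(post_m[i, j] - pre_m[i, j]),
                    }
                )

    tests = pd.DataFrame(rows)
    tests["q"] = np.nan
    for metric in ("BC", "DC"):
        mask = tests["metric"] == metric
        tests.loc[mask, "q"] = fdr_bh(tests.loc[mask, "p"].to_numpy())
    tests["family"] = "regional_" + tests["metric"]
    tests["flag"] = [
        classify(p, q, config.alpha, config.trend_cut)
        for p, q in zip(tests["p"], tests["q"])
    ]
    return tests, pd.DataFrame(delta_rows)


def run_behavior_correlation(
    regional_deltas: pd.DataFrame,
    behavior: Sequence[BehavioralRecord],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Pearson correlation of every region x metric delta with every
    behavioral delta; FDR over the whole family."""
    deltas = change_scores(behavior)
    rows = []
    for (region, metric), grp in regional_deltas.groupby(["region", "metric"]):
        grp = grp.set_index("subject_id")
        for behavior_name, col in (("ARAT", "arat_delta"), ("9-HPT", "hpt_delta")):
            joined = grp.join(deltas, how="inner")
            x = joined["delta"].to_numpy()
            y = joined[col].to_numpy()
            try:
                res = pearson_with_p(
                    x, y, region=region, metric=metric, behavior=behavior_name
                )
            except ValueError as exc:
                warnings.warn(
                    f"{region}/{metric}/{behavior_name}: {exc}; skipped",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "region": region,
                    "metric": metric,
                    "behavior": behavior_name,
                    "R": res.R,
                    "n": res.n,
                    "p": res.p,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q"] = fdr_bh(df["p"].to_numpy())
    df["family"] = "correlations"
    df["flag"] = [
        classify(p, q, config.alpha, config.trend_cut)
        for p, q in zip(df["p"], df["q"])
    ]
    return df


def _behavioral_tests(behavior: Sequence[BehavioralRecord]) -> pd.DataFrame:
    rows = []
    specs = [
        ("ARAT", [r.arat_pre for r in behavior], [r.arat_post for r in behavior]),
        ("9-HPT", [r.hpt_pre for r in behavior], [r.hpt_post for r in behavior]),
    ]
    for name, pre, post in specs:
        pre_a = np.array([np.nan if v is None else v for v in pre], dtype=float)
        post_a = np.array([np.nan if v is None else v for v in post], dtype=float)
        res = wilcoxon_signed_rank_exact(pre_a, post_a)
        rows.append(
            {
                "measure": name,
                "n": res.n_total,
                "n_effective": res.n_effective,
                "W": res.statistic,
                "p": res.p,
                "p_rounded": round(res.p, 4),
            }
        )
    return pd.DataFrame(rows)


def _hash_sessions(sessions: Sequence[SessionPair]) -> str:
    h = hashlib.sha256()
    for pre, post in sessions:
        for ts in (pre, post):
            h.update(ts.subject_id.encode())
            h.update(ts.session.encode())
            h.update(np.ascontiguousarray(ts.data.to_numpy()).tobytes())
    return h.hexdigest()[:16]


def run_all(
    config: AnalysisConfig,
    sessions: Sequence[SessionPair] | None = None,
    behavior: Sequence[BehavioralRecord] | None = None,
    write: bool = True,
) -> ResultsBundle:
    """Execute connectivity -> graphs -> metrics -> statistics and write tables.

    If ``sessions`` is None the cohort is read from ``config.data_dir``;
    behavior defaults to the packaged study table when absent.
    """
    from .stats import load_behavior
    from .synthetic import read_cohort

    if sessions is None:
        if config.data_dir is None:
            raise ValueError("no sessions given and no data_dir configured")
        sessions, file_behavior = read_cohort(config.data_dir)
        if behavior is None and file_behavior:
            behavior = file_behavior
    if behavior is None:
        behavior = load_behavior()

    logger.info("stage=connectivity subjects=%d hash=%s",
                len(sessions), _hash_sessions(sessions))
    cms = session_connectivity(sessions)
    labels = cms[0][0].labels

    min_frac = min(
        significant_edge_fraction(cm, config.z_crit)
        for pair in cms
        for cm in pair
    )
    logger.info("stage=density min_significant_edge_fraction=%.4f", min_frac)

    median_pre = group_median_matrix([pre for pre, _ in cms])
    median_post = group_median_matrix([post for _, post in cms])

    logger.info("stage=sweep grid=%d", len(config.sparsity_grid))
    sweep = run_sweep(sessions, config, cms=cms)
    logger.info("stage=regional density=%.2f", config.fixed_density)
    regional, deltas = run_regional(sessions, config, cms=cms)
    logger.info("stage=correlations")
    correlations = run_behavior_correlation(deltas, behavior, config)
    behavioral = _behavioral_tests(behavior)

    provenance = {
        "package": "motorgraph",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_subjects": len(sessions),
        "input_hash": _hash_sessions(sessions),
        "min_significant_edge_fraction": min_frac,
    }

    bundle = ResultsBundle(
        global_sweep=sweep,
        regional=regional,
        regional_deltas=deltas,
        correlations=correlations,
        behavioral=behavioral,
        median_pre=median_pre,
        median_post=median_post,
        labels=labels,
        provenance=provenance,
    )
    if write:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _write_bundle(bundle: ResultsBundle, out_dir: Path) -> None:
    import datetime

    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.global_sweep.to_csv(out_dir / "global_sweep.csv", index=False)
    bundle.regional.to_csv(out_dir / "regional_tests.csv", index=False)
    bundle.regional_deltas.to_csv(out_dir / "regional_deltas.csv", index=False)
    bundle.correlations.to_csv(out_dir / "behavior_correlations.csv", index=False)
    bundle.behavioral.to_csv(out_dir / "behavioral_tests.csv", index=False)
    labels = list(bundle.labels)
    pd.DataFrame(bundle.median_pre, index=labels, columns=labels).to_csv(
        out_dir / "median_connectivity_pre.csv"
    )
    pd.DataFrame(bundle.median_post, index=labels, columns=labels).to_csv(
        out_dir / "median_connectivity_post.csv"
    )
    manifest = dict(bundle.provenance)
    manifest["written_utc"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    manifest["files"] = sorted(p.name for p in out_dir.glob("*.csv"))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
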