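"""Cohort-level orchestration: manifest in, report tables out.

Runs the full analysis over a cohort manifest: per-subject graphs at each
link density, the reference-group mean degree map, k_D per subject, consensus
partitions with NMI against the reference baseline, module-allegiance maps,
covariate correlations, and permutation-based nodal group contrasts with
Benjamini-Hochberg FDR.  Everything is deterministic given the config and its
single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import child_seeds, rng_from
from .community import (
    AllegianceMap,
    Partition,
    allegiance_map,
    consensus_partition,
    group_allegiance,
    nmi,
)
from .graphs import (
    CorrelationMatrix,
    TimeSeriesMatrix,
    correlation_matrix,
    is_fully_connected,
    threshold_to_density,
)
from .kd import kd_index, reference_degree_map
from .metrics import DegreeProfile, clustering_coefficient, degree, global_efficiency

logger = logging.getLogger("kdconn")

__all__ = [
    "CohortManifest",
    "RunConfig",
    "CohortReport",
    "read_manifest",
    "write_manifest",
    "load_timeseries",
    "covariate_correlation",
    "nodal_group_difference",
    "run_cohort",
    "write_report",
]

MANIFEST_REQUIRED = ("subject_id", "group", "file")


@dataclass
class CohortManifest:
    """Rows of (subject_id, group, file) plus optional scalar covariates."""

    table: pd.DataFrame
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing required columns: {missing}")
        dup = self.table["subject_id"][self.table["subject_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate subject ids: {sorted(set(dup))}")

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.table.columns if c not in MANIFEST_REQUIRED]

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def subjects(self, group: str | None = None) -> pd.DataFrame:
        if group is None:
            return self.table
        return self.table[self.table["group"] == group]

    def path_for(self, row: pd.Series) -> Path:
        p = Path(row["file"])
        return p if p.is_absolute() else self.root / p


def read_manifest(path: str | Path) -> CohortManifest:
    """Strict TSV manifest parse with line-numbered errors."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed manifest {path}: {exc}") from exc
    for col in MANIFEST_REQUIRED:
        if col not in table.columns:
            raise ValueError(f"{path}: header must contain {MANIFEST_REQUIRED}")
    for i, row in table.iterrows():
        for col in MANIFEST_REQUIRED:
            if pd.isna(row[col]) or str(row[col]).strip() == "":
                # +2: one for the header line, one for 1-based numbering
                raise ValueError(f"{path}, line {i + 2}: empty {col!r} field")
    manifest = CohortManifest(table=table, root=path.parent)
    for i, row in table.iterrows():
        p = manifest.path_for(row)
        if not p.exists():
            raise ValueError(f"{path}, line {i + 2}: file not found: {p}")
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def load_timeseries(path: str | Path, subject_id: str = "") -> TimeSeriesMatrix:
    """Read a delimited node x time matrix.

    Delimiter (tab or comma), an optional header line, and an optional
    leading node-id column are auto-detected.
    """
    path = Path(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    raw = pd.read_csv(path, sep=sep, header=None)
    node_ids = None
    # header row: first row non-numeric
    if raw.iloc[0].apply(lambda v: isinstance(v, str)).any():
        raw = pd.read_csv(path, sep=sep)
    # node-id column: first column non-numeric
    first = raw.iloc[:, 0]
    if first.dtype == object or not np.issubdtype(first.dtype, np.number):
        node_ids = [str(v) for v in first]
        raw = raw.iloc[:, 1:]
    values = raw.to_numpy(dtype=float)
    return TimeSeriesMatrix(values=values, node_ids=node_ids, subject_id=subject_id)


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> None:
    np.savetxt(path, ts.values, delimiter="\t", fmt="%.8g")


def covariate_correlation(
    scores: Sequence[float], covariate: Sequence[float]
) -> tuple[float, float, int]:
    """Pearson R between a score and a covariate with its two-sided p."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("score and covariate vectors must match")
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation inputs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in scores or covariate")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def nodal_group_difference(
    cohort_a: Sequence[DegreeProfile],
    cohort_b: Sequence[DegreeProfile],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-node permutation test of mean degree difference, BH-FDR across nodes.

    Two-sided p-values use the add-one permutation convention, so the floor
    is 1/(n_perm + 1).
    """
    a = np.vstack([p.degrees for p in cohort_a]).astype(float)
    b = np.vstack([p.degrees for p in cohort_b]).astype(float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("cohorts have different node counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("both cohorts need at least 2 subjects")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-value floor is %.3g", n_perm, 1 / (n_perm + 1))
    pooled = np.vstack([a, b])
    na = a.shape[0]
    obs = a.mean(axis=0) - b.mean(axis=0)
    rng = rng_from(seed)
    exceed = np.zeros(pooled.shape[1])
    for _ in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        diff = pooled[idx[:na]].mean(axis=0) - pooled[idx[na:]].mean(axis=0)
        exceed += np.abs(diff) >= np.abs(obs) - 1e-12
    pvals = (exceed + 1.0) / (n_perm + 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "node": np.arange(pooled.shape[1]),
            "mean_diff": obs,
            "p_perm": pvals,
            "q_fdr": qvals,
        }
    )


@dataclass
class RunConfig:
    """Configuration for a full cohort run.

    ``primary_density`` and ``gamma`` default to the operating point used for
    community analysis (10% link density, resolution 1.5); ``densities`` is
    the sweep for k_D and graph metrics.
    """

    manifest: str | Path | CohortManifest = ""
    reference_group: str = "control"
    densities: list[float] = field(default_factory=lambda: [0.1])
    primary_density: float = 0.1
    gamma: float = 1.5
    n_reps: int = 100
    consensus_threshold: float = 0.9
    compute_metrics: bool = True
    compute_communities: bool = True
    nodal_n_perm: int = 1000
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if isinstance(self.manifest, CohortManifest):
            d["manifest"] = "<in-memory>"
        else:
            d["manifest"] = str(self.manifest)
        return d


@dataclass
class CohortReport:
    subjects: pd.DataFrame
    group_summary: pd.DataFrame
    covariate_corr: pd.DataFrame
    nodal_diff: dict[str, pd.DataFrame]
    baseline_partition: Partition | None
    group_allegiance: pd.DataFrame | None
    config: RunConfig


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_jsonable(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_cohort(config: RunConfig) -> CohortReport:
    """Execute the full analysis for one manifest; deterministic given seed."""
    manifest = (
        config.manifest
        if isinstance(config.manifest, CohortManifest)
        else read_manifest(config.manifest)
    )
    if config.reference_group not in manifest.groups:
        raise ValueError(
            f"reference group {config.reference_group!r} not in manifest groups {manifest.groups}"
        )
    if config.primary_density not in config.densities:
        raise ValueError("primary_density must be one of densities")

    rows = list(manifest.table.itertuples(index=False))
    all_ts = {
        r.subject_id: load_timeseries(manifest.path_for(pd.Series(r._asdict())), r.subject_id)
        for r in rows
    }
    n_nodes = {sid: ts.n_nodes for sid, ts in all_ts.items()}
    if len(set(n_nodes.values())) > 1:
        raise ValueError(f"subjects have differing node counts: {n_nodes}")

    corrs = {sid: correlation_matrix(ts) for sid, ts in all_ts.items()}
    records: list[dict] = []
    profiles: dict[float, dict[str, DegreeProfile]] = {}
    for d in config.densities:
        profiles[d] = {}
        for r in rows:
            g = threshold_to_density(corrs[r.subject_id], d)
            prof = degree(g, subject_id=r.subject_id)
            profiles[d][r.subject_id] = prof
            rec = {
                "subject_id": r.subject_id,
                "group": r.group,
                "density": d,
                "connected": is_fully_connected(g),
            }
            if config.compute_metrics:
                rec["mean_clustering"] = clustering_coefficient(g)[1]
                rec["global_efficiency"] = global_efficiency(g)
            records.append(rec)

    ref_ids = list(manifest.subjects(config.reference_group)["subject_id"])
    kd_by_subject: dict[tuple[str, float], float] = {}
    for d in config.densities:
        ref_map = reference_degree_map(
            [profiles[d][sid] for sid in ref_ids], cohort_id=config.reference_group
        )
        for rec in records:
            if rec["density"] != d:
                continue
            res = kd_index(profiles[d][rec["subject_id"]], ref_map)
            rec.update(kd=res.kd, kd_intercept=res.b, kd_r_fit=res.r_fit)
            kd_by_subject[(rec["subject_id"], d)] = res.kd

    baseline_partition = None
    allegiance_df = None
    if config.compute_communities:
        seeds = child_seeds(config.seed, len(rows) + 1)
        ref_mean_r = CorrelationMatrix(
            r=np.mean([corrs[sid].r for sid in ref_ids], axis=0)
        )
        baseline_graph = threshold_to_density(ref_mean_r, config.primary_density)
        baseline_partition = consensus_partition(
            baseline_graph,
            gamma=config.gamma,
            n_reps=config.n_reps,
            threshold=config.consensus_threshold,
            seed=seeds[-1],
        ).partition
        maps: dict[str, AllegianceMap] = {}
        for r, s in zip(rows, seeds[:-1]):
            g = threshold_to_density(corrs[r.subject_id], config.primary_density)
            part = consensus_partition(
                g,
                gamma=config.gamma,
                n_reps=config.n_reps,
                threshold=config.consensus_threshold,
                seed=s,
            ).partition
            subject_nmi = nmi(part, baseline_partition)
            maps[r.subject_id] = allegiance_map(part, baseline_partition)
            for rec in records:
                if rec["subject_id"] == r.subject_id and rec["density"] == config.primary_density:
                    rec["nmi_vs_baseline"] = subject_nmi
        alleg_rows = []
        for grp in manifest.groups:
            ids = list(manifest.subjects(grp)["subject_id"])
            mean_map = group_allegiance([maps[sid] for sid in ids])
            alleg_rows.append(
                pd.DataFrame(
                    {"group": grp, "node": np.arange(mean_map.size), "allegiance": mean_map}
                )
            )
        allegiance_df = pd.concat(alleg_rows, ignore_index=True)

    subjects_df = pd.DataFrame(records)
    manifest_cols = manifest.table[["subject_id"] + manifest.covariates]
    subjects_df = subjects_df.merge(manifest_cols, on="subject_id", how="left")

    value_cols = [
        c
        for c in ("kd", "mean_clustering", "global_efficiency", "nmi_vs_baseline")
        if c in subjects_df.columns
    ]
    group_summary = (
        subjects_df.groupby(["group", "density"])[value_cols]
        .agg(["mean", "sem"])
        .reset_index()
    )
    group_summary.columns = [
        "_".join(c).rstrip("_") for c in group_summary.columns.to_flat_index()
    ]

    cov_rows = []
    for cov in manifest.covariates:
        for grp in manifest.groups:
            sub = subjects_df[
                (subjects_df["group"] == grp)
                & (subjects_df["density"] == config.primary_density)
            ]
            vals = pd.to_numeric(sub[cov], errors="coerce")
            kd_vals = sub["kd"]
            ok = vals.notna() & kd_vals.notna()
            if ok.sum() < 3 or np.ptp(vals[ok]) == 0 or np.ptp(kd_vals[ok]) == 0:
                continue
            r_val, p_val, n = covariate_correlation(kd_vals[ok], vals[ok])
            cov_rows.append(
                {"covariate": cov, "group": grp, "R": r_val, "p": p_val, "n": n}
            )
    covariate_df = pd.DataFrame(cov_rows, columns=["covariate", "group", "R", "p", "n"])

    nodal = {}
    perm_seeds = child_seeds(config.seed + 1, max(1, len(manifest.groups)))
    ref_profiles = [profiles[config.primary_density][sid] for sid in ref_ids]
    for i, grp in enumerate(g for g in manifest.groups if g != config.reference_group):
        ids = list(manifest.subjects(grp)["subject_id"])
        if len(ids) < 2 or len(ref_ids) < 2:
            continue
        grp_profiles = [profiles[config.primary_density][sid] for sid in ids]
        nodal[grp] = nodal_group_difference(
            grp_profiles, ref_profiles, n_perm=config.nodal_n_perm, seed=perm_seeds[i]
        )

    return CohortReport(
        subjects=subjects_df,
        group_summary=group_summary,
        covariate_corr=covariate_df,
        nodal_diff=nodal,
        baseline_partition=baseline_partition,
        group_allegiance=allegiance_df,
        config=config,
    )


def write_report(report: CohortReport, out_dir: str | Path) -> list[Path]:
    """Write all report tables as TSV plus a JSON config echo; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _tsv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.8g")
        written.append(p)

    _tsv(report.subjects, "subjects.tsv")
    _tsv(report.group_summary, "group_summary.tsv")
    _tsv(report.covariate_corr, "covariate_correlations.tsv")
    for grp, df in report.nodal_diff.items():
        _tsv(df, f"nodal_diff_{grp}.tsv")
    if report.baseline_partition is not None:
        _tsv(
            pd.DataFrame(
                {
                    "node": np.arange(report.baseline_partition.n_nodes),
                    "module": report.baseline_partition.labels,
                }
            ),
            "baseline_partition.tsv",
        )
    if report.group_allegiance is not None:
        _tsv(report.group_allegiance, "group_allegiance.tsv")
    meta = {
        "config": report.config.to_jsonable(),
        "config_hash": _config_hash(report.config),
        "seed": report.config.seed,
    }
    p = out / "run_config.json"
    p.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    written.append(p)
    return written
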