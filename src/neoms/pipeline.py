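"""End-to-end orchestration of the two analysis tracks.

The *group* track preprocesses every epoch, extracts individual maps,
pools them per (age group x sleep state) cell into group-level maps,
matches map order across cells, backfits the group maps to every member
epoch and runs the per-cell statistics (metrics, syntax tests, pairwise
TANOVA between cells).

The *individual* track extracts per-epoch maps, backfits them to their
own epoch, and summarizes each epoch by metrics that do not depend on a
shared map identity: overall mean duration, overall mean occurrence and
the Hurst exponent; these are then associated with PMA per sleep state.

All randomness derives from one root seed through fixed spawn keys, so
a rerun with the same seed reproduces every number.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from neoms import backfit as bf
from neoms import microstates as ms
from neoms import syntax as sx
from neoms.epoch import EEGEpoch
from neoms.maturation import hurst_dfa, metric_age_association, tanova_similarity
from neoms.preprocess import preprocess_epoch
from neoms.synthetic import AGE_GROUPS, CohortRecord

logger = logging.getLogger("neoms")

SLEEP_STATES = ("QS", "NQS")


def child_seed(root: int, *key: int) -> int:
    """Deterministic child seed below 2**31 from a root and a spawn key."""
    ss = np.random.SeedSequence(entropy=int(root), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full pipeline (defaults = study values)."""

    low_hz: float = 0.2
    high_hz: float = 25.0
    filter_order: int = 7
    fs_analysis: float = 100.0
    epoch_s: float = 300.0
    k_min: int = 3
    k_max: int = 15
    k_fixed: int = 4
    select_k: bool = False  # individual track: choose k per epoch by KL
    n_restarts: int = 20
    smooth_window_ms: float = 30.0
    smooth_penalty: float = 1.0
    n_perm_tanova: int = 5000
    n_perm_chisq: int = 5000
    age_boundaries: tuple[float, float, float] = (32.0, 34.0, 37.0)
    seed: int = 0
    manifest: str | None = None
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "age_boundaries" in raw:
            raw["age_boundaries"] = tuple(raw["age_boundaries"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["age_boundaries"] = list(self.age_boundaries)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class GroupResults:
    cell_maps: dict[tuple[str, str], ms.MapSet]
    cell_gev: pd.DataFrame
    metrics: pd.DataFrame  # one row per (epoch, map) + per-epoch summary rows
    syntax_edges: pd.DataFrame  # Fig-8-style edge list per cell
    syntax_chisq: pd.DataFrame
    tanova: pd.DataFrame
    seeds: dict = field(default_factory=dict)


@dataclass
class IndividualResults:
    per_epoch: pd.DataFrame
    associations: pd.DataFrame | None
    tidy: pd.DataFrame | None
    seeds: dict = field(default_factory=dict)


def _individual_maps(
    epoch: EEGEpoch, k: int, seed: int, n_restarts: int
) -> ms.ClusteringResult:
    gfp = ms.global_field_power(epoch)
    peaks = ms.gfp_peaks(gfp)
    samples = epoch.data[:, peaks].T
    return ms.modified_kmeans(samples, k, n_restarts=n_restarts, seed=seed)


def run_group_analysis(
    cohort: list[tuple[CohortRecord, EEGEpoch]],
    config: AnalysisConfig | None = None,
) -> GroupResults:
    """Group-level track: group maps per cell, metrics, syntax, TANOVA."""
    config = config or AnalysisConfig()
    root = config.seed
    channel_sets = {ep.channel_names for _, ep in cohort}
    if len(channel_sets) != 1:
        raise ValueError("mismatched channel sets across epochs")
    prepped = [
        preprocess_epoch(
            ep, config.low_hz, config.high_hz, config.filter_order, config.fs_analysis
        )
        for _, ep in cohort
    ]
    indiv = [
        _individual_maps(p, config.k_fixed, child_seed(root, 1, i), config.n_restarts)
        for i, p in enumerate(prepped)
    ]
    cells: dict[tuple[str, str], list[int]] = {}
    for i, (rec, _) in enumerate(cohort):
        cells.setdefault((rec.age_group, rec.sleep_state), []).append(i)
    expected = [(g, s) for g in AGE_GROUPS for s in SLEEP_STATES]
    for cell in expected:
        if cell not in cells:
            warnings.warn(f"empty cell {cell}: skipped", stacklevel=2)
    order = [c for c in expected if c in cells] + sorted(
        c for c in cells if c not in expected
    )
    cell_maps: dict[tuple[str, str], ms.MapSet] = {}
    for ci, cell in enumerate(order):
        sets = [indiv[i].mapset for i in cells[cell]]
        cell_maps[cell] = ms.group_maps(
            sets, config.k_fixed, seed=child_seed(root, 2, ci), n_restarts=config.n_restarts
        )
    ref_cell = order[0]
    others = [cell_maps[c] for c in order[1:]]
    reordered, _ = ms.match_map_order(cell_maps[ref_cell], others)
    for c, msr in zip(order[1:], reordered):
        cell_maps[c] = msr

    metric_rows, gev_rows, edge_frames, chisq_rows = [], [], [], []
    for ci, cell in enumerate(order):
        group, state = cell
        mapset = cell_maps[cell]
        stats_per_epoch, runs_per_epoch, gevs = [], [], []
        for i in cells[cell]:
            rec = cohort[i][0]
            labels = bf.backfit(
                prepped[i], mapset, config.smooth_window_ms, config.smooth_penalty
            )
            runs = bf.segment_runs(labels)
            met = bf.ms_metrics(runs)
            gev = ms.compute_gev(prepped[i], mapset, labels.labels)
            gevs.append(gev)
            runs_per_epoch.append(runs)
            stats_per_epoch.append(sx.transition_stats(runs, config.k_fixed))
            base = {
                "subject_id": rec.subject_id,
                "ga_weeks": rec.ga_weeks,
                "pma_weeks": rec.pma_weeks,
                "sleep_state": state,
                "age_group": group,
            }
            for m in range(config.k_fixed):
                metric_rows.append(
                    {
                        **base,
                        "map": m,
                        "duration_s": met.duration[m],
                        "occurrence_hz": met.occurrence[m],
                        "coverage": met.coverage[m],
                        "gev": gev,
                        "row_kind": "per_map",
                    }
                )
            metric_rows.append(
                {
                    **base,
                    "map": -1,
                    "duration_s": met.mean_duration,
                    "occurrence_hz": met.mean_occurrence,
                    "coverage": 1.0,
                    "gev": gev,
                    "row_kind": "epoch_summary",
                }
            )
        gev_rows.append(
            {"age_group": group, "sleep_state": state, "gev_mean": float(np.mean(gevs)),
             "gev_sd": float(np.std(gevs)), "n_epochs": len(gevs)}
        )
        if len(stats_per_epoch) >= 3:
            edges = sx.transition_group_test(stats_per_epoch)
            edges.insert(0, "age_group", group)
            edges.insert(1, "sleep_state", state)
            edge_frames.append(edges)
        chi2, p = sx.syntax_chisq_test_pooled(
            runs_per_epoch, config.k_fixed, config.n_perm_chisq, child_seed(root, 3, ci)
        )
        chisq_rows.append(
            {"age_group": group, "sleep_state": state, "chi2": chi2, "p": p,
             "n_perm": config.n_perm_chisq}
        )

    tanova_rows = []
    for (ca, cb) in combinations(range(len(order)), 2):
        for m in range(config.k_fixed):
            res = tanova_similarity(
                cell_maps[order[ca]].maps[m],
                cell_maps[order[cb]].maps[m],
                n_perm=config.n_perm_tanova,
                seed=child_seed(root, 4, ca, cb, m),
            )
            tanova_rows.append(
                {
                    "group_a": "/".join(order[ca]),
                    "group_b": "/".join(order[cb]),
                    "map": m,
                    "similarity": res.effect_size,
                    "p": res.p,
                }
            )
    results = GroupResults(
        cell_maps=cell_maps,
        cell_gev=pd.DataFrame(gev_rows),
        metrics=pd.DataFrame(metric_rows),
        syntax_edges=(
            pd.concat(edge_frames, ignore_index=True) if edge_frames else pd.DataFrame()
        ),
        syntax_chisq=pd.DataFrame(chisq_rows),
        tanova=pd.DataFrame(tanova_rows),
        seeds={"root": root},
    )
    if config.out_dir:
        _write_group(results, config)
    return results


def run_individual_analysis(
    cohort: list[tuple[CohortRecord, EEGEpoch]],
    config: AnalysisConfig | None = None,
) -> IndividualResults:
    """Individual track: per-epoch maps, individual metrics, PMA trends."""
    config = config or AnalysisConfig()
    if not cohort:
        raise ValueError("empty cohort")
    root = config.seed
    rows = []
    for i, (rec, ep) in enumerate(cohort):
        p = preprocess_epoch(
            ep, config.low_hz, config.high_hz, config.filter_order, config.fs_analysis
        )
        gfp = ms.global_field_power(p)
        peaks = ms.gfp_peaks(gfp)
        samples = p.data[:, peaks].T
        k = config.k_fixed
        k_kl = None
        if config.select_k:
            try:
                k_kl, _, _ = ms.select_k_kl(
                    samples, config.k_min, config.k_max,
                    seed=child_seed(root, 5, i), n_restarts=config.n_restarts,
                )
                k = k_kl
            except ValueError:
                logger.warning(
                    "epoch %d: KL selection failed, falling back to k=%d", i, k
                )
        res = ms.modified_kmeans(
            samples, k, n_restarts=config.n_restarts, seed=child_seed(root, 6, i)
        )
        labels = bf.backfit(p, res.mapset, config.smooth_window_ms, config.smooth_penalty)
        runs = bf.segment_runs(labels)
        met = bf.ms_metrics(runs)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "ga_weeks": rec.ga_weeks,
                "pma_weeks": rec.pma_weeks,
                "sleep_state": rec.sleep_state,
                "age_group": rec.age_group,
                "k": k,
                "k_kl": k_kl,
                "mean_duration": met.mean_duration,
                "mean_occurrence": met.mean_occurrence,
                "hurst": hurst_dfa(labels),
                "gev": ms.compute_gev(p, res.mapset, labels.labels),
            }
        )
    per_epoch = pd.DataFrame(rows)
    associations = tidy = None
    counts = per_epoch.groupby("sleep_state").size()
    if (counts >= 3).all() and len(counts) > 0:
        try:
            associations, tidy = metric_age_association(per_epoch)
        except ValueError as err:
            warnings.warn(f"association skipped: {err}", stacklevel=2)
    else:
        warnings.warn("association skipped: fewer than 3 epochs per sleep state",
                      stacklevel=2)
    results = IndividualResults(
        per_epoch=per_epoch, associations=associations, tidy=tidy, seeds={"root": root}
    )
    if config.out_dir:
        _write_individual(results, config)
    return results


def _write_group(results: GroupResults, config: AnalysisConfig) -> None:
    from neoms.io import write_mapset

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (group, state), mapset in results.cell_maps.items():
        write_mapset(mapset, out / f"maps_{group}_{state}.csv", group=group, state=state)
    results.cell_gev.to_csv(out / "cell_gev.csv", index=False)
    results.metrics.to_csv(out / "metrics.csv", index=False)
    results.syntax_edges.to_csv(out / "syntax_edges.csv", index=False)
    results.syntax_chisq.to_csv(out / "syntax_chisq.csv", index=False)
    results.tanova.to_csv(out / "tanova.csv", index=False)
    config.to_yaml(out / "config_used.yaml")


def _write_individual(results: IndividualResults, config: AnalysisConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.per_epoch.to_csv(out / "individual_metrics.csv", index=False)
    if results.associations is not None:
        results.associations.to_csv(out / "age_associations.csv", index=False)
    if results.tidy is not None:
        results.tidy.to_csv(out / "tidy_long.csv", index=False)
    config.to_yaml(out / "config_used.yaml")
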