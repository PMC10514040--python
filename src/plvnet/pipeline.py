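"""End-to-end orchestration: simulate -> connectivity -> graphs -> statistics
-> classification, with a serializable config, per-stage seed fan-out and a
deterministic results layout.

The config's scientific defaults are the study conditions (256 Hz, 20
epochs of 4 s, six sub-bands, surrogate M=100 at alpha=0.05, density grid
0.01..0.50 with features at 0.08, 29+14 subjects); the *extent* of a run —
how many moods, target frequencies and bands are actually simulated — is
set per run, since the full 24-cell x 6-band design is a cluster-scale
computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import assemble_features, evaluate_classifiers
from .connectivity import connectivity_for_recording
from .graph import (
    DEFAULT_DENSITY_GRID,
    FEATURE_DENSITY,
    metrics_over_density_sweep,
)
from .montage import biosemi64
from .preprocess import BAND_BY_NAME
from .stats import compare_edges, compare_global, compare_node_metrics
from .synth import (
    MOODS,
    TARGET_FREQUENCIES,
    default_coupling_plan,
    generate_cohort,
)


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run; serializes losslessly to YAML."""

    # cohort / acquisition
    n_ls: int = 29
    n_hs: int = 14
    fs: float = 256.0
    n_epochs: int = 20
    epoch_len: float = 4.0
    snr_db: float = 0.0
    # run extent (full design: all moods, 8 frequencies, 6 bands)
    moods: tuple[str, ...] = MOODS
    target_frequencies: tuple[float, ...] = TARGET_FREQUENCIES
    bands: tuple[str, ...] = tuple(BAND_BY_NAME)
    # connectivity
    n_surrogates: int = 100
    alpha: float = 0.05
    # graphs
    density_grid: tuple[float, ...] = DEFAULT_DENSITY_GRID
    feature_density: float = FEATURE_DENSITY
    # stats
    fdr_q: float = 0.05
    node_alpha: float = 0.05
    strong_alpha: float = 0.001
    # classification
    k_features: int = 10
    classifiers: tuple[str, ...] = ("dt", "knn", "lda", "svm", "rusboost")

    def __post_init__(self) -> None:
        if self.feature_density not in {round(d, 6) for d in map(float, self.density_grid)}:
            raise ValueError(
                f"feature density {self.feature_density} absent from the density grid"
            )
        for b in self.bands:
            if b not in BAND_BY_NAME:
                raise ValueError(f"unknown band {b!r}")

    def to_yaml(self) -> str:
        def native(v):
            if isinstance(v, (tuple, list)):
                return [native(x) for x in v]
            if isinstance(v, np.floating):
                return float(v)
            if isinstance(v, np.integer):
                return int(v)
            return v

        d = {k: native(v) for k, v in asdict(self).items()}
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        for k in ("moods", "target_frequencies", "bands", "density_grid", "classifiers"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig, seed: int) -> dict:
    return {"config_hash": config.config_hash, "seed": seed, "plvnet_version": __version__}


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    seed: int = 0,
    stages: tuple[str, ...] = ("simulate", "connectivity", "graph", "stats", "classify"),
) -> dict:
    """Run the requested stages and write CSV tables under ``out_dir``.

    Returns a dict with the in-memory products (pruned PLV matrices, metric
    tables, comparison tables, classification table). Deterministic under a
    fixed seed: the root seed is fanned out to (stage, subject, condition,
    band) RNG streams via a SeedSequence tree.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = biosemi64()
    plan = default_coupling_plan(montage)
    root = np.random.SeedSequence(seed)
    surrogate_seed = root.spawn(1)[0]
    bands = [BAND_BY_NAME[b] for b in config.bands]
    results: dict = {"config": config, "provenance": _provenance(config, seed)}
    (out / "provenance.json").write_text(json.dumps(results["provenance"], indent=1))
    (out / "config.yaml").write_text(config.to_yaml())

    if "simulate" not in stages:
        return results

    recordings = list(
        generate_cohort(
            n_ls=config.n_ls,
            n_hs=config.n_hs,
            plan=plan,
            montage=montage,
            moods=config.moods,
            target_frequencies=config.target_frequencies,
            fs=config.fs,
            n_epochs=config.n_epochs,
            epoch_len=config.epoch_len,
            seed=seed,
            snr_db=config.snr_db,
            bands=bands,
            keep_truth=False,
        )
    )
    subjects = sorted({(r.subject_id, r.group) for r in recordings})
    results["n_recordings"] = len(recordings)

    if "connectivity" not in stages:
        return results

    conn_dir = out / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    plv: dict = {}
    surr_rng = np.random.default_rng(surrogate_seed)
    for rec in recordings:
        for band in bands:
            mat = connectivity_for_recording(
                rec,
                band,
                M=config.n_surrogates,
                alpha=config.alpha,
                seed=surr_rng,
            )
            plv[(rec.subject_id, rec.condition.mood, rec.condition.target_frequency, band.name)] = mat
    results["plv"] = plv
    edge_rows = []
    for (sid, mood, tf, bname), mat in plv.items():
        iu, ju = np.triu_indices(mat.values.shape[0], k=1)
        keep = mat.values[iu, ju] > 0
        for i, j in zip(iu[keep], ju[keep]):
            edge_rows.append(
                (sid, mood, tf, bname, mat.labels[i], mat.labels[j], mat.values[i, j], mat.p_values[i, j])
            )
    pd.DataFrame(
        edge_rows,
        columns=["subject", "mood", "target_frequency", "band", "channel_i", "channel_j", "plv", "p_surrogate"],
    ).to_csv(conn_dir / "edges.csv", index=False)

    if "graph" not in stages:
        return results

    graph_dir = out / "graphs"
    graph_dir.mkdir(exist_ok=True)
    group_of = {sid: grp for sid, grp in subjects}
    node_rows, ge_rows = [], []
    metric_store: dict = {}
    for (sid, mood, tf, bname), mat in plv.items():
        sweep = metrics_over_density_sweep(mat.values, config.density_grid, labels=mat.labels)
        metric_store[(sid, mood, tf, bname)] = sweep
        gm = sweep[float(config.feature_density)]
        for c, lab in enumerate(mat.labels):
            node_rows.append(
                (sid, group_of[sid], mood, tf, bname, config.feature_density, lab, gm.strength[c], gm.clustering[c])
            )
        for d, g in sweep.items():
            ge_rows.append((sid, group_of[sid], mood, tf, bname, d, g.global_efficiency))
    node_df = pd.DataFrame(
        node_rows,
        columns=["subject", "group", "mood", "target_frequency", "band", "density", "channel", "strength", "cc"],
    )
    ge_df = pd.DataFrame(
        ge_rows, columns=["subject", "group", "mood", "target_frequency", "band", "density", "ge"]
    )
    node_df.to_csv(graph_dir / "node_metrics.csv", index=False)
    ge_df.to_csv(graph_dir / "global_efficiency.csv", index=False)
    results["node_metrics"] = node_df
    results["global_efficiency"] = ge_df

    if "stats" not in stages:
        return results

    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    sids = [sid for sid, _ in subjects]
    groups = np.array([group_of[s] for s in sids])
    edge_tabs, node_tabs, ge_tabs = [], [], []
    for mood in config.moods:
        for tf in config.target_frequencies:
            for band in bands:
                stack = np.stack([plv[(s, mood, tf, band.name)].values for s in sids])
                tab = compare_edges(stack, groups, montage.labels, q=config.fdr_q)
                tab.insert(0, "band", band.name)
                tab.insert(0, "target_frequency", tf)
                tab.insert(0, "mood", mood)
                edge_tabs.append(tab)
                for metric in ("strength", "cc"):
                    sub = node_df[
                        (node_df["mood"] == mood)
                        & (node_df["target_frequency"] == tf)
                        & (node_df["band"] == band.name)
                    ].pivot(index="subject", columns="channel", values=metric)
                    sub = sub.loc[sids, list(montage.labels)]
                    ntab = compare_node_metrics(
                        sub.to_numpy(), groups, montage.labels,
                        alpha=config.node_alpha, strong_alpha=config.strong_alpha,
                        check_normality=False,
                    )
                    ntab.insert(0, "metric", metric)
                    ntab.insert(0, "band", band.name)
                    ntab.insert(0, "target_frequency", tf)
                    ntab.insert(0, "mood", mood)
                    node_tabs.append(ntab)
                ge_sub = ge_df[
                    (ge_df["mood"] == mood)
                    & (ge_df["target_frequency"] == tf)
                    & (ge_df["band"] == band.name)
                ].pivot(index="subject", columns="density", values="ge").loc[sids]
                gtab = compare_global(ge_sub.to_numpy(), groups, ge_sub.columns.to_numpy())
                gtab.insert(0, "band", band.name)
                gtab.insert(0, "target_frequency", tf)
                gtab.insert(0, "mood", mood)
                ge_tabs.append(gtab)
    results["edge_stats"] = pd.concat(edge_tabs, ignore_index=True)
    results["node_stats"] = pd.concat(node_tabs, ignore_index=True)
    results["ge_stats"] = pd.concat(ge_tabs, ignore_index=True)
    results["edge_stats"].to_csv(stats_dir / "edge_comparisons.csv", index=False)
    results["node_stats"].to_csv(stats_dir / "node_comparisons.csv", index=False)
    results["ge_stats"].to_csv(stats_dir / "ge_comparisons.csv", index=False)

    if "classify" not in stages:
        return results

    cls_dir = out / "classification"
    cls_dir.mkdir(exist_ok=True)
    long_rows = []
    for (sid, mood, tf, bname), sweep in metric_store.items():
        gm = sweep[float(config.feature_density)]
        for c, lab in enumerate(montage.labels):
            long_rows.append((sid, group_of[sid], mood, bname, tf, lab, "strength", gm.strength[c]))
            long_rows.append((sid, group_of[sid], mood, bname, tf, lab, "cc", gm.clustering[c]))
        long_rows.append((sid, group_of[sid], mood, bname, tf, "GLOBAL", "ge", gm.global_efficiency))
    long_df = pd.DataFrame(
        long_rows,
        columns=["subject", "group", "mood", "band", "target_frequency", "channel", "metric", "value"],
    )
    cls_tabs = []
    for mood in config.moods:
        feats = assemble_features(
            long_df[long_df["mood"] == mood],
            montage.labels,
            tuple(config.bands),
            tuple(config.target_frequencies),
        )
        tab = evaluate_classifiers(
            feats, classifiers=config.classifiers, k=config.k_features, seed=seed
        )
        tab.insert(0, "mood", mood)
        cls_tabs.append(tab)
    results["classification"] = pd.concat(cls_tabs, ignore_index=True)
    results["classification"].to_csv(cls_dir / "metrics.csv", index=False)
    return results
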