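"""End-to-end orchestration: simulate -> coherence -> networks -> metrics
-> statistics, plus all interchange formats.

Every stage reads and writes plain-text files (CSV matrices, tidy CSV
tables, BrainNet Viewer .node/.edge exports), so externally produced
coherence matrices can enter the pipeline at the network stage. A single
master seed deterministically derives every stage seed (documented in
:func:`derive_stage_seeds`), and a JSON run manifest records the config,
per-stage seeds and output file hashes so a run can be reproduced
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as gm
from . import network as nw
from . import spectral as sp
from . import stats as st
from . import synthetic as sd

logger = logging.getLogger("cohnet")

__version__ = "0.1.0"

#: Fixed stage order used for seed derivation.
STAGES = ("behavior", "sources", "coherence", "network", "metrics",
          "compare", "edges")


def derive_stage_seeds(master_seed: int) -> dict[str, int]:
    """One independent 31-bit seed per pipeline stage.

    Children of ``np.random.SeedSequence(master_seed)`` are spawned in
    the fixed :data:`STAGES` order; each stage seed is the first word of
    the child's generated state, reduced mod 2**31.
    """
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(STAGES, children)}


# ---------------------------------------------------------------------------
# Matrix and table I/O
# ---------------------------------------------------------------------------

def write_matrix(matrix: np.ndarray, path, labels: list[str] | None = None
                 ) -> None:
    """Dense CSV with header labels (atlas indices by default)."""
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    cols = labels if labels is not None else [str(i) for i in
                                              range(m.shape[1])]
    pd.DataFrame(m, columns=cols).to_csv(path, index=False)


def read_matrix(path) -> np.ndarray:
    """Read a dense numeric CSV written by :func:`write_matrix`.

    Ragged rows or non-numeric cells raise with the offending row and
    column named.
    """
    df = pd.read_csv(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {bad[0]}, column {df.columns[bad[1]]!r}"
            f" in {path}")
    return numeric.to_numpy(dtype=float)


def export_brainnet(net: nw.BinaryNetwork, atlas: sd.RoiAtlas,
                    node_metric: np.ndarray, node_path, edge_path,
                    node_color: np.ndarray | None = None) -> None:
    """Write BrainNet Viewer .node and .edge text files.

    .node: six whitespace-separated columns per node -- x y z color size
    label -- with coordinates from the atlas's nominal centroids, color
    an integer class (module id; all 1 if not given) and size the
    supplied per-node metric. .edge: dense whitespace-separated
    adjacency, n rows x n columns.
    """
    if atlas.size != net.n_nodes:
        raise ValueError("atlas size does not match network")
    metric = np.asarray(node_metric, dtype=float)
    if metric.shape != (net.n_nodes,):
        raise ValueError("node_metric must have one value per node")
    color = (np.ones(net.n_nodes, dtype=int) if node_color is None
             else np.asarray(node_color, dtype=int) + 1)
    with open(node_path, "w") as fh:
        for e, c, s in zip(atlas.entries, color, metric):
            label = f"BA{e.ba_id}.{'L' if e.hemisphere == 'left' else 'R'}"
            fh.write(f"{e.x:.1f}\t{e.y:.1f}\t{e.z:.1f}\t{c}\t{s:.6g}"
                     f"\t{label}\n")
    np.savetxt(edge_path, net.adjacency, fmt="%d", delimiter="\t")


def read_brainnet_edge(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int)


# ---------------------------------------------------------------------------
# Configuration and manifest
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Complete, serializable description of one pipeline run."""

    design: sd.ExperimentDesign = field(default_factory=sd.ExperimentDesign)
    scenario: str = "strong_alpha_frontoparietal"  # or "null"
    spectral: sp.SpectralConfig = field(default_factory=sp.SpectralConfig)
    grid: nw.SparsityGrid = field(default_factory=nw.SparsityGrid)
    null_model: gm.NullModelConfig = field(default_factory=gm.NullModelConfig)
    edge_permutations: int = 5000
    metric_permutations: int = 30000
    alpha: float = 0.05
    master_seed: int = 0
    output_dir: str = "cohnet_output"
    log_level: str = "INFO"
    level_pairs: tuple = (("extremely_hard", "extremely_light"),)
    compare_bands: tuple = ("alpha", "beta")
    write_sources: bool = False         # per-epoch CSVs are bulky; opt-in
    nodal_comparisons: bool = False
    compute_sigma: bool = False         # surrogate ensemble is costly
    modularity_restarts: int = 20

    def coupling_spec(self) -> sd.CouplingSpec:
        atlas = sd.default_roi_atlas()
        if self.scenario == "strong_alpha_frontoparietal":
            return sd.scenario_strong_alpha_frontoparietal(atlas)
        if self.scenario == "null":
            return sd.scenario_null(atlas.size)
        raise ValueError(f"unknown scenario {self.scenario!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spectral"]["bands"] = {k: list(v) for k, v in
                                  self.spectral.bands.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "design" in d:
            dd = dict(d["design"])
            if "levels" in dd:
                dd["levels"] = tuple(dd["levels"])
            d["design"] = sd.ExperimentDesign(**dd)
        if "spectral" in d:
            ss = dict(d["spectral"])
            if "bands" in ss:
                ss["bands"] = {k: tuple(v) for k, v in ss["bands"].items()}
            d["spectral"] = sp.SpectralConfig(**ss)
        if "grid" in d:
            gv = d["grid"]["values"] if isinstance(d["grid"], dict) \
                else d["grid"]
            d["grid"] = nw.SparsityGrid(tuple(gv))
        if "null_model" in d:
            d["null_model"] = gm.NullModelConfig(**d["null_model"])
        if "level_pairs" in d:
            d["level_pairs"] = tuple(tuple(p) for p in d["level_pairs"])
        if "compare_bands" in d:
            d["compare_bands"] = tuple(d["compare_bands"])
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_seeds: dict
    file_hashes: dict
    timestamps: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def compute_subject_coherences(epochs: list[sd.EpochedSourceSeries],
                               config: sp.SpectralConfig,
                               levels: tuple[str, ...]
                               ) -> dict[tuple[int, str, str],
                                         sp.CoherenceMatrix]:
    """One band-coherence matrix per (subject, level, band), pooling the
    segments of all trials of that subject x level."""
    by_cell: dict[tuple[int, str], list] = {}
    for e in epochs:
        by_cell.setdefault((e.subject, e.level), []).append(e)
    out = {}
    for (subj, level), cell_epochs in sorted(by_cell.items()):
        for band, coh in sp.coherence_matrices(cell_epochs, config).items():
            out[(subj, level, band)] = coh
    return out


def metric_tables(coherences: dict, grid: nw.SparsityGrid, seed: int,
                  compute_sigma: bool = False,
                  null_model: gm.NullModelConfig | None = None,
                  modularity_restarts: int = 20,
                  nodal: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy global and nodal metric tables over the sparsity grid.

    Global rows: (subject, level, band, sparsity, metric, value);
    nodal rows additionally carry a node column.
    """
    g_rows, n_rows = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # disconnected-network warnings
        for (subj, level, band), coh in sorted(coherences.items()):
            for net in nw.sparsity_sweep(coh, grid):
                g = gm.global_metrics(
                    net, seed=seed, compute_sigma=compute_sigma,
                    null_config=null_model,
                    modularity_restarts=modularity_restarts)
                base = dict(subject=subj, level=level, band=band,
                            sparsity=net.sparsity)
                for name, value in (
                        ("clustering_C", g.clustering_C),
                        ("path_length_L", g.path_length_L),
                        ("efficiency_global_Eg", g.efficiency_global_Eg),
                        ("efficiency_local_Eloc", g.efficiency_local_Eloc),
                        ("modularity_Q", g.modularity_Q),
                        ("small_world_ratio", g.small_world_ratio),
                        ("small_world_sigma", g.small_world_sigma),
                        ("inverse_path_length", g.inverse_path_length)):
                    if value is not None:
                        g_rows.append(dict(base, metric=name, value=value))
                if nodal:
                    nm = gm.nodal_metrics(net)
                    for name, vec in (("degree", nm.degree),
                                      ("betweenness", nm.betweenness),
                                      ("nodal_efficiency",
                                       nm.nodal_efficiency)):
                        for node, value in enumerate(vec):
                            n_rows.append(dict(base, node=node, metric=name,
                                               value=float(value)))
    return pd.DataFrame(g_rows), pd.DataFrame(n_rows)


def metric_auc(global_table: pd.DataFrame) -> pd.DataFrame:
    """Area under the metric-vs-sparsity curve (trapezoid), one row per
    (subject, level, band, metric)."""
    def _auc(grp):
        grp = grp.sort_values("sparsity")
        return float(np.trapezoid(grp["value"], grp["sparsity"]))
    out = (global_table.groupby(["subject", "level", "band", "metric"])
           .apply(_auc, include_groups=False).rename("auc").reset_index())
    return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order, writing all interchange files and a
    JSON manifest to ``config.output_dir``."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    seeds = derive_stage_seeds(config.master_seed)
    timestamps = {}
    atlas = sd.default_roi_atlas()
    labels = atlas.labels()

    if config.design.n_subjects < 4:
        logger.warning("only %d subjects: permutation tests will be "
                       "underpowered", config.design.n_subjects)

    def _stage(name):
        timestamps[name] = time.time() - t0
        logger.info("stage %s at %.1fs", name, timestamps[name])

    # behavior
    _stage("behavior")
    records = sd.generate_behavior(config.design, seed=seeds["behavior"])
    behavior = sd.behavior_to_frame(records)
    behavior["pct_mvc"] = [st.percent_mvc(f, m) for f, m in
                           zip(behavior["force_N"], behavior["mvc_N"])]
    behavior.to_csv(out / "behavior.csv", index=False)
    atlas.to_frame().to_csv(out / "atlas.csv", index=False)

    for response, label in (("force_N", "force"), ("rppc", "rppc")):
        anova = st.anova_randomized_block(behavior, response,
                                          levels=config.design.levels)
        anova.to_csv(out / f"anova_{label}.csv", index=False)
        table = st.cell_means(behavior, response, config.design.levels)
        mse = float(anova.loc[anova["source"] == "error", "ms"].iloc[0])
        dfe = int(anova.loc[anova["source"] == "error", "df"].iloc[0])
        tk = st.tukey_hsd(table, mse, dfe, config.design.n_subjects,
                          alpha=config.alpha)
        tk.table.to_csv(out / f"tukey_{label}.csv", index=False)

    # sources
    _stage("sources")
    spec = config.coupling_spec()
    epochs = sd.generate_sources(config.design, spec, seeds["sources"])
    if config.write_sources:
        manifest_rows = []
        src_dir = out / "sources"
        src_dir.mkdir(exist_ok=True)
        for e in epochs:
            fn = f"sub{e.subject:02d}_{e.level}_trial{e.trial}.csv"
            write_matrix(e.data, src_dir / fn, labels)
            manifest_rows.append(dict(file=f"sources/{fn}",
                                      subject=e.subject, level=e.level,
                                      trial=e.trial,
                                      sample_rate=e.sample_rate))
        pd.DataFrame(manifest_rows).to_csv(out / "sources_manifest.csv",
                                           index=False)

    # coherence
    _stage("coherence")
    coherences = compute_subject_coherences(epochs, config.spectral,
                                            config.design.levels)
    coh_dir = out / "coherence"
    coh_dir.mkdir(exist_ok=True)
    for (subj, level, band), coh in sorted(coherences.items()):
        write_matrix(coh.C,
                     coh_dir / f"sub{subj:02d}_{level}_{band}.csv", labels)

    # networks (exported at the middle grid value for visualization)
    _stage("network")
    mid = config.grid.values[len(config.grid.values) // 2]
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for (subj, level, band), coh in sorted(coherences.items()):
        net = nw.binarize_by_sparsity(coh, mid, node_labels=labels)
        stem = f"sub{subj:02d}_{level}_{band}_s{int(round(mid * 100)):02d}"
        write_matrix(net.adjacency, net_dir / (stem + ".csv"), labels)
        edges = net.edge_list()
        pd.DataFrame({"node_i": edges[:, 0], "node_j": edges[:, 1],
                      "weight": 1}).to_csv(net_dir / (stem + ".tsv"),
                                           sep="\t", index=False)

    # metrics
    _stage("metrics")
    global_table, nodal_table = metric_tables(
        coherences, config.grid, seeds["metrics"],
        compute_sigma=config.compute_sigma, null_model=config.null_model,
        modularity_restarts=config.modularity_restarts,
        nodal=True)
    global_table.to_csv(out / "metrics_global.csv", index=False)
    nodal_table.to_csv(out / "metrics_nodal.csv", index=False)
    metric_auc(global_table).to_csv(out / "metrics_global_auc.csv",
                                    index=False)

    # group comparisons of metrics
    _stage("compare")
    comparisons = []
    for pair in config.level_pairs:
        comp = st.compare_network_metrics(
            global_table[global_table["band"].isin(config.compare_bands)],
            pair, n_perm=config.metric_permutations,
            seed=seeds["compare"], alpha=config.alpha)
        comparisons.append(comp)
        if config.nodal_comparisons:
            ncomp = st.compare_network_metrics(
                nodal_table[nodal_table["band"].isin(config.compare_bands)],
                pair, n_perm=config.metric_permutations,
                seed=seeds["compare"], alpha=config.alpha,
                bonferroni_m=atlas.size)
            ncomp.to_csv(out / f"compare_nodal_{pair[0]}_vs_{pair[1]}.csv",
                         index=False)
    pd.concat(comparisons).to_csv(out / "compare_global.csv", index=False)

    # edge-wise comparison with maximal-statistic correction
    _stage("edges")
    edge_rows = []
    for pair in config.level_pairs:
        for band in config.compare_bands:
            grp_a = [coherences[(s, pair[0], band)]
                     for s in range(config.design.n_subjects)]
            grp_b = [coherences[(s, pair[1], band)]
                     for s in range(config.design.n_subjects)]
            res = st.maximal_statistic_edge_test(
                grp_a, grp_b, n_perm=config.edge_permutations,
                seed=seeds["edges"], alpha=config.alpha)
            for i, j, sign in res.significant_edges:
                edge_rows.append(dict(pair=f"{pair[0]}-{pair[1]}",
                                      band=band, node_i=i, node_j=j,
                                      t=res.t_map[i, j], sign=sign))
    pd.DataFrame(edge_rows,
                 columns=["pair", "band", "node_i", "node_j", "t",
                          "sign"]).to_csv(out / "edges_significant.csv",
                                          index=False)

    # BrainNet export of one representative network (first subject,
    # hardest level, alpha band, mid sparsity)
    top = config.design.levels[-1]
    coh = coherences[(0, top, config.compare_bands[0])]
    net = nw.binarize_by_sparsity(coh, mid, node_labels=labels)
    _, partition = gm.modularity(net, seed=seeds["metrics"])
    deg = gm.degree_centrality(net)
    export_brainnet(net, atlas, deg, out / "example.node",
                    out / "example.edge", node_color=partition)

    hashes = {str(p.relative_to(out)): _sha256(p)
              for p in sorted(out.rglob("*"))
              if p.is_file() and p.suffix in (".csv", ".tsv", ".node",
                                              ".edge")}
    manifest = RunManifest(config.to_dict(), __version__, seeds, hashes,
                           timestamps)
    manifest.to_json(out / "manifest.json")
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return manifest
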