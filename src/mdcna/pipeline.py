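"""Config-driven orchestration: geometry -> PCA -> DCCM -> network -> report.

A run is described by a :class:`RunConfig` (typically loaded from YAML).  The
input is either a topology/trajectory pair on disk or an inline synthetic
design; the output directory receives every figure-grade artifact as a
deterministic plain-text table, plus a structured log of the thresholds and
seeds in effect.  Rerunning with an identical config and seed is
byte-identical.

Centrality is computed on a configurable frame window (default: the middle
half of the trajectory), while the DCCM/community stage uses all frames; the
two stages of a trajectory answer different questions (stable community
structure vs. transition-mediating hubs) and are windowed independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dccm as dccm_mod
from . import network as net_mod
from . import pca as pca_mod
from . import synthetic as syn_mod
from .ensemble_io import (
    CoordinateEnsemble,
    atoms_of_residue,
    read_ensemble,
    select,
    write_matrix,
    write_table,
    read_matrix,
)
from .geometry import distance_series, rmsd_series

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "compare_runs"]

_DCCM_DEFAULTS = {"magnitude_cutoff": 0.5, "occupancy_threshold": 0.75,
                  "contact_cutoff": 10.0, "align_to_first": True}


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated parameters of one analysis run.

    Defaults follow the analysis conventions this pipeline reproduces:
    |C| cutoff 0.5, contact cutoff 10 A held for 75% of frames, 10 PCs
    retained for subspace comparison, 98.5th-percentile centrality
    threshold, and a centrality window of the middle half of the frames.
    """

    input: dict  # {"topology","trajectory","format"} or {"design": {...}}
    out_dir: str | Path = "run_out"
    seed: int = 0
    analysis_selection: str | list | None = None  # default: every residue, CA
    fit_selection: str | list | None = None  # default: analysis selection
    rmsd_selections: dict = field(default_factory=dict)  # name -> expression
    distance_pairs: dict = field(default_factory=dict)  # name -> pair spec
    dccm: dict = field(default_factory=dict)
    pca_depth: int = 10
    projection_depth: int = 3
    centrality_percentile: float = 98.5
    centrality_window: tuple | None = None  # frame [start, stop); None = middle half
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(_DCCM_DEFAULTS)
        merged.update(self.dccm)
        self.dccm = merged
        if not 0 < self.centrality_percentile < 100:
            raise ValueError(
                f"centrality_percentile must be in (0, 100), got {self.centrality_percentile}"
            )
        if not 0 <= self.dccm["magnitude_cutoff"] <= 1:
            raise ValueError("magnitude_cutoff must be in [0, 1]")
        if not 0 <= self.dccm["occupancy_threshold"] <= 1:
            raise ValueError("occupancy_threshold must be in [0, 1]")
        if self.dccm["contact_cutoff"] <= 0:
            raise ValueError("contact_cutoff must be positive")
        if self.pca_depth < 1 or self.projection_depth < 1:
            raise ValueError("PCA depths must be >= 1")
        if self.centrality_window is not None:
            start, stop = self.centrality_window
            if start < 0 or stop <= start:
                raise ValueError(f"bad centrality window [{start}, {stop})")
            self.centrality_window = (int(start), int(stop))
        if "design" not in self.input and "topology" not in self.input:
            raise ValueError("input needs either a synthetic design or a topology")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        # Paths are interpreted relative to the config file.
        inp = raw.get("input", {})
        for key in ("topology", "trajectory"):
            if key in inp:
                inp[key] = str((path.parent / inp[key]).resolve())
        if "out_dir" in raw:
            raw["out_dir"] = str((path.parent / raw["out_dir"]).resolve())
        if "centrality_window" in raw and raw["centrality_window"] is not None:
            raw["centrality_window"] = tuple(raw["centrality_window"])
        return cls(**raw)

    def effective_dict(self) -> dict:
        return {
            "input": {k: str(v) if isinstance(v, Path) else v
                      for k, v in self.input.items() if k != "design_obj"},
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "analysis_selection": self.analysis_selection,
            "fit_selection": self.fit_selection,
            "rmsd_selections": self.rmsd_selections,
            "distance_pairs": self.distance_pairs,
            "dccm": self.dccm,
            "pca_depth": self.pca_depth,
            "projection_depth": self.projection_depth,
            "centrality_percentile": self.centrality_percentile,
            "centrality_window": list(self.centrality_window)
            if self.centrality_window else None,
            "annotations": {k: list(v) for k, v in self.annotations.items()},
        }


def design_from_dict(spec: dict) -> syn_mod.PlantedDesign:
    """Build a planted design from a plain config mapping."""
    kind = spec.get("type", "block")
    params = {k: v for k, v in spec.items() if k != "type"}
    if "sigma" in params and isinstance(params["sigma"], list):
        params["sigma"] = tuple(params["sigma"])
    if kind == "block":
        if "block_sizes" in params:
            params["block_sizes"] = tuple(params["block_sizes"])
            return syn_mod.multi_block_design(**params)
        return syn_mod.two_block_design(**params)
    if kind == "hinge":
        return syn_mod.hinge_design(**params)
    if kind == "coupled":
        return syn_mod.coupled_design(**params)
    if kind == "decoupled":
        return syn_mod.decoupled_design(**params)
    raise ValueError(f"unknown design type {kind!r}")


def _load_ensemble(config: RunConfig):
    """Returns (ensemble, truth-or-None)."""
    inp = config.input
    if "design" in inp:
        design = inp["design"]
        if isinstance(design, dict):
            design = design_from_dict(design)
        kind = "hinge" if design.hinge is not None else "block"
        sampler = (syn_mod.sample_hinge_ensemble if kind == "hinge"
                   else syn_mod.sample_block_ensemble)
        ensemble, truth = sampler(design, seed=config.seed)
        return ensemble, truth
    ensemble = read_ensemble(
        inp["topology"], inp.get("trajectory"), inp.get("format", "multimodel-pdb")
    )
    return ensemble, None


def _resolve(ensemble, expr, atom_name="CA"):
    if expr is None:
        numbers = sorted(
            ensemble.atom_table.loc[
                ensemble.atom_table["atom_name"] == atom_name, "residue_number"
            ].unique()
        )
        return select(ensemble, list(numbers), atom_name)
    return select(ensemble, expr, atom_name)


def _atom_set(ensemble, spec) -> np.ndarray:
    if "atoms" in spec:
        return atoms_of_residue(ensemble, spec["residue"], spec.get("chain"),
                                atom_names=spec["atoms"])
    return atoms_of_residue(ensemble, spec["residue"], spec.get("chain"),
                            sidechain_only=spec.get("sidechain_only", False))


@dataclass
class RunResult:
    """In-memory handle on a finished run (all artifacts also on disk)."""

    out_dir: Path
    config: RunConfig
    ensemble: CoordinateEnsemble
    pca_result: pca_mod.PcaResult
    correlation: dccm_mod.CorrelationMatrix
    filtered: dccm_mod.FilteredCorrelation
    partition: net_mod.CommunityPartition
    centrality: net_mod.CentralityProfile
    truth: dict | None = None


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages and write the result bundle under ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                log(f"stage: {name}")

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc
        return _Ctx()

    with stage("input"):
        ensemble, truth = _load_ensemble(config)
        if ensemble.n_frames < 2:
            raise ValueError("need at least 2 frames")
        log(f"frames={ensemble.n_frames} atoms={ensemble.n_atoms} seed={config.seed}")

    with stage("selections"):
        analysis_sel = _resolve(ensemble, config.analysis_selection)
        fit_sel = (analysis_sel if config.fit_selection is None
                   else _resolve(ensemble, config.fit_selection))
        log(f"analysis selection: {len(analysis_sel)} residues; "
            f"fit selection: {len(fit_sel)} residues")

    with stage("geometry"):
        rmsd_frames = pd.DataFrame({"frame": np.arange(ensemble.n_frames)})
        rmsd_frames["total"] = rmsd_series(ensemble, None, fit_sel, analysis_sel)
        for name in sorted(config.rmsd_selections):
            sel = _resolve(ensemble, config.rmsd_selections[name])
            rmsd_frames[name] = rmsd_series(ensemble, None, fit_sel, sel)
        write_table(rmsd_frames, out_dir / "rmsd.tsv")
        dist_frames = pd.DataFrame({"frame": np.arange(ensemble.n_frames)})
        for name in sorted(config.distance_pairs):
            spec = config.distance_pairs[name]
            series = distance_series(
                ensemble, _atom_set(ensemble, spec["a"]), _atom_set(ensemble, spec["b"]),
                rule=spec.get("rule", "min"),
            )
            dist_frames[name] = series.values
        write_table(dist_frames, out_dir / "distances.tsv")

    with stage("pca"):
        aligned_mean = pca_mod.align_to_mean(ensemble, fit_sel)
        pca_result = pca_mod.compute_pca(aligned_mean, analysis_sel)
        depth = min(config.pca_depth, pca_result.n_modes)
        var_table = pd.DataFrame(
            {
                "pc": np.arange(1, pca_result.n_modes + 1),
                "eigenvalue_A2": pca_result.eigenvalues,
                # reported to two decimals, like the variance bar plots this mirrors
                "variance_pct": np.round(pca_result.variance_fraction, 2),
                "cumulative_pct": np.round(pca_result.cumulative_fraction, 2),
            }
        )
        write_table(var_table, out_dir / "pca_variance.tsv")
        k = min(config.projection_depth, pca_result.n_modes)
        proj = pca_mod.project(aligned_mean, pca_result, k, analysis_sel)
        proj_table = pd.DataFrame(
            proj.scores, columns=[f"pc{i+1}" for i in range(k)]
        )
        proj_table.insert(0, "frame", np.arange(ensemble.n_frames))
        write_table(proj_table, out_dir / "projections.tsv")
        coord_names = [f"{lab}_{ax}" for lab in pca_result.labels for ax in "xyz"]
        modes = pd.DataFrame(
            pca_result.eigenvectors[:depth].T,
            columns=[f"pc{i+1}" for i in range(depth)],
        )
        modes.insert(0, "coordinate", coord_names)
        write_table(modes, out_dir / "pca_modes.tsv")
        pca_mod.export_mode_pdb(
            pca_result,
            1,
            ensemble.atom_table.iloc[analysis_sel.atom_indices],
            out_dir / "pc1_mode.pdb",
        )
        log(f"pca: {pca_result.n_modes} modes, PC1 {pca_result.variance_fraction[0]:.2f}%")

    with stage("dccm"):
        # Trajectories with rigid-body drift must be superposed first; a
        # synthetic ensemble generated in one laboratory frame may disable
        # this (fitting would subtract shared displacement factors).
        if config.dccm["align_to_first"]:
            aligned_first = dccm_mod.align_to_first_frame(ensemble, analysis_sel)
        else:
            aligned_first = ensemble
        corr = dccm_mod.compute_dccm(aligned_first, analysis_sel)
        occ = dccm_mod.contact_occupancy(
            aligned_first, analysis_sel, config.dccm["contact_cutoff"]
        )
        filtered = dccm_mod.filter_correlations(
            corr, occ, config.dccm["magnitude_cutoff"], config.dccm["occupancy_threshold"]
        )
        labels = list(corr.residue_labels)
        write_matrix(corr.values, labels, out_dir / "dccm.txt")
        write_matrix(occ.values, labels, out_dir / "occupancy.txt")
        log("dccm: thresholds |C|>=%g, occupancy>=%g within %g A"
            % (config.dccm["magnitude_cutoff"], config.dccm["occupancy_threshold"],
               config.dccm["contact_cutoff"]))

    with stage("network"):
        graph = net_mod.build_network(filtered)
        partition = net_mod.girvan_newman(graph)
        write_table(net_mod.network_to_edge_table(graph), out_dir / "network_edges.tsv")
        members = pd.DataFrame(
            sorted(partition.membership.items()), columns=["node", "community"]
        )
        write_table(members, out_dir / "communities.tsv")
        coupling = pd.DataFrame(
            [
                {"community_a": a, "community_b": b, "summed_correlation": v}
                for (a, b), v in sorted(partition.coupling.items())
            ],
            columns=["community_a", "community_b", "summed_correlation"],
        )
        write_table(coupling, out_dir / "community_coupling.tsv")
        log(f"network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges; "
            f"{partition.n_communities} communities, Q={partition.modularity:.6f}")

    with stage("centrality"):
        if config.centrality_window is not None:
            start, stop = config.centrality_window
        else:
            start, stop = ensemble.n_frames // 4, ensemble.n_frames - ensemble.n_frames // 4
        win = ensemble.window(start, stop)
        log(f"centrality window: frames [{start}, {stop}) -> {win.n_frames} frames")
        win_aligned = (dccm_mod.align_to_first_frame(win, analysis_sel)
                       if config.dccm["align_to_first"] else win)
        win_corr = dccm_mod.compute_dccm(win_aligned, analysis_sel)
        win_occ = dccm_mod.contact_occupancy(
            win_aligned, analysis_sel, config.dccm["contact_cutoff"]
        )
        win_filtered = dccm_mod.filter_correlations(
            win_corr, win_occ, config.dccm["magnitude_cutoff"],
            config.dccm["occupancy_threshold"],
        )
        win_graph = net_mod.build_network(win_filtered)
        profile = net_mod.node_betweenness(win_graph)
        profile = net_mod.centrality_threshold(profile, config.centrality_percentile)
        cent = pd.DataFrame(sorted(profile.centrality.items()),
                            columns=["node", "betweenness"])
        cent["above_threshold"] = cent["node"].isin(profile.high_set).astype(int)
        write_table(cent, out_dir / "centrality.tsv")
        log(f"centrality: percentile={profile.percentile} threshold={profile.threshold!r} "
            f"high_set={list(profile.high_set)}")

    with stage("annotations"):
        report = net_mod.annotate_residues(partition, profile, config.annotations)
        if len(report):
            write_table(report, out_dir / "annotations.tsv")

    with stage("summary"):
        summary_rows = [
            ("n_frames", ensemble.n_frames),
            ("n_residues", len(analysis_sel)),
            ("n_modes", pca_result.n_modes),
            ("pc1_variance_pct", round(float(pca_result.variance_fraction[0]), 2)),
            ("first3_variance_pct", round(float(pca_result.cumulative_fraction[min(2, pca_result.n_modes - 1)]), 2)),
            ("n_network_edges", graph.number_of_edges()),
            ("n_communities", partition.n_communities),
            ("modularity", partition.modularity),
            ("total_intercommunity_coupling", partition.total_coupling),
            ("centrality_percentile", profile.percentile),
            ("centrality_threshold", profile.threshold),
            ("n_high_centrality", len(profile.high_set)),
        ]
        if truth is not None and "partition" in truth:
            planted = truth["partition"]
            recovered = [partition.membership[l] for l in analysis_sel.labels]
            summary_rows.append(
                ("planted_ari", _adjusted_rand_index(planted, recovered))
            )
        write_table(
            pd.DataFrame(summary_rows, columns=["quantity", "value"]),
            out_dir / "summary.tsv",
        )
        with open(out_dir / "config_effective.yaml", "w") as fh:
            yaml.safe_dump(config.effective_dict(), fh, sort_keys=True)
        with open(out_dir / "run_log.txt", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")

    return RunResult(out_dir, config, ensemble, pca_result, corr, filtered,
                     partition, profile, truth)


def _adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (pair-counting form)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    comb = lambda x: x * (x - 1) / 2.0
    sum_cells = comb(table).sum()
    sum_rows = comb(table.sum(axis=1)).sum()
    sum_cols = comb(table.sum(axis=0)).sum()
    total = comb(len(a))
    expected = sum_rows * sum_cols / total if total else 0.0
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def compare_runs(dir_a, dir_b, threshold_from: str = "a") -> pd.DataFrame:
    """Compare two result bundles the way paired wild-type/mutant runs are.

    Reports community counts, summed inter-community coupling, each run's
    high-centrality set under the *reference* run's threshold, and the RMSIP
    between the stored leading PC subspaces.  Residue labels must match.
    """
    dir_a, dir_b = Path(dir_a), Path(dir_b)
    if threshold_from not in ("a", "b"):
        raise ValueError('threshold_from must be "a" or "b"')

    def load(d: Path) -> dict:
        cent = pd.read_csv(d / "centrality.tsv", sep="\t")
        comm = pd.read_csv(d / "communities.tsv", sep="\t")
        coup = pd.read_csv(d / "community_coupling.tsv", sep="\t")
        modes = pd.read_csv(d / "pca_modes.tsv", sep="\t")
        summary = dict(
            pd.read_csv(d / "summary.tsv", sep="\t").itertuples(index=False, name=None)
        )
        return {"cent": cent, "comm": comm, "coup": coup, "modes": modes,
                "summary": summary}

    a, b = load(dir_a), load(dir_b)
    if list(a["cent"]["node"]) != list(b["cent"]["node"]):
        raise ValueError("runs cover different residue sets; cannot compare")
    ref = a if threshold_from == "a" else b
    percentile = float(ref["summary"]["centrality_percentile"])
    thr = net_mod.nearest_rank_threshold(ref["cent"]["betweenness"], percentile)
    high_a = sorted(a["cent"].loc[a["cent"]["betweenness"] > thr, "node"])
    high_b = sorted(b["cent"].loc[b["cent"]["betweenness"] > thr, "node"])
    mode_cols_a = [c for c in a["modes"].columns if c.startswith("pc")]
    mode_cols_b = [c for c in b["modes"].columns if c.startswith("pc")]
    d = min(len(mode_cols_a), len(mode_cols_b))
    vec_a = a["modes"][mode_cols_a[:d]].to_numpy().T
    vec_b = b["modes"][mode_cols_b[:d]].to_numpy().T
    overlap = pca_mod.rmsip(vec_a, vec_b, d=d)
    rows = [
        ("n_communities_a", a["summary"]["n_communities"]),
        ("n_communities_b", b["summary"]["n_communities"]),
        ("intercommunity_coupling_a", a["summary"]["total_intercommunity_coupling"]),
        ("intercommunity_coupling_b", b["summary"]["total_intercommunity_coupling"]),
        ("shared_threshold", thr),
        ("threshold_percentile", percentile),
        ("high_set_a", ",".join(map(str, high_a))),
        ("high_set_b", ",".join(map(str, high_b))),
        ("n_high_a", len(high_a)),
        ("n_high_b", len(high_b)),
        (f"rmsip_first_{d}", overlap),
    ]
    return pd.DataFrame(rows, columns=["quantity", "value"])
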