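"""End-to-end orchestration: trajectory → RMSD profiles → windowed DCCMs →
networks → centralities → power-law fit → communities → optional paths and
wild-type-vs-mutant comparison.

A run is driven by an :class:`AnalysisConfig` (serialisable to an INI-style
text file), writes every artifact into one output directory, and records a
manifest with the config hash so that identical config + seed reproduces
identical outputs. Default windows are the four quarters of the trajectory
plus the full range, labelled by frame numbers (the mapping of frames to
nanoseconds is data-dependent and left to the caller's time metadata).
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import network as net_mod
from . import powerlaw as pl_mod
from .dccm import WindowSpec, compute_dccm, write_dccm_csv
from .errors import StageError, TrajnetError
from .trajectory import (
    DomainDefinition,
    domain_rmsd_profile,
    read_structure,
    read_trajectory,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "run_comparison"]


@dataclass
class AnalysisConfig:
    """Everything a full analysis run needs; see module docstring.

    ``domains`` maps a domain name to inclusive residue-number ranges;
    ``windows`` is a list of ``(start, stop, label)`` frame windows (quarters
    plus full range when empty); ``path_endpoints`` enables suboptimal-path
    analysis between two residue numbers.
    """

    trajectory: str
    target: str
    outdir: str
    trajectory_format: str | None = None
    topology: str | None = None
    domains: dict = field(default_factory=dict)
    windows: list = field(default_factory=list)
    c_thr: float = 0.3
    threshold_mode: str = "magnitude"
    betweenness_normalization: str = "all-pairs"
    powerlaw_method: str = "mle"
    communities: bool = True
    path_endpoints: tuple | None = None
    n_suboptimal: int = 10
    superpose_dccm: bool = True
    rmsd_mode: str = "per-domain"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.c_thr < 1.0):
            raise ValueError("c_thr must lie in [0, 1)")

    # -- INI round trip ----------------------------------------------------

    def to_ini(self) -> str:
        cp = configparser.ConfigParser()
        cp.optionxform = str  # keep domain/window names case-sensitive
        cp["inputs"] = {"trajectory": self.trajectory, "target": self.target}
        if self.trajectory_format:
            cp["inputs"]["trajectory_format"] = self.trajectory_format
        if self.topology:
            cp["inputs"]["topology"] = self.topology
        cp["analysis"] = {
            "c_thr": repr(self.c_thr),
            "threshold_mode": self.threshold_mode,
            "betweenness_normalization": self.betweenness_normalization,
            "powerlaw_method": self.powerlaw_method,
            "communities": str(self.communities),
            "superpose_dccm": str(self.superpose_dccm),
            "rmsd_mode": self.rmsd_mode,
            "seed": str(self.seed),
        }
        cp["output"] = {"outdir": self.outdir}
        if self.domains:
            cp["domains"] = {
                name: ",".join(f"{lo}-{hi}" for lo, hi in rngs)
                for name, rngs in self.domains.items()
            }
        if self.windows:
            cp["windows"] = {
                (label or f"w{i}"): f"{start}:{stop}"
                for i, (start, stop, label) in enumerate(self.windows)
            }
        if self.path_endpoints:
            cp["paths"] = {
                "source": str(self.path_endpoints[0]),
                "sink": str(self.path_endpoints[1]),
                "k": str(self.n_suboptimal),
            }
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    @classmethod
    def from_ini(cls, text_or_path: str | Path) -> "AnalysisConfig":
        cp = configparser.ConfigParser()
        cp.optionxform = str
        p = Path(str(text_or_path))
        if p.exists():
            cp.read_string(p.read_text())
        else:
            cp.read_string(str(text_or_path))
        inputs = cp["inputs"]
        analysis = cp["analysis"] if cp.has_section("analysis") else {}
        domains = {}
        if cp.has_section("domains"):
            for name, spec in cp["domains"].items():
                domains[name] = [
                    tuple(int(x) for x in rng.split("-"))
                    for rng in spec.split(",")
                ]
        windows = []
        if cp.has_section("windows"):
            for label, spec in cp["windows"].items():
                start, stop = (int(x) for x in spec.split(":"))
                windows.append((start, stop, label))
        endpoints = None
        k = 10
        if cp.has_section("paths"):
            endpoints = (int(cp["paths"]["source"]), int(cp["paths"]["sink"]))
            k = int(cp["paths"].get("k", "10"))
        get = lambda key, default: analysis.get(key, default)
        return cls(
            trajectory=inputs["trajectory"],
            target=inputs["target"],
            outdir=cp["output"]["outdir"],
            trajectory_format=inputs.get("trajectory_format") or None,
            topology=inputs.get("topology") or None,
            domains=domains,
            windows=windows,
            c_thr=float(get("c_thr", "0.3")),
            threshold_mode=get("threshold_mode", "magnitude"),
            betweenness_normalization=get("betweenness_normalization", "all-pairs"),
            powerlaw_method=get("powerlaw_method", "mle"),
            communities=str(get("communities", "True")).lower() == "true",
            path_endpoints=endpoints,
            n_suboptimal=k,
            superpose_dccm=str(get("superpose_dccm", "True")).lower() == "true",
            rmsd_mode=get("rmsd_mode", "per-domain"),
            seed=int(get("seed", "0")),
        )

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_ini().encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Manifest of produced artifacts plus run metadata."""

    manifest: dict
    metadata: dict

    def verify(self) -> None:
        missing = [p for p in self.manifest.values() if not Path(p).exists()]
        if missing:
            raise TrajnetError(f"manifest entries missing on disk: {missing}")


def _default_windows(n_frames: int) -> list[WindowSpec]:
    windows = [WindowSpec(0, n_frames, "full")]
    if n_frames >= 8:
        q = n_frames // 4
        bounds = [0, q, 2 * q, 3 * q, n_frames]
        for i in range(4):
            windows.append(
                WindowSpec(bounds[i], bounds[i + 1], f"quarter{i + 1}")
            )
    return windows


def _stage(name: str):
    """Decorator-free stage guard: use as context manager."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s: FAILED (%s)", name, exc)
                if not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
                return False
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_analysis(cfg: AnalysisConfig) -> AnalysisReport:
    """Execute every stage in dependency order and return the manifest.

    The run is fully deterministic for a fixed config; a stage failure
    raises :class:`StageError` naming the stage, after logging it to the
    run log in the output directory.
    """
    for path in filter(None, [cfg.trajectory, cfg.target, cfg.topology]):
        if not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("trajnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict[str, str] = {}

    def record(key: str, path: Path) -> Path:
        manifest[key] = str(path)
        return path

    try:
        with _stage("load"):
            traj = read_trajectory(
                cfg.trajectory, format=cfg.trajectory_format, topology=cfg.topology
            )
            target = read_structure(cfg.target)
            if not np.array_equal(traj.resnums, target.resnums):
                raise ValueError("trajectory and target residue sets differ")

        with _stage("rmsd"):
            domains = dict(cfg.domains)
            domains.setdefault(
                "overall", [(int(traj.resnums.min()), int(traj.resnums.max()))]
            )
            profile = domain_rmsd_profile(
                traj, target, DomainDefinition(domains), mode=cfg.rmsd_mode
            )
            profile.to_csv(record("rmsd_profile", outdir / "rmsd_profile.csv"),
                           index=False)

        windows = (
            [WindowSpec(s, t, lbl) for s, t, lbl in cfg.windows]
            if cfg.windows
            else _default_windows(traj.n_frames)
        )
        networks = {}
        with _stage("dccm"):
            dccms = {}
            for w in windows:
                d = compute_dccm(traj, w, superpose=cfg.superpose_dccm)
                write_dccm_csv(d, record(f"dccm_{w.name}", outdir / f"dccm_{w.name}.csv"))
                dccms[w.name] = d

        with _stage("network"):
            for name, d in dccms.items():
                g = net_mod.build_network(d, cfg.c_thr, cfg.threshold_mode)
                net_mod.write_edge_csv(
                    g, record(f"edges_{name}", outdir / f"edges_{name}.csv")
                )
                net_mod.write_graphml(
                    g, record(f"graphml_{name}", outdir / f"network_{name}.graphml")
                )
                networks[name] = g

        with _stage("centrality"):
            reports = {}
            for name, g in networks.items():
                rep = net_mod.centrality_report(
                    g, normalization=cfg.betweenness_normalization
                )
                net_mod.write_centrality_csv(
                    rep, record(f"centrality_{name}", outdir / f"centrality_{name}.csv")
                )
                reports[name] = rep

        full_name = windows[0].name
        with _stage("powerlaw"):
            bet = reports[full_name].table["betweenness"].to_numpy()
            hist_vals = bet[bet > 0]
            fit = None
            if len(hist_vals) >= 3:
                if cfg.powerlaw_method == "loglog":
                    h = pl_mod.histogram(hist_vals, "logarithmic",
                                         n_bins=min(10, max(3, len(hist_vals) // 5)))
                    fit = pl_mod.fit_power_law_loglog(h)
                else:
                    fit = pl_mod.fit_power_law_mle(bet)
                h_out = pl_mod.histogram(hist_vals, "logarithmic",
                                         n_bins=min(10, max(3, len(hist_vals) // 5)))
                pl_mod.write_histogram_csv(
                    h_out, record("betweenness_histogram",
                                  outdir / "betweenness_histogram.csv")
                )
                pl_mod.write_fit_json(
                    fit, record("powerlaw_fit", outdir / "powerlaw_fit.json")
                )
            else:
                logger.warning("too few positive betweenness values; fit skipped")

        if cfg.communities:
            with _stage("communities"):
                part = net_mod.detect_communities(networks[full_name])
                net_mod.write_community_csv(
                    part, record("communities", outdir / "communities.csv")
                )
                logger.info(
                    "communities: %d (modularity %.4f)",
                    part.n_communities, part.modularity,
                )

        if cfg.path_endpoints:
            with _stage("paths"):
                ps = net_mod.suboptimal_paths(
                    networks[full_name], cfg.path_endpoints[0],
                    cfg.path_endpoints[1], cfg.n_suboptimal,
                )
                net_mod.write_paths_json(
                    ps, record("suboptimal_paths", outdir / "suboptimal_paths.json")
                )

        with _stage("manifest"):
            import networkx
            metadata = {
                "config_hash": cfg.config_hash,
                "seed": cfg.seed,
                "n_frames": traj.n_frames,
                "n_residues": traj.n_residues,
                "versions": {
                    "numpy": np.__version__,
                    "pandas": pd.__version__,
                    "networkx": networkx.__version__,
                },
            }
            report = AnalysisReport(manifest=dict(manifest), metadata=metadata)
            payload = {"manifest": report.manifest, "metadata": report.metadata}
            (outdir / "manifest.json").write_text(json.dumps(payload, indent=1))
            report.manifest["manifest"] = str(outdir / "manifest.json")
        report.verify()
        return report
    finally:
        root.removeHandler(handler)
        handler.close()


def run_comparison(cfg_a: AnalysisConfig, cfg_b: AnalysisConfig) -> dict:
    """Run two configurations (e.g. wild type and mutant) and compare their
    whole-trajectory networks and RMSD profiles.

    Writes a per-node differential CSV, a summary JSON and a paired RMSD
    table into ``cfg_b.outdir``; returns the summary as a dict.
    """
    rep_a = run_analysis(cfg_a)
    rep_b = run_analysis(cfg_b)

    from .dccm import read_dccm_csv

    full_a = read_dccm_csv(rep_a.manifest["dccm_full"])
    full_b = read_dccm_csv(rep_b.manifest["dccm_full"])
    g_a = net_mod.build_network(full_a, cfg_a.c_thr, cfg_a.threshold_mode)
    g_b = net_mod.build_network(full_b, cfg_b.c_thr, cfg_b.threshold_mode)
    comp = net_mod.compare_networks(
        g_a, g_b, normalization=cfg_a.betweenness_normalization
    )

    outdir = Path(cfg_b.outdir)
    comp.per_node.to_csv(outdir / "comparison_per_node.csv", index=False)

    prof_a = pd.read_csv(rep_a.manifest["rmsd_profile"])
    prof_b = pd.read_csv(rep_b.manifest["rmsd_profile"])
    paired = prof_a.merge(
        prof_b, on=["frame", "domain"], suffixes=("_a", "_b")
    )[["frame", "domain", "rmsd_A_a", "rmsd_A_b"]]
    paired.to_csv(outdir / "comparison_rmsd.csv", index=False)

    summary = {
        "communities_a": comp.communities_a,
        "communities_b": comp.communities_b,
        "n_edges_only_a": len(comp.edges_only_a),
        "n_edges_only_b": len(comp.edges_only_b),
        "max_betweenness_shift_residue": int(
            comp.max_shift_residue("betweenness")
        ),
    }
    (outdir / "comparison_summary.json").write_text(json.dumps(summary, indent=1))
    return summary
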