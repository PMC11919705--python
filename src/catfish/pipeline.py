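"""End-to-end orchestration: simulate -> quantify -> describe -> behave ->
stats -> select, driven by a single YAML config with reproducible seeds.

Every stage reads and writes the file formats owned by its module, so stages
can equally be run standalone through the CLI. A run manifest (config hash,
seeds, package version, outputs) makes deterministic stages reproducible
bit-for-bit from the config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from . import __version__
from .behavior import CageGeometry, Trajectory, score_table
from .descriptors import DEFAULT_IEG_MAP, DESCRIPTOR_NAMES, feature_matrix, frame_to_records, records_to_frame
from .errors import ParameterError
from .imagequant import QuantParams, SegmentationParams, SpotParams, ZStack, load_rois, quantify_roi, save_rois, ROI
from .select import FeatureMatrix, stable_select, rank_table
from .stats import correlation_network, graph_to_json, group_tests
from .synth import (
    ActivityModel,
    render_zstack,
    sample_nuclei,
    save_ground_truth,
    simulate_trajectory,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "describe", "behave", "stats", "select")


@dataclass
class RunConfig:
    """Validated pipeline configuration (one YAML document)."""

    out_dir: str = "catfish_run"
    seed: int = 7
    n_animals: int = 4
    structures: tuple[str, ...] = ("VTA", "CA3")
    conditioned: str = "c3"
    ieg_map: dict = field(default_factory=lambda: dict(DEFAULT_IEG_MAP))
    stages: tuple[str, ...] = STAGES
    synth: dict = field(default_factory=dict)
    imagequant: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    select: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ParameterError("seed must be an integer")
        if self.n_animals < 2:
            raise ParameterError("need at least 2 animals")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ParameterError(f"unknown stages: {sorted(bad)}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _animal_ids(n: int) -> list[str]:
    return [f"a{i + 1:02d}" for i in range(n)]


def _groups(animals: list[str]) -> dict[str, str]:
    half = len(animals) // 2
    return {a: ("recent" if i < half else "remote") for i, a in enumerate(animals)}


def _quant_params(block: Mapping[str, Any]) -> QuantParams:
    return QuantParams(
        segmentation=SegmentationParams(**block.get("segmentation", {})),
        spots=SpotParams(**block.get("spots", {})),
        positivity_threshold=int(block.get("positivity_threshold", 1)),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order; return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": list(config.stages),
        "outputs": [],
    }
    animals = _animal_ids(config.n_animals)
    groups = _groups(animals)

    def record(path: Path) -> Path:
        manifest["outputs"].append(str(path))
        return path

    try:
        if "simulate" in config.stages:
            _stage_simulate(config, out, animals, groups, record)
        if "quantify" in config.stages:
            _stage_quantify(config, out, animals, record)
        if "describe" in config.stages:
            _stage_describe(config, out, groups, record)
        if "behave" in config.stages:
            _stage_behave(config, out, animals, record)
        if "stats" in config.stages:
            _stage_stats(config, out, record)
        if "select" in config.stages:
            _stage_select(config, out, record)
    except Exception as exc:  # identify the failing stage for the operator
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _stage_simulate(config, out, animals, groups, record) -> None:
    blk = dict(config.synth)
    shape = tuple(blk.get("shape", (192, 192)))
    n_layers = int(blk.get("n_layers", 7))
    density = float(blk.get("density", 5e-4))
    noise = tuple(blk.get("noise", (2.0, 1.0)))
    models = {
        "recent": ActivityModel(
            p_first=float(blk.get("p_first", 0.30)),
            p_second=float(blk.get("p_second", 0.25)),
            rho=float(blk.get("rho_recent", 0.0)),
            dot_count_mean=float(blk.get("dot_count_mean", 3.0)),
        ),
        "remote": ActivityModel(
            p_first=float(blk.get("p_first_remote", blk.get("p_first", 0.30))),
            p_second=float(blk.get("p_second_remote", blk.get("p_second", 0.25))),
            rho=float(blk.get("rho_remote", blk.get("rho_recent", 0.0))),
            dot_count_mean=float(blk.get("dot_count_mean", 3.0)),
        ),
    }
    margin = 6
    poly = [
        (margin, margin), (shape[1] - margin, margin),
        (shape[1] - margin, shape[0] - margin), (margin, shape[0] - margin),
    ]
    sim_dir = out / "sim"
    sim_dir.mkdir(exist_ok=True)
    save_rois({s: [ROI(structure=s, polygon=np.asarray(poly, float))]
               for s in config.structures}, record(sim_dir / "rois.json"))
    traj_blk = dict(config.behavior)
    geom = CageGeometry(
        side=float(traj_blk.get("side", 1.0)),
        corner_size=float(traj_blk.get("corner_size", 1.0 / 3.0)),
    )
    ss = np.random.SeedSequence(config.seed)
    seeds = iter(ss.generate_state(10 * len(animals) * (len(config.structures) + 2)))
    meta_rows = []
    for animal in animals:
        group = groups[animal]
        for structure in config.structures:
            seed = int(next(seeds)) % (2**31)
            nuclei = sample_nuclei(poly, density, models[group], n_layers, seed)
            stack = render_zstack(
                nuclei, shape, noise=noise, rng_seed=seed, n_layers=n_layers
            )
            stack.save(record(sim_dir / f"{animal}_{structure}.tiff"))
            save_ground_truth(
                nuclei, record(sim_dir / f"{animal}_{structure}_truth.json")
            )
        for entry in ("first", "second"):
            seed = int(next(seeds)) % (2**31)
            bias = traj_blk.get(
                "bias", {config.conditioned: 3.0}
            )
            traj = simulate_trajectory(
                geom,
                bias=bias,
                duration_s=float(traj_blk.get("duration_s", 300.0)),
                dt_s=float(traj_blk.get("dt_s", 0.2)),
                rng_seed=seed,
                entry_label=entry,
            )
            traj.save(record(sim_dir / f"{animal}_{entry}.csv"))
        # appetitive 50-kHz call counts vary over roughly an order of
        # magnitude between animals: log-normal around ~150 calls
        usv_rng = np.random.default_rng(int(next(seeds)) % (2**31))
        meta_rows.append(
            {"animal_id": animal, "group": group,
             "usv_count": int(round(float(usv_rng.lognormal(5.0, 0.8))))}
        )
    pd.DataFrame(meta_rows).to_csv(record(out / "metadata.csv"), index=False)


def _stage_quantify(config, out, animals, record) -> None:
    sim_dir = out / "sim"
    rois = load_rois(sim_dir / "rois.json")
    params = _quant_params(config.imagequant)
    records = []
    for animal in animals:
        for structure in config.structures:
            stack = ZStack.load(sim_dir / f"{animal}_{structure}.tiff")
            records.append(
                quantify_roi(stack, rois[structure], params, animal_id=animal)
            )
    records_to_frame(records).to_csv(record(out / "activity.csv"), index=False)


def _stage_describe(config, out, groups, record) -> None:
    df = pd.read_csv(out / "activity.csv")
    features = feature_matrix(frame_to_records(df), config.ieg_map)
    meta = pd.read_csv(out / "metadata.csv", index_col="animal_id")
    fm = FeatureMatrix(X=features, y=meta.loc[features.index, "group"])
    fm.to_csv(record(out / "features.csv"))


def _stage_behave(config, out, animals, record) -> None:
    blk = dict(config.behavior)
    geom = CageGeometry(
        side=float(blk.get("side", 1.0)),
        corner_size=float(blk.get("corner_size", 1.0 / 3.0)),
    )
    sim_dir = out / "sim"
    rows = []
    for entry in ("first", "second"):
        trajs = {
            a: Trajectory.load(sim_dir / f"{a}_{entry}.csv", entry_label=entry)
            for a in animals
        }
        rows.append(score_table(trajs, geom, conditioned=config.conditioned))
    pd.concat(rows, ignore_index=True).to_csv(
        record(out / "behaviour.csv"), index=False
    )


def _stage_stats(config, out, record) -> None:
    alpha = float(config.stats.get("alpha", 0.05))
    fm = FeatureMatrix.from_csv(out / "features.csv")
    tests = group_tests(fm.X, fm.y)
    tests.to_csv(record(out / "group_tests.csv"), index=False)
    graphs = {}
    for klass in DESCRIPTOR_NAMES:
        try:
            g = correlation_network(fm.X, klass, alpha=alpha)
        except ParameterError:
            continue
        graphs[klass] = graph_to_json(g)
        nx.write_graphml(g, record(out / f"network_{klass}.graphml"))
    with open(record(out / "networks.json"), "w") as fh:
        json.dump(graphs, fh, indent=2)


def _stage_select(config, out, record) -> None:
    blk = dict(config.select)
    fm = FeatureMatrix.from_csv(out / "features.csv")
    result = stable_select(
        fm.X,
        fm.y,
        n_repeats=int(blk.get("n_repeats", 30)),
        stability_threshold=float(blk.get("stability_threshold", 0.5)),
        base_seed=int(blk.get("seed", config.seed)),
        n_trees=int(blk.get("n_trees", 500)),
        max_iter=int(blk.get("max_iter", 50)),
        alpha=float(blk.get("alpha", 0.01)),
    )
    result.to_frame().to_csv(record(out / "selection.csv"))
    if result.selected_features:
        rank_table(fm.X, result.selected_features).to_csv(
            record(out / "selection_ranks.csv")
        )
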