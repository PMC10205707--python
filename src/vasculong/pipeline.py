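"""One-shot orchestration: simulate -> measure -> stats as a reproducible
run directory with a manifest.

A :class:`RunConfig` (YAML-serializable, round-trip stable) names the
stages to execute and their parameter blocks; ``run_pipeline`` executes
them in order, preserves partial results if a stage fails, and writes a
manifest with the config hash, package version and seeds so a run can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as vio
from . import network as netmod
from . import stats as statsmod
from . import synthetic as synth

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    stages: tuple = ("simulate", "measure", "stats")
    n_vessels: int = 80
    voxel_um: float = 2.5
    volume_mm3: float = 0.05
    alpha: float = 0.05
    cohort_path: str | None = None      # external cohort instead of simulate
    nol_path: str | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Identical configs produce identical artifacts (all randomness flows
    from ``config.seed``). On stage failure a :class:`StageError` is
    raised after flushing the manifest, so completed artifacts survive.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(config),
                "config_hash": config.digest(),
                "version": __version__,
                "completed": []}

    def _flush():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))

    try:
        if "simulate" in config.stages:
            _stage_simulate(config, out)
            manifest["completed"].append("simulate")
            _flush()
        if "measure" in config.stages:
            _stage_measure(config, out)
            manifest["completed"].append("measure")
            _flush()
        if "stats" in config.stages:
            _stage_stats(config, out)
            manifest["completed"].append("stats")
            _flush()
    except StageError:
        _flush()
        raise
    except Exception as e:
        _flush()
        stage = next((s for s in config.stages
                      if s not in manifest["completed"]), "?")
        raise StageError(stage, e) from e
    _flush()
    return out


def _stage_simulate(config: RunConfig, out: Path) -> None:
    bed = synth.make_capillary_bed(synth.NetworkSpec(
        target_vessel_count=config.n_vessels, seed=config.seed))
    vio.write_graphml(bed, out / "bed.graphml")
    vol = synth.render_angiogram(bed, voxel_um=config.voxel_um,
                                 noise_sd=0.0, seed=config.seed)
    vio.write_tiff(vol, out / "angiogram.tif")
    from .cli import _cohort_trajectories
    cohort = synth.simulate_cohort(synth.CohortSpec(
        trajectories=_cohort_trajectories({}), seed=config.seed))
    cohort.to_csv(out / "cohort.csv", index=False)
    nol = pd.concat([
        synth.simulate_nol(7, synth.DEFAULT_AGES_WEEKS, (0.75, -0.012),
                           seed=config.seed, z_sd=0.05, group="AD"),
        synth.simulate_nol(6, synth.DEFAULT_AGES_WEEKS, 0.75,
                           seed=config.seed + 1, z_sd=0.05, group="WT")])
    nol.to_csv(out / "nol.csv", index=False)


def _stage_measure(config: RunConfig, out: Path) -> None:
    graph = out / "bed.graphml"
    if not graph.exists():
        raise StageError("measure",
                         FileNotFoundError(f"missing input {graph}; run "
                                           "the simulate stage first"))
    net = vio.read_graphml(graph)
    mask_path = out / "angiogram.tif"
    vol = vio.read_tiff(mask_path) if mask_path.exists() else None
    if vol is not None and vol.mask is None:
        vol.mask = vol.data > 0.5
    summ = netmod.summarize(net, config.volume_mm3, mask=vol)
    summ.to_frame("SIM", 11.0).to_csv(out / "network_properties.csv",
                                      index=False)


def _stage_stats(config: RunConfig, out: Path) -> None:
    cohort_path = Path(config.cohort_path) if config.cohort_path \
        else out / "cohort.csv"
    if not cohort_path.exists():
        raise StageError("stats",
                         FileNotFoundError(f"missing input {cohort_path}; "
                                           "run the simulate stage or set "
                                           "cohort_path"))
    cohort = vio.read_cohort_csv(cohort_path)
    results = statsmod.run_property_panel(cohort, alpha=config.alpha)
    statsmod.panel_to_frame(results).to_csv(out / "panel.csv", index=False)
    statsmod.chronology(results).to_csv(out / "chronology.csv", index=False)
    nol_path = Path(config.nol_path) if config.nol_path else out / "nol.csv"
    if nol_path.exists():
        nol = vio.read_nol_csv(nol_path)
        statsmod.lagged_correlation(cohort, nol).to_csv(
            out / "nol_correlations.csv", index=False)
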