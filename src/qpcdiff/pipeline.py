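"""End-to-end orchestration of the simulated 15-day culture campaign.

A :class:`RunConfig` fixes the optics, the phenotype parameter set, the
day-by-day phenotype mixture and a master seed. The default schedule
mirrors the biology the instrument was built to watch: a pure progenitor
culture for the first five days, then a mixed neuron + astrocyte
population from day 6 on. Because astrocytes flatten onto the coverslip
while neuron cell bodies sit beyond the evanescent reach, the
total-internal-reflection channel samples the astrocyte layer and the
phase channel the tall, phase-dense neurons — the modality split the
discrimination protocol detects.

ROI export emulates the analyst tracing cells that are actually visible in
each channel: a cell enters the TIRM ROI set when its evanescent contrast
``exp(-gap/d)`` exceeds a floor, and the QPC set when its peak phase delay
exceeds a floor. Cells visible in both channels are assigned to exactly
one (seeded split), so the per-day samples compared by the rank-sum test
are independent rather than paired.

Seeds for every stage/day are derived from the master seed by hashing, so
stages are reproducible independently of call order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (
    OpticalConfig,
    PhenotypeParams,
    ScenePhantom,
    ValidationError,
    default_phenotypes,
)
from .discriminate import DiscriminationReport, run_discrimination
from .morphometry import CellROI, batch_metrics
from .reconstruct import phase_delay, phase_to_height, reconstruct_field
from .simulate import make_phantom, render_qpc_stack, render_tirm
from . import io as qio

logger = logging.getLogger(__name__)

# visibility floors for ROI export
QPC_THETA_MIN = 0.35   # rad: minimum peak phase delay to stand out in QPC
TIRM_CONTRAST_MIN = 0.2  # minimum exp(-gap/d): evanescent contrast floor


def default_schedule() -> dict[int, dict[str, int]]:
    """Default 15-day mixture: pure progenitor, then neurons + astrocytes."""
    schedule: dict[int, dict[str, int]] = {}
    for day in range(1, 6):
        schedule[day] = {"progenitor": 40}
    for day in range(6, 16):
        schedule[day] = {"neuron": 14, "astrocyte": 14}
    return schedule


@dataclass
class RunConfig:
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    phenotypes: dict[str, PhenotypeParams] = field(
        default_factory=default_phenotypes)
    schedule: dict[int, dict[str, int]] = field(
        default_factory=default_schedule)
    grid_shape: tuple[int, int] = (900, 900)
    master_seed: int = 0
    output_dir: str = "qpcdiff_run"
    alpha: float = 0.05
    standardize: bool = True
    division_rule: str = "both"

    def __post_init__(self) -> None:
        days = sorted(self.schedule)
        if days != list(self.schedule):
            self.schedule = {d: self.schedule[d] for d in days}

    def to_dict(self) -> dict:
        return {
            "optics": dataclasses.asdict(self.optics),
            "phenotypes": {k: dataclasses.asdict(v)
                           for k, v in self.phenotypes.items()},
            "schedule": {int(d): dict(m) for d, m in self.schedule.items()},
            "grid_shape": list(self.grid_shape),
            "master_seed": self.master_seed,
            "output_dir": self.output_dir,
            "alpha": self.alpha,
            "standardize": self.standardize,
            "division_rule": self.division_rule,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def _pairs(v):
            return {kk: tuple(vv) if isinstance(vv, (list, tuple)) else vv
                    for kk, vv in v.items()}
        return cls(
            optics=OpticalConfig(**d.get("optics", {})),
            phenotypes={k: PhenotypeParams(**_pairs(v))
                        for k, v in d["phenotypes"].items()}
            if "phenotypes" in d else default_phenotypes(),
            schedule={int(k): {str(c): int(n) for c, n in v.items()}
                      for k, v in d["schedule"].items()}
            if "schedule" in d else default_schedule(),
            grid_shape=tuple(d.get("grid_shape", (900, 900))),
            master_seed=int(d.get("master_seed", 0)),
            output_dir=d.get("output_dir", "qpcdiff_run"),
            alpha=float(d.get("alpha", 0.05)),
            standardize=bool(d.get("standardize", True)),
            division_rule=d.get("division_rule", "both"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def derive_seed(master_seed: int, stage_name: str, day: int = 0) -> int:
    """Stable per-(stage, day) seed below 2^31, independent of call order."""
    digest = hashlib.sha256(
        f"{master_seed}:{stage_name}:{day}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def rois_from_phantom(phantom: ScenePhantom, optics: OpticalConfig,
                      seed: int) -> list[CellROI]:
    """Export per-modality ROIs for the cells visible in each channel.

    Visibility: peak phase delay >= QPC_THETA_MIN for the phase channel;
    ``exp(-gap/penetration_depth)`` >= TIRM_CONTRAST_MIN for the
    evanescent channel. Cells visible in both are assigned to exactly one
    modality by a seeded coin flip so the two per-day samples stay
    disjoint and independent.
    """
    rng = np.random.default_rng(seed)
    rois: list[CellROI] = []
    for cell in phantom.cells:
        theta_peak = (2 * np.pi * optics.delta_n * cell.height_peak
                      / optics.wavelength)
        qpc_ok = theta_peak >= QPC_THETA_MIN
        tirm_ok = (np.exp(-cell.substrate_gap / optics.penetration_depth)
                   >= TIRM_CONTRAST_MIN)
        if qpc_ok and tirm_ok:
            modality = "QPC" if rng.random() < 0.5 else "TIRM"
        elif qpc_ok:
            modality = "QPC"
        elif tirm_ok:
            modality = "TIRM"
        else:
            continue
        rois.append(CellROI(cell_id=cell.cell_id, day=phantom.day,
                            modality=modality, outline=cell.outline))
    return rois


def simulate_metrics(config: RunConfig) -> pd.DataFrame:
    """Metrics-level campaign: phantoms -> ROIs -> trace/segment/measure.

    Runs the whole measurement chain for every scheduled day without
    rendering the optical images (those are exercised by
    :func:`run_experiment` and by the reconstruction round-trip checks);
    returns the pooled per-cell metrics table.
    """
    tables = []
    for day, mixture in config.schedule.items():
        phantom = make_phantom(day, mixture, config.phenotypes,
                               config.grid_shape,
                               seed=derive_seed(config.master_seed,
                                                "phantom", day))
        rois = rois_from_phantom(phantom, config.optics,
                                 seed=derive_seed(config.master_seed,
                                                  "rois", day))
        tables.append(batch_metrics(rois, config.grid_shape))
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()


def simulate_and_discriminate(config: RunConfig) -> DiscriminationReport:
    """Convenience wrapper: metrics campaign + discrimination protocol."""
    metrics = simulate_metrics(config)
    return run_discrimination(metrics, alpha=config.alpha,
                              seed=derive_seed(config.master_seed, "kmeans"),
                              division_rule=config.division_rule,
                              standardize=config.standardize)


def _write_report(outdir: Path, report: DiscriminationReport) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["summaries"] = str(outdir / "summaries.csv")
    report.summaries.to_csv(paths["summaries"], index=False,
                            lineterminator="\n")
    paths["ranksum"] = str(outdir / "ranksum.csv")
    report.ranksum.to_csv(paths["ranksum"], index=False, lineterminator="\n")
    if report.cluster is not None:
        paths["cluster"] = str(outdir / "cluster.json")
        cluster_payload = {
            "points": report.cluster.points.to_dict(orient="records"),
            "standardization": report.cluster.standardization,
            "labels": report.cluster.labels.tolist(),
            "centroids": report.cluster.centroids.tolist(),
            "inertia": report.cluster.inertia,
            "seed": report.cluster.seed,
            "n_restarts": report.cluster.n_restarts,
            "phenotype_labels": {str(k): v for k, v
                                 in report.phenotype_labels.items()},
        }
        Path(paths["cluster"]).write_text(
            json.dumps(cluster_payload, indent=1, sort_keys=True))
    lines = [
        f"division day: {report.division_day}",
        f"alpha: {report.alpha}  rule: {report.division_rule}",
    ]
    if report.cluster is not None:
        for (_, row), lab in zip(report.cluster.points.iterrows(),
                                 report.cluster.labels):
            lines.append(
                f"day {int(row['day']):2d} {row['modality']:4s} "
                f"median area {row['median_area']:8.1f} px^2  "
                f"median AR {row['median_aspect_ratio']:5.2f}  -> "
                f"{report.phenotype_labels[int(lab)]}")
    paths["report_txt"] = str(outdir / "report.txt")
    Path(paths["report_txt"]).write_text("\n".join(lines) + "\n")
    return paths


def run_experiment(config: RunConfig) -> dict:
    """Full campaign with image rendering; returns the run manifest.

    For each scheduled day: phantom -> phase-step stack + evanescent frame
    -> field reconstruction (E0, E1, dphi, theta, height maps) -> ROI
    export -> morphometry. Pooled metrics then run through the
    discrimination protocol. Every stage seed derives from the master
    seed, so a re-run with the same config reproduces the outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "days": {},
        "seeds": {},
    }
    tables = []
    for day, mixture in config.schedule.items():
        stage = f"day {day}"
        try:
            daydir = out / f"day_{day:02d}"
            fields_dir = daydir / "fields"
            fields_dir.mkdir(parents=True, exist_ok=True)
            seeds = {s: derive_seed(config.master_seed, s, day)
                     for s in ("phantom", "qpc", "tirm", "rois")}
            manifest["seeds"][day] = seeds

            phantom = make_phantom(day, mixture, config.phenotypes,
                                   config.grid_shape, seed=seeds["phantom"])
            qio.write_ground_truth(daydir / "ground_truth.json", phantom)

            paths = {"ground_truth": str(daydir / "ground_truth.json")}
            if phantom.cells:
                stack = render_qpc_stack(phantom, config.optics,
                                         seed=seeds["qpc"])
                qio.write_stack(daydir / "qpc_stack.tif", stack)
                tirm = render_tirm(phantom, config.optics, seed=seeds["tirm"])
                qio.write_image(daydir / "tirm.tif", tirm)
                fieldmap = reconstruct_field(stack)
                phase = phase_to_height(
                    phase_delay(fieldmap, reference="background"),
                    config.optics.wavelength, config.optics.n_cell,
                    config.optics.n_medium)
                for name, arr in (("E0", fieldmap.E0), ("E1", fieldmap.E1),
                                  ("delta_phi", fieldmap.delta_phi),
                                  ("theta", phase.theta),
                                  ("height", phase.height)):
                    qio.write_image(fields_dir / f"{name}.tif", arr)
                paths.update(qpc_stack=str(daydir / "qpc_stack.tif"),
                             tirm=str(daydir / "tirm.tif"),
                             fields=str(fields_dir))

            rois = rois_from_phantom(phantom, config.optics,
                                     seed=seeds["rois"])
            qio.write_rois(daydir / "rois.json", rois)
            paths["rois"] = str(daydir / "rois.json")
            tables.append(batch_metrics(rois, config.grid_shape))
            manifest["days"][day] = paths
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    metrics = (pd.concat(tables, ignore_index=True) if tables
               else pd.DataFrame(columns=["cell_id", "day", "modality",
                                          "area_px", "major_axis_px",
                                          "minor_axis_px", "aspect_ratio"]))
    qio.write_metrics(out / "metrics.csv", metrics)
    manifest["metrics"] = str(out / "metrics.csv")

    complete_days = {
        day for day, g in metrics.groupby("day")
        if {"QPC", "TIRM"} <= set(g["modality"])
    }
    if len(complete_days) >= 2:
        report = run_discrimination(
            metrics, alpha=config.alpha,
            seed=derive_seed(config.master_seed, "kmeans"),
            division_rule=config.division_rule,
            standardize=config.standardize)
        manifest["report"] = _write_report(out / "report", report)
        manifest["division_day"] = report.division_day
    else:
        reason = "fewer than 2 days with both modalities; analysis skipped"
        logger.warning(reason)
        manifest["report"] = None
        manifest["analysis_skipped"] = reason

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest
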