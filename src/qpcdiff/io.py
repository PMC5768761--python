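"""File formats: TIFF stacks and maps, JSON ground truth / ROIs, CSV metrics.

Phase-stepped stacks are stored as multi-page 32-bit float TIFFs with page
order equal to phase-step order k = 0..n-1 (alternatively four single-page
files carrying a ``_k{0..3}`` suffix). Reconstructed maps are single-page
32-bit float TIFFs. Ground truth and ROIs are JSON; metrics are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import CellGroundTruth, ScenePhantom
from .morphometry import METRIC_COLUMNS, CellROI
from .reconstruct import PhaseStepStack


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_stack(path: str | Path, stack: PhaseStepStack) -> None:
    """Write a phase-step stack as one multi-page float32 TIFF."""
    pages = np.stack([f.astype(np.float32) for f in stack.frames])
    tifffile.imwrite(str(path), pages, photometric="minisblack",
                     metadata={"phase_step_rad": float(stack.step)})


def read_stack(path: str | Path, step: float = np.pi / 2) -> PhaseStepStack:
    """Read a stack from a multi-page TIFF or a ``_k0`` suffix pattern.

    If ``path`` names an existing file, its pages become frames in page
    order. Otherwise ``path`` is treated as the k=0 member of a
    ``name_k{0..3}.tif`` family.
    """
    p = Path(path)
    if p.exists():
        pages = tifffile.imread(str(p)).astype(float)
        frames = [pages[k] for k in range(pages.shape[0])]
    else:
        if "_k0" not in p.name:
            raise FileNotFoundError(f"{p} not found and not a _k0 pattern")
        frames = []
        k = 0
        while True:
            member = p.with_name(p.name.replace("_k0", f"_k{k}"))
            if not member.exists():
                break
            frames.append(tifffile.imread(str(member)).astype(float))
            k += 1
        if not frames:
            raise FileNotFoundError(f"no files matching {p}")
    return PhaseStepStack(frames=frames, step=step)


def write_ground_truth(path: str | Path, phantom: ScenePhantom) -> None:
    """JSON sidecar of the phantom's ground truth, keyed by cell id."""
    payload = {
        "day": phantom.day,
        "grid_shape": list(phantom.grid_shape),
        "cells": {
            c.cell_id: {
                "class_label": c.class_label,
                "outline": c.outline.tolist(),
                "area": c.area,
                "aspect_ratio": c.aspect_ratio,
                "height_peak_nm": c.height_peak,
                "substrate_gap_nm": c.substrate_gap,
                "amplitude_transmittance": c.amplitude_transmittance,
            }
            for c in phantom.cells
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_rois(path: str | Path, rois: list[CellROI]) -> None:
    payload = [
        {"cell_id": r.cell_id, "day": r.day, "modality": r.modality,
         "outline": np.asarray(r.outline).tolist()}
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois(path: str | Path) -> list[CellROI]:
    payload = json.loads(Path(path).read_text())
    return [CellROI(cell_id=r["cell_id"], day=int(r["day"]),
                    modality=r["modality"],
                    outline=np.asarray(r["outline"], dtype=float))
            for r in payload]


def write_metrics(path: str | Path, metrics: pd.DataFrame) -> None:
    metrics.to_csv(path, index=False, columns=METRIC_COLUMNS,
                   lineterminator="\n")


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
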