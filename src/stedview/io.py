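"""Readers and writers for the pipeline's on-disk formats.

Scenes are stored as OME-TIFF (channels in spec order) with a JSON sidecar
carrying channel names, roles and the pixel size; ground truth as CSV with
nm coordinates, origin at the top-left pixel center.  Manual side-view
ROIs are CSV lines drawn across the scaffold bar (from the postsynaptic
toward the presynaptic side).  Traces are two-column CSV plus a stimulus
sidecar.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .profiling import SideViewROI
from .synthetic import SyntheticScene


def write_scene(scene: SyntheticScene, path: str | Path) -> Path:
    """Write a scene as OME-TIFF + JSON sidecar + ground-truth CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = [c.marker_name for c in scene.spec.channels]
    stack = np.stack([scene.images[n] for n in names]).astype(np.float32)
    px_um = scene.spec.pixel_size / 1000.0
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": px_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": px_um,
            "PhysicalSizeYUnit": "µm",
        },
    )
    sidecar = {
        "pixel_size_nm": scene.spec.pixel_size,
        "channels": [
            {"marker_name": c.marker_name, "role": c.role, "modality": c.modality,
             "psf_fwhm_nm": c.psf_fwhm}
            for c in scene.spec.channels
        ],
        "noise": scene.spec.noise,
        "seed": scene.spec.seed,
        "dropped_synapses": scene.dropped,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    scene.truth.to_csv(path.with_suffix(".truth.csv"), index=False)
    return path


def read_scene_images(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Read an OME-TIFF written by :func:`write_scene`.

    Returns (images-by-marker, sidecar-metadata dict).
    """
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    names = [c["marker_name"] for c in sidecar["channels"]]
    if len(names) != stack.shape[0]:
        raise ValueError(f"{path}: sidecar lists {len(names)} channels, TIFF has {stack.shape[0]}")
    return {n: stack[i].astype(float) for i, n in enumerate(names)}, sidecar


def read_manual_rois(path: str | Path, profile_length: float = 1000.0,
                     profile_width: float = 250.0) -> pd.DataFrame:
    """Read a manual ROI CSV: image_id, x1, y1, x2, y2 (nm), culture, genotype.

    The drawn line runs across the bar from the postsynaptic to the
    presynaptic side; its midpoint becomes the profile center and its
    direction the signed profile normal.  Returns the table with an extra
    ``roi`` column of :class:`SideViewROI`.
    """
    df = pd.read_csv(path)
    required = {"image_id", "x1", "y1", "x2", "y2", "culture", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manual ROI file missing columns: {sorted(missing)}")
    rois = []
    for _, r in df.iterrows():
        dx, dy = r.x2 - r.x1, r.y2 - r.y1
        n = math.hypot(dx, dy)
        if n == 0:
            raise ValueError(f"zero-length ROI line in image {r.image_id}")
        rois.append(
            SideViewROI(
                bar_center=((r.x1 + r.x2) / 2.0, (r.y1 + r.y2) / 2.0),
                axis_normal=(dx / n, dy / n),
                profile_length=profile_length,
                profile_width=profile_width,
                source="manual",
            )
        )
    out = df.copy()
    out["roi"] = rois
    return out


def write_trace_csv(trace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_ms": trace.time, "current_pA": trace.current}).to_csv(path, index=False)
    path.with_suffix(".stim.json").write_text(
        json.dumps({"stimulus_times_ms": list(trace.stimulus_times)})
    )
    return path


def read_trace_csv(path: str | Path, stimulus_times=None):
    """Read a two-column trace CSV; stimulus times from sidecar unless given."""
    from .ephys import Trace

    path = Path(path)
    df = pd.read_csv(path)
    if stimulus_times is None:
        sidecar = path.with_suffix(".stim.json")
        if not sidecar.exists():
            raise ValueError(f"{path}: no stimulus times given and no {sidecar.name} sidecar")
        stimulus_times = json.loads(sidecar.read_text())["stimulus_times_ms"]
    return Trace(
        time=df["time_ms"].to_numpy(),
        current=df["current_pA"].to_numpy(),
        stimulus_times=tuple(float(s) for s in stimulus_times),
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
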