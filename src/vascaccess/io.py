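"""File conventions: PNG frames, JSON-lines annotations, YAML configs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .detection import Detection
from .phantom import (AnatomyPriors, BModeFrame, GroundTruthRecord,
                      ImagingConfig)
from .segmentation import VesselFit

__all__ = [
    "save_frames", "load_frames", "save_ground_truth", "load_ground_truth",
    "save_detections", "load_detections", "save_fits", "load_fits",
    "load_config", "write_manifest",
]


def save_frames(frames: list[BModeFrame], out_dir: str | Path) -> list[Path]:
    """One 8-bit grayscale PNG per frame, zero-padded index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    meta = []
    for frame in frames:
        path = out_dir / f"frame_{frame.frame_index:06d}.png"
        iio.imwrite(path, frame.pixels)
        paths.append(path)
        meta.append({"frame": frame.frame_index,
                     "pixel_spacing_mm": frame.pixel_spacing_mm,
                     "probe_lateral_mm": frame.probe_lateral_mm,
                     "probe_cc_mm": frame.probe_cc_mm,
                     "frame_rate_hz": frame.frame_rate_hz})
    (out_dir / "frames.json").write_text(json.dumps(meta, indent=1))
    return paths


def load_frames(in_dir: str | Path) -> list[BModeFrame]:
    in_dir = Path(in_dir)
    meta = {m["frame"]: m
            for m in json.loads((in_dir / "frames.json").read_text())}
    frames = []
    for path in sorted(in_dir.glob("frame_*.png")):
        index = int(path.stem.split("_")[1])
        m = meta[index]
        frames.append(BModeFrame(
            pixels=np.asarray(iio.imread(path), dtype=np.uint8),
            pixel_spacing_mm=m["pixel_spacing_mm"],
            probe_lateral_mm=m["probe_lateral_mm"],
            probe_cc_mm=m["probe_cc_mm"], frame_index=index,
            frame_rate_hz=m["frame_rate_hz"]))
    return frames


def save_ground_truth(records: list[GroundTruthRecord],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")


def load_ground_truth(path: str | Path) -> list[GroundTruthRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        d = json.loads(line)
        records.append(GroundTruthRecord(
            frame_index=d["frame"], cls=d["class"], bbox=tuple(d["bbox"]),
            centroid_mm=tuple(d["centroid_mm"]),
            boundary_mm=np.asarray(d["boundary_mm"])))
    return records


def save_detections(detections: list[Detection], path: str | Path) -> None:
    with open(path, "w") as fh:
        for det in detections:
            fh.write(json.dumps({"frame": det.frame_index, "class": det.cls,
                                 "bbox": list(det.bbox),
                                 "score": round(det.score, 6),
                                 "age": det.age}) + "\n")


def load_detections(path: str | Path) -> list[Detection]:
    out = []
    for line in Path(path).read_text().splitlines():
        d = json.loads(line)
        out.append(Detection(cls=d["class"], bbox=tuple(d["bbox"]),
                             score=d["score"], frame_index=d["frame"],
                             age=d.get("age", 0)))
    return out


def save_fits(fits: list[VesselFit], frames: list[int],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        for fit, frame in zip(fits, frames):
            fh.write(json.dumps({
                "frame": frame, "class": fit.cls,
                "center_mm": [round(v, 6) for v in fit.center_mm],
                "semi_axes_mm": [round(v, 6) for v in fit.semi_axes_mm],
                "rotation_deg": round(fit.rotation_deg, 4)}) + "\n")


def load_fits(path: str | Path) -> tuple[list[VesselFit], list[int]]:
    fits, frames = [], []
    for line in Path(path).read_text().splitlines():
        d = json.loads(line)
        fits.append(VesselFit(center_mm=tuple(d["center_mm"]),
                              semi_axes_mm=tuple(d["semi_axes_mm"]),
                              rotation_deg=d["rotation_deg"],
                              boundary_points_mm=np.empty((0, 2)),
                              cls=d["class"]))
        frames.append(d["frame"])
    return fits, frames


def load_config(path: str | Path) -> dict:
    """YAML config -> {'priors': AnatomyPriors, 'imaging': ImagingConfig}."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    priors = AnatomyPriors(**raw.get("priors", {}))
    imaging = ImagingConfig(**raw.get("imaging", {}))
    return {"priors": priors, "imaging": imaging, "raw": raw}


def write_manifest(out_dir: str | Path, seed: int, config: object) -> Path:
    """Reproducibility manifest (config hash, seed, package version)."""
    from . import __version__
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = config
    blob = json.dumps(payload, sort_keys=True, default=str)
    manifest = {"seed": seed, "version": __version__,
                "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
                "config": payload}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
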