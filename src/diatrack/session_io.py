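"""On-disk exchange formats for frames and template banks.

Frames are 16-bit grayscale TIFFs named ``frame_{imager}_{index:04d}.tif``
with a ``frames_index.json`` carrying times, gantry angles, geometry
parameters and known marker pixels.  Templates are TIFFs plus a
``templates_index.json`` mapping gantry angle to file and apex offset.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .geometry import PixelCoord, ViewGeometry
from .imaging import DiaphragmTemplate, ProjectionImage

__all__ = ["write_frames", "read_frames", "write_templates", "read_templates"]


def _to_uint16(a: np.ndarray) -> np.ndarray:
    return np.round(np.clip(a, 0, 65535)).astype(np.uint16)


def write_frames(frames: dict[int, list[ProjectionImage]], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index: dict = {"imagers": {}, "n_frames": 0}
    for imager, seq in sorted(frames.items()):
        entries = []
        for k, img in enumerate(seq):
            name = f"frame_{imager}_{k:04d}.tif"
            tifffile.imwrite(out_dir / name, _to_uint16(img.intensity))
            g = img.view
            entries.append(
                {
                    "file": name,
                    "time_s": img.time_s,
                    "gantry_angle": g.gantry_angle if g else None,
                    "markers_px": [[q.u, q.v] for q in img.known_marker_pixels],
                }
            )
        geom = seq[0].view
        index["imagers"][str(imager)] = {
            "frames": entries,
            "geometry": {
                "sad": geom.sad,
                "sid": geom.sid,
                "isocenter_pixel_size": geom.isocenter_pixel_size,
                "image_width": geom.image_width,
                "image_height": geom.image_height,
                "imager_index": geom.imager_index,
            }
            if geom
            else None,
        }
        index["n_frames"] = len(seq)
    with open(out_dir / "frames_index.json", "w") as fh:
        json.dump(index, fh, indent=2)


def read_frames(in_dir) -> dict[int, list[ProjectionImage]]:
    in_dir = Path(in_dir)
    with open(in_dir / "frames_index.json") as fh:
        index = json.load(fh)
    frames: dict[int, list[ProjectionImage]] = {}
    for imager_str, block in index["imagers"].items():
        imager = int(imager_str)
        gp = block.get("geometry")
        seq = []
        for entry in block["frames"]:
            data = tifffile.imread(in_dir / entry["file"]).astype(float)
            view = None
            if gp is not None and entry["gantry_angle"] is not None:
                view = ViewGeometry(
                    gantry_angle=entry["gantry_angle"],
                    imager_index=gp["imager_index"],
                    sad=gp["sad"],
                    sid=gp["sid"],
                    isocenter_pixel_size=gp["isocenter_pixel_size"],
                    image_width=gp["image_width"],
                    image_height=gp["image_height"],
                )
            seq.append(
                ProjectionImage(
                    intensity=data,
                    time_s=entry["time_s"],
                    view=view,
                    known_marker_pixels=tuple(
                        PixelCoord(u, v) for u, v in entry["markers_px"]
                    ),
                )
            )
        frames[imager] = seq
    return frames


def write_templates(banks: dict[int, list[DiaphragmTemplate]], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index: dict = {}
    for imager, bank in sorted(banks.items()):
        entries = []
        for k, t in enumerate(bank):
            name = f"template_{imager}_{k:04d}.tif"
            tifffile.imwrite(out_dir / name, _to_uint16(t.intensity))
            entries.append(
                {
                    "file": name,
                    "gantry_angle": t.gantry_angle,
                    "apex_offset": [t.apex_offset.u, t.apex_offset.v],
                }
            )
        index[str(imager)] = entries
    with open(out_dir / "templates_index.json", "w") as fh:
        json.dump(index, fh, indent=2)


def read_templates(in_dir) -> dict[int, list[DiaphragmTemplate]]:
    in_dir = Path(in_dir)
    with open(in_dir / "templates_index.json") as fh:
        index = json.load(fh)
    banks: dict[int, list[DiaphragmTemplate]] = {}
    for imager_str, entries in index.items():
        banks[int(imager_str)] = [
            DiaphragmTemplate(
                intensity=tifffile.imread(in_dir / e["file"]).astype(float),
                gantry_angle=e["gantry_angle"],
                apex_offset=PixelCoord(*e["apex_offset"]),
            )
            for e in entries
        ]
    return banks
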