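"""Readers and writers for outlines, trees and result tables.

Outlines come in three forms: CSV polygon files (columns id, x, y,
vertex_order), TPS outline files, and binary mask images (PNG/TIFF) traced
with marching squares.  Warp models are written as standalone SVG files.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .outlines import Outline, WarpModel, canonicalize

__all__ = [
    "read_outline_csv",
    "write_outline_csv",
    "read_tps",
    "outline_from_mask",
    "read_mask_image",
    "write_warp_svg",
    "write_csv_with_seed",
]


def read_outline_csv(path: str, canonical: bool = True) -> list[Outline]:
    """Read closed polygons from a CSV with columns id, x, y, vertex_order."""
    df = pd.read_csv(path, comment="#")
    needed = {"id", "x", "y", "vertex_order"}
    if not needed.issubset(df.columns):
        raise ValueError(f"outline CSV needs columns {sorted(needed)}")
    outlines = []
    for oid, grp in df.groupby("id", sort=False):
        pts = grp.sort_values("vertex_order")[["x", "y"]].to_numpy(float)
        if canonical:
            pts = canonicalize(pts)
        outlines.append(Outline(pts, id=str(oid), canonical=canonical))
    return outlines


def write_outline_csv(outlines: list[Outline], path: str, seed: int | None = None) -> None:
    frames = []
    for o in outlines:
        frames.append(
            pd.DataFrame(
                {
                    "id": o.id,
                    "x": o.points[:, 0],
                    "y": o.points[:, 1],
                    "vertex_order": np.arange(o.k),
                }
            )
        )
    write_csv_with_seed(pd.concat(frames, ignore_index=True), path, seed)


def read_tps(path: str, canonical: bool = True) -> list[Outline]:
    """Minimal TPS outline reader: uses OUTLINES/POINTS blocks (or LM as a
    fallback) plus the ID field."""
    outlines: list[Outline] = []
    coords: list[list[float]] = []
    oid = ""
    in_block = False

    def flush():
        nonlocal coords, oid
        if coords:
            pts = np.asarray(coords, float)
            if canonical:
                pts = canonicalize(pts)
            outlines.append(Outline(pts, id=oid or f"tps_{len(outlines)}", canonical=canonical))
        coords = []
        oid = ""

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith(("LM=", "OUTLINES=", "POINTS=", "CURVES=")):
                if upper.startswith(("LM=", "OUTLINES=")) and coords:
                    flush()
                in_block = True
            elif upper.startswith("ID="):
                oid = line.split("=", 1)[1].strip()
            elif "=" in line and not any(ch.isdigit() for ch in line.split("=", 1)[0]):
                continue  # IMAGE=, SCALE=, ...
            elif in_block:
                parts = line.split()
                if len(parts) == 2:
                    coords.append([float(parts[0]), float(parts[1])])
    flush()
    return outlines


def outline_from_mask(
    mask: np.ndarray, id: str = "", pixel_size: float = 1.0, canonical: bool = True
) -> Outline:
    """Trace the largest foreground component of a binary mask with marching
    squares at the 0.5 level.  Image rows map to -y so dorsal is +y."""
    from skimage import measure

    mask = np.asarray(mask) > 0
    labels = measure.label(mask)
    if labels.max() == 0:
        raise ValueError("mask has no foreground component")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    contours = measure.find_contours((labels == largest).astype(float), 0.5)
    contour = max(contours, key=len)
    pts = np.column_stack([contour[:, 1], -contour[:, 0]]) * pixel_size
    # marching squares emits an explicitly closed chain: drop the closure
    # point, then thin any near-duplicate steps
    if np.hypot(*(pts[0] - pts[-1])) <= 1e-9 * pixel_size:
        pts = pts[:-1]
    keep = np.ones(len(pts), bool)
    keep[1:] = np.hypot(*np.diff(pts, axis=0).T) > 1e-9 * pixel_size
    pts = pts[keep]
    if canonical:
        pts = canonicalize(pts)
    return Outline(pts, id=id, canonical=canonical)


def read_mask_image(path: str, id: str = "", pixel_size: float = 1.0) -> Outline:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    return outline_from_mask(img > img.max() / 2, id=id or os.path.basename(path), pixel_size=pixel_size)


def write_warp_svg(warp: WarpModel, path: str, scale: float = 100.0) -> None:
    pts = warp.outline.points * scale
    pts[:, 1] *= -1  # SVG y runs down
    mins = pts.min(axis=0) - 5
    size = pts.max(axis=0) - mins + 10
    d = "M " + " L ".join(f"{x - mins[0]:.2f},{y - mins[1]:.2f}" for x, y in pts) + " Z"
    colour = "#444444" if warp.valid else "#cc3333"
    svg = (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size[0]:.0f}" height="{size[1]:.0f}">\n'
        f'  <path d="{d}" fill="none" stroke="{colour}" stroke-width="1"/>\n'
        "</svg>\n"
    )
    with open(path, "w") as fh:
        fh.write(svg)


def write_csv_with_seed(df: pd.DataFrame, path: str, seed: int | None = None) -> None:
    """Write a CSV with a provenance comment header recording the seed."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)
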