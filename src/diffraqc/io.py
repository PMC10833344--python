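"""HDF5 containers for image stacks, labels and geometry.

Layout of a simulator container:

* ``/images`` — (N, H, W) integer stack (raw frames or conditioned
  quadrants, see the ``kind`` attribute);
* ``/labels/inverse_resolution``, ``/labels/n_lattices``, ``/labels/B`` —
  per-image ground truth (when produced by the simulator);
* ``/geometry/...`` — per-image arrays (``distance_mm``,
  ``center_fast_px``, ``center_slow_px``) plus a detector-level YAML
  config block in the root attribute ``geometry_config``;
* root attributes ``kind`` (``raw`` | ``quadrants``) and ``seed``.

A plain-text manifest (``<path>.manifest.txt``) lists the master seed and
image count so a run can be reproduced without opening the container.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .geometry import GeometryContext

__all__ = ["write_container", "read_container", "write_manifest"]


def write_container(path, images: np.ndarray, geometry: GeometryContext,
                    labels: dict | None = None,
                    per_image_geometry: dict | None = None,
                    kind: str = "raw", seed: int | None = None) -> None:
    images = np.asarray(images)
    if images.ndim != 3:
        raise ValueError("images must be a (N, H, W) stack")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("images", data=images, compression="gzip",
                          compression_opts=4, chunks=(1,) + images.shape[1:])
        if labels:
            grp = fh.create_group("labels")
            for name, arr in labels.items():
                grp.create_dataset(name, data=np.asarray(arr))
        if per_image_geometry:
            grp = fh.create_group("geometry")
            for name, arr in per_image_geometry.items():
                grp.create_dataset(name, data=np.asarray(arr))
        fh.attrs["geometry_config"] = geometry.to_yaml()
        fh.attrs["kind"] = kind
        if seed is not None:
            fh.attrs["seed"] = int(seed)


def read_container(path) -> dict:
    """Load a container into memory: images, labels, geometry, attributes."""
    out: dict = {}
    with h5py.File(path, "r") as fh:
        out["images"] = fh["images"][...]
        out["labels"] = {k: fh["labels"][k][...] for k in fh.get("labels", {})}
        out["per_image_geometry"] = {k: fh["geometry"][k][...]
                                     for k in fh.get("geometry", {})}
        out["geometry"] = GeometryContext.from_yaml(fh.attrs["geometry_config"])
        out["kind"] = fh.attrs.get("kind", "raw")
        out["seed"] = int(fh.attrs["seed"]) if "seed" in fh.attrs else None
    return out


def write_manifest(path, seed: int, n_images: int, note: str = "") -> None:
    manifest = Path(str(path) + ".manifest.txt")
    lines = [f"seed: {seed}", f"n_images: {n_images}"]
    if note:
        lines.append(f"note: {note}")
    manifest.write_text("\n".join(lines) + "\n")
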