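"""Inference over image stacks: per-quadrant predictions, aggregation,
overlap thresholding and dataset summaries.

For each image the model is evaluated once per requested conditioned
quadrant (1 for the monitoring fast path, 4 for full coverage).  For the
resolution head, per-quadrant inverse resolutions are aggregated two
ways: ``d_min`` — the best (smallest d, largest 1/d) quadrant value — and
``d_mean`` — the reciprocal of the mean inverse resolution (averaging in
the model's native inverse units; a direct mean of d is available via
``mean_space="d"``).  ``B_min`` is derived from ``d_min`` through the
resolution trend.  For the overlap head, the per-image probability
``p in [0, 1]`` is thresholded at 0.5: an image is called overlapped when
``p >= 0.5`` (so ``p < 0.5`` defines the single-lattice class).

Dataset summaries average per-image quantities over all images:
``<B_min>``, ``<d_min>`` and the overlapped fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .condition import ConditionedQuadrant
from .model import QuadrantModel
from .trend import DEFAULT_TREND, TrendModel, b_from_resolution

__all__ = [
    "InferenceRecord", "DatasetSummary", "infer_image", "classify_overlap",
    "sort_and_split", "summarize_dataset", "records_to_frame",
]


@dataclass
class InferenceRecord:
    """Per-image predictions: quadrant values plus aggregates."""

    image_id: str
    task: str                                # resolution | overlap
    quadrant_values: list[float]             # 1/d (A^-1) or p per quadrant
    d_min_A: float | None = None
    d_mean_A: float | None = None
    B_min_A2: float | None = None
    p_overlap: float | None = None
    overlap_label: bool | None = None


@dataclass
class DatasetSummary:
    """Averages over all images of a data set."""

    n_images: int
    mean_B_min_A2: float | None = None
    mean_d_min_A: float | None = None
    overlap_fraction: float | None = None


def classify_overlap(p: float, threshold: float = 0.5) -> bool:
    """True (overlapped) iff ``p >= threshold``; ``p < threshold`` is single."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("overlap probability must lie in [0, 1]")
    return bool(p >= threshold)


def infer_image(model: QuadrantModel, quadrants, geometry_args: dict,
                n_quadrants: int = 4, image_id: str = "0",
                trend: TrendModel = DEFAULT_TREND,
                mean_space: str = "inverse") -> InferenceRecord:
    """Run the model over the requested quadrants and aggregate.

    ``quadrants`` is the list from the conditioning pipeline
    (:class:`ConditionedQuadrant` or bare 512 x 512 arrays);
    ``geometry_args`` maps ``wavelength_A``/``p_eff_mm``/``distance_mm``
    to scalars for the geometry output stage.  With ``n_quadrants=1``
    only the first quadrant (same conditioning, same weights) is used.
    """
    if n_quadrants not in (1, 4):
        raise ValueError("n_quadrants must be 1 or 4")
    arrays = [q.pixels if isinstance(q, ConditionedQuadrant) else np.asarray(q)
              for q in quadrants[:n_quadrants]]
    if len(arrays) < n_quadrants:
        raise ValueError(f"need {n_quadrants} quadrants, got {len(arrays)}")
    x = np.stack([np.clip(a, 0, None) for a in arrays]).astype(np.float32)
    task = ("resolution" if model.spec.head == "geometry_resolution"
            else "overlap")
    if task == "resolution":
        geom = {k: np.full(len(arrays), float(v))
                for k, v in geometry_args.items()}
        inv_d = model.predict(x, geom=geom)
        values = [float(v) for v in inv_d]
        inv_min = float(np.max(inv_d))          # best resolution
        if mean_space == "inverse":
            inv_mean = float(np.mean(inv_d))
            d_mean = 1.0 / inv_mean if inv_mean > 0 else np.inf
        elif mean_space == "d":
            with np.errstate(divide="ignore"):
                d_mean = float(np.mean(np.where(inv_d > 0, 1.0 / inv_d, np.inf)))
        else:
            raise ValueError("mean_space must be 'inverse' or 'd'")
        d_min = 1.0 / inv_min if inv_min > 0 else np.inf
        b_min = (float(b_from_resolution(d_min, trend))
                 if np.isfinite(d_min) else None)
        return InferenceRecord(image_id=image_id, task=task,
                               quadrant_values=values, d_min_A=d_min,
                               d_mean_A=d_mean, B_min_A2=b_min)
    probs = model.predict(x)
    values = [float(p) for p in probs]
    p_img = values[0]       # single-quadrant convention for the overlap task
    return InferenceRecord(image_id=image_id, task=task,
                           quadrant_values=values, p_overlap=p_img,
                           overlap_label=classify_overlap(p_img))


def sort_and_split(records: list[InferenceRecord], n_groups: int,
                   key=None) -> tuple[list[list[str]], list[float]]:
    """Stable sort by ``key`` (default: overlap probability) and split.

    Groups are near-equal in size with the remainder going to earlier
    groups; returns ``(groups_of_image_ids, boundary_key_values)`` where
    boundaries are the key values at each split point.
    """
    if not records:
        raise ValueError("no records to split")
    if n_groups < 1 or n_groups > len(records):
        raise ValueError("n_groups must be in [1, n_records]")
    if key is None:
        key = lambda r: r.p_overlap if r.p_overlap is not None else r.d_min_A
    ordered = sorted(records, key=key)        # Python sort is stable
    n = len(ordered)
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if g < rem else 0) for g in range(n_groups)]
    groups, boundaries, i = [], [], 0
    for size in sizes:
        groups.append([r.image_id for r in ordered[i:i + size]])
        i += size
        if i < n:
            boundaries.append(float(key(ordered[i])))
    return groups, boundaries


def summarize_dataset(records: list[InferenceRecord]) -> DatasetSummary:
    """Arithmetic means of per-image aggregates over the full image list."""
    if not records:
        raise ValueError("no records to summarize")
    b_vals = [r.B_min_A2 for r in records if r.B_min_A2 is not None]
    d_vals = [r.d_min_A for r in records if r.d_min_A is not None]
    o_vals = [r.overlap_label for r in records if r.overlap_label is not None]
    return DatasetSummary(
        n_images=len(records),
        mean_B_min_A2=float(np.mean(b_vals)) if b_vals else None,
        mean_d_min_A=float(np.mean(d_vals)) if d_vals else None,
        overlap_fraction=float(np.mean(o_vals)) if o_vals else None,
    )


def records_to_frame(records: list[InferenceRecord]) -> pd.DataFrame:
    """Report table: image_id, q1..q4 values, aggregates, overlap call."""
    rows = []
    for r in records:
        row = {"image_id": r.image_id}
        for i in range(4):
            row[f"q{i + 1}"] = (r.quadrant_values[i]
                                if i < len(r.quadrant_values) else np.nan)
        row.update(d_min_A=r.d_min_A, d_mean_A=r.d_mean_A,
                   B_min_A2=r.B_min_A2, p_overlap=r.p_overlap,
                   overlap_label=r.overlap_label)
        rows.append(row)
    return pd.DataFrame(rows)
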