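"""Patch-based inference over full fields with median stitching.

Full fields are larger than the network's training patch, so inference
slides a 256×256 window with stride 128 (half the patch, so tile edges
meet along common lines) and reconstructs each pixel as the median of the
predictions that cover it — 4 in the interior, fewer in the edge bands.
An even number of covering values uses the mean of the two middle order
statistics.  The final row/column of origins is clamped to the image edge
when the stride grid does not land exactly (e.g. 998 = 742 + 256).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import PairedField


@dataclass
class TilingPlan:
    image_height: int
    image_width: int
    patch: int
    stride: int
    origins: list[tuple[int, int]]
    coverage_map: np.ndarray

    @property
    def n_tiles(self) -> int:
        return len(self.origins)


def _axis_origins(length: int, patch: int, stride: int) -> list[int]:
    origins = list(range(0, length - patch + 1, stride))
    last = length - patch
    if origins[-1] != last:
        origins.append(last)  # clamped final origin at the image edge
    return origins


def plan_tiles(H: int, W: int, patch: int = 256, stride: int = 128) -> TilingPlan:
    """Grid of patch origins covering an H×W image, plus the coverage map."""
    if H < patch or W < patch:
        raise ValueError(f"image ({H}, {W}) smaller than patch {patch}")
    if stride < 1 or stride > patch:
        raise ValueError(f"stride must be in [1, patch], got {stride}")
    rows = _axis_origins(H, patch, stride)
    cols = _axis_origins(W, patch, stride)
    origins = [(r, c) for r in rows for c in cols]
    coverage = np.zeros((H, W), dtype=np.int32)
    for r, c in origins:
        coverage[r:r + patch, c:c + patch] += 1
    return TilingPlan(H, W, patch, stride, origins, coverage)


def stitch_median(patch_predictions: list[np.ndarray], plan: TilingPlan) -> np.ndarray:
    """Per-pixel median over all patches covering each pixel.

    ``patch_predictions``: one (C, patch, patch) array per plan origin, in
    plan order.  Memory is bounded by patch² × max coverage, not by the
    number of tiles: values are accumulated into per-coverage-slot layers.
    """
    if len(patch_predictions) != plan.n_tiles:
        raise ValueError(
            f"got {len(patch_predictions)} patch predictions for {plan.n_tiles} planned tiles")
    C = np.asarray(patch_predictions[0]).shape[0]
    H, W, P = plan.image_height, plan.image_width, plan.patch
    max_cov = int(plan.coverage_map.max())
    dtype = np.result_type(np.asarray(patch_predictions[0]).dtype, np.float32)
    layers = np.full((max_cov, C, H, W), np.nan, dtype=dtype)
    slot = np.zeros((H, W), dtype=np.int32)
    for (r, c), pred in zip(plan.origins, patch_predictions):
        pred = np.asarray(pred)
        if pred.shape[-2:] != (P, P):
            raise ValueError(f"patch prediction has shape {pred.shape}, expected (*, {P}, {P})")
        s = slot[r:r + P, c:c + P]
        layers[s, :, np.arange(r, r + P)[:, None], np.arange(c, c + P)[None, :]] = \
            np.moveaxis(pred, 0, -1)
        slot[r:r + P, c:c + P] += 1
    return np.nanmedian(layers, axis=0)


def predict_field(generator, field: PairedField, patch: int = 256,
                  stride: int = 128) -> np.ndarray:
    """Tiled forward pass + median stitching; deterministic given weights.

    ``generator`` needs a ``predict((3, P, P) -> (5, P, P))`` method; the
    identity contract is that stitching patches of the truth reproduces it
    bit-exactly.
    """
    H, W = field.shape
    plan = plan_tiles(H, W, patch, stride)
    preds = []
    for (r, c) in plan.origins:
        tile = field.brightfield[:, r:r + patch, c:c + patch]
        preds.append(np.asarray(generator.predict(tile)))
    return stitch_median(preds, plan)
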