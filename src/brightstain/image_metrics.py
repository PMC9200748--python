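"""Paired-image evaluation metrics: MAE, MSE, SSIM, PSNR, PCC.

All five are computed per fluorescent channel on the (typically
z-normalized) predicted/ground-truth pair, then averaged across channels.
Two conventions need fixing because they are not determined by the metric
names alone:

* **PSNR** is defined on 8-bit conversions: both images are mapped to
  [0, 255] by a single shared affine map built from the min/max of their
  union, then PSNR = 10·log10(255² / MSE₈).  The shared map keeps the
  metric symmetric in its arguments.  Identical images give ``inf``.
* **SSIM** uses a 7×7 uniform window with the standard stabilizers
  C1 = (0.01·L)², C2 = (0.03·L)² where L is the dynamic range of the pair,
  and averages the per-window index over all fully-interior windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .constants import FLUOR_CHANNELS

METRIC_NAMES = ("MAE", "MSE", "SSIM", "PSNR", "PCC")


def _check_pair(a, b):
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mae(a, b) -> float:
    a, b = _check_pair(a, b)
    return float(np.abs(a - b).mean())


def mse(a, b) -> float:
    a, b = _check_pair(a, b)
    return float(((a - b) ** 2).mean())


def pcc(a, b) -> float:
    """Pearson correlation over flattened pixels; errors on zero variance."""
    a, b = _check_pair(a, b)
    av, bv = a.ravel(), b.ravel()
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("PCC undefined: an image has zero pixel variance")
    return float(np.corrcoef(av, bv)[0, 1])


def psnr_8bit(a, b) -> float:
    """PSNR after a shared affine conversion of both images to [0, 255]."""
    a, b = _check_pair(a, b)
    if np.array_equal(a, b):
        return float("inf")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    scale = 255.0 / (hi - lo)
    a8 = (a - lo) * scale
    b8 = (b - lo) * scale
    m = ((a8 - b8) ** 2).mean()
    if m == 0:
        return float("inf")
    return float(10.0 * np.log10(255.0 ** 2 / m))


def ssim(a, b, win_size: int = 7, k1: float = 0.01, k2: float = 0.03,
         data_range: float | None = None) -> float:
    """Mean structural similarity over fully-interior uniform windows."""
    a, b = _check_pair(a, b)
    if min(a.shape) < win_size:
        raise ValueError(f"image {a.shape} smaller than SSIM window {win_size}")
    if data_range is None:
        both = np.concatenate([a.ravel(), b.ravel()])
        data_range = float(both.max() - both.min())
        if data_range == 0:
            data_range = 1.0  # two constant images: luminance term decides
    C1 = (k1 * data_range) ** 2
    C2 = (k2 * data_range) ** 2

    def filt(x):
        return uniform_filter(x, size=win_size)

    mu_a, mu_b = filt(a), filt(b)
    # unbiased (n/(n-1)) window variances/covariance, matching the reference
    n = win_size ** 2
    cov_norm = n / (n - 1)
    var_a = cov_norm * (filt(a * a) - mu_a ** 2)
    var_b = cov_norm * (filt(b * b) - mu_b ** 2)
    cov = cov_norm * (filt(a * b) - mu_a * mu_b)
    num = (2 * mu_a * mu_b + C1) * (2 * cov + C2)
    den = (mu_a ** 2 + mu_b ** 2 + C1) * (var_a + var_b + C2)
    s = num / den
    pad = (win_size - 1) // 2
    interior = s[pad:s.shape[0] - pad, pad:s.shape[1] - pad]
    return float(interior.mean())


@dataclass
class MetricReport:
    """Per-channel and channel-mean metric values for one field."""

    per_channel: pd.DataFrame  # index: channel (DNA..Mito); columns: metric names

    @property
    def means(self) -> pd.Series:
        return self.per_channel.mean(axis=0)

    @property
    def mean_pcc(self) -> float:
        return float(self.per_channel["PCC"].mean())

    def to_frame(self, field_id: str = "") -> pd.DataFrame:
        df = self.per_channel.copy()
        if field_id:
            df.insert(0, "field_id", field_id)
        return df


def evaluate_field(prediction: np.ndarray, truth: np.ndarray) -> MetricReport:
    """All five metrics for each of the five channels of one field."""
    prediction, truth = np.asarray(prediction), np.asarray(truth)
    if prediction.shape != truth.shape:
        raise ValueError(f"shape mismatch: {prediction.shape} vs {truth.shape}")
    if prediction.shape[0] != len(FLUOR_CHANNELS):
        raise ValueError(f"expected {len(FLUOR_CHANNELS)}-channel stacks")
    rows = {}
    for i, ch in enumerate(FLUOR_CHANNELS):
        p, t = prediction[i], truth[i]
        rows[ch] = {
            "MAE": mae(t, p),
            "MSE": mse(t, p),
            "SSIM": ssim(t, p),
            "PSNR": psnr_8bit(t, p),
            "PCC": pcc(t, p),
        }
    return MetricReport(pd.DataFrame(rows).T.loc[list(FLUOR_CHANNELS), list(METRIC_NAMES)])


def aggregate_reports(reports: list[MetricReport]) -> pd.DataFrame:
    """Mean ± sd over a set of fields, per channel and metric (long format)."""
    stack = pd.concat([r.per_channel.assign(_f=i) for i, r in enumerate(reports)])
    grouped = stack.drop(columns="_f").groupby(level=0, sort=False)
    out = grouped.agg(["mean", "std"])
    return out.loc[list(FLUOR_CHANNELS)]
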