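"""Morphological profiling: feature extraction, selection, comparison.

The real assay's features come from a CellProfiler segmentation pipeline;
this module accepts any such table but also ships a lightweight stand-in
extractor so the whole stage runs on synthetic images.  The stand-in
computes, per compartment (cell / cytoplasm / nuclei) and channel, the same
*kinds* of measurements CellProfiler reports — intensity, area/shape,
granularity, texture, neighbors, radial distribution — with the same
annotation schema, without claiming CellProfiler's exact formulas.

Feature selection is the four-rule reduction applied to ground-truth
profiles only (so the survivor set is blind to model predictions), in
order:

1. drop features with > 5% missing values, or > 5% zero values;
2. drop blocklisted feature names (a published list of unreliable features);
3. drop features correlating > 0.9 (absolute Pearson) with a kept feature,
   scanning features in decreasing-variance order;
4. drop features with standard deviation > 15 over DMSO (negative-control)
   wells, on raw feature values.

Predicted-vs-truth agreement is the per-feature Spearman correlation
across wells, averaged within (compartment, channel, feature_type) groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, uniform_filter
from scipy.stats import spearmanr
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .constants import COMPARTMENTS, FLUOR_CHANNELS
from .feature_table import FeatureTable, make_feature_name

#: a small fixture blocklist in the spirit of the published one: stand-in
#: feature names known to be scale-dependent / unstable in this extractor.
DEFAULT_BLOCKLIST = (
    "cell_intensity_DNA_integrated",
    "nuclei_intensity_AGP_integrated",
)


# ---------------------------------------------------------------------------
# stand-in feature extraction
# ---------------------------------------------------------------------------

def segment_field(fluorescent: np.ndarray) -> dict[str, np.ndarray]:
    """Threshold-and-watershed segmentation of nuclei and cells.

    A deliberately simple proxy for the external segmentation pipeline:
    nuclei from Otsu on the DNA channel; cells by watershed on the summed
    cytoplasmic channels seeded from the nuclei.
    """
    dna = np.asarray(fluorescent[0], dtype=np.float64)
    smooth = gaussian_filter(dna, 1.0)
    try:
        thr = threshold_otsu(smooth)
    except ValueError:  # constant image
        return {"nuclei": np.zeros(dna.shape, np.int32), "cells": np.zeros(dna.shape, np.int32)}
    nuclei = cc_label(smooth > thr)
    body = gaussian_filter(np.asarray(fluorescent[1] + fluorescent[2], dtype=np.float64), 2.0)
    try:
        body_mask = body > threshold_otsu(body)
    except ValueError:
        body_mask = nuclei > 0
    body_mask |= nuclei > 0
    cells = watershed(-body, markers=nuclei, mask=body_mask)
    return {"nuclei": nuclei.astype(np.int32), "cells": cells.astype(np.int32)}


def _compartment_masks(masks: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    nuclei = masks["nuclei"] > 0
    cells = masks["cells"] > 0
    return {"cell": cells, "nuclei": nuclei, "cytoplasm": cells & ~nuclei}


def extract_standin_features(fluorescent: np.ndarray,
                             masks: dict[str, np.ndarray] | None = None,
                             neighbor_radius: float = 40.0,
                             n_rings: int = 3) -> pd.Series:
    """Per-image feature vector over compartment × channel × feature type.

    ``masks``: dict with integer label images ``nuclei`` and ``cells``; when
    None a built-in segmentation of the fluorescent stack is used.  An empty
    segmentation yields a row of missing values.
    """
    fluorescent = np.asarray(fluorescent, dtype=np.float64)
    if masks is None:
        masks = segment_field(fluorescent)
    comp_masks = _compartment_masks(masks)
    cells_lbl = masks["cells"]
    nuclei_lbl = masks["nuclei"]
    labels = [l for l in np.unique(cells_lbl) if l != 0]
    features: dict[str, float] = {}

    def put(comp, ftype, chan, detail, value):
        features[make_feature_name(comp, ftype, chan, detail)] = value

    empty = len(labels) == 0

    # area/shape: mean object area (pixel count) per compartment
    for comp, lbl in (("cell", cells_lbl), ("nuclei", nuclei_lbl)):
        objs = [l for l in np.unique(lbl) if l != 0]
        area = np.nan if not objs else float(np.mean([(lbl == l).sum() for l in objs]))
        put(comp, "area_shape", "none", "area", area)
    cyto_area = np.nan if empty else float(comp_masks["cytoplasm"].sum() / len(labels))
    put("cytoplasm", "area_shape", "none", "area", cyto_area)
    put("cell", "area_shape", "none", "count", np.nan if empty else float(len(labels)))

    # neighbors: mean number of other cells with centroid within the radius
    if empty:
        put("cell", "neighbors", "none", "count", np.nan)
    else:
        cents = np.array([np.argwhere(cells_lbl == l).mean(axis=0) for l in labels])
        if len(cents) == 1:
            put("cell", "neighbors", "none", "count", 0.0)
        else:
            d = np.sqrt(((cents[:, None] - cents[None]) ** 2).sum(-1))
            counts = ((d < neighbor_radius).sum(axis=1) - 1)
            put("cell", "neighbors", "none", "count", float(counts.mean()))

    for ci, chan in enumerate(FLUOR_CHANNELS):
        img = fluorescent[ci]
        blur_small = gaussian_filter(img, 1.0)
        blur_large = gaussian_filter(img, 3.0)
        local_var = (img - uniform_filter(img, 5)) ** 2
        for comp in COMPARTMENTS:
            mask = comp_masks[comp]
            if empty or not mask.any():
                vals = {"mean": np.nan, "integrated": np.nan, "gran": np.nan, "tex": np.nan}
            else:
                pix = img[mask]
                vals = {
                    "mean": float(pix.mean()),
                    "integrated": float(pix.sum()),
                    "gran": float(((blur_small - blur_large)[mask] ** 2).mean()),
                    "tex": float(local_var[mask].mean()),
                }
            put(comp, "intensity", chan, "mean", vals["mean"])
            put(comp, "intensity", chan, "integrated", vals["integrated"])
            put(comp, "granularity", chan, "dog_energy", vals["gran"])
            put(comp, "texture", chan, "local_variance", vals["tex"])

        # radial distribution: intensity fraction in concentric rings, per cell
        ring_fracs = np.full(n_rings, np.nan)
        if not empty:
            per_cell = []
            for l in labels:
                obj = cells_lbl == l
                coords = np.argwhere(obj)
                cent = coords.mean(axis=0)
                r = np.sqrt(((coords - cent) ** 2).sum(axis=1))
                rmax = r.max()
                if rmax == 0:
                    continue
                intens = img[obj]
                total = intens.sum()
                if total <= 0:
                    continue
                edges = np.linspace(0, rmax, n_rings + 1)
                edges[-1] += 1e-9
                which = np.digitize(r, edges) - 1
                per_cell.append([intens[which == k].sum() / total for k in range(n_rings)])
            if per_cell:
                ring_fracs = np.mean(per_cell, axis=0)
        for k in range(n_rings):
            put("cell", "radial_distribution", chan, f"ring{k}", float(ring_fracs[k]))

    ann = pd.DataFrame(
        [dict(zip(("compartment", "feature_type", "channel"),
                  (n.split("_")[0],
                   "_".join(n.split("_")[1:-2]),
                   n.split("_")[-2])))
         for n in features],
        index=list(features),
    )
    s = pd.Series(features)
    s.attrs["annotations"] = ann
    return s


def features_to_table(rows: dict[str, pd.Series], meta: pd.DataFrame) -> FeatureTable:
    """Stack per-image feature Series (keyed by row id) into a FeatureTable."""
    data = pd.DataFrame(rows).T
    any_series = next(iter(rows.values()))
    ann = any_series.attrs["annotations"]
    return FeatureTable(data=data, annotations=ann.loc[data.columns], meta=meta.loc[data.index])


# ---------------------------------------------------------------------------
# aggregation and selection
# ---------------------------------------------------------------------------

def aggregate_profiles(table: FeatureTable, by: str = "well_id") -> FeatureTable:
    """Median per group (missing values excluded per feature)."""
    if by not in table.meta.columns:
        raise KeyError(f"grouping key {by!r} not in metadata")
    keys = table.meta[by]
    data = table.data.groupby(keys).median()
    meta = table.meta.groupby(keys).first()
    meta[by] = meta.index
    return FeatureTable(data=data, annotations=table.annotations.copy(), meta=meta)


@dataclass
class SelectionReport:
    survivors: list[str]
    rule1_missing: list[str] = dc_field(default_factory=list)
    rule2_blocklist: list[str] = dc_field(default_factory=list)
    rule3_correlated: list[str] = dc_field(default_factory=list)
    rule4_variable: list[str] = dc_field(default_factory=list)

    @property
    def dropped(self) -> list[str]:
        return self.rule1_missing + self.rule2_blocklist + self.rule3_correlated + self.rule4_variable

    def __post_init__(self):
        lists = [self.rule1_missing, self.rule2_blocklist, self.rule3_correlated,
                 self.rule4_variable, self.survivors]
        flat = [f for lst in lists for f in lst]
        if len(flat) != len(set(flat)):
            raise ValueError("selection drop lists must be disjoint from each other and survivors")


def select_features(table: FeatureTable, blocklist: list[str] | None = None,
                    dmso_mask: pd.Series | None = None,
                    nan_threshold: float = 0.05, zero_threshold: float = 0.05,
                    corr_threshold: float = 0.9,
                    sd_threshold: float = 15.0) -> SelectionReport:
    """Four-rule feature selection on ground-truth profiles.

    The survivor set is computed on this table only (use the ground-truth
    source) and then applied to every source via ``FeatureTable.select``.
    """
    if table.n_rows == 0:
        raise ValueError("empty feature table")
    if dmso_mask is None:
        dmso_mask = table.meta["role"] == "negative_control"
    if not bool(np.any(dmso_mask)):
        raise ValueError("no DMSO / negative-control rows for the variability rule")
    data = table.data
    remaining = list(data.columns)

    frac_nan = data.isna().mean()
    frac_zero = (data == 0).mean()
    rule1 = [f for f in remaining if frac_nan[f] > nan_threshold or frac_zero[f] > zero_threshold]
    remaining = [f for f in remaining if f not in set(rule1)]

    block = set(blocklist or [])
    rule2 = [f for f in remaining if f in block]
    remaining = [f for f in remaining if f not in set(rule2)]

    # greedy decorrelation, highest-variance feature kept first
    variances = data[remaining].var()
    order = variances.sort_values(ascending=False).index
    corr = data[remaining].corr().abs()
    kept: list[str] = []
    rule3: list[str] = []
    for f in order:
        if kept and (corr.loc[f, kept] > corr_threshold).any():
            rule3.append(f)
        else:
            kept.append(f)
    remaining = [f for f in remaining if f not in set(rule3)]

    sd_dmso = data.loc[np.asarray(dmso_mask), remaining].std()
    rule4 = [f for f in remaining if sd_dmso[f] > sd_threshold]
    survivors = [f for f in remaining if f not in set(rule4)]

    return SelectionReport(survivors=survivors, rule1_missing=rule1,
                           rule2_blocklist=rule2, rule3_correlated=rule3,
                           rule4_variable=rule4)


# ---------------------------------------------------------------------------
# predicted vs truth comparison
# ---------------------------------------------------------------------------

def grouped_feature_correlation(pred: FeatureTable, truth: FeatureTable):
    """Per-feature Spearman correlation across wells, averaged per group.

    Returns ``(group_means, per_feature, summary)`` where ``group_means`` is
    indexed by (compartment, channel, feature_type), ``per_feature`` is a
    Series of Spearman r (midranks for ties; missing for zero-variance
    columns), and ``summary`` holds the overall mean, the top-decile mean
    and the count of features with r > 0.8.
    """
    if list(pred.features) != list(truth.features):
        diff = set(pred.features) ^ set(truth.features)
        raise ValueError(f"feature sets differ between sources: {sorted(diff)[:5]} ...")
    if set(pred.data.index) != set(truth.data.index):
        raise ValueError("row identifiers differ between sources")
    t = truth.data
    p = pred.data.loc[t.index]
    rs = {}
    for f in t.columns:
        a, b = p[f].to_numpy(float), t[f].to_numpy(float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
            rs[f] = np.nan
            continue
        rs[f] = float(spearmanr(a[ok], b[ok]).statistic)
    per_feature = pd.Series(rs, name="spearman_r")

    ann = truth.annotations.loc[per_feature.index]
    grouped = per_feature.groupby(
        [ann["compartment"], ann["channel"], ann["feature_type"]])
    group_means = grouped.agg(mean_r="mean", n_features="count")

    valid = per_feature.dropna().sort_values(ascending=False)
    n_top = max(int(np.ceil(0.1 * len(valid))), 1) if len(valid) else 0
    summary = {
        "overall_mean": float(valid.mean()) if len(valid) else np.nan,
        "top_decile_mean": float(valid.iloc[:n_top].mean()) if n_top else np.nan,
        "n_above_0.8": int((valid > 0.8).sum()),
        "n_features": int(len(per_feature)),
    }
    return group_means, per_feature, summary


def embed_profiles(profiles: FeatureTable, method: str = "umap",
                   n_neighbors: int = 15, min_dist: float = 0.8,
                   n_components: int = 2, seed: int = 0) -> pd.DataFrame:
    """2-D embedding of profiles (UMAP by default, PCA as the check)."""
    X = profiles.data.to_numpy(float)
    if method == "umap" and X.shape[0] < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1 = {n_neighbors + 1} rows, have {X.shape[0]}")
    X = np.nan_to_num(X, nan=0.0)
    if method == "umap":
        import umap

        emb = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                        n_components=n_components, random_state=seed).fit_transform(X)
    elif method == "pca":
        from sklearn.decomposition import PCA

        emb = PCA(n_components=n_components, random_state=seed).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    cols = [f"dim{i + 1}" for i in range(n_components)]
    return pd.DataFrame(emb, index=profiles.data.index, columns=cols)
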