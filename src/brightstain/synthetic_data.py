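"""Synthetic paired-microscopy generator.

Every stage of the pipeline is testable without real data because this
module renders fields of view with a *known* deterministic brightfield →
fluorescence relationship:

* cells are non-overlapping ellipses (cytoplasm) containing smaller
  elliptical nuclei;
* the five fluorescent channels are deterministic functions of the scene —
  DNA marks nuclei (with chromatin texture), ER is a cytoplasmic texture,
  RNA adds bright nucleolar spots, AGP is a thin membrane rim plus 1-px
  filaments, Mito is a field of 1–2 px granular puncta;
* the three brightfield planes are channel mixtures of the same structures
  blurred with plane-specific widths (defocus), plus noise.  The 1–2 px
  AGP/Mito detail is mostly destroyed by the blur, so those channels are
  only partially recoverable from brightfield — by construction the hardest
  to predict, mirroring what fine subcellular structure does to real
  virtual-staining models.

Positive-control scenes model a mitoxantrone-like cytostatic phenotype:
cell area is enlarged and mitochondrial puncta density suppressed, both
scaled by ``toxic_effect_size``.

All generators are pure functions of their spec including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, gaussian_filter

from .constants import COMPARTMENTS, FEATURE_TYPES, FLUOR_CHANNELS, ROLES
from .data_io import PairedField, save_field
from .feature_table import FeatureTable

FLUOR_BACKGROUND = 0.02
BF_BACKGROUND = 0.10
#: defocus blur sigma (px) per brightfield plane, order (z−4, z0, z+4):
#: information loss grows with |z| away from focus.
BF_SIGMAS = (2.0, 1.0, 3.0)
#: channel-mixing weights per plane over (nucleus, cytoplasm, ER, AGP, Mito)
#: structures; three distinct mixtures make the planes complementary views.
BF_MIX = np.array([
    [0.55, 0.45, 0.25, 0.18, 0.10],
    [0.85, 0.55, 0.15, 0.22, 0.15],
    [0.35, 0.65, 0.35, 0.08, 0.20],
])


@dataclass
class SceneSpec:
    """Parameters of one rendered field of view."""

    image_size: int = 256
    n_cells: int = 14
    batch_id: str = "A"
    batch_intensity_shift: float | tuple = 1.0
    role: str = "treatment"
    toxic_effect_size: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError(f"image_size must be >= 64, got {self.image_size}")
        if self.n_cells < 0:
            raise ValueError(f"n_cells must be >= 0, got {self.n_cells}")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        shift = np.asarray(self.batch_intensity_shift, dtype=float)
        if shift.ndim not in (0, 1) or (shift.ndim == 1 and shift.size != 5):
            raise ValueError("batch_intensity_shift must be a scalar or a 5-vector")
        if np.any(shift <= 0):
            raise ValueError("batch_intensity_shift must be positive")


def _place_cells(rng: np.random.Generator, spec: SceneSpec) -> list[dict]:
    """Rejection-sample non-overlapping elliptical cells."""
    S = spec.image_size
    enlarge = 1.0
    if spec.role == "positive_control":
        enlarge = 1.0 + 0.30 * spec.toxic_effect_size
    cells: list[dict] = []
    attempts = 0
    max_attempts = 400 * max(spec.n_cells, 1)
    while len(cells) < spec.n_cells:
        if attempts > max_attempts:
            raise ValueError(
                f"could not place n_cells={spec.n_cells} non-overlapping cells "
                f"in a {S}x{S} field; reduce n_cells or toxic_effect_size")
        attempts += 1
        a = rng.uniform(10.0, 14.0) * enlarge
        b = a * rng.uniform(0.65, 0.95)
        theta = rng.uniform(0, np.pi)
        margin = a + 1
        cy = rng.uniform(margin, S - margin)
        cx = rng.uniform(margin, S - margin)
        if any(np.hypot(cy - c["cy"], cx - c["cx"]) < 1.02 * (a + c["a"]) for c in cells):
            continue
        cells.append({"cy": cy, "cx": cx, "a": a, "b": b, "theta": theta,
                      "intensity": rng.uniform(0.8, 1.2)})
    return cells


def _ellipse_mask(S: int, cy, cx, a, b, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:S, 0:S]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _stamp_gaussian(img: np.ndarray, cy: float, cx: float, sigma: float, amp: float):
    """Add a small Gaussian spot in place (windowed for speed)."""
    S = img.shape[0]
    r = max(2, int(np.ceil(3 * sigma)))
    y0, y1 = max(0, int(cy) - r), min(S, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(S, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))


def render_scene(spec: SceneSpec) -> dict:
    """Render the noiseless scene: structure maps and label masks.

    Returns a dict with per-structure float maps (``nucleus``, ``cytoplasm``,
    ``er``, ``rna``, ``agp``, ``mito``), integer label images
    (``nuclei_labels``, ``cell_labels``) and the cell list.
    """
    rng = np.random.default_rng(spec.seed)
    S = spec.image_size
    cells = _place_cells(rng, spec)

    nucleus = np.zeros((S, S), dtype=np.float32)
    cyto = np.zeros((S, S), dtype=np.float32)
    rna_spots = np.zeros((S, S), dtype=np.float32)
    agp_fil = np.zeros((S, S), dtype=np.float32)
    mito = np.zeros((S, S), dtype=np.float32)
    nuclei_labels = np.zeros((S, S), dtype=np.int32)
    cell_labels = np.zeros((S, S), dtype=np.int32)

    mito_density = 0.030
    if spec.role == "positive_control":
        mito_density /= (1.0 + spec.toxic_effect_size)

    for idx, c in enumerate(cells, start=1):
        cmask = _ellipse_mask(S, c["cy"], c["cx"], c["a"], c["b"], c["theta"])
        nmask = _ellipse_mask(S, c["cy"], c["cx"], 0.45 * c["a"], 0.45 * c["b"], c["theta"])
        cell_labels[cmask] = idx
        nuclei_labels[nmask] = idx
        cyto[cmask] = np.maximum(cyto[cmask], c["intensity"])
        nucleus[nmask] = c["intensity"]

        # nucleoli: 2-3 bright sub-nuclear spots (RNA channel)
        for _ in range(rng.integers(2, 4)):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 0.25 * c["a"])
            _stamp_gaussian(rna_spots, c["cy"] + rad * np.sin(ang),
                            c["cx"] + rad * np.cos(ang), sigma=1.1,
                            amp=rng.uniform(0.9, 1.3))

        # actin-like filaments: thin random chords through the cytoplasm
        n_fil = rng.integers(3, 6)
        for _ in range(n_fil):
            ang = rng.uniform(0, np.pi)
            offs = rng.uniform(-0.5, 0.5) * c["b"]
            length = rng.uniform(0.8, 1.6) * c["a"]
            t = np.linspace(-length, length, int(4 * length))
            ys = c["cy"] + t * np.sin(ang) + offs * np.cos(ang)
            xs = c["cx"] + t * np.cos(ang) - offs * np.sin(ang)
            ok = (ys >= 0) & (ys < S) & (xs >= 0) & (xs < S)
            yi, xi = ys[ok].astype(int), xs[ok].astype(int)
            inside = cmask[yi, xi]
            agp_fil[yi[inside], xi[inside]] = rng.uniform(0.5, 0.8)

        # mitochondrial puncta: 1-2 px granules in the cytoplasmic ring
        area = np.pi * c["a"] * c["b"]
        n_puncta = rng.poisson(mito_density * area)
        for _ in range(n_puncta):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.5, 0.95)
            py = c["cy"] + rad * c["a"] * np.sin(ang) * 0.9
            px = c["cx"] + rad * c["b"] * np.cos(ang) * 0.9
            _stamp_gaussian(mito, py, px, sigma=0.7, amp=rng.uniform(0.7, 1.3))

    # chromatin / cytoplasm textures (smooth multiplicative fields)
    chromatin = gaussian_filter(rng.normal(0, 1, (S, S)), 1.5).astype(np.float32)
    cyto_tex = gaussian_filter(rng.normal(0, 1, (S, S)), 3.0).astype(np.float32)
    for tex in (chromatin, cyto_tex):
        sd = tex.std()
        if sd > 0:
            tex /= sd

    nucleus_map = nucleus * (1.0 + 0.18 * chromatin) * (nuclei_labels > 0)
    rim = (cell_labels > 0) & ~binary_erosion(cell_labels > 0, iterations=2)
    er_map = cyto * (0.55 + 0.25 * cyto_tex) * (cell_labels > 0)

    return {
        "nucleus": nucleus_map.astype(np.float32),
        "cytoplasm": cyto.astype(np.float32),
        "er": er_map.astype(np.float32),
        "rna": (0.25 * cyto + rna_spots).astype(np.float32),
        "agp": (0.9 * rim.astype(np.float32) + agp_fil + 0.15 * cyto).astype(np.float32),
        "mito": (mito + 0.10 * cyto).astype(np.float32),
        "nuclei_labels": nuclei_labels,
        "cell_labels": cell_labels,
        "cells": cells,
        "rng": rng,
    }


def generate_field(spec: SceneSpec, return_masks: bool = False):
    """Render one paired field from its spec (bit-identical per spec + seed)."""
    scene = render_scene(spec)
    rng = scene["rng"]
    S = spec.image_size

    fluor = np.stack([
        scene["nucleus"],
        scene["er"],
        scene["rna"],
        scene["agp"],
        scene["mito"],
    ]) + FLUOR_BACKGROUND

    shift = np.asarray(spec.batch_intensity_shift, dtype=np.float32)
    shift5 = np.broadcast_to(shift.reshape(-1, 1, 1) if shift.ndim else shift, (5, 1, 1))
    fluor = fluor * shift5

    structures = np.stack([
        scene["nucleus"], scene["cytoplasm"], scene["er"],
        scene["agp"], scene["mito"],
    ])
    bf = np.empty((3, S, S), dtype=np.float32)
    bf_gain = float(np.mean(shift)) ** 0.5  # batch illumination drift
    for p in range(3):
        mix = np.tensordot(BF_MIX[p], structures, axes=1)
        bf[p] = gaussian_filter(mix, BF_SIGMAS[p]) * bf_gain + BF_BACKGROUND

    if spec.noise_sd > 0:
        bf = bf + rng.normal(0, spec.noise_sd, bf.shape).astype(np.float32)
        fluor = fluor + rng.normal(0, spec.noise_sd, fluor.shape).astype(np.float32)

    field = PairedField(
        brightfield=bf.astype(np.float32),
        fluorescent=fluor.astype(np.float32),
        batch_id=spec.batch_id,
        role=spec.role,
    )
    if return_masks:
        return field, {"nuclei": scene["nuclei_labels"], "cells": scene["cell_labels"]}
    return field


def default_batch_plan() -> list[SceneSpec]:
    """Two batches, B with a +30% intensity shift relative to A."""
    return [
        SceneSpec(batch_id="A", batch_intensity_shift=1.0),
        SceneSpec(batch_id="B", batch_intensity_shift=1.3),
    ]


def _role_for(i: int) -> str:
    """Deterministic role cycle ≈ 10% positive, 30% negative, 60% treatment."""
    r = i % 10
    if r == 0:
        return "positive_control"
    if r in (1, 2, 3):
        return "negative_control"
    return "treatment"


def generate_dataset(n_fields: int, batch_plan: list[SceneSpec] | None,
                     out_dir: Path, seed: int, image_size: int = 256,
                     n_cells: int = 14, noise_sd: float = 0.02) -> pd.DataFrame:
    """Write a dataset of paired fields as 16-bit TIFFs plus a manifest.

    Fields are assigned round-robin to the batch-plan templates; roles cycle
    deterministically; per-field seeds derive from the master seed.  The
    manifest (``manifest.csv``) has one row per field with one path column
    per channel (8 TIFFs per row).
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    plan = batch_plan or default_batch_plan()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_fields) & 0x7FFFFFFF
    rows = []
    for i in range(n_fields):
        template = plan[i % len(plan)]
        spec = replace(template, image_size=image_size, n_cells=n_cells,
                       noise_sd=noise_sd, role=_role_for(i), seed=int(child_seeds[i]))
        field = generate_field(spec)
        field.field_id = f"f{i:04d}"
        field.well_id = f"{field.batch_id}{i:03d}"
        field.batch_id = spec.batch_id
        paths = save_field(field, out_dir / spec.batch_id)
        row = {"field_id": field.field_id, "batch": spec.batch_id,
               "well": field.well_id, "role": spec.role, "seed": spec.seed}
        row.update({f"path_{ch}": p for ch, p in paths.items()})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def generate_feature_table(n_wells: int, n_features: int, fraction_nan: float = 0.1,
                           n_duplicate_pairs: int = 3, n_toxic: int = 8,
                           effect_size: float = 3.0, seed: int = 0) -> FeatureTable:
    """Gaussian feature matrix with planted structure for pipeline tests.

    Planted structure, all recorded in the returned table's attributes:

    * ``round(fraction_nan * n_features)`` features get >5% missing values
      (every other feature has none);
    * ``n_duplicate_pairs`` feature pairs are near-duplicates (r > 0.9);
    * ``n_toxic`` wells carry a mean shift of ``effect_size`` on a fixed
      quarter of the features.  Half of them are labelled positive controls,
      half toxic treatments; an equal number of clean wells are labelled
      negative controls, the remainder treatments.  ``meta['is_toxic']``
      records the ground truth.
    """
    if n_features <= 2 * n_duplicate_pairs:
        raise ValueError("n_features must exceed 2 * n_duplicate_pairs")
    if n_toxic * 2 > n_wells:
        raise ValueError("n_toxic must be at most half of n_wells")
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n_wells, n_features))

    # duplicate pairs occupy the first 2*n_duplicate_pairs columns
    dup_pairs = []
    for j in range(n_duplicate_pairs):
        a, b = 2 * j, 2 * j + 1
        X[:, b] = X[:, a] + rng.normal(0, 0.2, n_wells)
        dup_pairs.append((a, b))

    # toxic phenotype: mean shift on the last quarter of features
    shifted = np.arange(n_features - max(n_features // 4, 1), n_features)
    toxic_wells = np.arange(n_toxic)
    X[np.ix_(toxic_wells, shifted)] += effect_size

    # missing-value features (outside the duplicate block)
    n_nan = int(round(fraction_nan * n_features))
    nan_features = np.arange(2 * n_duplicate_pairs, 2 * n_duplicate_pairs + n_nan)
    for j in nan_features:
        k = max(int(0.08 * n_wells), int(0.05 * n_wells) + 1)  # strictly > 5%
        rows = rng.choice(n_wells, size=k, replace=False)
        X[rows, j] = np.nan

    names, ann = [], []
    for j in range(n_features):
        comp = COMPARTMENTS[j % len(COMPARTMENTS)]
        ftype = FEATURE_TYPES[j % len(FEATURE_TYPES)]
        chan = FLUOR_CHANNELS[j % len(FLUOR_CHANNELS)]
        names.append(f"{comp}_{ftype}_{chan}_{j}")
        ann.append({"compartment": comp, "feature_type": ftype, "channel": chan})

    roles = np.array(["treatment"] * n_wells, dtype=object)
    roles[toxic_wells[: n_toxic // 2]] = "positive_control"
    clean = np.arange(n_toxic, n_toxic + n_toxic)
    roles[clean] = "negative_control"
    is_toxic = np.zeros(n_wells, dtype=bool)
    is_toxic[toxic_wells] = True

    wells = [f"W{i:04d}" for i in range(n_wells)]
    data = pd.DataFrame(X, index=wells, columns=names)
    annotations = pd.DataFrame(ann, index=names)
    meta = pd.DataFrame({"well_id": wells, "batch": "A", "role": roles,
                         "source": "ground_truth", "is_toxic": is_toxic}, index=wells)
    table = FeatureTable(data=data, annotations=annotations, meta=meta)
    table.planted = {
        "nan_features": [names[j] for j in nan_features],
        "duplicate_pairs": [(names[a], names[b]) for a, b in dup_pairs],
        "shifted_features": [names[j] for j in shifted],
        "toxic_wells": [wells[i] for i in toxic_wells],
    }
    return table
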