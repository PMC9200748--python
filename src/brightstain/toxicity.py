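"""Profile-level toxicity calling.

Wells are classified toxic / non-toxic from their morphological profiles
with a K-NN classifier (k = 5, Euclidean) trained on control wells:
positive controls (mitoxantrone-like phenotype) versus negative controls
(DMSO).  Because the control classes are imbalanced, each of ``n_runs``
(default 100) runs draws an equal number of profiles per class with
replacement; the final call per well is the majority vote over runs, with
an exact tie called non-toxic (the specificity-preserving default).

Control wells are themselves evaluated leave-self-out: a control's own
resampled copies are excluded from its neighbour set, otherwise every
control would trivially vote for its own class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .feature_table import FeatureTable


def normalize_profiles(profiles: FeatureTable) -> FeatureTable:
    """Per-feature z-score across rows; zero-variance features map to zero."""
    if profiles.n_rows < 2:
        raise ValueError("need at least 2 rows to normalize profiles")
    data = profiles.data
    mu = data.mean()
    sd = data.std(ddof=0)
    z = (data - mu).div(sd.replace(0, np.inf))
    out = profiles.copy()
    out.data = z
    return out


@dataclass
class ToxicityResult:
    table: pd.DataFrame  # well_id, votes, call, role (+ truth when known)
    n_runs: int
    sensitivity: float | None = None
    specificity: float | None = None

    @property
    def identified(self) -> list[str]:
        return list(self.table.loc[self.table["call"], "well_id"])

    def summary(self) -> str:
        line = (f"toxicity calls: {int(self.table['call'].sum())} of "
                f"{len(self.table)} wells over {self.n_runs} runs")
        if self.sensitivity is not None:
            line += (f"; sensitivity {100 * self.sensitivity:.1f}%"
                     f", specificity {100 * self.specificity:.1f}%")
        return line


def classify_toxicity(profiles: FeatureTable, k: int = 5, n_runs: int = 100,
                      seed: int = 0, truth_column: str = "is_toxic") -> ToxicityResult:
    """Balanced-resample K-NN with majority voting over ``n_runs`` runs.

    ``profiles`` must be normalized; control labels come from
    ``meta['role']``.  Every well is classified each run (controls with
    their own resampled copies excluded); sensitivity/specificity are
    computed against ``meta[truth_column]`` when present.
    """
    roles = profiles.meta["role"]
    pos_idx = np.flatnonzero((roles == "positive_control").to_numpy())
    neg_idx = np.flatnonzero((roles == "negative_control").to_numpy())
    if pos_idx.size == 0:
        raise ValueError("no positive-control wells to train on")
    if neg_idx.size == 0:
        raise ValueError("no negative-control wells to train on")
    X = np.nan_to_num(profiles.data.to_numpy(float), nan=0.0)
    n_wells = X.shape[0]
    rng = np.random.default_rng(seed)
    n_per_class = int(max(pos_idx.size, neg_idx.size))

    # distances from every well to every potential training well
    pool = np.concatenate([pos_idx, neg_idx])
    D = cdist(X, X[pool])
    pool_pos = np.arange(pool.size) < pos_idx.size

    votes = np.zeros(n_wells, dtype=int)
    for _ in range(n_runs):
        sel_pos = rng.integers(0, pos_idx.size, size=n_per_class)
        sel_neg = pos_idx.size + rng.integers(0, neg_idx.size, size=n_per_class)
        sel = np.concatenate([sel_pos, sel_neg])          # indices into pool
        d_run = D[:, sel]                                  # (n_wells, 2·n_per_class)
        toxic_label = pool_pos[sel]
        origin = pool[sel]                                 # well index of each sample
        # leave-self-out: a well never sees its own resampled copies
        d_run = np.where(origin[None, :] == np.arange(n_wells)[:, None], np.inf, d_run)
        nearest = np.argpartition(d_run, k - 1, axis=1)[:, :k]
        toxic_votes = toxic_label[nearest].sum(axis=1)
        votes += (toxic_votes > k / 2).astype(int)

    calls = votes > n_runs / 2  # exact tie -> non-toxic
    table = pd.DataFrame({
        "well_id": profiles.meta["well_id"].to_numpy(),
        "votes": votes,
        "call": calls,
        "role": roles.to_numpy(),
    }, index=profiles.data.index)
    result = ToxicityResult(table=table, n_runs=n_runs)
    if truth_column in profiles.meta.columns:
        truth = profiles.meta[truth_column].astype(bool).to_numpy()
        table["truth"] = truth
        if truth.any() and (~truth).any():
            result.sensitivity, result.specificity = confusion_metrics(calls, truth)
    return result


def confusion_metrics(calls, truth) -> tuple[float, float]:
    """(sensitivity, specificity) = (TP/(TP+FN), TN/(TN+FP))."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    if not truth.any() or truth.all():
        raise ValueError("truth must contain both classes")
    tp = int((calls & truth).sum())
    fn = int((~calls & truth).sum())
    tn = int((~calls & ~truth).sum())
    fp = int((calls & ~truth).sum())
    return tp / (tp + fn), tn / (tn + fp)
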