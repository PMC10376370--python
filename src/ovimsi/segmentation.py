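"""Spatial segmentation by bisecting k-means under the Manhattan metric, and
epithelium ROI selection against a reference mask.

Starting from one cluster containing every spot, the leaf with the largest
total L1 dispersion about its component-wise median is repeatedly split by a
2-cluster alternating minimization (Manhattan assignment, component-wise
median centers — the L1 dispersion minimizer), for a configured depth.  The
epithelial cluster is then identified by Dice overlap with a user-supplied
reference mask, the stand-in for manual co-registration with a stained
optical scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io import IonImageDataset
from .peaks import FeatureTable


@dataclass
class RoiMask:
    """Per-spot boolean region of interest."""

    mask: np.ndarray
    source: str = "reference"  # "reference" or "cluster_match"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask must select at least one spot")

    @property
    def n_spots(self) -> int:
        return int(self.mask.sum())


@dataclass
class SegmentationResult:
    labels: np.ndarray  # leaf id per spot, 0..depth
    tree: list[dict] = field(default_factory=list)
    depth: int = 0
    seed: int = 0

    def leaf_ids(self) -> np.ndarray:
        return np.unique(self.labels)


def _l1_dispersion(x: np.ndarray) -> float:
    """Total Manhattan deviation about the component-wise median."""
    if x.shape[0] == 0:
        return 0.0
    return float(np.abs(x - np.median(x, axis=0)).sum())


def _split_l1(
    x: np.ndarray, rng: np.random.Generator, restarts: int, max_iter: int = 50
) -> np.ndarray | None:
    """2-means under L1 with median centers; best of ``restarts`` random
    initializations.  Returns a boolean assignment or None if every restart
    produced an empty child (degenerate data)."""
    n = x.shape[0]
    # canonical (lexicographic) row order makes the split invariant to the
    # ordering of the input spots for a fixed seed
    canon = np.lexsort(x.T)
    best_obj, best_assign = np.inf, None
    for _ in range(restarts):
        idx = canon[rng.choice(n, size=2, replace=False)]
        centers = x[idx].astype(np.float64)
        if np.array_equal(centers[0], centers[1]):
            continue
        assign = None
        for _ in range(max_iter):
            d = cdist(x, centers, metric="cityblock")
            new_assign = d[:, 1] < d[:, 0]
            if assign is not None and np.array_equal(new_assign, assign):
                break
            assign = new_assign
            if assign.all() or not assign.any():
                assign = None
                break
            centers = np.vstack(
                [np.median(x[~assign], axis=0), np.median(x[assign], axis=0)]
            )
        if assign is None:
            continue
        obj = float(
            np.abs(x[~assign] - centers[0]).sum() + np.abs(x[assign] - centers[1]).sum()
        )
        if obj < best_obj:
            best_obj, best_assign = obj, assign
    return best_assign


def bisecting_kmeans(
    table: FeatureTable | np.ndarray,
    depth: int = 3,
    seed: int = 0,
    restarts: int = 5,
) -> SegmentationResult:
    """Hierarchically split spots into ``depth + 1`` clusters.

    The leaf with the largest within-cluster L1 dispersion is split at each
    step; per-split dispersions are recorded in the result tree so a user can
    judge a sensible depth (the interactive choice of the original workflow
    becomes an inspectable diagnostic).
    """
    x = table.values if isinstance(table, FeatureTable) else np.asarray(table, float)
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty feature table")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if depth + 1 > n:
        raise ValueError(f"depth {depth} requires more than {n} spots")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=np.int64)
    tree: list[dict] = []
    next_id = 1
    for _ in range(depth):
        leaf_disp = {lid: _l1_dispersion(x[labels == lid]) for lid in np.unique(labels)}
        parent = max(leaf_disp, key=lambda k: (leaf_disp[k], -k))
        rows = labels == parent
        assign = _split_l1(x[rows], rng, restarts)
        if assign is None:
            raise ValueError(
                f"cluster {parent} could not be split after {restarts} restarts "
                "(degenerate or constant data)"
            )
        child = next_id
        next_id += 1
        sub = labels[rows]
        sub[assign] = child
        labels[rows] = sub
        after = _l1_dispersion(x[labels == parent]) + _l1_dispersion(x[labels == child])
        tree.append(
            {
                "parent": int(parent),
                "children": (int(parent), int(child)),
                "dispersion_before": leaf_disp[parent],
                "dispersion_after": after,
            }
        )
    return SegmentationResult(labels=labels, tree=tree, depth=depth, seed=seed)


def segmentation_feature_columns(table: FeatureTable, top_k: int | None = 100) -> np.ndarray:
    """Columns used for spatial segmentation: the ``top_k`` peaks with the
    highest mean intensity (all peaks if ``top_k`` is None).

    A generous peak-picking budget admits atoms that model residual noise;
    restricting the segmentation to the most intense peaks is the usual
    dimension reduction before clustering and keeps the tissue signature from
    being diluted by noise-level features.  Sorted so column order is stable.
    """
    if top_k is None or top_k >= table.values.shape[1]:
        return np.arange(table.values.shape[1])
    idx = np.argsort(table.values.mean(axis=0))[::-1][:top_k]
    return np.sort(idx)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else 0.0


def select_roi(
    seg: SegmentationResult,
    reference: RoiMask,
    min_dice: float = 0.2,
    union_threshold: float | None = None,
) -> RoiMask:
    """Pick the leaf cluster(s) matching the reference epithelium mask.

    By default the single best-Dice leaf is returned; with
    ``union_threshold`` set, all leaves whose Dice exceeds it are united.

    Raises
    ------
    ValueError
        If the best Dice is below ``min_dice`` — the segmentation failed to
        isolate the epithelium.
    """
    ref = reference.mask
    if ref.shape[0] != seg.labels.shape[0]:
        raise ValueError("reference mask length mismatch")
    scores = {int(l): dice(seg.labels == l, ref) for l in seg.leaf_ids()}
    best = max(scores, key=scores.get)
    if scores[best] < min_dice:
        raise ValueError(
            f"segmentation failed to isolate the epithelium (best Dice {scores[best]:.3f})"
        )
    if union_threshold is None:
        mask = seg.labels == best
    else:
        chosen = [l for l, s in scores.items() if s > union_threshold] or [best]
        mask = np.isin(seg.labels, chosen)
    return RoiMask(mask=mask, source="cluster_match")


def ion_density_map(
    dataset: IonImageDataset, center_mz: float, half_width: float
) -> np.ndarray:
    """Per-spot summed intensity of one peak interval arranged on the grid.

    Returns a 2-D array (NaN outside acquired spots), rendered elsewhere with
    a blue-to-red gradient.
    """
    mz = dataset.mz_axis
    lo = np.searchsorted(mz, center_mz - half_width)
    hi = np.searchsorted(mz, center_mz + half_width, side="right")
    if hi <= lo:
        raise ValueError(
            f"no channels in interval {center_mz - half_width:.2f}..{center_mz + half_width:.2f}"
            " (outside the axis or inside an excluded window)"
        )
    vals = dataset.intensities[:, lo:hi].sum(axis=1)
    nx = int(dataset.coords[:, 0].max()) + 1
    ny = int(dataset.coords[:, 1].max()) + 1
    img = np.full((nx, ny), np.nan)
    img[dataset.coords[:, 0], dataset.coords[:, 1]] = vals
    return img


def save_map_png(img: np.ndarray, path, title: str | None = None) -> None:
    """Render an ion-density or label map as PNG (blue -> red gradient)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(img.T, origin="lower", cmap="jet", interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
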