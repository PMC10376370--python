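"""Peak detection and per-spot feature extraction.

Peaks are detected once per (time point, mode) batch on the pooled mean
spectrum by orthogonal matching pursuit over a dictionary of unit-norm
Gaussian atoms, one centered at every channel: the atom best correlated with
the residual is selected, all selected coefficients are refit by least
squares, and the residual is updated, until the relative residual norm drops
below a tolerance or a peak budget is exhausted.  Detected centers are then
aligned to the mean spectrum by intensity-weighted centroids, and per-spot
intensities are aggregated over disjoint peak intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .io import IonImageDataset


@dataclass
class PeakSet:
    """Sorted detected peaks: centers (Th) and half-widths (Th) of pairwise
    disjoint aggregation intervals ``[center - hw, center + hw]``."""

    centers: np.ndarray
    half_widths: np.ndarray
    sigma: float
    mode: str = "positive"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.half_widths = np.asarray(self.half_widths, dtype=np.float64)
        if self.centers.size:
            if np.any(np.diff(self.centers) <= 0):
                raise ValueError("peak centers must be strictly increasing")
            lo = self.centers - self.half_widths
            hi = self.centers + self.half_widths
            if np.any(hi[:-1] > lo[1:] + 1e-12):
                raise ValueError("peak intervals must be pairwise disjoint")

    def __len__(self) -> int:
        return self.centers.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"center_mz": self.centers, "half_width": self.half_widths})


@dataclass
class FeatureTable:
    """Spots x peaks intensity matrix with per-row sample labels.

    ``spots`` carries sample_id/group/timepoint/mode/x/y per row; ``values``
    is the nonnegative aggregated intensity per peak interval.
    """

    spots: pd.DataFrame
    values: np.ndarray
    peak_set: PeakSet

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.spots), len(self.peak_set)):
            raise ValueError("values shape inconsistent with spots x peaks")

    def rows_for_sample(self, sample_id: str) -> np.ndarray:
        return (self.spots["sample_id"] == sample_id).to_numpy()

    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.spots["sample_id"]))

    def roi_row_mask(self, rois: Mapping[str, np.ndarray]) -> np.ndarray:
        """Per-row boolean built from per-sample ROI masks (each aligned with
        that sample's spot order)."""
        mask = np.zeros(len(self.spots), dtype=bool)
        for sid in self.sample_ids():
            rows = self.rows_for_sample(sid)
            roi = np.asarray(getattr(rois[sid], "mask", rois[sid]), dtype=bool)
            if roi.shape[0] != int(rows.sum()):
                raise ValueError(f"ROI length mismatch for sample {sid}")
            mask[rows] = roi
        return mask

    def to_frame(self) -> pd.DataFrame:
        cols = [f"mz_{c:.4f}" for c in self.peak_set.centers]
        return pd.concat(
            [self.spots.reset_index(drop=True), pd.DataFrame(self.values, columns=cols)],
            axis=1,
        )


def _check_shared_axis(datasets: Sequence[IonImageDataset]) -> np.ndarray:
    if not datasets:
        raise ValueError("no datasets")
    mz = datasets[0].mz_axis
    for d in datasets[1:]:
        if not np.array_equal(d.mz_axis, mz):
            raise ValueError("datasets do not share one m/z axis")
    return mz


def mean_spectrum(datasets: Sequence[IonImageDataset]) -> np.ndarray:
    """Unweighted mean over all spots of all datasets."""
    mz = _check_shared_axis(datasets)
    total = np.zeros(mz.size)
    n = 0
    for d in datasets:
        total += d.intensities.sum(axis=0, dtype=np.float64)
        n += d.n_spots
    return total / n


def skyline_spectrum(datasets: Sequence[IonImageDataset]) -> np.ndarray:
    """Skyline projection: per-channel maximum over all spots of one group."""
    mz = _check_shared_axis(datasets)
    groups = {d.group for d in datasets}
    if len(groups) != 1:
        raise ValueError(f"skyline spectra are per group; got {sorted(groups)}")
    out = np.zeros(mz.size)
    for d in datasets:
        np.maximum(out, d.intensities.max(axis=0), out=out)
    return out


def _gaussian_dictionary(mz_axis: np.ndarray, sigma: float) -> sparse.csc_matrix:
    """Unit-norm Gaussian atoms (support truncated at 4 sigma) centered at
    every channel, as a sparse [n_channels x n_atoms] matrix.  Atom values use
    true m/z differences, so excluded-window gaps in the axis are handled."""
    n = mz_axis.size
    spacing = np.median(np.diff(mz_axis))
    w = max(1, int(np.ceil(4 * sigma / spacing)))
    offsets = np.arange(-w, w + 1)
    rows = np.arange(n)[:, None] + offsets[None, :]
    valid = (rows >= 0) & (rows < n)
    rows_c = np.clip(rows, 0, n - 1)
    dmz = mz_axis[rows_c] - mz_axis[:, None]
    vals = np.exp(-0.5 * (dmz / sigma) ** 2)
    vals[~valid | (np.abs(dmz) > 4 * sigma)] = 0.0
    cols = np.repeat(np.arange(n), offsets.size)
    mat = sparse.csc_matrix(
        (vals.ravel(), (rows_c.ravel(), cols)), shape=(n, n)
    )
    norms = np.sqrt(np.asarray(mat.multiply(mat).sum(axis=0)).ravel())
    norms[norms == 0] = 1.0
    return mat @ sparse.diags(1.0 / norms)


def _apex_center(r: np.ndarray, mz_axis: np.ndarray, i: int, sigma: float) -> float:
    """Sub-channel peak center near channel ``i`` of the residual spectrum.

    Locates the apex within +/- sigma and applies three-point Gaussian
    (log-parabolic) interpolation — exact for a sampled Gaussian; falls back
    to the intensity-weighted centroid when the interpolation is undefined.
    """
    lo = np.searchsorted(mz_axis, mz_axis[i] - sigma)
    hi = np.searchsorted(mz_axis, mz_axis[i] + sigma, side="right")
    j = lo + int(np.argmax(r[lo:hi]))
    if 0 < j < r.size - 1 and r[j - 1] > 0 and r[j] > 0 and r[j + 1] > 0:
        la, lb, lc = np.log(r[j - 1]), np.log(r[j]), np.log(r[j + 1])
        denom = la - 2 * lb + lc
        if denom < 0:  # concave apex
            delta = 0.5 * (la - lc) / denom
            if abs(delta) <= 1.0:
                spacing = (mz_axis[j + 1] - mz_axis[j - 1]) / 2.0
                return float(mz_axis[j] + delta * spacing)
    wgt = np.clip(r[lo:hi], 0.0, None)
    if wgt.sum() > 0:
        return float((mz_axis[lo:hi] * wgt).sum() / wgt.sum())
    return float(mz_axis[i])


def omp_detect_peaks(
    mean_spec: np.ndarray,
    mz_axis: np.ndarray,
    sigma: float = 0.25,
    max_peaks: int = 500,
    residual_tol: float = 0.02,
    mode: str = "positive",
) -> PeakSet:
    """Greedy OMP peak detection on a mean spectrum.

    Parameters
    ----------
    sigma
        Width (Th) of the Gaussian atoms; should match the instrument peak
        width at the analysed resolution.
    max_peaks
        Iteration budget (atoms selected).
    residual_tol
        Stop when ||residual|| / ||mean_spec|| falls below this fraction.

    Returns
    -------
    PeakSet with centroid-refined centers and disjoint intervals
    ``[center +/- 3 sigma]``, truncated at midpoints between neighbours.
    Residual norms per iteration are recorded in ``provenance``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    if not (0 < residual_tol < 1):
        raise ValueError("residual_tol must be in (0, 1)")
    y = np.asarray(mean_spec, dtype=np.float64)
    mz_axis = np.asarray(mz_axis, dtype=np.float64)
    if y.shape != mz_axis.shape:
        raise ValueError("spectrum and axis length mismatch")
    y_norm = np.linalg.norm(y)
    if y_norm == 0:
        return PeakSet(np.empty(0), np.empty(0), sigma, mode, {"residual_norms": []})

    D = _gaussian_dictionary(mz_axis, sigma)

    def off_grid_atom(center: float) -> np.ndarray:
        lo = np.searchsorted(mz_axis, center - 4 * sigma)
        hi = np.searchsorted(mz_axis, center + 4 * sigma, side="right")
        v = np.zeros(y.size)
        v[lo:hi] = np.exp(-0.5 * ((mz_axis[lo:hi] - center) / sigma) ** 2)
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > 0 else v

    centers_sel: list[float] = []
    # atoms within 3 sigma of a selected center are blocked — the same
    # radius as the aggregation interval half-width, so intervals cannot
    # collide and a peak is modeled by a single atom
    blocked = np.zeros(y.size, dtype=bool)
    A = np.empty((y.size, 0))  # dense selected-atom matrix, grown column-wise
    L = np.empty((0, 0))  # Cholesky factor of the selected Gram matrix
    b = np.empty(0)
    r = y.copy()
    residual_norms = [y_norm]

    while len(centers_sel) < max_peaks and residual_norms[-1] / y_norm > residual_tol:
        corr = D.T @ r
        corr[blocked] = -np.inf
        i = int(np.argmax(corr))
        # correlation floor: an atom whose gain is below the residual
        # tolerance (relative to the spectrum norm) cannot help reach it
        if not np.isfinite(corr[i]) or corr[i] <= residual_tol * y_norm:
            break
        # centroid matching against the residual: the selected grid channel
        # is refined to the intensity-weighted centroid within +/- sigma, and
        # the atom is rebuilt at that (off-grid) center so a sub-channel peak
        # offset does not leave spurious flank residue
        center = _apex_center(r, mz_axis, i, sigma)
        atom = off_grid_atom(center)
        # rank-1 Cholesky extension of the Gram matrix (atoms are unit norm)
        g = A.T @ atom
        if L.size:
            w = np.linalg.solve(L, g)
            d2 = 1.0 - w @ w
            if d2 <= 1e-12:
                break  # numerically collinear with span of selected atoms
            L = np.block([[L, np.zeros((L.shape[0], 1))], [w[None, :], np.sqrt([[d2]])]])
        else:
            L = np.array([[1.0]])
        blocked |= np.abs(mz_axis - center) < 3 * sigma
        centers_sel.append(center)
        A = np.column_stack([A, atom])
        b = np.append(b, atom @ y)
        coef = np.linalg.solve(L.T, np.linalg.solve(L, b))
        r = y - A @ coef
        residual_norms.append(float(np.linalg.norm(r)))

    if not centers_sel:
        return PeakSet(np.empty(0), np.empty(0), sigma, mode, {"residual_norms": []})

    # discard atoms whose refit coefficient is non-positive
    sel = np.asarray(centers_sel)
    keep = coef > 0
    while not keep.all() and keep.any():
        sel, A = sel[keep], A[:, keep]
        G = A.T @ A
        coef = np.linalg.solve(G, A.T @ y)
        keep = coef > 0
    if not keep.any():
        return PeakSet(np.empty(0), np.empty(0), sigma, mode, {"residual_norms": residual_norms})

    centers = np.unique(sel)
    # merge centroids that collapsed onto (nearly) the same channel
    spacing = float(np.median(np.diff(mz_axis)))
    merged = [centers[0]]
    for c in centers[1:]:
        if c - merged[-1] >= spacing:
            merged.append(c)
    centers = np.asarray(merged)

    half = np.full(centers.size, 3 * sigma)
    if centers.size > 1:  # truncate overlapping intervals at midpoints
        gaps_half = np.diff(centers) / 2.0
        half[:-1] = np.minimum(half[:-1], gaps_half)
        half[1:] = np.minimum(half[1:], gaps_half)

    return PeakSet(
        centers,
        half,
        sigma,
        mode,
        {
            "residual_norms": residual_norms,
            "max_peaks": max_peaks,
            "residual_tol": residual_tol,
            "n_iterations": len(residual_norms) - 1,
        },
    )


def extract_features(
    datasets: Sequence[IonImageDataset] | IonImageDataset, peak_set: PeakSet
) -> FeatureTable:
    """Aggregate per-spot intensity for every peak interval.

    For each spot and peak: locate the local maximum inside the interval,
    compute the intensity-weighted centroid in a +/- sigma window around it,
    and record the summed intensity over the interval if the centroid falls
    inside the interval (centroid matching); otherwise 0.
    """
    if isinstance(datasets, IonImageDataset):
        datasets = [datasets]
    _check_shared_axis(datasets)
    frames, blocks = [], []
    for d in datasets:
        mz = d.mz_axis
        vals = np.zeros((d.n_spots, len(peak_set)))
        for j, (c, hw) in enumerate(zip(peak_set.centers, peak_set.half_widths)):
            lo = np.searchsorted(mz, c - hw)
            hi = np.searchsorted(mz, c + hw, side="right")
            if hi <= lo:
                raise ValueError(f"peak interval around {c:.4f} outside the m/z axis")
            sub = d.intensities[:, lo:hi].astype(np.float64)
            sub_mz = mz[lo:hi]
            peak_pos = sub_mz[np.argmax(sub, axis=1)]
            in_win = np.abs(sub_mz[None, :] - peak_pos[:, None]) <= peak_set.sigma
            wsum = (sub * in_win).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                centroid = np.where(
                    wsum > 0, (sub * in_win * sub_mz[None, :]).sum(axis=1) / wsum, np.inf
                )
            accepted = np.abs(centroid - c) <= hw
            vals[:, j] = np.where(accepted, sub.sum(axis=1), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": d.sample_id,
                    "group": d.group,
                    "timepoint": d.timepoint,
                    "mode": d.mode,
                    "x": d.coords[:, 0],
                    "y": d.coords[:, 1],
                }
            )
        )
        blocks.append(vals)
    return FeatureTable(
        spots=pd.concat(frames, ignore_index=True),
        values=np.vstack(blocks),
        peak_set=peak_set,
    )


def average_peak_intensity(table: FeatureTable, roi_rows: np.ndarray) -> float:
    """Mean feature intensity over (ROI spots x all peaks) — the scalar
    summarised per group in intensity-overview plots."""
    roi_rows = np.asarray(roi_rows, dtype=bool)
    if roi_rows.shape[0] != len(table.spots):
        raise ValueError("roi mask length mismatch")
    if not roi_rows.any():
        raise ValueError("empty ROI")
    return float(table.values[roi_rows].mean())
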