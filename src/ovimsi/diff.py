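"""Bidirectional ROC analysis of epithelium spectra.

For every detected peak, the ROI spot intensities of the two diet groups are
pooled across replicates and compared by the area under the ROC curve — the
probability that a random HFHS spot exceeds a random CTRL spot, ties
half-credited (the Mann-Whitney convention).  A mass is called discriminative
(DM) when the AUC of either direction reaches the threshold (default 0.7):
HFHS-vs-CTRL calls mark masses more abundant under the high-fat/high-sugar
diet, CTRL-vs-HFHS calls the reverse.  No multiple-testing correction is
applied: calling is by AUC threshold alone, and replicate spots are pooled
rather than averaged per animal — both inherited from the source workflow and
to be kept in mind when interpreting calls (a per-sample-mean alternative is
available via ``pool_samples=False``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import MODES, TIMEPOINTS
from .peaks import FeatureTable

HFHS_VS_CTRL = "HFHS_vs_CTRL"
CTRL_VS_HFHS = "CTRL_vs_HFHS"
DIRECTIONS = (HFHS_VS_CTRL, CTRL_VS_HFHS)


@dataclass(frozen=True)
class DiscriminativeMass:
    """One DM call: peak center, AUC in the called direction, direction,
    acquisition mode and feeding time point."""

    center_mz: float
    auc: float
    direction: str
    mode: str
    timepoint: str
    peak_index: int = -1

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1]")


def roc_auc(positives: Sequence[float], negatives: Sequence[float]) -> float:
    """AUC = [#(p > n) + 0.5 #(p = n)] / (|P| |N|), via rank statistics.

    Equivalent to the Mann-Whitney U statistic normalised by |P||N|; the rank
    formulation matches the brute-force pairwise count exactly, including
    half-credit for ties.
    """
    p = np.asarray(positives, dtype=np.float64)
    n = np.asarray(negatives, dtype=np.float64)
    if p.size == 0 or n.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = rankdata(np.concatenate([p, n]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * n.size))


def detect_dms(
    table: FeatureTable,
    rois: Mapping[str, object],
    threshold: float = 0.7,
    pool_samples: bool = True,
) -> list[DiscriminativeMass]:
    """Call discriminative masses on one (time point, mode) batch.

    Parameters
    ----------
    table
        Features of every sample in the batch (both groups).
    rois
        Per-sample epithelium masks (sample_id -> RoiMask or boolean array),
        each aligned with that sample's spot order; an empty ROI for any
        sample is an error.
    threshold
        AUC calling threshold; must exceed 0.5 so at most one direction can
        be called per peak.
    pool_samples
        Pool ROI spots across replicates (the source workflow) or reduce each
        replicate to its ROI mean first (no pseudoreplication).
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")
    tps = set(table.spots["timepoint"])
    modes = set(table.spots["mode"])
    if len(tps) != 1 or len(modes) != 1:
        raise ValueError("detect_dms operates on one (timepoint, mode) batch")
    timepoint, mode = tps.pop(), modes.pop()

    roi_rows = table.roi_row_mask(rois)
    for sid in table.sample_ids():
        if not roi_rows[table.rows_for_sample(sid)].any():
            raise ValueError(f"empty ROI for sample {sid}")
    groups = table.spots["group"].to_numpy()
    if not {"CTRL", "HFHS"} <= set(groups):
        raise ValueError("both CTRL and HFHS samples are required")

    if pool_samples:
        pos = table.values[roi_rows & (groups == "HFHS")]
        neg = table.values[roi_rows & (groups == "CTRL")]
    else:
        means = {}
        for sid in table.sample_ids():
            rows = table.rows_for_sample(sid) & roi_rows
            means[sid] = (table.values[rows].mean(axis=0), groups[table.rows_for_sample(sid)][0])
        pos = np.array([m for m, g in means.values() if g == "HFHS"])
        neg = np.array([m for m, g in means.values() if g == "CTRL"])

    dms: list[DiscriminativeMass] = []
    for j, center in enumerate(table.peak_set.centers):
        auc_h = roc_auc(pos[:, j], neg[:, j])
        if auc_h >= threshold:
            dms.append(
                DiscriminativeMass(float(center), auc_h, HFHS_VS_CTRL, mode, timepoint, j)
            )
        elif 1.0 - auc_h >= threshold:
            dms.append(
                DiscriminativeMass(
                    float(center), 1.0 - auc_h, CTRL_VS_HFHS, mode, timepoint, j
                )
            )
    return dms


def summary_from_counts(counts: Mapping[str, Mapping[tuple[str, str], int]]) -> pd.DataFrame:
    """DM summary table from per-cell counts.

    ``counts`` maps timepoint -> {(mode, direction): count}.  Returns the
    per-(mode, direction) cells plus per-direction totals and the grand total
    per time point — the layout of the DM-count overview table.
    """
    rows = []
    for tp in [t for t in TIMEPOINTS if t in counts] + [
        t for t in counts if t not in TIMEPOINTS
    ]:
        cell = counts[tp]
        row = {"timepoint": tp}
        for mode in MODES:
            for d in DIRECTIONS:
                row[f"{mode}_{d}"] = int(cell.get((mode, d), 0))
        for d in DIRECTIONS:
            row[f"total_{d}"] = sum(row[f"{m}_{d}"] for m in MODES)
        row["total_dms"] = row[f"total_{DIRECTIONS[0]}"] + row[f"total_{DIRECTIONS[1]}"]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_dms(dms: Iterable[DiscriminativeMass]) -> pd.DataFrame:
    """Count DM calls per (timepoint x mode x direction), with row totals."""
    counts: dict[str, dict[tuple[str, str], int]] = {}
    for dm in dms:
        cell = counts.setdefault(dm.timepoint, {})
        key = (dm.mode, dm.direction)
        cell[key] = cell.get(key, 0) + 1
    return summary_from_counts(counts)


def overlap_dms(
    dms_a: Sequence[DiscriminativeMass],
    dms_b: Sequence[DiscriminativeMass],
    mz_tol: float = 0.1,
) -> list[tuple[DiscriminativeMass, DiscriminativeMass]]:
    """Greedy nearest-m/z pairing of DMs across two analyses (same mode only,
    each DM matched at most once, |dmz| <= mz_tol)."""
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    cand = [
        (abs(a.center_mz - b.center_mz), i, j)
        for i, a in enumerate(dms_a)
        for j, b in enumerate(dms_b)
        if a.mode == b.mode and abs(a.center_mz - b.center_mz) <= mz_tol
    ]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((dms_a[i], dms_b[j]))
    return pairs


def dm_intensity_summary(
    table: FeatureTable,
    rois: Mapping[str, object],
    dms: Sequence[DiscriminativeMass],
    direction: str,
) -> pd.DataFrame:
    """Per-ROI-spot mean intensity over one direction's DM peaks, labeled by
    group — the distribution behind the DM-intensity box plots.
    """
    cols = [dm.peak_index for dm in dms if dm.direction == direction]
    if not cols:
        raise ValueError(f"no DMs in direction {direction}")
    if min(cols) < 0:
        raise ValueError("DMs lack peak indices into this table")
    roi_rows = table.roi_row_mask(rois)
    sub = table.spots.loc[roi_rows, ["sample_id", "group"]].reset_index(drop=True)
    sub["mean_dm_intensity"] = table.values[np.asarray(roi_rows)][:, cols].mean(axis=1)
    return sub


def dms_to_frame(dms: Iterable[DiscriminativeMass]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "center_mz": d.center_mz,
                "auc": d.auc,
                "direction": d.direction,
                "mode": d.mode,
                "timepoint": d.timepoint,
            }
            for d in dms
        ]
    )
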