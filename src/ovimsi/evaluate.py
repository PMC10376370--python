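"""Scoring a pipeline run against the generator's planted ground truth:
discriminative-mass recovery, annotation accuracy and partition agreement."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import annotation as ann
from .diff import HFHS_VS_CTRL, DiscriminativeMass
from .synth import UP, PlantedDrl


def direction_agrees(dm: DiscriminativeMass, drl: PlantedDrl) -> bool:
    return (dm.direction == HFHS_VS_CTRL) == (drl.direction == UP)


def score_dm_recovery(
    dms: Sequence[DiscriminativeMass],
    drls: Sequence[PlantedDrl],
    mz_tol: float = 0.25,
) -> dict:
    """Sensitivity and false-discovery proportion of DM calls.

    A planted DRL counts as recovered when some called DM lies within
    ``mz_tol`` of its m/z with the matching direction; a call is false when no
    planted DRL lies within ``mz_tol`` regardless of direction.
    """
    recovered: dict[float, DiscriminativeMass] = {}
    n_false = 0
    for dm in dms:
        near = [d for d in drls if abs(d.mz - dm.center_mz) <= mz_tol]
        if not near:
            n_false += 1
            continue
        hit = [d for d in near if direction_agrees(dm, d)]
        if hit and hit[0].mz not in recovered:
            recovered[hit[0].mz] = dm
    return {
        "sensitivity": len(recovered) / len(drls) if drls else float("nan"),
        "fdp": n_false / len(dms) if dms else 0.0,
        "n_called": len(dms),
        "n_true": len(drls),
        "n_false": n_false,
        "recovered": recovered,  # planted m/z -> matched call
    }


def annotation_true_class_hits(
    recovered: dict[float, DiscriminativeMass],
    drls: Sequence[PlantedDrl],
    tolerance: float = 0.05,
    db=None,
) -> tuple[int, int]:
    """(hits, total) over recovered lipid-derived DRLs whose putative
    annotation category contains the planted class."""
    db = db if db is not None else ann.build_lipid_db()
    by_mz = {d.mz: d for d in drls}
    hits = total = 0
    for mz, dm in recovered.items():
        drl = by_mz[mz]
        if drl.lipid_class is None:
            continue
        total += 1
        rec = ann.annotate_mz(dm.center_mz, dm.mode, db, tolerance=tolerance)
        if drl.lipid_class in rec.category.split("/"):
            hits += 1
    return hits, total


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Chance-corrected agreement between two partitions (pair counting)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    n_pairs = comb2(a.size)
    expected = sum_a * sum_b / n_pairs
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
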