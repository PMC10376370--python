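"""End-to-end study orchestration and the small printed-statistic utilities.

``run_study`` drives the full analysis per (time point, mode) batch — all
samples of a batch are preprocessed and peak-picked together, mirroring
batch-wise acquisition and analysis — and emits the report tables: detected
peaks, segmentation labels, ROI Dice diagnostics, skyline spectra, per-group
average peak intensities, the DM table and its count summary, putative
annotations with class-category counts, and cross-time-point DM overlap.
Reruns with an identical config are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import diff, peaks, segmentation, synth
from .io import IonImageDataset, read_imzml
from .preprocess import PreprocessParams, preprocess_dataset

log = logging.getLogger(__name__)


@dataclass
class OmpParams:
    sigma: float = 0.25
    max_peaks: int = 500
    residual_tol: float = 0.02


@dataclass
class PipelineConfig:
    """One config drives the whole run; exactly one input source (a sample
    manifest of imzML paths + reference masks, or a synthetic config) must be
    present, and the ROC threshold must lie in (0.5, 1]."""

    synthetic: synth.SyntheticConfig | None = None
    seed: int = 0
    input_manifest: list[dict] | None = None  # [{imzml, mask_tsv}, ...]
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    omp: OmpParams = field(default_factory=OmpParams)
    segmentation_depth: int = 2
    segmentation_seed: int = 0
    segmentation_restarts: int = 5
    segmentation_top_k: int | None = 100  # most intense peaks used for clustering
    roc_threshold: float = 0.7
    annotation_tolerance: float = 0.05
    overlap_tol: float = 0.1
    output_dir: str = "results/run"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_manifest is None):
            raise ValueError("exactly one of synthetic / input_manifest must be set")
        if not (0.5 < self.roc_threshold <= 1.0):
            raise ValueError("roc_threshold must lie in (0.5, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kw = dict(raw)
        if "synthetic" in kw and kw["synthetic"] is not None:
            syn = dict(kw["synthetic"])
            if "design" in syn:
                from .io import StudyDesign

                d = dict(syn["design"])
                for k in ("timepoints", "groups", "modes"):
                    if k in d:
                        d[k] = tuple(d[k])
                syn["design"] = StudyDesign(**d)
            for k in ("grid", "mz_range"):
                if k in syn:
                    syn[k] = tuple(syn[k])
            kw["synthetic"] = synth.SyntheticConfig(**syn)
        if "preprocess" in kw:
            pp = dict(kw["preprocess"])
            if "exclusion_windows" in pp:
                pp["exclusion_windows"] = [tuple(w) for w in pp["exclusion_windows"]]
            kw["preprocess"] = PreprocessParams(**pp)
        if "omp" in kw:
            kw["omp"] = OmpParams(**kw["omp"])
        return cls(**kw)


def percent_group_difference(mean_a: float, mean_b: float) -> float:
    """Percent difference of a group mean relative to a reference mean,
    100 x (a - b) / b, reported to one decimal."""
    if mean_b <= 0:
        raise ValueError("reference mean must be positive")
    return round(100.0 * (mean_a - mean_b) / mean_b, 1)


def proportion_of_category(count: int, total: int) -> float:
    """Percentage count/total to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= count <= total):
        raise ValueError("count must lie in [0, total]")
    return round(100.0 * count / total, 1)


def _load_real_samples(config: PipelineConfig):
    datasets, masks = [], {}
    for entry in config.input_manifest:
        ds = read_imzml(entry["imzml"])
        datasets.append(ds)
        mask_df = pd.read_csv(entry["mask_tsv"], sep="\t")
        lut = {
            (int(r.x), int(r.y)): bool(r.roi) for r in mask_df.itertuples()
        }
        masks[ds.sample_id] = np.array(
            [lut[(int(x), int(y))] for x, y in ds.coords]
        )
    return datasets, masks


def run_study(config: PipelineConfig) -> dict:
    """Run the full pipeline and write the report bundle to the output dir.

    Returns a dict with the in-memory results: DM lists, summary tables,
    annotation records, per-batch diagnostics.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        datasets, manifest = synth.generate_study(config.synthetic, config.seed)
        ref_masks = None  # looked up per dataset from the truth manifest
    else:
        datasets, ref_masks = _load_real_samples(config)
        manifest = None

    batches: dict[tuple[str, str], list[IonImageDataset]] = {}
    for ds in datasets:
        batches.setdefault((ds.timepoint, ds.mode), []).append(ds)

    all_dms: list[diff.DiscriminativeMass] = []
    annotations: list[tuple[str, str, ann.AnnotationRecord]] = []
    segmentations: dict[str, np.ndarray] = {}
    avg_rows, dice_rows = [], []
    dms_by_batch: dict[tuple[str, str], list[diff.DiscriminativeMass]] = {}
    db = ann.build_lipid_db()

    for (tp, mode), batch in sorted(batches.items()):
        log.info("batch %s/%s: %d samples", tp, mode, len(batch))
        processed = [preprocess_dataset(ds, config.preprocess) for ds in batch]

        mean_spec = peaks.mean_spectrum(processed)
        peak_set = peaks.omp_detect_peaks(
            mean_spec,
            processed[0].mz_axis,
            sigma=config.omp.sigma,
            max_peaks=config.omp.max_peaks,
            residual_tol=config.omp.residual_tol,
            mode=mode,
        )
        peak_set.to_frame().to_csv(
            outdir / f"peaks_{tp}_{mode}.tsv", sep="\t", index=False
        )

        table = peaks.extract_features(processed, peak_set)
        seg_cols = segmentation.segmentation_feature_columns(table, config.segmentation_top_k)
        rois: dict[str, segmentation.RoiMask] = {}
        for ds in processed:
            rows = table.rows_for_sample(ds.sample_id)
            seg = segmentation.bisecting_kmeans(
                table.values[np.asarray(rows)][:, seg_cols],
                depth=config.segmentation_depth,
                seed=config.segmentation_seed,
                restarts=config.segmentation_restarts,
            )
            if manifest is not None:
                ref = segmentation.RoiMask(
                    mask=manifest.mask_for_coords(ds.coords), source="reference"
                )
            else:
                ref = segmentation.RoiMask(mask=ref_masks[ds.sample_id], source="reference")
            roi = segmentation.select_roi(seg, ref)
            rois[ds.sample_id] = roi
            segmentations[ds.sample_id] = (ds.coords, seg.labels)
            dice_rows.append(
                {
                    "sample_id": ds.sample_id,
                    "timepoint": tp,
                    "mode": mode,
                    "dice": segmentation.dice(roi.mask, ref.mask),
                    "n_roi_spots": roi.n_spots,
                }
            )
            pd.DataFrame(
                {
                    "x": ds.coords[:, 0],
                    "y": ds.coords[:, 1],
                    "label": seg.labels,
                    "roi": roi.mask.astype(int),
                }
            ).to_csv(outdir / f"segmentation_{ds.sample_id}.tsv", sep="\t", index=False)
            if config.make_plots:
                img = np.full((ds.coords[:, 0].max() + 1, ds.coords[:, 1].max() + 1), np.nan)
                img[ds.coords[:, 0], ds.coords[:, 1]] = seg.labels
                segmentation.save_map_png(
                    img, outdir / f"segmentation_{ds.sample_id}.png", ds.sample_id
                )

        for group in ("CTRL", "HFHS"):
            grp = [d for d in processed if d.group == group]
            if not grp:
                continue
            sky = peaks.skyline_spectrum(grp)
            pd.DataFrame({"mz": processed[0].mz_axis, "intensity": sky}).to_csv(
                outdir / f"skyline_{group}_{tp}_{mode}.tsv", sep="\t", index=False
            )
            grp_rows = table.spots["group"].to_numpy() == group
            roi_rows = table.roi_row_mask(rois) & grp_rows
            avg_rows.append(
                {
                    "timepoint": tp,
                    "mode": mode,
                    "group": group,
                    "average_peak_intensity": peaks.average_peak_intensity(table, roi_rows),
                }
            )

        dms = diff.detect_dms(table, rois, threshold=config.roc_threshold)
        dms_by_batch[(tp, mode)] = dms
        all_dms.extend(dms)
        for dm in dms:
            annotations.append(
                (tp, dm.direction, ann.annotate_dm(dm, db, config.annotation_tolerance))
            )

    # report bundle
    diff.dms_to_frame(all_dms).to_csv(outdir / "dms.tsv", sep="\t", index=False)
    summary = diff.summarize_dms(all_dms)
    summary.to_csv(outdir / "dm_summary.csv", index=False)
    cat = ann.summarize_classes(annotations)
    cat.to_csv(outdir / "annotation_categories.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "timepoint": tp,
                "direction": dr,
                "observed_mz": rec.observed_mz,
                "category": rec.category,
                "best_match": rec.candidates[0][0].name if rec.candidates else "",
                "best_adduct": rec.candidates[0][1] if rec.candidates else "",
                "mass_error_da": rec.candidates[0][3] if rec.candidates else np.nan,
            }
            for tp, dr, rec in annotations
        ]
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    pd.DataFrame(avg_rows).to_csv(outdir / "average_intensity.tsv", sep="\t", index=False)
    pd.DataFrame(dice_rows).to_csv(outdir / "roi_dice.tsv", sep="\t", index=False)

    overlaps = {}
    batch_keys = sorted(dms_by_batch)
    for i, ka in enumerate(batch_keys):
        for kb in batch_keys[i + 1 :]:
            if ka[1] != kb[1]:
                continue
            pairs = diff.overlap_dms(
                dms_by_batch[ka], dms_by_batch[kb], mz_tol=config.overlap_tol
            )
            overlaps[f"{ka[0]}_{ka[1]}_vs_{kb[0]}_{kb[1]}"] = len(pairs)
    (outdir / "dm_overlap.json").write_text(json.dumps(overlaps, indent=1))

    run_manifest = {
        "seed": config.seed,
        "roc_threshold": config.roc_threshold,
        "segmentation_depth": config.segmentation_depth,
        "segmentation_seed": config.segmentation_seed,
        "annotation_tolerance": config.annotation_tolerance,
        "omp": asdict(config.omp),
        "n_batches": len(batches),
        "n_dms": len(all_dms),
        "fraction_annotated": cat.attrs.get("fraction_annotated"),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1))

    return {
        "dms": all_dms,
        "dms_by_batch": dms_by_batch,
        "summary": summary,
        "annotations": annotations,
        "category_summary": cat,
        "average_intensity": pd.DataFrame(avg_rows),
        "roi_dice": pd.DataFrame(dice_rows),
        "overlaps": overlaps,
        "segmentations": segmentations,
        "manifest": manifest,
    }
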