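"""imzML input/output and the in-memory ion-image data model.

A MALDI-MSI sample is a raster of spots, each carrying a full mass spectrum.
In continuous-mode imzML every spot shares one m/z axis, which is the contract
the rest of the pipeline (baseline correction, peak picking on the mean
spectrum, per-peak feature extraction) relies on.  Processed-mode files, where
each spot has its own axis, are rejected rather than silently resampled.

Sample-level metadata (diet group, feeding time point, ionization mode) has no
standard slot in imzML, so it travels in a JSON sidecar written next to the
.imzML file (``<stem>.meta.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

GROUPS = ("CTRL", "HFHS")
TIMEPOINTS = ("3d", "1w", "4w", "8w", "12w", "16w")
MODES = ("positive", "negative")

#: m/z acquisition window; masses below the lower edge are deflected at the
#: instrument and the pipeline crops to this range before any statistics.
MZ_MIN = 400.0
MZ_MAX = 2000.0


class UnsupportedDialectError(ValueError):
    """Raised for imzML files the pipeline cannot analyse (processed mode)."""


@dataclass
class StudyDesign:
    """Factorial layout of the feeding study: diet groups x time points x
    biological replicates, acquired in one or both ionization modes."""

    timepoints: tuple[str, ...] = TIMEPOINTS
    groups: tuple[str, ...] = GROUPS
    samples_per_group: int = 3
    modes: tuple[str, ...] = MODES

    def __post_init__(self) -> None:
        if self.samples_per_group < 1:
            raise ValueError("samples_per_group must be >= 1")
        for g in self.groups:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
        for t in self.timepoints:
            if t not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {t!r}")
        for m in self.modes:
            if m not in MODES:
                raise ValueError(f"unknown mode {m!r}")


@dataclass
class IonImageDataset:
    """One sample's ion images: a spot grid, a shared m/z axis and the
    [n_spots x n_channels] intensity matrix.

    Parameters
    ----------
    sample_id
        Unique identifier, e.g. ``"HFHS_16w_s1_positive"``.
    group
        Diet group, ``"CTRL"`` or ``"HFHS"`` (high-fat / high-sugar).
    timepoint
        Feeding duration (``"3d"`` ... ``"16w"``).
    mode
        Ionization mode, ``"positive"`` or ``"negative"``.
    coords
        Integer (x, y) grid positions, 0-based, one per spot, no duplicates.
    mz_axis
        Strictly increasing m/z values (Th) shared by every spot.
    intensities
        Nonnegative float matrix, one row per spot.
    """

    sample_id: str
    group: str
    timepoint: str
    mode: str
    coords: np.ndarray
    mz_axis: np.ndarray
    intensities: np.ndarray
    pixel_size_um: float = 10.0  # lateral resolution; metadata only
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D [n_spots x n_channels]")
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_spots == 0:
            raise ValueError("dataset has no spots")
        if self.mz_axis.ndim != 1 or np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("mz_axis must be 1-D and strictly increasing")
        if self.intensities.shape != (self.n_spots, self.n_channels):
            raise ValueError(
                f"intensities shape {self.intensities.shape} inconsistent with "
                f"{self.n_spots} spots x {self.n_channels} channels"
            )
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        uniq = {tuple(c) for c in self.coords.tolist()}
        if len(uniq) != self.n_spots:
            raise ValueError("duplicate spot coordinates")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    @property
    def n_channels(self) -> int:
        return self.mz_axis.shape[0]

    def copy_with(self, **kw) -> "IonImageDataset":
        params = dict(
            sample_id=self.sample_id,
            group=self.group,
            timepoint=self.timepoint,
            mode=self.mode,
            coords=self.coords.copy(),
            mz_axis=self.mz_axis.copy(),
            intensities=self.intensities.copy(),
            pixel_size_um=self.pixel_size_um,
            extra=dict(self.extra),
        )
        params.update(kw)
        return IonImageDataset(**params)


def sidecar_path(path: str | Path) -> Path:
    """JSON sidecar path for an imzML file: ``sample.imzML -> sample.meta.json``."""
    p = Path(path)
    return p.with_name(p.stem + ".meta.json")


def write_imzml(dataset: IonImageDataset, path: str | Path) -> None:
    """Write a dataset as continuous-mode imzML (+.ibd) with a JSON sidecar.

    imzML requires 1-based coordinates; the 0-based grid indices of the data
    model are shifted on write and shifted back on read.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    dataset.validate()
    path = Path(path)
    with ImzMLWriter(str(path), mode="continuous") as writer:
        for row, (x, y) in zip(dataset.intensities, dataset.coords):
            writer.addSpectrum(
                dataset.mz_axis, np.asarray(row, dtype=np.float64), (int(x) + 1, int(y) + 1)
            )
    meta = {
        "sample_id": dataset.sample_id,
        "group": dataset.group,
        "timepoint": dataset.timepoint,
        "mode": dataset.mode,
        "pixel_size_um": dataset.pixel_size_um,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_imzml(path: str | Path, metadata: dict | None = None) -> IonImageDataset:
    """Read a continuous-mode imzML file pair into an :class:`IonImageDataset`.

    Parameters
    ----------
    path
        Path to the ``.imzML`` XML part; the ``.ibd`` binary must sit beside it.
    metadata
        Optional dict overriding the JSON sidecar ({sample_id, group,
        timepoint, mode, ...}).

    Raises
    ------
    FileNotFoundError
        If the .imzML or .ibd part is missing.
    UnsupportedDialectError
        For processed-mode files (per-spot m/z axes): the pipeline's shared
        axis contract cannot be met without resampling, which is refused.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FileNotFoundError(f"missing binary part: {ibd}")

    parser = ImzMLParser(str(path))
    try:
        n = len(parser.coordinates)
        mz0, _ = parser.getspectrum(0)
        mz0 = np.asarray(mz0, dtype=np.float64)
        lengths = set(parser.mzLengths)
        if len(lengths) != 1:
            raise UnsupportedDialectError(
                "processed-mode imzML (per-spot m/z axes) is not supported; "
                "the pipeline requires a shared continuous-mode axis"
            )
        intensities = np.empty((n, mz0.size), dtype=np.float32)
        coords = np.empty((n, 2), dtype=np.int64)
        for i in range(n):
            mz_i, ints_i = parser.getspectrum(i)
            if not np.array_equal(np.asarray(mz_i), mz0):
                raise UnsupportedDialectError(
                    "spectra do not share one m/z axis; refusing to resample"
                )
            intensities[i] = ints_i
            x, y = parser.coordinates[i][:2]
            coords[i] = (x - 1, y - 1)
    finally:
        if hasattr(parser, "m") and parser.m is not None:
            parser.m.close()

    meta = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta.update(json.loads(sc.read_text()))
    if metadata:
        meta.update(metadata)
    return IonImageDataset(
        sample_id=meta.get("sample_id", path.stem),
        group=meta.get("group", "CTRL"),
        timepoint=meta.get("timepoint", "16w"),
        mode=meta.get("mode", "positive"),
        coords=coords,
        mz_axis=mz0,
        intensities=np.clip(intensities, 0, None),
        pixel_size_um=float(meta.get("pixel_size_um", 10.0)),
    )
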