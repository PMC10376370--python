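"""Synthetic ion-image study generator with planted ground truth.

Emulates the structure of a diet-intervention MSI study on oviduct cross
sections: a 2-D spot grid containing a stromal core, an epithelial ring and
matrix-only background, each with its own lipid profile; two diet groups with
biological replicates acquired at several feeding time points in positive
and/or negative mode; peaks concentrated near m/z 700-900 (drawn from the
packaged lipid mass table so annotation has recoverable truth) with a minor
unassignable component at 1400-1600; a matrix-cluster artifact peak at m/z
500; smooth baseline drift; per-spot TIC variation; additive noise; and
differentially regulated lipids (DRLs) planted in the epithelium in both
directions of change.

Every random draw flows from one seed, so identical (config, seed) pairs
yield bit-identical datasets, and a ground-truth manifest records everything
a test needs to score recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from . import annotation as ann
from .io import IonImageDataset, StudyDesign

REGIONS = ("epithelium", "stroma", "background")

UP = "up_in_HFHS"
DOWN = "down_in_HFHS"


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic experiment.

    Intensity units are arbitrary; ``amplitude_scale`` (the reference peak
    height, 100) anchors every other scale: baseline drift ~20% of it, additive
    noise sigma 8% of it (single-pixel MALDI-TOF spectra are noisy; spot-level
    peak-area CVs come out around 10-30%), 5% replicate-to-replicate amplitude
    jitter and a 0.15 lognormal sigma of per-spot TIC variation.
    """

    grid: tuple[int, int] = (20, 20)
    mz_range: tuple[float, float] = (400.0, 2000.0)
    channel_spacing: float = 0.1
    sigma_peak: float = 0.25  # Gaussian peak width (Th)

    n_peaks: int = 80
    lipid_fraction: float = 0.7  # fraction of peaks drawn from the lipid DB
    n_highmass: int = 6  # unassignable minor component at 1400-1600
    min_separation: float = 2.0  # Th between planted centers

    amplitude_scale: float = 100.0
    amplitude_sigma: float = 0.5  # lognormal sigma of peak heights
    p_epithelium: float = 0.4  # region-affinity category probabilities
    p_stroma: float = 0.4
    minor_weight: float = 0.2  # off-region weight of a dominant peak
    background_weight: float = 0.03
    matrix_peak_mz: float = 500.0  # matrix-cluster artifact, everywhere
    matrix_peak_amplitude: float = 400.0

    n_up: int = 3  # DRLs raised in HFHS epithelium (fold 2.0)
    fold_up: float = 2.0
    n_down: int = 5  # DRLs lowered in HFHS epithelium (fold 0.4)
    fold_down: float = 0.4

    baseline_amplitude: float = 20.0
    baseline_knots: int = 8
    tic_sigma: float = 0.15
    sample_jitter: float = 0.05
    noise_sigma: float = 8.0

    stroma_radius_frac: float = 0.225  # of min(grid); stroma disk
    epithelium_radius_frac: float = 0.375  # epithelial ring outer radius

    design: StudyDesign = field(
        default_factory=lambda: StudyDesign(timepoints=("16w",), modes=("positive",))
    )

    def __post_init__(self) -> None:
        for name in ("channel_spacing", "sigma_peak", "min_separation", "amplitude_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("tic_sigma", "sample_jitter", "noise_sigma", "baseline_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for n, fold in ((self.n_up, self.fold_up), (self.n_down, self.fold_down)):
            if n > 0 and (fold <= 0 or fold == 1.0):
                raise ValueError("DRL fold changes must be positive and != 1")
        if self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("bad mz_range")

    @property
    def mz_axis(self) -> np.ndarray:
        lo, hi = self.mz_range
        n = int(round((hi - lo) / self.channel_spacing)) + 1
        return lo + np.arange(n) * self.channel_spacing


@dataclass
class PlantedPeak:
    mz: float
    amplitude: float
    weights: tuple[float, float, float]  # (epithelium, stroma, background)
    lipid_class: str | None = None
    species_name: str | None = None
    is_matrix: bool = False


@dataclass
class PlantedDrl:
    mz: float
    direction: str  # up_in_HFHS / down_in_HFHS
    fold_change: float  # multiplier on the HFHS epithelium amplitude
    peak_index: int
    lipid_class: str | None = None
    species_name: str | None = None


@dataclass
class GroundTruthManifest:
    """Everything needed to score a pipeline run against the planted truth."""

    seed: int
    grid: tuple[int, int]
    coords: np.ndarray  # [n_spots x 2]
    region_labels: np.ndarray  # str per spot
    planted_peaks: dict[str, list[PlantedPeak]]  # per mode
    planted_drls: dict[str, list[PlantedDrl]]  # per mode
    baseline_params: tuple[float, int]
    tic_sigma: float
    noise_sigma: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.region_labels = np.asarray(self.region_labels)
        if self.region_labels.shape[0] != self.coords.shape[0]:
            raise ValueError("region_mask must cover all coords")
        for mode, drls in self.planted_drls.items():
            peak_mzs = {p.mz for p in self.planted_peaks[mode]}
            for d in drls:
                if d.mz not in peak_mzs:
                    raise ValueError("planted DRL m/z not among planted peaks")
                if d.fold_change <= 0 or d.fold_change == 1.0:
                    raise ValueError("DRL fold change must be positive and != 1")

    def epithelium_mask(self) -> np.ndarray:
        return self.region_labels == "epithelium"

    def mask_for_coords(self, coords: np.ndarray) -> np.ndarray:
        """Epithelium truth mask re-indexed to an arbitrary coordinate list
        (e.g. after zero-TIC spots were dropped)."""
        lut = {
            (int(x), int(y)): bool(v)
            for (x, y), v in zip(self.coords.tolist(), self.epithelium_mask())
        }
        return np.array([lut[(int(x), int(y))] for x, y in np.asarray(coords)])

    def regions_for_coords(self, coords: np.ndarray) -> np.ndarray:
        lut = {
            (int(x), int(y)): r
            for (x, y), r in zip(self.coords.tolist(), self.region_labels.tolist())
        }
        return np.array([lut[(int(x), int(y))] for x, y in np.asarray(coords)])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "grid": list(self.grid),
            "coords": self.coords.tolist(),
            "region_labels": self.region_labels.tolist(),
            "planted_peaks": {
                m: [asdict(p) for p in ps] for m, ps in self.planted_peaks.items()
            },
            "planted_drls": {
                m: [asdict(d) for d in ds] for m, ds in self.planted_drls.items()
            },
            "baseline_params": list(self.baseline_params),
            "tic_sigma": self.tic_sigma,
            "noise_sigma": self.noise_sigma,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            grid=tuple(d["grid"]),
            coords=np.asarray(d["coords"]),
            region_labels=np.asarray(d["region_labels"]),
            planted_peaks={
                m: [PlantedPeak(**{**p, "weights": tuple(p["weights"])}) for p in ps]
                for m, ps in d["planted_peaks"].items()
            },
            planted_drls={
                m: [PlantedDrl(**x) for x in ds] for m, ds in d["planted_drls"].items()
            },
            baseline_params=tuple(d["baseline_params"]),
            tic_sigma=d["tic_sigma"],
            noise_sigma=d["noise_sigma"],
        )


def grid_regions(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """All grid coordinates and their region labels (disk stroma surrounded
    by an epithelial ring, matrix background outside — a cross-section of a
    tubular organ)."""
    nx, ny = config.grid
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r = np.hypot(coords[:, 0] - cx, coords[:, 1] - cy)
    r_stroma = config.stroma_radius_frac * min(nx, ny)
    r_epi = config.epithelium_radius_frac * min(nx, ny)
    labels = np.where(
        r < r_stroma, "stroma", np.where(r < r_epi, "epithelium", "background")
    )
    return coords, labels


_POS_CLASSES = ("PC", "PE", "SM", "LPC", "LPE")
_NEG_CLASSES = ("PE", "PS", "PI", "LPE", "LPS", "LPI")
_POS_ADDUCTS = ("[M+H]+", "[M+Na]+", "[M+K]+")


def _draw_layout(
    rng: np.random.Generator, config: SyntheticConfig, mode: str
) -> tuple[list[PlantedPeak], list[PlantedDrl]]:
    """Draw one mode's peak layout: centers, region affinities, amplitudes,
    the matrix artifact, and the planted DRLs."""
    lo, hi = config.mz_range
    db = ann.build_lipid_db(_POS_CLASSES if mode == "positive" else _NEG_CLASSES)
    n_lipid = int(round(config.n_peaks * config.lipid_fraction))
    n_high = min(config.n_highmass, config.n_peaks - n_lipid)
    n_rand = config.n_peaks - n_lipid - n_high

    taken: list[float] = [config.matrix_peak_mz]

    def admissible(mz: float) -> bool:
        if not (lo + 10 < mz < hi - 10):
            return False
        return all(abs(mz - t) >= config.min_separation for t in taken)

    peaks: list[PlantedPeak] = []
    # lipid-derived centers: species + adduct, exact theoretical m/z
    order = rng.permutation(len(db))
    adduct_p = np.array([0.6, 0.25, 0.15])
    i = 0
    while sum(p.lipid_class is not None for p in peaks) < n_lipid and i < len(order):
        sp = db[order[i]]
        i += 1
        adduct = (
            str(rng.choice(_POS_ADDUCTS, p=adduct_p)) if mode == "positive" else "[M-H]-"
        )
        mz = ann.adduct_mz(sp, adduct)
        if admissible(mz):
            taken.append(mz)
            peaks.append(
                PlantedPeak(
                    mz=float(mz),
                    amplitude=0.0,
                    weights=(0, 0, 0),
                    lipid_class=sp.lipid_class,
                    species_name=f"{sp.name}{adduct}",
                )
            )
    # random unassignable centers, mass-weighted toward 700-900 with the
    # minor high-mass component at 1400-1600; windows are clipped to the
    # configured range (narrow ranges fall back to uniform placement)
    def _clip(wlo: float, whi: float) -> tuple[float, float] | None:
        a, b = max(wlo, lo + 10), min(whi, hi - 10)
        return (a, b) if b > a else None

    high_win = _clip(1400.0, 1600.0)
    mid_wins = [w for w in (_clip(700.0, 900.0), _clip(420.0, 700.0)) if w] or [
        (lo + 10, hi - 10)
    ]
    for n_want, wins in (
        (n_high if high_win else 0, [high_win]),
        (n_rand + (0 if high_win else n_high), mid_wins),
    ):
        placed = 0
        attempts = 0
        while placed < n_want and attempts < 10000:
            attempts += 1
            w = wins[0] if len(wins) == 1 else wins[0 if rng.random() < 0.6 else 1]
            mz = rng.uniform(*w)
            if admissible(mz):
                taken.append(float(mz))
                peaks.append(PlantedPeak(mz=float(mz), amplitude=0.0, weights=(0, 0, 0)))
                placed += 1

    # region affinities and amplitudes
    w_min, w_bg = config.minor_weight, config.background_weight
    cats = rng.choice(
        3,
        size=len(peaks),
        p=[config.p_epithelium, config.p_stroma, 1 - config.p_epithelium - config.p_stroma],
    )
    for p, c in zip(peaks, cats):
        p.weights = [(1.0, w_min, w_bg), (w_min, 1.0, w_bg), (1.0, 1.0, w_bg)][int(c)]
        p.amplitude = float(
            config.amplitude_scale * rng.lognormal(0.0, config.amplitude_sigma)
        )

    # DRLs: epithelium-dominant lipid peaks outside the matrix window, at the
    # common reference amplitude; 3 up x fold 2 and 5 down x fold 0.4 leave
    # the total epithelial signal (hence the per-spot TIC) nearly unchanged.
    n_drl = config.n_up + config.n_down
    eligible = [
        k
        for k, p in enumerate(peaks)
        if p.lipid_class is not None and abs(p.mz - config.matrix_peak_mz) > 10.0
    ]
    if len(eligible) < n_drl:
        raise ValueError("not enough lipid-derived peaks to plant the requested DRLs")
    chosen = rng.choice(len(eligible), size=n_drl, replace=False)
    drls: list[PlantedDrl] = []
    for j, k in enumerate(chosen):
        idx = eligible[int(k)]
        p = peaks[idx]
        p.weights = (1.0, w_min, w_bg)
        p.amplitude = config.amplitude_scale
        up = j < config.n_up
        drls.append(
            PlantedDrl(
                mz=p.mz,
                direction=UP if up else DOWN,
                fold_change=config.fold_up if up else config.fold_down,
                peak_index=idx,
                lipid_class=p.lipid_class,
                species_name=p.species_name,
            )
        )

    # matrix-cluster artifact: present in every region including background
    peaks.append(
        PlantedPeak(
            mz=config.matrix_peak_mz,
            amplitude=config.matrix_peak_amplitude,
            weights=(1.0, 1.0, 1.0),
            is_matrix=True,
        )
    )
    return peaks, drls


def _region_profiles(
    mz: np.ndarray,
    peaks: list[PlantedPeak],
    drls: list[PlantedDrl],
    group: str,
    jitter: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Noise-free signal profile per region, [3 x n_channels], region order
    as in :data:`REGIONS`."""
    fold_at = {d.peak_index: d.fold_change for d in drls} if group == "HFHS" else {}
    profiles = np.zeros((3, mz.size))
    for idx, p in enumerate(peaks):
        loi = np.searchsorted(mz, p.mz - 5 * sigma)
        hii = np.searchsorted(mz, p.mz + 5 * sigma)
        if hii <= loi:
            continue
        shape = np.exp(-0.5 * ((mz[loi:hii] - p.mz) / sigma) ** 2)
        amp = p.amplitude * jitter[idx]
        fold = fold_at.get(idx, 1.0)
        for r, w in enumerate(p.weights):
            f = fold if (r == 0 and fold != 1.0) else 1.0  # DRLs act in epithelium
            profiles[r, loi:hii] += amp * w * f * shape
    return profiles


def generate_study(
    config: SyntheticConfig | None = None, seed: int = 0
) -> tuple[list[IonImageDataset], GroundTruthManifest]:
    """Generate one dataset per (mode, timepoint, group, replicate) of the
    configured design, plus the ground-truth manifest.

    The spot model is ``tic_mult x (signal(region) + baseline) + noise``,
    clipped at zero, where the signal is a sum of Gaussian peaks whose
    amplitudes depend on the spot's region (and, for planted DRLs in HFHS
    epithelium, on the diet group).
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    mz = config.mz_axis
    coords, regions = grid_regions(config)
    region_idx = np.array([REGIONS.index(r) for r in regions])

    layouts = {m: _draw_layout(rng, config, m) for m in config.design.modes}

    datasets: list[IonImageDataset] = []
    knot_x = np.linspace(mz[0], mz[-1], config.baseline_knots)
    for mode in config.design.modes:
        peaks, drls = layouts[mode]
        for tp in config.design.timepoints:
            for group in config.design.groups:
                for s in range(config.design.samples_per_group):
                    jitter = (
                        rng.lognormal(0.0, config.sample_jitter, size=len(peaks))
                        if config.sample_jitter > 0
                        else np.ones(len(peaks))
                    )
                    profiles = _region_profiles(mz, peaks, drls, group, jitter, config.sigma_peak)
                    if config.baseline_amplitude > 0:
                        knot_y = config.baseline_amplitude * rng.uniform(
                            0.5, 1.5, size=config.baseline_knots
                        )
                        baseline = np.clip(PchipInterpolator(knot_x, knot_y)(mz), 0, None)
                    else:
                        baseline = np.zeros_like(mz)
                    tic_mult = (
                        rng.lognormal(0.0, config.tic_sigma, size=coords.shape[0])
                        if config.tic_sigma > 0
                        else np.ones(coords.shape[0])
                    )
                    spots = tic_mult[:, None] * (profiles[region_idx] + baseline[None, :])
                    if config.noise_sigma > 0:
                        spots = spots + rng.normal(0.0, config.noise_sigma, size=spots.shape)
                    datasets.append(
                        IonImageDataset(
                            sample_id=f"{group}_{tp}_s{s + 1}_{mode}",
                            group=group,
                            timepoint=tp,
                            mode=mode,
                            coords=coords.copy(),
                            mz_axis=mz,
                            intensities=np.clip(spots, 0, None).astype(np.float32),
                            extra={"tic_multipliers": tic_mult},
                        )
                    )

    manifest = GroundTruthManifest(
        seed=seed,
        grid=config.grid,
        coords=coords,
        region_labels=regions,
        planted_peaks={m: layouts[m][0] for m in layouts},
        planted_drls={m: layouts[m][1] for m in layouts},
        baseline_params=(config.baseline_amplitude, config.baseline_knots),
        tic_sigma=config.tic_sigma,
        noise_sigma=config.noise_sigma,
    )
    return datasets, manifest


def reference_mask(manifest: GroundTruthManifest):
    """Epithelium reference ROI (the stand-in for histology co-registration)."""
    from .segmentation import RoiMask

    mask = manifest.epithelium_mask()
    if not mask.any():
        raise ValueError("manifest contains no epithelium spots")
    return RoiMask(mask=mask, source="reference")
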