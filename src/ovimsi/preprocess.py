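"""Spectrum preprocessing: mass filters, Tophat baseline correction, TIC
normalization.

The pipeline applies the steps in a fixed order — crop/exclude, then baseline
correction, then TIC normalization — because the total ion count of a spot
depends on which channels are retained: excluding the matrix-cluster window
before normalizing prevents matrix signal from dominating the per-spot scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import IonImageDataset, MZ_MIN, MZ_MAX

log = logging.getLogger(__name__)

#: matrix-cluster artifact window: the m/z 500 interval of total width 14,
#: interpreted as centered, i.e. [493, 507].
MATRIX_EXCLUSION = (493.0, 507.0)


@dataclass
class PreprocessParams:
    """Knobs of the preprocessing stage.

    tophat_width
        Width (channels, odd, >= 3) of the flat structuring element for the
        morphological opening.  Default 31 channels, about five times the
        FWHM of the peaks the synthetic generator emits at the default
        channel spacing.
    tic_target
        "unit_sum": every spot's channel sum becomes 1; "mean_tic": every
        spot's sum becomes the pre-normalization mean TIC over spots.
    deflect_below
        Channels below this m/z are removed (instrument deflects them).
    exclusion_windows
        (low, high) m/z intervals removed before any statistics.
    """

    tophat_width: int = 31
    tic_target: str = "unit_sum"
    deflect_below: float = MZ_MIN
    exclusion_windows: list[tuple[float, float]] = field(
        default_factory=lambda: [MATRIX_EXCLUSION]
    )

    def __post_init__(self) -> None:
        if self.tophat_width < 3 or self.tophat_width % 2 == 0:
            raise ValueError("tophat_width must be odd and >= 3")
        if self.tic_target not in ("unit_sum", "mean_tic"):
            raise ValueError("tic_target must be 'unit_sum' or 'mean_tic'")
        for lo, hi in self.exclusion_windows:
            if not (lo < hi):
                raise ValueError(f"bad exclusion window ({lo}, {hi})")
            if lo < MZ_MIN or hi > MZ_MAX:
                raise ValueError(
                    f"exclusion window ({lo}, {hi}) outside [{MZ_MIN}, {MZ_MAX}]"
                )


def tophat_baseline_correct(spectrum: np.ndarray, width: int) -> np.ndarray:
    """Tophat baseline correction: spectrum minus its morphological opening.

    The opening (erosion then dilation with a flat structuring element of
    ``width`` channels) tracks slowly varying background while passing under
    narrow peaks, so the difference removes baseline and preserves peaks.
    Output is elementwise nonnegative and <= input.
    """
    spectrum = np.asarray(spectrum)
    if spectrum.ndim not in (1, 2):
        raise ValueError("spectrum must be a vector or a [spots x channels] matrix")
    n = spectrum.shape[-1]
    if width % 2 == 0 or width < 3 or width > n:
        raise ValueError(f"width must be odd, >= 3 and <= {n}; got {width}")
    size = (1, width) if spectrum.ndim == 2 else width
    opening = ndimage.grey_opening(spectrum, size=size, mode="nearest")
    return spectrum - opening


def tic_normalize(dataset: IonImageDataset, target: str = "unit_sum") -> IonImageDataset:
    """Scale each spot so its total ion count hits the target.

    Zero-TIC spots cannot be normalized; they are dropped with a logged
    warning rather than imputed or silently kept.
    """
    if target not in ("unit_sum", "mean_tic"):
        raise ValueError("target must be 'unit_sum' or 'mean_tic'")
    tic = dataset.intensities.sum(axis=1)
    keep = tic > 0
    if not np.all(keep):
        log.warning(
            "%s: dropping %d zero-TIC spot(s) before normalization",
            dataset.sample_id,
            int((~keep).sum()),
        )
    if not np.any(keep):
        raise ValueError(f"{dataset.sample_id}: all spots have zero TIC")
    scale = 1.0 if target == "unit_sum" else float(tic[keep].mean())
    out = dataset.intensities[keep] * (scale / tic[keep])[:, None]
    return dataset.copy_with(coords=dataset.coords[keep], intensities=out)


def apply_mass_filters(
    dataset: IonImageDataset, params: PreprocessParams
) -> IonImageDataset:
    """Remove deflected low masses and excluded m/z windows from the axis."""
    mz = dataset.mz_axis
    keep = mz >= params.deflect_below
    for lo, hi in params.exclusion_windows:
        keep &= ~((mz >= lo) & (mz <= hi))
    n_removed = int((~keep).sum())
    if not np.any(keep):
        raise ValueError("mass filters removed every channel")
    log.info("%s: mass filters removed %d channel(s)", dataset.sample_id, n_removed)
    return dataset.copy_with(
        mz_axis=mz[keep], intensities=dataset.intensities[:, keep]
    )


def preprocess_dataset(
    dataset: IonImageDataset, params: PreprocessParams | None = None
) -> IonImageDataset:
    """Full preprocessing in the pipeline's fixed order:

    1. mass filters (deflection crop + exclusion windows),
    2. Tophat baseline correction per spot,
    3. TIC normalization.
    """
    params = params or PreprocessParams()
    ds = apply_mass_filters(dataset, params)
    corrected = tophat_baseline_correct(ds.intensities, params.tophat_width)
    ds = ds.copy_with(intensities=corrected)
    return tic_normalize(ds, params.tic_target)
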