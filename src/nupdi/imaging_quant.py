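"""Mask-based detachment-index (DI) quantification.

The DI of a tagged nucleoporin is the mean nucleoplasmic intensity
divided by the mean nuclear-envelope intensity, measured on a single
mid-nucleus z-slice after rolling-ball background subtraction.  The
nuclear mask comes from the histone channel; eroding it gives the
nucleoplasmic mask, dilating it gives the outer boundary of the
envelope region, and the envelope signal is what remains of the total
nuclear signal once the nucleoplasmic part is subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, restoration
from skimage.filters import threshold_otsu

__all__ = [
    "CompartmentMasks",
    "DIMeasurement",
    "subtract_background",
    "select_mid_slice",
    "make_nuclear_mask",
    "make_compartment_masks",
    "compute_di_mask",
    "normalize_di",
    "mask_circularity",
]

DEFAULT_ROLLING_BALL_RADIUS = 15
DEFAULT_EROSION_RADIUS = 4
DEFAULT_DILATION_RADIUS = 2
MIN_NUCLEOPLASM_PIXELS = 25


@dataclass
class CompartmentMasks:
    """Nuclear, nucleoplasmic and envelope-annulus masks for one nucleus."""

    nuclear: np.ndarray
    nucleoplasm: np.ndarray
    envelope_region: np.ndarray
    erosion_radius: int
    dilation_radius: int
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (self.nuclear.shape == self.nucleoplasm.shape
                == self.envelope_region.shape):
            raise ValueError("compartment masks must share one shape")
        if (self.nucleoplasm & ~self.nuclear).any():
            raise ValueError("nucleoplasm mask must be contained in nuclear mask")
        if (self.nucleoplasm & self.envelope_region).any():
            raise ValueError("nucleoplasm and envelope masks must be disjoint")

    @property
    def dilated(self) -> np.ndarray:
        """Full measurement region: nucleoplasm plus envelope annulus."""
        return self.nucleoplasm | self.envelope_region


@dataclass
class DIMeasurement:
    cell_id: str
    timepoint: float  # minutes
    di: float
    method: str  # "mask" or "line_profile"
    di_normalized: float | None = None
    circularity: float | None = None  # nuclear-geometry covariate
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.di < 0:
            raise ValueError("DI is a ratio of nonnegative means; must be >= 0")


def subtract_background(image: np.ndarray, radius: int = DEFAULT_ROLLING_BALL_RADIUS
                        ) -> np.ndarray:
    """Rolling-ball background subtraction, clipped at zero.

    A ball of the given radius rolled under the intensity surface
    estimates the smooth background; structures narrower than the ball
    survive subtraction.
    """
    image = np.asarray(image, dtype=float)
    if radius < 1:
        raise ValueError("rolling-ball radius must be >= 1")
    if radius > min(image.shape):
        raise ValueError(
            f"rolling-ball radius {radius} exceeds image extent {image.shape}"
        )
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    background = restoration.rolling_ball(image, radius=radius)
    return np.clip(image - background, 0.0, None)


def select_mid_slice(zstack: np.ndarray) -> int:
    """Index of the z-slice through the middle of the nucleus.

    The middle slice is where the histone-channel nuclear cross-section
    is largest (the equator of the nucleus).  A single global Otsu
    threshold over the stack defines "nuclear" pixels; ties break toward
    the lower index.

    Parameters
    ----------
    zstack : (Z, Y, X) histone-channel intensities, background subtracted.
    """
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("expected a (Z, Y, X) stack with >= 1 slice")
    if zstack.shape[0] == 1:
        return 0
    if zstack.max() <= zstack.min():
        raise ValueError("no nucleus detected: stack has no contrast")
    thresh = threshold_otsu(zstack)
    areas = (zstack > thresh).sum(axis=(1, 2))
    if areas.max() == 0:
        raise ValueError("no nucleus detected in any z-slice")
    return int(np.argmax(areas))  # argmax returns the first (lowest) maximum


def make_nuclear_mask(histone_slice: np.ndarray,
                      window: tuple[slice, slice] | None = None) -> np.ndarray:
    """Nuclear mask from a background-subtracted histone slice.

    Otsu threshold, hole filling, then the largest connected component
    (restricted to ``window`` when cropping a multi-cell field).
    """
    img = np.asarray(histone_slice, dtype=float)
    if img.max() <= img.min():
        raise ValueError("cannot segment nucleus: slice is constant "
                         f"(min=max={img.max():g})")
    mask = img > threshold_otsu(img)
    mask = ndimage.binary_fill_holes(mask)
    if window is not None:
        selector = np.zeros_like(mask)
        selector[window] = True
        seed_region = mask & selector
    else:
        seed_region = mask
    labels = measure.label(mask)
    candidate_labels = np.unique(labels[seed_region & (labels > 0)])
    if len(candidate_labels) == 0:
        raise ValueError("empty nuclear mask after thresholding")
    sizes = {lab: (labels == lab).sum() for lab in candidate_labels}
    best = max(sizes, key=sizes.get)
    return labels == best


def make_compartment_masks(
    nuclear: np.ndarray,
    erosion_radius: int = DEFAULT_EROSION_RADIUS,
    dilation_radius: int = DEFAULT_DILATION_RADIUS,
) -> CompartmentMasks:
    """Erode the nuclear mask for the nucleoplasm, dilate it for the
    envelope annulus (dilated minus nucleoplasm)."""
    nuclear = np.asarray(nuclear, dtype=bool)
    if not nuclear.any():
        raise ValueError("nuclear mask is empty")
    qc: set[str] = set()
    if erosion_radius > 0:
        nucleoplasm = morphology.erosion(
            nuclear, morphology.disk(erosion_radius)).astype(bool)
    else:
        nucleoplasm = nuclear.copy()
    if not nucleoplasm.any():
        raise ValueError(
            f"erosion radius {erosion_radius} annihilated the nuclear mask")
    if nucleoplasm.sum() < MIN_NUCLEOPLASM_PIXELS:
        qc.add("small_nucleoplasm")
    if dilation_radius > 0:
        dilated = morphology.dilation(
            nuclear, morphology.disk(dilation_radius)).astype(bool)
    else:
        dilated = nuclear.copy()
    envelope = dilated & ~nucleoplasm
    if not envelope.any():
        raise ValueError("envelope region is empty "
                         "(erosion and dilation radii both zero?)")
    return CompartmentMasks(nuclear, nucleoplasm, envelope,
                            erosion_radius, dilation_radius, qc)


def mask_circularity(mask: np.ndarray) -> float:
    """Circularity 4*pi*A/P^2 of a boolean mask (1 for a perfect disk)."""
    area = mask.sum()
    perim = measure.perimeter(mask)
    if perim == 0:
        return float("nan")
    return float(4 * np.pi * area / perim**2)


def compute_di_mask(
    nup_slice: np.ndarray,
    masks: CompartmentMasks,
    cell_id: str = "",
    timepoint: float = 0.0,
    total_region: str = "dilated",
) -> DIMeasurement:
    """Detachment index from compartment masks.

    The envelope mean is derived by subtracting the summed nucleoplasmic
    signal from the summed total nuclear signal and dividing by the
    corresponding area; DI = nucleoplasmic mean / envelope mean.

    ``total_region`` selects what counts as "total nuclear": the dilated
    region (default; the reading under which total minus nucleoplasm is
    the envelope annulus) or the original nuclear mask (sensitivity
    variant).
    """
    img = np.asarray(nup_slice, dtype=float)
    if np.isnan(img[masks.dilated]).any():
        raise ValueError("NaN pixels inside the measurement region")
    img = np.clip(img, 0.0, None)
    if total_region == "dilated":
        total_mask = masks.dilated
    elif total_region == "nuclear":
        total_mask = masks.nuclear
    else:
        raise ValueError("total_region must be 'dilated' or 'nuclear'")
    np_sum = img[masks.nucleoplasm].sum()
    np_area = int(masks.nucleoplasm.sum())
    tot_sum = img[total_mask].sum()
    tot_area = int(total_mask.sum())
    env_area = tot_area - np_area
    if env_area <= 0:
        raise ValueError("envelope area is zero under the chosen total region")
    env_mean = (tot_sum - np_sum) / env_area
    if env_mean <= 0:
        raise ValueError("envelope mean intensity <= 0; DI undefined")
    di = (np_sum / np_area) / env_mean
    return DIMeasurement(
        cell_id=cell_id,
        timepoint=timepoint,
        di=float(di),
        method="mask",
        circularity=mask_circularity(masks.nuclear),
        qc_flags=set(masks.qc_flags),
    )


def normalize_di(
    measurements: list[DIMeasurement],
    reference: list[DIMeasurement] | None = None,
    reference_mean: float | None = None,
) -> list[DIMeasurement]:
    """Normalize DI values to the mean DI of a reference group.

    The reference is either an explicit list of measurements (e.g. the
    pre-anaphase timepoint of a control nucleoporin) or a precomputed
    mean.  After normalization the reference group's mean normalized DI
    is exactly 1.
    """
    if reference_mean is None:
        if not reference:
            raise ValueError("reference group is empty")
        reference_mean = float(np.mean([m.di for m in reference]))
    if reference_mean <= 0:
        raise ValueError("reference mean DI must be positive")
    out = []
    for m in measurements:
        out.append(
            DIMeasurement(
                cell_id=m.cell_id,
                timepoint=m.timepoint,
                di=m.di,
                method=m.method,
                di_normalized=m.di / reference_mean,
                circularity=m.circularity,
                qc_flags=set(m.qc_flags),
            )
        )
    return out
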