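"""Line-profile detachment-index method.

Used where histone-based masking fails (mitosis, fission yeast): a
five-pixel-wide intensity profile is drawn across the nucleus, the two
nuclear-envelope crossings appear as peaks, and DI is the mean of the
middle 50% of the inter-peak span (the nucleoplasm, clear of the peak
tails) divided by the mean of the two peak heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks, peak_prominences

from .imaging_quant import DIMeasurement

__all__ = [
    "LineProfile",
    "PeakPair",
    "PeakDetectionError",
    "extract_profile",
    "find_ne_peaks",
    "compute_di_profile",
    "minmax_normalize",
    "profiles_to_csv",
]

DEFAULT_WIDTH = 5
DEFAULT_PROMINENCE_FRACTION = 0.10
MIN_PROFILE_LENGTH = 7  # two peaks plus an interior window


class PeakDetectionError(ValueError):
    """Fewer than two envelope peaks found; carries the candidate list."""

    def __init__(self, message: str, candidates: list[int]):
        super().__init__(message)
        self.candidates = candidates


@dataclass
class LineProfile:
    positions: np.ndarray  # px along the line, strictly increasing
    intensities: np.ndarray  # a.u., averaged over the line width
    width: int = DEFAULT_WIDTH
    cell_id: str = ""
    timepoint: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities must have equal length")
        if len(self.positions) < MIN_PROFILE_LENGTH:
            raise ValueError(
                f"profile needs >= {MIN_PROFILE_LENGTH} samples, "
                f"got {len(self.positions)}")
        if not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class PeakPair:
    left_index: int
    right_index: int
    left_height: float
    right_height: float
    prominences: tuple[float, float] = (np.nan, np.nan)
    corrected: bool = False  # more than two candidates were pruned
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.left_index >= self.right_index:
            raise ValueError("left peak must precede right peak")


def extract_profile(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    width: int = DEFAULT_WIDTH,
    cell_id: str = "",
    timepoint: float = 0.0,
) -> LineProfile:
    """Sample intensities along a line, averaging over ``width``
    perpendicular offsets with bilinear interpolation.

    Endpoints are (y, x) pixel coordinates; samples are spaced one pixel
    apart along the line.
    """
    image = np.asarray(image, dtype=float)
    if width < 1 or width % 2 == 0:
        raise ValueError("line width must be a positive odd integer")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    length = float(np.hypot(*(end - start)))
    if length == 0:
        raise ValueError("profile endpoints coincide")
    for pt in (start, end):
        if not (0 <= pt[0] <= image.shape[0] - 1
                and 0 <= pt[1] <= image.shape[1] - 1):
            raise ValueError(f"endpoint {tuple(pt)} outside image")
    n = int(np.floor(length)) + 1
    ts = np.linspace(0.0, length, n)
    direction = (end - start) / length
    normal = np.array([-direction[1], direction[0]])
    offsets = np.arange(width) - (width - 1) / 2
    vals = np.zeros(n)
    for off in offsets:
        pts = start[None, :] + ts[:, None] * direction[None, :] + off * normal[None, :]
        vals += ndimage.map_coordinates(image, pts.T, order=1, mode="nearest")
    vals /= width
    return LineProfile(ts, vals, width=width, cell_id=cell_id, timepoint=timepoint)


def find_ne_peaks(
    profile: LineProfile,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> PeakPair:
    """Detect the two nuclear-envelope peaks of a profile.

    Local maxima with prominence above ``prominence_fraction`` of the
    profile's dynamic range are candidates.  More than two candidates are
    pruned to the two most prominent with a QC flag — an automated
    stand-in for manual correction of misidentified peaks; fewer than two
    raises :class:`PeakDetectionError`.
    """
    y = profile.intensities
    dynamic_range = float(y.max() - y.min())
    if dynamic_range <= 0:
        raise PeakDetectionError("flat profile: no peaks", [])
    floor = prominence_fraction * dynamic_range
    idx, props = find_peaks(y, prominence=floor)
    if len(idx) < 2:
        raise PeakDetectionError(
            f"found {len(idx)} envelope peak(s), need 2", list(idx))
    qc: set[str] = set()
    corrected = False
    if len(idx) > 2:
        order = np.argsort(props["prominences"])[::-1][:2]
        keep = np.sort(idx[order])
        proms = peak_prominences(y, keep)[0]
        qc.add("extra_peaks_pruned")
        corrected = True
    else:
        keep = idx
        proms = props["prominences"]
    li, ri = int(keep[0]), int(keep[1])
    return PeakPair(
        left_index=li,
        right_index=ri,
        left_height=float(y[li]),
        right_height=float(y[ri]),
        prominences=(float(proms[0]), float(proms[1])),
        corrected=corrected,
        qc_flags=qc,
    )


def compute_di_profile(profile: LineProfile, peaks: PeakPair,
                       cell_id: str | None = None) -> DIMeasurement:
    """DI from a profile and its envelope peak pair.

    The envelope intensity is the mean of the two peak heights; the
    nucleoplasmic intensity is the mean over the middle 50% of the
    inter-peak span, which keeps clear of the peak tails.
    """
    ne = (peaks.left_height + peaks.right_height) / 2.0
    if ne <= 0:
        raise ValueError("mean envelope peak height <= 0; DI undefined")
    pos = profile.positions
    left, right = pos[peaks.left_index], pos[peaks.right_index]
    d = right - left
    lo, hi = left + 0.25 * d, right - 0.25 * d
    window = (pos >= lo) & (pos <= hi)
    if not window.any():
        raise ValueError("middle-50% window contains no samples")
    nucleoplasm = float(profile.intensities[window].mean())
    return DIMeasurement(
        cell_id=cell_id if cell_id is not None else profile.cell_id,
        timepoint=profile.timepoint,
        di=nucleoplasm / ne,
        method="line_profile",
        qc_flags=set(peaks.qc_flags),
    )


def profiles_to_csv(profiles: list[LineProfile], path) -> None:
    """Export profiles as long-format CSV (cell_id, timepoint, position,
    intensity), the layout used for overlaying per-cell profiles."""
    import pandas as pd

    rows = [
        dict(cell_id=p.cell_id, timepoint=p.timepoint, position=pos,
             intensity=val)
        for p in profiles
        for pos, val in zip(p.positions, p.intensities)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def minmax_normalize(profile: LineProfile) -> LineProfile:
    """Map intensities to [0, 1] via (x - min) / (max - min)."""
    y = profile.intensities
    lo, hi = float(y.min()), float(y.max())
    if hi <= lo:
        raise ValueError("cannot min-max normalize a constant profile")
    return LineProfile(
        positions=profile.positions.copy(),
        intensities=(y - lo) / (hi - lo),
        width=profile.width,
        cell_id=profile.cell_id,
        timepoint=profile.timepoint,
    )
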